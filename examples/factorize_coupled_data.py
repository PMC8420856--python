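"""Factorize a coupled serology dataset and inspect the components.

Builds a cohort-shaped synthetic dataset (181 subjects x 22 receptors x 39
antigens plus a 181 x 25 glycan matrix observed for half the subjects,
~40% of tensor entries missing), balances the matrix to equal variance,
fits a six-component coupled factorization, and standardizes the factors
for display.
"""

import numpy as np

import serotensor as st

d, truth, _ = st.hiv_shaped(seed=3)
d = st.scale_matrix_variance(d, ratio=1.0)

res = st.fit_cmtf(d, st.FitConfig(R=6, n_starts=4, seed=0))
overall, tensor_r2x, matrix_r2x = st.compute_r2x(d, res.factors)
print(f"converged: {res.converged} after {res.iterations_run} sweeps")
print(f"R2X overall {overall:.3f}  tensor {tensor_r2x:.3f}  matrix {matrix_r2x:.3f}")
# R2X is the fraction of observed variance the 6 components reconstruct.

f = st.standardize_components(res.factors)
print("per-component display scaling factors:", np.round(f.scale, 1))
# Components are ordered by explained variance; subject/receptor/antigen
# columns lie in [-1, 1] and `scale` records the removed magnitude.

size = st.factorization_size(f)
total = np.prod(d.tensor.shape) + np.prod(d.matrix.shape)
print(f"stored values: {size} of {total} original positions "
      f"({100 * size / total:.1f}%)")
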