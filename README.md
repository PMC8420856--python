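# serotensor

Coupled matrix–tensor factorization (CMTF) for systems serology profiling.

Systems serology panels measure antigen-specific antibody features in a
consistent multimodal layout: antibodies are captured on a panel of
antigens and probed against a panel of Fc receptors and detection
reagents, giving a **subject × receptor × antigen** tensor **X**, while
antigen-generic measurements such as Fc glycan composition form a
**subject × glycan** matrix **Y** sharing the subject mode.  Not every
receptor–antigen pair is measured, so the tensor has structurally missing
entries.

`serotensor` reduces both blocks jointly into R interpretable components,

```
X ≈ Σ_r  a_r ∘ b_r ∘ c_r          Y ≈ Σ_r  a_r ∘ d_r
```

(`∘` the vector outer product), fit by alternating least squares in which
the shared subject factors **A** are solved against the column-concatenation
of the unfolded tensor and the matrix, and every update uses **censored
least squares** — the equations for unobserved entries are simply dropped.
Fidelity is measured as R2X, the fraction of observed variance explained
(variance = sum of squared entries, missing values ignored); Q2X is the
same statistic restricted to deliberately held-out entries and measures
imputation.  On top of the factors, the package provides nested
cross-validated elastic-net regression and penalized logistic
classification of subject outcomes, bootstrap weight-stability analysis,
and 4-parameter logistic summaries of temporal component trajectories.
Without a coupled matrix the same engine performs plain CP decomposition.

No external cohort data are required: `serotensor.synthetic` generates
coupled datasets with known ground-truth factors, configurable noise,
missingness and outcome structure, including presets shaped like the two
cohorts the method is designed around (a 181 × 22 × 39 tensor + 181 × 25
matrix, and a complete 438 × 6 × 11 longitudinal tensor).

## Worked example

```python
import serotensor as st

d, truth, _ = st.hiv_shaped(seed=3)            # synthetic cohort-shaped data
d = st.scale_matrix_variance(d, ratio=1.0)     # balance matrix vs tensor variance
res = st.fit_cmtf(d, st.FitConfig(R=6, n_starts=4, seed=0))
overall, tensor_r2x, matrix_r2x = st.compute_r2x(d, res.factors)
f = st.standardize_components(res.factors)
print(overall, st.factorization_size(f))
```

Running `examples/factorize_coupled_data.py` (this code plus reporting)
prints:

```
converged: True after 50 sweeps
R2X overall 1.000  tensor 1.000  matrix 1.000
per-component display scaling factors: [13.8 14.6 13.7 13.9 11.9 11. ]
stored values: 1602 of 159823 original positions (1.0%)
```

The six components reconstruct essentially all observed variance of this
noiseless rank-6 dataset while storing 1,602 numbers in place of 159,823
positions; the scaling factors record each component's magnitude after its
subject/receptor/antigen loadings are normalized to [−1, 1].  The other
scripts in `examples/` walk through the imputation benchmark
(chord/entry hold-out Q2X vs flattened-PCA and mean baselines), outcome
prediction with shuffled-label controls and bootstrap stability, and the
two-component longitudinal analysis with sigmoidal trajectory fits.

## Layout

- `serotensor.datamodel` — masked tensor/matrix containers, Khatri–Rao,
  unfolding, reconstruction, delimited-table readers and writers
- `serotensor.preprocess` — clip → log → per-measurement centering and
  tensor/matrix variance balancing
- `serotensor.cmtf` — censored least squares, SVD initialization, coupled
  ALS, R2X, component standardization
- `serotensor.evaluation` — Q2X, chord/entry imputation benchmarks, EM-PCA
  baseline, factorization-size vs error curves
- `serotensor.prediction` — elastic net / logistic regression with nested
  10-fold CV, bootstrap weight stability, sigmoidal temporal fits
- `serotensor.synthetic` — ground-truth data generator and cohort-shaped
  presets

See `docs/methods.md` for the model, algorithmic choices and limitations.
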