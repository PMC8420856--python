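import numpy as np
import pytest

from serotensor import (CoupledDataset, CoupledMatrix, MaskedTensor, SimSpec,
                        generate_coupled)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_coupled():
    """Noiseless rank-2 coupled dataset, complete, small enough for brute force."""
    d, truth, _ = generate_coupled(SimSpec(
        n_subjects=25, n_receptors=5, n_antigens=6, n_glycans=7,
        R_true=2, seed=42))
    return d, truth


@pytest.fixture
def masked_coupled():
    """Noiseless rank-3 coupled dataset with 30% entries missing."""
    d, truth, _ = generate_coupled(SimSpec(
        n_subjects=40, n_receptors=6, n_antigens=8, n_glycans=9,
        R_true=3, missing_fraction=0.3, seed=7))
    return d, truth


def make_dataset(values, mask=None, matrix=None, matrix_mask=None):
    """Hand-build a CoupledDataset from raw arrays with generated labels."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    n, j, k = values.shape
    tensor = MaskedTensor(values, mask,
                          [f"S{i}" for i in range(n)],
                          [f"R{x}" for x in range(j)],
                          [f"A{x}" for x in range(k)])
    cm = None
    if matrix is not None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix_mask is None:
            matrix_mask = np.ones(matrix.shape, dtype=bool)
        cm = CoupledMatrix(matrix, matrix_mask, [f"S{i}" for i in range(n)],
                           [f"G{x}" for x in range(matrix.shape[1])])
    return CoupledDataset(tensor, cm)
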