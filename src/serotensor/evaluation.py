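"""Reconstruction fidelity and imputation benchmarking.

Q2X is the explained-variance statistic restricted to deliberately held-out
entries: it measures how faithfully a factorization imputes data it never
saw.  Two hold-out schemes are supported, mirroring the two distinct
difficulty levels of structural imputation:

* ``chord`` — entire receptor–antigen pairs masked across all subjects
  (whole tensor fibers; a flattened-matrix method cannot impute these at
  all, since it amounts to deleting whole columns), and
* ``entry`` — individual observed values masked at random.

The flattened-PCA baseline completes missing entries by an
expectation–maximization loop: fill with the current rank-R SVD
reconstruction, refit, repeat to convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cmtf import FitConfig, compute_r2x, fit_cmtf
from .datamodel import CoupledDataset, KruskalFactors, reconstruct

logger = logging.getLogger(__name__)

__all__ = ["ImputationScheme", "q2x", "run_imputation_benchmark",
           "summarize_benchmark", "pca_em_impute", "size_vs_error_curves",
           "flatten_dataset"]


@dataclass
class ImputationScheme:
    """Hold-out design: ``kind`` is "chord" (receptor–antigen pairs removed
    across all subjects) or "entry" (individual values); ``n_removed`` per
    trial (default 15); ``n_trials`` defaults to 20 for chord, 10 for entry."""

    kind: str = "chord"
    n_removed: int = 15
    n_trials: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("chord", "entry"):
            raise ValueError("kind must be 'chord' or 'entry'")
        if self.n_removed < 1:
            raise ValueError("n_removed must be >= 1")
        if self.n_trials is None:
            self.n_trials = 20 if self.kind == "chord" else 10


def q2x(d_true: CoupledDataset, f: KruskalFactors, heldout_mask: np.ndarray) -> float:
    """Explained variance on held-out tensor entries only:
    1 − ‖X_held − X̂_held‖²/‖X_held‖²."""
    heldout_mask = np.asarray(heldout_mask, dtype=bool)
    if not heldout_mask.any():
        raise ValueError("held-out set is empty")
    xhat, _ = reconstruct(f)
    x = d_true.tensor.values
    num = float(np.sum((x[heldout_mask] - xhat[heldout_mask]) ** 2))
    den = float(np.sum(x[heldout_mask] ** 2))
    if den == 0.0:
        raise ValueError("held-out values have zero variance")
    return 1.0 - num / den


def _sample_heldout(tensor_mask: np.ndarray, scheme: ImputationScheme,
                    rng: np.random.Generator) -> np.ndarray:
    """Boolean held-out mask over tensor positions, drawn from observed ones."""
    n, j, k = tensor_mask.shape
    held = np.zeros_like(tensor_mask)
    if scheme.kind == "chord":
        # universe: receptor-antigen pairs with at least one observation
        pair_obs = tensor_mask.any(axis=0)
        candidates = np.flatnonzero(pair_obs.ravel())
        if candidates.size < scheme.n_removed:
            raise ValueError("not enough observed receptor-antigen pairs to remove")
        chosen = rng.choice(candidates, size=scheme.n_removed, replace=False)
        jj, kk = np.unravel_index(chosen, (j, k))
        held[:, jj, kk] = tensor_mask[:, jj, kk]
    else:
        candidates = np.flatnonzero(tensor_mask.ravel())
        if candidates.size < scheme.n_removed:
            raise ValueError("not enough observed entries to remove")
        chosen = rng.choice(candidates, size=scheme.n_removed, replace=False)
        held.ravel()[chosen] = True
    return held


def _mean_baseline(d: CoupledDataset, train_mask: np.ndarray, axis: int) -> np.ndarray:
    """Predict each entry by the observed mean along the receptor (axis=1) or
    antigen (axis=2) dimension."""
    x = np.where(train_mask, d.tensor.values, 0.0)
    cnt = train_mask.sum(axis=axis, keepdims=True)
    means = np.divide(x.sum(axis=axis, keepdims=True), np.maximum(cnt, 1))
    return np.broadcast_to(means, d.tensor.shape).copy()


def run_imputation_benchmark(d: CoupledDataset, scheme: ImputationScheme,
                             R_values: list[int],
                             fit_kwargs: dict | None = None) -> pd.DataFrame:
    """Repeatedly hold out data, refit, and score Q2X on the removals.

    Per trial: sample removals (without replacement) from observed tensor
    positions, mask them, fit the coupled factorization at each R, and
    report Q2X on the removed entries.  Chord trials also score the two
    naive baselines (mean along the receptor / antigen dimension); entry
    trials also score flattened EM-PCA imputation.  Returns a long table
    (method, R, trial, q2x, n_masked) plus trials aggregate via
    ``df.groupby([...])``.
    """
    fit_kwargs = dict(fit_kwargs or {})
    rng_root = np.random.default_rng(scheme.seed)
    rows = []
    for trial in range(scheme.n_trials):
        rng = np.random.default_rng(rng_root.integers(2**31))
        for _attempt in range(20):
            held = _sample_heldout(d.tensor.mask, scheme, rng)
            train_mask = d.tensor.mask & ~held
            # a removal must not leave any mode slice fully unobserved
            ok = (train_mask.any(axis=(1, 2)).all()
                  and train_mask.any(axis=(0, 2)).all()
                  and train_mask.any(axis=(0, 1)).all())
            if ok:
                break
            logger.info("trial %d: resampling removals (empty mode slice)", trial)
        d_train = d.copy()
        d_train.tensor.mask = train_mask
        n_masked = int(held.sum())

        for R in R_values:
            res = fit_cmtf(d_train, FitConfig(R=R, **fit_kwargs))
            rows.append(("cmtf", R, trial, q2x(d, res.factors, held), n_masked))
            if scheme.kind == "entry":
                from .datamodel import fold
                flat, fmask = flatten_dataset(d_train)
                completed, _ = pca_em_impute(flat, fmask, R)
                n, j, k = d.tensor.shape
                xhat = fold(completed[:, :j * k], 0, (n, j, k))
                num = float(np.sum((d.tensor.values[held] - xhat[held]) ** 2))
                den = float(np.sum(d.tensor.values[held] ** 2))
                rows.append(("pca", R, trial, 1.0 - num / den, n_masked))
        if scheme.kind == "chord":
            for method, axis in (("receptor_mean", 1), ("antigen_mean", 2)):
                pred = _mean_baseline(d, train_mask, axis)
                num = float(np.sum((d.tensor.values[held] - pred[held]) ** 2))
                den = float(np.sum(d.tensor.values[held] ** 2))
                for R in R_values:
                    rows.append((method, R, trial, 1.0 - num / den, n_masked))
    return pd.DataFrame(rows, columns=["method", "R", "trial", "q2x", "n_masked"])


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± standard error of Q2X per (method, R) across trials."""
    g = table.groupby(["method", "R"])["q2x"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "q2x_mean", "sem": "q2x_sem", "count": "n_trials"})


# ---------------------------------------------------------------------------
# EM-PCA baseline
# ---------------------------------------------------------------------------

def pca_em_impute(M: np.ndarray, mask: np.ndarray, R: int,
                  max_iters: int = 100, tol: float = 1e-5
                  ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Complete a masked matrix by iterated truncated-SVD refitting.

    Missing entries are filled with the current rank-R reconstruction and
    the SVD refit, until the change in the imputed-value sum of squares
    falls below ``tol`` or 100 iterations.  On complete data this is a
    single SVD pass.  Entirely-missing columns are removed before fitting
    and restored as zeros.  Returns the completed matrix and the factor
    pair (scores U·S, loadings Vᵀ rows).
    """
    M = np.asarray(M, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != M.shape:
        raise ValueError("mask shape must match matrix shape")
    if R > min(M.shape):
        raise ValueError(f"R={R} exceeds min(shape)={min(M.shape)}")

    keep = mask.any(axis=0)
    if not keep.all():
        logger.warning("pca_em_impute: %d entirely-missing column(s) removed",
                       int((~keep).sum()))
    sub = np.where(mask, M, 0.0)[:, keep]
    msub = mask[:, keep]

    if R == 0:
        # rank-0 model: the reconstruction is the empty sum
        return np.zeros_like(M), (np.zeros((M.shape[0], 0)), np.zeros((0, M.shape[1])))

    filled = sub.copy()  # missing start at zero
    prev_ssq = 0.0
    for _ in range(max_iters):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :R] * s[:R]) @ Vt[:R]
        if msub.all():
            filled = recon
            break
        ssq = float(np.sum(recon[~msub] ** 2))
        filled = np.where(msub, sub, recon)
        if abs(ssq - prev_ssq) < tol:
            break
        prev_ssq = ssq
    else:
        logger.info("pca_em_impute: reached iteration cap without convergence")

    U, s, Vt = np.linalg.svd(filled, full_matrices=False)
    recon = (U[:, :R] * s[:R]) @ Vt[:R]
    completed = np.zeros_like(M)
    completed[:, keep] = recon
    scores = np.zeros((M.shape[0], R))
    loadings = np.zeros((R, M.shape[1]))
    scores[:] = U[:, :R] * s[:R]
    loadings[:, keep] = Vt[:R]
    return completed, (scores, loadings)


# ---------------------------------------------------------------------------
# Size-vs-error comparison
# ---------------------------------------------------------------------------

def flatten_dataset(d: CoupledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Subjects × (receptor·antigen [+ glycan]) flattened matrix with mask.

    Tensor fibers are laid out in the mode-0 unfolding order, so the first
    J·K columns invert back via ``reshape(n, J, K, order='F')``.
    """
    from .datamodel import unfold
    flat, fmask = unfold(d.tensor.values, 0, d.tensor.mask)
    flat = np.where(fmask, flat, 0.0)
    if d.matrix is not None:
        flat = np.concatenate([flat, d.matrix.observed_values()], axis=1)
        fmask = np.concatenate([fmask, d.matrix.mask], axis=1)
    return flat, fmask


def size_vs_error_curves(d: CoupledDataset, R_values: list[int],
                         fit_kwargs: dict | None = None) -> pd.DataFrame:
    """Factorization size vs normalized unexplained variance (1 − R2X) for
    the coupled factorization and flattened PCA, per component count."""
    fit_kwargs = dict(fit_kwargs or {})
    n, j, k = d.tensor.shape
    g = 0 if d.matrix is None else d.matrix.shape[1]
    n_flat = j * k + g
    flat, fmask = flatten_dataset(d)
    vtotal = float(np.sum(np.where(fmask, flat, 0.0) ** 2))
    rows = []
    for R in R_values:
        if R == 0:
            rows.append(("cmtf", 0, 0, 1.0))
            rows.append(("pca", 0, 0, 1.0))
            continue
        res = fit_cmtf(d, FitConfig(R=R, **fit_kwargs))
        cmtf_size = (n + j + k + g) * R
        rows.append(("cmtf", R, cmtf_size, 1.0 - res.r2x))
        completed, _ = pca_em_impute(flat, fmask, R)
        resid = float(np.sum(np.where(fmask, flat - completed, 0.0) ** 2))
        rows.append(("pca", R, (n + n_flat) * R, resid / vtotal))
    return pd.DataFrame(rows, columns=["method", "R", "factorization_size",
                                       "unexplained_variance"])
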