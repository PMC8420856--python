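"""Coupled matrix–tensor factorization by censored alternating least squares.

The model approximates the (subject × receptor × antigen) tensor X and the
(subject × glycan) matrix Y jointly as sums of R rank-1 terms sharing the
subject factors::

    X ≈ Σ_r a_r ∘ b_r ∘ c_r        Y ≈ Σ_r a_r ∘ d_r

Each ALS sweep solves four linear least-squares problems — the subject
update against the column-concatenation of the unfolded tensor and the
matrix, which is what couples the two blocks::

    min_A ‖[X₁ Y] − A [(C⊙B)ᵀ Dᵀ]‖      min_B ‖X₂ − B (C⊙A)ᵀ‖
    min_C ‖X₃ − C (B⊙A)ᵀ‖               min_D ‖Y − A Dᵀ‖

Missing values are handled by censored solving: for every target column the
equations (rows) corresponding to unobserved entries are dropped.  Each
update is then an exact coordinate minimization of the observed-entry
objective, so the R2X trace is monotone non-decreasing.

With no coupled matrix the same engine performs plain CP decomposition of
the tensor — a first-class mode, used for datasets with no antigen-generic
measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (CoupledDataset, KruskalFactors, khatri_rao,
                        reconstruct, unfold)

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitResult", "censored_lstsq", "initialize_factors",
           "fit_cmtf", "compute_r2x", "standardize_components",
           "factor_congruence"]


@dataclass
class FitConfig:
    """ALS control parameters.

    Up to ``max_iters`` sweeps (default 2000); R2X is checked every
    ``check_every`` sweeps (default 2) and the fit stops early once the
    absolute change between checks falls below ``tol`` (default 1e-5).
    """

    R: int = 6
    max_iters: int = 2000
    tol: float = 1e-5
    check_every: int = 2
    seed: int = 0
    n_starts: int = 1

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    factors: KruskalFactors
    r2x_trace: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = False
    iterations_run: int = 0

    @property
    def r2x(self) -> float:
        return self.r2x_trace[-1][1]


# ---------------------------------------------------------------------------
# Censored least squares
# ---------------------------------------------------------------------------

def censored_lstsq(B: np.ndarray, X: np.ndarray, mask: np.ndarray | None = None
                   ) -> np.ndarray:
    """Solve min_w ‖B w − x_j‖ per target column j, using only observed rows.

    ``B`` is the n×R design; ``X`` is n×m with an optional boolean ``mask``
    of the same shape (True = observed).  Returns the m×R solution matrix.
    Columns with no observed rows get a zero solution; rank-deficient
    observed designs get the minimum-norm solution.

    Solved via per-column normal equations, batched: with R small the
    conditioning penalty is negligible and the Gram systems are tiny.
    ``pinv(BᵀMB)·BᵀMx`` equals ``pinv(B_obs)·x_obs`` since the normal system
    is always consistent.
    """
    B = np.asarray(B, dtype=float)
    X = np.asarray(X, dtype=float)
    n, r = B.shape
    if X.shape[0] != n:
        raise ValueError("design and target row counts differ")
    m = X.shape[1]

    if mask is None or mask.all():
        sol, *_ = np.linalg.lstsq(B, X, rcond=None)
        return sol.T

    M = mask.astype(float)
    Xf = np.where(mask, X, 0.0)
    # G[j] = B_obs(j)ᵀ B_obs(j);  c[j] = B_obs(j)ᵀ x_obs(j)
    G = np.einsum("ir,ij,is->jrs", B, M, B, optimize=True)
    c = B.T @ Xf  # r×m

    out = np.empty((m, r))
    n_obs = mask.sum(axis=0)
    empty = n_obs == 0
    if empty.any():
        logger.warning("censored_lstsq: %d target column(s) with zero observed rows",
                       int(empty.sum()))
        out[empty] = 0.0
    todo = np.flatnonzero(~empty)
    if todo.size:
        try:
            out[todo] = np.linalg.solve(G[todo], c.T[todo, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            for j in todo:
                out[j] = np.linalg.lstsq(G[j], c[:, j], rcond=None)[0]
    return out


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _fix_svd_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each column positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def _rank1_impute(flat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill missing entries of a matrix by a one-component PCA model."""
    from .evaluation import pca_em_impute  # local import avoids a cycle
    completed, _ = pca_em_impute(flat, mask, 1)
    return completed


def _mode_svd(flat: np.ndarray, mask: np.ndarray, R: int) -> np.ndarray:
    """Leading-R left singular vectors of an unfolding, missing values imputed
    by a one-component PCA model and all-missing columns removed first."""
    keep = mask.any(axis=0)
    if not keep.any():
        raise ValueError("cannot initialize from an all-missing unfolding")
    sub = flat[:, keep]
    msub = mask[:, keep]
    if not msub.all():
        sub = _rank1_impute(sub, msub)
    U, _, _ = np.linalg.svd(sub, full_matrices=False)
    U = _fix_svd_signs(U)
    k = min(R, U.shape[1])
    out = np.zeros((flat.shape[0], R))
    out[:, :k] = U[:, :k]
    return out


def initialize_factors(d: CoupledDataset, cfg: FitConfig) -> KruskalFactors:
    """SVD initialization of all modes from the (imputed) unfoldings.

    The subject mode is initialized from the unfolding of the tensor
    concatenated column-wise with the matrix, mirroring the coupled subject
    update.  If R exceeds a mode size the extra columns are zero-padded.
    """
    t = d.tensor
    if not t.mask.any() and (d.matrix is None or not d.matrix.mask.any()):
        raise ValueError("dataset is entirely missing")
    x0, m0 = unfold(t.values, 0, t.mask)
    if d.matrix is not None:
        x0 = np.concatenate([x0, d.matrix.values], axis=1)
        m0 = np.concatenate([m0, d.matrix.mask], axis=1)
    A = _mode_svd(np.where(m0, x0, 0.0), m0, cfg.R)
    x1_, m1_ = unfold(t.values, 1, t.mask)
    B = _mode_svd(np.where(m1_, x1_, 0.0), m1_, cfg.R)
    x2_, m2_ = unfold(t.values, 2, t.mask)
    C = _mode_svd(np.where(m2_, x2_, 0.0), m2_, cfg.R)
    D = None
    if d.matrix is not None:
        D = _mode_svd(np.where(d.matrix.mask, d.matrix.values, 0.0).T,
                      d.matrix.mask.T, cfg.R)
    return KruskalFactors(A, B, C, D)


# ---------------------------------------------------------------------------
# R2X
# ---------------------------------------------------------------------------

def compute_r2x(d: CoupledDataset, f: KruskalFactors
                ) -> tuple[float, float, float | None]:
    """Fraction of observed variance explained, overall and per block.

    vtotal = ‖X‖² + ‖Y‖² over observed entries; R2X = 1 − (residual tensor
    variance + residual matrix variance)/vtotal.  Returns
    ``(overall, tensor_r2x, matrix_r2x or None)``.
    """
    xhat, yhat = reconstruct(f)
    t = d.tensor
    vx = float(np.sum(t.observed_values() ** 2))
    res_x = float(np.sum(np.where(t.mask, t.values - xhat, 0.0) ** 2))
    vy = res_y = 0.0
    if d.matrix is not None:
        m = d.matrix
        vy = float(np.sum(m.observed_values() ** 2))
        if yhat is None:
            yhat = np.zeros(m.shape)
        res_y = float(np.sum(np.where(m.mask, m.values - yhat, 0.0) ** 2))
    vtotal = vx + vy
    if vtotal == 0.0:
        raise ValueError("dataset has zero observed variance")
    overall = 1.0 - (res_x + res_y) / vtotal
    tensor_r2x = 1.0 - res_x / vx if vx > 0 else float("nan")
    matrix_r2x = (1.0 - res_y / vy) if d.matrix is not None and vy > 0 else None
    return overall, tensor_r2x, matrix_r2x


# ---------------------------------------------------------------------------
# The ALS loop
# ---------------------------------------------------------------------------

def fit_cmtf(d: CoupledDataset, cfg: FitConfig) -> FitResult:
    """Fit the coupled decomposition by censored ALS.

    With ``n_starts > 1`` the SVD-initialized fit is supplemented by
    seeded random initializations and the result with the highest final
    R2X is returned — ALS can stall in degenerate basins (two components
    collapsing onto one direction) on exactly-low-rank data with heavy
    missingness, and restarts escape them.  The default is the plain
    single SVD-initialized fit.

    Raises if R exceeds every mode size or if the factors diverge (NaN).
    """
    t = d.tensor
    sizes = list(t.shape) + ([d.matrix.shape[1]] if d.matrix is not None else [])
    if all(cfg.R > s for s in sizes):
        raise ValueError(f"R={cfg.R} exceeds every mode size {sizes}")

    if cfg.n_starts == 1:
        return _als(d, cfg, initialize_factors(d, cfg))

    rng = np.random.default_rng(cfg.seed)
    best: FitResult | None = None
    last_err: Exception | None = None
    for start in range(cfg.n_starts):
        try:
            if start == 0:
                f0 = initialize_factors(d, cfg)
            else:
                f0 = KruskalFactors(
                    rng.standard_normal((t.shape[0], cfg.R)),
                    rng.standard_normal((t.shape[1], cfg.R)),
                    rng.standard_normal((t.shape[2], cfg.R)),
                    None if d.matrix is None else
                    rng.standard_normal((d.matrix.shape[1], cfg.R)))
            res = _als(d, cfg, f0)
        except FloatingPointError as err:
            last_err = err
            continue
        if best is None or res.r2x > best.r2x:
            best = res
    if best is None:
        raise last_err if last_err is not None else RuntimeError("no fit succeeded")
    return best


def _als(d: CoupledDataset, cfg: FitConfig, f: KruskalFactors) -> FitResult:
    """One censored-ALS run from the given starting factors."""
    t = d.tensor
    A, B, C, D = f.A, f.B, f.C, f.D

    x1, m1 = unfold(t.values, 0, t.mask)
    x2, m2 = unfold(t.values, 1, t.mask)
    x3, m3 = unfold(t.values, 2, t.mask)
    x1 = np.where(m1, x1, 0.0)
    x2 = np.where(m2, x2, 0.0)
    x3 = np.where(m3, x3, 0.0)
    if d.matrix is not None:
        y = d.matrix.observed_values()
        my = d.matrix.mask
        targ_a = np.concatenate([x1, y], axis=1).T
        mask_a = np.concatenate([m1, my], axis=1).T
    else:
        targ_a, mask_a = x1.T, m1.T

    trace: list[tuple[int, float]] = []
    last = -np.inf
    converged = False
    it = 0
    for it in range(1, cfg.max_iters + 1):
        if d.matrix is not None:
            design_a = np.concatenate([khatri_rao([C, B]), D], axis=0)
        else:
            design_a = khatri_rao([C, B])
        A = censored_lstsq(design_a, targ_a, mask_a)
        B = censored_lstsq(khatri_rao([C, A]), x2.T, m2.T)
        C = censored_lstsq(khatri_rao([B, A]), x3.T, m3.T)
        if d.matrix is not None:
            D = censored_lstsq(A, y, my)
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))
                and np.all(np.isfinite(C))
                and (D is None or np.all(np.isfinite(D)))):
            raise FloatingPointError(f"factor divergence (NaN/inf) at iteration {it}")

        if it % cfg.check_every == 0 or it == cfg.max_iters:
            r2x, _, _ = compute_r2x(d, KruskalFactors(A, B, C, D))
            trace.append((it, r2x))
            if abs(r2x - last) < cfg.tol:
                converged = True
                break
            last = r2x

    factors = KruskalFactors(A, B, C, D)
    if not trace:
        trace.append((it, compute_r2x(d, factors)[0]))
    return FitResult(factors=factors, r2x_trace=trace,
                     converged=converged, iterations_run=it)


# ---------------------------------------------------------------------------
# Display standardization
# ---------------------------------------------------------------------------

def factor_congruence(truth: KruskalFactors, est: KruskalFactors) -> np.ndarray:
    """Per-component congruence between two factor sets, up to
    permutation/sign/scale.

    For each candidate pairing the score is the product over modes of the
    absolute cosine similarity of the factor columns; components are matched
    by maximizing total congruence (Hungarian assignment).  Returns the
    matched per-component scores (1.0 = perfect recovery)."""
    from scipy.optimize import linear_sum_assignment

    def cols(f):
        mats = [f.A, f.B, f.C] + ([f.D] if f.D is not None and est.D is not None
                                  and truth.D is not None else [])
        return mats

    score = np.ones((truth.R, est.R))
    for Mt, Me in zip(cols(truth), cols(est)):
        nt = Mt / np.maximum(np.linalg.norm(Mt, axis=0), 1e-300)
        ne = Me / np.maximum(np.linalg.norm(Me, axis=0), 1e-300)
        score *= np.abs(nt.T @ ne)
    rows, cols_ = linear_sum_assignment(-score)
    return score[rows, cols_]


def _component_variance(f: KruskalFactors, r: int) -> float:
    """Squared Frobenius norm of rank-1 term r summed over both blocks."""
    na = float(np.sum(f.A[:, r] ** 2))
    v = (f.scale[r] ** 2) * na * float(np.sum(f.B[:, r] ** 2)) * float(np.sum(f.C[:, r] ** 2))
    if f.D is not None:
        v += na * float(np.sum(f.D[:, r] ** 2))
    return v


def standardize_components(f: KruskalFactors) -> KruskalFactors:
    """Order, sign-fix and scale components for display.

    Components are sorted by descending explained variance; signs are
    flipped pairwise across two modes so receptor and antigen columns have
    non-negative mean; A, B, C columns are divided by their max-abs value
    with the removed tensor-block magnitude recorded in ``scale``.  Glycan
    factors are not normalized per component (their relative scale is
    informative); they absorb the subject-column scale so the matrix
    reconstruction A Dᵀ is unchanged.  Reconstruction is invariant
    throughout.
    """
    f = f.copy()
    order = np.argsort([-_component_variance(f, r) for r in range(f.R)],
                       kind="stable")
    f.A = f.A[:, order]
    f.B = f.B[:, order]
    f.C = f.C[:, order]
    if f.D is not None:
        f.D = f.D[:, order]
    f.scale = f.scale[order]

    for r in range(f.R):
        # flipping (A,B) then (A,C) keeps every tensor rank-1 term invariant;
        # D follows every A flip so the matrix block A Dᵀ is invariant too
        if np.mean(f.B[:, r]) < 0:
            f.B[:, r] *= -1
            f.A[:, r] *= -1
            if f.D is not None:
                f.D[:, r] *= -1
        if np.mean(f.C[:, r]) < 0:
            f.C[:, r] *= -1
            f.A[:, r] *= -1
            if f.D is not None:
                f.D[:, r] *= -1

        sa = float(np.max(np.abs(f.A[:, r])))
        sb = float(np.max(np.abs(f.B[:, r])))
        sc = float(np.max(np.abs(f.C[:, r])))
        if sa == 0 or sb == 0 or sc == 0:
            logger.warning("component %d has a zero factor column; not rescaled", r + 1)
            continue
        f.A[:, r] /= sa
        f.B[:, r] /= sb
        f.C[:, r] /= sc
        f.scale[r] *= sa * sb * sc
        if f.D is not None:
            f.D[:, r] *= sa  # keep Y = A Dᵀ exact
    return f
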