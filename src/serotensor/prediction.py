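"""Supervised layer on top of the subject factors.

Functional responses (ADCD, ADCC, ADNP, NK-cell activation markers) are
regressed on the per-subject component weights with an elastic net
(L1 fraction 0.8); binary subject classes (e.g. controller vs progressor)
use elastic-net-penalized logistic regression with the SAGA solver.  The
regularization strength is chosen by an inner 10-fold CV, and performance
is quantified on outer folds assigned independently of the inner ones — a
nested scheme, since sharing the fold structure between hyperparameter
selection and benchmarking consistently overfits.

Accuracy is the Pearson correlation of held-out predictions with truth for
continuous responses, and the fraction classified correctly for classes.
Weight stability is assessed by bootstrapping subjects with replacement.
Temporal trajectories of component weights are summarized by a 4-parameter
logistic curve y = A/[1 + exp(−k(x − x0))] + C.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr
from sklearn.linear_model import ElasticNetCV, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = ["SigmoidParams", "fit_response_model", "fit_class_model",
           "nested_cv", "bootstrap_weights", "fit_sigmoid", "roc_auc"]

L1_FRACTION = 0.8
N_ALPHAS = 50  # log-spaced regularization grid, auto-scaled from the data


def _standardize(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and variance-normalize columns; also return the scale so fitted
    weights can be reported on the original feature scale (comparable across
    bootstrap resamples)."""
    F = np.asarray(F, dtype=float)
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    return (F - mu) / sd, sd


def _inner_enet(seed: int) -> ElasticNetCV:
    return ElasticNetCV(l1_ratio=L1_FRACTION, alphas=N_ALPHAS, cv=KFold(
        n_splits=10, shuffle=True, random_state=seed), max_iter=20000)


def _inner_logistic(seed: int) -> LogisticRegressionCV:
    return LogisticRegressionCV(
        penalty="elasticnet", solver="saga", l1_ratios=[L1_FRACTION],
        Cs=N_ALPHAS, cv=StratifiedKFold(n_splits=10, shuffle=True,
                                        random_state=seed),
        max_iter=10000, tol=1e-3)


def fit_response_model(F: np.ndarray, y: np.ndarray, cv_seed: int = 0,
                       compute_cv: bool = True
                       ) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Elastic-net regression of a continuous response on subject factors.

    Subjects with a missing response are dropped.  Returns (full-data
    weights per component, held-out predictions under one nested 10-fold
    pass, Pearson-r accuracy).  ``compute_cv=False`` skips the outer CV and
    returns only the full-data weights (useful inside bootstraps).
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    F, y = F[ok], y[ok]
    if y.size < 20:
        raise ValueError("need at least 20 subjects with a non-missing response")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    Fs, fscale = _standardize(F)

    rng = np.random.default_rng(cv_seed)
    preds, r = None, float("nan")
    if compute_cv:
        preds = np.empty_like(y)
        outer = KFold(n_splits=10, shuffle=True, random_state=int(rng.integers(2**31)))
        for tr, te in outer.split(Fs):
            model = _inner_enet(int(rng.integers(2**31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Fs[tr], y[tr])
            preds[te] = model.predict(Fs[te])
        r = float(pearsonr(y, preds).statistic)

    full = _inner_enet(int(rng.integers(2**31)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full.fit(Fs, y)
    return full.coef_ / fscale, preds, r


def fit_class_model(F: np.ndarray, labels: np.ndarray, cv_seed: int = 0,
                    compute_cv: bool = True
                    ) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Penalized logistic classification of a binary subject label.

    Outer folds are stratified so each holds both classes.  Returns
    (full-data weights, held-out fraction-correct accuracy, held-out
    positive-class probabilities for ROC analysis).  ``compute_cv=False``
    skips the outer CV (weights only).
    """
    F = np.asarray(F, dtype=float)
    labels = np.asarray(labels)
    ok = np.array([x is not None and x == x for x in labels])
    F, labels = F[ok], labels[ok]
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if min(np.bincount(y)) < 5:
        raise ValueError("each class needs at least 5 subjects")
    Fs, fscale = _standardize(F)

    rng = np.random.default_rng(cv_seed)
    proba, accuracy = None, float("nan")
    if compute_cv:
        proba = np.empty(y.size)
        outer = StratifiedKFold(n_splits=10, shuffle=True,
                                random_state=int(rng.integers(2**31)))
        for tr, te in outer.split(Fs, y):
            model = _inner_logistic(int(rng.integers(2**31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Fs[tr], y[tr])
            proba[te] = model.predict_proba(Fs[te])[:, 1]
        accuracy = float(np.mean((proba >= 0.5) == y))

    full = _inner_logistic(int(rng.integers(2**31)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full.fit(Fs, y)
    return full.coef_.ravel() / fscale, accuracy, proba


def nested_cv(model_fitter, F: np.ndarray, targets: np.ndarray,
              n_folds: int = 10, n_repeats: int = 10, seed: int = 0
              ) -> tuple[float, float, np.ndarray]:
    """Repeat a nested n_folds CV with reshuffled folds; return
    (mean accuracy, standard deviation across repeats, per-repeat values).

    ``model_fitter`` is :func:`fit_response_model` or :func:`fit_class_model`
    (or any callable with the same (F, targets, cv_seed) signature whose
    second-or-later return value is the accuracy)."""
    if n_folds > len(np.asarray(targets)):
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_repeats):
        out = model_fitter(F, targets, int(rng.integers(2**31)))
        acc = out[2] if model_fitter is fit_response_model else out[1]
        if not np.isscalar(acc):  # generic fitter: find the scalar
            acc = next(v for v in out if np.isscalar(v))
        accs.append(float(acc))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std()), accs


def bootstrap_weights(model_fitter, F: np.ndarray, targets: np.ndarray,
                      n_boot: int = 20, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Resample subjects with replacement, refit, and return the mean and
    standard deviation of the model weights per component."""
    F = np.asarray(F, dtype=float)
    targets = np.asarray(targets)
    if n_boot == 1:
        logger.warning("bootstrap with n_boot=1: standard deviation is 0 by convention")
    rng = np.random.default_rng(seed)
    n = F.shape[0]
    all_w = []
    for _ in range(n_boot):
        for _redraw in range(100):
            idx = rng.integers(n, size=n)
            if np.unique(targets[idx]).size >= min(2, np.unique(targets).size):
                break
        w = model_fitter(F[idx], targets[idx], int(rng.integers(2**31)))[0]
        all_w.append(w)
    all_w = np.asarray(all_w)
    sd = all_w.std(axis=0) if n_boot > 1 else np.zeros(all_w.shape[1])
    return all_w.mean(axis=0), sd


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve for binary labels (0/1) and scores."""
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(y_true, scores))


# ---------------------------------------------------------------------------
# Sigmoidal temporal fits
# ---------------------------------------------------------------------------

@dataclass
class SigmoidParams:
    """Four-parameter logistic y = A/[1 + exp(−k(x − x0))] + C."""

    A: float
    k: float
    x0: float
    C: float
    rss: float = float("nan")
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(x, dtype=float), self.A, self.k, self.x0, self.C)


def _sigmoid(x, A, k, x0, C):
    return A / (1.0 + np.exp(-k * (x - x0))) + C


def sigmoid_initial_guess(x: np.ndarray, y: np.ndarray
                          ) -> tuple[float, float, float, float]:
    """Initial point: A = 0.6 of the y range; C = min(y); x0 = median(x);
    k = −0.5 when the first half of y averages larger than the latter half
    (falling trend), +0.5 otherwise (rising trend)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    half = y.size // 2
    k0 = -0.5 if np.mean(y[:half]) > np.mean(y[half:]) else 0.5
    return 0.6 * float(np.ptp(y)), k0, float(np.median(x)), float(np.min(y))


def fit_sigmoid(x: np.ndarray, y: np.ndarray) -> SigmoidParams:
    """Levenberg–Marquardt fit of the 4-parameter logistic from the stated
    initial point.  On non-convergence, returns the initial-point fit
    flagged unconverged."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    p0 = sigmoid_initial_guess(x, y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_sigmoid, x, y, p0=p0, method="lm", maxfev=10000)
        rss = float(np.sum((y - _sigmoid(x, *popt)) ** 2))
        return SigmoidParams(*popt, rss=rss, converged=True)
    except RuntimeError:
        rss = float(np.sum((y - _sigmoid(x, *p0)) ** 2))
        return SigmoidParams(*p0, rss=rss, converged=False)
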