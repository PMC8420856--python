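"""Preprocessing chain for raw serology measurements.

Raw median-fluorescence-type values are clipped from below at an
assay-noise floor, log-transformed, and centered per measurement (each
receptor–antigen pair, and each glycan feature) across subjects.  When a
coupled glycan matrix is present it is then rescaled so its total observed
variance stands in a chosen ratio to the tensor's — equal variance by
default, so neither block dominates the joint factorization.  Variance is
the sum of squared observed entries; missing values are ignored throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import CoupledDataset

logger = logging.getLogger(__name__)

__all__ = ["PreprocessPolicy", "clip_log_center", "scale_matrix_variance"]


@dataclass
class PreprocessPolicy:
    """Knobs of the preprocessing chain.

    ``clip_floor_tensor``/``clip_floor_matrix`` are detection floors in raw
    assay units (1.0 is typical for bead-array biophysical panels, 10.0 for
    higher-background panels, 0.1 for glycan fractions).  ``log_base`` is 10
    by default; the base only rescales globally and is absorbed by centering.
    ``matrix_variance_ratio`` is the target ‖Y‖²/‖X‖² after balancing
    (1.0 = equal variance).
    """

    clip_floor_tensor: float = 1.0
    clip_floor_matrix: float = 0.1
    log_base: float = 10.0
    matrix_variance_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.clip_floor_tensor <= 0 or self.clip_floor_matrix <= 0:
            raise ValueError("clip floors must be strictly positive")
        if self.log_base <= 1:
            raise ValueError("log base must exceed 1")
        if self.matrix_variance_ratio <= 0:
            raise ValueError("matrix_variance_ratio must be positive")


def _clip_log(values: np.ndarray, mask: np.ndarray, floor: float, base: float) -> np.ndarray:
    out = values.copy()
    obs = mask & np.isfinite(values)
    out[obs] = np.log(np.maximum(values[obs], floor)) / np.log(base)
    return out


def _center_columns(flat: np.ndarray, mask: np.ndarray, what: str) -> None:
    """Subtract the observed-subject mean from each measurement column, in place."""
    n_obs = mask.sum(axis=0)
    empty = n_obs == 0
    if empty.any():
        logger.warning("%d %s column(s) have no observed subjects; left unchanged",
                       int(empty.sum()), what)
    safe = np.maximum(n_obs, 1)
    means = np.where(mask, flat, 0.0).sum(axis=0) / safe
    means[empty] = 0.0
    flat -= np.where(mask, means[None, :], 0.0)


def clip_log_center(d: CoupledDataset, p: PreprocessPolicy) -> CoupledDataset:
    """Clip at the assay floor, log-transform, and center per measurement.

    Each observed value v becomes log_base(max(v, floor)); then every
    (receptor, antigen) fiber of the tensor and every glycan column of the
    matrix has its mean over observed subjects subtracted.  Unobserved
    entries are untouched.
    """
    d = d.copy()
    t = d.tensor
    t.values = _clip_log(t.values, t.mask, p.clip_floor_tensor, p.log_base)
    n = t.shape[0]
    flat = t.values.reshape(n, -1)  # columns = (receptor, antigen) fibers
    _center_columns(flat, t.mask.reshape(n, -1), "tensor measurement")
    t.values = flat.reshape(t.shape)

    if d.matrix is not None:
        m = d.matrix
        m.values = _clip_log(m.values, m.mask, p.clip_floor_matrix, p.log_base)
        _center_columns(m.values, m.mask, "glycan")
    d.log_step("clip_log_center", clip_floor_tensor=p.clip_floor_tensor,
               clip_floor_matrix=p.clip_floor_matrix, log_base=p.log_base)
    return d


def scale_matrix_variance(d: CoupledDataset, ratio: float = 1.0) -> CoupledDataset:
    """Rescale the coupled matrix so ‖Y‖² = ratio × ‖X‖² over observed entries.

    The applied constant is recorded in provenance for back-transformation.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    d = d.copy()
    if d.matrix is None:
        logger.warning("scale_matrix_variance: no coupled matrix present; no-op")
        return d
    vx = float(np.sum(d.tensor.observed_values() ** 2))
    vy = float(np.sum(d.matrix.observed_values() ** 2))
    if vx == 0.0:
        raise ValueError("tensor has zero observed variance")
    if vy == 0.0:
        raise ValueError("matrix has zero observed variance")
    s = float(np.sqrt(ratio * vx / vy))
    d.matrix.values = d.matrix.values * s
    d.log_step("scale_matrix_variance", ratio=ratio, scale_constant=s)
    return d
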