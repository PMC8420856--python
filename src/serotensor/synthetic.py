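"""Synthetic coupled datasets with known ground truth.

The generator draws factor matrices with standard-normal entries, forms the
tensor and coupled matrix as the corresponding Kruskal sums, and layers on
(optionally) homoscedastic Gaussian noise, entry-wise missingness, whole
receptor–antigen chord removal, and per-subject outcomes linked linearly to
the subject factors.  Two presets mirror the shapes of published cohorts:

* ``hiv_shaped`` — a 181 × 22 × 39 tensor coupled to a 181 × 25 glycan
  matrix, six underlying components, ~40% of tensor entries unobserved and
  the glycan matrix observed for half the subjects;
* ``sars_shaped`` — a complete 438 × 6 × 11 tensor, two components, with
  sampling times over ~4 weeks and severity groups whose component-1
  trajectories follow group-specific sigmoids (severe above moderate —
  illustrative, not calibrated to any cohort).

Everything is reproducible from the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (CoupledDataset, CoupledMatrix, KruskalFactors,
                        MaskedTensor, OutcomeTable)

__all__ = ["SimSpec", "generate_coupled", "hiv_shaped", "sars_shaped"]


@dataclass
class OutcomeSpec:
    """One synthetic outcome: ``kind`` "continuous" or "binary"; ``weights``
    over the true components; ``noise_sd`` relative to the linear signal."""

    name: str
    kind: str
    weights: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError("outcome kind must be 'continuous' or 'binary'")
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class SimSpec:
    n_subjects: int = 60
    n_receptors: int = 8
    n_antigens: int = 10
    n_glycans: int | None = 12
    R_true: int = 3
    noise_sd: float = 0.0        # relative to signal RMS
    missing_fraction: float = 0.0
    chord_missing_pairs: int = 0
    matrix_row_fraction: float = 1.0  # fraction of subjects with glycan rows
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    heavy_tails: bool = False    # t(3)-distributed factors instead of normal
    heteroscedastic: bool = False  # per-fiber noise scale spread
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = [self.n_subjects, self.n_receptors, self.n_antigens]
        if self.n_glycans is not None:
            sizes.append(self.n_glycans)
        if self.R_true > min(sizes):
            raise ValueError("R_true exceeds the smallest mode size")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        chord_frac = self.chord_missing_pairs / (self.n_receptors * self.n_antigens)
        if self.missing_fraction + chord_frac >= 1:
            raise ValueError("missingness would leave (almost) nothing observed")


def _draw_factors(rng: np.random.Generator, n: int, R: int, heavy: bool) -> np.ndarray:
    if heavy:
        return rng.standard_t(3, size=(n, R))
    return rng.standard_normal((n, R))


def generate_coupled(spec: SimSpec
                     ) -> tuple[CoupledDataset, KruskalFactors, OutcomeTable]:
    """Draw a coupled dataset plus its ground-truth factors and outcomes."""
    rng = np.random.default_rng(spec.seed)
    A = _draw_factors(rng, spec.n_subjects, spec.R_true, spec.heavy_tails)
    B = _draw_factors(rng, spec.n_receptors, spec.R_true, spec.heavy_tails)
    C = _draw_factors(rng, spec.n_antigens, spec.R_true, spec.heavy_tails)
    D = None
    if spec.n_glycans is not None:
        D = _draw_factors(rng, spec.n_glycans, spec.R_true, spec.heavy_tails)
    truth = KruskalFactors(A, B, C, D)

    x = np.einsum("ir,jr,kr->ijk", A, B, C)
    if spec.noise_sd > 0:
        rms = float(np.sqrt(np.mean(x**2)))
        scale = np.full((spec.n_receptors, spec.n_antigens), spec.noise_sd * rms)
        if spec.heteroscedastic:
            scale *= rng.lognormal(0.0, 0.5, size=scale.shape)
        x = x + rng.standard_normal(x.shape) * scale[None, :, :]
    mask = np.ones(x.shape, dtype=bool)
    if spec.missing_fraction > 0:
        mask &= rng.random(x.shape) >= spec.missing_fraction
    if spec.chord_missing_pairs > 0:
        flat = rng.choice(spec.n_receptors * spec.n_antigens,
                          size=spec.chord_missing_pairs, replace=False)
        jj, kk = np.unravel_index(flat, (spec.n_receptors, spec.n_antigens))
        mask[:, jj, kk] = False

    subjects = [f"S{i:04d}" for i in range(spec.n_subjects)]
    tensor = MaskedTensor(np.where(mask, x, np.nan), mask, subjects,
                          [f"R{j:02d}" for j in range(spec.n_receptors)],
                          [f"Ag{k:02d}" for k in range(spec.n_antigens)])

    matrix = None
    if D is not None:
        y = A @ D.T
        if spec.noise_sd > 0:
            rms_y = float(np.sqrt(np.mean(y**2)))
            y = y + rng.standard_normal(y.shape) * spec.noise_sd * rms_y
        ymask = np.ones(y.shape, dtype=bool)
        if spec.matrix_row_fraction < 1.0:
            n_rows = int(np.floor(spec.n_subjects * spec.matrix_row_fraction))
            unobserved = rng.choice(spec.n_subjects,
                                    size=spec.n_subjects - n_rows, replace=False)
            ymask[unobserved, :] = False
        matrix = CoupledMatrix(np.where(ymask, y, np.nan), ymask, subjects,
                               [f"G{g:02d}" for g in range(spec.n_glycans)])

    dataset = CoupledDataset(tensor, matrix)
    dataset.log_step("synthetic", R_true=spec.R_true, noise_sd=spec.noise_sd,
                     missing_fraction=spec.missing_fraction, seed=spec.seed)

    continuous: dict[str, np.ndarray] = {}
    classes: dict[str, np.ndarray] = {}
    for oc in spec.outcomes:
        signal = A @ oc.weights
        if oc.kind == "continuous":
            noise = rng.standard_normal(spec.n_subjects) * oc.noise_sd * (
                float(np.std(signal)) or 1.0)
            continuous[oc.name] = signal + noise
        else:
            logits = signal / (float(np.std(signal)) or 1.0)
            if oc.noise_sd > 0:
                p = 1.0 / (1.0 + np.exp(-logits / oc.noise_sd))
                lab = rng.random(spec.n_subjects) < p
            else:
                lab = logits > np.median(logits)
            classes[oc.name] = np.where(lab, "positive", "negative")
    outcomes = OutcomeTable(subjects, continuous, classes)
    return dataset, truth, outcomes


def hiv_shaped(seed: int = 0, R_true: int = 6, noise_sd: float = 0.0,
               missing_fraction: float = 0.4
               ) -> tuple[CoupledDataset, KruskalFactors, OutcomeTable]:
    """Preset with the HIV-cohort structure: 181 × 22 × 39 tensor plus a
    181 × 25 glycan matrix observed for half the subjects, six components,
    ~40% of tensor entries unobserved."""
    spec = SimSpec(
        n_subjects=181, n_receptors=22, n_antigens=39, n_glycans=25,
        R_true=R_true, noise_sd=noise_sd, missing_fraction=missing_fraction,
        matrix_row_fraction=0.5,
        outcomes=[
            OutcomeSpec("ADCD", "continuous",
                        _spread_weights(R_true, (0, 1), (1.0, -0.6)), 0.1),
            OutcomeSpec("ADCC", "continuous",
                        _spread_weights(R_true, (1, 2), (0.8, 0.5)), 0.1),
            OutcomeSpec("progression", "binary",
                        _spread_weights(R_true, (0,), (1.0,)), 0.0),
        ],
        seed=seed)
    return generate_coupled(spec)


def _spread_weights(R: int, idx: tuple, vals: tuple) -> np.ndarray:
    w = np.zeros(R)
    for i, v in zip(idx, vals):
        w[i % R] = v
    return w


def sars_shaped(seed: int = 0, noise_sd: float = 0.05
                ) -> tuple[CoupledDataset, KruskalFactors, OutcomeTable]:
    """Preset with the SARS-CoV-2-cohort structure: a complete 438 × 6 × 11
    tensor (samples × receptors × antigens), two components.

    Each sample carries a time (days after symptom onset, ~4 weeks) and a
    severity group; component-1 sample weights follow group-specific
    sigmoidal trajectories (severe starting and ending higher than
    moderate), component 2 a shared rising trend, so temporal curve fitting
    and group classification are exercised end to end.
    """
    n, n_rec, n_ant, R = 438, 6, 11, 2
    rng = np.random.default_rng(seed)
    time = rng.uniform(0.0, 28.0, size=n)
    groups = rng.choice(["negative", "moderate", "severe", "deceased"], size=n,
                        p=[0.08, 0.28, 0.45, 0.19])

    # group-specific 4PL trajectories for component 1 (amplitude, rate, midpoint, offset)
    traj = {"negative": (0.2, 0.4, 12.0, 0.05),
            "moderate": (1.6, 0.5, 9.0, 0.10),
            "severe": (1.8, 0.5, 8.0, 0.60),
            "deceased": (1.5, 0.45, 10.0, 0.15)}
    a1 = np.empty(n)
    for g, (amp, k, x0, c) in traj.items():
        sel = groups == g
        a1[sel] = amp / (1.0 + np.exp(-k * (time[sel] - x0))) + c
    a1 += rng.standard_normal(n) * 0.08
    a2 = 1.0 / (1.0 + np.exp(-0.3 * (time - 14.0))) + rng.standard_normal(n) * 0.08
    a2[groups == "negative"] += rng.random((groups == "negative").sum()) * 0.5

    A = np.column_stack([a1, a2])
    B = rng.standard_normal((n_rec, R))
    C = rng.standard_normal((n_ant, R))
    truth = KruskalFactors(A, B, C, None)
    x = np.einsum("ir,jr,kr->ijk", A, B, C)
    if noise_sd > 0:
        x = x + rng.standard_normal(x.shape) * noise_sd * float(np.sqrt(np.mean(x**2)))

    subjects = [f"P{i:04d}" for i in range(n)]
    tensor = MaskedTensor(x, np.ones(x.shape, dtype=bool), subjects,
                          [f"Det{j}" for j in range(n_rec)],
                          [f"Ag{k:02d}" for k in range(n_ant)])
    dataset = CoupledDataset(tensor, None)
    dataset.log_step("synthetic_sars_preset", seed=seed, noise_sd=noise_sd)
    outcomes = OutcomeTable(subjects, {}, {"severity": groups}, time=time)
    return dataset, truth, outcomes
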