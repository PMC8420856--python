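"""Core containers and tensor algebra for coupled serology profiling data.

Antigen-specific antibody measurements are arranged as a three-mode tensor
``X`` indexed (subject, receptor, antigen); antigen-generic measurements
(e.g. Fc glycan composition) form a matrix ``Y`` indexed (subject, glycan)
that shares the subject mode with the tensor.  Both carry an explicit
boolean observation mask: the mask is authoritative, and values at
unobserved positions never enter any norm or solve.

The unfolding convention is fixed so that the mode-0 matricization of a
rank-1 tensor ``a ∘ b ∘ c`` equals ``outer(a, kron(c, b))`` — i.e.
``unfold(X, 0) = A @ khatri_rao([C, B]).T`` — which makes the alternating
least squares normal equations read off directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MaskedTensor",
    "CoupledMatrix",
    "KruskalFactors",
    "CoupledDataset",
    "OutcomeTable",
    "unfold",
    "fold",
    "khatri_rao",
    "reconstruct",
    "factorization_size",
    "read_serology_tables",
    "write_factors",
]


def _check_labels(labels: Sequence[str], n: int, mode: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"{mode}: {len(labels)} labels for size-{n} mode")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{mode}: duplicate labels")
    return labels


@dataclass
class MaskedTensor:
    """Three-mode (subject × receptor × antigen) array with observation mask."""

    values: np.ndarray
    mask: np.ndarray
    subject_ids: list[str]
    receptor_ids: list[str]
    antigen_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("tensor must have exactly 3 modes")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must equal values shape")
        n, j, k = self.values.shape
        self.subject_ids = _check_labels(self.subject_ids, n, "subject")
        self.receptor_ids = _check_labels(self.receptor_ids, j, "receptor")
        self.antigen_ids = _check_labels(self.antigen_ids, k, "antigen")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def observed_values(self) -> np.ndarray:
        """Values with unobserved positions zeroed (safe for norms/sums)."""
        return np.where(self.mask, self.values, 0.0)

    def copy(self) -> "MaskedTensor":
        return MaskedTensor(self.values.copy(), self.mask.copy(),
                            list(self.subject_ids), list(self.receptor_ids),
                            list(self.antigen_ids))


@dataclass
class CoupledMatrix:
    """(subject × glycan) matrix sharing the subject mode with a MaskedTensor."""

    values: np.ndarray
    mask: np.ndarray
    subject_ids: list[str]
    glycan_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("coupled matrix must have exactly 2 modes")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must equal values shape")
        n, g = self.values.shape
        self.subject_ids = _check_labels(self.subject_ids, n, "subject")
        self.glycan_ids = _check_labels(self.glycan_ids, g, "glycan")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def observed_values(self) -> np.ndarray:
        return np.where(self.mask, self.values, 0.0)

    def copy(self) -> "CoupledMatrix":
        return CoupledMatrix(self.values.copy(), self.mask.copy(),
                             list(self.subject_ids), list(self.glycan_ids))


@dataclass
class KruskalFactors:
    """Per-component factor vectors of a (coupled) CP decomposition.

    ``A`` holds the shared subject factors; ``B``/``C`` the receptor and
    antigen factors of the tensor block; ``D`` (optional) the glycan factors
    of the coupled matrix.  ``scale`` records per-component magnitude removed
    from the tensor-block columns by display standardization; it is all-ones
    for freshly fitted factors.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.D is not None:
            self.D = np.asarray(self.D, dtype=float)
        r = self.A.shape[1] if self.A.ndim == 2 else 0
        for name, arr in (("B", self.B), ("C", self.C), ("D", self.D)):
            if arr is not None and arr.shape[1] != r:
                raise ValueError(f"factor {name} has {arr.shape[1]} columns, expected {r}")
        if self.scale is None:
            self.scale = np.ones(r)
        else:
            self.scale = np.asarray(self.scale, dtype=float)
            if self.scale.shape != (r,):
                raise ValueError("scale must have one entry per component")

    @property
    def R(self) -> int:
        return self.A.shape[1]

    def mode_sizes(self) -> tuple[int, ...]:
        sizes = [self.A.shape[0], self.B.shape[0], self.C.shape[0]]
        if self.D is not None:
            sizes.append(self.D.shape[0])
        return tuple(sizes)

    def copy(self) -> "KruskalFactors":
        return KruskalFactors(self.A.copy(), self.B.copy(), self.C.copy(),
                              None if self.D is None else self.D.copy(),
                              self.scale.copy())


@dataclass
class CoupledDataset:
    """A MaskedTensor plus optional CoupledMatrix and preprocessing provenance."""

    tensor: MaskedTensor
    matrix: CoupledMatrix | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix is not None and self.matrix.subject_ids != self.tensor.subject_ids:
            raise ValueError("matrix subject ids must match tensor subject ids in order")

    @property
    def n_subjects(self) -> int:
        return self.tensor.shape[0]

    def log_step(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})

    def copy(self) -> "CoupledDataset":
        return CoupledDataset(self.tensor.copy(),
                              None if self.matrix is None else self.matrix.copy(),
                              [dict(p) for p in self.provenance])


@dataclass
class OutcomeTable:
    """Per-subject outcomes: continuous functional responses, binary classes,
    and optional sampling time (days after symptom onset)."""

    subject_ids: list[str]
    continuous: dict[str, np.ndarray] = field(default_factory=dict)
    classes: dict[str, np.ndarray] = field(default_factory=dict)
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        self.continuous = {k: np.asarray(v, dtype=float) for k, v in self.continuous.items()}
        self.classes = {k: np.asarray(v) for k, v in self.classes.items()}
        for name, v in {**self.continuous, **self.classes}.items():
            if len(v) != n:
                raise ValueError(f"outcome {name!r} length {len(v)} != {n} subjects")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)


# ---------------------------------------------------------------------------
# Tensor algebra primitives
# ---------------------------------------------------------------------------

def unfold(values: np.ndarray, mode: int, mask: np.ndarray | None = None):
    """Mode-n matricization (Fortran/Kolda–Bader column ordering).

    Returns the unfolded array, or ``(array, mask)`` when a mask is given.
    Under this convention ``unfold(a∘b∘c, 0) = outer(a, khatri_rao([C, B]))``.
    """
    values = np.asarray(values)
    if mode not in range(values.ndim):
        raise ValueError(f"invalid mode {mode} for {values.ndim}-mode tensor")
    out = np.reshape(np.moveaxis(values, mode, 0), (values.shape[mode], -1), order="F")
    if mask is None:
        return out
    m = np.reshape(np.moveaxis(np.asarray(mask), mode, 0), out.shape, order="F")
    return out, m


def fold(unfolded: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold`: restore the full tensor of given shape."""
    shape = tuple(shape)
    if mode not in range(len(shape)):
        raise ValueError(f"invalid mode {mode} for shape {shape}")
    moved = (shape[mode],) + tuple(s for i, s in enumerate(shape) if i != mode)
    return np.moveaxis(np.reshape(np.asarray(unfolded), moved, order="F"), 0, mode)


def khatri_rao(factors: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise Kronecker product of factor matrices (in input order)."""
    factors = [np.asarray(f) for f in factors]
    if not factors:
        raise ValueError("need at least one factor matrix")
    r = factors[0].shape[1]
    if any(f.shape[1] != r for f in factors):
        raise ValueError("all factors must have the same number of columns")
    out = factors[0]
    for f in factors[1:]:
        # rows of `out` vary slower than rows of `f`, matching kron order
        out = (out[:, None, :] * f[None, :, :]).reshape(-1, r)
    return out


def reconstruct(f: KruskalFactors) -> tuple[np.ndarray, np.ndarray | None]:
    """Dense reconstruction: X̂[i,j,k] = Σ_r s_r A[i,r] B[j,r] C[k,r] and
    Ŷ = A Dᵀ (no mask applied; per-component ``scale`` folded back in)."""
    tensor = np.einsum("r,ir,jr,kr->ijk", f.scale, f.A, f.B, f.C)
    matrix = None if f.D is None else f.A @ f.D.T
    return tensor, matrix


def factorization_size(f: KruskalFactors) -> int:
    """Number of stored values: (sum of mode sizes across factor arrays) × R."""
    return int(sum(f.mode_sizes()) * f.R)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

MIN_RECEPTORS_PER_ANTIGEN = 3  # antigens measured against fewer receptors are dropped


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def _long_from_wide(df: pd.DataFrame, split_char: str, split_first: bool) -> pd.DataFrame:
    subject_col = df.columns[0]
    records = []
    for col in df.columns[1:]:
        if split_first:
            receptor, _, antigen = col.partition(split_char)
        else:
            receptor, _, antigen = col.rpartition(split_char)
        if not receptor or not antigen:
            raise ValueError(f"cannot split wide column {col!r} on {split_char!r}")
        for subj, val in zip(df[subject_col], df[col]):
            records.append((subj, receptor, antigen, val))
    return pd.DataFrame(records, columns=["subject", "receptor", "antigen", "value"])


def read_serology_tables(
    antigen_specific_path,
    antigen_generic_path=None,
    metadata_path=None,
    *,
    wide: bool = False,
    split_char: str = ".",
    split_first: bool = True,
    min_receptors: int = MIN_RECEPTORS_PER_ANTIGEN,
) -> tuple[CoupledDataset, OutcomeTable | None]:
    """Read delimited serology tables into a CoupledDataset.

    The antigen-specific table is long form ``subject, receptor, antigen,
    value`` (or wide form ``subject × "receptor.antigen"`` with ``wide=True``;
    column names split on the first occurrence of ``split_char`` by default,
    since receptor names may themselves contain dots).  Never-measured
    (receptor, antigen) combinations become unobserved tensor positions.
    Antigens measured against fewer than ``min_receptors`` receptors are
    dropped with a warning — their factor values would be unstable.  Labels
    are ordered lexicographically for determinism.
    """
    df = _read_table(antigen_specific_path)
    if wide:
        df = _long_from_wide(df, split_char, split_first)
    else:
        df = df.rename(columns=dict(zip(df.columns[:4],
                                        ["subject", "receptor", "antigen", "value"])))
    for col in ("subject", "receptor", "antigen"):
        df[col] = df[col].astype(str)
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric value in antigen-specific table at row {row}")
    df["value"] = pd.to_numeric(df["value"])
    df = df.dropna(subset=["value"])

    dup = df.duplicated(subset=["subject", "receptor", "antigen"], keep=False)
    if dup.any():
        t = df.loc[dup, ["subject", "receptor", "antigen"]].iloc[0]
        raise ValueError(
            f"duplicate record for (subject={t.subject!r}, receptor={t.receptor!r}, "
            f"antigen={t.antigen!r})")

    # antigen filter: keep antigens measured against >= min_receptors receptors
    n_receptors = df.groupby("antigen")["receptor"].nunique()
    drop = sorted(n_receptors.index[n_receptors < min_receptors])
    if drop:
        logger.warning("dropping antigens with <%d receptor measurements: %s",
                       min_receptors, ", ".join(drop))
        df = df[~df["antigen"].isin(drop)]

    generic = None
    if antigen_generic_path is not None:
        generic = _read_table(antigen_generic_path)
        generic = generic.rename(columns=dict(zip(generic.columns[:3],
                                                  ["subject", "feature", "value"])))
        generic["subject"] = generic["subject"].astype(str)
        generic["feature"] = generic["feature"].astype(str)
        generic["value"] = pd.to_numeric(generic["value"])
        generic = generic.dropna(subset=["value"])

    subjects = set(df["subject"])
    if generic is not None:
        subjects |= set(generic["subject"])
    subject_ids = sorted(subjects)
    receptor_ids = sorted(df["receptor"].unique())
    antigen_ids = sorted(df["antigen"].unique())

    si = {s: i for i, s in enumerate(subject_ids)}
    ri = {r: i for i, r in enumerate(receptor_ids)}
    ai = {a: i for i, a in enumerate(antigen_ids)}

    shape = (len(subject_ids), len(receptor_ids), len(antigen_ids))
    values = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    ii = df["subject"].map(si).to_numpy()
    jj = df["receptor"].map(ri).to_numpy()
    kk = df["antigen"].map(ai).to_numpy()
    values[ii, jj, kk] = df["value"].to_numpy()
    mask[ii, jj, kk] = True
    tensor = MaskedTensor(values, mask, subject_ids, receptor_ids, antigen_ids)

    matrix = None
    if generic is not None:
        glycan_ids = sorted(generic["feature"].unique())
        gi = {g: i for i, g in enumerate(glycan_ids)}
        mvals = np.full((len(subject_ids), len(glycan_ids)), np.nan)
        mmask = np.zeros_like(mvals, dtype=bool)
        mvals[generic["subject"].map(si), generic["feature"].map(gi)] = generic["value"]
        mmask[generic["subject"].map(si), generic["feature"].map(gi)] = True
        matrix = CoupledMatrix(mvals, mmask, subject_ids, glycan_ids)

    dataset = CoupledDataset(tensor, matrix)
    dataset.log_step("import", dropped_antigens=drop)

    outcomes = None
    if metadata_path is not None:
        meta = _read_table(metadata_path)
        meta = meta.rename(columns={meta.columns[0]: "subject"})
        meta["subject"] = meta["subject"].astype(str)
        meta = meta.set_index("subject").reindex(subject_ids)
        continuous, classes, time = {}, {}, None
        for col in meta.columns:
            as_num = pd.to_numeric(meta[col], errors="coerce")
            if col.lower() in ("time", "day", "days"):
                time = as_num.to_numpy()
            elif as_num.notna().sum() == meta[col].notna().sum():
                continuous[col] = as_num.to_numpy()
            else:
                classes[col] = meta[col].to_numpy()
        outcomes = OutcomeTable(subject_ids, continuous, classes, time)
    return dataset, outcomes


def write_factors(f: KruskalFactors, dataset: CoupledDataset, outdir,
                  manifest_extra: dict | None = None) -> None:
    """Write one delimited table per mode plus a JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp_cols = [f"Cmp{r + 1}" for r in range(f.R)]
    tables = {
        "subject_factors.csv": (dataset.tensor.subject_ids, f.A),
        "receptor_factors.csv": (dataset.tensor.receptor_ids, f.B),
        "antigen_factors.csv": (dataset.tensor.antigen_ids, f.C),
    }
    if f.D is not None and dataset.matrix is not None:
        tables["glycan_factors.csv"] = (dataset.matrix.glycan_ids, f.D)
    for name, (labels, arr) in tables.items():
        pd.DataFrame(arr, index=labels, columns=comp_cols).to_csv(
            outdir / name, index_label="label")
    manifest = {
        "R": f.R,
        "mode_sizes": list(f.mode_sizes()),
        "scale": f.scale.tolist(),
        "provenance": dataset.provenance,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
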