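"""Core in-memory containers for multi-group expression data.

The central object is :class:`OmicsMatrix`, a genes x samples intensity
matrix with an explicit boolean missingness mask.  Missing is a *state*,
never a sentinel number, so that an observed zero (single-cell counts)
and a missing measurement (proteomics ``NA``) remain distinct.  A
``space`` flag records whether values are linear intensities or log2
intensities; conversions between the two act on observed entries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LINEAR",
    "LOG2",
    "OmicsMatrix",
    "GroupLabels",
    "MissingnessTruth",
    "to_log2",
    "to_linear",
]

LINEAR = "linear"
LOG2 = "log2"
_SPACES = (LINEAR, LOG2)


def _as_str_list(ids: Iterable) -> list[str]:
    return [str(x) for x in ids]


@dataclass
class OmicsMatrix:
    """Genes x samples expression matrix with an explicit missing mask.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``.  Entries at masked
        positions carry no information and are never read downstream.
    mask
        Boolean matrix of the same shape; ``True`` marks a missing cell.
    space
        ``"linear"`` or ``"log2"``.  Linear-space observed values must be
        nonnegative.
    gene_ids, sample_ids
        Unique ordered identifiers for rows and columns.
    """

    values: np.ndarray
    mask: np.ndarray
    space: str
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.gene_ids = _as_str_list(self.gene_ids)
        self.sample_ids = _as_str_list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if self.space not in _SPACES:
            raise ValueError(f"space must be one of {_SPACES}, got {self.space!r}")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must match number of rows")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length must match number of columns")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValueError(f"duplicate {name} ids: {dupes[:5]}")
        obs = self.values[~self.mask]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError("observed values must be finite")
        if self.space == LINEAR and obs.size and np.any(obs < 0):
            raise ValueError("linear-space observed values must be nonnegative")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def observed_values(self) -> np.ndarray:
        """Flat array of all observed entries."""
        return self.values[~self.mask]

    def masked_values(self) -> np.ndarray:
        """Observed-value matrix with NaN at masked positions."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values.copy(), self.mask.copy(), self.space,
            list(self.gene_ids), list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view with NaN at masked positions."""
        return pd.DataFrame(self.masked_values(), index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, space: str) -> "OmicsMatrix":
        """Build from a DataFrame where NaN marks missing cells."""
        vals = frame.to_numpy(dtype=float)
        mask = np.isnan(vals)
        vals = np.where(mask, 0.0, vals)
        return cls(vals, mask, space, list(frame.index), list(frame.columns))


def to_log2(m: OmicsMatrix, pseudo: float = 0.0) -> OmicsMatrix:
    """Convert a linear-space matrix to log2: ``log2(value + pseudo)``.

    The mask is unchanged; masked cells are left at 0 (they carry no
    information in either space).
    """
    if m.space != LINEAR:
        raise ValueError("to_log2 requires a linear-space matrix")
    if pseudo < 0:
        raise ValueError("pseudo must be nonnegative")
    obs = ~m.mask
    if np.any(m.values[obs] + pseudo <= 0):
        raise ValueError("log2 of nonpositive value; increase pseudo")
    vals = np.zeros_like(m.values)
    vals[obs] = np.log2(m.values[obs] + pseudo)
    return OmicsMatrix(vals, m.mask.copy(), LOG2, list(m.gene_ids), list(m.sample_ids))


def to_linear(m: OmicsMatrix, pseudo: float = 0.0) -> OmicsMatrix:
    """Invert :func:`to_log2`: ``2**value - pseudo`` at observed entries."""
    if m.space != LOG2:
        raise ValueError("to_linear requires a log2-space matrix")
    if pseudo < 0:
        raise ValueError("pseudo must be nonnegative")
    obs = ~m.mask
    vals = np.zeros_like(m.values)
    vals[obs] = np.exp2(m.values[obs]) - pseudo
    # guard tiny negative round-off when pseudo > 0
    vals[obs] = np.where(np.abs(vals[obs]) < 1e-12, np.abs(vals[obs]), vals[obs])
    return OmicsMatrix(vals, m.mask.copy(), LINEAR, list(m.gene_ids), list(m.sample_ids))


@dataclass
class GroupLabels:
    """Sample -> group assignment with a deterministic group order.

    Group order is the order of first appearance in the input; every
    sample carries exactly one group and at least two groups exist.
    """

    assignment: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignment = {str(k): str(v) for k, v in self.assignment.items()}
        if not self.groups:
            seen: list[str] = []
            for g in self.assignment.values():
                if g not in seen:
                    seen.append(g)
            self.groups = seen
        else:
            self.groups = _as_str_list(self.groups)
        missing = set(self.assignment.values()) - set(self.groups)
        if missing:
            raise ValueError(f"groups list omits assigned groups: {sorted(missing)}")
        if len(self.groups) < 2:
            raise ValueError("at least two groups are required")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GroupLabels":
        return cls(dict((str(s), str(g)) for s, g in pairs))

    def group_of(self, sample_id: str) -> str:
        return self.assignment[str(sample_id)]

    def indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Integer group index (position in ``groups``) per sample."""
        pos = {g: i for i, g in enumerate(self.groups)}
        try:
            return np.array([pos[self.assignment[str(s)]] for s in sample_ids])
        except KeyError as exc:
            raise KeyError(f"sample without group label: {exc}") from None

    def members(self, group_id: str, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask over ``sample_ids`` selecting one group."""
        return np.array([self.assignment[str(s)] == group_id for s in sample_ids])

    def check_cover(self, sample_ids: Sequence[str]) -> None:
        unlabeled = [s for s in sample_ids if str(s) not in self.assignment]
        if unlabeled:
            raise ValueError(f"samples without group label: {unlabeled[:5]}")


MECHANISMS = ("LLOD", "MAR")


@dataclass
class MissingnessTruth:
    """Ground-truth record of masked entries: the index set Omega.

    Each entry stores the position, the true (pre-masking) value and the
    mechanism (``LLOD`` censoring or ``MAR``) that removed it.  Used only
    for evaluation; positions must be unique.
    """

    table: pd.DataFrame  # columns: gene_id, sample_id, true_value, mechanism

    COLUMNS = ("gene_id", "sample_id", "true_value", "mechanism")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table, columns=list(self.COLUMNS))
        df["gene_id"] = df["gene_id"].astype(str)
        df["sample_id"] = df["sample_id"].astype(str)
        df["true_value"] = df["true_value"].astype(float)
        df["mechanism"] = df["mechanism"].astype(str)
        bad = set(df["mechanism"]) - set(MECHANISMS)
        if bad:
            raise ValueError(f"unknown mechanisms: {sorted(bad)}")
        if df.duplicated(["gene_id", "sample_id"]).any():
            raise ValueError("duplicate Omega positions")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_omega(self) -> int:
        return len(self.table)

    def positions(self, m: OmicsMatrix) -> tuple[np.ndarray, np.ndarray]:
        """(row_idx, col_idx) arrays of Omega within a companion matrix."""
        gi = {g: i for i, g in enumerate(m.gene_ids)}
        si = {s: i for i, s in enumerate(m.sample_ids)}
        rows = self.table["gene_id"].map(gi)
        cols = self.table["sample_id"].map(si)
        if rows.isna().any() or cols.isna().any():
            raise KeyError("Omega refers to ids absent from the matrix")
        return rows.to_numpy(dtype=int), cols.to_numpy(dtype=int)

    def check_masked_in(self, m: OmicsMatrix) -> None:
        rows, cols = self.positions(m)
        if not m.mask[rows, cols].all():
            raise ValueError("Omega contains positions not masked in the matrix")
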