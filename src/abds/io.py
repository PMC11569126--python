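"""Readers and writers for the suite's on-disk formats.

Matrix TSV/CSV: first column gene ids, header row sample ids, ``NA`` or
empty cells mark missing.  MatrixMarket triplets (single-cell counts)
come with two sidecar id files; absent triplet entries are *observed
zeros*, not missing.  Labels: two-column TSV ``sample_id<TAB>group_id``.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .matrix import LINEAR, GroupLabels, MissingnessTruth, OmicsMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_table",
    "read_truth",
    "read_scores",
]

_NA_STRINGS = ("", "NA", "NaN", "nan")


def read_matrix(path: str, format: str = "tsv", space: str = LINEAR,
                genes_path: str | None = None,
                samples_path: str | None = None) -> OmicsMatrix:
    """Read an expression matrix.

    Parameters
    ----------
    format
        ``"tsv"``/``"csv"``: dense table, NA/empty = missing.
        ``"mtx"``: MatrixMarket triplet; requires ``genes_path`` and
        ``samples_path`` id files (one id per line).  Entries absent from
        the triplet are observed zeros, never missing.
    """
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(_NA_STRINGS),
                         keep_default_na=False, dtype=str)
        df.index = df.index.astype(str)
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric cell {df.iat[i, j]!r} at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}")
        vals = numeric.to_numpy(dtype=float)
        mask = np.isnan(vals)
        vals = np.where(mask, 0.0, vals)
        return OmicsMatrix(vals, mask, space, list(df.index), list(df.columns))
    if format == "mtx":
        if genes_path is None or samples_path is None:
            raise ValueError("mtx format requires genes_path and samples_path")
        mat = sp.coo_matrix(spio.mmread(path)).toarray().astype(float)
        gene_ids = _read_id_file(genes_path)
        sample_ids = _read_id_file(samples_path)
        mask = np.zeros_like(mat, dtype=bool)  # sparse zeros are observed
        return OmicsMatrix(mat, mask, space, gene_ids, sample_ids)
    raise ValueError(f"unknown format {format!r}")


def _read_id_file(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_matrix(m: OmicsMatrix, path: str, format: str = "tsv") -> None:
    """Write a matrix as TSV/CSV with ``NA`` at masked cells."""
    sep = "\t" if format == "tsv" else ","
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")


def read_labels(path: str) -> GroupLabels:
    """Read a two-column sample/group TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("labels file needs two columns: sample_id, group_id")
    first = tuple(df.iloc[0])
    if first[:2] == ("sample_id", "group_id"):
        df = df.iloc[1:]
    return GroupLabels.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(g: GroupLabels, path: str) -> None:
    with open(path, "w") as fh:
        for s, grp in g.assignment.items():
            fh.write(f"{s}\t{grp}\n")


_SCORE_COLUMNS = ["gene_id", "direction", "assigned_group", "score",
                  "p_value", "q_value", "rank"]


def write_table(obj, path: str) -> None:
    """Write one of the suite's tabular results as TSV.

    Accepts a score table (DataFrame with the score schema), a
    :class:`MissingnessTruth`, or any DataFrame; column order is fixed
    per type so round trips are deterministic.
    """
    if isinstance(obj, MissingnessTruth):
        df = obj.table[list(MissingnessTruth.COLUMNS)]
    elif isinstance(obj, pd.DataFrame):
        if set(_SCORE_COLUMNS) <= set(obj.columns):
            ordered = _SCORE_COLUMNS + [c for c in obj.columns if c not in _SCORE_COLUMNS]
            df = obj[ordered]
        else:
            df = obj
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_truth(path: str) -> MissingnessTruth:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    return MissingnessTruth(df)


def read_scores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})
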