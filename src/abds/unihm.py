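"""Unified heatmap layout for multi-group signature display.

Classical per-gene z-scoring destroys the common reference origin:
zero expression maps to a different negative value for every gene, so
colour no longer ranks signature quality.  The unified design instead
(1) projects every sample value of gene ``i`` onto the scatter simplex
by dividing by the sum of the gene's group means (perspective
projection; the projected group means of each gene sum to one), then
(2) standardizes in log space with *group-centric* statistics — centred
on the mean of the K log-space group means and scaled by the pooled
within-group SD with equal group weighting — after clamping at a
gene-invariant floor.  Zero expression therefore maps to one common
display value across all genes, and within a group the displayed
contrast follows the cosine score ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LINEAR, LOG2, GroupLabels, OmicsMatrix, to_linear
from .signatures import DSG, SG, reference_vectors

__all__ = [
    "HeatmapLayout",
    "simplex_project",
    "display_standardize",
    "classical_zscore",
    "build_layout",
    "export_layout",
]

logger = logging.getLogger(__name__)


@dataclass
class HeatmapLayout:
    """Ordered, display-standardized heatmap contract.

    ``display`` and ``projected`` are genes x samples DataFrames already
    permuted into ``row_order`` / ``col_order``; ``group_boundaries``
    are the column indices where a new group starts (excluding 0).
    """

    display: pd.DataFrame
    projected: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    group_boundaries: list[int] = field(default_factory=list)


def _group_means(vals: np.ndarray, obs: np.ndarray, gidx: np.ndarray,
                 K: int) -> np.ndarray:
    out = np.full((vals.shape[0], K), np.nan)
    for k in range(K):
        sel = gidx == k
        n = obs[:, sel].sum(axis=1)
        s = np.where(obs[:, sel], vals[:, sel], 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[:, k] = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return out


def simplex_project(m: OmicsMatrix, g: GroupLabels) -> pd.DataFrame:
    """Perspective projection onto the scatter simplex.

    Every cell of gene ``i`` is divided by the sum of the gene's
    group-specific means, so the projected group means sum to exactly
    one.  Genes whose group-mean sum is zero (or not computable) are
    dropped with a warning.  Masked cells come back as NaN.
    """
    if m.space == LOG2:
        m = to_linear(m)
    g.check_cover(m.sample_ids)
    gidx = g.indices(m.sample_ids)
    obs = ~m.mask
    gm = _group_means(m.values, obs, gidx, g.n_groups)
    denom = gm.sum(axis=1)
    keep = np.isfinite(denom) & (denom > 0)
    if not keep.all():
        logger.warning("simplex_project: dropped %d genes with zero or "
                       "undefined group-mean sum", int((~keep).sum()))
    vals = np.where(obs, m.values, np.nan)[keep] / denom[keep, None]
    return pd.DataFrame(vals,
                        index=[gid for gid, k in zip(m.gene_ids, keep) if k],
                        columns=m.sample_ids)


def default_floor(projected: pd.DataFrame) -> float:
    """Half the smallest positive projected value (matrix-wide).

    Shared across genes so that the clamped origin is gene-invariant.
    """
    vals = projected.to_numpy(dtype=float)
    pos = vals[np.isfinite(vals) & (vals > 0)]
    if pos.size == 0:
        raise ValueError("projected matrix has no positive values")
    return float(pos.min() / 2.0)


def display_standardize(projected: pd.DataFrame, g: GroupLabels,
                        floor: float | None = None) -> pd.DataFrame:
    """Log-space group-centric standardization for display.

    Values are clamped below at ``floor`` (gene-invariant), moved to
    log2, then each gene is centred on the mean of its K log-space group
    means and scaled by the pooled within-group log-space SD (equal
    group weighting regardless of group size).  Genes with zero pooled
    SD render as all zeros (flagged).  NaN (missing) cells stay NaN.
    """
    if floor is None:
        floor = default_floor(projected)
    if floor <= 0:
        raise ValueError("floor must be positive")
    vals = projected.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    logv = np.where(obs, np.log2(np.maximum(vals, floor)), np.nan)
    gidx = g.indices(list(projected.columns))
    K = g.n_groups
    gm = _group_means(logv, obs, gidx, K)
    center = np.nanmean(gm, axis=1)
    # pooled within-group variance, equal weight per group
    var = np.full((vals.shape[0], K), np.nan)
    for k in range(K):
        sel = gidx == k
        with np.errstate(invalid="ignore"):
            resid2 = np.where(obs[:, sel], (logv[:, sel] - gm[:, k][:, None]) ** 2, np.nan)
            var[:, k] = np.nanmean(resid2, axis=1)
    pooled = np.sqrt(np.nanmean(var, axis=1))
    flat = ~(pooled > 0)
    if flat.any():
        logger.warning("display_standardize: %d genes have zero pooled "
                       "within-group SD; rendered as zeros", int(flat.sum()))
    scale = np.where(flat, 1.0, pooled)
    out = (logv - center[:, None]) / scale[:, None]
    out[flat] = np.where(obs[flat], 0.0, np.nan)
    return pd.DataFrame(out, index=projected.index, columns=projected.columns)


def classical_zscore(m: OmicsMatrix) -> pd.DataFrame:
    """Per-gene z-scoring comparator (the design this layout replaces).

    Centres and scales each gene over all samples; zero expression lands
    at a gene-dependent negative value, breaking the common origin.
    """
    vals = m.masked_values()
    mu = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return pd.DataFrame((vals - mu) / sd, index=m.gene_ids, columns=m.sample_ids)


def _sample_cosines(projected: pd.DataFrame, g: GroupLabels,
                    scores: pd.DataFrame) -> pd.Series:
    """Per-sample averaged cosine against the signature references.

    For each sample ``s`` (group ``k``) and displayed gene ``i``, the
    gene's group-mean profile with the ``k`` entry replaced by the
    sample's own projected value is scored against the reference of the
    gene's assigned group and direction; the sample's key is the mean
    over genes.  Measures how well the individual sample conforms to the
    signature patterns.
    """
    gidx = g.indices(list(projected.columns))
    K = g.n_groups
    vals = projected.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    gm = _group_means(vals, obs, gidx, K)
    meta = scores.set_index("gene_id")
    group_pos = {gname: i for i, gname in enumerate(g.groups)}
    refs = {SG: reference_vectors(K, SG), DSG: reference_vectors(K, DSG)}
    ref_rows = np.zeros((len(projected.index), K))
    for r, gid in enumerate(projected.index):
        ref_rows[r] = refs[meta.at[gid, "direction"]][group_pos[meta.at[gid, "assigned_group"]]]
    out = {}
    for j, s in enumerate(projected.columns):
        k = gidx[j]
        prof = gm.copy()
        col = vals[:, j]
        prof[:, k] = np.where(np.isfinite(col), col, prof[:, k])
        num = (prof * ref_rows).sum(axis=1)
        den = np.linalg.norm(prof, axis=1) * np.linalg.norm(ref_rows, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(den > 0, num / den, np.nan)
        out[s] = float(np.nanmean(cos))
    return pd.Series(out)


def build_layout(m: OmicsMatrix, g: GroupLabels, scores: pd.DataFrame,
                 floor: float | None = None) -> HeatmapLayout:
    """Assemble the ordered heatmap layout.

    Rows: genes grouped by assigned group (group order), score
    descending, ties by gene id.  Columns: samples grouped by group
    label, within group by sample-averaged cosine descending.  Genes in
    the matrix but absent from ``scores`` are excluded with a warning.
    """
    projected = simplex_project(m, g)
    scored = set(scores["gene_id"])
    keep = [gid for gid in projected.index if gid in scored]
    if len(keep) < len(projected.index):
        logger.warning("build_layout: %d genes have no score and are excluded",
                       len(projected.index) - len(keep))
    projected = projected.loc[keep]
    display = display_standardize(projected, g, floor)

    meta = scores.set_index("gene_id")
    group_pos = {gname: i for i, gname in enumerate(g.groups)}
    row_key = sorted(keep, key=lambda gid: (group_pos[meta.at[gid, "assigned_group"]],
                                            -float(meta.at[gid, "score"]), gid))
    cos = _sample_cosines(projected.loc[row_key], g, scores)
    col_key = sorted(projected.columns,
                     key=lambda s: (group_pos[g.group_of(s)], -cos[s], s))
    boundaries = []
    prev = None
    for j, s in enumerate(col_key):
        grp = g.group_of(s)
        if prev is not None and grp != prev:
            boundaries.append(j)
        prev = grp
    return HeatmapLayout(
        display=display.loc[row_key, col_key],
        projected=projected.loc[row_key, col_key],
        row_order=row_key,
        col_order=list(col_key),
        group_boundaries=boundaries,
    )


def export_layout(layout: HeatmapLayout, prefix: str, png: bool = False) -> list[str]:
    """Write ``<prefix>.display.tsv``, row/col order files, optional PNG."""
    paths = []
    display_path = f"{prefix}.display.tsv"
    df = layout.display.copy()
    df.index.name = "gene_id"
    df.to_csv(display_path, sep="\t", na_rep="NA", float_format="%.10g")
    paths.append(display_path)
    for name, order in (("roworder", layout.row_order), ("colorder", layout.col_order)):
        p = f"{prefix}.{name}.txt"
        with open(p, "w") as fh:
            fh.write("\n".join(order) + "\n")
        paths.append(p)
    if png:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 6))
        vals = layout.display.to_numpy(dtype=float)
        lim = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 1.0
        im = ax.imshow(vals, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
        for b in layout.group_boundaries:
            ax.axvline(b - 0.5, color="black", lw=0.8)
        ax.set_xlabel("samples")
        ax.set_ylabel("genes")
        fig.colorbar(im, ax=ax, label="standardized log2 simplex projection")
        p = f"{prefix}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths
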