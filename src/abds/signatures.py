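"""Cosine-based one-sample detection of signature genes.

A signature gene (SG) of group ``k`` is uniquely highly expressed in
``k`` and near-silent elsewhere; its ideal cross-group pattern is the
Cartesian unit vector ``e_k``.  A *downregulated* signature gene (DSG)
is uniquely silent in ``k`` and expressed everywhere else; its ideal
pattern is the XOR complement ``e_k (+) 1`` — zero at ``k``, one
elsewhere.  The test statistic for gene ``i`` with group-averaged
profile ``x(i)`` is the maximum over the K enumerated references of the
cosine ``cos(x(i), ref_k)``: magnitude-invariant, with range
``[1/sqrt(K), 1]`` for SG mode and ``[1/sqrt(K-1), 1]`` for DSG mode on
nonnegative profiles.

P-values come from the empirical null: with most genes obeying the null
hypothesis, the histogram of the statistics themselves approximates the
null distribution, and the upper-tail empirical proportion is the
p-value.  One-versus-rest t-test and fold-change comparators are
included as the standard baselines.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import LINEAR, LOG2, GroupLabels, OmicsMatrix, to_linear, to_log2

__all__ = [
    "supersample",
    "reference_vectors",
    "cosine_scores",
    "empirical_null_pvalues",
    "ovr_ttest_scores",
    "ovr_fc_scores",
    "detect",
    "score_genes",
]

logger = logging.getLogger(__name__)

SG = "SG"
DSG = "DSG"

SCORE_COLUMNS = ["gene_id", "direction", "assigned_group", "score",
                 "p_value", "q_value", "rank"]


def supersample(m: OmicsMatrix, g: GroupLabels) -> pd.DataFrame:
    """Group-averaged linear-space expression profiles x(i).

    Returns a genes x groups DataFrame (columns in group order).  Means
    use observed entries only; a gene with an all-missing group is
    dropped with a warning, since its profile is undefined there.
    """
    if m.space == LOG2:
        m = to_linear(m)
    g.check_cover(m.sample_ids)
    gidx = g.indices(m.sample_ids)
    obs = ~m.mask
    cols = []
    counts = []
    for k in range(g.n_groups):
        sel = gidx == k
        if not sel.any():
            raise ValueError(f"group {g.groups[k]!r} has no samples")
        n = obs[:, sel].sum(axis=1)
        s = np.where(obs[:, sel], m.values[:, sel], 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            cols.append(np.where(n > 0, s / np.maximum(n, 1), np.nan))
        counts.append(n)
    prof = np.column_stack(cols)
    keep = ~np.isnan(prof).any(axis=1)
    if not keep.all():
        dropped = [m.gene_ids[i] for i in np.nonzero(~keep)[0]]
        logger.warning("supersample: dropped %d genes with an all-missing "
                       "group (e.g. %s); impute first to retain them",
                       len(dropped), dropped[:3])
    return pd.DataFrame(prof[keep], index=[gid for gid, k in
                                           zip(m.gene_ids, keep) if k],
                        columns=list(g.groups))


def reference_vectors(K: int, direction: str) -> np.ndarray:
    """K x K matrix of ideal patterns: rows are e_k (SG) or e_k (+) 1 (DSG)."""
    eye = np.eye(K)
    if direction == SG:
        return eye
    if direction == DSG:
        return 1.0 - eye
    raise ValueError(f"direction must be {SG!r} or {DSG!r}")


def _max_cosine(profiles: np.ndarray, refs: np.ndarray):
    """(best cosine, argmax reference index) per row, ties to smallest index."""
    norms = np.linalg.norm(profiles, axis=1, keepdims=True)
    ref_norms = np.linalg.norm(refs, axis=1)
    cos = (profiles @ refs.T) / (norms * ref_norms[None, :])
    best = np.argmax(cos, axis=1)  # argmax takes the first maximum
    return cos[np.arange(len(cos)), best], best


def cosine_scores(profiles: pd.DataFrame, direction: str = DSG) -> pd.DataFrame:
    """Max-over-k cosine statistic against the SG/DSG references.

    ``profiles`` is the genes x groups super-sample table.  All-zero
    profiles are excluded with a warning (their direction is undefined).
    Returns the score-table schema with p/q values unset.
    """
    mat = profiles.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("super-sample profiles must be nonnegative")
    nz = np.linalg.norm(mat, axis=1) > 0
    if not nz.all():
        logger.warning("cosine_scores: excluded %d all-zero profiles",
                       int((~nz).sum()))
    mat = mat[nz]
    genes = profiles.index[nz]
    refs = reference_vectors(profiles.shape[1], direction)
    score, best = _max_cosine(mat, refs)
    out = pd.DataFrame({
        "gene_id": genes.astype(str),
        "direction": direction,
        "assigned_group": [profiles.columns[b] for b in best],
        "score": score,
        "p_value": np.nan,
        "q_value": np.nan,
    })
    return _rank(out)


def _rank(table: pd.DataFrame) -> pd.DataFrame:
    table = table.sort_values(["score", "gene_id"],
                              ascending=[False, True], kind="stable")
    table = table.reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[SCORE_COLUMNS]


def empirical_null_pvalues(scores: pd.DataFrame, bh: bool = True) -> pd.DataFrame:
    """Self-inclusive upper-tail empirical p-values.

    ``p(i) = #{j : t_j >= t_i} / N`` over all scored genes — the
    empirical-histogram null under the assumption that most genes obey
    the null hypothesis.  Optionally appends Benjamini-Hochberg q-values.
    """
    out = scores.copy()
    t = out["score"].to_numpy(dtype=float)
    n = len(t)
    if n == 0:
        return out
    if n < 100:
        warnings.warn("empirical null from fewer than 100 genes is unstable",
                      stacklevel=2)
    order = np.sort(t)
    # #{t_j >= t_i} = n - (number strictly below t_i)
    below = np.searchsorted(order, t, side="left")
    out["p_value"] = (n - below) / n
    if bh:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def _group_rest_stats(m: OmicsMatrix, g: GroupLabels):
    gidx = g.indices(m.sample_ids)
    obs = ~m.mask
    vals = np.where(obs, m.values, np.nan)
    return gidx, vals


def ovr_ttest_scores(m: OmicsMatrix, g: GroupLabels,
                     direction: str = DSG) -> pd.DataFrame:
    """One-versus-rest Welch t-test comparator (log2 space).

    For each group ``k`` a Welch two-sample t compares group-``k``
    samples against the merged rest; the DSG score is ``max_k(-t_k)``
    (lower in ``k`` = positive evidence) and the SG score ``max_k(+t_k)``.
    Genes with zero variance on both sides get t = 0.
    """
    if m.space == LINEAR:
        m = to_log2(m, 1.0)
    g.check_cover(m.sample_ids)
    gidx, vals = _group_rest_stats(m, g)
    K = g.n_groups
    tmat = np.zeros((m.n_genes, K))
    for k in range(K):
        a = vals[:, gidx == k]
        b = vals[:, gidx != k]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=False,
                                  nan_policy="omit")
        t = np.asarray(res.statistic, dtype=float)
        tmat[:, k] = np.where(np.isfinite(t), t, 0.0)
    signed = -tmat if direction == DSG else tmat
    best = np.argmax(signed, axis=1)
    out = pd.DataFrame({
        "gene_id": m.gene_ids,
        "direction": direction,
        "assigned_group": [g.groups[b] for b in best],
        "score": signed[np.arange(len(best)), best],
        "p_value": np.nan,
        "q_value": np.nan,
    })
    return _rank(out)


def ovr_fc_scores(m: OmicsMatrix, g: GroupLabels, direction: str = DSG,
                  pseudocount: float | None = None) -> pd.DataFrame:
    """One-versus-rest fold-change comparator (linear space).

    DSG score = ``max_k mean_rest / (mean_k + pseudocount)``; SG score is
    the reciprocal ratio.  The pseudocount defaults to 1e-6 x the grand
    observed mean to keep ratios finite.
    """
    if m.space == LOG2:
        m = to_linear(m)
    g.check_cover(m.sample_ids)
    gidx, vals = _group_rest_stats(m, g)
    if pseudocount is None:
        grand = float(np.nanmean(vals))
        pseudocount = 1e-6 * grand if grand > 0 else 1e-6
    K = g.n_groups
    ratio = np.zeros((m.n_genes, K))
    with np.errstate(invalid="ignore"):
        for k in range(K):
            mk = np.nanmean(vals[:, gidx == k], axis=1)
            mr = np.nanmean(vals[:, gidx != k], axis=1)
            if direction == DSG:
                ratio[:, k] = mr / (mk + pseudocount)
            else:
                ratio[:, k] = mk / (mr + pseudocount)
    ratio = np.where(np.isfinite(ratio), ratio, 0.0)
    best = np.argmax(ratio, axis=1)
    out = pd.DataFrame({
        "gene_id": m.gene_ids,
        "direction": direction,
        "assigned_group": [g.groups[b] for b in best],
        "score": ratio[np.arange(len(best)), best],
        "p_value": np.nan,
        "q_value": np.nan,
    })
    return _rank(out)


def detect(scores: pd.DataFrame, rule: str, value: float) -> pd.DataFrame:
    """Filter a score table by ``top_n``, ``score_min`` or ``q_max``.

    Surviving rows are sorted by score descending within assigned group.
    """
    if rule == "top_n":
        keep = scores.sort_values(["score", "gene_id"],
                                  ascending=[False, True]).head(int(value))
    elif rule == "score_min":
        keep = scores[scores["score"] >= value]
    elif rule == "q_max":
        keep = scores[scores["q_value"] <= value]
    else:
        raise ValueError(f"unknown detection rule {rule!r}")
    keep = keep.sort_values(["assigned_group", "score", "gene_id"],
                            ascending=[True, False, True], kind="stable")
    return keep.reset_index(drop=True)


def score_genes(m: OmicsMatrix, g: GroupLabels, direction: str = DSG,
                method: str = "ecot") -> pd.DataFrame:
    """End-to-end scoring dispatch: ecot (cosine) | ovr-t | ovr-fc."""
    if method == "ecot":
        prof = supersample(m, g)
        return empirical_null_pvalues(cosine_scores(prof, direction))
    if method == "ovr-t":
        return ovr_ttest_scores(m, g, direction)
    if method == "ovr-fc":
        return ovr_fc_scores(m, g, direction)
    raise ValueError(f"unknown detection method {method!r}")
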