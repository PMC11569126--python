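"""Missing-value imputation for multi-group expression matrices.

The centrepiece is MGpI — mechanism-integrated group-wise pre-imputation.
Within each phenotypic group the observed log-intensities of a gene are
modelled as approximately normal; the probability ``alpha`` that a
missing value fell below the global lower limit of detection (LLOD
floor ``epsilon``) is the lower normal tail at ``epsilon``.  A missing
cell of gene ``i`` in group ``k`` is then imputed by the mechanism-
weighted blend

    x~_k(i) = alpha_k(i) * epsilon / 2 + (1 - alpha_k(i)) * xbar_k(i)

i.e. an "overall min / 2" fill for the LLOD/MNAR share and the
group-specific mean for the MAR/MCAR share.

Seven classical comparators are provided: half-minimum, per-gene mean,
sample-wise weighted kNN, and four low-rank matrix-completion methods
(PPCA, NIPALS, EM-SVD, SVT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .matrix import LINEAR, LOG2, GroupLabels, OmicsMatrix, to_linear, to_log2

__all__ = [
    "GroupModel",
    "ImputationResult",
    "normalize_on_complete_genes",
    "estimate_epsilon",
    "fit_group_model",
    "mgpi_impute",
    "halfmin_impute",
    "mean_impute",
    "swknn_impute",
    "lowrank_impute",
    "impute",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("mgpi", "min2", "mean", "swknn", "ppca", "nipals", "svd", "svt")

#: pseudocount used when a linear-space matrix must be moved to log2
#: internally (zeros are legal linear intensities).
LOG_PSEUDO = 1.0


@dataclass
class GroupModel:
    """Per-gene, per-group normal model plus the global LLOD floor.

    ``llod_prob[i, k]`` is ``Phi((epsilon - mean[i, k]) / sd[i, k])`` —
    the lower-tail mass below the detection floor.  All statistics are
    computed from observed entries only.
    """

    epsilon: float
    group_mean: np.ndarray  # genes x groups
    group_sd: np.ndarray    # genes x groups (ddof=1; NaN when n<2)
    llod_prob: np.ndarray   # genes x groups, in [0, 1]
    n_observed: np.ndarray  # genes x groups
    groups: list[str] = field(default_factory=list)


@dataclass
class ImputationResult:
    """A completed matrix; observed input cells are carried over exactly."""

    matrix: OmicsMatrix
    method: str
    params: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# MGpI


def normalize_on_complete_genes(m: OmicsMatrix, statistic: str = "median") -> OmicsMatrix:
    """Per-sample additive alignment in log space using complete genes.

    Samples are shifted so that each sample's ``statistic`` (median by
    default) over the genes with no missingness matches the grand
    statistic of the complete-gene submatrix.  Masked cells are untouched.
    """
    if m.space != LOG2:
        raise ValueError("normalization operates in log2 space")
    complete = ~m.mask.any(axis=1)
    if not complete.any():
        raise ValueError(
            "no gene is complete across all samples; pre-normalize the "
            "matrix externally before imputation")
    sub = m.values[complete]
    fn = np.median if statistic == "median" else np.mean
    grand = float(fn(sub))
    per_sample = fn(sub, axis=0)
    offsets = grand - per_sample
    out = m.copy()
    out.values = out.values + offsets[None, :]
    out.values[out.mask] = m.values[m.mask]
    return out


def estimate_epsilon(m: OmicsMatrix) -> float:
    """Global LLOD floor: the minimum over all observed log-space values."""
    if m.space != LOG2:
        raise ValueError("epsilon is defined on the log2-space matrix")
    obs = m.observed_values()
    if obs.size == 0:
        raise ValueError("matrix has no observed values")
    return float(obs.min())


def fit_group_model(m: OmicsMatrix, g: GroupLabels,
                    epsilon: float | None = None) -> GroupModel:
    """Estimate per-gene, per-group mean/SD and the LLOD probability.

    Degenerate cells follow the continuous limits of the imputation
    blend: a fully missing group gets ``alpha = 1`` (pure floor fill); a
    single observation uses the gene's pooled across-group SD; zero SD
    gives ``alpha = 1`` if the mean is at or below the floor, else 0.
    """
    if m.space != LOG2:
        raise ValueError("group model is fit in log2 space")
    g.check_cover(m.sample_ids)
    if epsilon is None:
        epsilon = estimate_epsilon(m)
    K = g.n_groups
    n_genes = m.n_genes
    gidx = g.indices(m.sample_ids)

    mean = np.full((n_genes, K), np.nan)
    sd = np.full((n_genes, K), np.nan)
    n_obs = np.zeros((n_genes, K), dtype=int)
    obs = ~m.mask
    for k in range(K):
        cols = gidx == k
        vals = m.values[:, cols]
        ok = obs[:, cols]
        n = ok.sum(axis=1)
        n_obs[:, k] = n
        with np.errstate(invalid="ignore"):
            s = np.where(ok, vals, 0.0).sum(axis=1)
            mu = np.where(n > 0, s / np.maximum(n, 1), np.nan)
            resid2 = np.where(ok, (vals - mu[:, None]) ** 2, 0.0).sum(axis=1)
            sdk = np.where(n > 1, np.sqrt(resid2 / np.maximum(n - 1, 1)), np.nan)
        mean[:, k] = mu
        sd[:, k] = sdk

    # pooled across-group SD per gene (groups with >=2 observations),
    # used as the spread for single-observation cells
    with np.errstate(invalid="ignore"):
        valid = ~np.isnan(sd)
        pooled = np.where(valid.any(axis=1),
                          np.sqrt(np.nansum(sd ** 2 * valid, axis=1)
                                  / np.maximum(valid.sum(axis=1), 1)),
                          np.nan)

    alpha = np.empty((n_genes, K))
    for k in range(K):
        mu = mean[:, k]
        sdk = sd[:, k].copy()
        single = n_obs[:, k] == 1
        sdk[single] = pooled[single]
        empty = n_obs[:, k] == 0
        degenerate = (~empty) & (np.isnan(sdk) | (sdk == 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            a = stats.norm.cdf((epsilon - mu) / sdk)
        a[degenerate] = np.where(mu[degenerate] <= epsilon, 1.0, 0.0)
        a[empty] = 1.0
        alpha[:, k] = a

    return GroupModel(epsilon=float(epsilon), group_mean=mean, group_sd=sd,
                      llod_prob=alpha, n_observed=n_obs, groups=list(g.groups))


def mgpi_impute(m: OmicsMatrix, g: GroupLabels,
                llod_fill: Literal["half_log_min", "log_of_half_linear_min"] = "half_log_min",
                normalize: bool = False) -> ImputationResult:
    """Mechanism-integrated group-wise pre-imputation.

    Operates in log2 space (a linear input is converted internally and
    converted back).  Every missing cell of gene ``i`` in group ``k``
    receives the same mechanism-weighted value; observed cells are
    returned exactly as given.

    Parameters
    ----------
    llod_fill
        ``"half_log_min"`` applies the floor fill literally in log space
        (``epsilon / 2``); ``"log_of_half_linear_min"`` uses the log of
        half the linear-space minimum (``epsilon - 1`` in log2).
    normalize
        Run the complete-gene per-sample alignment before fitting the
        model.  Off by default so that observed values pass through
        untouched; turn it on only when the matrix is not yet
        between-sample normalized (the fills are then computed on the
        aligned scale but mapped back to the input scale).
    """
    work, back = _to_log_space(m)
    fitted = normalize_on_complete_genes(work) if normalize else work
    model = fit_group_model(fitted, g)
    fill_floor = model.epsilon / 2 if llod_fill == "half_log_min" else model.epsilon - 1.0
    fills = model.llod_prob * fill_floor + (1.0 - model.llod_prob) * model.group_mean
    # fully missing group cells: mean is NaN but alpha == 1 -> pure floor
    fills = np.where(np.isnan(fills), fill_floor, fills)

    gidx = g.indices(work.sample_ids)
    out = work.copy()
    rows, cols = np.nonzero(work.mask)
    if normalize:
        # undo the per-sample offsets on the fills so output matches input scale
        offsets = fitted.values[~fitted.mask] - work.values[~work.mask]
        # offsets are per-sample constants; recover them column-wise
        col_off = np.zeros(work.n_samples)
        for j in range(work.n_samples):
            col_obs = ~work.mask[:, j]
            if col_obs.any():
                col_off[j] = fitted.values[col_obs, j][0] - work.values[col_obs, j][0]
        out.values[rows, cols] = fills[rows, gidx[cols]] - col_off[cols]
    else:
        out.values[rows, cols] = fills[rows, gidx[cols]]
    out.mask[:] = False
    res = back(out)
    _restore_observed(res, m)
    return ImputationResult(res, "mgpi", {
        "epsilon": model.epsilon, "llod_fill": llod_fill, "normalize": normalize})


# ----------------------------------------------------------------------
# simple per-gene comparators


def halfmin_impute(m: OmicsMatrix) -> ImputationResult:
    """Half-minimum fill: per-gene min/2 of observed linear intensities."""
    work = to_linear(m, LOG_PSEUDO) if m.space == LOG2 else m
    vals = work.masked_values()
    fully_missing = np.all(np.isnan(vals), axis=1)
    if fully_missing.any():
        gene = work.gene_ids[int(np.argmax(fully_missing))]
        raise ValueError(f"gene {gene!r} has no observed value")
    fill = np.nanmin(vals, axis=1) / 2.0
    out = work.copy()
    rows, cols = np.nonzero(work.mask)
    out.values[rows, cols] = fill[rows]
    out.mask[:] = False
    res = to_log2(out, LOG_PSEUDO) if m.space == LOG2 else out
    _restore_observed(res, m)
    return ImputationResult(res, "min2", {})


def mean_impute(m: OmicsMatrix) -> ImputationResult:
    """Per-gene observed-mean fill (computed in log2 space)."""
    work, back = _to_log_space(m)
    vals = work.masked_values()
    fully_missing = np.all(np.isnan(vals), axis=1)
    if fully_missing.any():
        gene = work.gene_ids[int(np.argmax(fully_missing))]
        raise ValueError(f"gene {gene!r} has no observed value")
    fill = np.nanmean(vals, axis=1)
    out = work.copy()
    rows, cols = np.nonzero(work.mask)
    out.values[rows, cols] = fill[rows]
    out.mask[:] = False
    res = back(out)
    _restore_observed(res, m)
    return ImputationResult(res, "mean", {})


def swknn_impute(m: OmicsMatrix, k: int = 10, delta: float = 1e-6) -> ImputationResult:
    """Sample-wise weighted k-nearest-neighbour fill.

    For a missing cell ``(i, s)`` the candidates are samples with gene
    ``i`` observed; distance is Euclidean over features co-observed in
    both samples and the fill is the ``1/(d + delta)``-weighted mean of
    the k nearest candidates' gene-``i`` values.  Cells with no usable
    neighbour fall back to the per-gene observed mean (logged).
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k >= m.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    work, back = _to_log_space(m)
    vals = work.masked_values()
    obs = ~work.mask
    gene_means = np.nanmean(np.where(obs, work.values, np.nan), axis=1)

    n = work.n_samples
    # pairwise distances over co-observed features
    dist = np.zeros((n, n))
    for a in range(n):
        co = obs[:, a][:, None] & obs
        diff = np.where(co, work.values[:, a][:, None] - work.values, 0.0)
        cnt = co.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[a] = np.sqrt((diff ** 2).sum(axis=0))
        dist[a, cnt == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    out = work.copy()
    n_fallback = 0
    rows, cols = np.nonzero(work.mask)
    for i, s in zip(rows, cols):
        cand = np.nonzero(obs[i] & np.isfinite(dist[s]))[0]
        if cand.size == 0:
            out.values[i, s] = gene_means[i]
            n_fallback += 1
            continue
        order = cand[np.argsort(dist[s, cand], kind="stable")][:k]
        w = 1.0 / (dist[s, order] + delta)
        out.values[i, s] = float(np.average(work.values[i, order], weights=w))
    if n_fallback:
        logger.warning("swknn: %d cells had no co-observed neighbour; "
                       "used per-gene mean", n_fallback)
    out.mask[:] = False
    res = back(out)
    _restore_observed(res, m)
    return ImputationResult(res, "swknn", {"k": k, "n_fallback": n_fallback})


# ----------------------------------------------------------------------
# low-rank matrix completion


def _default_rank(filled: np.ndarray, var_target: float = 0.9) -> int:
    """Smallest rank explaining ``var_target`` of the mean-filled variance."""
    centered = filled - filled.mean(axis=1, keepdims=True)
    svals = np.linalg.svd(centered, compute_uv=False)
    energy = np.cumsum(svals ** 2) / max(np.sum(svals ** 2), np.finfo(float).tiny)
    rank = int(np.searchsorted(energy, var_target) + 1)
    return max(1, min(rank, min(filled.shape) - 1))


def _mean_fill(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    nanned = np.where(mask, np.nan, vals)
    gene_mean = np.nanmean(nanned, axis=1)
    gene_mean = np.where(np.isnan(gene_mean), np.nanmean(nanned), gene_mean)
    filled = vals.copy()
    rows, cols = np.nonzero(mask)
    filled[rows, cols] = gene_mean[rows]
    return filled


def lowrank_impute(m: OmicsMatrix, method: str = "svd", rank: int | None = None,
                   tol: float = 1e-6, max_iter: int = 500,
                   seed: int | None = None, tau: float | None = None,
                   step: float = 1.0) -> ImputationResult:
    """Low-rank matrix completion (ppca | nipals | svd | svt).

    All four alternate between reconstructing the matrix from a low-rank
    model and overwriting the missing cells with the reconstruction,
    until the imputed cells move less than ``tol`` (Frobenius) or
    ``max_iter`` is hit.  Observed cells are restored exactly at the end.
    """
    if method not in ("ppca", "nipals", "svd", "svt"):
        raise ValueError(f"unknown low-rank method {method!r}")
    if method == "ppca" and seed is None:
        raise ValueError("ppca requires a seed for its random initialization")
    work, back = _to_log_space(m)
    vals, mask = work.values.copy(), work.mask
    if not mask.any():
        res = back(work.copy())
        res.mask[:] = False
        _restore_observed(res, m)
        return ImputationResult(res, method, {"rank": rank, "converged": True})

    filled = _mean_fill(vals, mask)
    if rank is None:
        rank = _default_rank(filled)
    if rank >= min(vals.shape):
        raise ValueError("rank must be below min(genes, samples)")

    params: dict = {"rank": rank, "tol": tol, "max_iter": max_iter}
    if method == "svt":
        if tau is not None:
            params["tau"] = tau
        params["step"] = step
        filled, converged, iters = _svt_complete(vals, mask, filled, tol, max_iter, params)
    elif method == "nipals":
        filled, converged, iters = _nipals_complete(vals, mask, filled, rank, tol, max_iter)
    elif method == "ppca":
        filled, converged, iters = _ppca_complete(vals, mask, filled, rank, tol,
                                                  max_iter, seed)
    else:  # EM-SVD
        filled, converged, iters = _emsvd_complete(vals, mask, filled, rank, tol, max_iter)
    params.update({"converged": converged, "iterations": iters})
    if not converged:
        logger.warning("%s did not converge in %d iterations", method, max_iter)

    out = work.copy()
    out.values = filled
    out.mask = np.zeros_like(mask)
    res = back(out)
    _restore_observed(res, m)
    return ImputationResult(res, method, params)


def _iterate(filled, mask, reconstruct, tol, max_iter):
    prev = filled[mask]
    for it in range(1, max_iter + 1):
        recon = reconstruct(filled)
        filled = np.where(mask, recon, filled)
        cur = filled[mask]
        if np.linalg.norm(cur - prev) < tol:
            return filled, True, it
        prev = cur
    return filled, False, max_iter


def _emsvd_complete(vals, mask, filled, rank, tol, max_iter):
    def reconstruct(x):
        mu = x.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(x - mu, full_matrices=False)
        return mu + (u[:, :rank] * s[:rank]) @ vt[:rank]
    return _iterate(filled, mask, reconstruct, tol, max_iter)


def _ppca_complete(vals, mask, filled, rank, tol, max_iter, seed):
    """EM for probabilistic PCA with the missing cells as extra latents.

    Each M-step uses the closed-form ML solution (principal eigenvectors
    scaled by eigenvalue minus noise variance); the E-step replaces the
    missing cells by the model reconstruction.  Random rotation of the
    start point comes from ``seed``.
    """
    rng = np.random.default_rng(seed)
    filled = filled + rng.normal(0.0, 1e-6, size=filled.shape) * mask

    def reconstruct(x):
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        n = x.shape[1]
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        eigvals = s ** 2 / n
        noise = float(np.mean(eigvals[rank:])) if eigvals.size > rank else 0.0
        w = u[:, :rank] * np.sqrt(np.maximum(eigvals[:rank] - noise, 0.0))
        # posterior mean of latents: (W'W + noise I)^-1 W' xc
        mmat = w.T @ w + noise * np.eye(rank)
        z = np.linalg.solve(mmat, w.T @ xc)
        return mu + w @ z
    return _iterate(filled, mask, reconstruct, tol, max_iter)


def _nipals_complete(vals, mask, filled, rank, tol, max_iter):
    """NIPALS PCA with missing-data-tolerant score/loading regressions."""
    obs = ~mask
    nanned = np.where(obs, vals, np.nan)
    mu = np.nanmean(nanned, axis=1, keepdims=True)
    resid = np.where(obs, vals - mu, 0.0)
    recon = np.zeros_like(vals)
    for _ in range(rank):
        # initialize loading from the column with most observed mass
        j0 = int(np.argmax((resid ** 2).sum(axis=0)))
        t = resid[:, j0].copy()
        p = np.zeros(vals.shape[1])
        for _ in range(max_iter):
            denom = (t ** 2)[:, None] * obs
            p_new = (resid * t[:, None] * obs).sum(axis=0) / np.maximum(
                denom.sum(axis=0), np.finfo(float).tiny)
            nrm = np.linalg.norm(p_new)
            if nrm == 0:
                break
            p_new /= nrm
            t_new = (resid * p_new[None, :] * obs).sum(axis=1) / np.maximum(
                ((p_new ** 2)[None, :] * obs).sum(axis=1), np.finfo(float).tiny)
            if np.linalg.norm(t_new - t) < tol * max(np.linalg.norm(t), 1.0):
                t, p = t_new, p_new
                break
            t, p = t_new, p_new
        recon = recon + np.outer(t, p)
        resid = np.where(obs, resid - np.outer(t, p), 0.0)
    filled = np.where(mask, mu + recon, vals)
    return filled, True, rank


def _svt_complete(vals, mask, filled, tol, max_iter, params):
    """Singular value thresholding by dual ascent (nuclear-norm completion).

    ``X = S_tau(Y); Y <- Y + step * P_obs(M - X)``: the dual update
    forces the observed residual to zero, so the shrinkage bias of the
    threshold vanishes at convergence.  Threshold tau defaults to 0.1 x
    the largest singular value of the mean-filled matrix, step size 1.
    """
    obs = ~mask
    tau = params.get("tau")
    if tau is None:
        tau = 0.1 * np.linalg.svd(filled, compute_uv=False)[0]
        params["tau"] = float(tau)
    step = params.get("step", 1.0)

    y = np.where(obs, vals, 0.0)
    prev = filled[mask]
    for it in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(y, full_matrices=False)
        x = (u * np.maximum(s - tau, 0.0)) @ vt
        y = y + step * np.where(obs, vals - x, 0.0)
        cur = x[mask]
        if np.linalg.norm(cur - prev) < tol:
            return np.where(mask, x, vals), True, it
        prev = cur
    return np.where(mask, x, vals), False, max_iter


# ----------------------------------------------------------------------
# shared helpers / dispatch


def _to_log_space(m: OmicsMatrix):
    """Return (log2-space matrix, function mapping a result back)."""
    if m.space == LOG2:
        return m, (lambda x: x)
    return to_log2(m, LOG_PSEUDO), (lambda x: to_linear(x, LOG_PSEUDO))


def _restore_observed(res: OmicsMatrix, original: OmicsMatrix) -> None:
    """Copy originally observed entries back bit-identically."""
    obs = ~original.mask
    res.values[obs] = original.values[obs]


def impute(m: OmicsMatrix, method: str, g: GroupLabels | None = None,
           **kwargs) -> ImputationResult:
    """Dispatch by method name (``METHODS``)."""
    if method == "mgpi":
        if g is None:
            raise ValueError("mgpi requires group labels")
        return mgpi_impute(m, g, **kwargs)
    if method == "min2":
        return halfmin_impute(m)
    if method == "mean":
        return mean_impute(m)
    if method == "swknn":
        return swknn_impute(m, **kwargs)
    if method in ("ppca", "nipals", "svd", "svt"):
        return lowrank_impute(m, method=method, **kwargs)
    raise ValueError(f"unknown imputation method {method!r}; choose from {METHODS}")
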