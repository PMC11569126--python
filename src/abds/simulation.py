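"""Ground-truth simulation designs for benchmarking the suite.

Two generators mirror the study conditions the methods are evaluated
under:

* **Simplex profile design** (detection benchmarking): K = 3-5 groups;
  null genes are a mixture of a flat symmetric Dirichlet (alpha = 1,
  1200 genes) and a centre-peaked Dirichlet (alpha = 4, 1200 genes);
  signature genes are truncated-Gaussian clusters around the simplex
  vertices (20 per group) and downregulated signatures around the facet
  centres (50 per group).  Profiles are expanded to per-sample replicates
  with per-gene log-normal magnitudes and truncated additive noise.

* **Mixed-mechanism missingness injection** (imputation benchmarking):
  an overall missing rate of 40-60% of eligible entries, of which
  30-50% are MAR (uniform over remaining eligible cells) and the rest
  LLOD (the lowest-intensity cells).  Because LLOD removes low
  intensities, a signature gene automatically loses values by LLOD in
  its silent groups and by MAR in its expressed group.

A separate panel generator draws signature genes at exact target
cosines (0.7-0.95 by default), matching the proteomics-style design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LINEAR, GroupLabels, MissingnessTruth, OmicsMatrix

__all__ = [
    "SimplexSimConfig",
    "MissingnessConfig",
    "simulate_simplex_profiles",
    "expand_to_samples",
    "generate_sg_panel",
    "inject_missingness",
    "simulate_dataset",
]

CLASS_NULL_FLAT = "null_flat"
CLASS_NULL_PEAKED = "null_peaked"
CLASS_SG = "SG"
CLASS_DSG = "DSG"


@dataclass
class SimplexSimConfig:
    """Design constants for the simplex profile simulation.

    The default counts are the benchmark design: 1200 flat-Dirichlet
    nulls, 1200 alpha=4 Dirichlet nulls, 20 vertex SGs and 50 facet DSGs
    per group.  Noise SDs, magnitude law and replicate counts are the
    package's declared defaults (exposed, not hard-wired).
    """

    K: int = 3
    n_null_flat: int = 1200
    n_null_peaked: int = 1200
    n_sg_per_group: int = 20
    n_dsg_per_group: int = 50
    vertex_noise_sd: float = 0.01
    facet_noise_sd: float = 0.01
    group_sizes: tuple[int, ...] | None = None  # default 10 per group
    magnitude_meanlog: float = 5.0
    magnitude_sdlog: float = 1.0
    replicate_noise_sd: float = 0.02
    seed: int = 0

    def resolved_group_sizes(self) -> tuple[int, ...]:
        if self.group_sizes is None:
            return tuple([10] * self.K)
        if len(self.group_sizes) != self.K:
            raise ValueError("group_sizes length must equal K")
        return tuple(self.group_sizes)


@dataclass
class MissingnessConfig:
    """Missingness injection parameters.

    ``overall_rate`` is the fraction of eligible entries to mask
    (benchmarked range 0.40-0.60) and ``mar_proportion`` the MAR share
    of the masked set (0.30-0.50); the remainder is LLOD censoring.
    """

    overall_rate: float = 0.5
    mar_proportion: float = 0.4
    mode: str = "threshold_llod"  # or "probabilistic_llod"
    nonzero_only: bool = False
    min_observed_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overall_rate <= 1.0:
            raise ValueError("overall_rate must be in [0, 1]")
        if not 0.0 <= self.mar_proportion <= 1.0:
            raise ValueError("mar_proportion must be in [0, 1]")
        if self.mode not in ("threshold_llod", "probabilistic_llod"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _truncated_cluster(center: np.ndarray, sd: float, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian around ``center``, reflected at 0, renormalized."""
    pts = np.abs(center[None, :] + rng.normal(0.0, sd, size=(n, center.size)))
    return pts / pts.sum(axis=1, keepdims=True)


def simulate_simplex_profiles(cfg: SimplexSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the mixture of null and signature profiles on the simplex.

    Returns ``(profiles, truth)``: a genes x K DataFrame of simplex
    profiles (rows sum to 1) and a truth table with columns ``gene_id``,
    ``class``, ``true_group``, ``true_cosine``.
    """
    K = cfg.K
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    rows, classes, true_groups, true_cos = [], [], [], []

    flat = rng.dirichlet(np.ones(K), size=cfg.n_null_flat)
    rows.append(flat)
    classes += [CLASS_NULL_FLAT] * cfg.n_null_flat
    true_groups += [""] * cfg.n_null_flat
    true_cos += [np.nan] * cfg.n_null_flat

    peaked = rng.dirichlet(np.full(K, 4.0), size=cfg.n_null_peaked)
    rows.append(peaked)
    classes += [CLASS_NULL_PEAKED] * cfg.n_null_peaked
    true_groups += [""] * cfg.n_null_peaked
    true_cos += [np.nan] * cfg.n_null_peaked

    eye = np.eye(K)
    for k in range(K):
        sg = _truncated_cluster(eye[k], cfg.vertex_noise_sd, cfg.n_sg_per_group, rng)
        rows.append(sg)
        classes += [CLASS_SG] * cfg.n_sg_per_group
        true_groups += [f"G{k + 1}"] * cfg.n_sg_per_group
        cosines = sg[:, k] / np.linalg.norm(sg, axis=1)
        true_cos += list(cosines)
    for k in range(K):
        center = (1.0 - eye[k]) / (K - 1)
        dsg = _truncated_cluster(center, cfg.facet_noise_sd, cfg.n_dsg_per_group, rng)
        rows.append(dsg)
        classes += [CLASS_DSG] * cfg.n_dsg_per_group
        true_groups += [f"G{k + 1}"] * cfg.n_dsg_per_group
        ref = 1.0 - eye[k]
        cosines = (dsg @ ref) / (np.linalg.norm(dsg, axis=1) * np.linalg.norm(ref))
        true_cos += list(cosines)

    mat = np.vstack(rows) if rows else np.empty((0, K))
    gene_ids = [f"g{i + 1:05d}" for i in range(mat.shape[0])]
    profiles = pd.DataFrame(mat, index=gene_ids, columns=[f"G{k + 1}" for k in range(K)])
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "class": classes,
        "true_group": true_groups,
        "true_cosine": true_cos,
    })
    return profiles, truth


def expand_to_samples(profiles: pd.DataFrame,
                      cfg: SimplexSimConfig) -> tuple[OmicsMatrix, GroupLabels]:
    """Expand simplex profiles to per-sample linear-space replicates.

    Sample ``s`` in group ``k`` for gene ``i`` receives
    ``m_i * max(0, p_ik + N(0, replicate_noise_sd^2))`` with a per-gene
    log-normal magnitude ``m_i``.  A fresh generator seeded from
    ``cfg.seed + 1`` keeps the expansion independent of the profile draw.
    """
    K = profiles.shape[1]
    if K != cfg.K:
        raise ValueError("profiles width does not match cfg.K")
    sizes = cfg.resolved_group_sizes()
    rng = np.random.default_rng(cfg.seed + 1)
    mags = rng.lognormal(cfg.magnitude_meanlog, cfg.magnitude_sdlog,
                         size=profiles.shape[0])
    cols, labels = [], []
    sample_ids = []
    for k, (gname, nk) in enumerate(zip(profiles.columns, sizes)):
        base = profiles.to_numpy()[:, k][:, None]
        noise = rng.normal(0.0, cfg.replicate_noise_sd, size=(profiles.shape[0], nk)) \
            if cfg.replicate_noise_sd > 0 else np.zeros((profiles.shape[0], nk))
        cols.append(np.maximum(base + noise, 0.0) * mags[:, None])
        ids = [f"{gname}_s{j + 1}" for j in range(nk)]
        sample_ids += ids
        labels += [(sid, gname) for sid in ids]
    vals = np.hstack(cols)
    m = OmicsMatrix(vals, np.zeros_like(vals, dtype=bool), LINEAR,
                    list(profiles.index), sample_ids)
    return m, GroupLabels.from_pairs(labels)


def generate_sg_panel(K: int, n_per_group: int,
                      cosine_range: tuple[float, float] = (0.7, 0.95),
                      seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signature-gene panel with exact target cosines.

    For each SG of group ``k`` a target cosine ``c ~ U(lo, hi)`` is
    drawn and a nonnegative unit profile built with on-target component
    ``c`` and the off-target mass a random nonnegative direction of norm
    ``sqrt(1 - c^2)``, so ``cos(profile, e_k) = c`` exactly.
    """
    lo, hi = cosine_range
    if not (1.0 / np.sqrt(K) < lo <= hi < 1.0):
        raise ValueError(f"cosine range must satisfy 1/sqrt(K) < lo <= hi < 1 "
                         f"for K={K}")
    rng = np.random.default_rng(seed)
    rows, gene_ids, groups, targets = [], [], [], []
    for k in range(K):
        for j in range(n_per_group):
            c = float(rng.uniform(lo, hi))
            off = np.abs(rng.normal(size=K - 1))
            nrm = np.linalg.norm(off)
            while nrm == 0:  # vanishing draw; retry
                off = np.abs(rng.normal(size=K - 1))
                nrm = np.linalg.norm(off)
            off = off / nrm * np.sqrt(1.0 - c * c)
            prof = np.insert(off, k, c)
            rows.append(prof)
            gene_ids.append(f"sg{k + 1}_{j + 1:03d}")
            groups.append(f"G{k + 1}")
            targets.append(c)
    profiles = pd.DataFrame(np.vstack(rows), index=gene_ids,
                            columns=[f"G{k + 1}" for k in range(K)])
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "class": CLASS_SG,
        "true_group": groups,
        "true_cosine": targets,
    })
    return profiles, truth


def inject_missingness(m: OmicsMatrix, cfg: MissingnessConfig
                       ) -> tuple[OmicsMatrix, MissingnessTruth]:
    """Mask observed entries under the mixed LLOD + MAR design.

    ``threshold_llod`` masks exactly the ``n_llod`` lowest-valued
    eligible entries (ties broken by row-major position), then
    ``n_mar`` uniformly random remaining entries.
    ``probabilistic_llod`` instead samples the LLOD set without
    replacement with logistic weights decreasing in intensity (matched
    in expectation), trading exact determinism of the censored set for
    a softer, more realistic threshold.

    Every gene keeps at least ``cfg.min_observed_per_gene`` observed
    entries (entries that would violate the guard are skipped in favour
    of the next candidate), so downstream per-gene statistics stay
    defined; totals remain exact whenever the guard leaves room.
    """
    eligible = ~m.mask
    if cfg.nonzero_only:
        eligible &= m.values != 0
    flat = np.flatnonzero(eligible.ravel())
    n_eligible = flat.size
    if n_eligible == 0:
        raise ValueError("no eligible entries to mask")
    n_miss = int(round(cfg.overall_rate * n_eligible))
    if n_miss >= n_eligible and n_miss > 0:
        raise ValueError("overall_rate leaves no observed remainder")
    n_llod = int(round((1.0 - cfg.mar_proportion) * n_miss))
    n_mar = n_miss - n_llod

    n_samples = m.shape[1]
    # observed count per gene, updated as entries are masked
    obs_left = (~m.mask).sum(axis=1).astype(int)
    floor_obs = max(0, int(cfg.min_observed_per_gene))

    def take(candidates: np.ndarray, want: int) -> np.ndarray:
        chosen = []
        for idx in candidates:
            if len(chosen) == want:
                break
            r = idx // n_samples
            if obs_left[r] - 1 < floor_obs:
                continue
            obs_left[r] -= 1
            chosen.append(idx)
        if len(chosen) < want:
            raise ValueError(
                "cannot reach the requested missing rate while keeping "
                f"{floor_obs} observed value(s) per gene")
        return np.asarray(chosen, dtype=int)

    vals = m.values.ravel()[flat]
    rng = np.random.default_rng(cfg.seed)
    if cfg.mode == "threshold_llod":
        order = np.lexsort((flat, vals))  # value asc, position asc on ties
        llod_idx = take(flat[order], n_llod)
    else:
        center = np.quantile(vals, (1.0 - cfg.mar_proportion) * cfg.overall_rate) \
            if n_llod else vals.min()
        scale = max(np.std(vals) * 0.25, np.finfo(float).tiny)
        w = 1.0 / (1.0 + np.exp((vals - center) / scale))
        w = w / w.sum()
        ranked = rng.choice(flat, size=n_eligible, replace=False, p=w)
        llod_idx = take(ranked, n_llod)
    remaining = np.setdiff1d(flat, llod_idx, assume_unique=False)
    mar_idx = take(rng.permutation(remaining), n_mar) if n_mar else \
        np.empty(0, dtype=int)

    out = m.copy()
    entries = []
    for idx_set, mech in ((llod_idx, "LLOD"), (mar_idx, "MAR")):
        rows, cols = np.unravel_index(np.asarray(idx_set, dtype=int), m.shape)
        for r, c in zip(rows, cols):
            entries.append((m.gene_ids[r], m.sample_ids[c], m.values[r, c], mech))
        out.mask[rows, cols] = True
    out.values[out.mask] = 0.0
    truth = MissingnessTruth(pd.DataFrame(entries, columns=list(MissingnessTruth.COLUMNS)))
    return out, truth


def simulate_dataset(cfg: SimplexSimConfig
                     ) -> tuple[OmicsMatrix, GroupLabels, pd.DataFrame]:
    """Profiles + expansion in one call: (matrix, labels, truth)."""
    profiles, truth = simulate_simplex_profiles(cfg)
    m, g = expand_to_samples(profiles, cfg)
    return m, g, truth


def simulate_sg_panel_dataset(K: int = 4, n_sg_per_group: int = 30,
                              n_background: int = 593,
                              group_sizes: tuple[int, ...] = (10, 20, 30, 10),
                              cosine_range: tuple[float, float] = (0.7, 0.95),
                              seed: int = 0
                              ) -> tuple[OmicsMatrix, GroupLabels, pd.DataFrame]:
    """Proteomics-style panel: SGs at exact target cosines + background.

    Defaults follow the four-group artery benchmark: 30 SGs per group
    with cosines 0.7-0.95, background features filling the panel to 713,
    and imbalanced group sizes (10, 20, 30, 10).  Background profiles
    are flat-Dirichlet draws.  Returns (matrix, labels, truth).
    """
    sg_prof, sg_truth = generate_sg_panel(K, n_sg_per_group, cosine_range, seed)
    # normalize SG profiles onto the simplex for consistent expansion
    sg_mat = sg_prof.to_numpy()
    sg_mat = sg_mat / sg_mat.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed + 7)
    bg = rng.dirichlet(np.ones(K), size=n_background)
    gene_ids = list(sg_prof.index) + [f"bg{i + 1:04d}" for i in range(n_background)]
    profiles = pd.DataFrame(np.vstack([sg_mat, bg]), index=gene_ids,
                            columns=list(sg_prof.columns))
    truth = pd.concat([sg_truth, pd.DataFrame({
        "gene_id": gene_ids[len(sg_prof):],
        "class": CLASS_NULL_FLAT,
        "true_group": "",
        "true_cosine": np.nan,
    })], ignore_index=True)
    cfg = SimplexSimConfig(K=K, group_sizes=tuple(group_sizes), seed=seed)
    m, g = expand_to_samples(profiles, cfg)
    return m, g, truth
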