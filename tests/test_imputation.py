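"""Group-wise mechanism-aware imputation and the classical comparators."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_masked_matrix
from abds.imputation import (estimate_epsilon, fit_group_model, halfmin_impute,
                             impute, lowrank_impute, mean_impute, mgpi_impute,
                             normalize_on_complete_genes, swknn_impute)
from abds.matrix import LINEAR, LOG2, GroupLabels, OmicsMatrix


def normal_cdf(z: float) -> float:
    """Independent lower-tail normal CDF via the error function."""
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def make(vals, mask, space=LOG2, genes=None, samples=None):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    samples = samples or [f"s{j}" for j in range(vals.shape[1])]
    return OmicsMatrix(vals, np.asarray(mask, bool), space, genes, samples)


# ------------------------------------------------------------- normalization

def test_normalize_matches_sample_medians_to_grand_median():
    # complete genes with per-sample medians 5 and 7; grand median 6
    vals = np.array([[4.0, 6.0], [5.0, 7.0], [6.0, 8.0], [1.0, 0.0]])
    mask = np.zeros((4, 2), bool)
    mask[3, 1] = True  # gene 4 incomplete -> excluded from the fit
    m = make(vals, mask)
    out = normalize_on_complete_genes(m)
    np.testing.assert_allclose(out.values[:3, 0] - vals[:3, 0], 1.0)
    np.testing.assert_allclose(out.values[:3, 1] - vals[:3, 1], -1.0)
    # masked cell untouched
    assert out.values[3, 1] == vals[3, 1]


def test_normalize_identity_when_aligned():
    vals = np.array([[4.0, 4.0], [5.0, 5.0], [6.0, 6.0]])
    m = make(vals, np.zeros_like(vals, bool))
    out = normalize_on_complete_genes(m)
    np.testing.assert_allclose(out.values, vals)


def test_normalize_single_complete_gene_aligns_it():
    vals = np.array([[3.0, 5.0], [1.0, 0.0]])
    mask = np.array([[False, False], [False, True]])
    out = normalize_on_complete_genes(make(vals, mask))
    assert out.values[0, 0] == out.values[0, 1]


def test_normalize_requires_a_complete_gene():
    mask = np.array([[True, False], [False, True]])
    with pytest.raises(ValueError, match="complete"):
        normalize_on_complete_genes(make([[0, 1], [2, 0]], mask))


# ------------------------------------------------------------------ epsilon

def test_epsilon_is_min_observed_and_ignores_masked():
    m = make([[3.2, 5.0], [7.1, -100.0]], [[False, False], [False, True]])
    assert estimate_epsilon(m) == 3.2
    const = make([[2.0, 2.0]], [[False, False]])
    assert estimate_epsilon(const) == 2.0


# -------------------------------------------------------------- group model

def test_group_stats_two_point():
    m = make([[4.0, 6.0, 1.0, 1.0]], [[False, False, False, False]])
    g = GroupLabels.from_pairs([("s0", "A"), ("s1", "A"), ("s2", "B"), ("s3", "B")])
    model = fit_group_model(m, g)
    assert model.group_mean[0, 0] == pytest.approx(5.0)
    assert model.group_sd[0, 0] == pytest.approx(math.sqrt(2.0))


def test_alpha_matches_independent_cdf_oracle():
    # epsilon = 2 (observed floor), group A {4, 6, 8}: mean 6, sd 2
    vals = np.array([[4.0, 6.0, 8.0, 2.0, 2.0]])
    m = make(vals, np.zeros_like(vals, bool))
    g = GroupLabels.from_pairs([("s0", "A"), ("s1", "A"), ("s2", "A"),
                                ("s3", "B"), ("s4", "B")])
    model = fit_group_model(m, g)
    assert model.epsilon == 2.0
    expected = normal_cdf((2.0 - 6.0) / 2.0)  # Phi(-2) ~ 0.02275
    assert model.llod_prob[0, 0] == pytest.approx(expected, abs=1e-6)
    assert expected == pytest.approx(0.02275, abs=1e-5)


def test_fully_missing_group_gets_alpha_one():
    vals = np.array([[0.0, 0.0, 5.0, 6.0]])
    mask = np.array([[True, True, False, False]])
    g = GroupLabels.from_pairs([("s0", "A"), ("s1", "A"), ("s2", "B"), ("s3", "B")])
    model = fit_group_model(make(vals, mask), g)
    assert model.llod_prob[0, 0] == 1.0
    assert model.n_observed[0, 0] == 0


def test_zero_sd_alpha_degenerate():
    # group A constant at the floor -> alpha 1; group B constant above -> alpha 0
    vals = np.array([[2.0, 2.0, 6.0, 6.0]])
    g = GroupLabels.from_pairs([("s0", "A"), ("s1", "A"), ("s2", "B"), ("s3", "B")])
    model = fit_group_model(make(vals, np.zeros_like(vals, bool)), g)
    assert model.llod_prob[0, 0] == 1.0
    assert model.llod_prob[0, 1] == 0.0


# --------------------------------------------------------------------- MGpI

def mgpi_fill_for(vals, mask, groups):
    m = make(vals, mask)
    g = GroupLabels.from_pairs(groups)
    return mgpi_impute(m, g)


def test_mgpi_limits_and_hand_case():
    # gene 1 group A: mean 6, sd 2; global epsilon 2 from gene 2
    vals = np.array([[4.0, 8.0, 7.0, 0.0], [2.0, 3.0, 2.5, 3.5]])
    mask = np.zeros((2, 4), bool)
    mask[0, 3] = True
    groups = [("s0", "A"), ("s1", "A"), ("s2", "B"), ("s3", "B")]
    res = mgpi_fill_for(vals, mask, groups)
    alpha = normal_cdf((2.0 - 6.0) / 2.0)
    # fill in group B of gene 1: alpha from (mean 7, sd from pooled), but the
    # masked cell shares group B whose observed value is s2 only
    model = fit_group_model(make(vals, mask),
                            GroupLabels.from_pairs(groups))
    a_b = model.llod_prob[0, 1]
    expected = a_b * 1.0 + (1 - a_b) * 7.0
    assert res.matrix.values[0, 3] == pytest.approx(expected, abs=1e-9)
    # hand case for the blend itself
    assert alpha * 1.0 + (1 - alpha) * 6.0 == pytest.approx(5.88626, abs=1e-4)


def test_mgpi_alpha_extremes():
    # group B fully missing -> pure floor fill epsilon/2
    vals = np.array([[6.0, 6.0, 0.0, 0.0], [2.0, 2.2, 2.4, 2.6]])
    mask = np.zeros((2, 4), bool)
    mask[0, 2] = mask[0, 3] = True
    res = mgpi_fill_for(vals, mask,
                        [("s0", "A"), ("s1", "A"), ("s2", "B"), ("s3", "B")])
    assert res.matrix.values[0, 2] == pytest.approx(1.0)  # epsilon/2 = 1
    assert res.matrix.values[0, 3] == pytest.approx(1.0)
    # group far above the floor: alpha ~ 0 -> fill ~ group mean
    vals2 = np.array([[20.0, 20.2, 20.4, 0.0], [2.0, 2.2, 2.4, 2.6]])
    mask2 = np.zeros((2, 4), bool)
    mask2[0, 3] = True
    res2 = mgpi_fill_for(vals2, mask2,
                         [("s0", "A"), ("s1", "B"), ("s2", "B"), ("s3", "B")])
    assert res2.matrix.values[0, 3] == pytest.approx(20.3, abs=1e-6)


def test_mgpi_fill_lies_between_floor_and_group_mean(rng):
    m = random_masked_matrix(rng, n_genes=40, n_samples=10)
    g = GroupLabels.from_pairs([(f"s{j}", "A" if j < 5 else "B") for j in range(10)])
    model = fit_group_model(m, g)
    res = mgpi_impute(m, g)
    gidx = g.indices(m.sample_ids)
    lo_hi = np.sort(np.stack([
        np.full_like(model.group_mean, model.epsilon / 2),
        model.group_mean]), axis=0)
    rows, cols = np.nonzero(m.mask)
    fills = res.matrix.values[rows, cols]
    ks = gidx[cols]
    assert np.all(fills >= lo_hi[0][rows, ks] - 1e-12)
    assert np.all(fills <= lo_hi[1][rows, ks] + 1e-12)


def test_mgpi_groupwise_behavior_for_signature_gene():
    """SG high in group 1, near the floor elsewhere: fills track mechanism."""
    rng = np.random.default_rng(0)
    high = rng.normal(12.0, 0.5, size=8)
    low = rng.normal(2.05, 0.05, size=8)
    vals = np.vstack([np.concatenate([high, low]),
                      rng.normal(7, 1, size=16)])
    vals[1, 0] = 2.0  # global floor from a background gene
    mask = np.zeros_like(vals, bool)
    mask[0, 0] = True   # missing in the high group (MAR-like)
    mask[0, 8] = True   # missing in the low group (LLOD-like)
    groups = [(f"s{j}", "HI" if j < 8 else "LO") for j in range(16)]
    m = make(vals, mask)
    g = GroupLabels.from_pairs(groups)
    model = fit_group_model(m, g)
    res = mgpi_impute(m, g)
    hi_fill = res.matrix.values[0, 0]
    lo_fill = res.matrix.values[0, 8]
    hi_mean = vals[0, 1:8].mean()
    lo_mean = vals[0, 9:].mean()
    assert abs(hi_fill - hi_mean) < 1e-6          # alpha ~ 0 -> group mean
    assert model.llod_prob[0, 1] > 100 * model.llod_prob[0, 0]
    assert lo_fill < lo_mean                      # pulled toward the floor fill


# ---------------------------------------------------------------- half-min

def test_halfmin_examples():
    m = make([[4.0, 8.0, 0.0]], [[False, False, True]], space=LINEAR)
    assert halfmin_impute(m).matrix.values[0, 2] == pytest.approx(2.0)
    m2 = make([[0.5, 0.0]], [[False, True]], space=LINEAR)
    assert halfmin_impute(m2).matrix.values[0, 1] == pytest.approx(0.25)


def test_halfmin_identity_without_missing():
    m = make([[4.0, 8.0]], [[False, False]], space=LINEAR)
    np.testing.assert_array_equal(halfmin_impute(m).matrix.values, m.values)


def test_halfmin_fully_missing_gene_errors():
    m = make([[0.0, 0.0], [1.0, 2.0]], [[True, True], [False, False]],
             space=LINEAR)
    with pytest.raises(ValueError, match="g0"):
        halfmin_impute(m)


# --------------------------------------------------------------------- mean

def test_mean_impute_examples():
    m = make([[4.0, 8.0, 0.0]], [[False, False, True]])
    assert mean_impute(m).matrix.values[0, 2] == pytest.approx(6.0)
    single = make([[3.0, 0.0]], [[False, True]])
    assert mean_impute(single).matrix.values[0, 1] == pytest.approx(3.0)


# -------------------------------------------------------------------- swknn

def test_swknn_k1_uses_closest_coobserved_sample():
    vals = np.array([[1.0, 1.1, 5.0],
                     [2.0, 2.1, 9.0],
                     [3.0, 0.0, 7.0]])
    mask = np.zeros((3, 3), bool)
    mask[2, 1] = True
    m = make(vals, mask)
    res = swknn_impute(m, k=1)
    assert res.matrix.values[2, 1] == pytest.approx(3.0)  # s0 is closest to s1


def test_swknn_equidistant_neighbors_average():
    vals = np.array([[0.0, 1.0, -1.0],
                     [5.0, 2.0, 4.0]])
    mask = np.zeros((2, 3), bool)
    mask[1, 0] = True
    res = swknn_impute(make(vals, mask), k=2)
    assert res.matrix.values[1, 0] == pytest.approx(3.0)


def test_swknn_duplicate_sample_dominates():
    rng = np.random.default_rng(1)
    vals = rng.normal(5, 1, size=(6, 4))
    vals[:, 1] = vals[:, 0]  # s1 duplicates s0
    mask = np.zeros((6, 4), bool)
    mask[0, 1] = True
    res = swknn_impute(OmicsMatrix(vals, mask, LOG2,
                                   [f"g{i}" for i in range(6)],
                                   ["s0", "s1", "s2", "s3"]), k=3)
    # distance ~0 to the duplicate: weight 1/delta overwhelms the others
    assert res.matrix.values[0, 1] == pytest.approx(vals[0, 0], abs=1e-4)


# ----------------------------------------------------------------- low-rank

@pytest.mark.parametrize("method", ["ppca", "nipals", "svd", "svt"])
def test_lowrank_identity_without_missing(method):
    rng = np.random.default_rng(2)
    vals = rng.normal(5, 1, size=(8, 5))
    m = make(vals, np.zeros_like(vals, bool))
    res = lowrank_impute(m, method=method, rank=2, seed=0)
    np.testing.assert_array_equal(res.matrix.values, vals)


def test_emsvd_recovers_rank_one_matrix():
    u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    v = np.array([2.0, 1.0, 3.0, 2.5])
    vals = np.outer(u, v)
    mask = np.zeros_like(vals, bool)
    mask[1, 2] = True
    m = make(vals, mask)
    res = lowrank_impute(m, method="svd", rank=1, tol=1e-12, max_iter=2000)
    assert res.matrix.values[1, 2] == pytest.approx(u[1] * v[2], abs=1e-6)


def test_svt_recovers_rank_one_matrix():
    u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    v = np.array([2.0, 1.0, 3.0, 2.5])
    vals = np.outer(u, v)
    mask = np.zeros_like(vals, bool)
    mask[1, 2] = True
    # threshold at the top singular value: small against the classical
    # O(sqrt(mn) * scale) recommendation, large enough for exact completion
    sigma1 = np.linalg.svd(np.where(mask, 0.0, vals), compute_uv=False)[0]
    res = lowrank_impute(make(vals, mask), method="svt", tol=1e-9,
                         max_iter=2000, tau=float(sigma1))
    assert res.matrix.values[1, 2] == pytest.approx(u[1] * v[2], abs=1e-3)


def test_ppca_requires_seed():
    m = make([[1.0, 2.0], [3.0, 4.0], [5.0, 0.0]],
             [[False, False], [False, False], [False, True]])
    with pytest.raises(ValueError, match="seed"):
        lowrank_impute(m, method="ppca", rank=1)


# ------------------------------------------------------------- shared rules

@pytest.mark.parametrize("method,kwargs", [
    ("mgpi", {}), ("min2", {}), ("mean", {}), ("swknn", {"k": 3}),
    ("ppca", {"rank": 2, "seed": 7}), ("nipals", {"rank": 2}),
    ("svd", {"rank": 2}), ("svt", {}),
])
def test_observed_entries_bit_identical(method, kwargs, rng):
    m = random_masked_matrix(rng, n_genes=20, n_samples=10)
    g = GroupLabels.from_pairs([(f"s{j}", "A" if j < 5 else "B") for j in range(10)])
    res = impute(m, method, g=g, **kwargs)
    obs = ~m.mask
    assert np.array_equal(res.matrix.values[obs], m.values[obs])
    assert not res.matrix.mask.any()
    assert res.matrix.space == m.space


def test_mgpi_beats_simple_fills_on_signature_rows():
    """Group-structured gene: MGpI fill error below half-min and mean fills."""
    from abds.matrix import to_log2
    from abds.simulation import (MissingnessConfig, inject_missingness,
                                 simulate_sg_panel_dataset)
    from abds.evaluation import rmse
    from abds.matrix import MissingnessTruth
    wins = 0
    for seed in range(3):
        m, g, truth = simulate_sg_panel_dataset(
            K=3, n_sg_per_group=10, n_background=60,
            group_sizes=(8, 8, 8), seed=seed)
        masked, omega = inject_missingness(
            to_log2(m, 1.0), MissingnessConfig(overall_rate=0.5,
                                               mar_proportion=0.4, seed=seed))
        sgs = set(truth[truth["class"] == "SG"]["gene_id"])
        sub = MissingnessTruth(omega.table[omega.table["gene_id"].isin(sgs)])
        e_mgpi = rmse(mgpi_impute(masked, g), sub)
        if e_mgpi < rmse(halfmin_impute(masked), sub) and \
           e_mgpi < rmse(mean_impute(masked), sub):
            wins += 1
    assert wins == 3
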