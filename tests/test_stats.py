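import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from igeprs.stats import (
    adjusted_group_comparison,
    chi_square_independence,
    dunn_bonferroni,
    kruskal_wallis,
    normality_variance_gate,
    pearson_r2,
)




# --------------------------------------------------------------------- #
# chi-square on the published cohort contingency tables
# --------------------------------------------------------------------- #
# Counts from the study cohorts (denominators follow the missing-data
# footnotes); each printed p-value is recovered to 2 significant figures.
COHORT_TABLES = {
    "sex_controls_vs_cases": ([[662, 625], [427, 318]], 0.010),
    "smoking_controls_vs_cases": ([[718, 168, 399], [442, 106, 182]], 0.014),
    "atopy_controls_vs_cases": ([[745, 542], [498, 209]], 3.1e-8),
    "sex_by_cluster": ([[125, 74], [82, 75], [82, 96], [114, 59]], 3.5e-4),
    "smoking_by_cluster": ([[124, 22, 52], [101, 29, 25], [78, 30, 68], [123, 22, 27]], 3.3e-7),
    "atopy_by_cluster": ([[134, 63], [133, 15], [133, 36], [78, 82]], 5.0e-15),
    "dermatitis_by_cluster": ([[4, 156], [34, 96], [7, 128], [2, 137]], 1.9e-15),
    "rhinitis_by_cluster": ([[47, 113], [50, 80], [36, 99], [37, 103]], 0.111),
}


@pytest.mark.parametrize("name", list(COHORT_TABLES))
def test_published_contingency_pvalues_recovered(name):
    table, printed = COHORT_TABLES[name]
    _, _, p = chi_square_independence(table)
    # agreement at the printed (2 significant figure) precision
    assert p == pytest.approx(printed, rel=0.05)


def test_chi_square_proportional_rows_null():
    stat, df, p = chi_square_independence([[10, 20, 30], [20, 40, 60]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_equals_brute_force():
    rng = np.random.default_rng(2)
    t = rng.integers(1, 80, (3, 4)).astype(float)
    stat, df, p = chi_square_independence(t)
    exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
    assert stat == pytest.approx(((t - exp) ** 2 / exp).sum(), abs=1e-10)
    assert df == 6


def test_chi_square_zero_margin_named():
    with pytest.raises(ValueError, match="column 1"):
        chi_square_independence([[5, 0], [3, 0]])
    with pytest.raises(ValueError, match="row 0"):
        chi_square_independence([[0, 0], [3, 2]])


# --------------------------------------------------------------------- #
# Kruskal-Wallis
# --------------------------------------------------------------------- #
def test_kruskal_identical_groups_null():
    g = [1.0, 2.0, 3.0]
    h, p = kruskal_wallis([g, list(g), list(g)])
    assert h == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_kruskal_rank_invariance_under_log(rng):
    groups = [rng.lognormal(0, 1, 30), rng.lognormal(0.5, 1, 25), rng.lognormal(1, 1, 35)]
    h1, p1 = kruskal_wallis(groups)
    h2, p2 = kruskal_wallis([np.log(g) for g in groups])
    assert h1 == pytest.approx(h2, rel=1e-12)
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_kruskal_matches_permutation_oracle(rng):
    groups = [[3.1, 0.2, 5.5, 2.2], [4.4, 8.1, 6.3, 7.7], [1.0, 2.9, 3.3, 0.7]]
    h_obs, p_chi2 = kruskal_wallis(groups)
    values = np.concatenate(groups)
    ranks = sps.rankdata(values)
    n, sizes = len(values), [4, 4, 4]
    n_perm = 100_000
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_ranks = ranks[idx]
    h_perm = np.zeros(n_perm)
    start = 0
    for sz in sizes:
        rsum = perm_ranks[:, start:start + sz].sum(axis=1)
        h_perm += rsum**2 / sz
        start += sz
    h_perm = 12.0 / (n * (n + 1)) * h_perm - 3 * (n + 1)
    p_perm = np.mean(h_perm >= h_obs - 1e-12)
    mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert abs(p_chi2 - p_perm) < max(4 * mc_se, 0.02)


def test_kruskal_empty_group_rejected():
    with pytest.raises(ValueError, match="empty"):
        kruskal_wallis([[1.0, 2.0], []])


# --------------------------------------------------------------------- #
# Dunn-Bonferroni
# --------------------------------------------------------------------- #
def test_dunn_two_groups_no_correction():
    out = dunn_bonferroni([[1.0, 2.0, 5.0], [3.0, 7.0, 8.0]])
    assert out.n_pairs == 1
    row = out.table.iloc[0]
    assert row["p_adjusted"] == pytest.approx(row["p_raw"])


def test_dunn_adjusted_p_capped_at_one(rng):
    groups = [rng.normal(0, 1, 8) for _ in range(5)]  # 10 pairs, null data
    out = dunn_bonferroni(groups)
    assert (out.table["p_adjusted"] <= 1.0).all()
    assert (out.table["p_adjusted"] >= out.table["p_raw"]).all()


def test_dunn_z_matches_hand_formula():
    groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 6.0, 8.0], [7.0, 9.0, 10.0]]
    out = dunn_bonferroni(groups)
    values = np.concatenate(groups)
    ranks = sps.rankdata(values)
    rbars = [ranks[:3].mean(), ranks[3:7].mean(), ranks[7:].mean()]
    n = len(values)
    var = n * (n + 1) / 12.0  # no ties here
    for _, row in out.table.iterrows():
        i, j = int(row["group1"]), int(row["group2"])
        sizes = [3, 4, 3]
        z = (rbars[i] - rbars[j]) / np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
        assert row["z"] == pytest.approx(z, abs=1e-10)
        assert row["p_adjusted"] == pytest.approx(min(1.0, 2 * sps.norm.sf(abs(z)) * 3), abs=1e-10)


def test_dunn_z_antisymmetric():
    a, b = [1.0, 2.0, 9.0], [4.0, 5.0, 6.0]
    z_ab = dunn_bonferroni([a, b]).table.iloc[0]["z"]
    z_ba = dunn_bonferroni([b, a]).table.iloc[0]["z"]
    assert z_ab == pytest.approx(-z_ba, abs=1e-12)


# --------------------------------------------------------------------- #
# adjusted group comparison
# --------------------------------------------------------------------- #
def test_orthogonal_covariate_equals_mean_difference(rng):
    group = np.repeat([0.0, 1.0], 40)
    cov = np.tile([-1.0, 1.0], 40)  # exactly orthogonal to group
    y = rng.normal(size=80) + 0.8 * group
    beta, se, p = adjusted_group_comparison(y, group, pd.DataFrame({"c": cov}))
    diff = y[group == 1].mean() - y[group == 0].mean()
    assert beta == pytest.approx(diff, abs=1e-10)


def test_group_comparison_matches_normal_equations(rng):
    y = rng.normal(size=10)
    group = rng.integers(0, 2, 10).astype(float)
    cov = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
    beta, se, p = adjusted_group_comparison(y, group, cov)
    X = np.column_stack([np.ones(10), group, cov["a"], cov["b"]])
    XtX_inv = np.linalg.inv(X.T @ X)
    b = XtX_inv @ X.T @ y
    resid = y - X @ b
    sigma2 = resid @ resid / (10 - 4)
    assert beta == pytest.approx(b[1], abs=1e-10)
    assert se == pytest.approx(np.sqrt(sigma2 * XtX_inv[1, 1]), abs=1e-10)


def test_group_comparison_null_pvalues_uniform(rng):
    n, reps = 40, 1500
    y = rng.normal(size=n)
    cov = pd.DataFrame({"c": rng.normal(size=n)})
    ps = []
    for _ in range(reps):
        g = rng.permutation(np.repeat([0.0, 1.0], n // 2))
        ps.append(adjusted_group_comparison(y, g, cov)[2])
    assert sps.kstest(ps, "uniform").statistic < 0.05


def test_collinear_covariates_rejected(rng):
    y = rng.normal(size=20)
    g = np.repeat([0.0, 1.0], 10)
    cov = pd.DataFrame({"a": g * 2})  # collinear with group
    with pytest.raises(ValueError, match="collinear"):
        adjusted_group_comparison(y, g, cov)


# --------------------------------------------------------------------- #
# Pearson r^2
# --------------------------------------------------------------------- #
def test_pearson_identity_and_orthogonal():
    x = np.array([-1.0, 0.0, 1.0])
    assert pearson_r2(x, x)[0] == pytest.approx(1.0)
    assert pearson_r2(x, np.array([1.0, -2.0, 1.0]))[0] == pytest.approx(0.0, abs=1e-12)


def test_pearson_fixed_instance_matches_formula(rng):
    x = rng.normal(size=6)
    y = 0.4 * x + rng.normal(size=6)
    r2, p = pearson_r2(x, y)
    r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert r2 == pytest.approx(r * r, abs=1e-12)
    t = r * np.sqrt(4 / (1 - r * r))
    assert p == pytest.approx(2 * sps.t.sf(abs(t), 4), rel=1e-9)


def test_pearson_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# --------------------------------------------------------------------- #
# normality / variance gate
# --------------------------------------------------------------------- #
def test_gate_parametric_for_normal_groups():
    # three Shapiro tests + Levene, each at alpha 0.05: expected parametric
    # rate is 0.95^4 ~ 81%; assert well above chance and near that rate
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(10_000 + seed)
        groups = [rng.normal(0, 1, 200) for _ in range(3)]
        hits += normality_variance_gate(groups).decision == "parametric"
    assert hits >= 70


def test_gate_nonparametric_for_skewed_groups():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(20_000 + seed)
        groups = [rng.normal(0, 1, 200), rng.lognormal(0, 1.5, 200)]
        hits += normality_variance_gate(groups).decision == "nonparametric"
    assert hits >= 99


def test_gate_small_group_routes_nonparametric():
    out = normality_variance_gate([[1.0, 2.0], [1.0, 2.0, 3.0]])
    assert out.decision == "nonparametric"
    assert "small" in out.reason
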