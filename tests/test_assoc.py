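import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from igeprs import (
    SimConfig,
    genotype_pca,
    gwas_casecontrol,
    gwas_quantitative,
    select_lead_snps,
    simulate_reference_panel,
)
from igeprs.assoc import build_design, P_FLOOR
from igeprs.genotypes import GenotypeMatrix, pairwise_r2


def _matrix_from(dosages, pos_step=1000, chrom="1"):
    d = np.asarray(dosages, dtype=float)
    snps = pd.DataFrame({
        "id": [f"v{j}" for j in range(d.shape[1])],
        "chrom": chrom,
        "pos": np.arange(1, d.shape[1] + 1) * pos_step,
        "effect_allele": "A",
        "other_allele": "G",
    })
    return GenotypeMatrix(d, [f"s{i}" for i in range(d.shape[0])], snps)


# --------------------------------------------------------------------- #
# PCA
# --------------------------------------------------------------------- #
class TestPca:
    def test_two_subpopulations_separated_by_pc1(self, rng):
        m, n_half = 1000, 150
        pa = rng.uniform(0.1, 0.6, m)
        pb = np.clip(pa + 0.2, 0.0, 0.95)
        d = np.vstack([
            rng.binomial(2, pa, (n_half, m)),
            rng.binomial(2, pb, (n_half, m)),
        ]).astype(float)
        pca = genotype_pca(_matrix_from(d), k=3)
        pop = np.repeat([0, 1], n_half)
        r = np.corrcoef(pca.scores["PC1"], pop)[0, 1]
        assert abs(r) > 0.9

    def test_k_zero_gives_empty_scores(self):
        g = _matrix_from(np.random.default_rng(0).integers(0, 3, (20, 10)).astype(float))
        pca = genotype_pca(g, k=0)
        assert pca.scores.shape[1] == 0

    def test_small_matrix_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (5, 4)).astype(float)
        g = _matrix_from(d)
        pca = genotype_pca(g, k=2)
        # oracle: explicit standardization + full SVD
        p = d.mean(axis=0) / 2
        ok = (p > 0) & (p < 1)
        X = (d[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        X = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        want = np.abs(U[:, :2] * s[:2])
        np.testing.assert_allclose(np.abs(pca.scores.to_numpy()), want, atol=1e-8)

    def test_scores_centered_and_orthogonal(self, panel500):
        _, g, _, _ = panel500
        pca = genotype_pca(g, k=4)
        S = pca.scores.to_numpy()
        np.testing.assert_allclose(S.mean(axis=0), 0.0, atol=1e-8)
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.diag(gram).max()

    def test_projection_matches_training_scores(self, panel500):
        _, g, _, _ = panel500
        pca = genotype_pca(g, k=3)
        proj = pca.project(g)
        # projection differs from SVD scores only by the exact-centering step
        r = np.corrcoef(proj["PC1"], pca.scores["PC1"])[0, 1]
        assert r > 0.999


# --------------------------------------------------------------------- #
# quantitative GWAS
# --------------------------------------------------------------------- #
class TestGwasQuantitative:
    def test_perfect_fit_beta_one_p_floor(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, (30, 1)).astype(float)
        g = _matrix_from(d)
        stats = gwas_quantitative(g, d[:, 0] + 5.0)
        assert stats.loc[0, "beta"] == pytest.approx(1.0, abs=1e-10)
        assert stats.loc[0, "p"] == P_FLOOR

    def test_zero_variance_snp_is_na(self):
        d = np.column_stack([np.ones(20), np.random.default_rng(1).integers(0, 3, 20)])
        g = _matrix_from(d)
        stats = gwas_quantitative(g, np.random.default_rng(2).normal(size=20))
        assert np.isnan(stats.loc[0, "beta"]) and stats.loc[0, "n"] == 0
        assert np.isfinite(stats.loc[1, "beta"])

    def test_fixed_instance_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, (8, 1)).astype(float)
        cov = pd.DataFrame({"c": rng.normal(size=8)})
        y = rng.normal(size=8)
        stats = gwas_quantitative(_matrix_from(d), y, cov)
        X = np.column_stack([d[:, 0], np.ones(8), cov["c"]])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (8 - 3)
        se = np.sqrt(sigma2 * XtX_inv[0, 0])
        assert stats.loc[0, "beta"] == pytest.approx(beta[0], abs=1e-10)
        assert stats.loc[0, "se"] == pytest.approx(se, abs=1e-10)
        t = beta[0] / se
        assert stats.loc[0, "p"] == pytest.approx(2 * sps.t.sf(abs(t), 5), rel=1e-10)

    def test_missing_dosage_path_matches_complete_subset_fit(self):
        rng = np.random.default_rng(9)
        d = rng.integers(0, 3, (40, 1)).astype(float)
        d[:5, 0] = np.nan
        y = rng.normal(size=40)
        stats = gwas_quantitative(_matrix_from(d), y)
        ok = ~np.isnan(d[:, 0])
        X = np.column_stack([d[ok, 0], np.ones(ok.sum())])
        beta = np.linalg.lstsq(X, y[ok], rcond=None)[0]
        assert stats.loc[0, "beta"] == pytest.approx(beta[0], abs=1e-10)
        assert stats.loc[0, "n"] == 35

    def test_collinear_covariates_named(self):
        g = _matrix_from(np.random.default_rng(1).integers(0, 3, (20, 2)).astype(float))
        cov = pd.DataFrame({"a": np.arange(20.0)})
        cov["b"] = 2 * cov["a"]
        with pytest.raises(ValueError, match="b"):
            gwas_quantitative(g, np.random.default_rng(2).normal(size=20), cov)

    def test_null_pvalues_uniform(self):
        cfg = SimConfig(n_controls=300, n_cases=0, n_snps=2000, n_blocks=2000,
                        block_corr=0.0, missing_rate=0.0, n_causal=0, seed=33)
        g, _ = simulate_reference_panel(cfg)
        y = np.random.default_rng(34).normal(size=300)
        stats = gwas_quantitative(g, y)
        ps = stats["p"].dropna().to_numpy()
        ks = sps.kstest(ps, "uniform").statistic
        assert ks < 0.05


# --------------------------------------------------------------------- #
# case-control GWAS
# --------------------------------------------------------------------- #
class TestGwasCaseControl:
    def test_equal_allele_frequencies_give_null(self):
        block = np.array([2.0] * 10 + [1.0] * 20 + [0.0] * 10)
        d = np.concatenate([block, block])[:, None]
        labels = np.repeat([1, 0], 40)
        stats = gwas_casecontrol(_matrix_from(d), labels)
        assert stats.loc[0, "p"] == pytest.approx(1.0)

    def test_fixed_allele_table_matches_chi_square(self):
        # cases: alleles (120, 80); controls: (100, 100)
        cases = np.array([2.0] * 20 + [1.0] * 80)
        controls = np.array([2.0] * 25 + [1.0] * 50 + [0.0] * 25)
        d = np.concatenate([cases, controls])[:, None]
        labels = np.repeat([1, 0], 100)
        stats = gwas_casecontrol(_matrix_from(d), labels)
        table = np.array([[120, 80], [100, 100]])
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - exp) ** 2 / exp).sum()
        assert stats.loc[0, "p"] == pytest.approx(sps.chi2.sf(chi2, 1), rel=1e-10)
        want_or = np.log((120 * 100) / (80 * 100))
        assert stats.loc[0, "beta"] == pytest.approx(want_or, rel=1e-10)

    def test_monomorphic_snp_is_na(self):
        d = np.zeros((30, 1))
        stats = gwas_casecontrol(_matrix_from(d), np.repeat([1, 0], 15))
        assert np.isnan(stats.loc[0, "beta"]) and np.isnan(stats.loc[0, "p"])

    def test_empty_class_rejected(self):
        g = _matrix_from(np.ones((10, 2)))
        with pytest.raises(ValueError, match="non-empty"):
            gwas_casecontrol(g, np.zeros(10))


# --------------------------------------------------------------------- #
# lead SNPs
# --------------------------------------------------------------------- #
def _greedy_oracle(stats, geno, p_max, r2_max, window_kb):
    """Independent brute-force greedy selection for small instances."""
    df = stats[stats["p"] < p_max].sort_values(["p", "pos", "snp"]).reset_index(drop=True)
    removed, kept = set(), []
    col = {s: i for i, s in enumerate(geno.snps["id"])}
    for _, row in df.iterrows():
        if row["snp"] in removed:
            continue
        kept.append(row["snp"])
        for _, other in df.iterrows():
            if other["snp"] in removed or other["snp"] == row["snp"]:
                continue
            if str(other["chrom"]) != str(row["chrom"]):
                continue
            if abs(other["pos"] - row["pos"]) > window_kb * 1000:
                continue
            a = geno.dosages[:, col[row["snp"]]]
            b = geno.dosages[:, col[other["snp"]]]
            ok = ~(np.isnan(a) | np.isnan(b))
            if np.var(a[ok]) == 0 or np.var(b[ok]) == 0:
                continue
            if np.corrcoef(a[ok], b[ok])[0, 1] ** 2 >= r2_max:
                removed.add(other["snp"])
        removed.add(row["snp"])
    return kept


class TestLeadSnps:
    def test_no_suggestive_snp_gives_empty(self, panel500):
        _, g, _, _ = panel500
        stats = pd.DataFrame({
            "snp": g.snps["id"], "chrom": g.snps["chrom"], "pos": g.snps["pos"],
            "effect_allele": "A", "other_allele": "G",
            "beta": 0.0, "se": 1.0, "p": 0.5, "n": 500,
        })
        assert select_lead_snps(stats, g) == []

    def test_single_suggestive_snp_is_lone_lead(self, panel500):
        _, g, _, _ = panel500
        stats = pd.DataFrame({
            "snp": g.snps["id"], "chrom": g.snps["chrom"], "pos": g.snps["pos"],
            "effect_allele": "A", "other_allele": "G",
            "beta": 0.0, "se": 1.0, "p": 0.5, "n": 500,
        })
        stats.loc[37, "p"] = 5e-6
        assert select_lead_snps(stats, g) == [g.snps.loc[37, "id"]]

    def test_random_instance_matches_greedy_oracle(self):
        cfg = SimConfig(n_controls=150, n_cases=0, n_snps=20, n_blocks=2,
                        block_corr=0.6, missing_rate=0.0, n_causal=0, seed=55)
        g, _ = simulate_reference_panel(cfg)
        rng = np.random.default_rng(56)
        stats = pd.DataFrame({
            "snp": g.snps["id"], "chrom": g.snps["chrom"], "pos": g.snps["pos"],
            "effect_allele": "A", "other_allele": "G", "beta": rng.normal(size=20),
            "se": 1.0, "p": 10 ** (-rng.uniform(2, 9, 20)), "n": 150,
        })
        got = select_lead_snps(stats, g, p_max=1e-3, r2_max=0.1, window_kb=250)
        want = _greedy_oracle(stats, g, 1e-3, 0.1, 250)
        assert got == want

    def test_lead_set_mutually_independent(self):
        cfg = SimConfig(n_controls=200, n_cases=0, n_snps=60, n_blocks=6,
                        block_corr=0.7, missing_rate=0.0, n_causal=0, seed=57)
        g, _ = simulate_reference_panel(cfg)
        rng = np.random.default_rng(58)
        stats = pd.DataFrame({
            "snp": g.snps["id"], "chrom": g.snps["chrom"], "pos": g.snps["pos"],
            "effect_allele": "A", "other_allele": "G", "beta": 0.1,
            "se": 1.0, "p": 10 ** (-rng.uniform(4, 9, 60)), "n": 200,
        })
        leads = select_lead_snps(stats, g, p_max=1e-3, r2_max=0.1, window_kb=250)
        col = {s: i for i, s in enumerate(g.snps["id"])}
        pos = dict(zip(g.snps["id"], g.snps["pos"]))
        chrom = dict(zip(g.snps["id"], g.snps["chrom"]))
        for i, a in enumerate(leads):
            for b in leads[i + 1:]:
                same_chrom = chrom[a] == chrom[b]
                near = same_chrom and abs(pos[a] - pos[b]) <= 250_000
                if near:
                    r2 = pairwise_r2(g.dosages, col[a], np.array([col[b]]))[0]
                    assert r2 < 0.1


def test_build_design_without_covariates():
    W, names = build_design(None, 5)
    assert W.shape == (5, 1) and names == ["const"]
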