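"""Genotypic-model association, covariate PCs, inflation correction, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from keelgen.gwas import (
    build_covariates,
    correct_inflation,
    fit_snp,
    run_gwas,
    significance_thresholds,
)
from keelgen.pheno import log_transform
from keelgen.simulate import SimConfig, simulate_genotypes
from tests.conftest import random_genotype_matrix


class TestBuildCovariates:
    def test_single_balanced_factor_one_component(self):
        df = pd.DataFrame({"pen": ["a", "b"] * 10, "rearing_pen": ["x"] * 20})
        C = build_covariates(df)
        assert C.shape == (20, 1)

    def test_cross_classified_design_rank_bound(self):
        rng = np.random.default_rng(0)
        n = 400
        df = pd.DataFrame({
            "pen": rng.integers(0, 5, n).astype(str),
            "rearing_pen": rng.integers(0, 8, n).astype(str),
        })
        C = build_covariates(df, variance_keep=0.99)
        # centered additive two-factor design has rank <= (5-1)+(8-1)
        assert C.shape[1] <= 11
        D = pd.get_dummies(df, dtype=float).to_numpy()
        Dc = D - D.mean(axis=0)
        assert C.shape[1] <= np.linalg.matrix_rank(Dc)

    def test_components_orthogonal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "pen": rng.integers(0, 5, 200).astype(str),
            "rearing_pen": rng.integers(0, 8, 200).astype(str),
        })
        C = build_covariates(df)
        gram = C.T @ C
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-10

    def test_degenerate_single_levels_empty(self):
        df = pd.DataFrame({"pen": ["a"] * 15, "rearing_pen": ["x"] * 15})
        assert build_covariates(df).shape == (15, 0)


class TestFitSnp:
    def test_exact_fit_recovers_slope(self):
        g = np.array([0.0, 1.0, 2.0] * 10)
        rec = fit_snp(g.copy(), None, g)
        assert rec.beta_add == pytest.approx(1.0, abs=1e-10)
        assert rec.beta_dom == pytest.approx(0.0, abs=1e-10)
        assert rec.p_add < 1e-30

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        n = 30
        g = rng.integers(0, 3, n).astype(float)
        C = rng.normal(size=(n, 2))
        y = 0.4 * g + C @ [0.3, -0.2] + rng.normal(size=n)
        rec = fit_snp(y, C, g)
        # independent oracle: explicit normal equations + t distribution
        X = np.column_stack([np.ones(n), C, g - g.mean(), (g == 1).astype(float)])
        bhat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ bhat
        df = n - X.shape[1]
        s2 = resid @ resid / df
        covb = s2 * np.linalg.inv(X.T @ X)
        t_add = bhat[3] / np.sqrt(covb[3, 3])
        p_add = 2 * stats.t.sf(abs(t_add), df)
        assert rec.beta_add == pytest.approx(bhat[3], abs=1e-8)
        assert rec.p_add == pytest.approx(p_add, abs=1e-8)
        t_dom = bhat[4] / np.sqrt(covb[4, 4])
        assert rec.p_dom == pytest.approx(2 * stats.t.sf(abs(t_dom), df), abs=1e-8)

    def test_two_class_snp_equals_simple_regression(self):
        """Dominance column dropped -> additive p is the closed-form slope test."""
        rng = np.random.default_rng(11)
        n = 60
        g = rng.choice([0.0, 1.0], size=n)
        y = 0.5 * g + rng.normal(size=n)
        rec = fit_snp(y, None, g)
        assert np.isnan(rec.p_dom)
        res = stats.linregress(g, y)
        assert rec.p_add == pytest.approx(res.pvalue, abs=1e-10)
        assert rec.beta_add == pytest.approx(res.slope, abs=1e-10)

    def test_genotype_counts_and_casewise_deletion(self):
        g = np.array([0, 0, 1, 1, 1, 2, 2, 2, 2, np.nan, np.nan, 0, 1, 2, 0])
        y = np.arange(15, dtype=float)
        rec = fit_snp(y, None, g)
        assert (rec.n0, rec.n1, rec.n2, rec.n_missing) == (4, 4, 5, 2)
        # counted-allele freq 14/26 -> MAF is the complement 12/26
        assert rec.maf == pytest.approx(12 / 26, abs=1e-12)

    def test_monomorphic_and_tiny_flagged(self):
        y = np.arange(12, dtype=float)
        assert fit_snp(y, None, np.ones(12)).flag == "monomorphic"
        assert fit_snp(y[:5], None, np.array([0, 1, 2, 1, 0], dtype=float)).flag == "too_few_calls"


class TestRunGwas:
    @staticmethod
    def make_cohort(seed=13):
        cfg = SimConfig(n_sires=8, dams_per_sire=10, n_chromosomes=2,
                        snps_per_chromosome=60, seed=seed)
        geno, ped = simulate_genotypes(cfg)
        return geno

    def test_equals_per_snp_mapping(self):
        geno = self.make_cohort()
        rng = np.random.default_rng(0)
        samples = pd.DataFrame({
            "sample_id": geno.sample_ids,
            "pen": rng.integers(0, 3, geno.n_individuals).astype(str),
            "rearing_pen": rng.integers(0, 2, geno.n_individuals).astype(str),
            "kbf_score": rng.uniform(0, 5, geno.n_individuals),
        })
        samples = log_transform(samples)
        covs = build_covariates(samples)
        table = run_gwas(geno, samples, covs)
        y = samples["log_kbf"].to_numpy()
        for j in (0, 17, 59, 100):
            rec = fit_snp(y, covs, geno.dosages[:, j])
            assert table["beta_add"].iloc[j] == pytest.approx(rec.beta_add, nan_ok=True)
            assert table["p_add"].iloc[j] == pytest.approx(rec.p_add, nan_ok=True)

    def test_planted_qtl_tops_the_scan(self):
        """A large-effect QTL attains the genome-wide minimum p in >=18/20 runs."""
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            geno = random_genotype_matrix(rng, 400, 300, miss=0.0)
            qtl = 150
            y = 0.5 * geno.dosages[:, qtl] + rng.normal(size=400)
            samples = pd.DataFrame({
                "sample_id": geno.sample_ids, "pen": "p1", "rearing_pen": "r1",
                "kbf_score": np.clip(y + 3, 0, 10), "log_kbf": y,
            })
            table = run_gwas(geno, samples, None)
            wins += int(table["p_add"].idxmin() == qtl)
        assert wins >= 18


class TestInflationCorrection:
    @staticmethod
    def null_table(m=10_000, seed=0):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m)
        return pd.DataFrame({
            "p_add": p, "neglog10_p_add": -np.log10(p),
            "p_dom": p, "neglog10_p_dom": -np.log10(p),
        })

    def test_uniform_null_slope_near_one(self):
        df, fit = correct_inflation(self.null_table(), "additive")
        assert 0.95 <= fit.beta <= 1.05
        np.testing.assert_allclose(df["neglog10_p_add_corr"],
                                   df["neglog10_p_add"] / fit.beta)

    def test_constructed_slope_recovered_exactly(self):
        """Observed = 1.27 x expected for every SNP -> slope 1.27, correction exact."""
        m = 5000
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        obs = 1.27 * expected
        df = pd.DataFrame({"neglog10_p_add": obs, "p_add": 10.0**-obs})
        out, fit = correct_inflation(df, "additive")
        assert fit.beta == pytest.approx(1.27, abs=1e-9)
        np.testing.assert_allclose(np.sort(out["neglog10_p_add_corr"]),
                                   np.sort(expected), atol=1e-9)

    def test_extreme_point_excluded_from_fit_but_divided(self):
        m = 200
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        obs = expected.copy()
        obs[0] = 5.0  # far above the cutoff
        df = pd.DataFrame({"neglog10_p_add": obs, "p_add": 10.0**-obs})
        out, fit = correct_inflation(df, "additive", cutoff=3.0)
        assert fit.n_points_used == m - 1
        assert out["neglog10_p_add_corr"].max() == pytest.approx(5.0 / fit.beta)

    def test_ranking_preserved(self):
        df, _ = correct_inflation(self.null_table(seed=5), "additive")
        raw = df["neglog10_p_add"].to_numpy()
        corr = df["neglog10_p_add_corr"].to_numpy()
        assert (np.argsort(raw) == np.argsort(corr)).all()

    def test_channels_independent(self):
        tbl = self.null_table(seed=9)
        tbl["neglog10_p_dom"] *= 1.5
        _, fit_a = correct_inflation(tbl, "additive")
        _, fit_d = correct_inflation(tbl, "dominance")
        assert fit_d.beta > fit_a.beta

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError, match="100"):
            correct_inflation(self.null_table(m=50), "additive")


class TestThresholds:
    def test_printed_study_values(self):
        gw, sugg = significance_thresholds(2618)
        assert f"{gw:.2e}" == "1.91e-05"
        assert f"{sugg:.2e}" == "3.82e-05"

    def test_single_test_limits(self):
        assert significance_thresholds(1) == (0.05, 0.10)

    def test_halving_under_doubling(self):
        gw1, s1 = significance_thresholds(500)
        gw2, s2 = significance_thresholds(1000)
        assert gw1 == pytest.approx(2 * gw2) and s1 == pytest.approx(2 * s2)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            significance_thresholds(0)
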