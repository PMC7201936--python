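"""Association scans, the stacked time-interaction model, and clumping."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import make_cohort
from lifemr.scan import (bonferroni_threshold, cross_exposure_instrument_set,
                         ld_clump, scan, stacked_interaction_scan)
from lifemr.simulate import ScenarioSpec, simulate_cohort, simulate_panel


def _scan_oracle(cohort, phenotype, covariates):
    """Brute force: one statsmodels OLS per variant."""
    y = cohort.pheno[phenotype].to_numpy()
    C = np.column_stack([np.ones(cohort.n)]
                        + [cohort.pheno[c].to_numpy() for c in covariates])
    betas, ses = [], []
    for j in range(cohort.dosages.shape[1]):
        X = np.column_stack([cohort.dosages[:, j], C])
        fit = sm.OLS(y, X).fit()
        betas.append(fit.params[0])
        ses.append(fit.bse[0])
    return np.array(betas), np.array(ses)


class TestScan:
    def test_matches_per_variant_least_squares_oracle(self, rng):
        dosages = rng.binomial(2, 0.3, size=(50, 5)).astype(float)
        pheno = pd.DataFrame({
            "y": rng.normal(size=50), "age": rng.uniform(40, 70, 50),
            "sex": rng.integers(0, 2, 50).astype(float)})
        cohort = make_cohort(dosages, pheno)
        s = scan(cohort, "y", covariates=("age", "sex"))
        beta_o, se_o = _scan_oracle(cohort, "y", ("age", "sex"))
        np.testing.assert_allclose(s["beta"], beta_o, atol=1e-10)
        np.testing.assert_allclose(s["se"], se_o, atol=1e-10)

    def test_self_regression_recovers_unit_slope(self, rng):
        dosages = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        pheno = pd.DataFrame({"y": dosages[:, 1]})
        s = scan(make_cohort(dosages, pheno), "y")
        assert s["beta"].iloc[1] == pytest.approx(1.0, abs=1e-12)
        assert s["se"].iloc[1] < 1e-8

    def test_constant_dosage_reported_degenerate(self, rng):
        dosages = rng.binomial(2, 0.4, size=(60, 2)).astype(float)
        dosages[:, 0] = 2.0
        pheno = pd.DataFrame({"y": rng.normal(size=60)})
        s = scan(make_cohort(dosages, pheno), "y")
        assert s["beta"].iloc[0] == 0.0
        assert np.isinf(s["se"].iloc[0])
        assert s["pval"].iloc[0] == 1.0

    def test_independent_covariate_leaves_beta_stable(self, rng):
        dosages = rng.binomial(2, 0.3, size=(4000, 10)).astype(float)
        pheno = pd.DataFrame({
            "y": dosages[:, 0] * 0.3 + rng.normal(size=4000),
            "noise": rng.normal(size=4000)})
        cohort = make_cohort(dosages, pheno)
        plain = scan(cohort, "y")
        adj = scan(cohort, "y", covariates=("noise",))
        # independent covariate: betas shift only by Monte-Carlo jitter
        np.testing.assert_allclose(plain["beta"], adj["beta"], atol=0.01)

    def test_pvalues_consistent_with_beta_over_se(self, rng):
        from scipy.stats import norm
        dosages = rng.binomial(2, 0.3, size=(200, 5)).astype(float)
        pheno = pd.DataFrame({"y": rng.normal(size=200)})
        s = scan(make_cohort(dosages, pheno), "y")
        expect = 2 * norm.sf(np.abs(s["beta"] / s["se"]))
        np.testing.assert_allclose(s["pval"], expect, rtol=1e-6)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 1, 0.05),
        (0.05, 500, 1.0e-4),
        (0.05, 694, 0.05 / 694),   # = 7.2046e-5 to printed precision
    ])
    def test_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestStackedInteraction:
    def _cohort_with_effects(self, rng, n, beta_early, beta_adult):
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        pheno = pd.DataFrame({
            "early_category": beta_early * g[:, 0] + rng.normal(size=n),
            "adult_category": beta_adult * g[:, 0] + rng.normal(size=n),
            "age": rng.uniform(40, 70, n),
            "sex": rng.integers(0, 2, n).astype(float)})
        return make_cohort(g, pheno)

    def test_equal_effects_give_null_interaction(self, rng):
        cohort = self._cohort_with_effects(rng, 20_000, 0.1, 0.1)
        res = stacked_interaction_scan(cohort)
        assert abs(res["beta_interaction"].iloc[0]) \
            < 4 * res["se_interaction"].iloc[0]
        assert res["flag"].iloc[0] == "no-difference"

    def test_early_only_effect_gives_negative_interaction(self, rng):
        # interaction is coded adult minus early
        cohort = self._cohort_with_effects(rng, 50_000, 0.1, 0.0)
        res = stacked_interaction_scan(cohort)
        assert res["beta_interaction"].iloc[0] == pytest.approx(
            -0.1, abs=4 * res["se_interaction"].iloc[0])
        assert res["flag"].iloc[0] == "stronger-early"

    def test_cluster_robust_widens_se_for_duplicated_rows(self, rng):
        # identical measurements at both times: within-individual noise is
        # perfectly correlated, plain OLS ignores it
        g = rng.binomial(2, 0.3, size=(2000, 1)).astype(float)
        y = 0.05 * g[:, 0] + rng.normal(size=2000)
        pheno = pd.DataFrame({"early_category": y, "adult_category": y})
        cohort = make_cohort(g, pheno)
        robust = stacked_interaction_scan(cohort, covariates=())
        plain = stacked_interaction_scan(cohort, covariates=(),
                                         cluster_robust=False)
        ratio = robust["se_interaction"].iloc[0] \
            / plain["se_interaction"].iloc[0]
        assert ratio < 0.2   # interaction is exactly 0 with no free noise

    def test_missing_time_point_rejected(self, rng):
        g = rng.binomial(2, 0.3, size=(50, 1)).astype(float)
        pheno = pd.DataFrame({"early_category": rng.normal(size=50),
                              "adult_category": rng.normal(size=50)})
        pheno.loc[3, "adult_category"] = np.nan
        with pytest.raises(ValueError, match="both time points"):
            stacked_interaction_scan(make_cohort(g, pheno), covariates=())


def _clump_oracle(stats, r2, p_threshold, r2_threshold):
    """Independent greedy reimplementation on a precomputed r2 matrix."""
    order = stats[stats["pval"] < p_threshold].sort_values(
        ["pval", "SNP"]).index.to_list()
    kept = []
    while order:
        idx = order.pop(0)
        kept.append(idx)
        order = [o for o in order if r2[idx, o] < r2_threshold]
    return list(stats.loc[kept, "SNP"])


def _stats_frame(snps, pvals):
    return pd.DataFrame({
        "SNP": snps, "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.02, "pval": pvals,
        "samplesize": 1000})


class TestClumping:
    def test_hand_traced_example(self, rng):
        # r2(1,2) high, variant 3 independent but fails the p threshold
        n = 500
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = g1.copy()
        flip = rng.random(n) < 0.1
        g2[flip] = rng.binomial(2, 0.3, flip.sum())
        g3 = rng.binomial(2, 0.3, n).astype(float)
        reference = make_cohort(np.column_stack([g1, g2, g3]),
                                variant_ids=["rs1", "rs2", "rs3"])
        stats = _stats_frame(["rs1", "rs2", "rs3"], [1e-10, 5e-9, 1e-7])
        kept = ld_clump(stats, reference, p_threshold=5e-8,
                        r2_threshold=0.001)
        assert list(kept["SNP"]) == ["rs1"]

    def test_uncorrelated_variants_all_retained(self, rng):
        reference = make_cohort(
            rng.binomial(2, 0.3, size=(2000, 4)).astype(float),
            variant_ids=["rs1", "rs2", "rs3", "rs4"])
        stats = _stats_frame(["rs1", "rs2", "rs3", "rs4"],
                             [1e-10, 1e-9, 1e-12, 1e-11])
        kept = ld_clump(stats, reference, p_threshold=5e-8, r2_threshold=0.1)
        assert sorted(kept["SNP"]) == ["rs1", "rs2", "rs3", "rs4"]
        assert list(kept["pval"]) == sorted(kept["pval"])

    def test_idempotence(self, rng):
        reference = make_cohort(
            rng.binomial(2, 0.4, size=(500, 6)).astype(float),
            variant_ids=[f"rs{i}" for i in range(6)])
        stats = _stats_frame([f"rs{i}" for i in range(6)],
                             [1e-9, 1e-8 / 3, 2e-9, 4e-9, 1e-10, 3e-9])
        once = ld_clump(stats, reference, 5e-8, 0.05)
        twice = ld_clump(once, reference, 5e-8, 0.05)
        pd.testing.assert_frame_equal(once, twice)

    def test_matches_independent_oracle_on_random_panels(self, rng):
        spec = ScenarioSpec(n_variants=10, ld_block_size=5, ld_rho=0.7,
                            n_early_variants=2, n_adult_variants=2,
                            seed=31)
        panel = simulate_panel(spec)
        reference = simulate_cohort(panel, spec, 400, "reference")
        r = np.corrcoef(reference.dosages, rowvar=False) ** 2
        for trial in range(20):
            pvals = 10.0 ** rng.uniform(-12, -2, 10)
            stats = _stats_frame(list(panel.ids), pvals)
            kept = ld_clump(stats, reference, p_threshold=5e-8,
                            r2_threshold=0.2)
            expected = _clump_oracle(stats, r, 5e-8, 0.2)
            assert list(kept["SNP"]) == expected
            # validity: retained set is mutually below the r2 ceiling
            ids = {v: i for i, v in enumerate(panel.ids)}
            pos = [ids[v] for v in kept["SNP"]]
            for a in range(len(pos)):
                for b in range(a + 1, len(pos)):
                    assert r[pos[a], pos[b]] < 0.2

    def test_missing_reference_variant_reported(self, rng):
        reference = make_cohort(rng.binomial(2, 0.3, size=(100, 1)).astype(float),
                                variant_ids=["rs1"])
        stats = _stats_frame(["rs1", "rsX"], [1e-10, 1e-9])
        with pytest.raises(KeyError, match="rsX"):
            ld_clump(stats, reference)


class TestCrossExposure:
    def test_disjoint_sets_union(self, rng):
        reference = make_cohort(
            rng.binomial(2, 0.3, size=(2000, 4)).astype(float),
            variant_ids=["rs1", "rs2", "rs3", "rs4"])
        a = _stats_frame(["rs1", "rs2"], [1e-10, 1e-9])
        b = _stats_frame(["rs3", "rs4"], [1e-11, 1e-9])
        joint = cross_exposure_instrument_set(a, b, reference,
                                              r2_threshold=0.1)
        assert sorted(joint["SNP"]) == ["rs1", "rs2", "rs3", "rs4"]

    def test_shared_variant_keeps_smaller_p(self, rng):
        reference = make_cohort(
            rng.binomial(2, 0.3, size=(500, 2)).astype(float),
            variant_ids=["rs1", "rs2"])
        a = _stats_frame(["rs1", "rs2"], [1e-10, 1e-9])
        b = _stats_frame(["rs1"], [1e-15])
        joint = cross_exposure_instrument_set(a, b, reference,
                                              r2_threshold=0.1)
        assert len(joint) == 2
        assert joint.set_index("SNP").at["rs1", "pval"] == 1e-15

    def test_correlated_pair_across_sets_resolved(self, rng):
        n = 400
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = g1.copy()
        flip = rng.random(n) < 0.05
        g2[flip] = rng.binomial(2, 0.3, flip.sum())
        reference = make_cohort(np.column_stack([g1, g2]),
                                variant_ids=["rs1", "rs2"])
        a = _stats_frame(["rs1"], [1e-9])
        b = _stats_frame(["rs2"], [1e-12])
        joint = cross_exposure_instrument_set(a, b, reference,
                                              r2_threshold=0.001)
        assert list(joint["SNP"]) == ["rs2"]


def test_sex_stratified_scan_by_filtering():
    spec = ScenarioSpec(n_variants=20, n_early_variants=5,
                        n_adult_variants=5, effect_size_sd_early=0.5,
                        effect_size_sd_adult=0.5, seed=47)
    cohort = simulate_cohort(simulate_panel(spec), spec, 2000, "exposure")
    women = cohort.filter(cohort.pheno["sex"] == 1)
    assert women.n < cohort.n
    s = scan(women, "early_latent", covariates=("age",))
    assert (s["samplesize"] == women.n).all()
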