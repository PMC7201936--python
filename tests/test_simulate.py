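"""Synthetic cohort generator: determinism, marginals, path model, LD."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from lifemr.scan import scan
from lifemr.simulate import (ConfigurationError, MisclassModel, ScenarioSpec,
                             apply_misclassification,
                             expected_dosage_correlation, read_cohort,
                             simulate_cohort, simulate_panel, write_cohort)


class TestScenarioValidation:
    @pytest.mark.parametrize("field,value,match", [
        ("maf_range", (0.0, 0.4), "maf_range"),
        ("maf_range", (0.3, 0.6), "maf_range"),
        ("ld_rho", 1.0, "ld_rho"),
        ("ld_rho", -0.1, "ld_rho"),
        ("n_early_variants", 200, "n_variants"),
        ("category_proportions", (0.5, 0.5, 0.5), "sum to 1"),
        ("outcome_model", "probit", "outcome_model"),
        ("baseline_prevalence", 1.5, "baseline_prevalence"),
        ("ld_block_size", 0, "ld_block_size"),
    ])
    def test_invalid_field_named_in_error(self, field, value, match):
        spec = replace(ScenarioSpec(), **{field: value})
        with pytest.raises(ConfigurationError, match=match):
            spec.validate()

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ConfigurationError, match="bogus"):
            ScenarioSpec.from_dict({"bogus": 1})


class TestPanel:
    def test_null_architecture_has_zero_effects(self):
        spec = ScenarioSpec(n_early_variants=0, n_adult_variants=0,
                            n_shared_variants=0, seed=3)
        panel = simulate_panel(spec)
        assert not panel.beta_early.any()
        assert not panel.beta_adult.any()

    def test_same_seed_identical_panel(self):
        a = simulate_panel(ScenarioSpec(seed=9))
        b = simulate_panel(ScenarioSpec(seed=9))
        assert np.array_equal(a.maf, b.maf)
        assert np.array_equal(a.beta_early, b.beta_early)
        assert np.array_equal(a.ids, b.ids)

    def test_block_structure(self):
        spec = ScenarioSpec(n_variants=100, ld_block_size=10, ld_rho=0.8)
        panel = simulate_panel(spec)
        assert len(np.unique(panel.block)) == 10
        assert (np.bincount(panel.block) == 10).all()

    def test_no_palindromic_pairs_by_default(self):
        panel = simulate_panel(ScenarioSpec(n_variants=200, seed=5))
        pairs = {frozenset(p) for p in zip(panel.effect_allele,
                                           panel.other_allele)}
        assert frozenset("AT") not in pairs
        assert frozenset("GC") not in pairs

    def test_within_block_dosage_correlation_matches_threshold_model(self):
        # oracle: bivariate-normal orthant probability for the liability model
        spec = ScenarioSpec(n_variants=10, ld_block_size=5, ld_rho=0.8,
                            n_early_variants=0, n_adult_variants=0,
                            n_shared_variants=0, seed=11)
        panel = simulate_panel(spec)
        cohort = simulate_cohort(panel, spec, 50_000, "ld-check")
        corr = np.corrcoef(cohort.dosages, rowvar=False)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = expected_dosage_correlation(
                    spec.ld_rho, panel.maf[i], panel.maf[j])
                assert corr[i, j] == pytest.approx(expected, abs=0.02)
        # across blocks: independent
        assert abs(corr[:5, 5:]).max() < 0.02


class TestCohort:
    def test_same_seed_bit_identical_cohorts(self):
        spec = ScenarioSpec(seed=21)
        panel = simulate_panel(spec)
        a = simulate_cohort(panel, spec, 500, "exposure")
        b = simulate_cohort(panel, spec, 500, "exposure")
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.pheno, b.pheno)

    def test_two_sample_draws_differ(self):
        spec = ScenarioSpec(seed=21)
        panel = simulate_panel(spec)
        a = simulate_cohort(panel, spec, 500, "exposure")
        b = simulate_cohort(panel, spec, 500, "outcome")
        assert not np.array_equal(a.dosages, b.dosages)

    def test_category_marginals_match_proportions(self):
        props = (0.2, 0.5, 0.3)
        spec = ScenarioSpec(category_proportions=props, seed=8)
        panel = simulate_panel(spec)
        n = 5000
        cohort = simulate_cohort(panel, spec, n, "exposure")
        for col in ("early_category", "adult_category"):
            counts = np.bincount(cohort.pheno[col], minlength=3)
            for k, p in enumerate(props):
                # binomial 99% bounds (the cut is an empirical quantile,
                # so the real tolerance is rounding, far inside the bound)
                half = 2.576 * np.sqrt(p * (1 - p) / n)
                assert abs(counts[k] / n - p) <= half + 1 / n

    def test_path_model_total_effect(self):
        # pure mediation: regression of outcome on the early latent
        # recovers the path product 0.6 * 0.5 (no confounding)
        spec = ScenarioSpec(beta_early_to_adult=0.6, beta_adult_direct=0.5,
                            beta_early_direct=0.0, confounder_loading_early=0,
                            confounder_loading_adult=0,
                            confounder_loading_outcome=0, seed=13)
        panel = simulate_panel(spec)
        cohort = simulate_cohort(panel, spec, 100_000, "exposure")
        x = cohort.pheno["early_latent"].to_numpy()
        y = cohort.pheno["outcome"].to_numpy()
        slope, _, _, _, stderr = stats.linregress(x, y)
        assert abs(slope - 0.30) < 3 * stderr

    def test_global_null_scan_pvalues_uniform(self):
        spec = ScenarioSpec(n_variants=400, n_early_variants=0,
                            n_adult_variants=0, n_shared_variants=0,
                            beta_early_to_adult=0.0, beta_adult_direct=0.0,
                            seed=17)
        panel = simulate_panel(spec)
        cohort = simulate_cohort(panel, spec, 2000, "exposure")
        s = scan(cohort, "outcome", covariates=("age", "sex"))
        frac = (s["pval"] < 0.05).mean()
        assert abs(frac - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / 400)

    def test_binary_outcome_prevalence(self):
        spec = ScenarioSpec(outcome_model="binary-logistic",
                            baseline_prevalence=0.2, seed=19)
        panel = simulate_panel(spec)
        cohort = simulate_cohort(panel, spec, 20_000, "exposure")
        y = cohort.pheno["outcome"].to_numpy()
        assert set(np.unique(y)) <= {0.0, 1.0}
        assert y.mean() == pytest.approx(0.2, abs=0.02)

    def test_n_below_one_rejected(self):
        spec = ScenarioSpec(seed=1)
        panel = simulate_panel(spec)
        with pytest.raises(ValueError):
            simulate_cohort(panel, spec, 0, "exposure")

    def test_roundtrip_io(self, tmp_path):
        spec = ScenarioSpec(n_variants=10, n_early_variants=3,
                            n_adult_variants=3, seed=23)
        panel = simulate_panel(spec)
        cohort = simulate_cohort(panel, spec, 50, "exposure")
        prefix = str(tmp_path / "cohort")
        write_cohort(cohort, prefix)
        back = read_cohort(prefix, cohort.variants)
        assert np.array_equal(back.dosages, cohort.dosages)
        assert back.sample_label == "exposure"
        pd.testing.assert_frame_equal(back.pheno, cohort.pheno)


class TestMisclassification:
    @pytest.fixture
    def cohort(self):
        spec = ScenarioSpec(seed=29)
        return simulate_cohort(simulate_panel(spec), spec, 20_000,
                               "exposure"), spec

    def test_mode_none_is_identity(self, cohort):
        cohort, _ = cohort
        out = apply_misclassification(cohort, MisclassModel.none())
        assert (out.pheno["early_reported"]
                == out.pheno["early_category"]).all()

    def test_true_categories_retained(self, cohort):
        cohort, _ = cohort
        out = apply_misclassification(cohort, MisclassModel.symmetric(0.2))
        assert (out.pheno["early_category"]
                == cohort.pheno["early_category"]).all()
        assert (out.pheno["early_reported"]
                != out.pheno["early_category"]).mean() == pytest.approx(
                    0.2, abs=0.02)

    def test_symmetric_spill_attenuates_scan_betas(self, cohort):
        cohort, _ = cohort
        noisy = apply_misclassification(cohort, MisclassModel.symmetric(0.10))
        s_true = scan(cohort, "early_category")
        s_rep = scan(noisy, "early_reported")
        bt, br = s_true["beta"].to_numpy(), s_rep["beta"].to_numpy()
        shrink = (bt @ br) / (bt @ bt)
        # E[reported | true] has slope 1 - rate = 0.9
        assert 0.8 < shrink < 0.97

    def test_differential_mode_tracks_adult_size(self, cohort):
        cohort, _ = cohort
        model = MisclassModel.symmetric(0.2, mode="differential-on-adult",
                                        adult_dependence_slope=0.8)
        out = apply_misclassification(cohort, model)
        p = out.pheno
        mid = p[p["early_category"] == 1]
        big = mid["adult_latent"] > mid["adult_latent"].median()
        assert (mid.loc[big, "early_reported"].mean()
                > mid.loc[~big, "early_reported"].mean())

    def test_non_stochastic_confusion_rejected(self):
        bad = MisclassModel(mode="nondifferential",
                            confusion=np.full((3, 3), 0.5))
        with pytest.raises(ConfigurationError, match="sum to 1"):
            bad.validate()

    def test_mode_none_requires_identity_confusion(self):
        bad = MisclassModel(mode="none",
                            confusion=MisclassModel.symmetric(0.1).confusion)
        with pytest.raises(ConfigurationError, match="identity"):
            bad.validate()
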