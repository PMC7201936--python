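import numpy as np
import pandas as pd
import pytest

from lifemr.simulate import CohortData, ScenarioSpec, VariantPanel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Few strong variants: fast cohorts with usable instruments."""
    return ScenarioSpec(n_variants=30, n_early_variants=10,
                        n_adult_variants=10, n_shared_variants=0,
                        effect_size_sd_early=0.5, effect_size_sd_adult=0.5,
                        seed=42)


def make_cohort(dosages, pheno=None, variant_ids=None, label="exposure"):
    """Hand-built cohort for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if variant_ids is None:
        variant_ids = [f"rs{i + 1:05d}" for i in range(m)]
    variants = pd.DataFrame({"SNP": variant_ids,
                             "effect_allele": "A", "other_allele": "G"})
    if pheno is None:
        pheno = pd.DataFrame(index=range(n))
    return CohortData(dosages, variants, pheno.reset_index(drop=True), label)


def make_panel(beta_early, beta_adult, maf=0.3):
    m = len(beta_early)
    return VariantPanel(
        ids=np.array([f"rs{i + 1:05d}" for i in range(m)]),
        effect_allele=np.array(["A"] * m),
        other_allele=np.array(["G"] * m),
        maf=np.full(m, maf),
        block=np.arange(m),
        beta_early=np.asarray(beta_early, dtype=float),
        beta_adult=np.asarray(beta_adult, dtype=float),
    )
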