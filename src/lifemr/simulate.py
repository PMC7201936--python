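"""Synthetic two-sample cohorts for life-course Mendelian randomisation.

Generates individual-level data with the causal structure assumed by the
analysis: genetic variants in LD blocks acting on a latent early-life body
size, a latent adult body size partly mediated through the early trait, the
three-category measurement of both traits, covariates, a disease outcome,
an age-at-menarche negative-control trait, and optional misclassification
of the reported early-life category (possibly depending on actual adult
body size).

The path model
--------------
With genotype dosages ``G``, shared confounder ``U`` and independent noise::

    L_E = G @ b_E + c_E * U + covariate terms + eps_E        (early latent)
    L_A = theta * L_E + G @ b_A + c_A * U + ... + eps_A      (adult latent)
    eta = beta_ED * X_E + beta_AD * X_A + c_Y * U            (linear predictor)

where ``theta = beta_early_to_adult`` is the mediation arrow and
``X_E, X_A`` are the latents (default) or their categorical measurements
(``outcome_scale="category"``).  A continuous outcome is ``eta + eps_Y``;
a binary outcome is Bernoulli(expit(alpha + eta)) with the intercept solved
to give the requested baseline prevalence.  Age at menarche depends on the
early latent only, so adult body size can have no causal path to it.

Under this linear model the total effect of the early trait on a continuous
outcome equals ``beta_early_direct + beta_early_to_adult * beta_adult_direct``
and the indirect (adult-mediated) component is the path product.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ScenarioSpec",
    "MisclassModel",
    "VariantPanel",
    "CohortData",
    "ConfigurationError",
    "simulate_panel",
    "simulate_cohort",
    "apply_misclassification",
    "write_cohort",
    "read_cohort",
]


class ConfigurationError(ValueError):
    """A scenario or misclassification configuration field is invalid."""


# allele pairs; palindromic = strand-ambiguous complements (A/T, G/C)
_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


@dataclass
class ScenarioSpec:
    """Parameterisation of one causal scenario.

    The three canonical scenarios are obtained from the path coefficients:
    pure mediation (``beta_early_direct=0``, others non-zero), direct-only
    (``beta_adult_direct=0``) and both paths non-zero.

    Parameters
    ----------
    n_variants
        Total biallelic variants on the panel.
    maf_range
        Uniform sampling range for minor-allele frequencies, within (0, 0.5).
    ld_block_size, ld_rho
        Variants are arranged in consecutive blocks; within a block the
        latent allele liabilities are equicorrelated with correlation
        ``ld_rho``. ``ld_block_size=1`` or ``ld_rho=0`` gives independent
        variants.
    n_early_variants, n_adult_variants, n_shared_variants
        Counts of variants with per-allele effects on the early latent only,
        the adult latent only, or both. Remaining variants are null.
    effect_size_sd_early, effect_size_sd_adult
        Per-allele effects are drawn N(0, sd). Defaults of 0.15 give the
        causal panel a realistic share (~10-15%) of latent-trait variance.
    beta_early_to_adult
        Mediation path (tracking of body size from childhood to adulthood).
    beta_early_direct, beta_adult_direct
        Exposure -> outcome path coefficients on the linear predictor.
    outcome_model
        "continuous" or "binary-logistic".
    outcome_scale
        Whether the outcome depends on the latent traits ("latent",
        default) or their categorical measurements ("category").
    baseline_prevalence
        Marginal outcome probability for the binary model.
    confounder_sd, confounder_loading_*
        Shared confounder U ~ N(0, sd) loading on both latents and the
        outcome.
    menarche_beta_early
        Path from the early latent to age at menarche (negative control).
    category_proportions
        Marginal proportions of the three body-size categories, lowest
        first; the adult trait is cut at the same proportions.
    allow_palindromic
        Whether A/T and G/C allele pairs may occur on the panel.
    seed
        Base RNG seed; all draws are deterministic given it.
    """

    n_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.45)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    n_early_variants: int = 30
    n_adult_variants: int = 30
    n_shared_variants: int = 0
    effect_size_sd_early: float = 0.15
    effect_size_sd_adult: float = 0.15
    beta_early_to_adult: float = 0.6
    beta_early_direct: float = 0.0
    beta_adult_direct: float = 0.5
    outcome_model: str = "continuous"
    outcome_scale: str = "latent"
    baseline_prevalence: float = 0.1
    confounder_sd: float = 1.0
    confounder_loading_early: float = 0.2
    confounder_loading_adult: float = 0.2
    confounder_loading_outcome: float = 0.2
    menarche_beta_early: float = -0.5
    category_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    allow_palindromic: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo < hi < 0.5")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must be in [0, 1)")
        n_causal = (self.n_early_variants + self.n_adult_variants
                    + self.n_shared_variants)
        if min(self.n_early_variants, self.n_adult_variants,
               self.n_shared_variants) < 0 or n_causal > self.n_variants:
            raise ConfigurationError(
                "n_early_variants + n_adult_variants + n_shared_variants "
                "must be non-negative and <= n_variants")
        props = np.asarray(self.category_proportions, dtype=float)
        if props.shape != (3,) or (props <= 0).any():
            raise ConfigurationError(
                "category_proportions must be 3 positive numbers")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ConfigurationError("category_proportions must sum to 1")
        if self.outcome_model not in ("continuous", "binary-logistic"):
            raise ConfigurationError(
                "outcome_model must be 'continuous' or 'binary-logistic'")
        if self.outcome_scale not in ("latent", "category"):
            raise ConfigurationError(
                "outcome_scale must be 'latent' or 'category'")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ConfigurationError("baseline_prevalence must be in (0, 1)")
        if self.confounder_sd < 0:
            raise ConfigurationError("confounder_sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["category_proportions"] = list(self.category_proportions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown ScenarioSpec keys: {sorted(unknown)}")
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "category_proportions" in d:
            d["category_proportions"] = tuple(d["category_proportions"])
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class MisclassModel:
    """Reporting model for the early-life category.

    ``confusion[c, r]`` is the probability of reporting category ``r`` given
    true category ``c``. In ``differential-on-adult`` mode the row
    probabilities are exponentially tilted by the individual's adult latent:
    reporting ``r`` gets weight ``confusion[c, r] * exp(slope * L_A * r)``,
    renormalised, so a positive slope shifts reports upward for larger
    adults at every true category.
    """

    mode: str = "none"
    confusion: np.ndarray = field(
        default_factory=lambda: np.eye(3))
    adult_dependence_slope: float = 0.0

    def __post_init__(self):
        self.confusion = np.asarray(self.confusion, dtype=float)

    def validate(self) -> None:
        if self.mode not in ("none", "nondifferential", "differential-on-adult"):
            raise ConfigurationError(f"unknown misclassification mode {self.mode!r}")
        if self.confusion.shape != (3, 3) or (self.confusion < 0).any():
            raise ConfigurationError("confusion must be a non-negative 3x3 matrix")
        if np.abs(self.confusion.sum(axis=1) - 1.0).max() > 1e-12:
            raise ConfigurationError("confusion rows must each sum to 1")
        if self.mode == "none" and not np.array_equal(self.confusion, np.eye(3)):
            raise ConfigurationError("mode 'none' requires an identity confusion matrix")

    @classmethod
    def none(cls) -> "MisclassModel":
        return cls()

    @classmethod
    def symmetric(cls, rate: float, mode: str = "nondifferential",
                  adult_dependence_slope: float = 0.0) -> "MisclassModel":
        """Symmetric spill of probability `rate` to adjacent categories."""
        c = np.array([[1 - rate, rate, 0.0],
                      [rate / 2, 1 - rate, rate / 2],
                      [0.0, rate, 1 - rate]])
        m = cls(mode=mode, confusion=c,
                adult_dependence_slope=adult_dependence_slope)
        m.validate()
        return m

    def to_dict(self) -> dict:
        return {"mode": self.mode,
                "confusion": self.confusion.tolist(),
                "adult_dependence_slope": self.adult_dependence_slope}

    @classmethod
    def from_dict(cls, d: dict) -> "MisclassModel":
        known = {"mode", "confusion", "adult_dependence_slope"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown MisclassModel keys: {sorted(unknown)}")
        m = cls(**d)
        m.validate()
        return m


@dataclass
class VariantPanel:
    """Variant metadata and true per-allele latent-trait effects."""

    ids: np.ndarray                  # str array
    effect_allele: np.ndarray
    other_allele: np.ndarray
    maf: np.ndarray
    block: np.ndarray                # block index per variant
    beta_early: np.ndarray           # true effect on early latent
    beta_adult: np.ndarray           # true effect on adult latent

    @property
    def n_variants(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "SNP": self.ids, "effect_allele": self.effect_allele,
            "other_allele": self.other_allele, "maf": self.maf,
            "block": self.block, "beta_early": self.beta_early,
            "beta_adult": self.beta_adult,
        })


@dataclass
class CohortData:
    """Individual-level data for one sample (exposure or outcome arm)."""

    dosages: np.ndarray              # n x m, values 0/1/2
    variants: pd.DataFrame           # SNP, effect_allele, other_allele
    pheno: pd.DataFrame              # per-individual phenotypes/covariates
    sample_label: str = "exposure"

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["SNP"].to_numpy()

    def filter(self, mask: np.ndarray) -> "CohortData":
        """Row-subset the cohort (e.g. sex-stratified analyses)."""
        mask = np.asarray(mask, dtype=bool)
        return CohortData(self.dosages[mask], self.variants,
                          self.pheno.loc[mask].reset_index(drop=True),
                          self.sample_label)


def _rng_for(spec_seed: int, label: str) -> np.random.Generator:
    # label folded into the seed sequence so exposure/outcome arms are
    # independent streams of the same scenario seed
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(spec_seed) & 0x7FFFFFFF,
                               spawn_key=(zlib.crc32(label.encode()),)))


def simulate_panel(spec: ScenarioSpec) -> VariantPanel:
    """Draw a variant panel: MAFs, alleles, LD blocks and true effects.

    Variant classes (early-only / adult-only / shared / null) are assigned
    by a seeded permutation; effects are N(0, effect_size_sd).
    """
    spec.validate()
    rng = _rng_for(spec.seed, "panel")
    m = spec.n_variants
    maf = rng.uniform(*spec.maf_range, size=m)
    pairs = _NON_PALINDROMIC + (_PALINDROMIC if spec.allow_palindromic else [])
    pick = rng.integers(0, len(pairs), size=m)
    ea = np.array([pairs[i][0] for i in pick])
    oa = np.array([pairs[i][1] for i in pick])
    block = np.arange(m) // spec.ld_block_size
    ids = np.array([f"rs{i + 1:05d}" for i in range(m)])

    order = rng.permutation(m)
    n_e, n_a, n_s = (spec.n_early_variants, spec.n_adult_variants,
                     spec.n_shared_variants)
    early_idx = order[:n_e]
    adult_idx = order[n_e:n_e + n_a]
    shared_idx = order[n_e + n_a:n_e + n_a + n_s]
    b_e = np.zeros(m)
    b_a = np.zeros(m)
    b_e[early_idx] = rng.normal(0, spec.effect_size_sd_early, n_e)
    b_a[adult_idx] = rng.normal(0, spec.effect_size_sd_adult, n_a)
    b_e[shared_idx] = rng.normal(0, spec.effect_size_sd_early, n_s)
    b_a[shared_idx] = rng.normal(0, spec.effect_size_sd_adult, n_s)
    return VariantPanel(ids, ea, oa, maf, block, b_e, b_a)


def _draw_genotypes(panel: VariantPanel, spec: ScenarioSpec, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Dosages from per-block equicorrelated liability thresholds.

    Each haplotype's allele indicator is 1 when a standard-normal liability
    falls below the MAF quantile; liabilities within a block share an
    equicorrelation ``ld_rho``. Two independent haplotypes are summed.
    With ``ld_rho=0`` this reduces to Binomial(2, maf), which is drawn
    directly for speed.
    """
    m = panel.n_variants
    if spec.ld_rho == 0.0 or spec.ld_block_size == 1:
        return rng.binomial(2, panel.maf, size=(n, m)).astype(np.float64)
    thr = stats.norm.ppf(panel.maf)
    G = np.empty((n, m), dtype=np.float64)
    sr, si = np.sqrt(spec.ld_rho), np.sqrt(1.0 - spec.ld_rho)
    for b in np.unique(panel.block):
        cols = np.flatnonzero(panel.block == b)
        dose = np.zeros((n, len(cols)))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            z = sr * shared + si * rng.standard_normal((n, len(cols)))
            dose += (z < thr[cols])
        G[:, cols] = dose
    return G


def expected_dosage_correlation(rho: float, maf_a: float, maf_b: float) -> float:
    """Population dosage correlation implied by the liability-threshold
    LD model — the closed-form counterpart of the empirical within-block
    correlation.

    For one haplotype, cov = P(Z_a < t_a, Z_b < t_b) - p_a p_b with the
    bivariate-normal orthant probability at correlation ``rho``; dosages
    sum two independent haplotypes, leaving the correlation unchanged.
    """
    ta, tb = stats.norm.ppf(maf_a), stats.norm.ppf(maf_b)
    joint = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([ta, tb])
    cov = joint - maf_a * maf_b
    return cov / np.sqrt(maf_a * (1 - maf_a) * maf_b * (1 - maf_b))


def _categorise(values: np.ndarray, proportions: Sequence[float]) -> np.ndarray:
    """Empirical quantile cut into categories 0/1/2 at the given proportions."""
    cum = np.cumsum(proportions)[:2]
    cuts = np.quantile(values, cum)
    return np.digitize(values, cuts).astype(np.int64)


def simulate_cohort(panel: VariantPanel, spec: ScenarioSpec, n: int,
                    sample_label: str = "exposure") -> CohortData:
    """Simulate one sample of ``n`` individuals under the scenario.

    Exposure-arm and outcome-arm samples of the same scenario use
    independent RNG streams keyed by ``sample_label``, giving the
    two-sample design. Small age/sex/month-of-birth effects are placed on
    the latents so covariate adjustment in the scans is exercised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    rng = _rng_for(spec.seed, f"cohort:{sample_label}")
    m = panel.n_variants

    G = _draw_genotypes(panel, spec, n, rng)
    age = rng.uniform(40, 70, n)
    sex = rng.integers(0, 2, n).astype(np.float64)   # 1 = female
    month = rng.integers(1, 13, n).astype(np.float64)
    U = rng.normal(0.0, spec.confounder_sd, n)

    early = (G @ panel.beta_early
             + spec.confounder_loading_early * U
             + 0.01 * (month - 6.5) + 0.05 * sex
             + rng.standard_normal(n))
    adult = (spec.beta_early_to_adult * early
             + G @ panel.beta_adult
             + spec.confounder_loading_adult * U
             + 0.01 * (age - 55.0) + 0.05 * sex
             + rng.standard_normal(n))

    cat_e = _categorise(early, spec.category_proportions)
    # adult trait cut at the same proportions as the early-life variable
    cat_a = _categorise(adult, spec.category_proportions)

    if spec.outcome_scale == "latent":
        x_e, x_a = early, adult
    else:
        x_e, x_a = cat_e.astype(float), cat_a.astype(float)
    eta = (spec.beta_early_direct * x_e + spec.beta_adult_direct * x_a
           + spec.confounder_loading_outcome * U)
    if spec.outcome_model == "continuous":
        outcome = eta + rng.standard_normal(n)
    else:
        def mean_prev(alpha):
            return special.expit(alpha + eta).mean() - spec.baseline_prevalence
        alpha = optimize.brentq(mean_prev, -40.0, 40.0)
        outcome = rng.binomial(1, special.expit(alpha + eta)).astype(np.float64)

    menarche = 13.0 + spec.menarche_beta_early * early + rng.standard_normal(n)

    pheno = pd.DataFrame({
        "early_latent": early,
        "early_category": cat_e,
        "early_reported": cat_e.copy(),
        "adult_latent": adult,
        "adult_category": cat_a,
        "age": age, "sex": sex, "month_of_birth": month,
        "outcome": outcome, "menarche": menarche,
    })
    variants = pd.DataFrame({"SNP": panel.ids,
                             "effect_allele": panel.effect_allele,
                             "other_allele": panel.other_allele})
    return CohortData(G, variants, pheno, sample_label)


def apply_misclassification(cohort: CohortData,
                            model: MisclassModel) -> CohortData:
    """Redraw ``early_reported`` from the confusion model.

    True categories are retained in ``early_category`` so oracle
    comparisons against the error-free measure remain possible. The draw
    is seeded from the cohort's phenotype content, so it is deterministic
    for a given cohort and model.
    """
    model.validate()
    pheno = cohort.pheno.copy()
    true = pheno["early_category"].to_numpy()
    if model.mode == "none":
        pheno["early_reported"] = true.copy()
        return CohortData(cohort.dosages, cohort.variants, pheno,
                          cohort.sample_label)
    seed = zlib.crc32(pheno["early_latent"].to_numpy().tobytes()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    probs = model.confusion[true]                     # n x 3
    if model.mode == "differential-on-adult":
        adult = pheno["adult_latent"].to_numpy()
        tilt = np.exp(model.adult_dependence_slope
                      * adult[:, None] * np.arange(3)[None, :])
        probs = probs * tilt
        probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(len(true))[:, None]
    reported = (probs.cumsum(axis=1) < u).sum(axis=1)
    pheno["early_reported"] = reported.astype(np.int64)
    return CohortData(cohort.dosages, cohort.variants, pheno,
                      cohort.sample_label)


def write_cohort(cohort: CohortData, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.genotypes.tsv`` and ``<prefix>.pheno.tsv``."""
    gpath, ppath = f"{prefix}.genotypes.tsv", f"{prefix}.pheno.tsv"
    pd.DataFrame(cohort.dosages.astype(np.int64),
                 columns=cohort.variant_ids).to_csv(gpath, sep="\t", index=False)
    pheno = cohort.pheno.copy()
    pheno.insert(0, "sample_label", cohort.sample_label)
    pheno.to_csv(ppath, sep="\t", index=False)
    return gpath, ppath


def read_cohort(prefix: str,
                variants: pd.DataFrame | None = None) -> CohortData:
    """Read a cohort written by :func:`write_cohort`.

    Allele labels are not stored in the genotype matrix; pass the panel's
    variant table to restore them (identifiers default to the genotype
    header with placeholder alleles otherwise).
    """
    G = pd.read_csv(f"{prefix}.genotypes.tsv", sep="\t")
    pheno = pd.read_csv(f"{prefix}.pheno.tsv", sep="\t")
    label = str(pheno.pop("sample_label").iloc[0])
    if variants is None:
        variants = pd.DataFrame({"SNP": G.columns,
                                 "effect_allele": "A", "other_allele": "G"})
    return CohortData(G.to_numpy(dtype=np.float64), variants.reset_index(drop=True),
                      pheno, label)


def scenario_with(spec: ScenarioSpec, **overrides) -> ScenarioSpec:
    """Copy a spec with field overrides, revalidating."""
    out = replace(spec, **overrides)
    out.validate()
    return out
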