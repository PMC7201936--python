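"""End-to-end two-sample analysis on a simulated scenario.

One call runs the full workflow the framework defines: simulate the two
independent samples from a shared variant panel, scan the exposures in the
exposure sample and the outcome in the outcome sample, select instruments
by genome-wide significance and greedy LD clumping (jointly re-clumped
across exposures), harmonize, then fit univariable IVW (total effect of
the early-life exposure), multivariable MR (direct effects) and the
total/direct/indirect decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scan import cross_exposure_instrument_set, ld_clump, scan
from .harmonize import HarmonizedSet, harmonize
from .multivariable import Decomposition, MVMRFit, decompose, mvmr_fit
from .simulate import (CohortData, MisclassModel, ScenarioSpec,
                       apply_misclassification, simulate_cohort,
                       simulate_panel)
from .univariable import MRFit, ivw, mean_f

__all__ = ["TwoSampleResult", "run_two_sample"]

P_THRESHOLD = 5e-8
R2_THRESHOLD = 0.001


@dataclass
class TwoSampleResult:
    """All artefacts of one two-sample run."""

    early_total: MRFit | None
    mvmr: MVMRFit | None
    decomposition: Decomposition | None
    harmonized: HarmonizedSet | None
    n_instruments_early: int
    n_instruments_adult: int
    n_instruments_joint: int
    f_mean_early: float
    ok: bool
    reason: str = ""


def run_two_sample(spec: ScenarioSpec,
                   misclass: MisclassModel | None = None,
                   n_exposure: int = 20_000,
                   n_outcome: int = 20_000,
                   n_selection: int | None = None,
                   early_phenotype: str = "early_latent",
                   adult_phenotype: str = "adult_latent",
                   outcome_phenotype: str = "outcome",
                   p_threshold: float = P_THRESHOLD,
                   r2_threshold: float = R2_THRESHOLD,
                   outcome_log_odds: bool = False) -> TwoSampleResult:
    """Run the full scan -> clump -> harmonize -> IVW + MVMR pipeline.

    ``early_phenotype`` may be the latent trait, the true category, or —
    when a misclassification model is supplied — ``early_reported``.
    Early-life scans adjust for age, sex and month of birth; adult scans
    and the outcome scan adjust for age and sex. Returns a result with
    ``ok=False`` (rather than raising) when instrument selection leaves
    too few variants for the joint model.

    With ``n_selection`` set, a third independent sample of that size is
    simulated (with the same misclassification applied) and instruments
    are selected — significance filtering and LD clumping — on its scans,
    while the exposure betas entering the estimators come from the
    exposure sample. Selecting in an independent sample removes
    winner's-curse (regression-to-the-mean) inflation of the selected
    exposure betas, which would otherwise attenuate the causal estimates;
    the LD reference is then external to the estimation data, as when
    clumping against an external reference panel. With ``n_selection=None``
    selection and estimation use the exposure sample, as a discovery GWAS
    doubling as the exposure study would.
    """
    panel = simulate_panel(spec)
    exp_cohort = simulate_cohort(panel, spec, n_exposure, "exposure")
    out_cohort = simulate_cohort(panel, spec, n_outcome, "outcome")
    if misclass is not None:
        exp_cohort = apply_misclassification(exp_cohort, misclass)
    if n_selection is not None:
        sel_cohort = simulate_cohort(panel, spec, n_selection, "selection")
        if misclass is not None:
            sel_cohort = apply_misclassification(sel_cohort, misclass)
    else:
        sel_cohort = exp_cohort

    early_covs = ("age", "sex", "month_of_birth")
    adult_covs = ("age", "sex")
    s_early = scan(exp_cohort, early_phenotype, covariates=early_covs)
    s_adult = scan(exp_cohort, adult_phenotype, covariates=adult_covs)
    s_out = scan(out_cohort, outcome_phenotype,
                          covariates=("age", "sex"))
    if sel_cohort is exp_cohort:
        sel_early, sel_adult = s_early, s_adult
    else:
        sel_early = scan(sel_cohort, early_phenotype,
                                  covariates=early_covs)
        sel_adult = scan(sel_cohort, adult_phenotype,
                                  covariates=adult_covs)

    c_early = ld_clump(sel_early, sel_cohort,
                                p_threshold=p_threshold,
                                r2_threshold=r2_threshold)
    c_adult = ld_clump(sel_adult, sel_cohort,
                                p_threshold=p_threshold,
                                r2_threshold=r2_threshold)
    joint = cross_exposure_instrument_set(
        c_early, c_adult, sel_cohort,
        p_threshold=p_threshold, r2_threshold=r2_threshold)

    n_e, n_a, n_j = len(c_early), len(c_adult), len(joint)
    if n_e < 2 or n_j < 3:
        return TwoSampleResult(None, None, None, None, n_e, n_a, n_j,
                               np.nan, ok=False,
                               reason=f"too few instruments "
                                      f"(early {n_e}, joint {n_j})")

    keep = s_early["SNP"].isin(c_early["SNP"])
    h_total = harmonize(s_early[keep].reset_index(drop=True), s_out,
                        labels=["early"])
    total = ivw(h_total, exposure="early",
                outcome_log_odds=outcome_log_odds)

    keep_j = s_early["SNP"].isin(joint["SNP"])
    h_joint = harmonize(
        [s_early[keep_j].reset_index(drop=True),
         s_adult[keep_j].reset_index(drop=True)],
        s_out, labels=["early", "adult"])
    fit = mvmr_fit(h_joint, outcome_log_odds=outcome_log_odds)
    dec = decompose(total, fit, "early")
    return TwoSampleResult(
        early_total=total, mvmr=fit, decomposition=dec, harmonized=h_joint,
        n_instruments_early=n_e, n_instruments_adult=n_a,
        n_instruments_joint=n_j,
        f_mean_early=mean_f(s_early[keep]), ok=True)
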