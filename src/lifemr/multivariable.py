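"""Multivariable MR: joint direct effects, conditional instrument
strength, the total/direct/indirect decomposition, and the age-at-menarche
negative-control analysis.

The decomposition is the framework's core output: with the total effect of
the early-life exposure from univariable MR and its direct effect from
multivariable MR conditioning on the adult exposure, the indirect
(adult-mediated) component is ``total - direct`` on the analysis scale,
and the pattern of the two estimates classifies the causal scenario:
mediation only, direct only, or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MVMRRegressor
from .harmonize import HarmonizedSet
from .univariable import MRFit, ivw

__all__ = ["MVMRFit", "Decomposition", "NegativeControlReport",
           "mvmr_fit", "conditional_f", "decompose",
           "negative_control_analysis"]

_Z95 = 1.96


@dataclass
class MVMRFit:
    """Joint direct-effect estimates for k exposures."""

    exposures: tuple[str, ...]
    betas: np.ndarray
    ses: np.ndarray
    n_variants: int
    conditional_f: np.ndarray | None = None
    q: float = np.nan
    q_df: int = 0
    q_pvalue: float = np.nan
    outcome_log_odds: bool = False

    def beta(self, exposure: str) -> float:
        return float(self.betas[self.exposures.index(exposure)])

    def se(self, exposure: str) -> float:
        return float(self.ses[self.exposures.index(exposure)])

    def ci(self, exposure: str) -> tuple[float, float]:
        b, s = self.beta(exposure), self.se(exposure)
        return (b - _Z95 * s, b + _Z95 * s)

    def odds_ratio(self, exposure: str):
        if not self.outcome_log_odds:
            return None, None
        lo, hi = self.ci(exposure)
        return (float(np.exp(self.beta(exposure))),
                (float(np.exp(lo)), float(np.exp(hi))))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.exposures):
            lo, hi = self.ci(e)
            row = {"method": "MVMR", "exposure": e,
                   "beta": float(self.betas[i]), "se": float(self.ses[i]),
                   "ci_low": lo, "ci_high": hi,
                   "pvalue": float(2 * stats.norm.sf(
                       abs(self.betas[i] / self.ses[i]))),
                   "n_variants": self.n_variants,
                   "conditional_f": (float(self.conditional_f[i])
                                     if self.conditional_f is not None
                                     else np.nan),
                   "q": self.q, "q_df": self.q_df, "q_pvalue": self.q_pvalue}
            if self.outcome_log_odds:
                or_, ci = self.odds_ratio(e)
                row["odds_ratio"] = or_
                row["or_ci_low"], row["or_ci_high"] = ci
            rows.append(row)
        return pd.DataFrame(rows)


def mvmr_fit(h: HarmonizedSet, outcome_log_odds: bool = False) -> MVMRFit:
    """Direct effects of the k exposures by weighted normal equations.

    Weighted least squares of outcome betas on the k exposure-beta columns
    with no intercept, weights 1/se_outcome^2. Instrument orientation is
    not forced: signs are absorbed by the joint regression. With k=1 the
    result equals the univariable IVW estimate on the same variants.
    """
    X = h.exposure_betas()
    y = h.outcome_betas()
    w = 1.0 / h.outcome_ses() ** 2
    k = X.shape[1]
    if h.n_variants <= k:
        raise ValueError(
            f"need more variants ({h.n_variants}) than exposures ({k})")
    est = MVMRRegressor().fit(X, y, w)
    cf = est.conditional_f(X, h.exposure_ses()) if k >= 2 else None
    return MVMRFit(exposures=h.exposures, betas=est.coef_, ses=est.stderr_,
                   n_variants=h.n_variants, conditional_f=cf,
                   q=est.q_, q_df=est.q_df_, q_pvalue=est.q_pvalue_,
                   outcome_log_odds=outcome_log_odds)


def conditional_f(h: HarmonizedSet, exposure: str) -> float:
    """Instrument strength of one exposure conditional on the others."""
    if len(h.exposures) < 2:
        raise ValueError("conditional F needs k >= 2 exposures; "
                         "use mean_f for marginal strength")
    if exposure not in h.exposures:
        raise KeyError(f"exposure {exposure!r} not in harmonized set")
    X = h.exposure_betas()
    est = MVMRRegressor().fit(X, h.outcome_betas(),
                              1.0 / h.outcome_ses() ** 2)
    cf = est.conditional_f(X, h.exposure_ses())
    return float(cf[h.exposures.index(exposure)])


@dataclass
class Decomposition:
    """Total/direct/indirect decomposition for one exposure."""

    exposure: str
    total: float
    total_se: float
    direct: float
    direct_se: float
    indirect: float
    indirect_se: float              # independence approximation
    scenario: str                   # mediated | direct-only | both
    outcome_log_odds: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "exposure": self.exposure, "total": self.total,
            "total_se": self.total_se, "direct": self.direct,
            "direct_se": self.direct_se, "indirect": self.indirect,
            "indirect_se_approx": self.indirect_se,
            "scenario": self.scenario,
        }])

    def describe(self) -> str:
        labels = {
            "mediated": ("indirect effect only: the early-life effect is "
                         "mediated through the adult exposure"),
            "direct-only": ("direct effect only: the early-life effect is "
                            "independent of the adult exposure"),
            "both": "both direct and indirect effects are present",
        }
        return (f"exposure {self.exposure}: total {self.total:+.3f} "
                f"(se {self.total_se:.3f}), direct {self.direct:+.3f} "
                f"(se {self.direct_se:.3f}), indirect {self.indirect:+.3f} "
                f"(approx se {self.indirect_se:.3f}) -> "
                f"{self.scenario}: {labels[self.scenario]}")


def _ci_covers(beta: float, se: float, value: float = 0.0) -> bool:
    return beta - _Z95 * se <= value <= beta + _Z95 * se


def _cis_overlap(b1, s1, b2, s2) -> bool:
    return not (b1 + _Z95 * s1 < b2 - _Z95 * s2
                or b2 + _Z95 * s2 < b1 - _Z95 * s1)


def decompose(total: MRFit, direct: MVMRFit, exposure: str,
              similarity: float = 0.2) -> Decomposition:
    """Split a total effect into direct and indirect components.

    ``indirect = total - direct`` on the analysis (log-odds or linear)
    scale, with the independence approximation
    ``se = (se_total^2 + se_direct^2)^0.5`` — approximate because the two
    estimates share instruments. The scenario label is a reporting
    heuristic: "mediated" when the direct CI covers 0 while the total CI
    excludes it; "direct-only" when direct and total agree (difference
    below ``similarity * |total|`` with overlapping CIs); "both"
    otherwise.
    """
    if total.exposure != exposure:
        raise ValueError("total fit is for a different exposure")
    if total.outcome_log_odds != direct.outcome_log_odds:
        raise ValueError("total and direct fits are on different scales")
    d_beta, d_se = direct.beta(exposure), direct.se(exposure)
    indirect = total.beta - d_beta
    ind_se = float(np.hypot(total.se, d_se))
    if _ci_covers(d_beta, d_se) and not _ci_covers(total.beta, total.se):
        scenario = "mediated"
    elif (abs(indirect) < similarity * abs(total.beta)
          and _cis_overlap(total.beta, total.se, d_beta, d_se)):
        scenario = "direct-only"
    else:
        scenario = "both"
    return Decomposition(exposure=exposure, total=total.beta,
                         total_se=total.se, direct=d_beta, direct_se=d_se,
                         indirect=indirect, indirect_se=ind_se,
                         scenario=scenario,
                         outcome_log_odds=total.outcome_log_odds)


@dataclass
class NegativeControlReport:
    """Outcome of the age-at-menarche negative-control analysis.

    Adult body size cannot influence the timing of puberty, so a valid
    framework should find (a) an adult direct effect compatible with zero
    and (b) an early-life direct effect matching its univariable total.
    """

    fit: MVMRFit
    early_total: MRFit
    adult_ci_covers_zero: bool
    early_direct_matches_total: bool
    difference: float
    difference_se: float

    @property
    def passed(self) -> bool:
        return self.adult_ci_covers_zero and self.early_direct_matches_total


def negative_control_analysis(h: HarmonizedSet,
                              early: str = "early", adult: str = "adult",
                              total_fit: MRFit | None = None
                              ) -> NegativeControlReport:
    """MVMR of early and adult body size on age at menarche.

    Fits the joint model and checks the two falsifiable expectations.
    ``total_fit`` supplies the univariable early-life total effect (it is
    computed by IVW on this set's early columns when omitted; supplying a
    fit from the early-only clumped instrument list is more faithful).
    Equality of direct and total uses the independence-approximation
    standard error of the difference, which is conservative because the
    two estimates share instruments.
    """
    for lab in (early, adult):
        if lab not in h.exposures:
            raise KeyError(f"exposure {lab!r} not in harmonized set")
    fit = mvmr_fit(h)
    if total_fit is None:
        total_fit = ivw(h.subset_exposures((early,)), exposure=early)
    diff = fit.beta(early) - total_fit.beta
    diff_se = float(np.hypot(fit.se(early), total_fit.se))
    return NegativeControlReport(
        fit=fit, early_total=total_fit,
        adult_ci_covers_zero=_ci_covers(fit.beta(adult), fit.se(adult)),
        early_direct_matches_total=abs(diff) <= _Z95 * diff_se,
        difference=diff, difference_se=diff_se)
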