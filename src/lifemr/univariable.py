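"""Univariable two-sample MR: total effects and sensitivity statistics.

The reporting convention follows the categorical body-size scale: when the
outcome associations are log odds, estimates exponentiate to the change in
odds per additive change in body-size category. Confidence intervals use
the 1.96 normal quantile throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import IVWRegressor, MREggerRegressor
from .harmonize import HarmonizedSet

__all__ = ["MRFit", "wald_ratio", "ivw", "mr_egger", "cochran_q", "mean_f",
           "to_odds_ratio"]

_Z95 = 1.96


@dataclass
class MRFit:
    """A univariable MR estimate with sensitivity statistics."""

    method: str
    exposure: str
    beta: float
    se: float
    n_variants: int
    q: float = np.nan
    q_df: int = 0
    q_pvalue: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_pvalue: float = np.nan
    f_mean: float = np.nan
    outcome_log_odds: bool = False
    note: str = ""

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - _Z95 * self.se, self.beta + _Z95 * self.se)

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.beta)) if self.outcome_log_odds else None

    @property
    def odds_ratio_ci(self) -> tuple[float, float] | None:
        if not self.outcome_log_odds:
            return None
        lo, hi = self.ci
        return (float(np.exp(lo)), float(np.exp(hi)))

    @property
    def pvalue(self) -> float:
        return float(2 * stats.norm.sf(abs(self.beta / self.se)))

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci
        row = {"method": self.method, "exposure": self.exposure,
               "beta": self.beta, "se": self.se, "ci_low": lo, "ci_high": hi,
               "pvalue": self.pvalue, "n_variants": self.n_variants,
               "q": self.q, "q_df": self.q_df, "q_pvalue": self.q_pvalue,
               "egger_intercept": self.egger_intercept,
               "egger_intercept_pvalue": self.egger_intercept_pvalue,
               "f_mean": self.f_mean, "note": self.note}
        if self.outcome_log_odds:
            row["odds_ratio"] = self.odds_ratio
            row["or_ci_low"], row["or_ci_high"] = self.odds_ratio_ci
        return pd.DataFrame([row])


def wald_ratio(beta_exposure: float, se_exposure: float,
               beta_outcome: float, se_outcome: float,
               second_order: bool = False) -> tuple[float, float]:
    """Single-variant causal estimate: outcome beta over exposure beta.

    The default standard error is the first-order delta approximation
    ``se_outcome / |beta_exposure|`` (consistent with IVW weighting); the
    second-order form adds the exposure-uncertainty term.
    """
    if beta_exposure == 0:
        raise ZeroDivisionError("Wald ratio undefined for zero exposure beta")
    est = beta_outcome / beta_exposure
    se = abs(se_outcome / beta_exposure)
    if second_order:
        se = np.sqrt(se_outcome ** 2 / beta_exposure ** 2
                     + beta_outcome ** 2 * se_exposure ** 2
                     / beta_exposure ** 4)
    return float(est), float(se)


def _single_exposure(h: HarmonizedSet, exposure: str | None) -> str:
    if exposure is None:
        if len(h.exposures) != 1:
            raise ValueError("harmonized set has several exposures; "
                             "name the one to analyse")
        return h.exposures[0]
    if exposure not in h.exposures:
        raise KeyError(f"exposure {exposure!r} not in harmonized set")
    return exposure


def ivw(h: HarmonizedSet, exposure: str | None = None,
        outcome_log_odds: bool = False,
        random_effects: bool = False) -> MRFit:
    """Inverse-variance-weighted total effect (fixed-effect by default).

    Combines per-variant Wald ratios in a fixed-effect meta-analysis,
    i.e. weighted regression of outcome betas on exposure betas through
    the origin with weights 1/se_outcome^2. Requires at least two
    variants (use :func:`wald_ratio` for one).
    """
    exposure = _single_exposure(h, exposure)
    if h.n_variants < 2:
        raise ValueError("IVW needs >= 2 variants; use wald_ratio for one")
    x = h.table[f"beta_{exposure}"].to_numpy()
    y = h.outcome_betas()
    w = 1.0 / h.outcome_ses() ** 2
    est = IVWRegressor(random_effects=random_effects).fit(x[:, None], y, w)
    bx_se = h.table[f"se_{exposure}"].to_numpy()
    return MRFit(method="IVW" + ("-RE" if random_effects else ""),
                 exposure=exposure,
                 beta=float(est.coef_[0]), se=float(est.stderr_[0]),
                 n_variants=h.n_variants, q=est.q_, q_df=est.q_df_,
                 q_pvalue=est.q_pvalue_,
                 f_mean=float(np.mean((x / bx_se) ** 2)),
                 outcome_log_odds=outcome_log_odds)


def mr_egger(h: HarmonizedSet, exposure: str | None = None,
             outcome_log_odds: bool = False) -> MRFit:
    """MR-Egger slope and pleiotropy-intercept test (>= 3 variants)."""
    exposure = _single_exposure(h, exposure)
    if h.n_variants < 3:
        raise ValueError("MR-Egger needs >= 3 variants")
    x = h.table[f"beta_{exposure}"].to_numpy()
    y = h.outcome_betas()
    w = 1.0 / h.outcome_ses() ** 2
    est = MREggerRegressor().fit(x[:, None], y, w)
    return MRFit(method="MR-Egger", exposure=exposure,
                 beta=float(est.coef_[0]), se=float(est.stderr_[0]),
                 n_variants=h.n_variants, q=est.q_, q_df=est.q_df_,
                 egger_intercept=est.intercept_,
                 egger_intercept_se=est.intercept_stderr_,
                 egger_intercept_pvalue=est.intercept_pvalue_,
                 outcome_log_odds=outcome_log_odds)


def cochran_q(h: HarmonizedSet, fit: MRFit) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q for an IVW fit on the same variants.

    ``Q = sum_j w_j (beta_yj - beta_hat * beta_xj)^2`` with inverse-variance
    weights; referred to the chi-square with n_variants - 1 df.
    """
    if fit.n_variants != h.n_variants:
        raise ValueError("fit does not correspond to this harmonized set")
    if h.n_variants < 2:
        raise ValueError("Q undefined for a single variant (0 df)")
    x = h.table[f"beta_{fit.exposure}"].to_numpy()
    y = h.outcome_betas()
    w = 1.0 / h.outcome_ses() ** 2
    q = float(w @ (y - fit.beta * x) ** 2)
    df = h.n_variants - 1
    return q, df, float(stats.chi2.sf(q, df))


def mean_f(stats_table: pd.DataFrame) -> float:
    """Mean instrument-strength F: average of (beta/se)^2 over instruments."""
    if len(stats_table) == 0:
        raise ValueError("no instruments")
    z = stats_table["beta"].to_numpy() / stats_table["se"].to_numpy()
    return float(np.mean(z ** 2))


def to_odds_ratio(beta: float, se: float) -> tuple[float, tuple[float, float]]:
    """Exponentiate a log-odds estimate to OR with its 95% CI."""
    return (float(np.exp(beta)),
            (float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))))
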