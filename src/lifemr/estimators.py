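"""Summary-statistic MR estimators in the scikit-learn estimator idiom.

All three estimators are weighted least-squares regressions of per-variant
outcome associations on exposure associations:

* :class:`IVWRegressor` — through the origin with a single exposure; the
  classical inverse-variance-weighted fixed-effect combination of Wald
  ratios.
* :class:`MREggerRegressor` — with an intercept; the intercept estimates
  directional pleiotropy and the slope the causal effect.
* :class:`MVMRRegressor` — through the origin with k exposure columns;
  each coefficient is a direct effect conditional on the other exposures.

``fit(X, y, sample_weight)`` takes X = exposure betas (n_variants x k),
y = outcome betas, and sample_weight = 1 / se_outcome**2 (the inverse
variance weights; unweighted if omitted). The estimators are stateless
before fit, expose ``get_params``/``set_params``, and validate inputs, so
they compose with sklearn tooling; fitted quantities carry trailing
underscores.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["IVWRegressor", "MREggerRegressor", "MVMRRegressor"]


def _weights(y, sample_weight):
    if sample_weight is None:
        return np.ones_like(y)
    w = np.asarray(sample_weight, dtype=float)
    if w.shape != y.shape or (w <= 0).any():
        raise ValueError("sample_weight must be positive, one per variant")
    return w


class _WLSThroughOrigin(RegressorMixin, BaseEstimator):
    """Shared machinery: weighted normal equations without intercept."""

    def __init__(self, random_effects: bool = False):
        self.random_effects = random_effects

    def _fit_wls(self, X, y, w):
        XtW = X.T * w
        A = XtW @ X
        if np.linalg.matrix_rank(A) < A.shape[0]:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(X, rowvar=False)
            pairs = [(i, j) for i in range(X.shape[1])
                     for j in range(i + 1, X.shape[1])
                     if abs(corr[i, j]) > 1 - 1e-8] if X.shape[1] > 1 else []
            raise ValueError(
                "exposure-beta design matrix is rank deficient"
                + (f"; collinear exposure columns: {pairs}" if pairs else ""))
        Ainv = np.linalg.inv(A)
        coef = Ainv @ (XtW @ y)
        resid = y - X @ coef
        q = float(w @ resid ** 2)
        q_df = X.shape[0] - X.shape[1]
        cov = Ainv
        if self.random_effects and q_df > 0:
            cov = cov * max(1.0, q / q_df)   # multiplicative overdispersion
        return coef, cov, q, q_df

    def _finalise(self, coef, cov, q, q_df):
        self.coef_ = coef
        self.coef_cov_ = cov
        self.stderr_ = np.sqrt(np.diag(cov))
        self.q_ = q
        self.q_df_ = q_df
        self.q_pvalue_ = float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X @ self.coef_


class IVWRegressor(_WLSThroughOrigin):
    """Inverse-variance-weighted fixed-effect MR estimator.

    Equivalent to a fixed-effect meta-analysis of the per-variant Wald
    ratios, and exactly a weighted regression of outcome betas on exposure
    betas through the origin. ``random_effects=True`` inflates standard
    errors by the multiplicative dispersion factor ``max(1, Q/df)^0.5``
    (a sensitivity option; fixed-effect is the default).

    Fitted attributes: ``coef_`` (scalar in a length-1 array), ``stderr_``,
    ``q_``/``q_df_``/``q_pvalue_`` (Cochran's heterogeneity statistic).
    """

    def fit(self, X, y, sample_weight=None):
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("IVWRegressor takes a single exposure column; "
                             "use MVMRRegressor for several")
        w = _weights(y, sample_weight)
        self._finalise(*self._fit_wls(X, y, w))
        self.q_df_ = X.shape[0] - 1
        self.q_pvalue_ = float(stats.chi2.sf(self.q_, self.q_df_)) \
            if self.q_df_ > 0 else np.nan
        return self


class MVMRRegressor(_WLSThroughOrigin):
    """Multivariable MR: joint direct effects of k exposures.

    Weighted least squares of outcome betas on the k exposure-beta
    columns without intercept. With k=1 this is identical to
    :class:`IVWRegressor` apart from the heterogeneity degrees of freedom
    (n-k here). Requires more variants than exposures and a full-rank
    design.
    """

    def fit(self, X, y, sample_weight=None):
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        k = X.shape[1]
        if X.shape[0] <= k:
            raise ValueError("need n_variants > n_exposures")
        w = _weights(y, sample_weight)
        self._finalise(*self._fit_wls(X, y, w))
        return self

    def conditional_f(self, X, exposure_se, sample_weight=None):
        """Conditional instrument-strength F per exposure.

        For exposure j, its beta column is regressed on the other
        exposures' columns (weighted by that exposure's inverse-variance
        weights) and the weighted residual sum of squares is scaled by the
        residual degrees of freedom::

            F_j = sum_i r_ij^2 / se_x[i,j]^2 / (n - k + 1)

        Orthogonal, strong instruments give F_j near the marginal mean F;
        a duplicated exposure column gives F_j near 0.
        """
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        se_x = np.asarray(exposure_se, dtype=float)
        n, k = X.shape
        if k < 2:
            raise ValueError("conditional F requires k >= 2 exposures; "
                             "use the marginal mean F for one exposure")
        out = np.empty(k)
        for j in range(k):
            wj = 1.0 / se_x[:, j] ** 2
            others = np.delete(X, j, axis=1)
            XtW = others.T * wj
            delta = np.linalg.lstsq((XtW @ others), XtW @ X[:, j],
                                    rcond=None)[0]
            r = X[:, j] - others @ delta
            out[j] = float(wj @ r ** 2) / (n - k + 1)
        return out


class MREggerRegressor(RegressorMixin, BaseEstimator):
    """MR-Egger regression: pleiotropy-robust slope with intercept test.

    Weighted least squares of outcome betas on exposure betas *with* an
    intercept; a non-zero intercept indicates directional pleiotropy.
    Exposure betas are reoriented non-negative before fitting (the paired
    outcome beta flips with them), as the method requires. With
    ``fit_intercept=False`` the slope reduces exactly to the IVW estimate
    (a cross-check, not an analysis option).
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y, sample_weight=None):
        X, y = validate_data(self, X, y,
                             ensure_min_samples=3 if self.fit_intercept else 2)
        if X.shape[1] != 1:
            raise ValueError("MREggerRegressor takes a single exposure column")
        x = X[:, 0]
        w = _weights(y, sample_weight)
        sign = np.where(x < 0, -1.0, 1.0)
        x, y = x * sign, y * sign
        D = np.column_stack([np.ones_like(x), x]) if self.fit_intercept \
            else x[:, None]
        A = (D.T * w) @ D
        Ainv = np.linalg.inv(A)
        coef = Ainv @ ((D.T * w) @ y)
        resid = y - D @ coef
        self.q_ = float(w @ resid ** 2)
        self.q_df_ = len(y) - D.shape[1]
        cov = Ainv
        se = np.sqrt(np.diag(cov))
        if self.fit_intercept:
            self.intercept_ = float(coef[0])
            self.intercept_stderr_ = float(se[0])
            self.intercept_pvalue_ = float(
                2 * stats.norm.sf(abs(self.intercept_ / self.intercept_stderr_)))
            self.coef_ = coef[1:]
            self.stderr_ = se[1:]
        else:
            self.intercept_ = 0.0
            self.intercept_stderr_ = np.nan
            self.intercept_pvalue_ = np.nan
            self.coef_ = coef
            self.stderr_ = se
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.intercept_ + X @ self.coef_
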