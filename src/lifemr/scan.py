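"""Per-variant association scans, the stacked time-interaction analysis,
and greedy LD clumping.

The scan regresses a phenotype on each variant's dosage in turn with
covariate adjustment, by ordinary least squares. For the three-category
body-size measures this is linear regression of the 0/1/2 code on dosage,
i.e. it assumes the per-allele effect of moving from the lowest to the
middle category equals that of moving from the middle to the highest.
Simulated individuals are unrelated, so no mixed model is needed.

p-values use the two-sided normal approximation; intended sample sizes are
in the tens of thousands, where the t correction is negligible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CohortData

__all__ = [
    "scan",
    "stacked_interaction_scan",
    "bonferroni_threshold",
    "ld_clump",
    "cross_exposure_instrument_set",
    "SUMSTATS_COLUMNS",
]

SUMSTATS_COLUMNS = ["SNP", "effect_allele", "other_allele", "eaf",
                    "beta", "se", "pval", "samplesize"]


def _covariate_matrix(cohort: CohortData,
                      covariates: Sequence[str]) -> np.ndarray:
    n = cohort.n
    cols = [np.ones(n)]
    for name in covariates:
        if name not in cohort.pheno.columns:
            raise KeyError(f"covariate {name!r} not in cohort phenotypes")
        cols.append(cohort.pheno[name].to_numpy(dtype=np.float64))
    return np.column_stack(cols)


def _residualise(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the column space of X."""
    Q, _ = np.linalg.qr(X)
    return M - Q @ (Q.T @ M)


def scan(cohort: CohortData, phenotype: str,
         covariates: Sequence[str] = ()) -> pd.DataFrame:
    """Per-variant least-squares scan of ``phenotype`` on dosage.

    Uses Frisch-Waugh-Lovell residualisation so all variants are fitted in
    one vectorised pass: phenotype and dosages are residualised on
    [1, covariates], then each variant's slope, its standard error from the
    per-variant residual sum of squares, and a two-sided normal p-value are
    computed. Early-life scans conventionally add ``month_of_birth`` to the
    covariates; sex-stratified scans are run by filtering the cohort first.

    A constant (degenerate) dosage column is reported with beta 0,
    infinite se and p 1.

    Returns a summary-statistics table with columns
    ``SNP effect_allele other_allele eaf beta se pval samplesize``.
    """
    if phenotype not in cohort.pheno.columns:
        raise KeyError(f"phenotype {phenotype!r} not in cohort phenotypes")
    y = cohort.pheno[phenotype].to_numpy(dtype=np.float64)
    if np.var(y) == 0:
        raise ValueError(f"phenotype {phenotype!r} has zero variance")
    X = _covariate_matrix(cohort, covariates)
    n, p = X.shape
    G = cohort.dosages
    y_r = _residualise(y[:, None], X)[:, 0]
    G_r = _residualise(G, X)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    degenerate = gg <= n * 1e-24
    gg_safe = np.where(degenerate, 1.0, gg)
    gy = G_r.T @ y_r
    beta = gy / gg_safe
    rss = np.maximum(y_r @ y_r - beta ** 2 * gg_safe, 0.0)
    dof = n - p - 1
    se = np.sqrt(rss / dof / gg_safe)
    beta[degenerate] = 0.0
    se[degenerate] = np.inf
    z = np.where(se > 0, beta / np.where(se == np.inf, 1.0, se), 0.0)
    z[se == np.inf] = 0.0
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    pval[degenerate] = 1.0

    out = pd.DataFrame({
        "SNP": cohort.variant_ids,
        "effect_allele": cohort.variants["effect_allele"].to_numpy(),
        "other_allele": cohort.variants["other_allele"].to_numpy(),
        "eaf": G.mean(axis=0) / 2.0,
        "beta": beta, "se": se, "pval": pval,
        "samplesize": np.full(G.shape[1], n, dtype=np.int64),
    })
    out.attrs["phenotype"] = phenotype
    out.attrs["degenerate"] = cohort.variant_ids[degenerate].tolist()
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


def stacked_interaction_scan(cohort: CohortData,
                             covariates: Sequence[str] = ("age", "sex"),
                             alpha: float = 0.05,
                             cluster_robust: bool = True) -> pd.DataFrame:
    """Compare each variant's effect on early vs adult body size.

    Each individual contributes two stacked rows (their early and adult
    category measurements); the model per variant is::

        category ~ 1 + dosage + time + dosage:time + covariates

    with ``time`` = 1 for the adult row, so the interaction coefficient is
    the adult-minus-early difference in the per-allele effect. Because the
    two rows of an individual are correlated, standard errors are
    cluster-robust (CR1 sandwich, clustered on individual) by default;
    plain OLS standard errors are available for comparison.

    Variants are flagged ``stronger-early`` / ``stronger-adult`` when the
    interaction p-value clears the Bonferroni threshold
    ``alpha / n_variants``, else ``no-difference``.
    """
    need = {"early_category", "adult_category"}
    if not need <= set(cohort.pheno.columns):
        raise ValueError("cohort must carry both early and adult categories")
    if cohort.pheno[["early_category", "adult_category"]].isna().any().any():
        raise ValueError("both time points are required for every individual")
    n = cohort.n
    y = np.concatenate([
        cohort.pheno["early_category"].to_numpy(dtype=np.float64),
        cohort.pheno["adult_category"].to_numpy(dtype=np.float64)])
    time = np.concatenate([np.zeros(n), np.ones(n)])
    C = np.column_stack([
        np.tile(cohort.pheno[c].to_numpy(dtype=np.float64), 2)
        for c in covariates]) if covariates else np.empty((2 * n, 0))

    m = cohort.dosages.shape[1]
    rows = []
    threshold = bonferroni_threshold(alpha, m)
    for j in range(m):
        g = np.tile(cohort.dosages[:, j], 2)
        X = np.column_stack([np.ones(2 * n), g, time, g * time, C])
        p = X.shape[1]
        XtX = X.T @ X
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        bread = np.linalg.inv(XtX)
        if cluster_robust:
            S = X * resid[:, None]
            S_ind = S[:n] + S[n:]          # score summed within individual
            meat = S_ind.T @ S_ind
            corr = (n / (n - 1)) * ((2 * n - 1) / (2 * n - p))
            V = corr * bread @ meat @ bread
        else:
            sigma2 = resid @ resid / (2 * n - p)
            V = sigma2 * bread
        b_main, b_int = coef[1], coef[3]
        se_int = np.sqrt(V[3, 3])
        p_int = 2.0 * stats.norm.sf(abs(b_int) / se_int) if se_int > 0 else 1.0
        if p_int < threshold:
            flag = "stronger-adult" if b_int > 0 else "stronger-early"
        else:
            flag = "no-difference"
        rows.append((cohort.variant_ids[j], b_main, b_int, se_int, p_int, flag))
    out = pd.DataFrame(rows, columns=["SNP", "beta_main", "beta_interaction",
                                      "se_interaction", "pval_interaction",
                                      "flag"])
    out.attrs["bonferroni_threshold"] = threshold
    return out


def _dosage_r2(reference: CohortData, id_a: str, id_b: str) -> float:
    idx = {v: i for i, v in enumerate(reference.variant_ids)}
    a = reference.dosages[:, idx[id_a]]
    b = reference.dosages[:, idx[id_b]]
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_clump(stats_table: pd.DataFrame, reference: CohortData,
             p_threshold: float = 5e-8,
             r2_threshold: float = 0.001) -> pd.DataFrame:
    """Greedy LD clumping against a genotype reference panel.

    Repeatedly takes the smallest-p remaining variant with
    ``p < p_threshold`` as an index variant and discards every remaining
    variant whose squared dosage correlation with it is at least
    ``r2_threshold`` (composite LD on dosages, as a genotype reference
    panel affords). Ties on p are broken by variant id, for
    reproducibility. Returns the retained index variants ordered by p.
    """
    ids = stats_table["SNP"].to_numpy()
    ref_ids = set(reference.variant_ids)
    missing = [v for v in ids if v not in ref_ids]
    if missing:
        raise KeyError(f"variants absent from reference panel: {missing}")
    idx_of = {v: i for i, v in enumerate(reference.variant_ids)}
    cand = stats_table[stats_table["pval"] < p_threshold]
    cand = cand.sort_values(["pval", "SNP"], kind="mergesort")
    G = reference.dosages
    sd = G.std(axis=0)

    kept: list[int] = []
    remaining = cand.index.to_list()
    while remaining:
        index_row = remaining.pop(0)
        kept.append(index_row)
        gi = G[:, idx_of[cand.at[index_row, "SNP"]]]
        if not remaining:
            break
        cols = np.array([idx_of[cand.at[r, "SNP"]] for r in remaining])
        gc = G[:, cols]
        denom = sd[cols] * gi.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = ((gc - gc.mean(axis=0)) * (gi - gi.mean())[:, None]).mean(axis=0) / denom
        r2 = np.where(np.isfinite(r), r ** 2, 1.0)   # degenerate cols clump away
        remaining = [row for row, rr in zip(remaining, r2) if rr < r2_threshold]
    return cand.loc[kept].reset_index(drop=True)


def cross_exposure_instrument_set(stats_early: pd.DataFrame,
                                  stats_adult: pd.DataFrame,
                                  reference: CohortData,
                                  p_threshold: float = 5e-8,
                                  r2_threshold: float = 0.001) -> pd.DataFrame:
    """Joint instrument list for two exposures.

    Takes the union of the two (already clumped) instrument lists — a
    variant present in both keeps its smaller p — and re-clumps the union
    with the same greedy rule, so cross-exposure LD between the sets is
    removed exactly as within-exposure LD was.
    """
    both = pd.concat([stats_early, stats_adult], ignore_index=True)
    both = both.sort_values(["pval", "SNP"], kind="mergesort")
    both = both.drop_duplicates(subset="SNP", keep="first")
    return ld_clump(both, reference, p_threshold=p_threshold,
                    r2_threshold=r2_threshold)
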