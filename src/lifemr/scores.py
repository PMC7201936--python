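"""Genetic scores and ROC validation.

A score for each instrument set (early-life or adult) is built as the
weighted allele count, with the discovery-scan betas as weights. Applied
to an independent validation cohort whose adiposity measures are
dichotomised at the 85th centile ("overweight"), ROC curves show which
score better separates childhood from adult adiposity — the check that
the two instrument sets capture body size at different life stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .simulate import CohortData

__all__ = ["ScoreDefinition", "ROCResult", "build_score",
           "dichotomize_at_centile", "roc_auc"]


@dataclass
class ScoreDefinition:
    """Variant weights for a genetic score."""

    variant_ids: np.ndarray
    weights: np.ndarray
    source: str = ""          # "early" or "adult"

    def __post_init__(self):
        self.variant_ids = np.asarray(self.variant_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.variant_ids) != len(self.weights):
            raise ValueError("one weight per variant required")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant ids must be unique")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")

    @classmethod
    def from_sumstats(cls, stats_table: pd.DataFrame, source: str = "",
                      unit_weights: bool = False) -> "ScoreDefinition":
        w = (np.sign(stats_table["beta"].to_numpy()) if unit_weights
             else stats_table["beta"].to_numpy())
        return cls(stats_table["SNP"].to_numpy(), w, source)


@dataclass
class ROCResult:
    """ROC curve and area for one score against one binary label."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_cases: int
    n_controls: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def build_score(cohort: CohortData, score: ScoreDefinition) -> np.ndarray:
    """Per-individual score: sum of weight x dosage over score variants."""
    idx_of = {v: i for i, v in enumerate(cohort.variant_ids)}
    missing = [v for v in score.variant_ids if v not in idx_of]
    if missing:
        raise KeyError(f"score variants absent from cohort: {missing}")
    cols = np.array([idx_of[v] for v in score.variant_ids])
    return cohort.dosages[:, cols] @ score.weights


def dichotomize_at_centile(values: np.ndarray,
                           centile: float = 0.85) -> np.ndarray:
    """Binary labels: 1 for values strictly above the empirical centile.

    The convention is strict inequality, so with ties spanning the cut
    fewer than the nominal fraction may be labelled; a warning reports the
    achieved case fraction when it falls short by more than a quarter of
    the nominal fraction (or no cases remain).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise ValueError("need at least 20 values to dichotomise reliably")
    if not 0.0 <= centile < 1.0:
        raise ValueError("centile must be in [0, 1)")
    cut = np.quantile(values, centile)
    labels = (values > cut).astype(np.int64)
    expected = 1.0 - centile
    achieved = labels.mean()
    if achieved == 0.0 or achieved < 0.75 * expected:
        warnings.warn(
            f"ties at the {centile:.0%} centile: achieved case fraction "
            f"{achieved:.3f} vs nominal {expected:.3f}", stacklevel=2)
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and tie-corrected AUC.

    The AUC is computed by the rank (Mann-Whitney) formulation, with
    midranks handling ties; the curve itself comes from a threshold sweep
    and its trapezoidal area coincides with the rank AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(np.int64)
    n_cases = int(labels.sum())
    n_controls = int(len(labels) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both classes must be present for a ROC curve")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_cases * (n_cases + 1) / 2) \
        / (n_cases * n_controls)
    fpr, tpr, _ = roc_curve(labels, scores)
    return ROCResult(auc=float(auc), fpr=fpr, tpr=tpr,
                     n_cases=n_cases, n_controls=n_controls)
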