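"""Allele harmonization of exposure and outcome summary statistics, and
reading/writing of the tab-delimited summary-statistics dialect.

Two-sample MR combines per-variant effects estimated in different samples,
so all statistics must refer to the same effect allele. Where the outcome
study reports the opposite allele, its beta is negated and its frequency
complemented. Palindromic variants (A/T, G/C) cannot be strand-resolved
from allele labels; by default they are aligned by allele frequency unless
the frequency is too close to 0.5 to be informative, in which case they
are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import SUMSTATS_COLUMNS

__all__ = ["HarmonizedSet", "harmonize", "read_sumstats", "write_sumstats",
           "SumstatsFormatError"]

_PALINDROMES = {frozenset(("A", "T")), frozenset(("G", "C"))}

# case-insensitive synonyms accepted on read; written files are canonical
_SYNONYMS = {
    "snp": "SNP", "rsid": "SNP", "markername": "SNP", "variant_id": "SNP",
    "effect_allele": "effect_allele", "a1": "effect_allele",
    "other_allele": "other_allele", "a2": "other_allele",
    "eaf": "eaf", "freq": "eaf", "effect_allele_frequency": "eaf",
    "beta": "beta", "b": "beta",
    "se": "se", "standard_error": "se",
    "pval": "pval", "p": "pval", "p_value": "pval", "pvalue": "pval",
    "samplesize": "samplesize", "n": "samplesize",
}


class SumstatsFormatError(ValueError):
    """A summary-statistics file violates the expected dialect."""


def read_sumstats(path: str) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file.

    Headers are matched case-insensitively and common synonyms
    (``rsid``, ``A1``, ``A2``, ``freq``, ``b``, ``p``, ``N``) are mapped to
    the canonical columns. Malformed rows (non-positive se, p outside
    (0, 1], identical alleles) are rejected with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={})
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _SYNONYMS:
            rename[col] = _SYNONYMS[key]
    df = df.rename(columns=rename)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing mandatory column(s) {missing}")
    df = df[SUMSTATS_COLUMNS].copy()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # +2: header line plus 1-based numbering
    bad_se = df.index[~(df["se"] > 0)].to_numpy()
    if len(bad_se):
        raise SumstatsFormatError(
            f"{path}: non-positive or missing se at line(s) "
            f"{[int(i) + 2 for i in bad_se]}")
    bad_p = df.index[~((df["pval"] > 0) & (df["pval"] <= 1))].to_numpy()
    if len(bad_p):
        raise SumstatsFormatError(
            f"{path}: p-value outside (0, 1] at line(s) "
            f"{[int(i) + 2 for i in bad_p]}")
    same = df.index[df["effect_allele"].astype(str).str.upper()
                    == df["other_allele"].astype(str).str.upper()].to_numpy()
    if len(same):
        raise SumstatsFormatError(
            f"{path}: identical alleles at line(s) "
            f"{[int(i) + 2 for i in same]}")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["samplesize"] = df["samplesize"].astype(np.int64)
    return df


def write_sumstats(stats: pd.DataFrame, path: str) -> None:
    """Write the canonical tab-delimited form."""
    missing = [c for c in SUMSTATS_COLUMNS if c not in stats.columns]
    if missing:
        raise SumstatsFormatError(f"cannot write: missing column(s) {missing}")
    stats[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Allele-aligned effects for k exposures and one outcome.

    ``table`` has one row per retained variant with columns ``SNP``,
    ``effect_allele``, ``beta_<label>``/``se_<label>`` per exposure,
    ``beta_outcome``/``se_outcome`` and a provenance ``flag``
    (aligned/flipped). Dropped variants keep their reason in ``dropped``;
    exposure instruments absent from the outcome statistics are listed in
    ``missing_from_outcome``.
    """

    table: pd.DataFrame
    exposures: tuple[str, ...]
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)
    missing_from_outcome: tuple[str, ...] = ()

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def exposure_betas(self) -> np.ndarray:
        return self.table[[f"beta_{e}" for e in self.exposures]].to_numpy()

    def exposure_ses(self) -> np.ndarray:
        return self.table[[f"se_{e}" for e in self.exposures]].to_numpy()

    def outcome_betas(self) -> np.ndarray:
        return self.table["beta_outcome"].to_numpy()

    def outcome_ses(self) -> np.ndarray:
        return self.table["se_outcome"].to_numpy()

    def subset_exposures(self, labels: tuple[str, ...]) -> "HarmonizedSet":
        cols = ["SNP", "effect_allele"]
        for e in labels:
            cols += [f"beta_{e}", f"se_{e}"]
        cols += ["beta_outcome", "se_outcome", "flag"]
        return HarmonizedSet(self.table[cols].copy(), tuple(labels),
                             self.dropped, self.missing_from_outcome)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMES


def harmonize(exposures: list[pd.DataFrame] | pd.DataFrame,
              outcome: pd.DataFrame,
              labels: list[str] | None = None,
              palindrome_window: tuple[float, float] = (0.42, 0.58),
              drop_palindromic_in_window: bool = True) -> HarmonizedSet:
    """Align exposure(s) and outcome statistics to a shared effect allele.

    The first exposure's orientation is the reference. For each variant
    present in every table:

    * identical allele pair and ordering -> kept as is (``aligned``);
    * swapped effect/other alleles -> beta negated, frequency
      complemented (``flipped``);
    * palindromic pair -> dropped if any table's frequency lies inside
      ``palindrome_window`` (uninformative), otherwise aligned by
      frequency side;
    * any other allele pair -> dropped as a mismatch.

    Exposure instruments missing from the outcome statistics are reported
    in the result (with a warning) rather than raising.
    """
    if isinstance(exposures, pd.DataFrame):
        exposures = [exposures]
    if labels is None:
        labels = [f"exposure{i + 1}" for i in range(len(exposures))]
    if len(labels) != len(exposures):
        raise ValueError("labels must match the number of exposure tables")

    ref = exposures[0].set_index("SNP")
    others = [e.set_index("SNP") for e in exposures[1:]]
    out = outcome.set_index("SNP")

    missing = [v for v in ref.index if v not in out.index
               or any(v not in o.index for o in others)]
    if missing:
        warnings.warn(f"{len(missing)} exposure instrument(s) absent from "
                      "outcome or co-exposure statistics; excluded",
                      stacklevel=2)

    rows, dropped = [], []
    for snp in ref.index:
        if snp in missing:
            continue
        r = ref.loc[snp]
        a1, a2 = r["effect_allele"], r["other_allele"]
        pal = _is_palindromic(a1, a2)
        rec = {"SNP": snp, "effect_allele": a1,
               f"beta_{labels[0]}": r["beta"], f"se_{labels[0]}": r["se"]}
        flag = "aligned"
        ok = True
        for tbl, lab in zip(others + [out], labels[1:] + ["outcome"]):
            t = tbl.loc[snp]
            b1, b2 = t["effect_allele"], t["other_allele"]
            if pal:
                if _is_palindromic(b1, b2) and {b1, b2} == {a1, a2}:
                    lo, hi = palindrome_window
                    freqs = (r["eaf"], t["eaf"])
                    if drop_palindromic_in_window and any(
                            lo <= f <= hi for f in freqs):
                        dropped.append({"SNP": snp, "flag": "dropped-palindromic"})
                        ok = False
                        break
                    # align by frequency: same minor-allele side -> same strand
                    same_side = (r["eaf"] < 0.5) == (t["eaf"] < 0.5)
                    aligned_order = (b1 == a1)
                    flip = (same_side and not aligned_order) or \
                           (not same_side and aligned_order)
                else:
                    dropped.append({"SNP": snp, "flag": "dropped-mismatch"})
                    ok = False
                    break
            elif (b1, b2) == (a1, a2):
                flip = False
            elif (b1, b2) == (a2, a1):
                flip = True
            else:
                dropped.append({"SNP": snp, "flag": "dropped-mismatch"})
                ok = False
                break
            beta = -t["beta"] if flip else t["beta"]
            if flip:
                flag = "flipped"
            rec[f"beta_{lab}"] = beta
            rec[f"se_{lab}"] = t["se"]
        if ok:
            rec["flag"] = flag
            rows.append(rec)

    cols = ["SNP", "effect_allele"]
    for lab in labels:
        cols += [f"beta_{lab}", f"se_{lab}"]
    cols += ["beta_outcome", "se_outcome", "flag"]
    table = pd.DataFrame(rows, columns=cols)
    return HarmonizedSet(table, tuple(labels),
                         dropped=pd.DataFrame(dropped, columns=["SNP", "flag"]),
                         missing_from_outcome=tuple(missing))


def write_harmonized(h: HarmonizedSet, path: str) -> None:
    """Audit export: one wide TSV with a column block per exposure."""
    h.table.to_csv(path, sep="\t", index=False)


def read_harmonized(path: str) -> HarmonizedSet:
    """Read a wide harmonized TSV written by :func:`write_harmonized`.

    Exposure labels are recovered from the ``beta_<label>``/``se_<label>``
    column pairs (the outcome block excepted).
    """
    table = pd.read_csv(path, sep="\t")
    labels = [c[len("beta_"):] for c in table.columns
              if c.startswith("beta_") and c != "beta_outcome"]
    for lab in labels:
        if f"se_{lab}" not in table.columns:
            raise SumstatsFormatError(f"{path}: missing column se_{lab}")
    for col in ("beta_outcome", "se_outcome"):
        if col not in table.columns:
            raise SumstatsFormatError(f"{path}: missing column {col}")
    if "flag" not in table.columns:
        table["flag"] = "aligned"
    return HarmonizedSet(table, tuple(labels))
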