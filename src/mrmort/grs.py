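"""Genetic risk score construction.

Harmonises an external weight file (per-allele log odds ratios for the
exposure) against the genotype data's counted alleles, then computes overall
and pathway-specific weighted allele scores. Palindromic (A/T, C/G) variants
are dropped as strand-ambiguous, absent variants are dropped as unavailable,
and swapped-allele variants have their dosage flipped d -> 2 - d; every
exclusion is counted in a harmonisation report rather than silently applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizationReport",
    "GrsResult",
    "EmptyInstrumentError",
    "harmonize",
    "compute_grs",
    "pathway_scores",
    "quantile_bins",
    "SMALL_INSTRUMENT_SNPS",
]

#: below this many SNPs a pathway score carries a small-instrument warning
SMALL_INSTRUMENT_SNPS = 5

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
_VALID = set("ACGT")


class EmptyInstrumentError(ValueError):
    """No SNPs survived harmonisation: the instrument is empty."""


@dataclass
class HarmonizationReport:
    """Per-category accounting of what happened to each input SNP."""

    n_input: int
    n_scored: int
    n_unavailable: int
    n_ambiguous: int
    n_mismatch: int
    dropped: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_scored": self.n_scored,
            "n_unavailable": self.n_unavailable,
            "n_ambiguous": self.n_ambiguous,
            "n_mismatch": self.n_mismatch,
            "dropped": self.dropped,
        }


@dataclass
class GrsResult:
    """Per-individual weighted allele score with its per-SD standardised copy."""

    score: pd.Series          # raw, in log-odds (weight) units
    sd: float                 # sample SD of the raw score
    standardized: pd.Series   # mean 0, SD 1
    n_snps: int
    warnings: list[str] = field(default_factory=list)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def harmonize(weights: pd.DataFrame, variants: pd.DataFrame) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align a weight table with the genotype's counted alleles.

    Parameters
    ----------
    weights : DataFrame indexed by rsid with ``effect_allele``,
        ``other_allele`` and ``weight`` columns (``pathway`` optional).
    variants : DataFrame indexed by rsid with ``counted_allele`` and
        ``other_allele`` columns describing what the dosage matrix counts.

    Returns the aligned weight table — original columns plus a boolean
    ``flip`` column (True where the dosage must be replaced by 2 - d) — and a
    :class:`HarmonizationReport`. Irreconcilable allele pairs are dropped with
    reason "mismatch", never silently scored.
    """
    for col in ("effect_allele", "other_allele", "weight"):
        if col not in weights:
            raise ValueError(f"weights table lacks column {col!r}")
    bad = ~weights["effect_allele"].isin(_VALID) | ~weights["other_allele"].isin(_VALID)
    if bad.any():
        raise ValueError(
            f"non-ACGT alleles in weights for {list(weights.index[bad])[:5]}"
        )

    dropped: dict[str, list[str]] = {"unavailable": [], "ambiguous": [], "mismatch": []}
    keep_rows = []
    for rsid, row in weights.iterrows():
        ea, oa = row["effect_allele"], row["other_allele"]
        if _is_palindromic(ea, oa):
            dropped["ambiguous"].append(rsid)
            continue
        if rsid not in variants.index:
            dropped["unavailable"].append(rsid)
            continue
        counted = variants.at[rsid, "counted_allele"]
        gother = variants.at[rsid, "other_allele"]
        if {ea, oa} != {counted, gother}:
            dropped["mismatch"].append(rsid)
            continue
        keep_rows.append((rsid, ea != counted))

    if keep_rows:
        idx, flips = zip(*keep_rows)
        aligned = weights.loc[list(idx)].copy()
        aligned["flip"] = list(flips)
    else:
        aligned = weights.iloc[0:0].copy()
        aligned["flip"] = pd.Series(dtype=bool)

    report = HarmonizationReport(
        n_input=len(weights),
        n_scored=len(aligned),
        n_unavailable=len(dropped["unavailable"]),
        n_ambiguous=len(dropped["ambiguous"]),
        n_mismatch=len(dropped["mismatch"]),
        dropped=dropped,
    )
    return aligned, report


def compute_grs(dosages: pd.DataFrame, weights: pd.DataFrame) -> GrsResult:
    """Weighted allele score: score_i = sum_j w_j d_ij.

    ``weights`` must be harmonised (carry a ``flip`` column). Missing dosages
    are imputed as twice the effect-allele frequency estimated from
    non-missing individuals (mean imputation, unbiased under missingness at
    random); SNPs missing in every individual are dropped with a warning.
    """
    if len(weights) == 0:
        raise EmptyInstrumentError("no scored SNPs: instrument is empty")
    if "flip" not in weights:
        raise ValueError("weights are not harmonised (no 'flip' column)")
    missing_cols = [r for r in weights.index if r not in dosages.columns]
    if missing_cols:
        raise ValueError(f"dosage matrix lacks harmonised SNPs: {missing_cols[:5]}")

    d = dosages[list(weights.index)].to_numpy(float, copy=True)
    flip = weights["flip"].to_numpy(bool)
    d[:, flip] = 2.0 - d[:, flip]

    warns: list[str] = []
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        lost = list(weights.index[all_missing])
        warns.append(f"dropped {len(lost)} SNP(s) with 100% missingness: {lost[:5]}")
        warnings.warn(warns[-1])
        d = d[:, ~all_missing]
        weights = weights.loc[~all_missing]
        if d.shape[1] == 0:
            raise EmptyInstrumentError("all SNPs fully missing")

    col_mean = np.nanmean(d, axis=0)  # = 2 x effect-allele frequency
    nan_r, nan_c = np.where(np.isnan(d))
    d[nan_r, nan_c] = col_mean[nan_c]

    score = d @ weights["weight"].to_numpy(float)
    s = pd.Series(score, index=dosages.index, name="grs")
    sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
    if sd > 0:
        standardized = (s - s.mean()) / sd
    else:
        standardized = s * 0.0
    return GrsResult(score=s, sd=sd, standardized=standardized.rename("grs_std"),
                     n_snps=len(weights), warnings=warns)


def oriented_dosages(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Dosage matrix restricted to harmonised SNPs and re-oriented to count
    the weight file's effect allele (flipped columns become 2 - d)."""
    if "flip" not in weights:
        raise ValueError("weights are not harmonised (no 'flip' column)")
    d = dosages[list(weights.index)].copy()
    flip_cols = weights.index[weights["flip"].to_numpy(bool)]
    d[flip_cols] = 2.0 - d[flip_cols]
    return d


def pathway_scores(dosages: pd.DataFrame, weights: pd.DataFrame,
                   known_pathways: list[str] | None = None) -> dict[str, GrsResult]:
    """One score per pathway label, each using only its own SNPs.

    A pathway with fewer than :data:`SMALL_INSTRUMENT_SNPS` variants gets a
    small-instrument warning attached (legitimate — some biological pathways
    contribute only a couple of variants) but is still scored.
    """
    if "pathway" not in weights:
        raise ValueError("weights table lacks a 'pathway' column")
    labels = [p for p in weights["pathway"].unique() if p not in ("", None)]
    if known_pathways is not None:
        unknown = set(labels) - set(known_pathways)
        if unknown:
            raise ValueError(f"unknown pathway label(s): {sorted(unknown)}")
    out: dict[str, GrsResult] = {}
    for label in labels:
        sub = weights[weights["pathway"] == label]
        res = compute_grs(dosages, sub)
        if res.n_snps < SMALL_INSTRUMENT_SNPS:
            res.warnings.append(
                f"pathway {label!r} has only {res.n_snps} SNP(s); "
                "estimates may be unstable"
            )
        out[label] = res
    return out


def quantile_bins(scores: pd.Series, k: int) -> pd.Series:
    """Assign near-equal-size quantile bins (0..k-1, ascending score).

    Ties are broken by stable input order, so even a constant score vector
    spreads individuals into bins whose sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(scores)
    if k > n:
        raise ValueError(f"k={k} exceeds number of individuals ({n})")
    order = np.argsort(scores.to_numpy(), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    bins = (ranks * k) // n
    return pd.Series(bins, index=scores.index, name="grs_bin")
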