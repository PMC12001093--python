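"""Cohort assembly: diabetes classification, death-cause re-attribution,
eligibility cascade and baseline/balance summaries.

Diabetes status follows the study convention: previously diagnosed means a
self-reported doctor diagnosis or use of diabetes medication; undiagnosed
means no prior diagnosis but HbA1c >= 6.5%; likely type 1 diabetes (diagnosis
before age 35 while on insulin) takes precedence and is excluded downstream.

Deaths whose raw underlying cause is diabetes are accepted as such only when
an acute-crisis marker is present; other diabetes-coded deaths are
re-attributed to the highest-priority secondary cause on the certificate,
which avoids undercounting renal and vascular deaths among people with
diabetes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiabetesClass",
    "classify_diabetes",
    "CauseMap",
    "DEFAULT_CAUSE_MAP",
    "DEFAULT_REATTRIBUTION_PRIORITY",
    "reattribute_cause",
    "ExclusionLedger",
    "PlausibilityWindows",
    "apply_exclusions",
    "baseline_table",
    "confounder_balance",
]

HBA1C_THRESHOLD = 6.5  # % — diagnostic threshold for undiagnosed diabetes
T1D_AGE_CUTOFF = 35.0


class DiabetesClass:
    NONE = "none"
    PREVIOUS = "previously_diagnosed"
    UNDIAGNOSED = "undiagnosed"
    LIKELY_T1D = "likely_t1d"
    UNCLASSIFIED = "unclassified"  # missing-data gate, excluded downstream


def classify_diabetes(records: pd.DataFrame) -> pd.Series:
    """Classify each participant's diabetes status at recruitment.

    Precedence: likely T1D (diagnosis age < 35 and insulin use), then
    previously diagnosed (self-report or medication), then undiagnosed
    (HbA1c >= 6.5%), else none. Records with no self-report and missing HbA1c
    cannot be classified and are flagged for the missing-data exclusion.
    """
    self_rep = records["self_reported_diabetes"].fillna(False).astype(bool)
    meds = records["diabetes_medication"].fillna(False).astype(bool)
    insulin = records["insulin"].fillna(False).astype(bool)
    diag_age = pd.to_numeric(records["diabetes_diagnosis_age"], errors="coerce")
    hba1c = pd.to_numeric(records["hba1c"], errors="coerce")

    prev = self_rep | meds
    t1d = prev & insulin & (diag_age < T1D_AGE_CUTOFF)
    undiag = ~prev & (hba1c >= HBA1C_THRESHOLD)
    unclassified = ~prev & hba1c.isna()

    out = pd.Series(DiabetesClass.NONE, index=records.index, name="diabetes_class")
    out[undiag] = DiabetesClass.UNDIAGNOSED
    out[prev] = DiabetesClass.PREVIOUS
    out[t1d] = DiabetesClass.LIKELY_T1D
    out[unclassified] = DiabetesClass.UNCLASSIFIED
    return out


# ---------------------------------------------------------------------------
# cause-of-death grouping


@dataclass
class CauseMap:
    """Editable ICD-10 prefix -> cause-group table.

    The default grouping follows WHO chapter conventions and is deliberately
    coarse; the canonical per-endpoint code lists of any given study live in
    its own appendix, so this table is configuration, not doctrine. Prefixes
    are matched longest-first.
    """

    prefixes: dict[str, str]
    acute_diabetes_4th_chars: tuple[str, ...] = ("0", "1")

    def is_diabetes(self, code: str) -> bool:
        return code[:3] in {f"E{n}" for n in range(10, 15)}

    def is_acute_diabetes(self, code: str) -> bool:
        if not self.is_diabetes(code):
            return False
        tail = code.replace(".", "")[3:4]
        return tail in self.acute_diabetes_4th_chars

    def group(self, code: str) -> str:
        """Map a non-diabetes ICD-10 code to its cause group ('uncertain' if
        nothing matches)."""
        code = code.strip().upper()
        if not code:
            return "uncertain"
        for length in (5, 4, 3, 1):
            p = code.replace(".", "")[:length]
            if p in self.prefixes:
                return self.prefixes[p]
        return "uncertain"


def _default_prefixes() -> dict[str, str]:
    table: dict[str, str] = {}
    for ch in ("A", "B"):
        table[ch] = "infection"
    table["C"] = "cancer"
    for code in [f"D{n:02d}" for n in range(0, 49)]:
        table[code] = "cancer"
    for code in [f"I{n:02d}" for n in range(20, 26)] + [f"I{n:02d}" for n in range(30, 53)]:
        table[code] = "cardiac"
    for code in [f"I{n:02d}" for n in range(60, 70)]:
        table[code] = "stroke"
    table["I"] = "vascular_other"
    for code in [f"N{n:02d}" for n in range(0, 20)] + ["N25", "N26", "N27"]:
        table[code] = "renal"
    for code in ["K70", "K71", "K72", "K73", "K74"]:
        table[code] = "cirrhosis"
    for code in ["J40", "J41", "J42", "J43", "J44", "J47"]:
        table[code] = "copd"
    table["R"] = "ill_defined"
    for ch in ("V", "W", "X", "Y"):
        table[ch] = "external"
    for ch in ("D", "E", "F", "G", "H", "J", "K", "L", "M", "N", "O", "P", "Q"):
        table.setdefault(ch, "other_medical")
    return table


DEFAULT_CAUSE_MAP = CauseMap(prefixes=_default_prefixes())

#: order in which certificate secondary causes are consulted when a
#: diabetes-coded death is re-attributed
DEFAULT_REATTRIBUTION_PRIORITY = (
    "renal", "cardiac", "stroke", "vascular_other", "infection",
    "cirrhosis", "cancer", "copd", "other_medical", "external", "ill_defined",
)


def reattribute_cause(
    followup: pd.DataFrame,
    cause_map: CauseMap = DEFAULT_CAUSE_MAP,
    priority: tuple[str, ...] = DEFAULT_REATTRIBUTION_PRIORITY,
) -> pd.Series:
    """Assign the analysed cause group for each death.

    Diabetes-coded deaths with an acute 4th character become "acute diabetic
    crisis"; other diabetes-coded deaths are re-attributed to the
    highest-priority cause group found among the certificate's secondary
    causes; everything else passes through the ICD-10 group table. Deaths
    with no mappable cause become "uncertain" (excluded downstream).
    """
    rank = {g: i for i, g in enumerate(priority)}
    out = pd.Series("", index=followup.index, name="cause_group", dtype=object)
    died = followup["died"].astype(bool)
    for idx in followup.index[died]:
        raw = str(followup.at[idx, "underlying_cause_icd10"] or "")
        if cause_map.is_diabetes(raw):
            if cause_map.is_acute_diabetes(raw):
                out.at[idx] = "acute_diabetic_crisis"
                continue
            sec = str(followup.at[idx, "secondary_causes"] or "")
            groups = [
                cause_map.group(c) for c in sec.split(";") if c.strip()
            ]
            groups = [g for g in groups if g in rank]
            if groups:
                out.at[idx] = min(groups, key=rank.__getitem__)
            else:
                out.at[idx] = "uncertain"
        else:
            out.at[idx] = cause_map.group(raw)
    return out


# ---------------------------------------------------------------------------
# exclusion cascade


@dataclass
class ExclusionLedger:
    """Ordered (reason, count) accounting of an eligibility cascade."""

    n_input: int
    steps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return sum(c for _, c in self.steps)

    @property
    def remaining(self) -> int:
        return self.n_input - self.n_excluded

    def add(self, reason: str, count: int) -> None:
        self.steps.append((reason, int(count)))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "steps": [{"reason": r, "count": c} for r, c in self.steps],
            "n_excluded": self.n_excluded,
            "remaining": self.remaining,
        }


@dataclass(frozen=True)
class PlausibilityWindows:
    """Explicit, auditable windows for 'missing or extreme' covariate data."""

    height_cm: tuple[float, float] = (100.0, 220.0)
    weight_kg: tuple[float, float] = (25.0, 250.0)
    waist_cm: tuple[float, float] = (40.0, 200.0)
    hip_cm: tuple[float, float] = (40.0, 200.0)
    hba1c_pct: tuple[float, float] = (3.0, 20.0)


_REQUIRED_COVARIATES = ("age", "sex", "district", "education", "smoking",
                        "alcohol", "height", "weight", "waist", "hip")


def _covariate_problem(cohort: pd.DataFrame, windows: PlausibilityWindows) -> pd.Series:
    bad = pd.Series(False, index=cohort.index)
    for col in _REQUIRED_COVARIATES:
        if col in cohort:
            bad |= cohort[col].isna()
    for col, (lo, hi) in [
        ("height", windows.height_cm), ("weight", windows.weight_kg),
        ("waist", windows.waist_cm), ("hip", windows.hip_cm),
        ("hba1c", windows.hba1c_pct),
    ]:
        if col in cohort:
            v = pd.to_numeric(cohort[col], errors="coerce")
            bad |= v.notna() & ((v < lo) | (v > hi))
    return bad


def apply_exclusions(
    cohort: pd.DataFrame,
    analysis: str = "genetic",
    age_ceiling: float = 75.0,
    windows: PlausibilityWindows = PlausibilityWindows(),
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the eligibility cascade and return the ledger.

    ``cohort`` must already carry ``diabetes_class`` and ``cause_group``
    columns (classification and re-attribution done). Exclusions are applied
    in the stated order, each individual counted once under the first
    matching reason: age >= ceiling at recruitment; likely T1D; missing or
    extreme exposure/covariate data; uncertain cause of death; then, for the
    genetic analysis, missing/QC-failed genetic data, or, for the
    observational analysis, previously diagnosed chronic disease other than
    diabetes.
    """
    if analysis not in ("genetic", "observational"):
        raise ValueError("analysis must be 'genetic' or 'observational'")
    ledger = ExclusionLedger(n_input=len(cohort))
    alive_mask = pd.Series(True, index=cohort.index)

    def step(reason: str, mask: pd.Series) -> None:
        hit = mask & alive_mask
        ledger.add(reason, hit.sum())
        alive_mask[hit] = False

    step("aged 75 or older", cohort["age"] >= age_ceiling)
    step("likely type 1 diabetes", cohort["diabetes_class"] == DiabetesClass.LIKELY_T1D)
    missing = _covariate_problem(cohort, windows) | (
        cohort["diabetes_class"] == DiabetesClass.UNCLASSIFIED
    )
    step("missing or extreme data", missing)
    step("uncertain cause of death", cohort.get(
        "cause_group", pd.Series("", index=cohort.index)) == "uncertain")
    if analysis == "genetic":
        qc = cohort.get("genetic_qc_fail", pd.Series(False, index=cohort.index))
        missing_gen = cohort.get("missing_genetic_data",
                                 pd.Series(False, index=cohort.index))
        step("missing or QC-failed genetic data",
             qc.astype(bool) | missing_gen.astype(bool))
    else:
        prior_cols = [c for c in cohort.columns if c.startswith("prior_")]
        prior = cohort[prior_cols].any(axis=1) if prior_cols else pd.Series(
            False, index=cohort.index)
        step("prior chronic disease", prior)
    return cohort[alive_mask], ledger


# ---------------------------------------------------------------------------
# summaries

_CONTINUOUS = ("age", "height", "weight", "waist", "hip", "hba1c",
               "ancestry_fraction")
_CATEGORICAL = ("district", "education", "smoking", "alcohol")


def baseline_table(cohort: pd.DataFrame, by: str = "sex") -> pd.DataFrame:
    """Mean (SD) for continuous and n (%) for categorical covariates, overall
    and within each level of ``by``. With a single individual the SD is
    reported as 0."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    groups: list[tuple[str, pd.DataFrame]] = [("overall", cohort)]
    groups += [(str(level), g) for level, g in cohort.groupby(by)]
    rows = []
    for name, g in groups:
        for col in _CONTINUOUS:
            if col not in g:
                continue
            v = pd.to_numeric(g[col], errors="coerce").dropna()
            sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
            rows.append({"group": name, "variable": col, "level": "",
                         "mean": float(v.mean()), "sd": sd,
                         "n": len(v), "pct": np.nan})
        for col in _CATEGORICAL:
            if col not in g:
                continue
            counts = g[col].value_counts()
            for level, cnt in counts.items():
                rows.append({"group": name, "variable": col, "level": str(level),
                             "mean": np.nan, "sd": np.nan, "n": int(cnt),
                             "pct": 100.0 * cnt / len(g)})
    return pd.DataFrame(rows)


def confounder_balance(
    cohort: pd.DataFrame, bins: pd.Series,
    covariates: tuple[str, ...] = _CONTINUOUS,
) -> pd.DataFrame:
    """Per-bin covariate means plus a linear trend (regression on the bin
    midrank) with its SE, one row per covariate."""
    bins = bins.loc[cohort.index]
    k = int(bins.max()) + 1
    midrank = (bins.to_numpy(float) + 0.5) / k
    rows = []
    for col in covariates:
        if col not in cohort:
            continue
        y = pd.to_numeric(cohort[col], errors="coerce").to_numpy(float)
        ok = ~np.isnan(y)
        means = [float(np.nanmean(y[bins.to_numpy() == b])) for b in range(k)]
        if np.nanstd(y[ok]) == 0 or np.std(midrank[ok]) == 0:
            slope, se = 0.0, 0.0
        else:
            res = stats.linregress(midrank[ok], y[ok])
            slope, se = float(res.slope), float(res.stderr)
        rows.append({"covariate": col, "slope": slope, "se": se,
                     **{f"bin{b}_mean": m for b, m in enumerate(means)}})
    return pd.DataFrame(rows).set_index("covariate")
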