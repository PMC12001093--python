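"""One-sample Mendelian randomisation of genetically predicted T2D liability
against cause-specific mortality.

The causal contrast is the ratio-of-coefficients (Wald) estimator: the
GRS-mortality log hazard ratio from an age-at-risk and sex stratified Cox fit
divided by the GRS-T2D log odds ratio from a logistic fit, yielding the log
mortality rate ratio per 1-unit increase in genetically predicted log-odds of
T2D. For display the estimate and its SE are multiplied by ln k (default
k = 3) so they refer to a k-fold increase in predicted odds — a trebling of
odds moves genetic risk from 10% to 25%, from 25% to 50%, or from 50% to 75%.

`OneSampleMR` is the model object (built from an assembled analysis cohort);
`fit()` returns `OneSampleMRResults` carrying one `MREstimate` per cause
group plus subgroup and pathway machinery. `ObservationalMortality` provides
the conventional Cox contrast of T2D status for the genetic-vs-observational
comparison, on its own per-T2D-status scale (the two scales are never
auto-converted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DiabetesClass
from .survival import (
    AssocEstimate,
    DEFAULT_BAND_GRID,
    DegenerateDesignError,
    fit_logistic,
    fit_stratified_cox,
    lexis_expand,
)

__all__ = [
    "MREstimate",
    "WeakInstrumentError",
    "wald_ratio",
    "rescale_base",
    "odds_risk_example",
    "cochran_q",
    "OneSampleMR",
    "OneSampleMRResults",
    "ObservationalMortality",
    "CAUSE_GROUPS",
    "VASCULAR_MEMBERS",
]

#: analysed cause groups; "vascular" aggregates its member groups
VASCULAR_MEMBERS = ("cardiac", "stroke", "vascular_other")
CAUSE_GROUPS = (
    "all_cause", "vascular", "cardiac", "stroke", "infection", "renal",
    "cancer", "cirrhosis", "copd", "acute_diabetic_crisis",
)

WEAK_INSTRUMENT_Z = 10.0


class WeakInstrumentError(ValueError):
    """Instrument-exposure association too weak (or zero) to divide by."""


@dataclass
class MREstimate:
    """Log mortality rate ratio per k-fold increase in genetically predicted
    odds of the exposure."""

    log_rr: float
    se: float
    base_k: float          # estimate refers to a base_k-fold increase in odds
    cause: str = ""
    n_events: int = 0
    status: str = "ok"
    warnings: list[str] = field(default_factory=list)

    @property
    def rr(self) -> float:
        return math.exp(self.log_rr)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        q = stats.norm.ppf(0.5 + level / 2)
        return self.log_rr - q * self.se, self.log_rr + q * self.se

    def rr_ci(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = self.ci(level)
        return math.exp(lo), math.exp(hi)

    @property
    def z(self) -> float:
        return self.log_rr / self.se


def wald_ratio(
    grs_outcome: AssocEstimate,
    grs_exposure: AssocEstimate,
    se_method: str = "simple",
    cause: str = "",
) -> MREstimate:
    """Ratio-of-coefficients estimate on the natural (base-e) scale.

    ``se_method="simple"`` scales the numerator SE by |beta_exposure|
    (treats the strong-instrument denominator as fixed; the MR z-statistic
    then equals the numerator z-statistic exactly). ``"delta"`` adds the
    first-order term for denominator uncertainty assuming independence.
    """
    bo, so = grs_outcome.beta, grs_outcome.se
    be, se_e = grs_exposure.beta, grs_exposure.se
    if be == 0:
        raise WeakInstrumentError("exposure coefficient is zero")
    warns: list[str] = []
    if abs(be) / se_e < WEAK_INSTRUMENT_Z:
        warns.append(
            f"weak instrument: |beta_exp|/se = {abs(be) / se_e:.2f} < "
            f"{WEAK_INSTRUMENT_Z:g}"
        )
    ratio = bo / be
    if se_method == "simple":
        se = so / abs(be)
    elif se_method == "delta":
        se = math.sqrt(so**2 / be**2 + bo**2 * se_e**2 / be**4)
    else:
        raise ValueError("se_method must be 'simple' or 'delta'")
    return MREstimate(log_rr=ratio, se=se, base_k=math.e, cause=cause,
                      n_events=grs_outcome.n_events, warnings=warns)


def rescale_base(estimate: MREstimate, k: float) -> MREstimate:
    """Re-express the estimate per k-fold increase in predicted odds.

    Multiplies the log RR and SE by ln(k) / ln(current base); an exact group
    action, so rescaling is invertible and CI endpoints transform with the
    point estimate.
    """
    if k <= 1:
        raise ValueError("base k must exceed 1")
    factor = math.log(k) / math.log(estimate.base_k)
    return MREstimate(
        log_rr=estimate.log_rr * factor, se=estimate.se * factor, base_k=k,
        cause=estimate.cause, n_events=estimate.n_events,
        status=estimate.status, warnings=list(estimate.warnings),
    )


def odds_risk_example(risk: float, k: float) -> float:
    """Risk after a k-fold increase in odds: odds = r/(1-r), then
    k*odds/(1 + k*odds). The worked ladder: trebling odds takes 10% risk to
    25%, and 25% to 50%."""
    if not 0 < risk < 1:
        raise ValueError("risk must lie strictly between 0 and 1")
    odds = risk / (1 - risk)
    return k * odds / (1 + k * odds)


def cochran_q(estimates: list[MREstimate]) -> tuple[float, float, int]:
    """Cochran's Q across stratum estimates: Q, p-value, degrees of freedom."""
    usable = [e for e in estimates if e.status == "ok"]
    if len(usable) < 2:
        return 0.0, 1.0, 0
    b = np.array([e.log_rr for e in usable])
    w = np.array([1.0 / e.se**2 for e in usable])
    pooled = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - pooled) ** 2))
    dof = len(usable) - 1
    return q, float(stats.chi2.sf(q, dof)), dof


# ---------------------------------------------------------------------------
# model / results objects


def _estimates_frame(estimates: list[MREstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        lo, hi = e.rr_ci() if e.status == "ok" else (np.nan, np.nan)
        rows.append({
            "cause": e.cause, "log_rr": e.log_rr, "se": e.se, "rr": e.rr,
            "rr_lo": lo, "rr_hi": hi, "base_k": e.base_k,
            "n_events": e.n_events, "status": e.status,
            "warnings": "; ".join(e.warnings),
        })
    return pd.DataFrame(rows).set_index("cause")


class OneSampleMRResults:
    """Results container: per-cause MR estimates plus the underlying
    numerator/denominator fits."""

    def __init__(
        self,
        model: "OneSampleMR",
        estimates: list[MREstimate],
        exposure_fit: AssocEstimate,
        outcome_fits: dict[str, AssocEstimate],
    ):
        self.model = model
        self.mr_estimates = {e.cause: e for e in estimates}
        self.exposure_fit = exposure_fit
        self.outcome_fits = outcome_fits
        self.estimates = _estimates_frame(estimates)

    def summary(self) -> str:
        k = self.model.base_k
        lines = [
            "One-sample Mendelian randomisation (ratio of coefficients)",
            f"  exposure fit: log OR per GRS unit = {self.exposure_fit.beta:.4f}"
            f" (se {self.exposure_fit.se:.4f}), cases = {self.exposure_fit.n_events}",
            f"  mortality RRs per {k:g}-fold increase in predicted odds of T2D",
            "",
            f"  {'cause':<24}{'RR':>7}{'95% CI':>18}{'events':>9}  status",
        ]
        for cause, row in self.estimates.iterrows():
            if row["status"] == "ok":
                ci = f"({row['rr_lo']:.2f}-{row['rr_hi']:.2f})"
                lines.append(
                    f"  {cause:<24}{row['rr']:>7.2f}{ci:>18}"
                    f"{int(row['n_events']):>9}  {row['status']}"
                )
            else:
                lines.append(f"  {cause:<24}{'-':>7}{'-':>18}"
                             f"{int(row['n_events']):>9}  {row['status']}")
        return "\n".join(lines)


class OneSampleMR:
    """One-sample MR model over an assembled genetic-analysis cohort.

    Parameters
    ----------
    data : DataFrame with one row per participant carrying the GRS column,
        ``diabetes_class``, ``sex``, ``age``, follow-up columns
        (``entry_age``, ``exit_age``, ``died``, ``cause_group``) and the
        genetic principal components.
    grs_col : exposure column (raw log-odds units).
    base_k : reporting base for the odds scale (default 3, a trebling).
    se_method : "simple" (default; strong-instrument) or "delta".
    """

    def __init__(
        self,
        data: pd.DataFrame,
        grs_col: str = "grs",
        pc_cols: list[str] | None = None,
        band_grid: tuple[float, ...] = DEFAULT_BAND_GRID,
        base_k: float = 3.0,
        se_method: str = "simple",
    ):
        self.data = data
        self.grs_col = grs_col
        self.pc_cols = pc_cols if pc_cols is not None else [
            c for c in data.columns if c.startswith("pc")]
        self.band_grid = band_grid
        self.base_k = base_k
        self.se_method = se_method
        self._episodes: pd.DataFrame | None = None

    # -- pieces -------------------------------------------------------------

    @property
    def t2d(self) -> pd.Series:
        return self.data["diabetes_class"].isin(
            [DiabetesClass.PREVIOUS, DiabetesClass.UNDIAGNOSED])

    def fit_exposure(self, diagnosed_only: bool = False) -> AssocEstimate:
        """GRS -> T2D logistic fit adjusted for age, sex and the PCs."""
        if diagnosed_only:
            y = self.data["diabetes_class"] == DiabetesClass.PREVIOUS
        else:
            y = self.t2d
        covs = pd.DataFrame({
            "age": self.data["age"].to_numpy(float),
            "sex_f": (self.data["sex"] == "F").to_numpy(float),
        }, index=self.data.index)
        for c in self.pc_cols:
            covs[c] = self.data[c]
        return fit_logistic(y.astype(float), self.data[self.grs_col], covs)

    def episodes(self) -> pd.DataFrame:
        """Lexis episodes joined with exposure and covariates (cached)."""
        if self._episodes is None:
            d = self.data
            eps = lexis_expand(
                d["entry_age"].to_numpy(float), d["exit_age"].to_numpy(float),
                d["died"].to_numpy(bool), self.band_grid, ids=d.index,
            )
            keep = [self.grs_col, "sex", "cause_group"] + self.pc_cols
            eps = eps.join(d[keep], on="iid")
            self._episodes = eps
        return self._episodes

    def fit_outcome(self, cause: str, exposure_col: str | None = None,
                    episodes: pd.DataFrame | None = None) -> AssocEstimate:
        """GRS -> cause-specific mortality Cox fit, stratified by age band and
        sex, adjusted for the PCs; other-cause deaths are censored."""
        eps = self.episodes() if episodes is None else episodes
        eps = eps.copy()
        if cause == "all_cause":
            eps["event"] = eps["event"]
        elif cause == "vascular":
            eps["event"] = eps["event"] & eps["cause_group"].isin(VASCULAR_MEMBERS)
        else:
            eps["event"] = eps["event"] & (eps["cause_group"] == cause)
        return fit_stratified_cox(
            eps, exposure_col or self.grs_col, covariates=self.pc_cols,
            strata=["band_lo", "sex"],
        )

    # -- main entry points ----------------------------------------------------

    def fit(self, causes: tuple[str, ...] = CAUSE_GROUPS,
            min_events: int = 5) -> OneSampleMRResults:
        exposure = self.fit_exposure()
        estimates: list[MREstimate] = []
        outcome_fits: dict[str, AssocEstimate] = {}
        eps = self.episodes()
        for cause in causes:
            if cause == "all_cause":
                n_ev = int(eps["event"].sum())
            elif cause == "vascular":
                n_ev = int((eps["event"] & eps["cause_group"].isin(
                    VASCULAR_MEMBERS)).sum())
            else:
                n_ev = int((eps["event"] & (eps["cause_group"] == cause)).sum())
            if n_ev < min_events:
                estimates.append(MREstimate(
                    np.nan, np.inf, self.base_k, cause=cause, n_events=n_ev,
                    status="insufficient events"))
                continue
            out = self.fit_outcome(cause)
            outcome_fits[cause] = out
            est = wald_ratio(out, exposure, self.se_method, cause=cause)
            estimates.append(rescale_base(est, self.base_k))
        return OneSampleMRResults(self, estimates, exposure, outcome_fits)

    def fit_subgroups(
        self, subgroup: str, cause: str = "all_cause", min_events: int = 5,
    ) -> tuple[pd.DataFrame, tuple[float, float, int]]:
        """Per-stratum MR estimates with the denominator fixed at the overall
        exposure fit (subgroup-specific denominators would be unreliable),
        plus the between-stratum Cochran Q heterogeneity statistic."""
        exposure = self.fit_exposure()
        eps = self.episodes().join(
            self.data[[subgroup]].rename(columns={subgroup: "_sub"}), on="iid")
        estimates = []
        for level, sub_eps in eps.groupby("_sub", observed=True):
            n_ev = int(sub_eps["event"].sum())
            if n_ev < min_events:
                estimates.append(MREstimate(
                    np.nan, np.inf, self.base_k, cause=str(level),
                    n_events=n_ev, status="insufficient events"))
                continue
            sub_model_eps = sub_eps.drop(columns=["_sub"])
            out = self._fit_cause_on(sub_model_eps, cause)
            est = wald_ratio(out, exposure, self.se_method, cause=str(level))
            estimates.append(rescale_base(est, self.base_k))
        het = cochran_q(estimates)
        return _estimates_frame(estimates), het

    def _fit_cause_on(self, eps: pd.DataFrame, cause: str) -> AssocEstimate:
        eps = eps.copy()
        if cause == "vascular":
            eps["event"] = eps["event"] & eps["cause_group"].isin(VASCULAR_MEMBERS)
        elif cause != "all_cause":
            eps["event"] = eps["event"] & (eps["cause_group"] == cause)
        return fit_stratified_cox(eps, self.grs_col, covariates=self.pc_cols,
                                  strata=["band_lo", "sex"])

    def fit_pathways(
        self,
        pathway_scores: dict[str, pd.Series],
        cause: str = "all_cause",
        snp_counts: dict[str, int] | None = None,
    ) -> tuple[pd.DataFrame, tuple[float, float, int]]:
        """Each pathway GRS analysed as an instrument in its own right: its
        own logistic denominator and its own Cox numerator, rescaled to the
        reporting base. Returns the per-pathway table and Cochran's Q."""
        estimates = []
        for label, score in pathway_scores.items():
            col = "_pathway_grs"
            data = self.data.copy()
            data[col] = score.reindex(data.index)
            sub = OneSampleMR(data, grs_col=col, pc_cols=self.pc_cols,
                              band_grid=self.band_grid, base_k=self.base_k,
                              se_method=self.se_method)
            try:
                exposure = sub.fit_exposure()
                out = sub.fit_outcome(cause)
                est = wald_ratio(out, exposure, self.se_method, cause=label)
            except (DegenerateDesignError, WeakInstrumentError) as err:
                estimates.append(MREstimate(
                    np.nan, np.inf, self.base_k, cause=label,
                    status=f"failed: {err}"))
                continue
            est = rescale_base(est, self.base_k)
            if snp_counts is not None and label in snp_counts:
                est.warnings.append(f"n_snps={snp_counts[label]}")
            estimates.append(est)
        return _estimates_frame(estimates), cochran_q(estimates)


class ObservationalMortality:
    """Conventional Cox contrast of T2D status (previously diagnosed,
    undiagnosed, or combined) against cause-specific mortality, stratified by
    age band and sex and adjusted for district, education, smoking, alcohol
    and anthropometry in quarters. Reported per T2D status — a different
    scale from the genetic per-k-fold-of-odds estimates, deliberately never
    converted between."""

    ANTHROPOMETRY = ("height", "weight", "waist", "hip")
    CATEGORICAL = ("district", "education", "smoking", "alcohol")

    def __init__(self, data: pd.DataFrame,
                 band_grid: tuple[float, ...] = DEFAULT_BAND_GRID):
        self.data = data
        self.band_grid = band_grid

    def _design(self) -> tuple[pd.DataFrame, list[str]]:
        d = self.data
        cols = {}
        names: list[str] = []
        for col in self.CATEGORICAL:
            if col not in d:
                continue
            dummies = pd.get_dummies(d[col], prefix=col, drop_first=True)
            for c in dummies.columns:
                safe = c.replace(" ", "_").replace("-", "_")
                cols[safe] = dummies[c].to_numpy(float)
                names.append(safe)
        for col in self.ANTHROPOMETRY:
            if col not in d:
                continue
            quarters = pd.qcut(d[col], 4, labels=False, duplicates="drop")
            dummies = pd.get_dummies(quarters, prefix=f"{col}_q", drop_first=True)
            for c in dummies.columns:
                cols[str(c)] = dummies[c].to_numpy(float)
                names.append(str(c))
        return pd.DataFrame(cols, index=d.index), names

    def fit(self, causes: tuple[str, ...] = CAUSE_GROUPS,
            diabetes_classes: tuple[str, ...] = (
                DiabetesClass.PREVIOUS, DiabetesClass.UNDIAGNOSED),
            min_events: int = 5) -> pd.DataFrame:
        d = self.data
        exposed = d["diabetes_class"].isin(diabetes_classes)
        if exposed.sum() == 0:
            raise DegenerateDesignError(
                "no participants in the requested diabetes class(es)")
        eps = lexis_expand(
            d["entry_age"].to_numpy(float), d["exit_age"].to_numpy(float),
            d["died"].to_numpy(bool), self.band_grid, ids=d.index)
        design, names = self._design()
        design["t2d"] = exposed.to_numpy(float)
        design["sex"] = d["sex"]
        design["cause_group"] = d["cause_group"]
        eps = eps.join(design, on="iid")

        rows = []
        for cause in causes:
            eps_c = eps.copy()
            if cause == "vascular":
                eps_c["event"] = eps_c["event"] & eps_c["cause_group"].isin(
                    VASCULAR_MEMBERS)
            elif cause != "all_cause":
                eps_c["event"] = eps_c["event"] & (eps_c["cause_group"] == cause)
            n_ev = int(eps_c["event"].sum())
            if n_ev < min_events:
                rows.append({"cause": cause, "log_rr": np.nan, "se": np.nan,
                             "rr": np.nan, "rr_lo": np.nan, "rr_hi": np.nan,
                             "n_events": n_ev, "status": "insufficient events"})
                continue
            est = fit_stratified_cox(eps_c, "t2d", covariates=names,
                                     strata=["band_lo", "sex"],
                                     scale="per T2D status")
            lo, hi = est.ci()
            rows.append({"cause": cause, "log_rr": est.beta, "se": est.se,
                         "rr": math.exp(est.beta), "rr_lo": math.exp(lo),
                         "rr_hi": math.exp(hi), "n_events": est.n_events,
                         "status": "ok"})
        return pd.DataFrame(rows).set_index("cause")
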