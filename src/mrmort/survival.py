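"""Regression layer shared by the observational and genetic analyses.

Follow-up is split into 5-year age-at-risk bands (Lexis expansion); the Cox
partial likelihood then runs on the time-since-entry scale with age band x
sex strata, each episode entering as a left-truncated interval. Logistic
fits supply the instrument-exposure association and the per-allele scan, and
Nagelkerke's pseudo R-squared measures the share of liability the instrument
explains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssocEstimate",
    "DEFAULT_BAND_GRID",
    "lexis_expand",
    "fit_stratified_cox",
    "fit_logistic",
    "nagelkerke_r2",
    "per_allele_scan",
    "DegenerateDesignError",
    "SeparationError",
]

#: 5-year age bands covering the main analysis window (35-74); extend the
#: grid to 85 for the older-age sensitivity windows
DEFAULT_BAND_GRID = tuple(float(a) for a in range(35, 80, 5))


class DegenerateDesignError(ValueError):
    """Exposure (or design) is constant: the coefficient is undefined."""


class SeparationError(ValueError):
    """Logistic outcome perfectly separated; estimate withheld."""


@dataclass
class AssocEstimate:
    """A single association estimate: log hazard ratio or log odds ratio per
    unit exposure, with its SE, scale tag and event/case count."""

    beta: float
    se: float
    scale: str  # "per GRS unit" | "per SD" | "per T2D status" | "per allele"
    n_events: int
    loglik: float | None = None
    diagnostics: dict | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats
        q = stats.norm.ppf(0.5 + level / 2)
        return self.beta - q * self.se, self.beta + q * self.se

    def rescaled(self, factor: float, scale: str) -> "AssocEstimate":
        return AssocEstimate(self.beta * factor, self.se * abs(factor), scale,
                             self.n_events, self.loglik, self.diagnostics)


def lexis_expand(
    entry_age: np.ndarray,
    exit_age: np.ndarray,
    event: np.ndarray,
    band_grid: tuple[float, ...] = DEFAULT_BAND_GRID,
    ids: pd.Index | None = None,
) -> pd.DataFrame:
    """Split follow-up into age-band episodes.

    Returns one row per (individual, band) overlap with study-time ``start``
    and ``stop`` (years since entry, giving the left-truncated interval for
    the Cox fit on the time-since-entry scale), the attained-age ``band``
    label, ``time_in_band`` and the ``event`` flag (assigned to the band
    containing the exit age). Follow-up beyond the top of the grid is
    discarded — the analysis ceiling.
    """
    entry_age = np.asarray(entry_age, float)
    exit_age = np.asarray(exit_age, float)
    event = np.asarray(event, bool)
    if np.any(exit_age <= entry_age):
        raise ValueError("exit age must exceed entry age for every individual")
    bands_lo = np.asarray(band_grid[:-1], float)
    bands_hi = np.asarray(band_grid[1:], float)

    s = np.maximum(entry_age[:, None], bands_lo[None, :])
    e = np.minimum(exit_age[:, None], bands_hi[None, :])
    mask = e > s
    i_idx, b_idx = np.nonzero(mask)
    ceiling = band_grid[-1]
    # an event beyond the grid ceiling never enters; inside, it belongs to
    # the band containing the exit age
    ev = event[i_idx] & (e[i_idx, b_idx] == exit_age[i_idx]) & (
        exit_age[i_idx] <= ceiling)
    if ids is None:
        ids = pd.RangeIndex(len(entry_age))
    df = pd.DataFrame(
        {
            "iid": np.asarray(ids)[i_idx],
            "band_lo": bands_lo[b_idx],
            "start": s[i_idx, b_idx] - entry_age[i_idx],
            "stop": e[i_idx, b_idx] - entry_age[i_idx],
            "event": ev,
        }
    )
    df["time_in_band"] = df["stop"] - df["start"]
    return df


def fit_stratified_cox(
    episodes: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    strata: list[str] | None = None,
    scale: str = "per GRS unit",
) -> AssocEstimate:
    """Stratified Cox partial likelihood on left-truncated episodes.

    ``episodes`` must carry ``start``, ``stop``, ``event``, the exposure and
    covariate columns and the strata columns. Strata with no events are
    dropped with a warning (they contribute nothing to the partial
    likelihood). Ties are handled by Efron's method (the lifelines default);
    other-cause deaths should already be coded as censorings, making this a
    cause-specific hazard fit.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = covariates or []
    strata = strata or []
    cols = ["start", "stop", "event", exposure] + covariates + strata
    df = episodes[cols].copy()

    if np.isclose(df[exposure].std(), 0):
        raise DegenerateDesignError(f"exposure {exposure!r} is constant")

    if strata:
        # single factorised key: much faster stratum partitioning than a
        # MultiIndex, identical partial likelihood
        if len(strata) == 1:
            key = df[strata[0]].to_numpy()
        else:
            key = pd.MultiIndex.from_frame(df[strata]).to_flat_index().to_numpy()
        codes, _ = pd.factorize(key)
        df = df.drop(columns=strata)
        df["_stratum"] = codes
        ev_per = df.groupby("_stratum", observed=True)["event"].sum()
        dead_strata = ev_per[ev_per == 0].index
        if len(dead_strata):
            warnings.warn(f"dropping {len(dead_strata)} stratum/strata with no events")
            df = df[~df["_stratum"].isin(dead_strata)]
    elif df["event"].sum() == 0:
        raise ValueError("no events at all")

    cph = CoxPHFitter()
    try:
        cph.fit(
            df,
            duration_col="stop",
            entry_col="start",
            event_col="event",
            strata=["_stratum"] if strata else None,
            formula=" + ".join([exposure] + covariates),
        )
    except ConvergenceError as err:  # diagnostic error with the trace attached
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    beta = float(cph.params_[exposure])
    se = float(cph.standard_errors_[exposure])
    return AssocEstimate(
        beta=beta, se=se, scale=scale, n_events=int(df["event"].sum()),
        loglik=float(cph.log_likelihood_),
        diagnostics={"n_episodes": len(df)},
    )


def fit_logistic(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    scale: str = "per GRS unit",
) -> AssocEstimate:
    """Maximum-likelihood logistic fit of a binary outcome on the exposure.

    Raises :class:`SeparationError` when the likelihood is degenerate
    (perfect separation) and :class:`DegenerateDesignError` when only one
    outcome class is present or the exposure is constant.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, float)
    if len(np.unique(y)) < 2:
        raise DegenerateDesignError("both outcome classes must be present")
    x = np.asarray(exposure, float)
    if np.isclose(x.std(), 0):
        raise DegenerateDesignError("exposure is constant")
    X = pd.DataFrame({"const": 1.0, "exposure": x})
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], float)

    from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        warnings.simplefilter("error", category=ConvergenceWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (ConvergenceWarning, PerfectSeparationWarning) as err:
            # ML logistic failing to converge is, in practice, separation
            raise SeparationError(str(err)) from err
        except Exception as err:
            if "separat" in str(err).lower():
                raise SeparationError(str(err)) from err
            raise
    if not np.isfinite(res.bse["exposure"]) or res.bse["exposure"] > 1e4:
        raise SeparationError("non-finite or exploding standard error")
    return AssocEstimate(
        beta=float(res.params["exposure"]), se=float(res.bse["exposure"]),
        scale=scale, n_events=int(y.sum()), loglik=float(res.llf),
        diagnostics={"llnull": float(res.llnull), "n": len(y)},
    )


def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke's pseudo R-squared from the two log-likelihoods.

    R2 = [1 - exp(2 (ll0 - ll1) / n)] / [1 - exp(2 ll0 / n)], the
    Cox-and-Snell ratio rescaled to its attainable maximum; lies in [0, 1]
    for a genuine ML fit.
    """
    if ll_full < ll_null - 1e-8:
        raise ValueError("full-model likelihood below null likelihood")
    cs = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        raise ValueError("degenerate null likelihood")
    return float(cs / max_cs)


def per_allele_scan(
    dosages: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    external_weights: pd.Series | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Per-SNP logistic associations with the binary outcome.

    Missing dosages are mean-imputed per SNP; monomorphic SNPs are skipped
    with a reason. When ``external_weights`` is given, the correlation
    between in-cohort per-allele estimates and the external weights is
    returned alongside (the instrument-transferability diagnostic).
    """
    rows = []
    for rsid in dosages.columns:
        d = dosages[rsid].to_numpy(float, copy=True)
        m = np.isnan(d)
        if m.all():
            rows.append({"rsid": rsid, "beta": np.nan, "se": np.nan,
                         "status": "all_missing"})
            continue
        if m.any():
            d[m] = d[~m].mean()
        if np.isclose(d.std(), 0):
            rows.append({"rsid": rsid, "beta": np.nan, "se": np.nan,
                         "status": "monomorphic"})
            continue
        try:
            est = fit_logistic(outcome, pd.Series(d, index=dosages.index),
                               covariates, scale="per allele")
        except (SeparationError, DegenerateDesignError) as err:
            rows.append({"rsid": rsid, "beta": np.nan, "se": np.nan,
                         "status": type(err).__name__})
            continue
        rows.append({"rsid": rsid, "beta": est.beta, "se": est.se, "status": "ok"})
    table = pd.DataFrame(rows).set_index("rsid")
    corr = None
    if external_weights is not None:
        ok = table["status"] == "ok"
        merged = table.loc[ok, "beta"].to_frame().join(
            external_weights.rename("w"), how="inner").dropna()
        if len(merged) >= 3:
            corr = float(np.corrcoef(merged["beta"], merged["w"])[0, 1])
    return table, corr
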