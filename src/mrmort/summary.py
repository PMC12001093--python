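"""Two-sample summary-statistic MR sensitivity estimators.

Operates on per-SNP rows (exposure and outcome effect estimates with their
SEs): inverse-variance weighted regression through the origin, MR-Egger with
a free pleiotropy intercept, the weighted median, and MR-PRESSO's
residual-sum-of-squares global/outlier/distortion tests. These probe the
robustness of the ratio estimate to horizontal pleiotropy: IVW assumes all
instruments valid, Egger tolerates directional pleiotropy independent of
instrument strength, the weighted median tolerates up to half the weight
coming from invalid instruments, and MR-PRESSO removes individually
heterogeneous SNPs.

All stochastic pieces are seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "IvwResult",
    "EggerResult",
    "WeightedMedianResult",
    "PressoResult",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mr_presso",
    "SummaryMR",
]

REQUIRED_COLUMNS = ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome")


def _check_rows(rows: pd.DataFrame, min_rows: int, op: str) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in rows:
            raise ValueError(f"summary table lacks column {col!r}")
    if len(rows) < min_rows:
        raise ValueError(f"{op} requires at least {min_rows} SNPs, got {len(rows)}")
    if (rows["se_exposure"] <= 0).any() or (rows["se_outcome"] <= 0).any():
        raise ValueError("standard errors must be positive")
    return rows


class SummaryStats:
    """Thin validated wrapper for a per-SNP summary-statistics table."""

    def __init__(self, rows: pd.DataFrame):
        self.rows = _check_rows(rows, 1, "summary MR")

    @classmethod
    def from_arrays(cls, beta_exposure, se_exposure, beta_outcome, se_outcome,
                    rsid=None) -> "SummaryStats":
        df = pd.DataFrame({
            "beta_exposure": beta_exposure, "se_exposure": se_exposure,
            "beta_outcome": beta_outcome, "se_outcome": se_outcome,
        })
        if rsid is not None:
            df.index = pd.Index(rsid, name="rsid")
        return cls(df)


@dataclass
class IvwResult:
    beta: float
    se: float
    q: float
    q_pvalue: float
    n_snps: int
    model: str

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se


def ivw(rows: pd.DataFrame, model: str = "random") -> IvwResult:
    """Inverse-variance weighted estimate: regression of outcome betas on
    exposure betas through the origin with weights 1/se_outcome^2.

    The random-effects variant inflates the SE by max(1, sqrt(Q/(n-1))) to
    absorb balanced heterogeneity. A single row degenerates to that SNP's
    Wald ratio.
    """
    rows = _check_rows(rows, 1, "IVW")
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    if len(rows) < 2 and model == "random":
        raise ValueError("random-effects IVW requires at least 2 SNPs")
    x = rows["beta_exposure"].to_numpy(float)
    y = rows["beta_outcome"].to_numpy(float)
    w = 1.0 / rows["se_outcome"].to_numpy(float) ** 2
    sxx = float(np.sum(w * x * x))
    if sxx == 0:
        raise ValueError("all exposure betas are zero")
    beta = float(np.sum(w * x * y)) / sxx
    se = 1.0 / math.sqrt(sxx)
    q = float(np.sum(w * (y - beta * x) ** 2))
    dof = max(len(rows) - 1, 1)
    if model == "random":
        se *= max(1.0, math.sqrt(q / dof))
    return IvwResult(beta=beta, se=se, q=q,
                     q_pvalue=float(stats.chi2.sf(q, dof)) if len(rows) > 1 else 1.0,
                     n_snps=len(rows), model=model)


@dataclass
class EggerResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    n_snps: int

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.slope - z * self.slope_se, self.slope + z * self.slope_se


def mr_egger(rows: pd.DataFrame, model: str = "random") -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure betas with a free
    intercept, after orienting every row to a positive exposure beta (the
    standard InSIDE/NOME convention). A nonzero intercept estimates the
    average directional pleiotropic effect; the slope remains a consistent
    causal estimate under directional pleiotropy independent of instrument
    strength.
    """
    rows = _check_rows(rows, 3, "MR-Egger")
    sign = np.sign(rows["beta_exposure"].to_numpy(float))
    sign[sign == 0] = 1.0
    x = rows["beta_exposure"].to_numpy(float) * sign
    y = rows["beta_outcome"].to_numpy(float) * sign
    w = 1.0 / rows["se_outcome"].to_numpy(float) ** 2
    if np.isclose(np.std(x), 0):
        raise ValueError("exposure betas are collinear with the intercept")

    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    n = len(rows)
    scale = 1.0
    if model == "random":
        scale = max(1.0, math.sqrt(float(np.sum(w * resid**2)) / (n - 2)))
    slope_se = scale / math.sqrt(sxx)
    intercept_se = scale * math.sqrt(1.0 / sw + xbar**2 / sxx)
    z_int = intercept / intercept_se
    return EggerResult(
        slope=slope, slope_se=float(slope_se), intercept=intercept,
        intercept_se=float(intercept_se),
        intercept_pvalue=float(2 * stats.norm.sf(abs(z_int))), n_snps=n,
    )


@dataclass
class WeightedMedianResult:
    beta: float
    se: float
    n_snps: int
    n_boot: int
    seed: int

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # mid-point cumulative weight
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(rows: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0) -> WeightedMedianResult:
    """Weight-interpolated 50th percentile of per-SNP Wald ratios, with
    inverse-variance weights on the ratio scale; SE by seeded parametric
    bootstrap. Consistent while valid instruments hold at least half the
    total weight."""
    rows = _check_rows(rows, 3, "weighted median")
    x = rows["beta_exposure"].to_numpy(float)
    y = rows["beta_outcome"].to_numpy(float)
    sx = rows["se_exposure"].to_numpy(float)
    sy = rows["se_outcome"].to_numpy(float)
    if np.any(x == 0):
        raise ValueError("zero exposure beta gives an undefined Wald ratio")
    ratios = y / x
    var = sy**2 / x**2 + y**2 * sx**2 / x**4  # delta-method ratio variance
    weights = 1.0 / var
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.normal(x, sx)
        yb = rng.normal(y, sy)
        ok = xb != 0
        rb = yb[ok] / xb[ok]
        vb = sy[ok]**2 / xb[ok]**2 + yb[ok]**2 * sx[ok]**2 / xb[ok]**4
        boots[b] = _weighted_median_point(rb, 1.0 / vb)
    return WeightedMedianResult(beta=beta, se=float(boots.std(ddof=1)),
                                n_snps=len(rows), n_boot=n_boot, seed=seed)


@dataclass
class PressoResult:
    global_rss: float
    global_pvalue: float
    outliers: list = field(default_factory=list)
    outlier_pvalues: dict = field(default_factory=dict)
    raw_estimate: IvwResult | None = None
    corrected_estimate: IvwResult | None = None
    distortion_pvalue: float | None = None
    n_sim: int = 0
    seed: int = 0


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorised."""
    s_xy = np.sum(w * x * y)
    s_xx = np.sum(w * x * x)
    return (s_xy - w * x * y) / (s_xx - w * x * x)


def mr_presso(rows: pd.DataFrame, n_sim: int = 1000, threshold: float = 0.05,
              seed: int = 0) -> PressoResult:
    """Pleiotropy residual-sum-of-squares test with outlier removal.

    Global test: the observed weighted RSS of each SNP against its
    leave-one-out IVW prediction is compared with the RSS distribution under
    parametric draws from the per-SNP normal models. Outlier test: each
    SNP's weighted squared residual against its own simulated distribution,
    Bonferroni-corrected at ``threshold``. Distortion test: the relative
    difference between the full and outlier-corrected IVW slopes against a
    null built by removing random same-sized sets of non-outlier SNPs.
    """
    rows = _check_rows(rows, 4, "MR-PRESSO")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    x = rows["beta_exposure"].to_numpy(float)
    y = rows["beta_outcome"].to_numpy(float)
    sx = rows["se_exposure"].to_numpy(float)
    sy = rows["se_outcome"].to_numpy(float)
    w = 1.0 / sy**2
    n = len(rows)

    b_loo = _loo_slopes(x, y, w)
    resid2_obs = w * (y - b_loo * x) ** 2
    rss_obs = float(resid2_obs.sum())

    # parametric null: exposure betas redrawn about themselves, outcome betas
    # about the leave-one-out predictions
    xs = rng.normal(x, sx, size=(n_sim, n))
    ys = rng.normal(b_loo * x, sy, size=(n_sim, n))
    s_xy = np.sum(w * xs * ys, axis=1, keepdims=True)
    s_xx = np.sum(w * xs * xs, axis=1, keepdims=True)
    b_loo_sim = (s_xy - w * xs * ys) / (s_xx - w * xs * xs)
    resid2_sim = w * (ys - b_loo_sim * xs) ** 2
    rss_sim = resid2_sim.sum(axis=1)
    # plain empirical fractions (an observed statistic beyond every simulated
    # one yields p = 0, letting Bonferroni flag outliers at moderate n_sim)
    global_p = float(np.mean(rss_sim >= rss_obs))

    # per-SNP outlier p-values, Bonferroni corrected
    p_snp = np.mean(resid2_sim >= resid2_obs[None, :], axis=0)
    outlier_mask = p_snp * n < threshold
    outliers = list(rows.index[outlier_mask])

    raw = ivw(rows, model="random") if n >= 2 else None
    corrected = None
    distortion_p = None
    if outliers and (~outlier_mask).sum() >= 2:
        corrected = ivw(rows.loc[~outlier_mask], model="random")
        # distortion null: drop random same-sized subsets of inlier SNPs
        inlier_idx = np.where(~outlier_mask)[0]
        d_obs = (raw.beta - corrected.beta) / abs(corrected.beta)
        n_out = int(outlier_mask.sum())
        d_null = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(inlier_idx, size=n_out, replace=True)
            keep = np.setdiff1d(np.arange(n), drop)
            bb = ivw(rows.iloc[keep], model="fixed").beta
            d_null[b] = (raw.beta - bb) / abs(bb) if bb != 0 else 0.0
        distortion_p = float(np.mean(np.abs(d_null) >= abs(d_obs)))
    return PressoResult(
        global_rss=rss_obs, global_pvalue=global_p, outliers=outliers,
        outlier_pvalues={r: float(p) for r, p in zip(rows.index, p_snp)},
        raw_estimate=raw, corrected_estimate=corrected,
        distortion_pvalue=distortion_p, n_sim=n_sim, seed=seed,
    )


class SummaryMR:
    """Model-style wrapper: hold a summary-stats table, fit any estimator.

    The intended two-sample use pairs an external weight file (exposure side)
    with in-cohort per-allele mortality estimates (outcome side); sample
    non-overlap between the two sources is a documented assumption of the
    approach, not an enforced check.
    """

    def __init__(self, stats_: SummaryStats | pd.DataFrame):
        self.rows = stats_.rows if isinstance(stats_, SummaryStats) else \
            SummaryStats(stats_).rows

    def fit(self, method: str = "ivw", **kwargs):
        if method == "ivw":
            return ivw(self.rows, **kwargs)
        if method == "egger":
            return mr_egger(self.rows, **kwargs)
        if method == "weighted_median":
            return weighted_median(self.rows, **kwargs)
        if method == "presso":
            return mr_presso(self.rows, **kwargs)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, seed: int = 0, n_boot: int = 1000,
                n_sim: int = 1000) -> dict:
        return {
            "ivw": ivw(self.rows),
            "egger": mr_egger(self.rows),
            "weighted_median": weighted_median(self.rows, n_boot=n_boot, seed=seed),
            "presso": mr_presso(self.rows, n_sim=n_sim, seed=seed),
        }
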