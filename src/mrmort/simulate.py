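"""Synthetic admixed-cohort generator.

Emulates the statistical structure of a large prospective cohort with a
polygenic instrument for type 2 diabetes (T2D): a liability-threshold disease
model in which a genetic risk score (GRS) explains a single-digit share of
liability variance, confounders independent of genotype, cause-specific
mortality with hazards raised by T2D, and death-certificate miscoding in which
a share of deaths among diabetic participants carries "diabetes" as the raw
underlying cause.

Every operation is deterministic given ``SimulationConfig.seed``; each draws
from its own child stream so intermediate products can be regenerated
independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfounderEffect",
    "CauseHazard",
    "SimulationConfig",
    "TruePanel",
    "GenotypeData",
    "SimulationError",
    "simulate_panel",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_mortality",
    "simulate_gwas_weights",
    "simulate_cohort",
    "write_cohort",
    "DEFAULT_CAUSE_HAZARDS",
]

# child-stream codes so each operation has an independent, reproducible RNG
_OP_PANEL, _OP_GENO, _OP_PHENO, _OP_MORT, _OP_WEIGHTS = 11, 12, 13, 14, 15

PATHWAY_LABELS = (
    "beta-cell+proinsulin",
    "beta-cell-proinsulin",
    "residual glycaemia",
    "body fat",
    "metabolic syndrome",
    "obesity-mediated insulin resistance",
    "lipodystrophy",
    "liver/lipid metabolism",
)

_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class SimulationError(ValueError):
    """Raised when a simulation request is internally inconsistent."""


@dataclass(frozen=True)
class ConfounderEffect:
    """Effect of one baseline covariate on liability and on the log hazard.

    The covariate named by the key in ``SimulationConfig.confounder_effects``
    is standardised to unit variance before the coefficients apply, so both
    are per-SD effects.
    """

    liability: float = 0.0
    log_hazard: float = 0.0


@dataclass(frozen=True)
class CauseHazard:
    """Constant cause-specific hazard: baseline rate per person-year and the
    log rate ratio applied to T2D carriers."""

    base_rate: float
    log_rr: float = 0.0


# Baseline rates are per person-year among non-diabetic adults aged 35-74 and
# are chosen so that ~20 years of follow-up yields roughly 10% all-cause
# mortality with a cause mix dominated by vascular, infectious, renal and
# neoplastic deaths; T2D log rate-ratios encode strong causal effects on renal
# and acute diabetic deaths, moderate effects on vascular and infectious
# deaths, and none on cancer, cirrhosis, COPD or external causes.
DEFAULT_CAUSE_HAZARDS: dict[str, CauseHazard] = {
    "cardiac": CauseHazard(9.0e-4, np.log(1.8)),
    "stroke": CauseHazard(2.8e-4, np.log(1.8)),
    "infection": CauseHazard(9.0e-4, np.log(1.6)),
    "renal": CauseHazard(5.0e-4, np.log(4.0)),
    "cancer": CauseHazard(8.5e-4, 0.0),
    "cirrhosis": CauseHazard(3.7e-4, 0.0),
    "copd": CauseHazard(1.2e-4, 0.0),
    "acute_diabetic_crisis": CauseHazard(2.0e-6, np.log(650.0)),
    "other_medical": CauseHazard(1.1e-3, np.log(1.2)),
    "external": CauseHazard(4.0e-4, 0.0),
}

# representative ICD-10 underlying-cause code per generated cause group
CAUSE_ICD10 = {
    "cardiac": "I21.9",
    "stroke": "I64",
    "infection": "A41.9",
    "renal": "N18.5",
    "cancer": "C80.9",
    "cirrhosis": "K74.6",
    "copd": "J44.9",
    "acute_diabetic_crisis": "E11.1",  # diabetes code with acute 4th character
    "other_medical": "K85.9",
    "external": "V89.2",
}
DIABETES_NON_ACUTE_CODE = "E11.9"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults emulate the study conditions: 18% T2D prevalence via a liability
    threshold, a GRS explaining 6% of liability variance, eight SNP pathways,
    20 years of administrative follow-up, recruitment ages 35-74 with 68%
    women, and an admixed population whose mean indigenous-ancestry fraction
    is 0.67.
    """

    n_individuals: int = 20_000
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_prevalence: float = 0.18
    grs_liability_r2: float = 0.06
    n_pathways: int = 8
    palindromic_frac: float = 0.157
    confounder_effects: dict[str, ConfounderEffect] = field(default_factory=dict)
    cause_hazards: dict[str, CauseHazard] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_HAZARDS)
    )
    admin_censor_years: float = 20.0
    weibull_shape: float = 1.0
    diabetes_miscode_frac: float = 0.25
    missing_dosage_rate: float = 0.002
    genetic_qc_fail_rate: float = 0.01
    ancestry_beta: tuple[float, float] = (6.7, 3.3)
    female_frac: float = 0.68
    age_range: tuple[float, float] = (35.0, 74.0)
    frac_diagnosed_among_t2d: float = 0.72
    hba1c_no_diabetes: tuple[float, float] = (5.5, 0.4)
    hba1c_diagnosed: tuple[float, float] = (9.1, 2.5)
    # distribution among undiagnosed diabetes is a free choice (left-truncated
    # at the 6.5% diagnostic threshold so undiagnosed cases are detectable)
    hba1c_undiagnosed: tuple[float, float] = (7.5, 1.5)
    hba1c_missing_rate: float = 0.002
    insulin_frac_diagnosed: float = 0.08
    early_diagnosis_frac: float = 0.01  # diagnosed before 35 -> likely-T1D pool
    weight_true_corr: float = 0.5
    liability_logodds_scale: float = 1.7
    compute_pcs: bool = True
    n_pcs: int = 7
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise SimulationError("n_snps must be >= 1")
        if self.n_individuals < 1:
            raise SimulationError("n_individuals must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5]")
        for name, value in [
            ("target_prevalence", self.target_prevalence),
            ("grs_liability_r2", self.grs_liability_r2),
            ("palindromic_frac", self.palindromic_frac),
            ("diabetes_miscode_frac", self.diabetes_miscode_frac),
            ("missing_dosage_rate", self.missing_dosage_rate),
            ("female_frac", self.female_frac),
            ("frac_diagnosed_among_t2d", self.frac_diagnosed_among_t2d),
        ]:
            if not 0 <= value <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")
        for cause, ch in self.cause_hazards.items():
            if ch.base_rate < 0:
                raise SimulationError(f"negative base rate for cause {cause!r}")
        if self.grs_liability_r2 >= 1:
            raise SimulationError("grs_liability_r2 must be < 1")
        if self.n_pathways < 1:
            raise SimulationError("n_pathways must be >= 1")

    def rng(self, op_code: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, op_code)))


@dataclass
class TruePanel:
    """Ground-truth instrument panel: per-SNP source-population frequencies,
    true liability effects (per effect-allele dosage unit), pathway labels and
    strand/palindromicity flags."""

    table: pd.DataFrame  # rsid-indexed
    liability_sd: float  # total SD of the liability the effects live on

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def effects(self) -> np.ndarray:
        return self.table["effect"].to_numpy()


@dataclass
class GenotypeData:
    """Dosage matrix (individuals x SNPs) with injected missingness, the
    complete pre-missingness dosages, per-individual ancestry fractions and
    the counted-allele table used for harmonisation."""

    dosages: pd.DataFrame          # NaN where missing
    complete: np.ndarray           # no missingness; generator-internal truth
    ancestry: pd.Series
    variants: pd.DataFrame         # rsid, chrom, pos, counted_allele, other_allele


def _confounder_variance(config: SimulationConfig) -> float:
    return float(sum(e.liability**2 for e in config.confounder_effects.values()))


def simulate_panel(config: SimulationConfig) -> TruePanel:
    """Draw the ground-truth SNP panel.

    True effects are scaled so the population GRS explains
    ``grs_liability_r2`` of total liability variance: with per-SNP dosage
    variances v_j (analytic, under the ancestry-mixture model) the raw normal
    effects are rescaled so that sum(beta_j^2 v_j) = r2 (1 + c) / (1 - r2)
    where c is the confounder contribution to liability variance and the
    residual liability noise is standard normal.
    """
    config.validate()
    rng = config.rng(_OP_PANEL)
    m = config.n_snps

    lo, hi = config.maf_range
    maf1 = rng.uniform(lo, hi, m)
    maf2 = np.clip(maf1 + rng.normal(0, 0.1, m), 0.01, 0.5)

    palindromic = rng.random(m) < config.palindromic_frac
    pair_idx = rng.integers(0, 4, m)
    eff = np.where(
        palindromic,
        [ _PALINDROMIC_PAIRS[i][0] for i in pair_idx ],
        [ _NON_PALINDROMIC_PAIRS[i][0] for i in pair_idx ],
    )
    oth = np.where(
        palindromic,
        [ _PALINDROMIC_PAIRS[i][1] for i in pair_idx ],
        [ _NON_PALINDROMIC_PAIRS[i][1] for i in pair_idx ],
    )
    minus_strand = rng.random(m) < 0.5

    raw = rng.normal(0.0, 1.0, m)
    a, b = config.ancestry_beta
    anc_mean = a / (a + b)
    anc_var = a * b / ((a + b) ** 2 * (a + b + 1))
    fbar = anc_mean * maf1 + (1 - anc_mean) * maf2
    dos_var = 2 * fbar * (1 - fbar) + 2 * (maf1 - maf2) ** 2 * anc_var

    r2 = config.grs_liability_r2
    if r2 == 0:
        beta = np.zeros(m)
    else:
        c = _confounder_variance(config)
        target = r2 * (1 + c) / (1 - r2)
        beta = raw * np.sqrt(target / float(np.sum(raw**2 * dos_var)))
    liability_var = float(np.sum(beta**2 * dos_var)) + _confounder_variance(config) + 1.0

    labels = list(PATHWAY_LABELS) + [
        f"pathway_{k + 1}" for k in range(len(PATHWAY_LABELS), config.n_pathways)
    ]
    pathway = np.array(
        [labels[j % config.n_pathways] for j in range(m)], dtype=object
    )

    table = pd.DataFrame(
        {
            "chrom": [str(j % 22 + 1) for j in range(m)],
            "pos": np.arange(1, m + 1) * 10_000,
            "effect_allele": eff,
            "other_allele": oth,
            "maf_pop1": maf1,
            "maf_pop2": maf2,
            "effect": beta,
            "pathway": pathway,
            "palindromic": palindromic,
            "minus_strand": minus_strand,
        },
        index=pd.Index([f"rs{j + 1}" for j in range(m)], name="rsid"),
    )
    return TruePanel(table=table, liability_sd=float(np.sqrt(liability_var)))


def simulate_genotypes(panel: TruePanel, config: SimulationConfig) -> GenotypeData:
    """Draw effect-allele dosages under a two-way admixture model.

    Each individual carries an ancestry fraction a_i ~ Beta; each dosage is
    binomial(2, f_i) at the individual-specific mixed frequency
    f_i = a_i f1 + (1 - a_i) f2. Missing dosages are injected completely at
    random. The counted allele in the emitted variant table is the effect
    allele for a random half of SNPs and the other allele for the rest, so
    downstream harmonisation has real work to do.
    """
    if panel.n_snps == 0:
        raise SimulationError("panel is empty")
    rng = config.rng(_OP_GENO)
    n, m = config.n_individuals, panel.n_snps
    a, b = config.ancestry_beta
    anc = rng.beta(a, b, n)
    f1 = panel.table["maf_pop1"].to_numpy()
    f2 = panel.table["maf_pop2"].to_numpy()
    freq = anc[:, None] * f1[None, :] + (1 - anc[:, None]) * f2[None, :]
    # two independent allele draws at the individual-specific frequency
    complete = (
        (rng.random((n, m)) < freq).astype(float)
        + (rng.random((n, m)) < freq)
    )

    dosages = complete.copy()
    if config.missing_dosage_rate > 0:
        mask = rng.random((n, m)) < config.missing_dosage_rate
        dosages[mask] = np.nan

    ids = pd.Index([f"P{i + 1:06d}" for i in range(n)], name="iid")
    counted_is_effect = rng.random(m) < 0.5
    eff = panel.table["effect_allele"].to_numpy()
    oth = panel.table["other_allele"].to_numpy()
    variants = pd.DataFrame(
        {
            "chrom": panel.table["chrom"].to_numpy(),
            "pos": panel.table["pos"].to_numpy(),
            "counted_allele": np.where(counted_is_effect, eff, oth),
            "other_allele": np.where(counted_is_effect, oth, eff),
        },
        index=panel.table.index.copy(),
    )
    # the emitted dosage counts the counted allele
    emitted = np.where(counted_is_effect[None, :], dosages, 2.0 - dosages)
    emitted_complete = np.where(counted_is_effect[None, :], complete, 2.0 - complete)
    dosage_df = pd.DataFrame(emitted, index=ids, columns=panel.table.index.copy())
    return GenotypeData(
        dosages=dosage_df,
        complete=emitted_complete,
        ancestry=pd.Series(anc, index=ids, name="ancestry_fraction"),
        variants=variants,
    )


def _true_score(genotypes: GenotypeData, panel: TruePanel) -> np.ndarray:
    """True-weighted score on the effect-allele scale (uses complete dosages)."""
    counted_is_eff = (
        genotypes.variants["counted_allele"].to_numpy()
        == panel.table["effect_allele"].to_numpy()
    )
    d_eff = np.where(counted_is_eff[None, :], genotypes.complete,
                     2.0 - genotypes.complete)
    return d_eff @ panel.effects


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _resolve_covariate(df: pd.DataFrame, key: str) -> np.ndarray:
    """Resolve a confounder key to a unit-variance covariate vector.

    ``"weight"`` standardises the numeric column; ``"smoking=current_heavy"``
    builds a standardised indicator.
    """
    if "=" in key:
        col, value = key.split("=", 1)
        if col not in df:
            raise SimulationError(f"unknown covariate {col!r}")
        return _standardise((df[col] == value).to_numpy(float))
    if key not in df:
        raise SimulationError(f"unknown covariate {key!r}")
    return _standardise(df[key].to_numpy(float))


def simulate_phenotypes(
    genotypes: GenotypeData, panel: TruePanel, config: SimulationConfig
) -> pd.DataFrame:
    """Draw baseline covariates, liability, T2D status and HbA1c.

    Liability = true-weighted score + confounder contribution + N(0,1) noise;
    T2D is assigned above the empirical liability quantile matching the target
    prevalence (robust to any confounder configuration). Covariates are drawn
    independently of genotype. Principal components come from a truncated SVD
    of the centred, mean-imputed dosage matrix, exercising the same adjustment
    pathway as a real analysis.
    """
    rng = config.rng(_OP_PHENO)
    n = len(genotypes.dosages)
    ids = genotypes.dosages.index

    sex = np.where(rng.random(n) < config.female_frac, "F", "M")
    female = sex == "F"
    age = rng.uniform(*config.age_range, n)
    district = rng.choice(["Coyoacan", "Iztapalapa"], n, p=[0.39, 0.61])
    education = rng.choice(
        ["university_or_high_school", "middle_school", "elementary", "other"],
        n, p=[0.16, 0.22, 0.50, 0.12],
    )
    smoking = rng.choice(
        ["never", "former", "occasional", "current_lt10", "current_ge10"],
        n, p=[0.45, 0.18, 0.14, 0.13, 0.10],
    )
    alcohol = rng.choice(["never", "former", "current"], n, p=[0.20, 0.12, 0.68])
    # regular exercise: a lifestyle factor deliberately outside the
    # observational adjustment set, so planted confounding through it
    # survives covariate adjustment (as unmeasured confounding does)
    physical_activity = rng.choice(["inactive", "active"], n, p=[0.78, 0.22])

    height = np.where(female, rng.normal(152, 6, n), rng.normal(165, 7, n))
    weight = np.where(female, rng.normal(68.3, 12.4, n), rng.normal(76.3, 12.6, n))
    waist = np.where(female, rng.normal(93, 12, n), rng.normal(96, 10, n))
    hip = np.where(female, rng.normal(105.7, 9, n), rng.normal(101, 8, n))

    prior = {
        "prior_ihd": 0.012, "prior_stroke": 0.009, "prior_ckd": 0.008,
        "prior_cirrhosis": 0.0013, "prior_cancer": 0.011, "prior_emphysema": 0.002,
    }

    df = pd.DataFrame(
        {
            "sex": sex, "age": age, "district": district, "education": education,
            "smoking": smoking, "alcohol": alcohol,
            "physical_activity": physical_activity, "height": height,
            "weight": weight, "waist": waist, "hip": hip,
            "ancestry_fraction": genotypes.ancestry.to_numpy(),
        },
        index=ids,
    )
    for col, p in prior.items():
        df[col] = rng.random(n) < p

    grs_true = _true_score(genotypes, panel)
    conf = np.zeros(n)
    for key, effect in config.confounder_effects.items():
        conf += effect.liability * _resolve_covariate(df, key)
    noise = rng.normal(0.0, 1.0, n)
    liability = grs_true + conf + noise
    if np.std(liability) == 0:
        raise SimulationError("degenerate liability: prevalence not achievable")
    threshold = np.quantile(liability, 1 - config.target_prevalence)
    t2d = liability > threshold

    diagnosed = t2d & (rng.random(n) < config.frac_diagnosed_among_t2d)
    undiag = t2d & ~diagnosed

    mu0, sd0 = config.hba1c_no_diabetes
    mu_d, sd_d = config.hba1c_diagnosed
    mu_u, sd_u = config.hba1c_undiagnosed
    hba1c = np.clip(rng.normal(mu0, sd0, n), 3.5, None)
    hba1c[diagnosed] = np.clip(rng.normal(mu_d, sd_d, diagnosed.sum()), 4.0, None)
    # undiagnosed cases must clear the 6.5% diagnostic threshold to be
    # detectable, so draw from the left-truncated normal
    if undiag.any():
        a_trunc = (6.5 - mu_u) / sd_u
        hba1c[undiag] = stats.truncnorm.rvs(
            a_trunc, np.inf, loc=mu_u, scale=sd_u, size=undiag.sum(), random_state=rng
        )

    df["self_reported_diabetes"] = diagnosed
    df["diabetes_medication"] = diagnosed & (rng.random(n) < 0.79)
    df["insulin"] = diagnosed & (rng.random(n) < config.insulin_frac_diagnosed)
    diag_age = age - rng.exponential(6.0, n)
    early = diagnosed & (rng.random(n) < config.early_diagnosis_frac)
    diag_age[early] = rng.uniform(15, 34.9, early.sum())
    df["insulin"] |= early  # early-onset insulin users: the likely-T1D pool
    df["diabetes_diagnosis_age"] = np.where(diagnosed, np.clip(diag_age, 10, None), np.nan)
    df["hba1c"] = hba1c
    if config.hba1c_missing_rate > 0:
        miss = (rng.random(n) < config.hba1c_missing_rate) & ~diagnosed
        df.loc[miss, "hba1c"] = np.nan

    df["genetic_qc_fail"] = rng.random(n) < config.genetic_qc_fail_rate
    df["relatedness"] = "unrelated"
    df["liability"] = liability
    df["t2d_true"] = t2d
    df["grs_true"] = grs_true

    if config.compute_pcs and panel.n_snps > config.n_pcs:
        from sklearn.decomposition import TruncatedSVD

        x = genotypes.dosages.to_numpy(copy=True)
        col_mean = np.nanmean(x, axis=0)
        inds = np.where(np.isnan(x))
        x[inds] = np.take(col_mean, inds[1])
        x -= x.mean(axis=0)
        svd = TruncatedSVD(n_components=config.n_pcs, random_state=config.seed % (2**31))
        pcs = svd.fit_transform(x)
        for k in range(config.n_pcs):
            df[f"pc{k + 1}"] = pcs[:, k]
    else:
        for k in range(config.n_pcs):
            df[f"pc{k + 1}"] = 0.0
    return df


def simulate_mortality(records: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw cause-specific survival under constant (or Weibull) hazards.

    Each cause contributes an independent event time with log-hazard
    ``log(base_rate) + T2D * log_rr + covariate terms``; the earliest event
    before administrative censoring wins. Among deaths of T2D carriers (other
    than acute diabetic crises) a configurable fraction has the raw underlying
    cause miscoded as non-acute diabetes with the true cause retained on the
    certificate's secondary-cause list.
    """
    if not config.cause_hazards:
        raise SimulationError("cause_hazards must be non-empty")
    config.validate()
    rng = config.rng(_OP_MORT)
    n = len(records)
    causes = list(config.cause_hazards)
    t2d = records["t2d_true"].to_numpy(bool)

    cov_lp = np.zeros(n)
    for key, effect in config.confounder_effects.items():
        cov_lp += effect.log_hazard * _resolve_covariate(records, key)

    times = np.full((n, len(causes)), np.inf)
    for j, cause in enumerate(causes):
        ch = config.cause_hazards[cause]
        if ch.base_rate == 0:
            continue
        rate = ch.base_rate * np.exp(ch.log_rr * t2d + cov_lp)
        e = rng.exponential(1.0, n)
        if config.weibull_shape == 1.0:
            times[:, j] = e / rate
        else:
            times[:, j] = (e / rate) ** (1.0 / config.weibull_shape)

    t_min = times.min(axis=1)
    died = t_min < config.admin_censor_years
    follow = np.where(died, t_min, config.admin_censor_years)
    cause_idx = times.argmin(axis=1)
    true_cause = np.where(died, np.array(causes, dtype=object)[cause_idx], None)

    # custom cause labels fall back to an unspecific medical code
    raw_code = np.array(
        [CAUSE_ICD10.get(c, "K85.9") if c is not None else "" for c in true_cause],
        dtype=object,
    )
    secondary = np.array([""] * n, dtype=object)
    miscode = (
        died & t2d
        & (true_cause != "acute_diabetic_crisis")
        & (rng.random(n) < config.diabetes_miscode_frac)
    )
    secondary[miscode] = raw_code[miscode]
    raw_code[miscode] = DIABETES_NON_ACUTE_CODE

    entry = records["age"].to_numpy(float)
    out = pd.DataFrame(
        {
            "entry_age": entry,
            "exit_age": entry + follow,
            "died": died,
            "underlying_cause_icd10": raw_code,
            "secondary_causes": secondary,
            "true_cause_group": [c if c is not None else "" for c in true_cause],
        },
        index=records.index,
    )
    return out


def simulate_gwas_weights(panel: TruePanel, config: SimulationConfig) -> pd.DataFrame:
    """Emulate an external GWAS weight file for the panel.

    True per-allele log-odds weights are the liability effects mapped through
    a logistic scale factor; Gaussian noise with SE chosen from
    ``weight_true_corr`` (corr = sd / sqrt(sd^2 + se^2)) emulates external
    estimation error, so the correlation between in-cohort per-allele
    estimates and the weight file can be tuned toward the ~0.5 seen when
    external multi-ancestry weights meet an admixed target cohort.
    """
    if panel.n_snps == 0:
        raise SimulationError("panel is empty")
    rng = config.rng(_OP_WEIGHTS)
    kappa = config.liability_logodds_scale
    true_w = panel.effects * kappa / panel.liability_sd
    sd = true_w.std()
    rho = config.weight_true_corr
    if rho >= 1 or sd == 0:
        se = 0.0
    else:
        se = sd * np.sqrt(1.0 / rho**2 - 1.0)
    noise = rng.normal(0.0, 1.0, panel.n_snps) * se
    tbl = panel.table
    return pd.DataFrame(
        {
            "chrom": tbl["chrom"].to_numpy(),
            "pos": tbl["pos"].to_numpy(),
            "effect_allele": tbl["effect_allele"].to_numpy(),
            "other_allele": tbl["other_allele"].to_numpy(),
            "weight": true_w + noise,
            "weight_se": se if np.ndim(se) else np.full(panel.n_snps, se),
            "pathway": tbl["pathway"].to_numpy(),
        },
        index=tbl.index.copy(),
    )


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    panel: TruePanel
    genotypes: GenotypeData
    participants: pd.DataFrame
    followup: pd.DataFrame
    weights: pd.DataFrame

    def truth(self) -> dict:
        return {
            "seed": self.config.seed,
            "liability_sd": self.panel.liability_sd,
            "grs_liability_r2": self.config.grs_liability_r2,
            "target_prevalence": self.config.target_prevalence,
            "true_effects": self.panel.table["effect"].to_dict(),
            "cause_log_rr": {c: h.log_rr for c, h in self.config.cause_hazards.items()},
        }


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run every generator stage in order with the config's seed."""
    panel = simulate_panel(config)
    genotypes = simulate_genotypes(panel, config)
    participants = simulate_phenotypes(genotypes, panel, config)
    followup = simulate_mortality(participants, config)
    weights = simulate_gwas_weights(panel, config)
    return SyntheticCohort(config, panel, genotypes, participants, followup, weights)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the interchange files: phenotype CSV, follow-up CSV, dosage TSV
    ("NA" for missing), variants TSV, weights TSV and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.csv",
        "followup": outdir / "followup.csv",
        "dosages": outdir / "dosages.tsv",
        "variants": outdir / "variants.tsv",
        "weights": outdir / "weights.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.participants.to_csv(paths["phenotypes"])
    cohort.followup.to_csv(paths["followup"])
    cohort.genotypes.dosages.to_csv(paths["dosages"], sep="\t", na_rep="NA")
    cohort.genotypes.variants.to_csv(paths["variants"], sep="\t")
    cohort.weights.to_csv(paths["weights"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth(), fh, indent=1, default=float)
    return paths
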