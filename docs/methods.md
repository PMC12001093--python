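# Methods

## The analysis model

The package implements one-sample Mendelian randomisation of genetically
predicted type 2 diabetes (T2D) liability against cause-specific mortality
in a prospective cohort, together with the conventional observational
contrast, on a common code path.

**Exposure side.** T2D at recruitment is classified as previously diagnosed
(self-reported doctor diagnosis or diabetes medication), undiagnosed
(HbA1c ≥ 6.5% without a prior diagnosis), likely type 1 diabetes (diagnosis
before age 35 while on insulin; excluded), or none. The instrument is a
genetic risk score (GRS): the sum over harmonised variants of effect-allele
dosage times the external per-allele log odds ratio for T2D. The
GRS→T2D association is a maximum-likelihood logistic fit adjusted for age,
sex and the leading genetic principal components, reported per GRS unit
(raw log-odds scale) and per sample SD for display. The share of liability
the instrument explains is summarised by Nagelkerke's pseudo-R²,
`[1 − exp(2(ll₀ − ll₁)/n)] / [1 − exp(2 ll₀/n)]`, of the GRS + covariate
model against the covariate-only null.

**Outcome side.** Follow-up is expanded into Lexis episodes on a 5-year
attained-age grid (default 35–75, extendable to 85). Each episode enters a
Cox partial likelihood on the time-since-entry scale as a left-truncated
interval, stratified by age band × sex, adjusted for the principal
components; deaths from other causes are censored, giving cause-specific
hazards. The log hazard ratio is read as an average causal log mortality
rate ratio over follow-up, so no proportionality test gates the pipeline.

**The ratio.** β_MR = β_GRS→death / β_GRS→T2D is the log mortality rate
ratio per unit increase in genetically predicted log-odds of T2D. Its SE
defaults to the "simple" method (numerator SE divided by |β_GRS→T2D|),
which treats the denominator as fixed — justified when the instrument is
strong (the per-allele z of the denominator is checked and a weak-instrument
warning attaches below z = 10); a two-term delta method is available by
flag. Estimates are re-expressed per k-fold increase in predicted odds by
multiplying estimate and SE by ln k (default k = 3); rescaling is an exact
group action, so confidence limits transform with the point estimate.

**Subgroups, pathways, observational contrast.** Subgroup analyses refit
the numerator per stratum but keep the overall denominator (stratum-specific
denominators would be noisy); heterogeneity is summarised by Cochran's Q.
Pathway GRSs are analysed as instruments in their own right (own
denominator, own numerator), with a small-instrument warning below 5
variants. The observational analysis is a Cox contrast of T2D status
(diagnosed + undiagnosed) adjusted for district, education, smoking,
alcohol, and height/weight/waist/hip in quarters, on a cohort that
additionally excludes prior chronic disease. Genetic (per k-fold of
predicted odds) and observational (per T2D status) effects live on
different scales and are reported side by side, never converted.

**Sensitivity suite.** On per-variant summary statistics: IVW (weighted
regression through the origin, weights 1/se_out²; random-effects SE
inflation max(1, √(Q/(n−1)))), MR-Egger (same regression with a free
intercept after orienting exposure betas positive; the intercept estimates
directional pleiotropy), the weighted median (weight-interpolated 50th
percentile of per-variant Wald ratios, delta-method ratio weights,
parametric-bootstrap SE), and MR-PRESSO (leave-one-out residual sum of
squares against a parametric simulated null; per-variant outlier tests with
Bonferroni correction; distortion test comparing full and outlier-corrected
IVW slopes against a null built by removing random inlier subsets).
Empirical p-values are plain exceedance fractions, as in the published
implementation, so an extreme observed statistic can reach p = 0 at finite
n_sim. All stochastic pieces are seeded and bit-reproducible.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
defaults chosen to mirror a large urban Mexican cohort:

- **Panel.** n_snps variants with two source-population frequencies
  (correlated draws within the configured MAF range), a configurable
  palindromic fraction (default 0.157), and pathway labels partitioning the
  causal variants into up to 8 groups.
- **Admixture.** Per-individual ancestry fraction a ~ Beta(6.7, 3.3)
  (mean 0.67); each dosage is two allele draws at the mixed frequency
  a·f₁ + (1−a)·f₂. Dosage variance is therefore
  2f̄(1−f̄) + 2(f₁−f₂)²Var(a), which the effect-scaling uses analytically.
- **Liability.** liability = true-weighted score + confounder terms +
  N(0,1). True effects are rescaled so the score's share of liability
  variance equals `grs_liability_r2` (default 0.06) exactly in expectation;
  the disease threshold is the empirical liability quantile matching
  `target_prevalence` (default 0.18), which keeps prevalence calibrated
  under any confounder configuration.
- **Phenotypes.** Covariates (sex 68% female, age uniform 35–74, district,
  education, smoking, alcohol, physical activity, sex-specific
  anthropometry) are drawn independently of genotype. Among T2D carriers a
  fraction (default 0.72) is previously diagnosed with HbA1c ~ N(9.1, 2.5);
  the remainder draw HbA1c from a left-truncated normal above the 6.5%
  diagnostic threshold (default mean 7.5, SD 1.5 — a free configuration
  choice, since the undiagnosed distribution is not pinned down by data we
  hold). Non-diabetic HbA1c is N(5.5, 0.4), so ~0.6% of non-carriers exceed
  6.5% and are classified as undiagnosed T2D: a small, realistic
  misclassification the recovery suites absorb. Principal components are
  computed from the centred, mean-imputed dosage matrix by truncated SVD
  (top 7), exercising the same adjustment pathway as a real analysis.
- **Mortality.** Independent exponential cause-specific event times with
  log-hazard = log(base rate) + θ_cause·T2D + covariate terms; earliest
  event before 20-year administrative censoring wins (a Weibull shape hook
  exists; exponential keeps the test oracles closed-form). Default baseline
  rates give roughly 10% 20-year mortality with a vascular/infectious/
  renal/neoplastic-dominated cause mix; default θ values plant strong renal
  and acute-diabetic effects, moderate vascular/infectious effects, and
  none on cancer, cirrhosis, COPD or external causes. Among deaths of T2D
  carriers (outside acute diabetic crises) a fraction (default 0.25) has
  the raw underlying cause miscoded to non-acute diabetes with the true
  cause retained as a secondary code, exercising downstream re-attribution.
- **External weights.** True per-allele log-odds weights are the liability
  effects mapped through a logistic scale factor (1.7) and the liability
  SD; Gaussian noise with SE set from a target true-weight correlation
  (default 0.5) emulates external estimation error of the kind seen when
  multi-ancestry weights meet an admixed target cohort.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent), imputation quality, family relatedness (a relatedness
column is emitted but constant), time-varying hazards beyond the Weibull
hook, and registry-linkage error. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated
assumptions, not that those assumptions hold in any particular real cohort.

## The generative mapping for parameter recovery

The generator places the causal effect on T2D **status** (hazard multiplied
by e^θ for carriers) while the MR estimand is per unit of genetically
predicted log-odds of T2D — a deliberate mismatch that mirrors the
binary-exposure problem in real analyses. The ratio's probability limit
under the recovery design is the same for any valid instrument built on the
liability score (attenuation from noisy weights cancels between numerator
and denominator), so it was computed once by running the identical logistic
and stratified-Cox fitting code on eight pooled batches of 250,000
individuals with the true-weighted score: per unit log-odds, 0.0572 for
θ = ln 1.5 and 0.1118 for θ = ln 2 (`mrmort.calibration.PLIM_PER_UNIT`);
exactly 0 for θ = 0. Monte-Carlo error of these
constants is ~0.006 per unit, an order of magnitude below the per-replicate
CI half-width at n = 20,000, so it does not materially affect coverage
checks. Coverage is assessed over 200 full-pipeline replicates at
n = 20,000 with 200 variants — sizes chosen so the whole suite runs on one
CPU in minutes while the instrument stays strong (denominator z ≈ 10–12).

The confounding contrast plants a lifestyle covariate (physical inactivity)
with per-SD effects of 0.6 on both liability and log-hazard, and causal
effect off. The covariate is deliberately outside the observational
adjustment set, emulating unmeasured confounding: the observational
per-T2D-status RR is biased upward while the genetic estimate, whose
instrument is independent of the covariate by construction, stays
calibrated around the null.

## Numerical choices

- Cox ties: Efron's method (the lifelines default). Event times are
  continuous in the generator, so ties are measure-zero; the choice matters
  only for coarse real data.
- Strata with zero events are dropped with a warning (they contribute no
  partial-likelihood information); multi-column strata are factorised into
  a single key before fitting.
- Logistic fits: Newton ML with a 100-iteration cap; non-convergence and
  perfect separation surface as `SeparationError` with the estimate
  withheld.
- Missing dosages are mean-imputed at twice the effect-allele frequency
  among non-missing individuals (unbiased under missingness at random);
  fully missing variants are dropped with a warning.
- "Ambiguous" variants are palindromic (A/T, C/G) pairs, dropped rather
  than frequency-resolved — the safe default when strand provenance is
  unknown.
- Quantile bins break ties by stable input order, so bin sizes differ by at
  most one even for constant scores.
- "Missing or extreme" covariates are screened by explicit plausibility
  windows (height 100–220 cm, weight 25–250 kg, waist/hip 40–200 cm, HbA1c
  3–20%); the windows are configuration, not doctrine.
- The ICD-10 → cause-group table ships as an editable default following WHO
  chapter conventions; it is **non-canonical** — any given study's appendix
  code lists should replace it. Diabetes codes (E10–E14) with fourth
  character 0 or 1 count as acute crises; other diabetes-coded deaths are
  re-attributed to the highest-priority secondary cause (default priority
  renal > cardiac > stroke > other vascular > infection > …).
- Exclusions are applied in the stated order with each individual counted
  once under the first matching reason; the ledger identity
  input = remaining + Σ excluded is enforced by construction.
- Egger's null-calibration harness evaluates the fixed-effect intercept SE
  because the simulated null carries exactly the stated outcome noise; the
  random-effects default can only over-cover there.

## Known limitations

- The observational and genetic effect scales are intentionally
  incomparable; the package never converts between them.
- The per-allele mortality scan used to assemble two-sample summary rows in
  the end-to-end pipeline uses covariate-adjusted logistic fits on the
  death indicator rather than per-variant Cox fits — adequate for the
  rare-outcome, common-follow-up regime it is used in, and orders of
  magnitude faster.
- MR-PRESSO's distortion test follows the published bootstrap of inlier
  subsets; with very few variants its null distribution is coarse.
- The weighted median's breakdown point (50% of weight) is demonstrated,
  not proven, in the tests.
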