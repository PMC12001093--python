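"""Large-n oracle: probability limit of the one-sample MR ratio under the
generator's design (causal effect theta on T2D status; instrument = true
liability score).

Runs the same fitting code as the analysis (logistic denominator, age-band x
sex stratified Cox numerator on Lexis episodes) on batches of 250k
individuals and pools the per-unit ratio across batches. The pooled values
are frozen in mrmort.calibration.PLIM_PER_UNIT as the generative mapping.
"""
import numpy as np
import pandas as pd

from mrmort.simulate import (CauseHazard, SimulationConfig, simulate_genotypes,
                             simulate_panel)
from mrmort.survival import fit_logistic, fit_stratified_cox, lexis_expand
from mrmort.onesample import wald_ratio

BATCH = 250_000
N_BATCH = 8


def one_batch(theta: float, seed: int) -> tuple[float, float, float, float]:
    cfg = SimulationConfig(
        n_individuals=BATCH, n_snps=200, seed=seed, compute_pcs=False,
        missing_dosage_rate=0.0, genetic_qc_fail_rate=0.0,
        hba1c_missing_rate=0.0,
        cause_hazards={"all": CauseHazard(5.0e-3, theta)},
    )
    panel = simulate_panel(cfg)
    geno = simulate_genotypes(panel, cfg)
    rng = cfg.rng(99)
    # liability pieces, same construction as simulate_phenotypes
    counted_is_eff = (geno.variants["counted_allele"].to_numpy()
                      == panel.table["effect_allele"].to_numpy())
    d_eff = np.where(counted_is_eff[None, :], geno.complete, 2.0 - geno.complete)
    g = d_eff @ panel.effects
    liab = g + rng.normal(0, 1, BATCH)
    thr = np.quantile(liab, 1 - cfg.target_prevalence)
    d = liab > thr
    age = rng.uniform(35, 74, BATCH)
    sex = np.where(rng.random(BATCH) < 0.68, "F", "M")

    rate = 5.0e-3 * np.exp(theta * d)
    t = rng.exponential(1.0 / rate)
    died = t < cfg.admin_censor_years
    exit_age = age + np.minimum(t, cfg.admin_censor_years)

    idx = pd.RangeIndex(BATCH)
    covs = pd.DataFrame({"age": age, "sex_f": (sex == "F").astype(float)}, index=idx)
    lg = fit_logistic(pd.Series(d.astype(float), index=idx),
                      pd.Series(g, index=idx), covs)
    eps = lexis_expand(age, exit_age, died, ids=idx)
    eps = eps.join(pd.DataFrame({"g": g, "sex": sex}, index=idx), on="iid")
    cx = fit_stratified_cox(eps, "g", strata=["band_lo", "sex"])
    return cx.beta, cx.se, lg.beta, lg.se


for theta, name in [(np.log(1.5), "ln1.5"), (np.log(2.0), "ln2")]:
    nums, dens = [], []
    for b in range(N_BATCH):
        bo, so, be, se = one_batch(theta, seed=1000 + b)
        nums.append((bo, so)); dens.append((be, se))
        print(f"theta={name} batch={b} cox={bo:.5f}({so:.5f}) logit={be:.5f}({se:.5f})",
              flush=True)
    wn = np.array([1 / s**2 for _, s in nums]); bn = np.array([b for b, _ in nums])
    wd = np.array([1 / s**2 for _, s in dens]); bd = np.array([b for b, _ in dens])
    num = float(np.sum(wn * bn) / np.sum(wn)); den = float(np.sum(wd * bd) / np.sum(wd))
    ratio = num / den
    se_ratio = float(np.sqrt(1 / np.sum(wn)) / abs(den))
    print(f"POOLED theta={name}: num={num:.6f} den={den:.6f} "
          f"ratio_per_unit={ratio:.6f} (mc se {se_ratio:.6f}) "
          f"per_trebling={ratio * np.log(3):.6f}", flush=True)
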