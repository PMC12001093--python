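"""File formats, pipeline configuration and the end-to-end run.

TSV is the canonical interchange format (desk-scale, diffable); VCF import
(dosage ``DS`` field) is a convenience. Every reader/writer pair round-trips
losslessly on valid data, and a pipeline run writes a manifest (package
version, seeds, config hash) sufficient to reproduce it byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger("mrmort")

WEIGHT_COLUMNS = ("effect_allele", "other_allele", "weight")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# weights


def read_weights(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated weight file (rsid-indexed; requires
    effect_allele, other_allele and numeric weight columns; optional chrom,
    pos, weight_se, pathway). Duplicate rsids are rejected."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "rsid" not in df.columns:
        raise ParseError(f"{path}: missing 'rsid' column")
    for col in WEIGHT_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    dup = df["rsid"][df["rsid"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated rsid(s): {sorted(set(dup))[:5]}")
    for i, row in df.iterrows():
        for col in ("effect_allele", "other_allele"):
            if row[col] not in set("ACGT"):
                raise ParseError(
                    f"{path}, line {i + 2}: malformed allele {row[col]!r}")
        try:
            float(row["weight"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}, line {i + 2}: non-numeric weight {row['weight']!r}")
    df = df.set_index("rsid")
    df["weight"] = df["weight"].astype(float)
    for col in ("pos", "weight_se"):
        if col in df:
            df[col] = pd.to_numeric(df[col])
    return df


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, sep="\t", index_label="rsid")


# ---------------------------------------------------------------------------
# dosages


def read_dosages(path: str | Path, fmt: str = "tsv"):
    """Read a dosage matrix.

    ``tsv``: individuals as rows, SNPs as columns, "NA" for missing; returns
    a DataFrame. ``vcf``: reads the DS FORMAT field; returns
    ``(dosages, variants)`` where variants carries the counted (ALT) and
    other (REF) alleles.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        if df.shape[1] == 0 or df.shape[0] == 0:
            raise ParseError(f"{path}: empty dosage matrix")
        arr = df.to_numpy(float)
        bad = np.argwhere((arr < 0) | (arr > 2))
        if len(bad):
            i, j = bad[0]
            raise ParseError(
                f"{path}: dosage out of [0,2] at individual "
                f"{df.index[i]!r}, SNP {df.columns[j]!r}: {arr[i, j]}")
        return df
    if fmt == "vcf":
        return _read_vcf_dosages(path)
    raise ValueError("fmt must be 'tsv' or 'vcf'")


def _read_vcf_dosages(path: str | Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: no samples in VCF")
    cols, rows = [], []
    var_rows = []
    for v in vcf:
        rsid = v.ID or f"{v.CHROM}:{v.POS}"
        ds = v.format("DS")
        if ds is None:
            raise ParseError(f"{path}: record {rsid} lacks a DS field")
        vals = np.asarray(ds, float).reshape(-1)
        if np.any((vals < 0) | (vals > 2)):
            raise ParseError(f"{path}: dosage out of [0,2] at {rsid}")
        cols.append(rsid)
        rows.append(vals)
        var_rows.append({"rsid": rsid, "chrom": v.CHROM, "pos": v.POS,
                         "counted_allele": v.ALT[0], "other_allele": v.REF})
    if not cols:
        raise ParseError(f"{path}: empty VCF")
    dosages = pd.DataFrame(np.column_stack(rows),
                           index=pd.Index(samples, name="iid"), columns=cols)
    variants = pd.DataFrame(var_rows).set_index("rsid")
    return dosages, variants


def write_dosages(dosages: pd.DataFrame, path: str | Path) -> None:
    dosages.to_csv(path, sep="\t", na_rep="NA")


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="rsid", dtype=str)
    for col in ("counted_allele", "other_allele"):
        if col not in df:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_followup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, keep_default_na=False,
                     na_values=[""], dtype={"secondary_causes": str})
    df["died"] = df["died"].astype(bool)
    for col in ("underlying_cause_icd10", "secondary_causes"):
        if col in df:
            df[col] = df[col].fillna("")
    return df


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """End-to-end run configuration; mirrors the CLI flags."""

    outdir: str = "mrmort_out"
    seed: int = 0
    # either simulate a cohort ...
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # ... or point at existing files
    weights_path: str | None = None
    dosages_path: str | None = None
    variants_path: str | None = None
    phenotypes_path: str | None = None
    followup_path: str | None = None
    # analysis settings
    base_k: float = 3.0
    se_method: str = "simple"
    age_window: tuple[float, float] = (35.0, 75.0)
    causes: tuple[str, ...] = ("all_cause", "vascular", "renal", "infection",
                               "cancer")
    subgroup_variables: tuple[str, ...] = ("sex",)
    n_boot: int = 500
    n_sim_presso: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if sim_raw:
            cfg.sim = SimulationConfig(**sim_raw)
        cfg.sim.seed = cfg.seed if "seed" not in sim_raw else cfg.sim.seed
        if isinstance(cfg.age_window, list):
            cfg.age_window = tuple(cfg.age_window)
        if isinstance(cfg.causes, list):
            cfg.causes = tuple(cfg.causes)
        if isinstance(cfg.subgroup_variables, list):
            cfg.subgroup_variables = tuple(cfg.subgroup_variables)
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for name in ("weights_path", "dosages_path", "variants_path",
                         "phenotypes_path", "followup_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} missing or not found: {p}")
        lo, hi = self.age_window
        if lo % 5 or hi % 5:
            raise ValueError("age window bounds must sit on the 5-year grid")
        self.sim.validate()

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _band_grid(window: tuple[float, float]) -> tuple[float, ...]:
    lo, hi = window
    return tuple(float(a) for a in np.arange(lo, hi + 5, 5))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate (optional) -> score -> assemble -> fit -> mr ->
    sensitivity, writing result tables and a reproducibility manifest.

    Returns a dict of output paths plus the in-memory results. A stage
    failure raises with the stage name attached.
    """
    from .cohort import apply_exclusions, classify_diabetes, reattribute_cause
    from .grs import compute_grs, harmonize, oriented_dosages, pathway_scores
    from .onesample import ObservationalMortality, OneSampleMR
    from .summary import SummaryMR
    from .survival import nagelkerke_r2, per_allele_scan

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "init"
    try:
        # -- inputs --------------------------------------------------------
        if config.simulate:
            stage = "simulate"
            cohort = simulate_cohort(config.sim)
            write_cohort(cohort, outdir / "synthetic")
            weights = cohort.weights.copy()
            dosages = cohort.genotypes.dosages
            variants = cohort.genotypes.variants
            phenotypes = cohort.participants
            followup = cohort.followup
        else:
            stage = "load"
            weights = read_weights(config.weights_path)
            dosages = read_dosages(config.dosages_path)
            variants = read_variants(config.variants_path)
            phenotypes = read_phenotypes(config.phenotypes_path)
            followup = read_followup(config.followup_path)
        logger.info("stage=%s n_individuals=%d n_snps=%d", stage,
                    len(phenotypes), len(weights))

        # -- score -----------------------------------------------------------
        stage = "score"
        aligned, report = harmonize(weights, variants)
        grs = compute_grs(dosages, aligned)
        pscores = pathway_scores(dosages, aligned) if "pathway" in aligned else {}
        logger.info("stage=score scored=%d ambiguous=%d unavailable=%d",
                    report.n_scored, report.n_ambiguous, report.n_unavailable)

        # -- assemble ----------------------------------------------------------
        stage = "assemble"
        data = phenotypes.join(followup)
        data["diabetes_class"] = classify_diabetes(data)
        data["cause_group"] = reattribute_cause(data)
        data["grs"] = grs.score
        genetic, ledger_gen = apply_exclusions(
            data, "genetic", age_ceiling=config.age_window[1])
        observational, ledger_obs = apply_exclusions(
            data, "observational", age_ceiling=config.age_window[1])
        logger.info("stage=assemble genetic=%d observational=%d",
                    len(genetic), len(observational))

        # -- fit ---------------------------------------------------------------
        stage = "fit"
        band_grid = _band_grid(config.age_window)
        model = OneSampleMR(genetic, base_k=config.base_k,
                            se_method=config.se_method, band_grid=band_grid)
        exposure_fit = model.fit_exposure()
        # share of liability the instrument explains: GRS+covariate model
        # against the covariate-only null
        import statsmodels.api as sm
        y = model.t2d.to_numpy(float)
        covs = pd.DataFrame({
            "const": 1.0,
            "age": genetic["age"].to_numpy(float),
            "sex_f": (genetic["sex"] == "F").to_numpy(float),
        }, index=genetic.index)
        for c in model.pc_cols:
            covs[c] = genetic[c]
        ll_null = float(sm.Logit(y, covs).fit(disp=0).llf)
        r2 = nagelkerke_r2(exposure_fit.loglik, ll_null, len(genetic))

        # -- mr ----------------------------------------------------------------
        stage = "mr"
        results = model.fit(causes=config.causes)
        obs_table = ObservationalMortality(observational, band_grid).fit(
            causes=config.causes)
        subgroups = {}
        for var in config.subgroup_variables:
            tbl, het = model.fit_subgroups(var)
            subgroups[var] = {"table": tbl, "heterogeneity": het}
        pathway_tbl = None
        if pscores:
            pathway_tbl, _ = model.fit_pathways(
                {k: v.score for k, v in pscores.items()},
                snp_counts={k: v.n_snps for k, v in pscores.items()})

        # -- sensitivity -------------------------------------------------------
        stage = "sensitivity"
        oriented = oriented_dosages(dosages, aligned).loc[genetic.index]
        scan_covs = pd.DataFrame({
            "age": genetic["age"].to_numpy(float),
            "sex_f": (genetic["sex"] == "F").to_numpy(float),
        }, index=genetic.index)
        scan, corr = per_allele_scan(
            oriented, model.t2d.astype(float), covariates=scan_covs,
            external_weights=aligned["weight"])
        # outcome side: per-allele association with all-cause death
        death_scan, _ = per_allele_scan(
            oriented, genetic["died"].astype(float), covariates=scan_covs)
        ok = death_scan["status"] == "ok"
        summary_rows = pd.DataFrame({
            "beta_exposure": aligned.loc[ok[ok].index, "weight"],
            "se_exposure": aligned.loc[ok[ok].index, "weight_se"]
            if "weight_se" in aligned else 0.05,
            "beta_outcome": death_scan.loc[ok, "beta"],
            "se_outcome": death_scan.loc[ok, "se"],
        }).dropna()
        sens = SummaryMR(summary_rows).fit_all(
            seed=config.seed, n_boot=config.n_boot, n_sim=config.n_sim_presso)

        # -- outputs -----------------------------------------------------------
        stage = "write"
        results.estimates.to_csv(outdir / "mr_estimates.tsv", sep="\t")
        obs_table.to_csv(outdir / "observational_estimates.tsv", sep="\t")
        if pathway_tbl is not None:
            pathway_tbl.to_csv(outdir / "pathway_estimates.tsv", sep="\t")
        for var, sub in subgroups.items():
            sub["table"].to_csv(outdir / f"subgroup_{var}.tsv", sep="\t")
        with open(outdir / "harmonization.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        with open(outdir / "ledgers.json", "w") as fh:
            json.dump({"genetic": ledger_gen.to_dict(),
                       "observational": ledger_obs.to_dict()}, fh, indent=1)
        sens_out = {
            "ivw": dataclasses.asdict(sens["ivw"]),
            "egger": dataclasses.asdict(sens["egger"]),
            "weighted_median": dataclasses.asdict(sens["weighted_median"]),
            "presso": {
                "global_pvalue": sens["presso"].global_pvalue,
                "outliers": list(map(str, sens["presso"].outliers)),
                "distortion_pvalue": sens["presso"].distortion_pvalue,
            },
            "per_allele_weight_correlation": corr,
            "nagelkerke_r2": r2,
        }
        with open(outdir / "sensitivity.json", "w") as fh:
            json.dump(sens_out, fh, indent=1, default=float)
        manifest = {
            "package": "mrmort",
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "config": dataclasses.asdict(config),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {
        "outdir": outdir,
        "mr": results,
        "observational": obs_table,
        "subgroups": subgroups,
        "pathways": pathway_tbl,
        "sensitivity": sens,
        "harmonization": report,
        "ledgers": {"genetic": ledger_gen, "observational": ledger_obs},
        "nagelkerke_r2": r2,
        "per_allele_weight_correlation": corr,
        "manifest": manifest,
    }
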