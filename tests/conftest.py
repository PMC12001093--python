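import numpy as np
import pandas as pd
import pytest

from mrmort.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_individuals=3000, n_snps=60, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def assembled(small_cohort):
    """Small analysis-ready cohort: phenotypes + follow-up + classification +
    cause groups + GRS."""
    from mrmort.cohort import classify_diabetes, reattribute_cause
    from mrmort.grs import compute_grs, harmonize

    c = small_cohort
    data = c.participants.join(c.followup)
    data["diabetes_class"] = classify_diabetes(data)
    data["cause_group"] = reattribute_cause(data)
    aligned, report = harmonize(c.weights, c.genotypes.variants)
    grs = compute_grs(c.genotypes.dosages, aligned)
    data["grs"] = grs.score
    return data


def make_weights(rsids, effect, other, weight, pathway=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {"effect_allele": effect, "other_allele": other, "weight": weight},
        index=pd.Index(rsids, name="rsid"),
    )
    if pathway is not None:
        df["pathway"] = pathway
    return df


def make_variants(rsids, counted, other) -> pd.DataFrame:
    return pd.DataFrame(
        {"counted_allele": counted, "other_allele": other},
        index=pd.Index(rsids, name="rsid"),
    )
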