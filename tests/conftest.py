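import numpy as np
import pandas as pd
import pytest

from aneurysmo_mr.config import CisLayout, CovariateEffects, SimConfig
from aneurysmo_mr.simulate import simulate_cohort, simulate_two_sample_sumstats
from aneurysmo_mr.sumstats import MultiTraitSumstats


def make_ms(variant_ids, chrom="1", pos=None, effect_allele="A",
            other_allele="C", eaf=0.3, **traits) -> MultiTraitSumstats:
    """Hand-build a small multi-trait table; traits given as
    name=(beta, se) or name=(beta, se, pvalue) arrays."""
    n = len(variant_ids)
    df = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": [chrom] * n if isinstance(chrom, str) else chrom,
        "pos": pos if pos is not None else np.arange(1, n + 1) * 1000,
        "effect_allele": [effect_allele] * n
        if isinstance(effect_allele, str) else effect_allele,
        "other_allele": [other_allele] * n
        if isinstance(other_allele, str) else other_allele,
        "eaf": [eaf] * n if np.isscalar(eaf) else eaf,
    })
    for t, vals in traits.items():
        df[f"beta_{t}"] = np.asarray(vals[0], dtype=float)
        df[f"se_{t}"] = np.asarray(vals[1], dtype=float)
        df[f"pvalue_{t}"] = (np.asarray(vals[2], dtype=float)
                             if len(vals) > 2 else 0.5)
    return MultiTraitSumstats(df, validate=False)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_individuals=3000, m_variants=300,
                     cis=CisLayout(variants_per_gene=6, lpa_variants=8))


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_sumstats(small_config):
    return simulate_two_sample_sumstats(small_config)


@pytest.fixture(scope="session")
def null_config() -> SimConfig:
    """No causal effect, no covariate effects on the outcome."""
    return SimConfig(seed=11, n_individuals=6000, m_variants=200,
                     causal_logor_ldl=0.0, causal_logor_trl=0.0,
                     covariate_effects=CovariateEffects(
                         age_outcome=0.0, sex_outcome=0.0),
                     cis=CisLayout(variants_per_gene=0, lpa_variants=0))
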