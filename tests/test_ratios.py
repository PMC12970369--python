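"""Ratio statistics: delta-method CIs against Monte-Carlo oracles,
variant-set MR behaviour under generator truth, drug-target framing and
unit conversions."""

import math

import numpy as np
import pytest

from aneurysmo_mr.config import CisLayout, SimConfig
from aneurysmo_mr.instruments import InstrumentSet, partition_variant_sets
from aneurysmo_mr.mr import MREstimate, Z95, mvmr_ivw
from aneurysmo_mr.ratios import (MGDL_PER_MMOL, drug_target_mr,
                                 mgdl_mmol_convert, per_cholesterol_ratio,
                                 ratio_of_estimates,
                                 relative_aneurysmogenicity, variant_set_mr)
from aneurysmo_mr.simulate import simulate_two_sample_sumstats
from conftest import make_ms


def _est(beta, se, scale="per 10 mg/dL apoB"):
    return MREstimate(method="ivw_mre", beta=beta, se=se, scale=scale)


# ---------------------------------------------------------------------------
# relative aneurysmogenicity

def test_identical_inputs_give_ratio_one():
    r = relative_aneurysmogenicity(_est(0.3, 0.03), _est(0.3, 0.03))
    assert r.ratio == pytest.approx(1.0)
    assert r.ci_low < 1.0 < r.ci_high


def test_ratio_scale_invariance_exact():
    a, b = _est(0.4, 0.05), _est(0.1, 0.02)
    r1 = relative_aneurysmogenicity(a, b)
    r2 = relative_aneurysmogenicity(_est(0.4 * 7, 0.05 * 7),
                                    _est(0.1 * 7, 0.02 * 7))
    assert r2.ratio == r1.ratio
    assert r2.se == pytest.approx(r1.se)


def test_ratio_antisymmetric_under_swap():
    a, b = _est(0.5, 0.04), _est(0.2, 0.02)
    r_ab = relative_aneurysmogenicity(a, b)
    r_ba = relative_aneurysmogenicity(b, a)
    assert r_ab.ratio == pytest.approx(1.0 / r_ba.ratio)


def test_ratio_matches_monte_carlo_oracle_on_printed_ors():
    """Set-10 OR 1.89 (1.69-2.11) over set-1 OR 1.10 (1.05-1.14): the
    delta CI agrees with a 1e6-draw Monte-Carlo ratio distribution."""
    b_num = math.log(1.89)
    se_num = (math.log(2.11) - math.log(1.69)) / (2 * Z95)
    b_den = math.log(1.10)
    se_den = (math.log(1.14) - math.log(1.05)) / (2 * Z95)
    r = ratio_of_estimates(b_num, se_num, b_den, se_den)
    assert r.ratio == pytest.approx(6.68, abs=0.01)

    rng = np.random.default_rng(123)
    draws = rng.normal(b_num, se_num, 10 ** 6) / rng.normal(b_den, se_den,
                                                            10 ** 6)
    # point estimate agrees with the simulated distribution; the width
    # check is looser here because at a denominator z of ~4.5 the exact
    # ratio distribution is visibly right-skewed relative to the
    # symmetric first-order delta interval
    assert abs(np.median(draws) - r.ratio) < 0.05 * r.ratio
    mc_lo, mc_hi = np.percentile(draws, [2.5, 97.5])
    assert abs((mc_hi - mc_lo) - (r.ci_high - r.ci_low)) \
        < 0.20 * (mc_hi - mc_lo)


def test_delta_ci_close_to_mc_when_denominator_strong():
    """With a precisely estimated denominator (|beta_den| >= 10 se_den)
    the first-order delta CI width is within 5% of the Monte-Carlo
    width; weaker denominators inherit the ratio's skewness."""
    rng = np.random.default_rng(5)
    for bn, sn, bd, sd_ in [(0.6, 0.05, 0.2, 0.02), (0.3, 0.02, 0.3, 0.03),
                            (1.0, 0.1, 1.5, 0.1)]:
        assert abs(bd) >= 10 * sd_
        r = ratio_of_estimates(bn, sn, bd, sd_)
        draws = rng.normal(bn, sn, 10 ** 6) / rng.normal(bd, sd_, 10 ** 6)
        mc_lo, mc_hi = np.percentile(draws, [2.5, 97.5])
        assert abs((mc_hi - mc_lo) - (r.ci_high - r.ci_low)) \
            < 0.05 * (mc_hi - mc_lo)


def test_weak_denominator_flagged_unstable():
    with pytest.warns(UserWarning, match="unstable"):
        r = ratio_of_estimates(0.5, 0.05, 0.05, 0.04)
    assert r.unstable
    assert np.isfinite(r.ci_low) and np.isfinite(r.ci_high)


def test_mismatched_scales_rejected():
    with pytest.raises(ValueError, match="scales"):
        relative_aneurysmogenicity(_est(0.3, 0.03),
                                   _est(0.3, 0.03, scale="per 1 mmol/L"))


# ---------------------------------------------------------------------------
# per-cholesterol MVMR ratio

def test_per_cholesterol_equal_betas_ratio_one():
    est = [_est(0.2, 0.02, "per 10 mg/dL LDL-C"),
           _est(0.2, 0.05, "per 10 mg/dL TRL-C")]
    cov = np.array([[4e-4, 1e-4], [1e-4, 2.5e-3]])
    r = per_cholesterol_ratio(est, cov)
    assert r.ratio == pytest.approx(1.0)
    assert not r.independence_assumed


def test_per_cholesterol_zero_cov_reduces_to_independence_formula():
    est = [_est(0.15, 0.02), _est(0.45, 0.05)]
    cov0 = np.array([[4e-4, 0.0], [0.0, 2.5e-3]])
    r_joint = per_cholesterol_ratio(est, cov0)
    r_indep = ratio_of_estimates(0.45, 0.05, 0.15, 0.02)
    assert r_joint.ratio == r_indep.ratio
    assert r_joint.se == pytest.approx(r_indep.se, abs=1e-15)


def test_per_cholesterol_recovery_from_generator():
    """Planted per-cholesterol ratio recovered by MVMR over replicates."""
    reps = 60
    ratios = []
    for rep in range(reps):
        cfg = SimConfig(seed=900 + rep, m_variants=300,
                        cis=CisLayout(variants_per_gene=0, lpa_variants=0),
                        ld_rho=0.0)
        ms, truth = simulate_two_sample_sumstats(cfg)
        df = ms.df
        B = np.column_stack([df["beta_LDL_C"] / 10, df["beta_TRL_C"] / 10])
        est, cov = mvmr_ivw(B, df["beta_AAA"], df["se_AAA"])
        ratios.append(per_cholesterol_ratio(est, cov).ratio)
        truth_ratio = truth.per_cholesterol_ratio
    mc_se = np.std(ratios, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(ratios) - truth_ratio) < 3 * mc_se


# ---------------------------------------------------------------------------
# variant-set MR

def _partitioned(cfg):
    ms, truth = simulate_two_sample_sumstats(cfg)
    from aneurysmo_mr.sumstats import orient_to_raising_allele
    oms = orient_to_raising_allele(ms)
    import pandas as pd
    prov = pd.DataFrame({"variant_id": oms.df["variant_id"],
                         "retained": True})
    inst = InstrumentSet(sumstats=oms, provenance=prov)
    part = partition_variant_sets(inst, k=10)
    return oms, inst, part, truth


def test_variant_set_rescaling_is_exact_unit_arithmetic():
    cfg = SimConfig(seed=21, m_variants=200,
                    cis=CisLayout(variants_per_gene=0, lpa_variants=0),
                    ld_rho=0.0)
    ms, inst, part, _ = _partitioned(cfg)
    res = variant_set_mr(part, ms, sensitivity=False)
    df = ms.df.set_index("variant_id").loc[part.sets[0]]
    from aneurysmo_mr.mr import ivw
    per_1 = ivw(df["beta_APOB"], df["se_APOB"], df["beta_AAA"], df["se_AAA"])
    assert res[0]["ivw"].beta == pytest.approx(per_1.beta * 10, rel=1e-12)


def test_flat_truth_gives_flat_set_profile():
    """Equal per-apoB effects in both pathways: no trend of the set
    estimate on set index."""
    rng = np.random.default_rng(77)
    slopes = []
    for rep in range(40):
        cfg = SimConfig(seed=3000 + rep, m_variants=300,
                        causal_logor_ldl=0.3, causal_logor_trl=0.3,
                        cis=CisLayout(variants_per_gene=0, lpa_variants=0),
                        ld_rho=0.0)
        ms, inst, part, _ = _partitioned(cfg)
        res = variant_set_mr(part, ms, sensitivity=False)
        betas = np.array([r["ivw"].beta for r in res])
        x = np.arange(10.0)
        slopes.append(np.polyfit(x, betas, 1)[0])
    mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
    assert abs(np.mean(slopes)) < 3 * mc_se


def test_trl_heavier_sets_show_monotone_increase():
    """With the TRL pathway more aneurysmogenic, the set-wise log-OR
    rises with mean TRL share (positive rank correlation in >=95% of
    replicates; set 10 above set 1 in >=99%)."""
    from scipy.stats import spearmanr
    pos_rho = 0
    set10_gt_set1 = 0
    reps = 100
    for rep in range(reps):
        cfg = SimConfig(seed=4000 + rep, m_variants=200,
                        cis=CisLayout(variants_per_gene=0, lpa_variants=0),
                        ld_rho=0.0)
        ms, inst, part, _ = _partitioned(cfg)
        res = variant_set_mr(part, ms, sensitivity=False)
        betas = np.array([r["ivw"].beta for r in res])
        rho = spearmanr(part.mean_share, betas).statistic
        pos_rho += rho > 0
        set10_gt_set1 += betas[-1] > betas[0]
    assert pos_rho >= int(0.95 * reps)
    assert set10_gt_set1 >= int(0.99 * reps)


def test_small_set_skips_sensitivity_with_notice():
    ids = [f"v{i}" for i in range(4)]
    ms = make_ms(ids, APOB=([1.0, 1.2, 2.0, 2.2], [0.1] * 4),
                 AAA=([0.1, 0.12, 0.2, 0.22], [0.05] * 4),
                 LDL_C=([1.0] * 4, [0.1] * 4), TRL_C=([0.5] * 4, [0.1] * 4))
    import pandas as pd
    part = partition_variant_sets(
        InstrumentSet(sumstats=ms,
                      provenance=pd.DataFrame({"variant_id": ids})), k=2)
    with pytest.warns(UserWarning, match="sensitivity"):
        res = variant_set_mr(part, ms, sensitivity=True, n_boot=50, n_sim=100)
    assert "egger" not in res[0]
    assert "ivw" in res[0]


# ---------------------------------------------------------------------------
# drug targets

def test_drug_target_sign_convention_reciprocal():
    """OR 1.25 per 10 mg/dL higher apoB reports as 0.80 per 10 lower."""
    ids = [f"v{i}" for i in range(5)]
    bx = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
    by = math.log(1.25) * bx / 10.0
    ms = make_ms(ids, chrom="1", pos=[55_040_000 + i * 1000 for i in range(5)],
                 APOB=(bx, [0.05] * 5), AAA=(by, [0.05] * 5),
                 LDL_C=(bx / 0.77, [0.05] * 5),
                 TRL_C=([1e-6] * 5, [0.05] * 5))
    import pandas as pd
    inst = InstrumentSet(sumstats=ms,
                         provenance=pd.DataFrame({"variant_id": ids}))
    from aneurysmo_mr.instruments import select_cis_instruments
    from aneurysmo_mr.genes import DRUG_TARGET_REGIONS
    cis = select_cis_instruments(inst, DRUG_TARGET_REGIONS)
    dt = drug_target_mr(cis, ms)
    assert dt["per_gene"]["PCSK9"].odds_ratio == pytest.approx(1 / 1.25,
                                                               rel=1e-9)


def test_single_gene_group_equals_gene_estimate():
    ids = [f"v{i}" for i in range(4)]
    bx = np.array([1.0, 1.5, 2.0, 2.5])
    rng = np.random.default_rng(9)
    by = 0.05 * bx + rng.normal(0, 0.01, 4)
    ms = make_ms(ids, chrom="8", pos=[19_940_000 + i * 2000 for i in range(4)],
                 APOB=(bx, [0.05] * 4), AAA=(by, [0.05] * 4),
                 LDL_C=([0.1] * 4, [0.05] * 4), TRL_C=(bx / 0.63, [0.05] * 4))
    import pandas as pd
    inst = InstrumentSet(sumstats=ms,
                         provenance=pd.DataFrame({"variant_id": ids}))
    from aneurysmo_mr.instruments import select_cis_instruments
    from aneurysmo_mr.genes import DRUG_TARGET_REGIONS
    cis = select_cis_instruments(inst, DRUG_TARGET_REGIONS)
    dt = drug_target_mr(cis, ms, groups={"TRL": ["LPL"]})
    assert dt["per_group"]["TRL"].beta == dt["per_gene"]["LPL"].beta


def test_drug_target_per_mmol_ratio_recovers_planted_value():
    """TRL-pathway per-mmol effect ~3x LDL-pathway by construction of the
    conversion factors and causal log-ORs; recovered within 3 MC-SE."""
    reps = 40
    ratios = []
    for rep in range(reps):
        cfg = SimConfig(seed=5000 + rep, m_variants=400,
                        causal_logor_ldl=0.2, causal_logor_trl=0.6,
                        apob_per_mgdl_ldl=0.7, apob_per_mgdl_trl=0.7,
                        ld_rho=0.0)
        ms, truth = simulate_two_sample_sumstats(cfg)
        from aneurysmo_mr.sumstats import orient_to_raising_allele
        import pandas as pd
        oms = orient_to_raising_allele(ms)
        inst = InstrumentSet(sumstats=oms, provenance=pd.DataFrame(
            {"variant_id": oms.df["variant_id"]}))
        from aneurysmo_mr.instruments import select_cis_instruments
        from aneurysmo_mr.genes import DRUG_TARGET_REGIONS
        cis = select_cis_instruments(inst, DRUG_TARGET_REGIONS)
        dt = drug_target_mr(cis, oms)
        if dt["per_mmol_ratio"] is not None:
            ratios.append(dt["per_mmol_ratio"].ratio)
    # per-mmol estimand in each group is the apoB-share-weighted causal
    # log-OR times the pathway conversion factor; with equal factors and
    # near-pure planted shares the ratio is close to 0.6/0.2 = 3
    mc_se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert abs(np.mean(ratios) - 3.0) < max(3 * mc_se, 0.3)


def test_gene_with_no_instruments_reported_absent():
    ids = ["v0"]
    ms = make_ms(ids, chrom="1", pos=[55_040_000],
                 APOB=([1.0], [0.05]), AAA=([0.1], [0.05]),
                 LDL_C=([1.0], [0.05]), TRL_C=([0.1], [0.05]))
    import pandas as pd
    inst = InstrumentSet(sumstats=ms,
                         provenance=pd.DataFrame({"variant_id": ids}))
    from aneurysmo_mr.instruments import select_cis_instruments
    from aneurysmo_mr.genes import DRUG_TARGET_REGIONS
    cis = select_cis_instruments(inst, DRUG_TARGET_REGIONS)
    with pytest.warns(UserWarning):
        dt = drug_target_mr(cis, ms)
    assert "PCSK9" in dt["per_gene"]
    assert "LPL" not in dt["per_gene"]


# ---------------------------------------------------------------------------
# unit conversion

def test_mmol_conversion_values():
    assert mgdl_mmol_convert(1.0) == pytest.approx(38.67)
    assert round(mgdl_mmol_convert(1.0)) == 39
    assert mgdl_mmol_convert(0.0) == 0.0


def test_mmol_roundtrip():
    x = 123.456
    back = mgdl_mmol_convert(mgdl_mmol_convert(x, "mmol_to_mgdl"),
                             "mgdl_to_mmol")
    assert back == pytest.approx(x, abs=1e-12)
    with pytest.raises(ValueError):
        mgdl_mmol_convert(1.0, "sideways")
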