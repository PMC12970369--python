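"""GWAS, instrument-selection cascade, variant-set partition and
cis-region selection."""

import numpy as np
import pandas as pd
import pytest

from aneurysmo_mr.genes import GeneRegion
from aneurysmo_mr.instruments import (InstrumentSet, partition_variant_sets,
                                      run_gwas, select_cis_instruments,
                                      select_instruments, trl_share)
from aneurysmo_mr.ld import BlockLD, DenseLD, empirical_r2
from aneurysmo_mr.simulate import CohortTable
from aneurysmo_mr.sumstats import MultiTraitSumstats
from conftest import make_ms


def _mini_cohort(n=500, m=3, seed=0, beta=None, noise=1.0):
    """Tiny cohort with dosages and a trait built from known effects."""
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, 0.3, size=(n, m)).astype(np.float32)
    samples = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n).astype(float),
    })
    for j in range(10):
        samples[f"PC{j+1}"] = rng.standard_normal(n)
    beta = np.zeros(m) if beta is None else np.asarray(beta, dtype=float)
    y = dos @ beta + 0.5 * (samples["age"] - 60) + rng.normal(0, noise, n)
    samples["TRAIT"] = y
    # satisfy CohortTable lipid invariants with placeholder columns
    samples["LDL_C"] = 130.0
    samples["HDL_C"] = 50.0
    samples["TRL_C"] = 25.0
    samples["non_HDL_C"] = 155.0
    samples["TC"] = 205.0
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": "1", "pos": np.arange(1, m + 1) * 10_000,
        "effect_allele": "A", "other_allele": "G",
    })
    dx = pd.DataFrame(columns=["sample_id", "system", "code", "date"])
    return CohortTable(samples=samples, dosages=dos, variants=variants, dx=dx)


# ---------------------------------------------------------------------------
# run_gwas

def test_gwas_noiseless_trait_recovers_exact_beta():
    cohort = _mini_cohort(n=300, m=1, seed=1)
    cohort.samples["TRAIT"] = 0.5 * cohort.dosages[:, 0].astype(float)
    ms = run_gwas(cohort, "TRAIT", covariates=())
    assert np.allclose(ms.df["beta_TRAIT"], 0.5, atol=1e-10)
    assert (ms.df["pvalue_TRAIT"] < 1e-100).all()


def test_gwas_matches_normal_equations_oracle():
    """Single-variant fit equals an explicit (X'X)^-1 X'y solve."""
    cohort = _mini_cohort(n=500, m=1, seed=2, beta=[0.8], noise=2.0)
    covs = ("age", "sex", "PC1", "PC2", "PC3", "PC4", "PC5")
    ms = run_gwas(cohort, "TRAIT", covariates=covs)

    s = cohort.samples
    X = np.column_stack([np.ones(500), cohort.dosages[:, 0].astype(float)]
                        + [s[c].to_numpy(float) for c in covs])
    y = s["TRAIT"].to_numpy(float)
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    dof = 500 - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    assert ms.df["beta_TRAIT"].iloc[0] == pytest.approx(coef[1], abs=1e-8)
    assert ms.df["se_TRAIT"].iloc[0] == pytest.approx(se, abs=1e-8)


def test_gwas_null_calibration_permuted_trait():
    cohort = _mini_cohort(n=400, m=200, seed=3)
    rng = np.random.default_rng(4)
    cohort.samples["TRAIT"] = rng.permutation(
        cohort.samples["TRAIT"].to_numpy())
    ms = run_gwas(cohort, "TRAIT")
    frac = float((ms.df["pvalue_TRAIT"] < 0.05).mean())
    se = np.sqrt(0.05 * 0.95 / len(ms.df))
    assert abs(frac - 0.05) < 3 * se


def test_gwas_skips_monomorphic_with_warning():
    cohort = _mini_cohort(n=200, m=3, seed=5)
    cohort.dosages[:, 1] = 1.0
    with pytest.warns(UserWarning, match="monomorphic"):
        ms = run_gwas(cohort, "TRAIT", covariates=())
    assert ms.df["variant_id"].tolist() == ["v0", "v2"]


# ---------------------------------------------------------------------------
# select_instruments

def _selection_oracle(df, r2, p_threshold, r2_threshold, window_bp, maf_min):
    """Exhaustive-enumeration oracle: apply the filters in the declared
    order on plain Python structures."""
    sig = set()
    for i, row in df.iterrows():
        if any(row[f"pvalue_{t}"] < p_threshold
               for t in ("TG", "TRL_C", "LDL_C") if f"pvalue_{t}" in row):
            sig.add(i)
    mag = {i: np.hypot(df.loc[i, "beta_LDL_C"], df.loc[i, "beta_TRL_C"])
           for i in sig}
    kept = []
    for i in sorted(sig, key=lambda i: -mag[i]):
        if all(not (df.loc[i, "chrom"] == df.loc[j, "chrom"]
                    and abs(df.loc[i, "pos"] - df.loc[j, "pos"]) <= window_bp
                    and r2[i, j] >= r2_threshold) for j in kept):
            kept.append(i)
    kept = [i for i in kept
            if min(df.loc[i, "eaf"], 1 - df.loc[i, "eaf"]) > maf_min]
    m = len(df)
    kept = [i for i in kept if df.loc[i, "pvalue_LPA"] >= 0.05 / m]
    return sorted(df.loc[kept, "variant_id"])


def test_select_prune_keeps_larger_combined_magnitude():
    ms = make_ms(["a", "b"], pos=[1000, 2000],
                 LDL_C=([3.0, 2.0], [0.1, 0.1], [1e-10, 1e-10]),
                 TRL_C=([0.0, 0.0], [0.1, 0.1], [0.5, 0.5]),
                 TG=([0.0, 0.0], [0.1, 0.1], [0.5, 0.5]))
    ld = DenseLD(np.array([[1.0, 1.0], [1.0, 1.0]]))
    inst = select_instruments(ms, ld=ld)
    assert inst.variant_ids == ["a"]
    prov = inst.provenance.set_index("variant_id")
    assert bool(prov.loc["b", "pruned_out"])


def test_select_maf_filter_flags():
    ms = make_ms(["a", "b"], eaf=[0.5, 0.005],
                 LDL_C=([1.0, 1.0], [0.1, 0.1], [1e-10, 1e-10]),
                 TRL_C=([0.5, 0.5], [0.1, 0.1], [0.5, 0.5]),
                 TG=([0.0, 0.0], [0.1, 0.1], [0.5, 0.5]))
    inst = select_instruments(ms)
    assert inst.variant_ids == ["a"]
    prov = inst.provenance.set_index("variant_id")
    assert bool(prov.loc["b", "maf_failed"])


def test_select_matches_bruteforce_oracle_on_20_variant_toy():
    rng = np.random.default_rng(42)
    n = 20
    ids = [f"t{i:02d}" for i in range(n)]
    chrom = ["1"] * 10 + ["2"] * 10
    pos = list(range(10_000, 110_000, 10_000)) * 2
    bl = rng.normal(0, 2, n).round(2)
    bt = rng.normal(0, 1, n).round(2)
    p_ldl = np.where(rng.uniform(size=n) < 0.6, 1e-10, 1e-4)
    eaf = np.where(rng.uniform(size=n) < 0.2, 0.006, 0.3)
    p_lpa = np.where(rng.uniform(size=n) < 0.15, 1e-6, 0.5)
    df_r2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and chrom[i] == chrom[j] and rng.uniform() < 0.3:
                df_r2[i, j] = df_r2[j, i] = 0.5
    np.fill_diagonal(df_r2, 1.0)
    ms = make_ms(ids, chrom=chrom, pos=pos, eaf=eaf,
                 LDL_C=(bl, [0.1] * n, p_ldl),
                 TRL_C=(bt, [0.1] * n, [0.5] * n),
                 TG=([0.0] * n, [0.1] * n, [0.5] * n))
    ms.df["pvalue_LPA"] = p_lpa
    ms.df["beta_LPA"] = 0.0
    ms.df["se_LPA"] = 1.0
    inst = select_instruments(ms, ld=DenseLD(df_r2))
    expected = _selection_oracle(ms.df, df_r2, 5e-8, 0.1, 20_000_000, 0.01)
    assert sorted(inst.variant_ids) == expected


def test_select_empty_result_is_not_an_error():
    ms = make_ms(["a"], LDL_C=([0.1], [0.1], [0.9]),
                 TRL_C=([0.1], [0.1], [0.9]), TG=([0.0], [0.1], [0.9]))
    inst = select_instruments(ms)
    assert len(inst) == 0


def test_pruned_set_has_no_close_correlated_pair(small_sumstats):
    from aneurysmo_mr.sumstats import orient_to_raising_allele
    ms, truth = small_sumstats
    inst = select_instruments(orient_to_raising_allele(ms), ld=truth.ld())
    ld = truth.ld()
    idx = {v: i for i, v in enumerate(ms.df["variant_id"])}
    kept = [idx[v] for v in inst.variant_ids]
    chrom = ms.df["chrom"].to_numpy()
    pos = ms.df["pos"].to_numpy()
    for a in kept:
        for b in kept:
            if a < b and chrom[a] == chrom[b] \
                    and abs(int(pos[a]) - int(pos[b])) <= 20_000_000:
                assert ld.r2(a, b) < 0.1


def test_maf_and_lpa_filters_commute_when_independent():
    rng = np.random.default_rng(7)
    n = 30
    ids = [f"c{i}" for i in range(n)]
    eaf = rng.uniform(0.002, 0.5, n)
    p_lpa = rng.uniform(0.0001, 1.0, n)
    ms = make_ms(ids, eaf=eaf,
                 LDL_C=(rng.normal(0, 2, n), [0.1] * n, [1e-10] * n),
                 TRL_C=(rng.normal(0, 1, n), [0.1] * n, [0.5] * n),
                 TG=([0.0] * n, [0.1] * n, [0.5] * n))
    ms.df["pvalue_LPA"] = p_lpa
    ms.df["beta_LPA"] = 0.0
    ms.df["se_LPA"] = 1.0
    inst = select_instruments(ms)
    # oracle applying Lp(a) before MAF
    m = n
    surv = [i for i in range(n)
            if min(eaf[i], 1 - eaf[i]) > 0.01 and p_lpa[i] >= 0.05 / m]
    assert sorted(inst.variant_ids) == sorted(ids[i] for i in surv)


# ---------------------------------------------------------------------------
# partition

def _instrument_set(ids, bl, bt, **kw):
    n = len(ids)
    ms = make_ms(ids, LDL_C=(bl, [0.1] * n), TRL_C=(bt, [0.1] * n), **kw)
    prov = pd.DataFrame({"variant_id": ids, "retained": True})
    return InstrumentSet(sumstats=ms, provenance=prov)


def test_partition_20_variants_into_10_pairs():
    rng = np.random.default_rng(0)
    ids = [f"p{i:02d}" for i in range(20)]
    shares = rng.uniform(0, 1, 20)
    inst = _instrument_set(ids, (1 - shares) * 2, shares * 2)
    part = partition_variant_sets(inst, k=10)
    assert [len(s) for s in part.sets] == [2] * 10
    assert part.mean_share == sorted(part.mean_share)
    flat = [v for s in part.sets for v in s]
    assert sorted(flat) == sorted(ids)


def test_partition_1357_gives_spec_sizes():
    rng = np.random.default_rng(1)
    n = 1357
    ids = [f"q{i:04d}" for i in range(n)]
    shares = rng.uniform(0, 1, n)
    inst = _instrument_set(ids, (1 - shares), shares)
    part = partition_variant_sets(inst, k=10)
    assert [len(s) for s in part.sets] == [136] * 7 + [135] * 3


def test_partition_all_ties_stable_by_variant_id():
    ids = [f"z{i}" for i in range(6)]
    inst = _instrument_set(ids, [1.0] * 6, [1.0] * 6)
    part = partition_variant_sets(inst, k=3)
    assert part.sets == [["z0", "z1"], ["z2", "z3"], ["z4", "z5"]]
    assert np.allclose(part.mean_share, 0.5)


def test_partition_excludes_zero_denominator_with_warning():
    ids = ["a", "b", "c", "d"]
    inst = _instrument_set(ids, [1.0, -1.0, 0.5, 0.2],
                           [1.0, 1.0, 0.5, 0.6])
    with pytest.warns(UserWarning, match="zero combined"):
        part = partition_variant_sets(inst, k=3)
    flat = [v for s in part.sets for v in s]
    assert "b" not in flat and len(flat) == 3


def test_partition_k_larger_than_n_errors():
    inst = _instrument_set(["a", "b"], [1.0, 1.0], [0.5, 0.5])
    with pytest.raises(ValueError):
        partition_variant_sets(inst, k=5)


def test_partition_roles_tagged():
    rng = np.random.default_rng(2)
    ids = [f"r{i}" for i in range(30)]
    shares = rng.uniform(0, 1, 30)
    inst = _instrument_set(ids, 1 - shares, shares)
    part = partition_variant_sets(inst, k=10)
    assert part.roles[1] == "LDL-specific"
    assert part.roles[3] == "statin-like"
    assert part.roles[10] == "TRL-specific"


# ---------------------------------------------------------------------------
# cis selection

def test_cis_boundary_inclusion():
    region = GeneRegion("G1", "1", 100_000, 200_000, "LDL")
    ids = ["in_flank", "out_flank", "inside"]
    inst = _instrument_set(ids, [1.0] * 3, [0.5] * 3)
    inst.sumstats.df["chrom"] = "1"
    inst.sumstats.df["pos"] = [100_000 - 50_000, 100_000 - 50_001, 150_000]
    cis = select_cis_instruments(inst, [region], flank_bp=50_000)
    assert sorted(cis["G1"].variant_ids) == ["in_flank", "inside"]


def test_cis_planted_membership_recovered():
    """3 synthetic genes, 12 planted cis variants, plus decoys: exact
    membership recovered by construction."""
    regions = [GeneRegion("A", "1", 1_000_000, 1_050_000, "LDL"),
               GeneRegion("B", "2", 2_000_000, 2_080_000, "TRL"),
               GeneRegion("C", "2", 2_100_000, 2_150_000, "TRL")]
    rows = []
    expected = {"A": [], "B": [], "C": []}
    rng = np.random.default_rng(3)
    for g, region in zip("ABC", regions):
        for i in range(4):
            vid = f"cis_{g}{i}"
            pos = int(rng.integers(region.start, region.end))
            rows.append((vid, region.chrom, pos))
            for r2 in regions:
                if r2.contains(region.chrom, pos, flank=10_000):
                    expected[r2.gene].append(vid)
    for i in range(6):
        rows.append((f"decoy{i}", "3", 1_000_000 + i * 100_000))
    ids = [r[0] for r in rows]
    inst = _instrument_set(ids, [1.0] * len(ids), [0.5] * len(ids))
    inst.sumstats.df["chrom"] = [r[1] for r in rows]
    inst.sumstats.df["pos"] = [r[2] for r in rows]
    cis = select_cis_instruments(inst, regions, flank_bp=10_000)
    for g in "ABC":
        assert sorted(cis[g].variant_ids) == sorted(expected[g])


def test_cis_empty_region_list_errors(small_sumstats):
    inst = _instrument_set(["a"], [1.0], [0.5])
    with pytest.raises(ValueError):
        select_cis_instruments(inst, [])


# ---------------------------------------------------------------------------
def test_empirical_r2_reflects_block_structure(small_config, small_cohort):
    cohort, truth = small_cohort
    ld_true = truth.ld()
    ld_emp = empirical_r2(cohort.dosages)
    block = truth.variants["block"].to_numpy()
    rho = truth.variants["rho"].to_numpy()
    same = [(i, j) for i in range(60) for j in range(i + 1, 60)
            if block[i] == block[j] and block[i] >= 0 and rho[i] > 0.3]
    diff = [(i, j) for i in range(60) for j in range(i + 1, 60)
            if block[i] != block[j]]
    if same:
        mean_same = np.mean([ld_emp.r2(i, j) for i, j in same])
        mean_diff = np.mean([ld_emp.r2(i, j) for i, j in diff])
        assert mean_same > mean_diff + 0.02
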