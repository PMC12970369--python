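"""Synthetic cohorts and two-sample GWAS summary statistics with known
ground truth.

The generative model: each variant carries a total non-HDL-C effect
magnitude t (mg/dL per allele) split between the two particle classes by
a TRL share s, so beta_TRL = s*t and beta_LDL = (1-s)*t on the
raising-allele orientation.  ApoB tracks the two cholesterol pools
through fixed conversion factors, and the AAA log-odds is linear in the
two pathway-specific apoB components (per 10 mg/dL), plus age/sex/PC
terms.  Variants planted in the cis regions of the seven drug-target
genes draw pathway-typical shares; variants planted at the LPA locus
carry strong lipoprotein(a) associations so the Lp(a) exclusion filter
has work to do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import norm

from .config import SimConfig
from .genes import DRUG_TARGET_REGIONS, LPA_REGION
from .ld import BlockLD
from .sumstats import MultiTraitSumstats

# ---------------------------------------------------------------------------
# lipid derivations

class DerivedLipids(NamedTuple):
    non_hdl: Union[float, np.ndarray]
    trl_c: Union[float, np.ndarray]
    valid: Union[bool, np.ndarray]  # False where derived TRL-C < 0


def derive_lipids(tc, hdl, ldl) -> DerivedLipids:
    """non-HDL-C = TC - HDL-C; TRL-C = non-HDL-C - LDL-C (all mg/dL).

    A negative derived TRL-C (LDL-C exceeding non-HDL-C, a measurement
    artefact) is kept but flagged invalid.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    ldl = np.asarray(ldl, dtype=float)
    if not (np.all(np.isfinite(tc)) and np.all(np.isfinite(hdl))
            and np.all(np.isfinite(ldl))):
        raise ValueError("lipid inputs must be finite")
    if np.any(tc < hdl):
        raise ValueError("total cholesterol below HDL-C")
    non_hdl = tc - hdl
    trl = non_hdl - ldl
    valid = trl >= 0
    if non_hdl.ndim == 0:
        return DerivedLipids(float(non_hdl), float(trl), bool(valid))
    return DerivedLipids(non_hdl, trl, valid)


# ---------------------------------------------------------------------------
# ICD-based AAA phenotyping

AAA_CODES = {"ICD9": ("441.3", "441.4"), "ICD10": ("I71.3", "I71.4")}
#: exclusion ranges on the category (pre-dot) part of the code
EXCLUSION_RANGES = {
    "ICD9": [(440, 448)],
    "ICD10": [("I", 71, 75), ("I", 77, 79), ("K", 55, 55)],
}


def _normalize(system: str, code: str) -> Tuple[str, str]:
    system = str(system).strip().upper().replace("-", "")
    if system not in ("ICD9", "ICD10"):
        raise ValueError(f"unknown code system: {system!r}")
    return system, str(code).strip().upper()


def is_aaa_code(system: str, code: str) -> bool:
    system, code = _normalize(system, code)
    return any(code == base or code.startswith(base) for base in AAA_CODES[system])


def in_exclusion_range(system: str, code: str) -> bool:
    """Membership in the related-vascular-disease ranges, by
    prefix-numeric comparison on the category part of the code."""
    system, code = _normalize(system, code)
    category = code.split(".")[0]
    if system == "ICD9":
        if not category.isdigit():
            return False
        cat = int(category)
        return any(lo <= cat <= hi for lo, hi in EXCLUSION_RANGES["ICD9"])
    letter, digits = category[:1], category[1:3]
    if not digits.isdigit():
        return False
    num = int(digits)
    return any(letter == lt and lo <= num <= hi
               for lt, lo, hi in EXCLUSION_RANGES["ICD10"])


def phenotype_aaa(dx_codes: Iterable) -> str:
    """Classify one individual's diagnosis codes.

    ``dx_codes`` is an iterable of (system, code) or (system, code, date).
    Case: >= 2 occurrences (any mix) of the AAA codes.  Comparator: no
    AAA code and no code in the vascular-disease exclusion ranges.
    Anything in between (e.g. a single AAA code): excluded.
    """
    n_aaa = 0
    excluded = False
    for entry in dx_codes:
        system, code = entry[0], entry[1]
        if is_aaa_code(system, code):
            n_aaa += 1
        elif in_exclusion_range(system, code):
            excluded = True
    if n_aaa >= 2:
        return "case"
    if n_aaa == 0 and not excluded:
        return "comparator"
    return "excluded"


def phenotype_cohort(dx: pd.DataFrame, sample_ids: Sequence[str]) -> pd.Series:
    """Vectorised phenotype_aaa over a long-format dx table
    (sample_id, system, code, date)."""
    status = pd.Series("comparator", index=pd.Index(sample_ids, name="sample_id"))
    if len(dx) == 0:
        return status
    is_aaa = np.fromiter(
        (is_aaa_code(s, c) for s, c in zip(dx["system"], dx["code"])),
        dtype=bool, count=len(dx))
    is_excl = np.fromiter(
        (in_exclusion_range(s, c) for s, c in zip(dx["system"], dx["code"])),
        dtype=bool, count=len(dx))
    g = pd.DataFrame({"sample_id": dx["sample_id"].to_numpy(),
                      "aaa": is_aaa, "excl": is_excl & ~is_aaa})
    agg = g.groupby("sample_id").sum()
    n_aaa = agg["aaa"].reindex(status.index, fill_value=0)
    n_excl = agg["excl"].reindex(status.index, fill_value=0)
    status[(n_aaa > 0) | (n_excl > 0)] = "excluded"
    status[n_aaa >= 2] = "case"
    return status


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class SimTruth:
    """Generative values recorded for parameter-recovery testing."""

    config: SimConfig
    variants: pd.DataFrame  # variant_id chrom pos block rho maf gene is_lpa
    #                         share beta_ldl beta_trl beta_apob_ldl
    #                         beta_apob_trl beta_apob outcome_beta
    causal_logor_ldl: float
    causal_logor_trl: float

    @property
    def per_apob_ratio(self) -> float:
        return self.causal_logor_trl / self.causal_logor_ldl

    @property
    def per_cholesterol_ratio(self) -> float:
        c = self.config
        return (self.causal_logor_trl * c.apob_per_mgdl_trl) / (
            self.causal_logor_ldl * c.apob_per_mgdl_ldl)

    def ld(self) -> BlockLD:
        return BlockLD(self.variants["block"].to_numpy(),
                       self.variants["rho"].to_numpy())


_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT"
                 if a != b and b != {"A": "T", "T": "A", "C": "G", "G": "C"}[a]]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic substreams per generator stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _variant_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out planted cis / LPA variants and LD-blocked background
    variants across chromosomes 1-22."""
    cis = config.cis
    rows = []
    block_counter = 0

    def plant(region, count, rho):
        nonlocal block_counter
        if count == 0:
            return
        positions = np.linspace(region.start, region.end, count).astype(np.int64)
        for j, pos in enumerate(positions):
            if j % config.ld_block_size == 0:
                block_counter += 1
            rows.append((region.chrom, int(pos),
                         block_counter if rho > 0 else -1,
                         rho, region.gene))

    for region in DRUG_TARGET_REGIONS:
        plant(region, cis.variants_per_gene, cis.cis_rho)
    plant(LPA_REGION, cis.lpa_variants, cis.cis_rho)
    n_planted = len(rows)

    n_bg = config.m_variants - n_planted
    forbidden = {}  # chrom -> list of (lo, hi) to keep background out of
    for region in DRUG_TARGET_REGIONS + [LPA_REGION]:
        forbidden.setdefault(region.chrom, []).append(
            (region.start - 1_000_000, region.end + 1_000_000))
    per_chrom = int(np.ceil(n_bg / 22))
    placed = 0
    for chrom_i in range(1, 23):
        chrom = str(chrom_i)
        j = 0
        count = 0
        while count < per_chrom and placed < n_bg:
            pos = 60_000_000 + j * 500_000
            j += 1
            if any(lo <= pos <= hi for lo, hi in forbidden.get(chrom, [])):
                continue
            if count % config.ld_block_size == 0:
                block_counter += 1
            rows.append((chrom, pos,
                         block_counter if config.ld_rho > 0 else -1,
                         config.ld_rho, ""))
            count += 1
            placed += 1
        if placed >= n_bg:
            break

    df = pd.DataFrame(rows, columns=["chrom", "pos", "block", "rho", "gene"])
    df["is_lpa"] = df["gene"] == "LPA"
    df.loc[df["is_lpa"], "gene"] = ""
    df["variant_id"] = [f"var_{i:05d}" for i in range(len(df))]
    df["maf"] = rng.uniform(config.maf_range[0], config.maf_range[1], len(df))
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), len(df))
    df["effect_allele"] = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    df["other_allele"] = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    return df


def draw_truth(config: SimConfig) -> SimTruth:
    """Draw the per-variant generative effects shared by the cohort and
    two-sample generators under the same config."""
    config.validate()
    rng = _rng(config, 0)
    vm = _variant_map(config, rng)
    m = len(vm)
    cis = config.cis

    share = rng.beta(config.trl_share_spectrum.a, config.trl_share_spectrum.b, m)
    ldl_genes = {"PCSK9", "HMGCR", "NPC1L1", "LDLR"}
    trl_genes = {"LPL", "APOC3", "APOA5"}
    for genes, (a, b) in ((ldl_genes, cis.ldl_share_beta),
                          (trl_genes, cis.trl_share_beta)):
        mask = vm["gene"].isin(genes).to_numpy()
        share[mask] = rng.beta(a, b, int(mask.sum()))

    t = (np.abs(rng.normal(config.ldl_effect_dist.mean,
                           config.ldl_effect_dist.sd, m))
         + np.abs(rng.normal(config.trl_effect_dist.mean,
                             config.trl_effect_dist.sd, m)))
    # the listed effect allele is the raising allele for only half the
    # variants, as in real GWAS output
    sign = np.where(rng.uniform(size=m) < 0.5, 1.0, -1.0)
    beta_ldl = sign * (1.0 - share) * t
    beta_trl = sign * share * t
    beta_apob_ldl = config.apob_per_mgdl_ldl * beta_ldl
    beta_apob_trl = config.apob_per_mgdl_trl * beta_trl
    outcome_beta = (config.causal_logor_ldl * beta_apob_ldl / 10.0
                    + config.causal_logor_trl * beta_apob_trl / 10.0)

    vm = vm.assign(share=share, beta_ldl=beta_ldl, beta_trl=beta_trl,
                   beta_apob_ldl=beta_apob_ldl, beta_apob_trl=beta_apob_trl,
                   beta_apob=beta_apob_ldl + beta_apob_trl,
                   outcome_beta=outcome_beta)
    return SimTruth(config=config, variants=vm,
                    causal_logor_ldl=config.causal_logor_ldl,
                    causal_logor_trl=config.causal_logor_trl)


# ---------------------------------------------------------------------------
# two-sample summary statistics

def simulate_two_sample_sumstats(config: SimConfig
                                 ) -> Tuple[MultiTraitSumstats, SimTruth]:
    """Exposure and outcome GWAS summary statistics under the generative
    model: observed exposure betas are the true betas plus Normal noise at
    ``exposure_se_scale``; the outcome beta is the true causal combination
    plus Normal noise at ``outcome_se_scale`` (the reported outcome SE)."""
    truth = draw_truth(config)
    rng = _rng(config, 2)
    vm = truth.variants
    m = len(vm)
    se_x = config.exposure_se_scale
    se_col = se_x if se_x > 0 else 1e-8

    def noisy(true_beta, scale):
        return (true_beta + rng.normal(0.0, scale, m)) if scale > 0 \
            else np.asarray(true_beta, dtype=float).copy()

    df = vm[["variant_id", "chrom", "pos", "effect_allele",
             "other_allele", "maf"]].rename(columns={"maf": "eaf"}).copy()
    for trait, true_beta, scale, se in (
            ("LDL_C", vm["beta_ldl"].to_numpy(), se_x, se_col),
            ("TRL_C", vm["beta_trl"].to_numpy(), se_x, se_col),
            ("TG", 5.0 * vm["beta_trl"].to_numpy(), 5 * se_x, 5 * se_col),
            ("APOB", vm["beta_apob"].to_numpy(), se_x, se_col),
            ("AAA", vm["outcome_beta"].to_numpy(),
             config.outcome_se_scale, config.outcome_se_scale)):
        b = noisy(true_beta, scale)
        df[f"beta_{trait}"] = b
        df[f"se_{trait}"] = se
        df[f"pvalue_{trait}"] = np.clip(2.0 * norm.sf(np.abs(b) / se), 1e-320, 1.0)
        df[f"n_{trait}"] = config.n_individuals
    # lipoprotein(a): planted LPA-locus variants associate strongly,
    # everything else is null
    df["beta_LPA"] = 0.0
    df["se_LPA"] = 1.0
    p_lpa = rng.uniform(0.05, 1.0, m)
    lpa_mask = vm["is_lpa"].to_numpy()
    p_lpa[lpa_mask] = rng.uniform(1e-30, 1e-20, int(lpa_mask.sum()))
    df["pvalue_LPA"] = p_lpa

    units = {"LDL_C": "mg/dL", "TRL_C": "mg/dL", "TG": "mg/dL",
             "APOB": "mg/dL", "LPA": "arbitrary", "AAA": "log-odds"}
    return MultiTraitSumstats(df, units=units, validate=False), truth


# ---------------------------------------------------------------------------
# individual-level cohort

@dataclass
class CohortTable:
    """Synthetic individual-level data.

    ``samples`` holds covariates, lipids (mg/dL) and AAA status;
    ``dosages`` is an (n x m) float32 matrix in [0, 2] aligned to
    ``variants``; ``dx`` is a long-format diagnosis-code table."""

    samples: pd.DataFrame
    dosages: np.ndarray
    variants: pd.DataFrame
    dx: pd.DataFrame

    def validate(self) -> None:
        s = self.samples
        if not np.allclose(s["non_HDL_C"], s["TC"] - s["HDL_C"], atol=1e-9):
            raise AssertionError("non-HDL-C != TC - HDL-C")
        if not np.allclose(s["TRL_C"], s["non_HDL_C"] - s["LDL_C"], atol=1e-9):
            raise AssertionError("TRL-C != non-HDL-C - LDL-C")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise AssertionError("dosages outside [0, 2]")
        if self.dosages.shape != (len(s), len(self.variants)):
            raise AssertionError("dosage matrix shape mismatch")


_IRRELEVANT_CODES = [("ICD10", "E11.9"), ("ICD9", "250.00"), ("ICD10", "J45.9"),
                     ("ICD10", "M54.5"), ("ICD9", "715.90")]
_VASCULAR_CODES = [("ICD10", "I73.9"), ("ICD9", "440.2"), ("ICD10", "I77.1"),
                   ("ICD10", "K55.1"), ("ICD9", "443.9")]


def _draw_dosages(config: SimConfig, vm: pd.DataFrame,
                  rng: np.random.Generator) -> np.ndarray:
    n, m = config.n_individuals, len(vm)
    maf = vm["maf"].to_numpy()
    rho = vm["rho"].to_numpy()
    block = vm["block"].to_numpy()
    if np.all((rho == 0) | (block < 0)):
        return rng.binomial(2, maf, size=(n, m)).astype(np.float32)
    # Gaussian-copula alleles: exchangeable latent correlation rho within
    # a block approximates allele-level correlation rho (slightly
    # attenuated by dichotomisation)
    thresh = ndtri(maf)
    dos = np.zeros((n, m), dtype=np.float32)
    blocks = np.unique(block[block >= 0])
    b_index = {int(b): i for i, b in enumerate(blocks)}
    for copy in range(2):
        w = rng.standard_normal((n, len(blocks)))
        e = rng.standard_normal((n, m))
        z = np.empty((n, m))
        for j in range(m):
            r = rho[j] if block[j] >= 0 else 0.0
            if r > 0:
                z[:, j] = np.sqrt(r) * w[:, b_index[int(block[j])]] \
                    + np.sqrt(1 - r) * e[:, j]
            else:
                z[:, j] = e[:, j]
        dos += (z < thresh[None, :]).astype(np.float32)
    return dos


def _dates(rng: np.random.Generator, k: int) -> list:
    years = rng.integers(2000, 2021, k)
    months = rng.integers(1, 13, k)
    days = rng.integers(1, 29, k)
    return [f"{y:04d}-{mo:02d}-{d:02d}" for y, mo, d in zip(years, months, days)]


def simulate_cohort(config: SimConfig) -> Tuple[CohortTable, SimTruth]:
    """Generate an individual-level cohort: dosages, covariates, lipids,
    an EHR-style diagnosis-code table, and AAA status derived from it."""
    truth = draw_truth(config)
    rng = _rng(config, 1)
    vm = truth.variants
    n = config.n_individuals
    cov = config.covariate_effects
    noise = config.lipid_noise

    dosages = _draw_dosages(config, vm, rng)
    age = rng.normal(60.0, 8.0, n)
    sex = rng.integers(0, 2, n).astype(float)  # 1 = male
    pcs = rng.standard_normal((n, 10))

    ldl_gen = dosages @ vm["beta_ldl"].to_numpy(dtype=np.float64)
    trl_gen = dosages @ vm["beta_trl"].to_numpy(dtype=np.float64)
    age_c = age - 60.0

    ldl = (config.ldl_base + ldl_gen + cov.age_ldl * age_c + cov.sex_ldl * sex
           + rng.normal(0.0, noise.ldl, n))
    trl = (config.trl_base + trl_gen + cov.age_trl * age_c + cov.sex_trl * sex
           + rng.normal(0.0, noise.trl, n))
    # guard the (rare) individuals whose simulated non-HDL-C would be
    # non-positive: shift LDL and TRL equally so TC >= HDL always holds
    deficit = np.maximum(0.0, 1.0 - (ldl + trl))
    ldl = ldl + deficit / 2.0
    trl = trl + deficit / 2.0
    hdl = rng.normal(config.hdl_mean, noise.hdl, n)
    tc = ldl + trl + hdl  # identities exact by construction
    non_hdl, trl_derived, trl_valid = derive_lipids(tc, hdl, ldl)
    apob = (config.apob_per_mgdl_ldl * ldl_gen
            + config.apob_per_mgdl_trl * trl_gen
            + rng.normal(0.0, noise.apob, n))

    # outcome model uses allele-frequency-centred genetic components so
    # baseline_logodds is the log-odds at the population-mean genetic
    # apoB (centring only shifts the intercept, never the per-unit
    # effects)
    offset_ldl = float(2.0 * vm["maf"].to_numpy()
                       @ vm["beta_ldl"].to_numpy())
    offset_trl = float(2.0 * vm["maf"].to_numpy()
                       @ vm["beta_trl"].to_numpy())
    apob_ldl_gen = config.apob_per_mgdl_ldl * (ldl_gen - offset_ldl)
    apob_trl_gen = config.apob_per_mgdl_trl * (trl_gen - offset_trl)
    logit = (config.baseline_logodds
             + config.causal_logor_ldl * apob_ldl_gen / 10.0
             + config.causal_logor_trl * apob_trl_gen / 10.0
             + cov.age_outcome * age_c + cov.sex_outcome * sex
             + pcs @ np.asarray(cov.pc_outcome))
    y = rng.binomial(1, expit(logit)).astype(bool)

    sample_ids = [f"S{i:06d}" for i in range(n)]
    ehr = config.ehr
    dx_rows = []
    u_case = rng.uniform(size=n)
    u_vasc = rng.uniform(size=n)
    u_irr = rng.uniform(size=n)
    for i in range(n):
        if y[i]:
            n_codes = 1 if u_case[i] < ehr.p_single_code_case else 2
            for _ in range(n_codes):
                system = "ICD10" if rng.uniform() < 0.7 else "ICD9"
                code = AAA_CODES[system][int(rng.integers(0, 2))]
                dx_rows.append((sample_ids[i], system, code))
        elif u_vasc[i] < ehr.p_vascular_code_control:
            system, code = _VASCULAR_CODES[int(rng.integers(0, len(_VASCULAR_CODES)))]
            dx_rows.append((sample_ids[i], system, code))
        if u_irr[i] < ehr.p_irrelevant_code:
            system, code = _IRRELEVANT_CODES[int(rng.integers(0, len(_IRRELEVANT_CODES)))]
            dx_rows.append((sample_ids[i], system, code))
    dx = pd.DataFrame(dx_rows, columns=["sample_id", "system", "code"])
    dx["date"] = _dates(rng, len(dx))

    status = phenotype_cohort(dx, sample_ids)

    samples = pd.DataFrame({"sample_id": sample_ids, "age": age, "sex": sex})
    for j in range(10):
        samples[f"PC{j+1}"] = pcs[:, j]
    samples["TC"] = tc
    samples["HDL_C"] = hdl
    samples["LDL_C"] = ldl
    samples["non_HDL_C"] = non_hdl
    samples["TRL_C"] = trl_derived
    samples["trl_valid"] = trl_valid
    samples["apoB"] = apob
    samples["aaa_latent"] = y
    samples["aaa_status"] = status.to_numpy()

    cohort = CohortTable(samples=samples, dosages=dosages,
                         variants=vm.copy(), dx=dx)
    cohort.validate()
    if not np.allclose(trl_derived, trl, atol=1e-9):
        warnings.warn("derived TRL-C deviates from generated TRL-C")
    return cohort, truth
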