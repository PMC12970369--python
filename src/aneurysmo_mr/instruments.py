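"""Instrument selection: cohort GWAS, the significance -> LD-pruning ->
MAF -> Lp(a) filter cascade, TRL-share ranking into variant sets, and
cis-region instruments for drug-target genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .genes import GeneRegion
from .simulate import CohortTable
from .sumstats import MultiTraitSumstats

DEFAULT_COVARIATES = ("age", "sex", "PC1", "PC2", "PC3", "PC4", "PC5")
#: genome-wide significance in any of these lipid GWASs qualifies a variant
SIGNIFICANCE_TRAITS = ("TG", "TRL_C", "LDL_C")


# ---------------------------------------------------------------------------
def run_gwas(cohort: CohortTable, trait: str,
             covariates: Sequence[str] = DEFAULT_COVARIATES
             ) -> MultiTraitSumstats:
    """Per-variant OLS of ``trait`` on allele dosage with covariate
    adjustment (age, sex, PC1-5 by default).

    Residualises the trait and every dosage column against the covariate
    design once (Frisch-Waugh-Lovell), then solves the m single-variant
    regressions vectorised.  Monomorphic variants are skipped with a
    warning.  Individuals flagged ``on_lipid_rx`` are excluded if the
    column exists.
    """
    s = cohort.samples
    keep = np.ones(len(s), dtype=bool)
    if "on_lipid_rx" in s.columns:
        keep &= ~s["on_lipid_rx"].to_numpy(bool)
    y = s.loc[keep, trait].to_numpy(float)
    n = keep.sum()
    Z = np.column_stack([np.ones(n)]
                        + [s.loc[keep, c].to_numpy(float) for c in covariates])
    X = cohort.dosages[keep].astype(np.float64)

    q, _ = np.linalg.qr(Z)
    y_r = y - q @ (q.T @ y)
    X_r = X - q @ (q.T @ X)

    sxx = np.einsum("ij,ij->j", X_r, X_r)
    mono = cohort.dosages[keep].std(axis=0) == 0
    if mono.any():
        warnings.warn(f"skipping {int(mono.sum())} monomorphic variant(s)")
    sxx_safe = np.where(mono, 1.0, sxx)
    sxy = X_r.T @ y_r
    beta = sxy / sxx_safe
    dof = n - Z.shape[1] - 1
    rss = (y_r @ y_r) - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / sxx_safe)
    se = np.where(se > 0, se, np.finfo(float).tiny)
    tstat = beta / se
    pval = np.clip(2.0 * t_dist.sf(np.abs(tstat), dof), 1e-320, 1.0)

    vm = cohort.variants
    eaf = cohort.dosages[keep].mean(axis=0) / 2.0
    df = pd.DataFrame({
        "variant_id": vm["variant_id"].to_numpy(),
        "chrom": vm["chrom"].to_numpy(),
        "pos": vm["pos"].to_numpy(),
        "effect_allele": vm["effect_allele"].to_numpy(),
        "other_allele": vm["other_allele"].to_numpy(),
        "eaf": np.clip(eaf, 1e-6, 1 - 1e-6),
        f"beta_{trait}": beta, f"se_{trait}": se, f"pvalue_{trait}": pval,
        f"n_{trait}": int(n),
    })
    df = df.loc[~mono].reset_index(drop=True)
    return MultiTraitSumstats(df, units={trait: "mg/dL"}, validate=False)


# ---------------------------------------------------------------------------
@dataclass
class InstrumentSet:
    """Pruned instruments plus per-candidate provenance flags."""

    sumstats: MultiTraitSumstats
    provenance: pd.DataFrame  # variant_id gw_significant_traits pruned_out
    #                           maf_failed lpa_excluded retained
    ld: object = None

    @property
    def variant_ids(self) -> List[str]:
        return self.sumstats.df["variant_id"].tolist()

    def __len__(self) -> int:
        return len(self.sumstats.df)


def select_instruments(ms: MultiTraitSumstats, ld=None,
                       lpa_pvalues: Optional[pd.Series] = None,
                       p_threshold: float = 5e-8,
                       r2_threshold: float = 0.1,
                       window_bp: int = 20_000_000,
                       maf_min: float = 0.01) -> InstrumentSet:
    """Apply the instrument-selection cascade.

    1. keep variants genome-wide significant for >= 1 of TG, TRL-C, LDL-C;
    2. greedy LD pruning within ``window_bp``: between correlated variants
       (r^2 >= threshold) keep the larger combined magnitude
       sqrt(betaLDL^2 + betaTRL^2);
    3. MAF filter (> ``maf_min``);
    4. drop variants with Lp(a) p below 0.05/m (m = candidates tested).

    An empty survivor set is a valid result, not an error.
    """
    df = ms.df.reset_index(drop=True)
    m_total = len(df)
    prov = pd.DataFrame({"variant_id": df["variant_id"]})

    sig_traits = [t for t in SIGNIFICANCE_TRAITS if f"pvalue_{t}" in df.columns]
    if not sig_traits:
        raise ValueError("no lipid p-value columns for the significance filter")
    sig_matrix = np.column_stack(
        [df[f"pvalue_{t}"].to_numpy(float) < p_threshold for t in sig_traits])
    prov["gw_significant_traits"] = [
        ",".join(t for t, s in zip(sig_traits, row) if s)
        for row in sig_matrix]
    significant = sig_matrix.any(axis=1)

    # greedy pruning in descending combined-magnitude order
    combined = np.sqrt(df["beta_LDL_C"].to_numpy(float) ** 2
                       + df["beta_TRL_C"].to_numpy(float) ** 2)
    pruned_out = np.zeros(m_total, dtype=bool)
    if ld is not None:
        chrom = df["chrom"].astype(str).to_numpy()
        pos = df["pos"].to_numpy(np.int64)
        order = np.argsort(-combined, kind="stable")
        kept: List[int] = []
        for i in order:
            if not significant[i]:
                continue
            drop = False
            for j in kept:
                if chrom[i] == chrom[j] and abs(int(pos[i]) - int(pos[j])) <= window_bp \
                        and ld.r2(i, j) >= r2_threshold:
                    drop = True
                    break
            if drop:
                pruned_out[i] = True
            else:
                kept.append(i)
    prov["pruned_out"] = pruned_out

    eaf = df["eaf"].to_numpy(float)
    maf = np.minimum(eaf, 1 - eaf)
    maf_failed = maf <= maf_min
    prov["maf_failed"] = maf_failed

    if lpa_pvalues is None and "pvalue_LPA" in df.columns:
        lpa_pvalues = df["pvalue_LPA"]
    if lpa_pvalues is not None:
        lpa_excluded = np.asarray(lpa_pvalues, dtype=float) < 0.05 / m_total
    else:
        lpa_excluded = np.zeros(m_total, dtype=bool)
    prov["lpa_excluded"] = lpa_excluded

    retained = significant & ~pruned_out & ~maf_failed & ~lpa_excluded
    prov["retained"] = retained

    sub = MultiTraitSumstats(df.loc[retained].reset_index(drop=True),
                             units=ms.units, validate=False)
    return InstrumentSet(sumstats=sub, provenance=prov, ld=ld)


# ---------------------------------------------------------------------------
@dataclass
class VariantSetPartition:
    """k TRL-share-ranked variant sets (1 = LDL-specific ... k =
    TRL-specific; set 3 proxies statin-like lowering)."""

    sets: List[List[str]]
    mean_share: List[float]
    ratio_range: List[tuple]
    roles: Dict[int, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.sets)

    def check_invariants(self, all_ids: Sequence[str]) -> None:
        flat = [v for s in self.sets for v in s]
        if len(flat) != len(set(flat)):
            raise AssertionError("variant sets are not disjoint")
        if set(flat) != set(all_ids):
            raise AssertionError("union of sets != ranked instrument set")
        sizes = [len(s) for s in self.sets]
        if max(sizes) - min(sizes) > 1:
            raise AssertionError("set sizes differ by more than 1")
        shares = self.mean_share
        if any(b - a < -1e-12 for a, b in zip(shares, shares[1:])):
            raise AssertionError("mean TRL share not nondecreasing")


def trl_share(beta_ldl: np.ndarray, beta_trl: np.ndarray) -> np.ndarray:
    """TRL share of the non-HDL-C effect, s = betaTRL/(betaTRL+betaLDL).

    Bounded on raising-allele-oriented betas and order-equivalent to the
    raw TRL:LDL ratio where both betas are positive, without the ratio's
    blow-up as betaLDL -> 0."""
    denom = beta_trl + beta_ldl
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom == 0, np.nan, beta_trl / denom)


def partition_variant_sets(inst: InstrumentSet, k: int = 10
                           ) -> VariantSetPartition:
    """Rank instruments by TRL share and split into k contiguous sets
    whose sizes differ by at most one (earlier sets take the extra
    variant); ties broken by variant_id for a stable order."""
    df = inst.sumstats.df
    n = len(df)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available instruments")
    s = trl_share(df["beta_LDL_C"].to_numpy(float),
                  df["beta_TRL_C"].to_numpy(float))
    usable = ~np.isnan(s)
    if not usable.all():
        warnings.warn(f"excluding {int((~usable).sum())} variant(s) with "
                      "zero combined non-HDL effect from ranking")
    ranked = df.loc[usable, ["variant_id"]].assign(share=s[usable],
                                                   beta_ldl=df.loc[usable, "beta_LDL_C"],
                                                   beta_trl=df.loc[usable, "beta_TRL_C"])
    ranked = ranked.sort_values(["share", "variant_id"],
                                kind="stable").reset_index(drop=True)

    n_use = len(ranked)
    base, rem = divmod(n_use, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    sets, mean_share, ratio_range = [], [], []
    start = 0
    for size in sizes:
        chunk = ranked.iloc[start:start + size]
        start += size
        sets.append(chunk["variant_id"].tolist())
        mean_share.append(float(chunk["share"].mean()))
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = chunk["beta_trl"].to_numpy() / chunk["beta_ldl"].to_numpy()
        finite = raw[np.isfinite(raw)]
        ratio_range.append((float(finite.min()), float(finite.max()))
                           if len(finite) else (np.nan, np.nan))

    roles = {1: "LDL-specific", k: "TRL-specific"}
    if k >= 3:
        roles[3] = "statin-like"
    part = VariantSetPartition(sets=sets, mean_share=mean_share,
                               ratio_range=ratio_range, roles=roles)
    part.check_invariants(ranked["variant_id"].tolist())
    return part


# ---------------------------------------------------------------------------
def select_cis_instruments(inst: InstrumentSet,
                           regions: Sequence[GeneRegion],
                           flank_bp: int = 200_000
                           ) -> Dict[str, InstrumentSet]:
    """Per gene, the instruments with position inside [start - flank,
    end + flank] on the gene's chromosome.  A variant inside several
    (overlapping) windows instruments each of them."""
    if not regions:
        raise ValueError("empty gene-region list")
    df = inst.sumstats.df
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(np.int64)
    out = {}
    for region in regions:
        inside = (chrom == region.chrom) & \
                 (pos >= region.start - flank_bp) & (pos <= region.end + flank_bp)
        sub = MultiTraitSumstats(df.loc[inside].reset_index(drop=True),
                                 units=inst.sumstats.units, validate=False)
        out[region.gene] = InstrumentSet(
            sumstats=sub,
            provenance=inst.provenance[
                inst.provenance["variant_id"].isin(sub.df["variant_id"])
            ].reset_index(drop=True),
            ld=inst.ld)
    return out
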