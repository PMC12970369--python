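"""Relative-aneurysmogenicity statistics: variant-set MR per 10 mg/dL
apoB, ratios of log-odds ratios (delta-method CIs), the multivariable
per-cholesterol ratio, and drug-target / grouped-target MR with the
per-mmol comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .instruments import InstrumentSet, VariantSetPartition
from .mr import MREstimate, Z95, ivw, mr_egger, mr_presso, mvmr_ivw, weighted_median
from .sumstats import MultiTraitSumstats

#: mg/dL cholesterol per mmol/L (molar mass 386.65 g/mol / 10)
MGDL_PER_MMOL = 38.67


def mgdl_mmol_convert(value: float, direction: str = "mmol_to_mgdl") -> float:
    """Cholesterol unit conversion; 1.0 mmol/L -> 38.67 mg/dL."""
    if direction == "mmol_to_mgdl":
        return value * MGDL_PER_MMOL
    if direction == "mgdl_to_mmol":
        return value / MGDL_PER_MMOL
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
@dataclass
class RatioEstimate:
    """Ratio of two log-odds-ratio estimates with a first-order
    delta-method CI."""

    ratio: float
    se: float
    numerator_ref: str = ""
    denominator_ref: str = ""
    independence_assumed: bool = True
    unstable: bool = False
    method: str = "delta"

    @property
    def ci_low(self) -> float:
        return self.ratio - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.ratio + Z95 * self.se

    def to_dict(self) -> dict:
        return {"ratio": self.ratio, "se": self.se, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "method": self.method,
                "numerator_ref": self.numerator_ref,
                "denominator_ref": self.denominator_ref,
                "independence_assumed": self.independence_assumed,
                "unstable": self.unstable}


def ratio_of_estimates(beta_num: float, se_num: float, beta_den: float,
                       se_den: float, cov: float = 0.0,
                       numerator_ref: str = "", denominator_ref: str = "",
                       independence_assumed: bool = True) -> RatioEstimate:
    """R = beta_num/beta_den with first-order delta variance
    se_num^2/beta_den^2 + beta_num^2 se_den^2/beta_den^4
    - 2 beta_num cov / beta_den^3."""
    if beta_den == 0:
        raise ZeroDivisionError("denominator estimate is exactly zero")
    r = beta_num / beta_den
    var = (se_num ** 2 / beta_den ** 2
           + beta_num ** 2 * se_den ** 2 / beta_den ** 4
           - 2.0 * beta_num * cov / beta_den ** 3)
    unstable = abs(beta_den) < 2.0 * se_den
    if unstable:
        warnings.warn("denominator log-OR within 2 SE of zero; "
                      "ratio estimate flagged unstable")
    return RatioEstimate(ratio=float(r), se=float(np.sqrt(max(var, 0.0))),
                         numerator_ref=numerator_ref,
                         denominator_ref=denominator_ref,
                         independence_assumed=independence_assumed,
                         unstable=unstable)


def relative_aneurysmogenicity(num: MREstimate, den: MREstimate
                               ) -> RatioEstimate:
    """Ratio of the AAA log-OR per 10 mg/dL apoB for the TRL-specific
    set to the LDL-specific set; the sets are disjoint so independence
    is assumed."""
    if num.scale != den.scale:
        raise ValueError(f"estimates on different scales: "
                         f"{num.scale!r} vs {den.scale!r}")
    return ratio_of_estimates(num.beta, num.se, den.beta, den.se,
                              numerator_ref=num.method,
                              denominator_ref=den.method,
                              independence_assumed=True)


def per_cholesterol_ratio(estimates: List[MREstimate],
                          cov: np.ndarray) -> RatioEstimate:
    """TRL-C vs LDL-C aneurysmogenicity from a multivariable fit
    (exposure order: LDL-C first, TRL-C second), using the full joint
    coefficient covariance."""
    ldl, trl = estimates
    return ratio_of_estimates(trl.beta, trl.se, ldl.beta, ldl.se,
                              cov=float(cov[0, 1]),
                              numerator_ref="mvmr_TRL_C",
                              denominator_ref="mvmr_LDL_C",
                              independence_assumed=False)


# ---------------------------------------------------------------------------
PER_10_APOB = "per 10 mg/dL apoB"


def _set_arrays(ms: MultiTraitSumstats, ids: List[str]):
    df = ms.df.set_index("variant_id").loc[ids]
    return (df["beta_APOB"].to_numpy(float) / 10.0,
            df["se_APOB"].to_numpy(float) / 10.0,
            df["beta_AAA"].to_numpy(float),
            df["se_AAA"].to_numpy(float))


def variant_set_mr(partition: VariantSetPartition, ms: MultiTraitSumstats,
                   sensitivity: bool = True, n_boot: int = 1000,
                   n_sim: int = 1000, seed: int = 0
                   ) -> List[Dict[str, MREstimate]]:
    """Per variant set, IVW of the AAA log-odds on the apoB effect,
    reported per 10 mg/dL apoB, with weighted-median / MR-Egger /
    MR-PRESSO sensitivity estimates attached when the set is large
    enough."""
    out = []
    for idx, ids in enumerate(partition.sets):
        bx, sx, by, sy = _set_arrays(ms, ids)
        res = {"ivw": ivw(bx, sx, by, sy, scale=PER_10_APOB)}
        if sensitivity:
            if len(ids) >= 3:
                res["egger"] = mr_egger(bx, sx, by, sy, scale=PER_10_APOB)
                res["weighted_median"] = weighted_median(
                    bx, sx, by, sy, n_boot=n_boot,
                    seed=seed + idx, scale=PER_10_APOB)
            if len(ids) >= 4:
                res["presso"] = mr_presso(bx, sx, by, sy, n_sim=n_sim,
                                          seed=seed + idx,
                                          variant_ids=ids, scale=PER_10_APOB)
            if len(ids) < 3:
                warnings.warn(f"set {idx + 1}: <3 variants, "
                              "sensitivity estimators skipped")
        out.append(res)
    return out


def mvmr_per_cholesterol(inst: InstrumentSet):
    """Multivariable IVW of AAA on LDL-C and TRL-C effects (per 10 mg/dL
    cholesterol each) over the full instrument set, plus the
    per-cholesterol aneurysmogenicity ratio."""
    df = inst.sumstats.df
    B = np.column_stack([df["beta_LDL_C"].to_numpy(float) / 10.0,
                         df["beta_TRL_C"].to_numpy(float) / 10.0])
    estimates, cov = mvmr_ivw(B, df["beta_AAA"].to_numpy(float),
                              df["se_AAA"].to_numpy(float),
                              scales=("per 10 mg/dL LDL-C",
                                      "per 10 mg/dL TRL-C"))
    ratio = per_cholesterol_ratio(estimates, cov)
    return estimates, cov, ratio


# ---------------------------------------------------------------------------
def _lowering(est: MREstimate, scale: str) -> MREstimate:
    """Report a raising-allele estimate in the inhibition framing (per
    unit LOWER exposure): exact sign flip, OR is the reciprocal."""
    out = est.rescaled(-1.0, scale=scale)
    return out


def drug_target_mr(cis_map: Dict[str, InstrumentSet],
                   ms: MultiTraitSumstats,
                   groups: Optional[Dict[str, List[str]]] = None) -> dict:
    """Per-gene and per-pathway-group MR in the inhibition framing.

    Per gene and per pooled group: IVW with apoB exposure, sign-flipped
    to per 10 mg/dL lower apoB.  The per-mmol comparison re-runs each
    group with its own cholesterol trait (TRL-C for the TRL group,
    LDL-C for LDL) per 1 mmol/L, then takes the TRL:LDL ratio of the
    per-mmol lowering log-ORs.  Genes with no cis instruments are
    reported absent."""
    from .genes import PATHWAY_GROUPS
    groups = groups or PATHWAY_GROUPS
    lower_apob = "per 10 mg/dL lower apoB"

    per_gene: Dict[str, MREstimate] = {}
    for gene, inst in cis_map.items():
        if len(inst) == 0:
            warnings.warn(f"{gene}: no cis instruments; reported absent")
            continue
        bx, sx, by, sy = _set_arrays(ms, inst.variant_ids)
        per_gene[gene] = _lowering(ivw(bx, sx, by, sy, scale=PER_10_APOB),
                                   lower_apob)

    per_group: Dict[str, MREstimate] = {}
    per_group_mmol: Dict[str, MREstimate] = {}
    chol_trait = {"LDL": "LDL_C", "TRL": "TRL_C"}
    for group, genes in groups.items():
        ids: List[str] = []
        for g in genes:
            if g in cis_map:
                ids += [v for v in cis_map[g].variant_ids if v not in ids]
        if not ids:
            warnings.warn(f"group {group}: no instruments")
            continue
        bx, sx, by, sy = _set_arrays(ms, ids)
        per_group[group] = _lowering(ivw(bx, sx, by, sy, scale=PER_10_APOB),
                                     lower_apob)
        trait = chol_trait.get(group)
        if trait is not None:
            df = ms.df.set_index("variant_id").loc[ids]
            bxc = df[f"beta_{trait}"].to_numpy(float) / MGDL_PER_MMOL
            sxc = df[f"se_{trait}"].to_numpy(float) / MGDL_PER_MMOL
            per_group_mmol[group] = _lowering(
                ivw(bxc, sxc, by, sy, scale=f"per 1 mmol/L {trait}"),
                f"per 1 mmol/L lower {trait}")

    per_mmol_ratio = None
    if {"LDL", "TRL"} <= set(per_group_mmol):
        # ratio of risk-reduction magnitudes per mmol/L of the group's
        # own cholesterol measure
        per_mmol_ratio = ratio_of_estimates(
            per_group_mmol["TRL"].beta, per_group_mmol["TRL"].se,
            per_group_mmol["LDL"].beta, per_group_mmol["LDL"].se,
            numerator_ref="TRL group per mmol/L",
            denominator_ref="LDL group per mmol/L",
            independence_assumed=True)

    return {"per_gene": per_gene, "per_group": per_group,
            "per_group_mmol": per_group_mmol,
            "per_mmol_ratio": per_mmol_ratio}
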