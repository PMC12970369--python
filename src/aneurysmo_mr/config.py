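"""Simulation and pipeline configuration objects.

The generator's defaults define the study conditions for every analysis in
this package: a two-pathway lipid model in which each variant raises LDL
cholesterol (LDL-C) and triglyceride-rich-lipoprotein cholesterol (TRL-C)
in a variant-specific proportion, apolipoprotein B (apoB) tracks the two
cholesterol pools through fixed per-particle conversion factors, and the
log-odds of abdominal aortic aneurysm (AAA) is linear in the two
pathway-specific apoB components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass(frozen=True)
class EffectDist:
    """Normal spec for raw per-allele lipid effects, mg/dL per allele."""

    mean: float = 0.0
    sd: float = 1.2

    def validate(self) -> None:
        if not (self.sd > 0):
            raise ValueError(f"effect distribution sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class ShareSpectrum:
    """Beta-distribution spec for the per-variant TRL share of the
    non-HDL-C effect, s in [0, 1].

    The default U-shaped Beta(0.5, 0.5) yields many near-pure LDL and
    near-pure TRL variants plus a mixed middle, so a 10-way ranking spans
    TRL:LDL effect ratios from well below 0.2 to well above 3.
    """

    a: float = 0.5
    b: float = 0.5

    def validate(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("share spectrum Beta parameters must be > 0")


@dataclass(frozen=True)
class CovariateEffects:
    """Age/sex/PC effects on lipids (mg/dL) and on the AAA log-odds.

    Age is centred at 60 years internally.  AAA is strongly age- and
    male-sex-associated; lipid covariate effects are modest.
    """

    age_ldl: float = 0.2      # mg/dL per year
    age_trl: float = 0.15
    sex_ldl: float = 5.0      # male minus female, mg/dL
    sex_trl: float = 3.0
    age_outcome: float = 0.055  # log-odds per year
    sex_outcome: float = 0.9    # log-odds, male vs female
    pc_outcome: Tuple[float, ...] = (0.0,) * 10


@dataclass(frozen=True)
class LipidNoise:
    """Residual (non-genetic, non-covariate) SDs, mg/dL."""

    ldl: float = 25.0
    trl: float = 10.0
    hdl: float = 12.0
    apob: float = 8.0

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"lipid noise sd '{name}' must be >= 0, got {v}")


@dataclass(frozen=True)
class EHRConfig:
    """How latent AAA status surfaces as diagnosis codes.

    True cases usually receive two AAA codes on distinct dates; a small
    fraction receive only one (and are neither case nor comparator under
    the two-occurrence rule).  A small fraction of unaffected individuals
    carry some other vascular-disease code and are excluded from the
    comparator pool.  Irrelevant codes are sprinkled on everyone.
    """

    p_single_code_case: float = 0.05
    p_vascular_code_control: float = 0.04
    p_irrelevant_code: float = 0.30


@dataclass(frozen=True)
class CisLayout:
    """Planted cis-region variants for the seven drug-target genes and the
    LPA locus.

    Variants planted in LDL-pathway genes (PCSK9, HMGCR, NPC1L1, LDLR)
    draw their TRL share from a low-share Beta; TRL-pathway genes (LPL,
    APOC3, APOA5) from its mirror.  LPA-region variants get near-zero
    lipoprotein(a) p-values so the Lp(a) exclusion step has work to do.
    """

    variants_per_gene: int = 20
    lpa_variants: int = 28
    cis_rho: float = 0.25          # within-gene LD (below prune threshold)
    ldl_share_beta: Tuple[float, float] = (1.5, 13.5)   # mean share 0.10
    trl_share_beta: Tuple[float, float] = (13.5, 1.5)   # mean share 0.90

    def validate(self) -> None:
        if self.variants_per_gene < 0 or self.lpa_variants < 0:
            raise ValueError("planted variant counts must be >= 0")
        if not (0 <= self.cis_rho < 1):
            raise ValueError("cis_rho must be in [0, 1)")


# per 10 mg/dL pathway apoB; defaults reproduce a set-1 OR of 1.10 and a
# set-10 OR of 1.89 in a 10-way TRL-share partition.
DEFAULT_CAUSAL_LOGOR_LDL = math.log(1.10)
DEFAULT_CAUSAL_LOGOR_TRL = math.log(1.89)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic cohort / summary-statistics
    generators.  A fixed seed makes every output bit-reproducible.
    """

    seed: int = 0
    n_individuals: int = 20_000
    m_variants: int = 2_000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    ldl_effect_dist: EffectDist = field(default_factory=lambda: EffectDist(0.0, 1.2))
    trl_effect_dist: EffectDist = field(default_factory=lambda: EffectDist(0.0, 0.6))
    trl_share_spectrum: ShareSpectrum = field(default_factory=ShareSpectrum)
    # mg/dL apoB per mg/dL particle-class cholesterol
    apob_per_mgdl_ldl: float = 0.77
    apob_per_mgdl_trl: float = 0.63
    # AAA log-odds per 10 mg/dL pathway apoB
    causal_logor_ldl: float = DEFAULT_CAUSAL_LOGOR_LDL
    causal_logor_trl: float = DEFAULT_CAUSAL_LOGOR_TRL
    baseline_logodds: float = -3.5
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    ld_block_size: int = 4
    ld_rho: float = 0.35
    # two-sample mode: per-variant outcome / exposure SEs (constant)
    outcome_se_scale: float = 0.05
    exposure_se_scale: float = 0.05
    lipid_noise: LipidNoise = field(default_factory=LipidNoise)
    ldl_base: float = 130.0
    trl_base: float = 30.0
    hdl_mean: float = 55.0
    ehr: EHRConfig = field(default_factory=EHRConfig)
    cis: CisLayout = field(default_factory=CisLayout)

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be > 0")
        if self.m_variants <= 0:
            raise ValueError("m_variants must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must lie within (0, 1), got {self.maf_range}")
        if self.apob_per_mgdl_ldl <= 0 or self.apob_per_mgdl_trl <= 0:
            raise ValueError("apoB conversion factors must be > 0")
        if self.outcome_se_scale <= 0:
            raise ValueError("outcome_se_scale must be > 0")
        if self.exposure_se_scale < 0:
            raise ValueError("exposure_se_scale must be >= 0")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        self.ldl_effect_dist.validate()
        self.trl_effect_dist.validate()
        self.trl_share_spectrum.validate()
        self.lipid_noise.validate()
        self.cis.validate()
        n_planted = 7 * self.cis.variants_per_gene + self.cis.lpa_variants
        if self.m_variants < n_planted:
            raise ValueError(
                f"m_variants={self.m_variants} smaller than the "
                f"{n_planted} planted cis/LPA variants"
            )

    @property
    def true_per_apob_ratio(self) -> float:
        return self.causal_logor_trl / self.causal_logor_ldl

    @property
    def true_per_cholesterol_ratio(self) -> float:
        """TRL-C vs LDL-C aneurysmogenicity per mg/dL cholesterol."""
        return (self.causal_logor_trl * self.apob_per_mgdl_trl) / (
            self.causal_logor_ldl * self.apob_per_mgdl_ldl
        )
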