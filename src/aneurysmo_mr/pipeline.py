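"""End-to-end orchestration: simulate -> instruments -> variant sets ->
MR -> ratio statistics -> PRS/interaction -> results bundle.

Every stage is a plain function over in-memory objects with load/save
helpers for the declared file formats, so stages are independently
re-runnable from the CLI.  A fixed global seed makes the whole bundle
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (CisLayout, CovariateEffects, EffectDist, EHRConfig,
                     LipidNoise, ShareSpectrum, SimConfig)
from .genes import DRUG_TARGET_REGIONS, PATHWAY_GROUPS, read_gene_regions
from .instruments import (InstrumentSet, VariantSetPartition,
                          partition_variant_sets, select_cis_instruments,
                          select_instruments)
from .prs import compute_prs, fit_prs_logistic, interaction_analysis
from .ratios import (drug_target_mr, mvmr_per_cholesterol,
                     relative_aneurysmogenicity, variant_set_mr)
from .simulate import simulate_cohort, simulate_two_sample_sumstats
from .sumstats import MultiTraitSumstats, orient_to_raising_allele

logger = logging.getLogger("aneurysmo_mr")


# ---------------------------------------------------------------------------
@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    k_sets: int = 10
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    window_bp: int = 20_000_000
    maf_min: float = 0.01
    cis_flank_kb: float = 200.0
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    out_dir: str = "results/pipeline"
    log_level: str = "INFO"
    sensitivity: bool = True
    individual_level: bool = True
    make_plots: bool = False
    cis_regions_file: Optional[str] = None

    def __post_init__(self):
        # global seed propagates to every stochastic stage
        self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    def validate(self) -> None:
        if self.k_sets < 1:
            raise ValueError("k_sets must be >= 1")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.n_boot < 1 or self.n_sim < 1:
            raise ValueError("n_boot and n_sim must be >= 1")
        self.sim.validate()

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


_NESTED_FIELDS = {
    "ldl_effect_dist": EffectDist, "trl_effect_dist": EffectDist,
    "trl_share_spectrum": ShareSpectrum, "covariate_effects": CovariateEffects,
    "lipid_noise": LipidNoise, "ehr": EHRConfig, "cis": CisLayout,
}


def _build_dataclass(cls, data: dict, path: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {path}{key!r}{suffix}")
        if key == "sim":
            kwargs[key] = _build_dataclass(SimConfig, value, f"{path}sim.")
        elif key in _NESTED_FIELDS and isinstance(value, dict):
            kwargs[key] = _build_dataclass(_NESTED_FIELDS[key], value,
                                           f"{path}{key}.")
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v
                                for v in value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def validate_config(path) -> RunConfig:
    """Load a YAML run config, fill defaults, reject unknown keys (with a
    nearest-key suggestion) and validate values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _build_dataclass(RunConfig, data, "")
    cfg.validate()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def demo_config(seed: int = 0, out_dir: str = "results/pipeline") -> RunConfig:
    """A small configuration that runs the full pipeline in seconds."""
    sim = SimConfig(seed=seed, n_individuals=8000, m_variants=700,
                    outcome_se_scale=0.05)
    return RunConfig(sim=sim, seed=seed, out_dir=out_dir,
                     n_boot=100, n_sim=200, sensitivity=False)


# ---------------------------------------------------------------------------
def _json_dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def save_partition(part: VariantSetPartition, path) -> None:
    _json_dump({"k": part.k, "sets": part.sets,
                "mean_share": part.mean_share,
                "ratio_range": [list(r) for r in part.ratio_range],
                "roles": {str(k): v for k, v in part.roles.items()}}, path)


def load_partition(path) -> VariantSetPartition:
    with open(path) as fh:
        d = json.load(fh)
    return VariantSetPartition(
        sets=d["sets"], mean_share=d["mean_share"],
        ratio_range=[tuple(r) for r in d["ratio_range"]],
        roles={int(k): v for k, v in d["roles"].items()})


def set_mr_table(set_results: List[Dict], part: VariantSetPartition
                 ) -> pd.DataFrame:
    rows = []
    for i, res in enumerate(set_results):
        for method, est in res.items():
            rows.append({"set": i + 1, "mean_trl_share": part.mean_share[i],
                         **est.to_dict()})
    df = pd.DataFrame(rows)
    return df.drop(columns=[c for c in ("outlier_ids",) if c in df.columns])


# ---------------------------------------------------------------------------
def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on synthetic data and write the results
    bundle, a manifest and a log under ``config.out_dir``."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    handler = logging.FileHandler(os.path.join(out, "pipeline.log"), mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    bundle: dict = {"config_seed": config.seed, "stages": {}}
    try:
        # --- stage: simulate ------------------------------------------
        logger.info("=== stage: simulate (two-sample) ===")
        ms, truth = simulate_two_sample_sumstats(config.sim)
        ms.write(os.path.join(out, "sumstats.tsv"))
        bundle["truth"] = {
            "causal_logor_ldl": truth.causal_logor_ldl,
            "causal_logor_trl": truth.causal_logor_trl,
            "per_apob_ratio": truth.per_apob_ratio,
            "per_cholesterol_ratio": truth.per_cholesterol_ratio,
        }

        # --- stage: select -------------------------------------------
        logger.info("=== stage: select instruments ===")
        oriented = orient_to_raising_allele(ms)
        inst = select_instruments(
            oriented, ld=truth.ld(), p_threshold=config.p_threshold,
            r2_threshold=config.r2_threshold, window_bp=config.window_bp,
            maf_min=config.maf_min)
        inst.sumstats.write(os.path.join(out, "instruments.tsv"))
        inst.provenance.to_csv(os.path.join(out, "provenance.tsv"),
                               sep="\t", index=False)
        prov = inst.provenance
        bundle["stages"]["select"] = {
            "n_candidates": int(len(prov)),
            "n_retained": int(prov["retained"].sum()),
            "n_pruned": int(prov["pruned_out"].sum()),
            "n_maf_failed": int(prov["maf_failed"].sum()),
            "n_lpa_excluded": int(prov["lpa_excluded"].sum()),
        }
        logger.info("retained %d of %d candidates",
                    prov["retained"].sum(), len(prov))

        # --- stage: partition -----------------------------------------
        logger.info("=== stage: partition into %d sets ===", config.k_sets)
        part = partition_variant_sets(inst, k=config.k_sets)
        save_partition(part, os.path.join(out, "partition.json"))

        # --- stage: variant-set MR ------------------------------------
        logger.info("=== stage: variant-set MR ===")
        set_results = variant_set_mr(
            part, inst.sumstats, sensitivity=config.sensitivity,
            n_boot=config.n_boot, n_sim=config.n_sim,
            seed=config.stage_seed("set_mr"))
        tbl = set_mr_table(set_results, part)
        tbl.to_csv(os.path.join(out, "set_mr.tsv"), sep="\t", index=False,
                   float_format="%.10g")
        bundle["set_mr"] = [
            {m: e.to_dict() for m, e in res.items()} for res in set_results]
        bundle["mean_trl_share"] = part.mean_share

        # --- stage: summary-level ratios ------------------------------
        logger.info("=== stage: ratio statistics ===")
        rel_sum = relative_aneurysmogenicity(set_results[-1]["ivw"],
                                             set_results[0]["ivw"])
        mv_est, mv_cov, per_chol = mvmr_per_cholesterol(inst)
        bundle["relative_aneurysmogenicity_summary"] = rel_sum.to_dict()
        bundle["mvmr"] = {"ldl": mv_est[0].to_dict(),
                          "trl": mv_est[1].to_dict(),
                          "cov": mv_cov.tolist()}
        bundle["per_cholesterol_ratio"] = per_chol.to_dict()

        # --- stage: drug targets --------------------------------------
        logger.info("=== stage: drug-target MR ===")
        regions = (read_gene_regions(config.cis_regions_file)
                   if config.cis_regions_file else DRUG_TARGET_REGIONS)
        cis_map = select_cis_instruments(
            inst, regions, flank_bp=int(config.cis_flank_kb * 1000))
        dt = drug_target_mr(cis_map, inst.sumstats, groups=PATHWAY_GROUPS)
        bundle["drug_targets"] = {
            "per_gene": {g: e.to_dict() for g, e in dt["per_gene"].items()},
            "per_group": {g: e.to_dict() for g, e in dt["per_group"].items()},
            "per_group_mmol": {g: e.to_dict()
                               for g, e in dt["per_group_mmol"].items()},
            "per_mmol_ratio": (dt["per_mmol_ratio"].to_dict()
                               if dt["per_mmol_ratio"] else None),
        }

        # --- stage: individual level ----------------------------------
        if config.individual_level:
            logger.info("=== stage: individual-level PRS ===")
            cohort, _ = simulate_cohort(config.sim)
            idf = inst.sumstats.df.set_index("variant_id")
            apob = idf["beta_APOB"]
            alleles = idf["effect_allele"].to_dict()
            prs_results = []
            for ids in part.sets:
                weights = {v: float(apob.loc[v]) for v in ids}
                pr = compute_prs(cohort, weights, effect_alleles=alleles)
                prs_results.append(fit_prs_logistic(pr.scores, cohort))
            bundle["prs_set_logistic"] = [e.to_dict() for e in prs_results]
            rel_ind = relative_aneurysmogenicity(prs_results[-1],
                                                 prs_results[0])
            bundle["relative_aneurysmogenicity_individual"] = rel_ind.to_dict()

            statin_idx = 2 if config.k_sets >= 3 else 0
            w_a = {v: float(apob.loc[v]) for v in part.sets[statin_idx]}
            w_b = {v: float(apob.loc[v]) for v in part.sets[-1]}
            prs_a = compute_prs(cohort, w_a, effect_alleles=alleles)
            prs_b = compute_prs(cohort, w_b, effect_alleles=alleles)
            pd.DataFrame({"sample_id": prs_a.scores.index,
                          "prs_statin_like": prs_a.scores.to_numpy(),
                          "prs_trl": prs_b.scores.to_numpy()}).to_csv(
                os.path.join(out, "prs_scores.tsv"), sep="\t", index=False,
                float_format="%.10g")
            inter = interaction_analysis(
                prs_a.scores, prs_b.scores, cohort,
                n_boot=config.n_boot, seed=config.stage_seed("interaction"))
            bundle["interaction"] = inter.to_dict()
            _json_dump(inter.to_dict(), os.path.join(out, "interaction.json"))

        # --- report ----------------------------------------------------
        bundle_path = os.path.join(out, "bundle.json")
        _json_dump(bundle, bundle_path)
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "stage_seeds": {s: config.stage_seed(s)
                            for s in ("set_mr", "interaction")},
            "config": config_to_dict(config),
            "digests": {f: _sha256(os.path.join(out, f))
                        for f in sorted(os.listdir(out))
                        if f.endswith((".tsv", ".json"))
                        and f != "manifest.json"},
        }
        _json_dump(manifest, os.path.join(out, "manifest.json"))
        if config.make_plots:
            forest_plot(tbl, os.path.join(out, "forest_set_mr.svg"))
        logger.info("pipeline complete: %s", bundle_path)
        return bundle
    except Exception:
        logger.exception("pipeline stage failed; partial outputs retained "
                         "in %s", out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def forest_plot(set_table: pd.DataFrame, path) -> None:
    """Minimal forest-plot export of the per-set IVW odds ratios."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ivw_rows = set_table[set_table["method"].isin(["ivw_mre", "ivw_fixed",
                                                   "wald"])]
    fig, ax = plt.subplots(figsize=(5, 4))
    y = ivw_rows["set"]
    ax.errorbar(ivw_rows["odds_ratio"], y,
                xerr=[ivw_rows["odds_ratio"] - np.exp(ivw_rows["ci_low"]),
                      np.exp(ivw_rows["ci_high"]) - ivw_rows["odds_ratio"]],
                fmt="o", color="black", ecolor="gray", capsize=2)
    ax.axvline(1.0, color="red", lw=0.8, ls="--")
    ax.set_xlabel("AAA OR per 10 mg/dL apoB")
    ax.set_ylabel("variant set (1 = LDL-specific)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
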