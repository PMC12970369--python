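"""Individual-level analyses: polygenic scores on the apoB scale,
logistic AAA models, and multiplicative/additive interaction between two
scores.

Scores are weighted allele-dosage sums (weights = apoB betas, mg/dL per
allele) divided by 10, so one score unit represents 10 mg/dL apoB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mr import MREstimate
from .simulate import CohortTable

PRS_COVARIATES = ("age", "sex") + tuple(f"PC{i}" for i in range(1, 11))


@dataclass
class PRSResult:
    scores: pd.Series               # index sample_id, units of 10 mg/dL apoB
    weights: pd.DataFrame           # variant_id, apob_beta
    scaling: float = 10.0
    n_missing: int = 0


def compute_prs(cohort: CohortTable, weights: Mapping[str, float],
                effect_alleles: Optional[Mapping[str, str]] = None
                ) -> PRSResult:
    """score_i = sum_v dosage_iv * beta_v / 10.

    ``effect_alleles`` maps variant -> the allele each weight refers to;
    where it is the cohort's other allele the dosage is flipped to
    2 - dosage (as PLINK does when scoring), so weights from
    raising-allele-oriented summary statistics score correctly."""
    vm = cohort.variants
    index = {v: i for i, v in enumerate(vm["variant_id"])}
    absent = [v for v in weights if v not in index]
    if absent:
        raise ValueError(f"weight variants absent from cohort: {absent[:5]}")
    cols = [index[v] for v in weights]
    w = np.asarray(list(weights.values()), dtype=float)
    dos = cohort.dosages[:, cols].astype(float)
    if effect_alleles is not None:
        ea = vm["effect_allele"].to_numpy()
        oa = vm["other_allele"].to_numpy()
        for j, v in enumerate(weights):
            want = effect_alleles[v]
            i = index[v]
            if want == ea[i]:
                continue
            if want == oa[i]:
                dos[:, j] = 2.0 - dos[:, j]
            else:
                raise ValueError(
                    f"{v}: weight allele {want!r} matches neither cohort "
                    f"allele ({ea[i]}/{oa[i]})")
    score = dos @ w / 10.0
    missing = np.isnan(dos).any(axis=1)
    score[missing] = np.nan
    scores = pd.Series(score, index=pd.Index(cohort.samples["sample_id"],
                                             name="sample_id"), name="prs")
    wdf = pd.DataFrame({"variant_id": list(weights), "apob_beta": w})
    return PRSResult(scores=scores, weights=wdf, n_missing=int(missing.sum()))


# ---------------------------------------------------------------------------
class SeparationError(RuntimeError):
    """Logistic fit failed to converge (e.g. perfect separation)."""


def _logit_fit(y: np.ndarray, X: np.ndarray) -> sm.Logit:
    import warnings as _w
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    with _w.catch_warnings():
        _w.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationWarning, Exception) as exc:  # noqa: BLE001
            if isinstance(exc, np.linalg.LinAlgError) or \
                    "Separation" in type(exc).__name__ or \
                    "separation" in str(exc).lower() or \
                    "Singular" in str(exc):
                raise SeparationError(f"logistic fit failed: {exc}") from exc
            raise
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge "
                              "(possible separation)")
    return res


def _analysis_frame(cohort: CohortTable) -> pd.DataFrame:
    s = cohort.samples
    sub = s[s["aaa_status"].isin(["case", "comparator"])].copy()
    sub["y"] = (sub["aaa_status"] == "case").astype(int)
    return sub


def fit_prs_logistic(scores: pd.Series, cohort: CohortTable,
                     covariates: Tuple[str, ...] = PRS_COVARIATES
                     ) -> MREstimate:
    """Logistic regression of AAA case status (cases vs clean
    comparators; excluded individuals dropped) on the score with
    covariate adjustment.  Reports the log-OR per score unit, i.e. per
    10 mg/dL apoB."""
    sub = _analysis_frame(cohort)
    sc = scores.reindex(sub["sample_id"]).to_numpy(float)
    ok = ~np.isnan(sc)
    sub, sc = sub.loc[ok], sc[ok]
    X = np.column_stack([np.ones(len(sub)), sc]
                        + [sub[c].to_numpy(float) for c in covariates])
    res = _logit_fit(sub["y"].to_numpy(), X)
    return MREstimate(method="prs_logistic", beta=float(res.params[1]),
                      se=float(res.bse[1]), scale="per 10 mg/dL apoB",
                      n_variants=0)


# ---------------------------------------------------------------------------
@dataclass
class InteractionResult:
    mult_coef: float
    mult_se: float
    mult_p: float
    ic: float
    ic_ci: Tuple[float, float]
    n_boot: int
    seed: int
    or_b_at_a_mean: float
    or_b_at_a_p75: float
    rd_at_a_p25: float
    rd_at_a_p75: float
    cells: Dict[str, float] = field(default_factory=dict)
    percentiles: Tuple[float, float] = (25.0, 75.0)

    def to_dict(self) -> dict:
        return {"multiplicative": {"coef": self.mult_coef, "se": self.mult_se,
                                   "p": self.mult_p},
                "interaction_contrast": {"ic": self.ic,
                                         "ci_low": self.ic_ci[0],
                                         "ci_high": self.ic_ci[1],
                                         "n_boot": self.n_boot,
                                         "seed": self.seed},
                "or_prs_b": {"at_a_mean": self.or_b_at_a_mean,
                             "at_a_p75": self.or_b_at_a_p75},
                "risk_difference_per_unit_b": {"at_a_p25": self.rd_at_a_p25,
                                               "at_a_p75": self.rd_at_a_p75},
                "cells": self.cells,
                "percentiles": list(self.percentiles)}


def _gcomp_cells(params: np.ndarray, a: np.ndarray, b: np.ndarray,
                 Z: np.ndarray, lo: float, hi: float,
                 pcts: Tuple[float, float]):
    """Predicted AAA probability averaged over the empirical covariate
    distribution, at the four (A anchor) x (B anchor, anchor+1) points.
    B is anchored at its lower percentile."""
    from scipy.special import expit
    b0 = float(np.percentile(b, pcts[0]))
    cells = {}
    for a_lab, a_val in (("loA", lo), ("hiA", hi)):
        for b_lab, b_val in (("loB", b0), ("hiB", b0 + 1.0)):
            eta = (params[0] + params[1] * a_val + params[2] * b_val
                   + params[3] * a_val * b_val + Z @ params[4:])
            cells[f"{a_lab}_{b_lab}"] = float(np.mean(expit(eta)))
    return cells


def interaction_analysis(prs_a: pd.Series, prs_b: pd.Series,
                         cohort: CohortTable,
                         percentiles: Tuple[float, float] = (25.0, 75.0),
                         n_boot: int = 1000, seed: int = 0,
                         covariates: Tuple[str, ...] = PRS_COVARIATES
                         ) -> InteractionResult:
    """Multiplicative and additive interaction between two apoB-scale
    polygenic scores.

    Fits logit(AAA) ~ A + B + A*B + covariates, then standardises
    predicted probabilities over the empirical covariate distribution
    (g-computation) to form the interaction contrast
    IC = [p(hiA,hiB) - p(hiA,loB)] - [p(loA,hiB) - p(loA,loB)] at the
    25th/75th percentile anchors of A with B moved one unit (10 mg/dL
    apoB) from its 25th-percentile anchor.  CI by percentile bootstrap
    over individuals (anchors recomputed per resample)."""
    sub = _analysis_frame(cohort)
    a = prs_a.reindex(sub["sample_id"]).to_numpy(float)
    b = prs_b.reindex(sub["sample_id"]).to_numpy(float)
    ok = ~(np.isnan(a) | np.isnan(b))
    sub, a, b = sub.loc[ok], a[ok], b[ok]
    y = sub["y"].to_numpy()
    Z = (np.column_stack([sub[c].to_numpy(float) for c in covariates])
         if covariates else np.zeros((len(sub), 0)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate (constant) polygenic score")

    def fit_and_cells(y_, a_, b_, Z_):
        X = np.column_stack([np.ones(len(y_)), a_, b_, a_ * b_, Z_])
        res = _logit_fit(y_, X)
        lo = float(np.percentile(a_, percentiles[0]))
        hi = float(np.percentile(a_, percentiles[1]))
        cells = _gcomp_cells(res.params, a_, b_, Z_, lo, hi, percentiles)
        ic = ((cells["hiA_hiB"] - cells["hiA_loB"])
              - (cells["loA_hiB"] - cells["loA_loB"]))
        return res, cells, ic, lo, hi

    res, cells, ic, lo_a, hi_a = fit_and_cells(y, a, b, Z)

    rng = np.random.default_rng(seed)
    ics = np.empty(n_boot)
    n = len(y)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            _, _, ics[i], _, _ = fit_and_cells(y[idx], a[idx], b[idx], Z[idx])
        except SeparationError:
            ics[i] = np.nan
    ics = ics[~np.isnan(ics)]
    ci = (float(np.percentile(ics, 2.5)), float(np.percentile(ics, 97.5))) \
        if len(ics) else (np.nan, np.nan)

    # OR of B per unit at A = mean and A = 75th percentile
    b_b, b_ab = float(res.params[2]), float(res.params[3])
    or_mean = float(np.exp(b_b + b_ab * float(np.mean(a))))
    or_p75 = float(np.exp(b_b + b_ab * hi_a))
    rd_lo = cells["loA_hiB"] - cells["loA_loB"]
    rd_hi = cells["hiA_hiB"] - cells["hiA_loB"]

    return InteractionResult(
        mult_coef=b_ab, mult_se=float(res.bse[3]),
        mult_p=float(res.pvalues[3]), ic=float(ic), ic_ci=ci,
        n_boot=n_boot, seed=seed, or_b_at_a_mean=or_mean,
        or_b_at_a_p75=or_p75, rd_at_a_p25=float(rd_lo),
        rd_at_a_p75=float(rd_hi), cells=cells, percentiles=percentiles)
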