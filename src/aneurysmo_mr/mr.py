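"""Two-sample Mendelian-randomization estimators.

All estimators operate on per-variant exposure/outcome effect vectors
(b_exp, b_out) with outcome SEs, weight by 1/se_out^2, and report the
causal log-odds per declared exposure unit with a normal-approximation
95% CI.  The multiplicative random-effects convention inflates the
fixed-effect SE by sqrt(max(1, Q/df)) and never shrinks it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

Z95 = 1.959963984540054


@dataclass
class MREstimate:
    """A causal-effect estimate on a declared exposure scale."""

    method: str
    beta: float
    se: float
    scale: str = ""
    n_variants: int = 0
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    outlier_ids: Optional[List[str]] = None
    global_p: Optional[float] = None
    distortion: Optional[float] = None
    unstable: bool = False

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def rescaled(self, factor: float, scale: str = "") -> "MREstimate":
        """Exact unit change: beta and se multiplied by ``factor``."""
        out = MREstimate(**{**self.__dict__})
        out.beta = self.beta * factor
        out.se = abs(self.se * factor)
        out.scale = scale or self.scale
        return out

    def to_dict(self) -> dict:
        d = {"method": self.method, "scale": self.scale, "beta": self.beta,
             "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
             "odds_ratio": self.odds_ratio, "n_variants": self.n_variants,
             "q_stat": self.q_stat, "q_df": self.q_df}
        for k in ("egger_intercept", "egger_intercept_se", "outlier_ids",
                  "global_p", "distortion"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.unstable:
            d["unstable"] = True
        return d


def _as_arrays(*vecs):
    out = [np.asarray(v, dtype=float) for v in vecs]
    k = len(out[0])
    if any(len(v) != k for v in out):
        raise ValueError("input vectors must have equal length")
    return out


# ---------------------------------------------------------------------------
def ivw(b_exp, se_exp, b_out, se_out, random_effects: bool = True,
        scale: str = "") -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of b_out on b_exp through
    the origin with weights 1/se_out^2.  With one variant this is the
    Wald ratio b_out/b_exp."""
    b_exp, se_exp, b_out, se_out = _as_arrays(b_exp, se_exp, b_out, se_out)
    k = len(b_exp)
    if k == 0:
        raise ValueError("ivw requires at least one variant")
    if np.all(b_exp == 0):
        raise ValueError("all exposure betas are zero")
    if np.any(se_out <= 0):
        raise ValueError("outcome SEs must be > 0")
    w = 1.0 / se_out ** 2
    sxx = float(np.sum(w * b_exp ** 2))
    beta = float(np.sum(w * b_exp * b_out)) / sxx
    se_fe = np.sqrt(1.0 / sxx)
    resid = b_out - beta * b_exp
    q = float(np.sum(w * resid ** 2))
    df = k - 1
    se = se_fe
    method = "ivw_fixed"
    if k == 1:
        method = "wald"
    elif random_effects:
        se = se_fe * np.sqrt(max(1.0, q / df))
        method = "ivw_mre"
    return MREstimate(method=method, beta=beta, se=float(se), scale=scale,
                      n_variants=k, q_stat=q if k > 1 else None,
                      q_df=df if k > 1 else None)


# ---------------------------------------------------------------------------
def mr_egger(b_exp, se_exp, b_out, se_out, scale: str = "") -> MREstimate:
    """MR-Egger: weighted regression of b_out on b_exp with intercept,
    after orienting each variant to a non-negative exposure beta.  The
    intercept is the directional-pleiotropy diagnostic; the slope is the
    causal estimate, with multiplicative RE scaling on df k-2."""
    b_exp, se_exp, b_out, se_out = _as_arrays(b_exp, se_exp, b_out, se_out)
    k = len(b_exp)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    flip = np.sign(b_exp)
    flip[flip == 0] = 1.0
    x = b_exp * flip
    y = b_out * flip
    w = 1.0 / se_out ** 2
    X = np.column_stack([np.ones(k), x])
    A = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid ** 2))
    scale_fac = max(1.0, q / (k - 2))
    cov = np.linalg.inv(A) * scale_fac
    return MREstimate(method="egger", beta=float(coef[1]),
                      se=float(np.sqrt(cov[1, 1])), scale=scale,
                      n_variants=k, q_stat=q, q_df=k - 2,
                      egger_intercept=float(coef[0]),
                      egger_intercept_se=float(np.sqrt(cov[0, 0])))


# ---------------------------------------------------------------------------
def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(b_exp, se_exp, b_out, se_out, n_boot: int = 1000,
                    seed: int = 0, scale: str = "") -> MREstimate:
    """Weighted median of per-variant Wald ratios, weights proportional to
    the inverse first-order variance of each ratio; SE by seeded
    parametric bootstrap of b_out (and b_exp when se_exp > 0)."""
    b_exp, se_exp, b_out, se_out = _as_arrays(b_exp, se_exp, b_out, se_out)
    nonzero = b_exp != 0
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} variant(s) with "
                      "zero exposure beta (Wald ratio undefined)")
        b_exp, se_exp, b_out, se_out = (v[nonzero] for v in
                                        (b_exp, se_exp, b_out, se_out))
    k = len(b_exp)
    if k < 3:
        raise ValueError("weighted median requires at least 3 usable variants")
    ratios = b_out / b_exp
    var = se_out ** 2 / b_exp ** 2 + b_out ** 2 * se_exp ** 2 / b_exp ** 4
    weights = 1.0 / var
    est = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bo = rng.normal(b_out, se_out)
        bx = rng.normal(b_exp, se_exp) if np.any(se_exp > 0) else b_exp
        ok = bx != 0
        r = bo[ok] / bx[ok]
        v = se_out[ok] ** 2 / bx[ok] ** 2 + bo[ok] ** 2 * se_exp[ok] ** 2 / bx[ok] ** 4
        boots[i] = _weighted_median(r, 1.0 / v)
    se = float(np.std(boots, ddof=1))
    se = max(se, np.finfo(float).tiny)
    return MREstimate(method="weighted_median", beta=est, se=se, scale=scale,
                      n_variants=k)


# ---------------------------------------------------------------------------
def _loo_ivw_betas(b_exp, b_out, w):
    """Closed-form leave-one-out IVW slopes."""
    sxy = np.sum(w * b_exp * b_out)
    sxx = np.sum(w * b_exp ** 2)
    num = sxy - w * b_exp * b_out
    den = sxx - w * b_exp ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, sxy / sxx)


def mr_presso(b_exp, se_exp, b_out, se_out, n_sim: int = 1000, seed: int = 0,
              outlier_p: float = 0.05, variant_ids=None,
              scale: str = "") -> MREstimate:
    """MR-PRESSO-style residual-sum-of-squares outlier test.

    The observed RSS uses leave-one-out expected outcome values; its null
    distribution comes from ``n_sim`` parametric simulations under the
    IVW fit.  Per-variant outlier p-values (from each variant's simulated
    residual distribution, Bonferroni-adjusted) flag outliers, which are
    removed before re-running IVW.  On outlier-free data the corrected
    estimate equals plain IVW exactly.  The distortion field reports the
    relative difference between corrected and uncorrected estimates.
    """
    b_exp, se_exp, b_out, se_out = _as_arrays(b_exp, se_exp, b_out, se_out)
    k = len(b_exp)
    if k < 4:
        raise ValueError("MR-PRESSO requires at least 4 variants")
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} is small; p-values will be coarse")
    ids = list(variant_ids) if variant_ids is not None \
        else [str(i) for i in range(k)]

    w = 1.0 / se_out ** 2
    loo = _loo_ivw_betas(b_exp, b_out, w)
    resid_obs = b_out - loo * b_exp
    rss_obs = float(np.sum(w * resid_obs ** 2))

    rng = np.random.default_rng(seed)
    y_sim = rng.normal(loo[None, :] * b_exp[None, :],
                       se_out[None, :], size=(n_sim, k))
    sxy = y_sim @ (w * b_exp)
    sxx = float(np.sum(w * b_exp ** 2))
    num = sxy[:, None] - (w * b_exp)[None, :] * y_sim
    den = sxx - (w * b_exp ** 2)[None, :]
    loo_sim = num / den
    resid_sim = y_sim - loo_sim * b_exp[None, :]
    rss_sim = np.sum(w[None, :] * resid_sim ** 2, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    contrib_obs = w * resid_obs ** 2
    contrib_sim = w[None, :] * resid_sim ** 2
    p_var = (1 + np.sum(contrib_sim >= contrib_obs[None, :], axis=0)) / (n_sim + 1)
    outliers = np.minimum(p_var * k, 1.0) < outlier_p

    keep = ~outliers
    uncorrected = ivw(b_exp, se_exp, b_out, se_out, scale=scale)
    if outliers.any() and keep.sum() >= 1:
        corrected = ivw(b_exp[keep], se_exp[keep], b_out[keep], se_out[keep],
                        scale=scale)
    else:
        corrected = uncorrected
    distortion = (corrected.beta - uncorrected.beta) / uncorrected.beta \
        if uncorrected.beta != 0 else np.nan
    return MREstimate(method="presso_corrected", beta=corrected.beta,
                      se=corrected.se, scale=scale,
                      n_variants=int(keep.sum()),
                      q_stat=corrected.q_stat, q_df=corrected.q_df,
                      outlier_ids=[ids[i] for i in np.flatnonzero(outliers)],
                      global_p=global_p, distortion=float(distortion))


# ---------------------------------------------------------------------------
def mvmr_ivw(B_exposures: np.ndarray, b_out, se_out,
             scales: Tuple[str, str] = ("", "")
             ) -> Tuple[List[MREstimate], np.ndarray]:
    """Multivariable IVW: WLS of b_out on the exposure-beta columns
    jointly, no intercept, weights 1/se_out^2, multiplicative RE scaling
    with df k - p.  Returns per-exposure estimates and the full p x p
    coefficient covariance for downstream ratio CIs."""
    B = np.asarray(B_exposures, dtype=float)
    b_out, se_out = (np.asarray(v, dtype=float) for v in (b_out, se_out))
    if B.ndim != 2:
        raise ValueError("exposure matrix must be 2-D (k x p)")
    k, p = B.shape
    if k < p + 1:
        raise ValueError(f"need at least {p + 1} variants for {p} exposures")
    if np.linalg.matrix_rank(B) < p:
        raise ValueError("rank-deficient exposure matrix (collinear instruments)")
    w = 1.0 / se_out ** 2
    A = B.T @ (w[:, None] * B)
    coef = np.linalg.solve(A, B.T @ (w * b_out))
    resid = b_out - B @ coef
    q = float(np.sum(w * resid ** 2))
    scale_fac = max(1.0, q / (k - p))
    cov = np.linalg.inv(A) * scale_fac

    cond = np.linalg.cond(A)
    estimates = []
    for j in range(p):
        se_j = float(np.sqrt(cov[j, j]))
        est = MREstimate(method="mvmr_ivw", beta=float(coef[j]), se=se_j,
                         scale=scales[j] if j < len(scales) else "",
                         n_variants=k, q_stat=q, q_df=k - p,
                         unstable=bool(cond > 1e8
                                       or abs(coef[j]) < 2 * se_j))
        estimates.append(est)
    return estimates, cov
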