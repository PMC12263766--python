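"""Two-sample Mendelian randomization estimators on summary statistics.

Given harmonized per-variant associations (gamma_j, sigma_Xj) with the
exposure and (Gamma_j, sigma_Yj) with the outcome, each estimator combines
the per-variant ratio estimates theta_j = Gamma_j / gamma_j into a causal
effect of the exposure on the outcome:

* ratio — single-variant Wald estimate, first-order delta-method SE;
* IVW — inverse-variance weighted average with weights
  w_j = gamma_j^2 / sigma_Yj^2, equivalently weighted least squares of Gamma
  on gamma through the origin; fixed-effect or multiplicative-random-effects
  (MRE) standard errors, the MRE scale floored at 1;
* MR-Egger — the same weighted regression with an intercept, after orienting
  every variant so gamma_j > 0; a non-zero intercept indicates directional
  horizontal pleiotropy;
* weighted median — the 50% weighted quantile of the theta_j, consistent when
  valid instruments carry at least half the weight; SE by seeded parametric
  bootstrap.

All estimators are written directly from the defining formulas (no
regression library underneath) so their behaviour is fully specified here.
Confidence intervals are normal-approximation 95% throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonization import HarmonizedInstrumentSet, HarmonizedPair

__all__ = [
    "MREstimate",
    "ratio_estimate",
    "ivw_estimate",
    "egger_estimate",
    "weighted_median_estimate",
    "cochran_q",
    "ivw_arrays",
    "egger_arrays",
    "weighted_median_arrays",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty and diagnostics."""

    method: str  # ratio | ivw_fixed | ivw_mre | egger | weighted_median
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_variants: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        egger_block = (
            self.egger_intercept is not None
            and self.egger_intercept_se is not None
            and self.egger_intercept_p is not None
        )
        if (self.method == "egger") != egger_block:
            raise ValueError("egger intercept block present iff method == egger")

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_variants": self.n_variants,
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
        }


def _wald_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def _finish(method: str, beta: float, se: float, n: int, **kw) -> MREstimate:
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        pval=_wald_p(beta, se),
        n_variants=n,
        **kw,
    )


def _arrays(hset: HarmonizedInstrumentSet):
    g = np.array([p.exposure_beta for p in hset.pairs], dtype=float)
    sg = np.array([p.exposure_se for p in hset.pairs], dtype=float)
    G = np.array([p.outcome_beta for p in hset.pairs], dtype=float)
    sG = np.array([p.outcome_se for p in hset.pairs], dtype=float)
    return g, sg, G, sG


# ---------------------------------------------------------------------------
# ratio
# ---------------------------------------------------------------------------


def ratio_estimate(pair: HarmonizedPair) -> MREstimate:
    """Single-variant Wald ratio: beta = Gamma/gamma, se = sigma_Y/|gamma|."""
    gamma = pair.exposure_beta
    if gamma == 0:
        raise ValueError(
            f"exposure beta is 0 for {pair.variant_id}: ratio undefined"
        )
    beta = pair.outcome_beta / gamma
    se = pair.outcome_se / abs(gamma)
    return _finish("ratio", beta, se, 1)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------


def ivw_arrays(
    gamma: np.ndarray,
    Gamma: np.ndarray,
    se_out: np.ndarray,
    model: str = "ivw_mre",
) -> tuple[float, float, float, int]:
    """IVW on raw arrays; returns (beta, se, Q, df).

    Computed as weighted least squares of Gamma on gamma through the origin
    with weights 1/se_out^2, which tolerates gamma = 0 entries.
    """
    gamma = np.asarray(gamma, float)
    Gamma = np.asarray(Gamma, float)
    se_out = np.asarray(se_out, float)
    J = gamma.size
    if J == 0:
        raise ValueError("empty instrument set")
    if model not in ("ivw_fixed", "ivw_mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    inv_v = 1.0 / se_out**2
    denom = float(np.sum(gamma**2 * inv_v))
    if denom == 0:
        raise ValueError("all exposure betas are 0: IVW undefined")
    beta = float(np.sum(gamma * Gamma * inv_v)) / denom
    se_fixed = denom**-0.5
    q = float(np.sum((Gamma - beta * gamma) ** 2 * inv_v))
    df = J - 1
    se = se_fixed
    if model == "ivw_mre" and J >= 2:
        se = se_fixed * max(1.0, math.sqrt(q / df))
    return beta, se, q, df


def ivw_estimate(
    hset: HarmonizedInstrumentSet, model: str = "ivw_mre"
) -> MREstimate:
    """Inverse-variance weighted estimate over the kept instruments.

    ``model`` selects the fixed-effect SE or (default) the multiplicative
    random-effects SE, which inflates the fixed SE by sqrt(Q/(J-1)) when the
    heterogeneity statistic exceeds its degrees of freedom.  A single-variant
    set reduces exactly to the ratio estimate.
    """
    if len(hset) == 0:
        raise ValueError("empty instrument set")
    g, _, G, sG = _arrays(hset)
    beta, se, q, df = ivw_arrays(g, G, sG, model=model)
    kw = {}
    if len(hset) >= 2:
        kw = {"q_stat": q, "q_df": df, "q_pval": float(stats.chi2.sf(q, df))}
    return _finish(model, beta, se, len(hset), **kw)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def egger_arrays(
    gamma: np.ndarray, Gamma: np.ndarray, se_out: np.ndarray
) -> tuple[float, float, float, float]:
    """MR-Egger on raw arrays; returns (slope, slope_se, intercept, intercept_se).

    Orients every variant so gamma_j > 0 (flipping both betas), then solves
    the weighted normal equations for Gamma = a + b*gamma with weights
    1/se_out^2.  SEs use the classical WLS covariance inflated by the
    residual scale, floored at 1 (the usual MR-Egger overdispersion
    convention).
    """
    gamma = np.asarray(gamma, float)
    Gamma = np.asarray(Gamma, float)
    se_out = np.asarray(se_out, float)
    J = gamma.size
    if J < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.where(gamma < 0, -1.0, 1.0)
    g = gamma * sign
    G = Gamma * sign
    w = 1.0 / se_out**2
    X = np.column_stack([np.ones(J), g])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * G)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = G - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (J - 2)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    intercept, slope = float(coef[0]), float(coef[1])
    int_se, slope_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return slope, slope_se, intercept, int_se


def egger_estimate(hset: HarmonizedInstrumentSet) -> MREstimate:
    """MR-Egger regression; the intercept estimates directional pleiotropy."""
    if len(hset) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    g, _, G, sG = _arrays(hset)
    slope, slope_se, intercept, int_se = egger_arrays(g, G, sG)
    return _finish(
        "egger",
        slope,
        slope_se,
        len(hset),
        egger_intercept=intercept,
        egger_intercept_se=int_se,
        egger_intercept_p=_wald_p(intercept, int_se),
    )


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    theta = theta[order]
    w = w[order]
    s = (np.cumsum(w) - w / 2.0) / np.sum(w)
    return float(np.interp(0.5, s, theta))


def weighted_median_arrays(
    gamma: np.ndarray,
    se_exp: np.ndarray,
    Gamma: np.ndarray,
    se_out: np.ndarray,
    n_boot: int,
    seed: int,
) -> tuple[float, float]:
    """Weighted-median estimate and parametric-bootstrap SE on raw arrays."""
    gamma = np.asarray(gamma, float)
    se_exp = np.asarray(se_exp, float)
    Gamma = np.asarray(Gamma, float)
    se_out = np.asarray(se_out, float)
    theta = Gamma / gamma
    w = gamma**2 / se_out**2
    beta = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    J = gamma.size
    g_b = rng.normal(gamma, se_exp, size=(n_boot, J))
    G_b = rng.normal(Gamma, se_out, size=(n_boot, J))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        theta_b = G_b[b] / g_b[b]
        w_b = g_b[b] ** 2 / se_out**2
        boots[b] = _weighted_median(theta_b, w_b)
    return beta, float(np.std(boots, ddof=1))


def weighted_median_estimate(
    hset: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median causal estimate with a seeded bootstrap SE.

    The point estimate interpolates the per-variant ratio estimates theta_j
    across their standardized cumulative-weight midpoints at 0.5; the SE is
    the standard deviation of the statistic over ``n_boot`` parametric
    resamples of (gamma_j, Gamma_j).  ``seed`` is required so results are
    reproducible.
    """
    if len(hset) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    if seed is None:
        raise ValueError("weighted_median_estimate requires an explicit seed")
    g, sg, G, sG = _arrays(hset)
    if np.any(g == 0):
        raise ValueError("exposure beta of 0 makes a ratio estimate undefined")
    beta, se = weighted_median_arrays(g, sg, G, sG, n_boot=n_boot, seed=seed)
    return _finish("weighted_median", beta, se, len(hset))


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------


def cochran_q(
    hset: HarmonizedInstrumentSet, beta: float
) -> tuple[float, int, float]:
    """Cochran's Q about a given causal estimate; returns (Q, df, p).

    Q = sum_j w_j (theta_j - beta)^2 with w_j = gamma_j^2 / sigma_Yj^2,
    computed in the residual form sum_j (Gamma_j - beta*gamma_j)^2/sigma_Yj^2
    which tolerates gamma_j = 0.
    """
    if len(hset) < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    g, _, G, sG = _arrays(hset)
    q = float(np.sum((G - beta * g) ** 2 / sG**2))
    df = len(hset) - 1
    return q, df, float(stats.chi2.sf(q, df))
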