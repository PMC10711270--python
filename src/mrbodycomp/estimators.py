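"""Causal-effect estimators for two-sample MR on summary statistics.

All estimators consume a :class:`~mrbodycomp.harmonize.HarmonizedInstrumentSet`
with per-instrument variant-exposure effects ``bx`` (SE ``sx``) and
variant-outcome effects ``by`` (SE ``sy``) referring to a common effect
allele.

* **Wald ratio** — the single-instrument estimate by/bx, with the first-order
  delta-method standard error sy/|bx|.
* **IVW** — the inverse-variance-weighted mean of the per-instrument Wald
  ratios with weights bx²/sy², algebraically identical to weighted least
  squares of by on bx through the origin with weights 1/sy². Fixed-effect SE
  is (Σw)^(-1/2); the multiplicative-random-effects variant inflates it by
  max(1, sqrt(Q/(N-1))) where Q is Cochran's Q of the ratios.
* **Weighted median** — the ratio at the 50% point of the IVW-weight
  cumulative distribution; consistent when valid instruments carry a majority
  of the weight. Its SE comes from a seeded parametric bootstrap.
* **MR-Egger** — weighted regression of by on bx *with* an intercept after
  orienting every instrument to bx >= 0; the slope is the causal estimate and
  the intercept the average directional pleiotropy, valid under InSIDE
  (direct effects independent of instrument strength). SEs are inflated by
  the overdispersion factor max(1, sqrt(RSS/(N-2))).

P-values use the normal distribution throughout (the convention of z-scored
GWAS pipelines reporting p-values at extreme magnitudes), and 95% intervals
use the multiplier 1.959964.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .harmonize import HarmonizedInstrumentSet

__all__ = ["MREstimate", "wald_ratio", "ivw", "weighted_median", "mr_egger", "Z95"]

logger = logging.getLogger(__name__)

#: 97.5% normal quantile used for every 95% confidence interval.
Z95 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate beta_XY with normal-theory inference."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_pval: Optional[float] = None
    heterogeneity_q: Optional[float] = None

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int, **kw) -> "MREstimate":
        z = beta / se
        return cls(
            method=method, beta=float(beta), se=float(se),
            ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
            pval=float(2.0 * stats.norm.sf(abs(z))), n_snps=int(n_snps), **kw,
        )


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-instrument ratio estimate by/bx with SE sy/|bx| (first-order
    delta method; the sx term is deliberately omitted)."""
    if bx == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for bx = 0")
    return MREstimate.from_beta_se("wald", by / bx, sy / abs(bx), 1)


def _ivw_weights(hset: HarmonizedInstrumentSet) -> np.ndarray:
    return hset.bx**2 / hset.sy**2


def _cochran_q(hset: HarmonizedInstrumentSet, beta: float) -> float:
    ratios = hset.by / hset.bx
    w = _ivw_weights(hset)
    return float(np.sum(w * (ratios - beta) ** 2))


def ivw(hset: HarmonizedInstrumentSet, mode: Optional[str] = None) -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``mode`` is ``"fixed"`` or ``"multiplicative_random"``; the default picks
    multiplicative random effects whenever N >= 2 (fixed for N = 1).
    """
    n = len(hset)
    if mode is None:
        mode = "multiplicative_random" if n >= 2 else "fixed"
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    if mode == "multiplicative_random" and n < 2:
        raise InsufficientInstrumentsError("multiplicative-random IVW needs N >= 2")
    if n < 1:
        raise InsufficientInstrumentsError("IVW needs N >= 1")
    if np.any(hset.bx == 0):
        raise DegenerateInstrumentError("IVW ratios undefined for bx = 0")
    w = _ivw_weights(hset)
    ratios = hset.by / hset.bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = _cochran_q(hset, beta)
    if mode == "multiplicative_random":
        phi = max(1.0, np.sqrt(q / (n - 1)))
        se *= phi
    method = "ivw_fe" if mode == "fixed" else "ivw_mre"
    return MREstimate.from_beta_se(method, beta, se, n, heterogeneity_q=q)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights[order])
    p = np.cumsum(w) - w / 2.0
    # linear interpolation between the bracketing ratios; clamped at the ends
    return float(np.interp(0.5, p, r))


def weighted_median(
    hset: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate:
    """Weighted-median estimate with a parametric-bootstrap standard error.

    Ratios are sorted with normalized IVW weights; the estimate interpolates
    between the two ratios whose standardized cumulative weight brackets 0.5.
    The SE is the standard deviation of the estimate over ``n_boot``
    replicates resampling bx* ~ N(bx, sx) and by* ~ N(by, sy).
    """
    n = len(hset)
    if n < 3:
        raise InsufficientInstrumentsError("weighted median needs N >= 3")
    if seed is None:
        logger.warning("weighted_median called without a seed; defaulting to seed=0")
        seed = 0
    w = _ivw_weights(hset)
    beta = _weighted_median_point(hset.by / hset.bx, w)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(hset.bx, hset.sx, size=(n_boot, n))
    by_star = rng.normal(hset.by, hset.sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx_star[b]
        nz = bx_b != 0
        boots[b] = _weighted_median_point(
            by_star[b][nz] / bx_b[nz], bx_b[nz] ** 2 / hset.sy[nz] ** 2
        )
    se = float(np.std(boots, ddof=1))
    return MREstimate.from_beta_se("weighted_median", beta, se, n)


def mr_egger(hset: HarmonizedInstrumentSet) -> MREstimate:
    """MR-Egger regression: weighted fit of by on bx with an intercept.

    Instruments are first oriented so every bx >= 0 (negating the paired by),
    making the intercept interpretable as average directional pleiotropy.
    Slope and intercept SEs are inflated by max(1, sqrt(RSS/(N-2))).
    """
    n = len(hset)
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger needs N >= 3")
    sign = np.where(hset.bx < 0, -1.0, 1.0)
    bx = hset.bx * sign
    by = hset.by * sign
    if np.ptp(bx) == 0:
        raise CollinearityError("MR-Egger degenerate: all |bx| equal after orientation")
    weights = 1.0 / hset.sy**2
    fit = sm.WLS(by, sm.add_constant(bx), weights=weights).fit()
    intercept, slope = fit.params
    resid = by - fit.fittedvalues
    rss = float(np.sum(weights * resid**2))
    phi = max(1.0, np.sqrt(rss / (n - 2)))
    # statsmodels' bse already carries sqrt(RSS/(N-2)); rescale so the
    # inflation is exactly max(1, .) instead of allowing deflation below 1
    base_se = fit.bse / np.sqrt(fit.mse_resid)
    intercept_se, slope_se = base_se * phi

    ratios = hset.by / hset.bx
    w = _ivw_weights(hset)
    q = float(np.sum(w * (ratios - np.sum(w * ratios) / np.sum(w)) ** 2))
    z_int = intercept / intercept_se
    return MREstimate.from_beta_se(
        "egger_slope", slope, slope_se, n,
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        intercept_pval=float(2.0 * stats.norm.sf(abs(z_int))),
        heterogeneity_q=q,
    )
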