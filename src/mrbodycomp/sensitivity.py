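"""Sensitivity battery: leave-one-out, Steiger directionality, MR-PRESSO.

Leave-one-out re-estimates IVW omitting each instrument in turn, exposing
single-variant leverage. The Steiger test checks that the instruments explain
more variance in the exposure than in the outcome — the directionality
expected if the exposure causes the outcome rather than the reverse.
MR-PRESSO (Pleiotropy RESidual Sum and Outlier) detects horizontal-pleiotropy
outliers by comparing each instrument's residual from a leave-one-out IVW fit
against a parametric null simulated from the observed standard errors, then
re-estimates the effect without the flagged instruments and tests whether the
correction distorts the estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateCorrectionError,
    InsufficientInstrumentsError,
)
from .estimators import MREstimate, ivw
from .harmonize import HarmonizedInstrumentSet

__all__ = [
    "LeaveOneOutResult",
    "SteigerResult",
    "PressoResult",
    "leave_one_out",
    "steiger_test",
    "mr_presso",
]

logger = logging.getLogger(__name__)


@dataclass
class LeaveOneOutResult:
    """Full-set IVW estimate plus one IVW estimate per omitted instrument."""

    full: MREstimate
    rows: pd.DataFrame  # omitted_rsid, beta, se, ci_low, ci_high, pval, n_snps
    max_abs_deviation: float

    @property
    def most_influential(self) -> str:
        i = int((self.rows["beta"] - self.full.beta).abs().idxmax())
        return str(self.rows.loc[i, "omitted_rsid"])


def leave_one_out(hset: HarmonizedInstrumentSet, mode: Optional[str] = None) -> LeaveOneOutResult:
    """IVW re-estimated N times, each time omitting one instrument."""
    n = len(hset)
    if n < 3:
        raise InsufficientInstrumentsError("leave-one-out needs N >= 3")
    full = ivw(hset, mode)
    records = []
    for i in range(n):
        keep = np.arange(n) != i
        est = ivw(hset.subset(keep), mode)
        records.append(
            (hset.variants[i].rsid, est.beta, est.se, est.ci_low, est.ci_high,
             est.pval, est.n_snps)
        )
    rows = pd.DataFrame(
        records,
        columns=["omitted_rsid", "beta", "se", "ci_low", "ci_high", "pval", "n_snps"],
    )
    max_dev = float((rows["beta"] - full.beta).abs().max())
    return LeaveOneOutResult(full=full, rows=rows, max_abs_deviation=max_dev)


@dataclass(frozen=True)
class SteigerResult:
    """Directionality check: do instruments explain more exposure variance?"""

    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    pval: float


def _r2_from_t(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2.0)


def steiger_test(hset: HarmonizedInstrumentSet) -> SteigerResult:
    """Aggregate Steiger test from summary statistics.

    Per-instrument variance explained uses the t-statistic transform
    r² = t²/(t² + n − 2), which needs only beta, SE and sample size; the
    trait-level r² sums over instruments (independent after clumping).
    The p-value is a two-sided z-test on the difference of Fisher-transformed
    √r² values with variances 1/(n − 3).
    """
    if hset.n_exp is None or hset.n_out is None or \
            np.any(np.isnan(hset.n_exp)) or np.any(np.isnan(hset.n_out)):
        raise ConfigurationError("Steiger test needs per-instrument sample sizes")
    r2x = float(np.sum(_r2_from_t(hset.bx, hset.sx, hset.n_exp)))
    r2y = float(np.sum(_r2_from_t(hset.by, hset.sy, hset.n_out)))
    r2x = min(r2x, 1.0 - 1e-12)
    r2y = min(r2y, 1.0 - 1e-12)
    nx = float(np.mean(hset.n_exp))
    ny = float(np.mean(hset.n_out))
    z = (np.arctanh(np.sqrt(r2x)) - np.arctanh(np.sqrt(r2y))) / \
        np.sqrt(1.0 / (nx - 3.0) + 1.0 / (ny - 3.0))
    return SteigerResult(
        r2_exposure=r2x,
        r2_outcome=r2y,
        correct_direction=bool(r2x > r2y),
        pval=float(2.0 * stats.norm.sf(abs(z))),
    )


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    rss_obs: float
    global_pval: float
    per_snp_outlier_pval: np.ndarray
    outlier_indices: np.ndarray
    beta_raw: MREstimate
    beta_corrected: MREstimate
    distortion_pval: Optional[float]


def _loo_slopes(bx: np.ndarray, by: np.ndarray, inv_sy2: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted through-origin slopes, vectorized.

    Works on 1-D arrays or on (n_sim, N) batches along the last axis.
    """
    sxy = np.sum(bx * by * inv_sy2, axis=-1, keepdims=True)
    sxx = np.sum(bx * bx * inv_sy2, axis=-1, keepdims=True)
    return (sxy - bx * by * inv_sy2) / (sxx - bx * bx * inv_sy2)


def mr_presso(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: Optional[int] = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO outlier detection and correction.

    Global test: each instrument's residual from the IVW slope fitted without
    it, summed as RSS = Σ rᵢ²/syᵢ², is compared against ``n_sim`` parametric
    null datasets (bx* ~ N(bx, sx), by* ~ N(slope₋ᵢ·bx, sy)); Monte-Carlo
    p-values take the (1 + k)/(1 + n_sim) form and are never exactly 0.
    Outliers are instruments whose residual exceeds its simulated null at the
    Bonferroni-corrected level ``outlier_alpha / N``. The distortion test
    compares the raw-minus-corrected IVW difference against differences from
    removing random subsets of the same size.
    """
    n = len(hset)
    if n < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs N >= 4")
    if n_sim < 100:
        raise ConfigurationError("MR-PRESSO needs n_sim >= 100")
    if seed is None:
        logger.warning("mr_presso called without a seed; defaulting to seed=0")
        seed = 0
    rng = np.random.default_rng(seed)

    bx, by, sx, sy = hset.bx, hset.by, hset.sx, hset.sy
    inv_sy2 = 1.0 / sy**2

    slopes_loo = _loo_slopes(bx, by, inv_sy2)
    resid_obs = by - slopes_loo * bx
    rss_obs = float(np.sum(resid_obs**2 * inv_sy2))

    bx_star = rng.normal(bx, sx, size=(n_sim, n))
    by_star = rng.normal(slopes_loo * bx, sy, size=(n_sim, n))
    slopes_star = _loo_slopes(bx_star, by_star, inv_sy2)
    resid_star = by_star - slopes_star * bx_star
    rss_star = np.sum(resid_star**2 * inv_sy2, axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_snp_pval = (1 + np.sum(resid_star**2 >= resid_obs**2, axis=0)) / (n_sim + 1)
    outliers = np.flatnonzero(per_snp_pval < outlier_alpha / n)

    beta_raw = ivw(hset)
    if outliers.size == 0:
        return PressoResult(
            rss_obs=rss_obs, global_pval=global_pval,
            per_snp_outlier_pval=per_snp_pval, outlier_indices=outliers,
            beta_raw=beta_raw, beta_corrected=beta_raw, distortion_pval=None,
        )
    if n - outliers.size < 2:
        raise DegenerateCorrectionError(
            f"MR-PRESSO flagged {outliers.size}/{n} instruments; "
            "no corrected estimate possible"
        )
    keep = np.setdiff1d(np.arange(n), outliers)
    beta_corrected = ivw(hset.subset(keep))

    # distortion: difference distribution over random outlier-sized subsets
    d_obs = beta_raw.beta - beta_corrected.beta
    k = outliers.size
    d_null = np.empty(n_sim)
    w = bx**2 * inv_sy2
    ratios = by / bx
    sw, swr = np.sum(w), np.sum(w * ratios)
    for b in range(n_sim):
        drop = rng.choice(n, size=k, replace=False)
        beta_sub = (swr - np.sum(w[drop] * ratios[drop])) / (sw - np.sum(w[drop]))
        d_null[b] = beta_raw.beta - beta_sub
    distortion_pval = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))

    return PressoResult(
        rss_obs=rss_obs, global_pval=global_pval,
        per_snp_outlier_pval=per_snp_pval, outlier_indices=outliers,
        beta_raw=beta_raw, beta_corrected=beta_corrected,
        distortion_pval=distortion_pval,
    )
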