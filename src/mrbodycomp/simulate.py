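"""Synthetic GWAS summary statistics and LD reference panels with known truth.

The generator realizes the instrumental-variable model two-sample MR assumes:
each instrument i has a true effect γᵢ on the exposure; the outcome effect is
β_true·γᵢ plus an optional direct (horizontally pleiotropic) effect αᵢ that
bypasses the exposure. Observed effects add sampling noise whose scale follows
the standardized-trait approximation SE ≈ 1/sqrt(2·n·maf·(1−maf)), so SEs
shrink as n^(−1/2) and grow for rare alleles.

Pleiotropy modes:

* ``none`` — all instruments valid; the three IV assumptions hold by
  construction.
* ``balanced`` — invalid instruments draw αᵢ ~ N(0, pleio_sd²): extra
  heterogeneity, no systematic bias.
* ``directional`` — αᵢ ~ N(pleio_mean, pleio_sd²): a common-direction bias
  that IVW absorbs but the weighted median resists while invalid instruments
  stay in the minority. InSIDE still holds (α independent of γ), so the
  MR-Egger intercept estimates the mean direct effect.
* ``inside_violating`` — αᵢ correlated with instrument strength
  (inside_rho), breaking the Egger assumption.

By default instruments are oriented to the exposure-increasing allele
(γᵢ = |N(0, gamma_sd²)|), the usual coding in MR simulation studies; without
it a fixed-sign α is *not* directional on the Wald-ratio scale (α/γ takes
both signs) and directional pleiotropy would not bias IVW.
``orient_gamma=False`` restores sign-symmetric γ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .instruments import GenotypeReference
from .sumstats import MIN_PVAL, AssociationRecord, SumStats, VariantKey

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_sumstats",
    "simulate_ld_panel",
    "simulate_grid",
]

# non-palindromic allele pairs only, so harmonization keeps every instrument
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one exposure–outcome summary-statistic pair.

    Defaults mirror a body-composition -> testosterone style analysis:
    ~170 instruments from a GWAS of ~166k men, outcome GWAS of ~194k, causal
    effect −0.24 SD per exposure unit, instrument effects of SD 0.05 on the
    standardized exposure scale.
    """

    n_snps: int = 170
    beta_true: float = -0.24
    n_exp: float = 166_000
    n_out: float = 194_000
    gamma_sd: float = 0.05
    maf_range: tuple = (0.05, 0.45)
    pleiotropy_mode: str = "none"
    pleio_mean: float = 0.02
    pleio_sd: float = 0.01
    pleio_fraction: float = 0.3
    inside_rho: float = 0.6
    overlap_rho: float = 0.0
    orient_gamma: bool = True
    se_floor: float = 1e-12
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValidationError("maf_range must satisfy 0 < low <= high < 0.5")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if not (0 <= self.pleio_fraction <= 1):
            raise ValidationError("pleio_fraction must be in [0, 1]")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValidationError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if not (abs(self.inside_rho) <= 1 and abs(self.overlap_rho) <= 1):
            raise ValidationError("correlations must lie in [-1, 1]")
        if self.n_exp <= 2 or self.n_out <= 2:
            raise ValidationError("sample sizes must exceed 2")
        if self.gamma_sd <= 0 or self.se_floor <= 0:
            raise ValidationError("gamma_sd and se_floor must be positive")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated pair, for recovery tests."""

    beta_true: float
    gamma: np.ndarray
    alpha: np.ndarray
    invalid_mask: np.ndarray
    maf: np.ndarray
    se_x: np.ndarray
    se_y: np.ndarray
    rsids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "gamma": self.gamma,
                "alpha": self.alpha,
                "invalid": self.invalid_mask.astype(int),
                "maf": self.maf,
                "se_x": self.se_x,
                "se_y": self.se_y,
                "beta_true": self.beta_true,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _se_standardized(n: float, maf: np.ndarray, floor: float) -> np.ndarray:
    if math.isinf(n):
        return np.full_like(maf, floor)
    return np.maximum(1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf)), floor)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, MIN_PVAL, 1.0)


def simulate_sumstats(cfg: SimulationConfig) -> tuple[SumStats, SumStats, TruthRecord]:
    """Draw one exposure/outcome summary-statistic pair under ``cfg``.

    The two outputs share identical variant keys and allele coding; the
    exposure file plays the role of an already instrument-selected set.
    Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n)
    gamma = rng.normal(0.0, cfg.gamma_sd, size=n)
    if cfg.orient_gamma:
        gamma = np.abs(gamma)

    alpha = np.zeros(n)
    n_invalid = int(round(cfg.pleio_fraction * n)) if cfg.pleiotropy_mode != "none" else 0
    invalid = np.zeros(n, dtype=bool)
    if n_invalid > 0:
        idx = rng.choice(n, size=n_invalid, replace=False)
        invalid[idx] = True
        if cfg.pleiotropy_mode == "balanced":
            alpha[idx] = rng.normal(0.0, cfg.pleio_sd, size=n_invalid)
        elif cfg.pleiotropy_mode == "directional":
            alpha[idx] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=n_invalid)
        elif cfg.pleiotropy_mode == "inside_violating":
            scale = cfg.pleio_mean / max(cfg.gamma_sd, 1e-300)
            noise = rng.normal(0.0, cfg.pleio_sd, size=n_invalid)
            alpha[idx] = (cfg.inside_rho * gamma[idx] * scale
                          + math.sqrt(1.0 - cfg.inside_rho**2) * noise)
        # alpha exactly 0 for a nominally invalid instrument would break the
        # invalid_mask invariant; nudge such draws off zero
        zero = idx[alpha[idx] == 0.0]
        alpha[zero] = cfg.pleio_sd * 1e-9 if cfg.pleio_sd > 0 else 1e-12
    invalid = alpha != 0.0

    se_x = _se_standardized(cfg.n_exp, maf, cfg.se_floor)
    se_y = _se_standardized(cfg.n_out, maf, cfg.se_floor)

    eps_x = rng.standard_normal(n)
    eps_ind = rng.standard_normal(n)
    eps_y = cfg.overlap_rho * eps_x + math.sqrt(1.0 - cfg.overlap_rho**2) * eps_ind
    bx_hat = gamma + se_x * eps_x
    by_hat = cfg.beta_true * gamma + alpha + se_y * eps_y

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    chroms = [str((i % 22) + 1) for i in range(n)]
    positions = [1_000_000 + 500_000 * (i // 22) for i in range(n)]

    px = _pvals(bx_hat, se_x)
    py = _pvals(by_hat, se_y)

    exp = SumStats("sim_exposure", "exposure", n_default=cfg.n_exp)
    out = SumStats("sim_outcome", "outcome", n_default=cfg.n_out)
    rsids = []
    for i in range(n):
        ea, oa = _ALLELE_PAIRS[pair_idx[i]]
        v = VariantKey(f"rs{100000 + i}", chroms[i], positions[i], ea, oa)
        rsids.append(v.rsid)
        exp.add(AssociationRecord(v, float(bx_hat[i]), float(se_x[i]),
                                  float(px[i]), eaf=float(maf[i]), n=cfg.n_exp))
        out.add(AssociationRecord(v, float(by_hat[i]), float(se_y[i]),
                                  float(py[i]), eaf=float(maf[i]), n=cfg.n_out))

    truth = TruthRecord(
        beta_true=cfg.beta_true, gamma=gamma, alpha=alpha, invalid_mask=invalid,
        maf=maf, se_x=se_x, se_y=se_y, rsids=rsids,
    )
    return exp, out, truth


def simulate_grid(
    n_exposures: int = 13,
    n_outcomes: int = 3,
    n_snps_per_exposure: int = 50,
    beta_matrix: Optional[np.ndarray] = None,
    n_exp: float = 166_000,
    n_out: float = 194_000,
    gamma_sd: float = 0.05,
    maf_range: tuple = (0.05, 0.45),
    seed: int = 0,
) -> tuple[list[SumStats], list[SumStats], pd.DataFrame]:
    """A whole exposure x outcome grid of summary statistics with known truth.

    Each exposure owns a disjoint set of instruments (distinct rsids and
    loci); every outcome file carries the union of all instruments, with each
    instrument's outcome effect driven by its owning exposure's true causal
    effect on that outcome. ``beta_matrix`` (n_exposures x n_outcomes)
    defaults to draws from N(-0.1, 0.1²), a grid of mostly modest negative
    effects. Returns (exposures, outcomes, truth) where truth is a tidy
    frame of true betas per (exposure, outcome).
    """
    rng = np.random.default_rng(seed)
    if beta_matrix is None:
        beta_matrix = rng.normal(-0.1, 0.1, size=(n_exposures, n_outcomes))
    beta_matrix = np.asarray(beta_matrix, dtype=float)
    if beta_matrix.shape != (n_exposures, n_outcomes):
        raise ValidationError("beta_matrix must be n_exposures x n_outcomes")

    exposures = []
    outcomes = [SumStats(f"outcome_{o + 1}", "outcome", n_default=n_out)
                for o in range(n_outcomes)]
    truth_rows = []
    for e in range(n_exposures):
        ename = f"exposure_{e + 1}"
        exp = SumStats(ename, "exposure", n_default=n_exp)
        maf = rng.uniform(maf_range[0], maf_range[1], size=n_snps_per_exposure)
        gamma = np.abs(rng.normal(0.0, gamma_sd, size=n_snps_per_exposure))
        se_x = _se_standardized(n_exp, maf, 1e-12)
        se_y = _se_standardized(n_out, maf, 1e-12)
        bx_hat = rng.normal(gamma, se_x)
        px = _pvals(bx_hat, se_x)
        for i in range(n_snps_per_exposure):
            k = e * n_snps_per_exposure + i
            ea, oa = _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)]
            v = VariantKey(f"rs{200000 + k}", str((k % 22) + 1),
                           1_000_000 + 500_000 * (k // 22), ea, oa)
            exp.add(AssociationRecord(v, float(bx_hat[i]), float(se_x[i]),
                                      float(px[i]), eaf=float(maf[i]), n=n_exp))
            for o, out in enumerate(outcomes):
                by = rng.normal(beta_matrix[e, o] * gamma[i], se_y[i])
                out.add(AssociationRecord(v, float(by), float(se_y[i]),
                                          float(_pvals(np.array([by]),
                                                       np.array([se_y[i]]))[0]),
                                          eaf=float(maf[i]), n=n_out))
        exposures.append(exp)
        for o in range(n_outcomes):
            truth_rows.append((ename, f"outcome_{o + 1}", beta_matrix[e, o]))
    truth = pd.DataFrame(truth_rows, columns=["exposure", "outcome", "beta_true"])
    return exposures, outcomes, truth


def simulate_ld_panel(
    n_blocks: int,
    block_size: int,
    within_block_rho: float,
    n_samples: int = 503,
    maf_range: tuple = (0.05, 0.45),
    seed: int = 0,
    chrom: str = "1",
    block_spacing_kb: float = 20_000.0,
    within_spacing_bp: int = 1_000,
) -> tuple[GenotypeReference, np.ndarray]:
    """Block-LD dosage panel: latent MVN thresholded to {0, 1, 2} under HWE.

    Samples draw a latent normal vector with block-diagonal equicorrelation
    ``within_block_rho``; each variant's dosage is cut at the Hardy–Weinberg
    genotype quantiles for its allele frequency. Variants within a block sit
    ``within_spacing_bp`` apart (well inside any clump window) while
    consecutive blocks are separated by ``block_spacing_kb`` — larger than
    the default clump window, so sampling noise in cross-block r² cannot
    evict variants from other blocks. Returns the panel and the per-variant
    block index.
    """
    if n_blocks < 1 or block_size < 1 or n_samples < 2:
        raise ValidationError("n_blocks, block_size >= 1 and n_samples >= 2 required")
    if not abs(within_block_rho) < 1:
        raise ValidationError("|within_block_rho| must be < 1")
    lo, hi = maf_range
    if not (0 < lo <= hi < 0.5):
        raise ValidationError("maf_range must satisfy 0 < low <= high < 0.5")

    rng = np.random.default_rng(seed)
    n_var = n_blocks * block_size
    maf = rng.uniform(lo, hi, size=n_var)

    # latent one-factor construction gives exact equicorrelation |rho| within
    # a block; the sign is irrelevant for r², which is what clumping uses
    z = np.empty((n_var, n_samples))
    r = abs(within_block_rho)
    for b in range(n_blocks):
        shared = rng.standard_normal(n_samples)
        own = rng.standard_normal((block_size, n_samples))
        z[b * block_size:(b + 1) * block_size] = (
            math.sqrt(r) * shared + math.sqrt(1.0 - r) * own
        )

    p = maf[:, None]
    t0 = stats.norm.ppf((1.0 - p) ** 2)          # below: dosage 0
    t1 = stats.norm.ppf((1.0 - p) ** 2 + 2 * p * (1 - p))
    dosages = (z > t0).astype(float) + (z > t1).astype(float)

    variants = []
    blocks = np.empty(n_var, dtype=int)
    for i in range(n_var):
        b, j = divmod(i, block_size)
        pos = int(1_000_000 + b * block_spacing_kb * 1000 + j * within_spacing_bp)
        ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        variants.append(VariantKey(f"ld{i}", chrom, pos, ea, oa))
        blocks[i] = b
    return GenotypeReference(variants, dosages), blocks
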