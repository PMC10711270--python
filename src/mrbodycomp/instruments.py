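"""Instrument selection: genome-wide significance filtering and LD clumping.

Instruments are defined the way PLINK-style clumping does it: keep variants
below a p-value threshold, then greedily pick the most significant remaining
variant as an index and discard every other variant on the same chromosome
within ``window_kb`` whose squared correlation (r²) with it meets the
threshold. LD comes from a reference panel, either as a dosage matrix
(:class:`GenotypeReference`, r² = squared Pearson correlation of dosages,
composite/unphased LD) or as a precomputed pair table
(:class:`PrecomputedLDTable`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .errors import UndefinedLDError, UnknownVariantError, ValidationError
from .sumstats import SumStats, VariantKey

__all__ = [
    "GenotypeReference",
    "PrecomputedLDTable",
    "ClumpConfig",
    "filter_genomewide",
    "ld_r2",
    "clump",
]

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


class GenotypeReference:
    """Reference-panel dosages (variants x samples, values in [0, 2])."""

    def __init__(self, variants: list[VariantKey], dosages: np.ndarray):
        self.variants = list(variants)
        self.dosages = np.asarray(dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.variants):
            raise ValidationError("dosage matrix rows must align with the variant index")
        if self.dosages.shape[1] < 2:
            raise ValidationError("reference panel needs at least 2 samples")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValidationError("dosages must lie in [0, 2]")
        self._row_by_rsid = {v.rsid: i for i, v in enumerate(self.variants)}
        self._row_by_locus = {v.locus: i for i, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, v: VariantKey) -> bool:
        return v.rsid in self._row_by_rsid or v.locus in self._row_by_locus

    def row(self, v: VariantKey) -> np.ndarray:
        i = self._row_by_rsid.get(v.rsid)
        if i is None:
            i = self._row_by_locus.get(v.locus)
        if i is None:
            raise UnknownVariantError(f"variant {v.rsid} not in reference panel")
        return self.dosages[i]

    def r2(self, a: VariantKey, b: VariantKey) -> float:
        x, y = self.row(a), self.row(b)
        vx, vy = x.std(), y.std()
        if vx == 0 or vy == 0:
            raise UndefinedLDError(
                f"LD undefined: zero-variance dosages for {a.rsid if vx == 0 else b.rsid}"
            )
        r = np.corrcoef(x, y)[0, 1]
        return float(min(r * r, 1.0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rsid": [v.rsid for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
            }
        )
        dose = pd.DataFrame(self.dosages,
                            columns=[f"s{j}" for j in range(self.n_samples)])
        return pd.concat([df, dose], axis=1)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path) -> "GenotypeReference":
        df = pd.read_csv(path, sep="\t")
        key_cols = ["rsid", "chrom", "pos", "effect_allele", "other_allele"]
        variants = [
            VariantKey(str(r.rsid), str(r.chrom), int(r.pos),
                       str(r.effect_allele), str(r.other_allele))
            for r in df[key_cols].itertuples(index=False)
        ]
        dosages = df.drop(columns=key_cols).to_numpy(dtype=float)
        return cls(variants, dosages)


class PrecomputedLDTable:
    """Symmetric sparse (variant pair -> r²) lookup; absent pairs mean r² = 0."""

    def __init__(self, pairs: dict):
        self._r2 = {}
        self._known = set()
        for (a, b), r2 in pairs.items():
            if not (0 <= r2 <= 1):
                raise ValidationError(f"r² must be in [0,1], got {r2} for ({a},{b})")
            self._r2[frozenset((a, b))] = float(r2)
            self._known.update((a, b))

    def __contains__(self, v: VariantKey) -> bool:
        return v.rsid in self._known

    def r2(self, a: VariantKey, b: VariantKey) -> float:
        if a.rsid not in self._known:
            raise UnknownVariantError(f"variant {a.rsid} not in LD table")
        if b.rsid not in self._known:
            raise UnknownVariantError(f"variant {b.rsid} not in LD table")
        if a.rsid == b.rsid:
            return 1.0
        return self._r2.get(frozenset((a.rsid, b.rsid)), 0.0)

    @classmethod
    def read(cls, path) -> "PrecomputedLDTable":
        df = pd.read_csv(path, sep=None, engine="python")
        cols = list(df.columns[:3])
        return cls({(str(r[0]), str(r[1])): float(r[2])
                    for r in df[cols].itertuples(index=False)})


LDProvider = Union[GenotypeReference, PrecomputedLDTable]


def ld_r2(provider: LDProvider, a: VariantKey, b: VariantKey) -> float:
    """Squared correlation between two variants in the reference panel."""
    return provider.r2(a, b)


@dataclass(frozen=True)
class ClumpConfig:
    """Clumping parameters: P<5e-8 and r²<0.01 are the pipeline defaults;
    the 10 Mb window is the conservative two-sample-MR convention."""

    p_threshold: float = GENOME_WIDE_P
    r2_threshold: float = 0.01
    window_kb: float = 10_000.0
    missing_variant_policy: str = "independent"  # or "drop"

    def __post_init__(self):
        if not (0 < self.p_threshold <= 1):
            raise ValidationError("p_threshold must be in (0, 1]")
        if self.r2_threshold < 0:
            # values > 1 are allowed and retain every significant variant
            raise ValidationError("r2_threshold must be non-negative")
        if self.window_kb <= 0:
            raise ValidationError("window_kb must be positive")
        if self.missing_variant_policy not in ("independent", "drop"):
            raise ValidationError("missing_variant_policy must be 'independent' or 'drop'")


def filter_genomewide(s: SumStats, p_threshold: float = GENOME_WIDE_P) -> SumStats:
    """Keep records with p strictly below the threshold, preserving order."""
    return SumStats(
        s.trait_name, s.trait_role,
        (r for r in s if r.pval < p_threshold),
        n_default=s.n_default,
    )


def clump(s: SumStats, provider: LDProvider, cfg: ClumpConfig = ClumpConfig()) -> list[VariantKey]:
    """Greedy LD clumping; returns index variants in selection order.

    Records are sorted by ascending p (ties: chrom then pos, so output does
    not depend on input order); the best remaining record becomes an index
    variant and removes every remaining same-chromosome record within
    ``window_kb`` whose r² with it is >= ``r2_threshold``. Variants the LD
    provider does not know are, by default, treated as independent of
    everything (and logged); ``missing_variant_policy="drop"`` discards them.
    """
    records = [r for r in filter_genomewide(s, cfg.p_threshold)]

    def sort_key(rec):
        v = rec.variant
        return (rec.pval, _chrom_rank(v.chrom), v.pos)

    records.sort(key=sort_key)

    known = [provider is not None and rec.variant in provider for rec in records]
    for rec, k in zip(records, known):
        if not k:
            logger.warning(
                "clump: %s absent from LD provider (%s)",
                rec.variant.rsid, cfg.missing_variant_policy,
            )
    if cfg.missing_variant_policy == "drop":
        records = [rec for rec, k in zip(records, known) if k]
        known = [True] * len(records)

    window_bp = cfg.window_kb * 1000.0
    alive = [True] * len(records)
    index_variants: list[VariantKey] = []
    for i, rec in enumerate(records):
        if not alive[i]:
            continue
        v = rec.variant
        index_variants.append(v)
        alive[i] = False
        if not known[i]:
            continue  # unknown to panel: independent of everything
        for j in range(i + 1, len(records)):
            if not alive[j] or not known[j]:
                continue
            w = records[j].variant
            if w.chrom != v.chrom or abs(w.pos - v.pos) > window_bp:
                continue
            if provider.r2(v, w) >= cfg.r2_threshold:
                alive[j] = False
    return index_variants


def _chrom_rank(chrom: str):
    """Sortable chromosome rank: numeric chromosomes first, then lexical."""
    c = str(chrom).removeprefix("chr")
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)
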