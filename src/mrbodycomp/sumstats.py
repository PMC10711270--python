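"""Reading, validating, indexing and writing GWAS summary statistics.

Summary statistics arrive as delimited text with one row per variant. Layouts
differ between providers: the Neale Lab UK Biobank exports pack the variant
identity into a single ``chr:pos:ref:alt`` column, while GWAS Catalog
harmonized files carry separate ``hm_rsid`` / ``hm_effect_allele`` style
columns. A :class:`ColumnMap` names the source column for each field, and two
built-in dialects (``"neale"``, ``"gwascat"``) cover those layouts; a plain
``"generic"`` dialect matches this package's own output.

Only biallelic SNVs are kept: rows with indel or multi-allelic alleles,
non-positive standard errors, out-of-range p-values or frequencies, or
duplicated (chrom, pos, allele-pair) identity are dropped and recorded in a
:class:`ReadAudit`, so that parsed + dropped always equals the input row
count.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnknownVariantError, ValidationError

__all__ = [
    "VariantKey",
    "AssociationRecord",
    "SumStats",
    "ColumnMap",
    "ReadAudit",
    "DIALECTS",
    "read_sumstats",
    "write_sumstats",
    "intersect_variants",
]

VALID_ALLELES = frozenset("ACGT")

#: Smallest positive p-value substituted for an input p of exactly 0 so that
#: downstream z / Steiger statistics stay finite.
MIN_PVAL = sys.float_info.min


@dataclass(frozen=True)
class VariantKey:
    """Identity of one biallelic SNV: rsid, coordinates and allele pair."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: alleles must be single A/C/G/T bases, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: position must be >= 1, got {self.pos}")

    @property
    def allele_pair(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def locus(self) -> tuple:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's association statistics with one trait.

    ``beta`` is the per-effect-allele effect in the trait's native units
    (trait SD for standardized GWAS); ``eaf`` and ``n`` may be missing
    (``None``).
    """

    variant: VariantKey
    beta: float
    se: float
    pval: float
    eaf: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError(f"{self.variant.rsid}: se must be positive and finite")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.variant.rsid}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.variant.rsid}: eaf must be in [0, 1]")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.variant.rsid}: beta must be finite")


class SumStats:
    """A trait's summary-association statistics, indexed by rsid and locus.

    No two records may share (chrom, pos, unordered allele pair). Lookup works
    both by rsid and by (chrom, pos).
    """

    def __init__(
        self,
        trait_name: str,
        trait_role: str,
        records: Iterable[AssociationRecord] = (),
        n_default: Optional[float] = None,
    ):
        if trait_role not in ("exposure", "outcome"):
            raise ValidationError(f"trait_role must be 'exposure' or 'outcome', got {trait_role!r}")
        self.trait_name = trait_name
        self.trait_role = trait_role
        self.n_default = n_default
        self._records: list[AssociationRecord] = []
        self._by_rsid: dict[str, AssociationRecord] = {}
        self._by_locus: dict[tuple, AssociationRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: AssociationRecord) -> None:
        v = rec.variant
        ident = (v.chrom, v.pos, v.allele_pair)
        if (v.chrom, v.pos) in self._by_locus:
            prev = self._by_locus[(v.chrom, v.pos)]
            if (prev.variant.chrom, prev.variant.pos, prev.variant.allele_pair) == ident:
                raise ValidationError(f"duplicate record for {v.rsid} at {v.chrom}:{v.pos}")
        if v.rsid in self._by_rsid:
            raise ValidationError(f"duplicate rsid {v.rsid}")
        if rec.n is None and self.n_default is not None:
            rec = replace(rec, n=self.n_default)
        self._records.append(rec)
        self._by_rsid[v.rsid] = rec
        self._by_locus[(v.chrom, v.pos)] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self._records)

    def __contains__(self, key) -> bool:
        return self.get(key) is not None

    @property
    def records(self) -> list[AssociationRecord]:
        return list(self._records)

    @property
    def variants(self) -> list[VariantKey]:
        return [r.variant for r in self._records]

    def get(self, key: Union[str, VariantKey, tuple]) -> Optional[AssociationRecord]:
        """Look up a record by rsid, by (chrom, pos), or by a VariantKey
        (rsid first, locus fallback). Returns None when absent."""
        if isinstance(key, VariantKey):
            return self._by_rsid.get(key.rsid) or self._by_locus.get(key.locus)
        if isinstance(key, tuple):
            return self._by_locus.get(key)
        return self._by_rsid.get(key)

    def __getitem__(self, key) -> AssociationRecord:
        rec = self.get(key)
        if rec is None:
            raise UnknownVariantError(key)
        return rec

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the package's canonical columns."""
        return pd.DataFrame(
            {
                "rsid": [r.variant.rsid for r in self._records],
                "chrom": [r.variant.chrom for r in self._records],
                "pos": [r.variant.pos for r in self._records],
                "effect_allele": [r.variant.effect_allele for r in self._records],
                "other_allele": [r.variant.other_allele for r in self._records],
                "beta": [r.beta for r in self._records],
                "se": [r.se for r in self._records],
                "pval": [r.pval for r in self._records],
                "eaf": [np.nan if r.eaf is None else r.eaf for r in self._records],
                "n": [np.nan if r.n is None else r.n for r in self._records],
            }
        )


@dataclass
class ReadAudit:
    """Accounting of a read: parsed + dropped = input rows, always."""

    n_input: int = 0
    n_kept: int = 0
    n_pval_clamped: int = 0
    dropped: list = field(default_factory=list)  # (row_label, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def lines(self) -> list[str]:
        return [f"{label}\t{reason}" for label, reason in self.dropped]

    def write(self, path) -> None:
        Path(path).write_text(
            "\n".join([f"# input={self.n_input} kept={self.n_kept} "
                       f"dropped={self.n_dropped} pval_clamped={self.n_pval_clamped}"]
                      + self.lines()) + "\n"
        )


@dataclass(frozen=True)
class ColumnMap:
    """Maps AssociationRecord fields to source-file column names.

    Either ``variant`` names a composite ``chr:pos:ref:alt`` column (the
    effect allele is the *alt* allele, as in Neale Lab exports), or
    ``chrom``/``pos``/``effect_allele``/``other_allele`` name separate
    columns. ``rsid``, ``eaf`` and ``n`` are optional.
    """

    beta: str = "beta"
    se: str = "se"
    pval: str = "pval"
    rsid: Optional[str] = "rsid"
    chrom: Optional[str] = "chrom"
    pos: Optional[str] = "pos"
    effect_allele: Optional[str] = "effect_allele"
    other_allele: Optional[str] = "other_allele"
    variant: Optional[str] = None  # composite chr:pos:ref:alt column
    eaf: Optional[str] = "eaf"
    n: Optional[str] = "n"
    sep: Optional[str] = None  # None = sniff from the first line

    def mandatory(self) -> dict:
        cols = {"beta": self.beta, "se": self.se, "pval": self.pval}
        if self.variant is not None:
            cols["variant"] = self.variant
        else:
            for f in ("chrom", "pos", "effect_allele", "other_allele"):
                name = getattr(self, f)
                if name is None:
                    raise ConfigurationError(
                        f"ColumnMap needs either 'variant' or a '{f}' column"
                    )
                cols[f] = name
        return cols


DIALECTS: dict[str, ColumnMap] = {
    "generic": ColumnMap(),
    # Neale Lab UK Biobank round-2 export: variant = "chr:pos:ref:alt",
    # betas refer to the alt allele; minor_AF is used as a frequency proxy only
    # when an explicit alt-allele frequency column is absent.
    "neale": ColumnMap(
        variant="variant",
        rsid=None,
        chrom=None,
        pos=None,
        effect_allele=None,
        other_allele=None,
        beta="beta",
        se="se",
        pval="pval",
        eaf="minor_AF",
        n="n_complete_samples",
        sep="\t",
    ),
    # GWAS Catalog harmonized summary-statistics layout.
    "gwascat": ColumnMap(
        rsid="hm_rsid",
        chrom="hm_chrom",
        pos="hm_pos",
        effect_allele="hm_effect_allele",
        other_allele="hm_other_allele",
        beta="hm_beta",
        se="standard_error",
        pval="p_value",
        eaf="hm_effect_allele_frequency",
        n="n",
        sep="\t",
    ),
}


def _resolve_dialect(dialect: Union[str, ColumnMap]) -> ColumnMap:
    if isinstance(dialect, ColumnMap):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; built-ins: {sorted(DIALECTS)}"
        ) from None


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    f = float(value)
    return None if math.isnan(f) else f


def read_sumstats(
    path,
    dialect: Union[str, ColumnMap] = "generic",
    *,
    trait_name: str,
    trait_role: str,
    n_default: Optional[float] = None,
    audit_path=None,
) -> SumStats:
    """Read a delimited summary-statistics file into a :class:`SumStats`.

    Rows failing the domain invariants are dropped, not errored, and listed in
    the returned object's ``audit`` attribute (also written to ``audit_path``
    when given). Missing mandatory columns raise :class:`ConfigurationError`.
    """
    cmap = _resolve_dialect(dialect)
    sep = cmap.sep
    try:
        if sep is None:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                             compression="infer")
        else:
            df = pd.read_csv(path, sep=sep, dtype=str, compression="infer")
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise OSError(f"cannot read summary statistics from {path}: {exc}") from exc

    mandatory = cmap.mandatory()
    missing = [col for col in mandatory.values() if col not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mandatory column(s) {missing} not found in header "
            f"{list(df.columns)}"
        )

    audit = ReadAudit(n_input=len(df))
    s = SumStats(trait_name, trait_role, n_default=n_default)

    def col(name: Optional[str]):
        return df[name] if name is not None and name in df.columns else None

    rsid_c, eaf_c, n_c = col(cmap.rsid), col(cmap.eaf), col(cmap.n)
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        label = rowd.get(cmap.rsid) if cmap.rsid in df.columns else None
        try:
            if cmap.variant is not None:
                parts = str(rowd[cmap.variant]).split(":")
                if len(parts) != 4:
                    raise ValidationError("variant column is not chr:pos:ref:alt")
                chrom, pos_s, ref, alt = parts
                ea, oa = alt.strip().upper(), ref.strip().upper()
                rsid = (rowd.get(cmap.rsid) if rsid_c is not None else None) or rowd[cmap.variant]
                pos = int(pos_s)
            else:
                chrom = str(rowd[cmap.chrom]).strip()
                pos = int(float(rowd[cmap.pos]))
                ea = str(rowd[cmap.effect_allele]).strip().upper()
                oa = str(rowd[cmap.other_allele]).strip().upper()
                rsid = rowd[cmap.rsid] if rsid_c is not None else f"{chrom}:{pos}"
            label = label or rsid

            pval = float(rowd[cmap.pval])
            if pval == 0.0:
                # clamp so downstream z / Steiger statistics stay finite
                pval = MIN_PVAL
                audit.n_pval_clamped += 1
            rec = AssociationRecord(
                variant=VariantKey(str(rsid), chrom, pos, ea, oa),
                beta=float(rowd[cmap.beta]),
                se=float(rowd[cmap.se]),
                pval=pval,
                eaf=_opt_float(rowd.get(cmap.eaf)) if eaf_c is not None else None,
                n=_opt_float(rowd.get(cmap.n)) if n_c is not None else None,
            )
            s.add(rec)
            audit.n_kept += 1
        except ValidationError as exc:
            audit.dropped.append((label or f"row{i}", str(exc)))
        except (ValueError, TypeError) as exc:
            audit.dropped.append((label or f"row{i}", f"unparseable: {exc}"))

    s.audit = audit
    if audit_path is not None:
        audit.write(audit_path)
    return s


_CANONICAL_COLS = ["rsid", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "pval", "eaf", "n"]


def write_sumstats(s: SumStats, path) -> int:
    """Write a SumStats to tab-delimited text (gzip if the path ends in .gz).

    Numeric fields are written at 10 significant digits so that a read/write
    round trip reproduces every record. Returns the number of data rows.
    """
    df = s.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              compression="infer")
    return len(df)


def intersect_variants(a: SumStats, b: SumStats) -> list[VariantKey]:
    """Variant keys of ``a`` that resolve in ``b`` (rsid match, locus fallback).

    Allele compatibility is deliberately not checked here; that is
    harmonization's job.
    """
    return [rec.variant for rec in a if b.get(rec.variant) is not None]
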