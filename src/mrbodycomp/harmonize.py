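"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs the variant-exposure and variant-outcome effects to refer
to the *same* effect allele. For each instrument this module compares allele
labels between the exposure and outcome records and either keeps the outcome
effect unchanged, negates it (allele labels swapped), relabels across strands
(A<->T, C<->G complements), or drops the variant.

Palindromic variants (allele pair A/T or C/G) cannot be resolved from allele
labels alone: the same pair reads identically on both strands. The default
policy orients them by effect-allele frequency — both frequencies must sit
clearly away from 0.5 (outside ``0.5 ± eaf_window``) and on the same side;
anything ambiguous, discordant, or missing a frequency is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import NoUsableInstrumentsError, ValidationError
from .sumstats import AssociationRecord, SumStats, VariantKey

__all__ = [
    "complement_allele",
    "is_palindromic",
    "harmonize_pair",
    "harmonize_sets",
    "HarmonizedInstrumentSet",
    "HarmonizationAudit",
    "PairDecision",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Palindrome policies understood by :func:`harmonize_pair`.
POLICIES = ("drop_all", "infer_by_frequency")

DEFAULT_EAF_WINDOW = 0.08


def complement_allele(a: str) -> str:
    """Watson–Crick complement of a single base (A<->T, C<->G)."""
    try:
        return _COMPLEMENT[a]
    except KeyError:
        raise ValidationError(f"not a valid allele: {a!r}") from None


def is_palindromic(v: VariantKey) -> bool:
    """True for A/T and C/G variants, whose strand is ambiguous."""
    return complement_allele(v.effect_allele) == v.other_allele


@dataclass(frozen=True)
class PairDecision:
    """Outcome of harmonizing one exposure/outcome record pair."""

    kept: bool
    action: str  # kept: unchanged|flipped|strand|strand_flipped|palindromic_kept|palindromic_flipped
    # dropped: palindromic_drop_policy|palindromic_missing_eaf|palindromic_ambiguous|allele_mismatch
    exposure: Optional[AssociationRecord] = None
    outcome: Optional[AssociationRecord] = None


def _flip(rec: AssociationRecord) -> AssociationRecord:
    v = rec.variant
    return replace(
        rec,
        variant=VariantKey(v.rsid, v.chrom, v.pos, v.other_allele, v.effect_allele),
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def _strand_relabel(rec: AssociationRecord) -> AssociationRecord:
    v = rec.variant
    return replace(
        rec,
        variant=VariantKey(
            v.rsid, v.chrom, v.pos,
            complement_allele(v.effect_allele), complement_allele(v.other_allele),
        ),
    )


def harmonize_pair(
    exp: AssociationRecord,
    out: AssociationRecord,
    policy: str = "infer_by_frequency",
    eaf_window: float = DEFAULT_EAF_WINDOW,
) -> PairDecision:
    """Align one outcome record to the exposure record's effect allele.

    The two records must refer to the same variant (same rsid or same
    coordinates). Returns a :class:`PairDecision`; the exposure record is
    passed through untouched.
    """
    if policy not in POLICIES:
        raise ValidationError(f"unknown palindrome policy {policy!r}; choose from {POLICIES}")
    ev, ov = exp.variant, out.variant
    if ev.rsid != ov.rsid and ev.locus != ov.locus:
        raise ValidationError(
            f"harmonize_pair got different variants: {ev.rsid} vs {ov.rsid}"
        )

    if is_palindromic(ev):
        if ov.allele_pair != ev.allele_pair:
            return PairDecision(False, "allele_mismatch")
        if policy == "drop_all":
            return PairDecision(False, "palindromic_drop_policy")
        # align labels literally first; for a palindromic pair a strand flip
        # is indistinguishable from a label swap, so the frequencies decide
        out2 = out if ov.effect_allele == ev.effect_allele else _flip(out)
        action = "palindromic_kept" if out2 is out else "palindromic_flipped"
        if exp.eaf is None or out2.eaf is None:
            return PairDecision(False, "palindromic_missing_eaf")
        lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
        if lo <= exp.eaf <= hi or lo <= out2.eaf <= hi:
            return PairDecision(False, "palindromic_ambiguous")
        if (exp.eaf < 0.5) != (out2.eaf < 0.5):
            # frequencies disagree in orientation: strand flip suspected, drop
            return PairDecision(False, "palindromic_ambiguous")
        return PairDecision(True, action, exp, out2)

    # non-palindromic: try literal match, swap, strand relabel, strand+swap
    if (ov.effect_allele, ov.other_allele) == (ev.effect_allele, ev.other_allele):
        return PairDecision(True, "unchanged", exp, out)
    if (ov.effect_allele, ov.other_allele) == (ev.other_allele, ev.effect_allele):
        return PairDecision(True, "flipped", exp, _flip(out))
    oc = _strand_relabel(out)
    if (oc.variant.effect_allele, oc.variant.other_allele) == (ev.effect_allele, ev.other_allele):
        return PairDecision(True, "strand", exp, oc)
    if (oc.variant.effect_allele, oc.variant.other_allele) == (ev.other_allele, ev.effect_allele):
        return PairDecision(True, "strand_flipped", exp, _flip(oc))
    return PairDecision(False, "allele_mismatch")


@dataclass
class HarmonizationAudit:
    """Per-variant harmonization actions plus reconciling counts."""

    n_input: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_strand_corrected: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_mismatch: int = 0
    n_dropped_not_in_outcome: int = 0
    actions: list = field(default_factory=list)  # (rsid, action)

    @property
    def n_dropped(self) -> int:
        return (self.n_dropped_palindromic + self.n_dropped_mismatch
                + self.n_dropped_not_in_outcome)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.actions, columns=["rsid", "action"])


class HarmonizedInstrumentSet:
    """Aligned per-instrument effect arrays for one exposure–outcome pair.

    Parallel arrays: ``bx``/``sx`` are the variant-exposure effects and
    standard errors, ``by``/``sy`` the variant-outcome ones, all referring to
    the same (harmonized) effect allele per instrument.
    """

    def __init__(self, exposure_name, outcome_name, variants, bx, sx, by, sy,
                 eaf=None, n_exp=None, n_out=None):
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        self.variants = list(variants)
        self.bx = np.asarray(bx, dtype=float)
        self.sx = np.asarray(sx, dtype=float)
        self.by = np.asarray(by, dtype=float)
        self.sy = np.asarray(sy, dtype=float)
        n = len(self.variants)
        if not (len(self.bx) == len(self.sx) == len(self.by) == len(self.sy) == n):
            raise ValidationError("harmonized arrays must have equal length")
        if n < 1:
            raise NoUsableInstrumentsError(
                f"no usable instruments for {exposure_name} -> {outcome_name}"
            )
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValidationError("all standard errors must be positive")
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != n:
            raise ValidationError("duplicate variants in harmonized set")
        self.eaf = None if eaf is None else np.asarray(eaf, dtype=float)
        self.n_exp = None if n_exp is None else np.asarray(n_exp, dtype=float)
        self.n_out = None if n_out is None else np.asarray(n_out, dtype=float)

    def __len__(self) -> int:
        return len(self.variants)

    def subset(self, indices) -> "HarmonizedInstrumentSet":
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HarmonizedInstrumentSet(
            self.exposure_name, self.outcome_name,
            [self.variants[i] for i in idx],
            self.bx[idx], self.sx[idx], self.by[idx], self.sy[idx],
            None if self.eaf is None else self.eaf[idx],
            None if self.n_exp is None else self.n_exp[idx],
            None if self.n_out is None else self.n_out[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rsid": [v.rsid for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "bx": self.bx, "sx": self.sx, "by": self.by, "sy": self.sy,
            }
        )
        df["eaf"] = np.nan if self.eaf is None else self.eaf
        df["n_exp"] = np.nan if self.n_exp is None else self.n_exp
        df["n_out"] = np.nan if self.n_out is None else self.n_out
        df.insert(0, "exposure", self.exposure_name)
        df.insert(1, "outcome", self.outcome_name)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HarmonizedInstrumentSet":
        variants = [
            VariantKey(str(r.rsid), str(r.chrom), int(r.pos),
                       str(r.effect_allele), str(r.other_allele))
            for r in df.itertuples(index=False)
        ]

        def arr(col):
            if col not in df.columns or df[col].isna().all():
                return None
            return df[col].to_numpy(dtype=float)

        return cls(
            str(df["exposure"].iloc[0]) if "exposure" in df else "exposure",
            str(df["outcome"].iloc[0]) if "outcome" in df else "outcome",
            variants,
            df["bx"].to_numpy(float), df["sx"].to_numpy(float),
            df["by"].to_numpy(float), df["sy"].to_numpy(float),
            arr("eaf"), arr("n_exp"), arr("n_out"),
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path) -> "HarmonizedInstrumentSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def harmonize_sets(
    exposure_instruments: SumStats,
    outcome: SumStats,
    policy: str = "infer_by_frequency",
    eaf_window: float = DEFAULT_EAF_WINDOW,
) -> tuple[HarmonizedInstrumentSet, HarmonizationAudit]:
    """Harmonize every exposure instrument against the outcome statistics.

    Instruments absent from the outcome are dropped with reason
    ``not_in_outcome``. Raises :class:`NoUsableInstrumentsError` when nothing
    survives, so estimators never see an empty set.
    """
    audit = HarmonizationAudit(n_input=len(exposure_instruments))
    variants, bx, sx, by, sy, eaf, n_exp, n_out = [], [], [], [], [], [], [], []
    any_eaf = False
    for exp_rec in exposure_instruments:
        out_rec = outcome.get(exp_rec.variant)
        if out_rec is None:
            audit.n_dropped_not_in_outcome += 1
            audit.actions.append((exp_rec.variant.rsid, "not_in_outcome"))
            continue
        dec = harmonize_pair(exp_rec, out_rec, policy, eaf_window)
        audit.actions.append((exp_rec.variant.rsid, dec.action))
        if not dec.kept:
            if dec.action.startswith("palindromic"):
                audit.n_dropped_palindromic += 1
            else:
                audit.n_dropped_mismatch += 1
            continue
        audit.n_kept += 1
        if "flip" in dec.action:
            audit.n_flipped += 1
        if dec.action.startswith("strand"):
            audit.n_strand_corrected += 1
        e, o = dec.exposure, dec.outcome
        variants.append(e.variant)
        bx.append(e.beta); sx.append(e.se)
        by.append(o.beta); sy.append(o.se)
        eaf.append(np.nan if e.eaf is None else e.eaf)
        any_eaf = any_eaf or e.eaf is not None
        n_exp.append(np.nan if e.n is None else e.n)
        n_out.append(np.nan if o.n is None else o.n)
    if not variants:
        raise NoUsableInstrumentsError(
            f"no usable instruments for {exposure_instruments.trait_name} -> "
            f"{outcome.trait_name} (of {audit.n_input} inputs, "
            f"{audit.n_dropped_not_in_outcome} not in outcome, "
            f"{audit.n_dropped_palindromic} palindromic, "
            f"{audit.n_dropped_mismatch} allele mismatches)"
        )
    hset = HarmonizedInstrumentSet(
        exposure_instruments.trait_name, outcome.trait_name, variants,
        bx, sx, by, sy,
        eaf if any_eaf else None,
        n_exp, n_out,
    )
    return hset, audit
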