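"""Exposure x outcome grid orchestration with Bonferroni correction.

A grid run walks every (exposure, outcome) pair: instrument selection
(significance filter + LD clumping when a reference is given), allele
harmonization, estimation with the requested methods, and the sensitivity
battery. Statistical significance uses the family-wise Bonferroni threshold
alpha / (n_exposures x n_outcomes) — 0.05/39 for a 13 x 3 grid.

Every stochastic stage consumes a deterministic sub-seed derived from
(seed, exposure, outcome, stage), so a single pair rerun in isolation
reproduces its grid rows exactly, and identical configs yield byte-identical
output files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from io import StringIO
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import estimators, sensitivity as sens
from .errors import ConfigurationError, MRError
from .harmonize import DEFAULT_EAF_WINDOW, HarmonizedInstrumentSet, harmonize_sets
from .instruments import ClumpConfig, GenotypeReference, PrecomputedLDTable, clump
from .simulate import simulate_grid
from .sumstats import SumStats, read_sumstats

__all__ = [
    "TraitSpec",
    "GridConfig",
    "GridResult",
    "bonferroni_threshold",
    "run_grid",
    "format_results",
    "parse_results",
    "format_ci",
    "subseed",
    "write_outputs",
]

METHODS = ("ivw", "wm", "egger")
SENSITIVITY = ("presso", "steiger", "loo")

_LONG_COLS = ["exposure", "outcome", "method", "n_snps", "beta", "se",
              "ci_low", "ci_high", "pval", "significant", "reason"]


def bonferroni_threshold(alpha: float, n_exposures: int, n_outcomes: int) -> float:
    """Family-wise threshold alpha / (exposures x outcomes), full precision."""
    if alpha <= 0 or n_exposures <= 0 or n_outcomes <= 0:
        raise ConfigurationError("alpha and grid dimensions must be positive")
    return alpha / (n_exposures * n_outcomes)


def subseed(seed: int, *parts) -> int:
    """Deterministic sub-seed < 2^31 from a master seed and context labels."""
    digest = hashlib.sha256("|".join([str(seed), *map(str, parts)]).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class TraitSpec:
    """One trait input: either a file path (+dialect) or an in-memory SumStats."""

    name: str
    path: Optional[str] = None
    dialect: str = "generic"
    n_default: Optional[float] = None
    sumstats: Optional[SumStats] = None

    def load(self, role: str) -> SumStats:
        if self.sumstats is not None:
            return self.sumstats
        if self.path is not None:
            return read_sumstats(self.path, self.dialect, trait_name=self.name,
                                 trait_role=role, n_default=self.n_default)
        raise ConfigurationError(f"trait {self.name!r}: no path or sumstats given")


@dataclass
class GridConfig:
    """Declarative description of a full exposure x outcome analysis grid."""

    exposures: Sequence[TraitSpec]
    outcomes: Sequence[TraitSpec]
    ld_reference: Union[GenotypeReference, PrecomputedLDTable, None] = None
    clump_cfg: Optional[ClumpConfig] = ClumpConfig()
    palindrome_policy: str = "infer_by_frequency"
    eaf_window: float = DEFAULT_EAF_WINDOW
    methods: Sequence[str] = ("ivw", "wm")
    sensitivity: Sequence[str] = ()
    alpha: float = 0.05
    seed: int = 0
    ivw_mode: Optional[str] = None  # None = multiplicative random when N >= 2
    wm_n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    select_instruments: bool = True  # apply filter/clump to exposures

    def __post_init__(self):
        problems = []
        if not self.exposures:
            problems.append("at least one exposure required")
        if not self.outcomes:
            problems.append("at least one outcome required")
        if not (0 < self.alpha < 1):
            problems.append(f"alpha must be in (0,1), got {self.alpha}")
        bad = set(self.methods) - set(METHODS)
        if bad:
            problems.append(f"unknown methods {sorted(bad)}; choose from {METHODS}")
        bad = set(self.sensitivity) - set(SENSITIVITY)
        if bad:
            problems.append(f"unknown sensitivity {sorted(bad)}; choose from {SENSITIVITY}")
        if problems:
            raise ConfigurationError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "GridConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}

        def traits(key):
            return [TraitSpec(name=t["name"], path=t.get("path"),
                              dialect=t.get("dialect", "generic"),
                              n_default=t.get("n_default"))
                    for t in doc.get(key, [])]

        exposures, outcomes = traits("exposures"), traits("outcomes")
        select_instruments = doc.get("select_instruments", True)
        if "simulate" in doc:
            # a synthetic grid replaces file inputs entirely; the generator's
            # instruments are already selected, so skip filtering by default
            sim_doc = dict(doc["simulate"])
            sim_doc.setdefault("seed", doc.get("seed", 0))
            sim_exp, sim_out, _ = simulate_grid(**sim_doc)
            exposures = [TraitSpec(name=s.trait_name, sumstats=s) for s in sim_exp]
            outcomes = [TraitSpec(name=s.trait_name, sumstats=s) for s in sim_out]
            select_instruments = doc.get("select_instruments", False)

        ld = None
        ld_doc = doc.get("ld_reference")
        if isinstance(ld_doc, dict):
            if "genotypes" in ld_doc:
                ld = GenotypeReference.read(ld_doc["genotypes"])
            elif "table" in ld_doc:
                ld = PrecomputedLDTable.read(ld_doc["table"])
            else:
                raise ConfigurationError("ld_reference needs 'genotypes' or 'table'")
        clump_doc = doc.get("clump")
        kwargs = dict(
            exposures=exposures,
            outcomes=outcomes,
            ld_reference=ld,
            clump_cfg=ClumpConfig(**clump_doc) if clump_doc else ClumpConfig(),
            palindrome_policy=doc.get("palindrome_policy", "infer_by_frequency"),
            eaf_window=doc.get("eaf_window", DEFAULT_EAF_WINDOW),
            methods=tuple(doc.get("methods", ("ivw", "wm"))),
            sensitivity=tuple(doc.get("sensitivity", ())),
            alpha=doc.get("alpha", 0.05),
            seed=doc.get("seed", 0),
            ivw_mode=doc.get("ivw_mode"),
            wm_n_boot=doc.get("wm_n_boot", 1000),
            presso_n_sim=doc.get("presso_n_sim", 1000),
            presso_outlier_alpha=doc.get("presso_outlier_alpha", 0.05),
            select_instruments=select_instruments,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class GridResult:
    """Long-format estimates, per-pair sensitivity reports, and the run log."""

    results: pd.DataFrame
    sensitivity: dict = dc_field(default_factory=dict)  # (exp, out) -> dict
    harmonized: dict = dc_field(default_factory=dict)   # (exp, out) -> HarmonizedInstrumentSet
    log: list = dc_field(default_factory=list)
    bonferroni: float = 0.05


def _estimate(method, hset: HarmonizedInstrumentSet, cfg: GridConfig, seed: int):
    if method == "ivw":
        return estimators.ivw(hset, cfg.ivw_mode)
    if method == "wm":
        return estimators.weighted_median(hset, n_boot=cfg.wm_n_boot, seed=seed)
    if method == "egger":
        return estimators.mr_egger(hset)
    raise ConfigurationError(f"unknown method {method!r}")


def run_grid(cfg: GridConfig) -> GridResult:
    """Execute the full grid; failures of one pair yield NA rows, not aborts."""
    threshold = bonferroni_threshold(cfg.alpha, len(cfg.exposures), len(cfg.outcomes))
    result = GridResult(results=pd.DataFrame(columns=_LONG_COLS), bonferroni=threshold)
    log = result.log
    log.append(f"grid: {len(cfg.exposures)} exposures x {len(cfg.outcomes)} outcomes, "
               f"methods={list(cfg.methods)}, bonferroni={threshold:.6g}")

    rows = []
    outcomes = [(o.name, o.load("outcome")) for o in cfg.outcomes]

    for espec in cfg.exposures:
        exp_full = espec.load("exposure")
        instruments = exp_full
        if cfg.select_instruments and cfg.clump_cfg is not None:
            if cfg.ld_reference is not None:
                keys = clump(exp_full, cfg.ld_reference, cfg.clump_cfg)
                instruments = SumStats(exp_full.trait_name, "exposure",
                                       (exp_full[k] for k in keys),
                                       n_default=exp_full.n_default)
            else:
                from .instruments import filter_genomewide
                instruments = filter_genomewide(exp_full, cfg.clump_cfg.p_threshold)
        log.append(f"{espec.name}: {len(exp_full)} records, "
                   f"{len(instruments)} instruments selected")

        for oname, ostats in outcomes:
            try:
                hset, audit = harmonize_sets(instruments, ostats,
                                             cfg.palindrome_policy, cfg.eaf_window)
                log.append(f"{espec.name} -> {oname}: harmonized {audit.n_kept}"
                           f"/{audit.n_input} (flipped {audit.n_flipped}, "
                           f"dropped {audit.n_dropped})")
                result.harmonized[(espec.name, oname)] = hset
            except MRError as exc:
                for method in cfg.methods:
                    rows.append((espec.name, oname, method, 0, *[np.nan] * 5,
                                 False, str(exc)))
                continue

            for method in cfg.methods:
                seed = subseed(cfg.seed, espec.name, oname, method)
                try:
                    est = _estimate(method, hset, cfg, seed)
                    rows.append((espec.name, oname, method, est.n_snps, est.beta,
                                 est.se, est.ci_low, est.ci_high, est.pval,
                                 bool(est.pval < threshold), ""))
                except MRError as exc:
                    rows.append((espec.name, oname, method, len(hset),
                                 *[np.nan] * 5, False, str(exc)))

            reports = {}
            for stage in cfg.sensitivity:
                seed = subseed(cfg.seed, espec.name, oname, stage)
                try:
                    if stage == "presso":
                        reports["presso"] = sens.mr_presso(
                            hset, n_sim=cfg.presso_n_sim, seed=seed,
                            outlier_alpha=cfg.presso_outlier_alpha)
                    elif stage == "steiger":
                        reports["steiger"] = sens.steiger_test(hset)
                    elif stage == "loo":
                        reports["loo"] = sens.leave_one_out(hset, cfg.ivw_mode)
                except MRError as exc:
                    reports[stage] = None
                    log.append(f"{espec.name} -> {oname}: {stage} failed: {exc}")
            if reports:
                result.sensitivity[(espec.name, oname)] = reports

    result.results = pd.DataFrame(rows, columns=_LONG_COLS)
    return result


def format_ci(beta: float, ci_low: float, ci_high: float, decimals: int = 2) -> str:
    """Render "beta (low to high)" at fixed decimals, e.g. "-0.24 (-0.28 to -0.20)"."""
    fmt = f"{{:.{decimals}f}}"
    return f"{fmt.format(beta)} ({fmt.format(ci_low)} to {fmt.format(ci_high)})"


def format_results(table: pd.DataFrame, style: str = "long") -> str:
    """Serialize a results table as TSV text.

    ``long``: tidy one-row-per-estimate. ``wide``: one row per exposure with
    full-precision (outcome, method) column blocks, the shape of a published
    MR results table. ``pretty``: like wide but with "beta (low to high)"
    display strings at 2 decimals and p-values at 3 significant digits.
    """
    if table.empty:
        raise ConfigurationError("cannot format an empty results table")
    if style == "long":
        out = table.copy()
        out["pval"] = out["pval"].map(lambda p: f"{p:.3e}" if pd.notna(p) else "NA")
        buf = StringIO()
        out.to_csv(buf, sep="\t", index=False, float_format="%.10g")
        return buf.getvalue()
    if style in ("wide", "pretty"):
        wide = table.pivot_table(
            index="exposure",
            columns=["outcome", "method"],
            values=["n_snps", "beta", "se", "ci_low", "ci_high", "pval"],
            aggfunc="first", sort=False,
        )
        buf = StringIO()
        if style == "wide":
            wide.columns = [f"{o}:{m}:{v}" for v, o, m in wide.columns]
            wide.reset_index().to_csv(buf, sep="\t", index=False, float_format="%.10g")
            return buf.getvalue()
        pretty = pd.DataFrame(index=wide.index)
        pairs = sorted({(o, m) for _, o, m in wide.columns},
                       key=lambda om: str(om))
        for o, m in pairs:
            pretty[f"{o}:{m}"] = [
                format_ci(wide[("beta", o, m)][e], wide[("ci_low", o, m)][e],
                          wide[("ci_high", o, m)][e])
                for e in wide.index
            ]
            pretty[f"{o}:{m}:P"] = [f"{wide[('pval', o, m)][e]:.3g}" for e in wide.index]
        pretty.reset_index().to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    raise ConfigurationError(f"unknown style {style!r}")


def parse_results(text: str, style: str = "long") -> pd.DataFrame:
    """Inverse of :func:`format_results` for the long and wide styles."""
    df = pd.read_csv(StringIO(text), sep="\t")
    if style == "long":
        return df
    if style == "wide":
        records = []
        value_cols = [c for c in df.columns if c != "exposure"]
        pairs = []
        for c in value_cols:
            o, m, v = c.split(":")
            if (o, m) not in pairs:
                pairs.append((o, m))
        for _, row in df.iterrows():
            for o, m in pairs:
                records.append({
                    "exposure": row["exposure"], "outcome": o, "method": m,
                    **{v: row[f"{o}:{m}:{v}"]
                       for v in ("n_snps", "beta", "se", "ci_low", "ci_high", "pval")},
                })
        return pd.DataFrame(records)
    raise ConfigurationError(f"unknown style {style!r}")


def write_outputs(result: GridResult, out_dir) -> None:
    """Write results_long.tsv / results_wide.tsv / sensitivity reports / run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results_long.tsv").write_text(format_results(result.results, "long"))
    (out / "results_wide.tsv").write_text(format_results(result.results, "wide"))
    (out / "run.log").write_text("\n".join(result.log) + "\n")
    for (ename, oname), reports in result.sensitivity.items():
        pair_dir = out / "sensitivity" / f"{ename}__{oname}"
        pair_dir.mkdir(parents=True, exist_ok=True)
        for stage, rep in reports.items():
            path = pair_dir / f"{stage}.tsv"
            if rep is None:
                path.write_text("failed\n")
            elif stage == "loo":
                rep.rows.to_csv(path, sep="\t", index=False, float_format="%.10g")
            elif stage == "steiger":
                pd.DataFrame([{
                    "r2_exposure": rep.r2_exposure, "r2_outcome": rep.r2_outcome,
                    "correct_direction": rep.correct_direction, "pval": rep.pval,
                }]).to_csv(path, sep="\t", index=False, float_format="%.10g")
            elif stage == "presso":
                pd.DataFrame([{
                    "rss_obs": rep.rss_obs, "global_pval": rep.global_pval,
                    "n_outliers": len(rep.outlier_indices),
                    "outlier_rsids": ",".join(
                        result.harmonized[(ename, oname)].variants[i].rsid
                        for i in rep.outlier_indices),
                    "beta_raw": rep.beta_raw.beta,
                    "beta_corrected": rep.beta_corrected.beta,
                    "distortion_pval": rep.distortion_pval,
                }]).to_csv(path, sep="\t", index=False, float_format="%.10g")
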