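"""Summary-statistics I/O: parsing, validation, auditing, round trips."""

import gzip
import math

import numpy as np
import pandas as pd
import pytest

from mrbodycomp import (
    ColumnMap,
    ConfigurationError,
    SimulationConfig,
    SumStats,
    ValidationError,
    VariantKey,
    intersect_variants,
    read_sumstats,
    simulate_sumstats,
    write_sumstats,
)

from conftest import make_record, make_sumstats, make_variant

HEADER = "rsid\tchrom\tpos\teffect_allele\tother_allele\tbeta\tse\tpval\teaf\tn"


def _write(tmp_path, rows, header=HEADER, name="s.tsv"):
    path = tmp_path / name
    path.write_text("\n".join([header] + rows) + "\n")
    return path


VALID_ROWS = [
    "rs1\t1\t100\tA\tG\t0.1\t0.01\t1e-9\t0.3\t1000",
    "rs2\t1\t200\tC\tT\t-0.2\t0.02\t1e-12\t0.4\t1000",
    "rs3\t2\t300\tG\tA\t0.05\t0.01\t1e-8\t0.2\t1000",
    "rs4\t2\t400\tT\tC\t0.0\t0.03\t0.5\t0.1\t1000",
    "rs5\t3\t500\tA\tC\t0.3\t0.05\t1e-20\t0.45\t1000",
]


class TestRead:
    def test_all_valid_rows_kept(self, tmp_path):
        s = read_sumstats(_write(tmp_path, VALID_ROWS), trait_name="t", trait_role="exposure")
        assert len(s) == 5
        assert s.audit.n_dropped == 0
        assert s["rs2"].beta == -0.2
        assert s[("1", 100)].variant.rsid == "rs1"

    def test_invalid_rows_dropped_with_reasons(self, tmp_path):
        rows = VALID_ROWS + [
            "rs6\t3\t600\tA\tG\t0.1\t0\t1e-9\t0.3\t1000",      # se = 0
            "rs7\t3\t700\tAT\tG\t0.1\t0.01\t1e-9\t0.3\t1000",  # indel
        ]
        s = read_sumstats(_write(tmp_path, rows), trait_name="t", trait_role="exposure")
        assert len(s) == 5
        assert s.audit.n_dropped == 2
        assert s.audit.n_kept + s.audit.n_dropped == s.audit.n_input == 7
        reasons = dict(s.audit.dropped)
        assert "se" in reasons["rs6"]
        assert "allele" in reasons["rs7"].lower()

    def test_n_default_fills_missing_sample_size(self, tmp_path):
        rows = ["rs1\t1\t100\tA\tG\t0.1\t0.01\t1e-9\t0.3\t",
                "rs2\t1\t200\tC\tT\t0.2\t0.02\t1e-9\t0.4\t"]
        s = read_sumstats(_write(tmp_path, rows), trait_name="t",
                          trait_role="exposure", n_default=166413)
        assert all(rec.n == 166413 for rec in s)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = _write(tmp_path, ["rs1\t1\t100\tA\tG\t0.1\t0.01\t0.3\t1000"],
                      header=HEADER.replace("\tpval", ""))
        with pytest.raises(ConfigurationError, match="pval"):
            read_sumstats(path, trait_name="t", trait_role="exposure")

    def test_zero_pval_clamped_not_dropped(self, tmp_path):
        rows = ["rs1\t1\t100\tA\tG\t1.5\t0.01\t0\t0.3\t1000"]
        s = read_sumstats(_write(tmp_path, rows), trait_name="t", trait_role="exposure")
        assert len(s) == 1
        assert 0 < s["rs1"].pval < 1e-300
        assert s.audit.n_pval_clamped == 1

    def test_duplicate_locus_dropped(self, tmp_path):
        rows = ["rs1\t1\t100\tA\tG\t0.1\t0.01\t1e-9\t0.3\t1000",
                "rs1b\t1\t100\tA\tG\t0.2\t0.01\t1e-9\t0.3\t1000"]
        s = read_sumstats(_write(tmp_path, rows), trait_name="t", trait_role="exposure")
        assert len(s) == 1 and s.audit.n_dropped == 1

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            read_sumstats(tmp_path / "absent.tsv", trait_name="t", trait_role="exposure")


class TestDialects:
    def test_neale_composite_variant_column(self, tmp_path):
        path = tmp_path / "neale.tsv"
        path.write_text(
            "variant\tminor_AF\tn_complete_samples\tbeta\tse\tpval\n"
            "1:100:G:A\t0.3\t166413\t0.1\t0.01\t1e-9\n"
            "2:200:T:C\t0.4\t166413\t-0.2\t0.02\t1e-12\n"
        )
        s = read_sumstats(path, "neale", trait_name="t", trait_role="exposure")
        assert len(s) == 2
        rec = s[("1", 100)]
        # effect allele is the alt allele in the composite encoding
        assert rec.variant.effect_allele == "A" and rec.variant.other_allele == "G"
        assert rec.n == 166413

    def test_gwascat_harmonized_columns(self, tmp_path):
        path = tmp_path / "gc.tsv"
        path.write_text(
            "hm_rsid\thm_chrom\thm_pos\thm_effect_allele\thm_other_allele\t"
            "hm_beta\tstandard_error\tp_value\thm_effect_allele_frequency\tn\n"
            "rs10\t3\t500\tT\tG\t0.07\t0.008\t2e-15\t0.21\t194453\n"
        )
        s = read_sumstats(path, "gwascat", trait_name="TT", trait_role="outcome")
        assert len(s) == 1
        assert s["rs10"].variant.effect_allele == "T"

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError, match="dialect"):
            read_sumstats(_write(tmp_path, VALID_ROWS), "plink",
                          trait_name="t", trait_role="exposure")


class TestWriteRoundTrip:
    def test_count_conservation_and_header(self, tmp_path):
        s = make_sumstats([make_record(make_variant(i)) for i in range(5)])
        n = write_sumstats(s, tmp_path / "out.tsv")
        assert n == 5
        lines = (tmp_path / "out.tsv").read_text().strip().split("\n")
        assert len(lines) == 6  # header + 5 rows

    def test_empty_sumstats_writes_header_only(self, tmp_path):
        n = write_sumstats(make_sumstats([]), tmp_path / "empty.tsv")
        assert n == 0
        assert (tmp_path / "empty.tsv").read_text().strip() == "\t".join(
            ["rsid", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "pval", "eaf", "n"])

    def test_simulator_output_roundtrips_to_10_digits(self, tmp_path):
        exp, _, _ = simulate_sumstats(SimulationConfig(n_snps=30, seed=7))
        write_sumstats(exp, tmp_path / "rt.tsv")
        back = read_sumstats(tmp_path / "rt.tsv", trait_name=exp.trait_name,
                             trait_role="exposure")
        assert len(back) == len(exp)
        for rec in exp:
            b = back[rec.variant.rsid]
            assert b.variant == rec.variant
            for f in ("beta", "se", "pval", "eaf", "n"):
                x, y = getattr(rec, f), getattr(b, f)
                assert y == pytest.approx(x, rel=1e-9), f

    def test_gzip_roundtrip(self, tmp_path):
        s = make_sumstats([make_record(make_variant(i)) for i in range(4)])
        write_sumstats(s, tmp_path / "out.tsv.gz")
        with gzip.open(tmp_path / "out.tsv.gz", "rt") as fh:
            assert fh.readline().startswith("rsid\t")
        back = read_sumstats(tmp_path / "out.tsv.gz", trait_name="t", trait_role="exposure")
        assert len(back) == 4


class TestIntersect:
    def test_identical_sets(self):
        recs = [make_record(make_variant(i)) for i in range(10)]
        a, b = make_sumstats(recs), make_sumstats(recs, role="outcome")
        assert len(intersect_variants(a, b)) == 10

    def test_disjoint_sets(self):
        a = make_sumstats([make_record(make_variant(i)) for i in range(5)])
        b = make_sumstats([make_record(make_variant(i + 100)) for i in range(5)],
                          role="outcome")
        assert intersect_variants(a, b) == []

    def test_partial_overlap_matches_brute_force(self):
        a = make_sumstats([make_record(make_variant(i)) for i in range(10)])
        b = make_sumstats([make_record(make_variant(i)) for i in range(3, 13)],
                          role="outcome")
        got = {v.rsid for v in intersect_variants(a, b)}
        expected = {f"rs{i}" for i in range(10)} & {f"rs{i}" for i in range(3, 13)}
        assert got == expected and len(got) == 7

    def test_locus_fallback_when_rsids_differ(self):
        v1 = make_variant(1)
        v1_alias = VariantKey("rsX", v1.chrom, v1.pos, v1.effect_allele, v1.other_allele)
        a = make_sumstats([make_record(v1)])
        b = make_sumstats([make_record(v1_alias)], role="outcome")
        assert [v.rsid for v in intersect_variants(a, b)] == ["rs1"]


class TestInvariants:
    def test_rsid_and_locus_lookup_agree(self, tmp_path):
        s = read_sumstats(_write(tmp_path, VALID_ROWS), trait_name="t", trait_role="exposure")
        for rec in s:
            assert s.get(rec.variant.rsid) is s.get(rec.variant.locus)

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(se=-0.01), "se"),
        (dict(pval=0.0), "pval"),
        (dict(pval=1.5), "pval"),
        (dict(eaf=1.2), "eaf"),
        (dict(beta=math.inf), "beta"),
    ])
    def test_record_invariants_enforced(self, kwargs, msg):
        base = dict(beta=0.1, se=0.01, pval=1e-5, eaf=0.3)
        base.update(kwargs)
        with pytest.raises(ValidationError, match=msg):
            make_record(make_variant(0), **base)

    def test_variant_key_invariants(self):
        with pytest.raises(ValidationError):
            VariantKey("rs1", "1", 100, "A", "A")
        with pytest.raises(ValidationError):
            VariantKey("rs1", "1", 0, "A", "G")
        with pytest.raises(ValidationError):
            VariantKey("rs1", "1", 100, "N", "G")

    def test_duplicate_rsid_rejected_in_container(self):
        s = make_sumstats([make_record(make_variant(1))])
        clone = make_record(VariantKey("rs1", "9", 999, "A", "G"))
        with pytest.raises(ValidationError, match="duplicate"):
            s.add(clone)
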