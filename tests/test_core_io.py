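"""Core types, interval algebra, and reader/writer round trips."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_merge
from regcascade.core import (
    ChromSizes,
    ExpressionRecord,
    GeneSet,
    GenomicInterval,
    ParseError,
    RegionSet,
    ValidationError,
    merge_regions,
)
from regcascade import io as rcio
from conftest import random_region_set, triples


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="", start=0, end=10),
            dict(chrom="chr1", start=-1, end=10),
            dict(chrom="chr1", start=10, end=10),
            dict(chrom="chr1", start=10, end=5),
            dict(chrom="chr1", start=0, end=10, strand="x"),
            dict(chrom="chr1", start=0, end=10, summit=10),
        ],
    )
    def test_invalid_intervals_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            GenomicInterval(**kwargs)

    def test_half_open_overlap_semantics(self):
        a = GenomicInterval("chr1", 0, 10)
        assert a.overlaps(GenomicInterval("chr1", 9, 15))
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))  # book-ended
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))
        assert len(a) == 10


class TestMergeRegions:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([(0, 10), (10, 20)], [(0, 20)]),  # book-ended merge
            ([(0, 10), (5, 15), (30, 40)], [(0, 15), (30, 40)]),
            ([(0, 10), (20, 30)], [(0, 10), (20, 30)]),  # disjoint unchanged
        ],
    )
    def test_merge_examples(self, raw, expected):
        rs = RegionSet("x", [GenomicInterval("chr1", s, e) for s, e in raw])
        merged = merge_regions(rs)
        assert [(iv.start, iv.end) for iv in merged] == expected

    def test_merge_idempotent_and_coverage_preserving(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rs = random_region_set(rng, n=int(rng.integers(0, 15)))
            merged = merge_regions(rs)
            assert triples(merged) == brute_merge(triples(rs))
            assert triples(merge_regions(merged)) == triples(merged)
            assert merged.total_coverage() == rs.total_coverage()


class TestRegionSet:
    def test_sorted_on_construction_with_stable_ids(self):
        ivs = [GenomicInterval("chr2", 0, 5), GenomicInterval("chr1", 50, 60),
               GenomicInterval("chr1", 10, 20)]
        rs = RegionSet("t", ivs, region_ids=["a", "b", "c"])
        assert [iv.start for iv in rs] == [10, 50, 0]
        assert rs.region_ids == ("c", "b", "a")  # ids travel with intervals

    def test_duplicate_region_ids_rejected(self):
        with pytest.raises(ValidationError):
            RegionSet("t", [GenomicInterval("chr1", 0, 5)] * 2, region_ids=["a", "a"])

    def test_chrom_sizes_validation(self):
        sizes = ChromSizes({"chr1": 100})
        with pytest.raises(ValidationError):
            RegionSet("t", [GenomicInterval("chr1", 50, 120)], chrom_sizes=sizes)
        with pytest.raises(ValidationError):
            RegionSet("t", [GenomicInterval("chr9", 0, 10)], chrom_sizes=sizes)


class TestRegionReaders:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(rcio.read_regions(p, "bed3")) == 0

    def test_bed3_fixture_sorted(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t150\t250\nchr2\t0\t50\n")
        rs = rcio.read_regions(p, "bed3", label="a")
        assert len(rs) == 3
        assert (rs[0].chrom, rs[0].start, rs[0].end) == ("chr1", 100, 200)
        assert rs.region_ids == ("a:0", "a:1", "a:2")

    def test_narrowpeak_summit_absolute(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t200\tpk1\t500\t.\t8.5\t12.0\t9.1\t30\n")
        rs = rcio.read_regions(p, "narrowPeak")
        assert rs[0].summit == 130
        assert dict(rs[0].attrs)["signalValue"] == 8.5

    def test_narrowpeak_missing_summit(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t200\tpk1\t500\t.\t8.5\t12.0\t9.1\t-1\n")
        assert rcio.read_regions(p, "narrowPeak")[0].summit is None

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\tnope\t300\n")
        with pytest.raises(ParseError, match="2"):
            rcio.read_regions(p, "bed3")

    def test_end_not_greater_than_start_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValidationError):
            rcio.read_regions(p, "bed3")


class TestGeneReaders:
    def test_bed6_strand_aware_tss(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t1000\t5000\tgeneA\t0\t+\nchr1\t1000\t5000\tgeneB\t0\t-\n")
        genes = {g.gene_id: g for g in rcio.read_genes(p, "bed6")}
        assert genes["geneA"].tss == 1000
        assert genes["geneB"].tss == 4999

    def test_bed6_duplicate_and_missing_strand_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t10\tgA\t0\t+\nchr1\t20\t30\tgA\t0\t+\n")
        with pytest.raises(ValidationError, match="gA"):
            rcio.read_genes(p, "bed6")
        p.write_text("chr1\t0\t10\tgA\t0\t.\n")
        with pytest.raises(ValidationError):
            rcio.read_genes(p, "bed6")

    def test_gtf_coordinate_conversion(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text('chr1\tsrc\tgene\t2001\t6000\t.\t+\t.\tgene_id "gX";\n')
        (g,) = rcio.read_genes(p, "gtf")
        assert (g.gene_id, g.tss, g.strand) == ("gX", 2000, "+")

    def test_gtf_five_prime_most_transcript_wins(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\ts\ttranscript\t5001\t6000\t.\t-\t.\tgene_id "gY";\n'
            'chr1\ts\ttranscript\t4001\t9000\t.\t-\t.\tgene_id "gY";\n'
        )
        (g,) = rcio.read_genes(p, "gtf")
        assert g.tss == 8999  # 5'-most on minus strand = largest end - 1


class TestExpressionTable:
    def test_header_only_empty(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tlog2fc\tqvalue\n")
        assert len(rcio.read_expression_table(p)) == 0

    def test_simple_row_and_extra_columns_ignored(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tlog2fc\tpvalue\tqvalue\ng1\t1.0\t0.001\t0.05\n")
        table = rcio.read_expression_table(p)
        rec = table.get("g1")
        assert (rec.log2fc, rec.qvalue) == (1.0, 0.05)

    def test_duplicate_gene_rejected_by_name(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tlog2fc\tqvalue\ng1\t1.0\t0.05\ng1\t2.0\t0.01\n")
        with pytest.raises(ValidationError, match="g1"):
            rcio.read_expression_table(p)

    def test_qvalue_range_enforced(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tlog2fc\tqvalue\ng1\t1.0\t1.5\n")
        with pytest.raises(ValidationError):
            rcio.read_expression_table(p)

    def test_invalid_record_values(self):
        with pytest.raises(ValidationError):
            ExpressionRecord("g", float("nan"), 0.5)


class TestRoundTrips:
    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_region_round_trip_randomized(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        rs = random_region_set(rng, label="rt", n=int(rng.integers(0, 12)))
        p = tmp_path_factory.mktemp("rt") / "rt.bed"
        rcio.write_region_set(rs, p)
        back = rcio.read_regions(p, "bed6", label="rt")
        assert triples(back) == triples(rs)
        assert [iv.name for iv in back] == list(rs.region_ids)

    def test_gene_records_round_trip(self, tmp_path):
        import regcascade.core as core

        genes = [core.GeneRecord("gA", "chr1", 1000, "+"),
                 core.GeneRecord("gB", "chr1", 5000, "-")]
        p = tmp_path / "g.bed"
        rcio.write_gene_records(genes, p, body=100)
        back = rcio.read_genes(p, "bed6")
        assert [(g.gene_id, g.tss, g.strand) for g in back] == [
            ("gA", 1000, "+"), ("gB", 5000, "-")
        ]

    def test_gene_set_written_sorted_and_read_back(self, tmp_path):
        gs = GeneSet.build("stageX", ["g2", "g1"], stage="demo", params={"k": 1})
        p = tmp_path / "gs.tsv"
        rcio.write_gene_set(gs, p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["g1", "g2"]
        assert rcio.read_gene_set(p).gene_ids == gs.gene_ids

    def test_chrom_sizes_round_trip(self, tmp_path):
        sizes = ChromSizes({"chr1": 1000, "chr2": 500})
        p = tmp_path / "cs.tsv"
        rcio.write_chrom_sizes(sizes, p)
        assert rcio.read_chrom_sizes(p) == sizes


class TestGeneSet:
    def test_derivation_appends_provenance(self):
        base = GeneSet.build("responsive", ["g1", "g2", "g3"], stage="select", params={"q": 0.1})
        child = base.derive("regulated", ["g1"], stage="intersect", params={"w": 200})
        assert len(child.provenance) == 2
        assert child.provenance[0][0] == "select"

    def test_derive_rejects_non_subset(self):
        base = GeneSet.build("a", ["g1"])
        with pytest.raises(ValidationError):
            base.derive("b", ["g1", "g9"], stage="x")
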