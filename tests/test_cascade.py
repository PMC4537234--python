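"""Staged evidence integration: thresholds, intersections, invariants."""

from __future__ import annotations

import json

import numpy as np
import pytest

from regcascade.cascade import (
    RunConfig,
    ThresholdSpec,
    annotate_enhancer_state,
    derive_high_confidence,
    derive_in_vivo,
    derive_regulated,
    derive_rmj_regulated,
    rmj_regions,
    run_cascade,
    select_responsive,
)
from regcascade.core import (
    ExpressionRecord,
    ExpressionTable,
    GeneRecord,
    GeneSet,
    GenomicInterval,
    RegionSet,
    ValidationError,
)
from regcascade.simulate import SyntheticConfig, generate_dataset


def rs(label, raw, chrom="chr1"):
    return RegionSet(label, [GenomicInterval(chrom, s, e) for s, e in raw])


class TestThresholds:
    def test_spec_validation(self):
        with pytest.raises(ValidationError):
            ThresholdSpec(q_max=0.0, fc_min=1.5)
        with pytest.raises(ValidationError):
            ThresholdSpec(q_max=0.1, fc_min=1.0)

    def test_fold_change_is_linear_threshold(self):
        table = ExpressionTable(
            [
                ExpressionRecord("fc2", 1.0, 0.05),    # FC 2.0 > 1.5 -> up
                ExpressionRecord("fc14", 0.5, 0.01),   # FC 1.41 <= 1.5 -> out
            ]
        )
        up, down = select_responsive(table, ThresholdSpec(0.1, 1.5))
        assert up.gene_ids == {"fc2"} and len(down) == 0

    def test_four_row_fixture(self):
        table = ExpressionTable(
            [
                ExpressionRecord("r1", 1.0, 0.05),
                ExpressionRecord("r2", 0.5, 0.01),
                ExpressionRecord("r3", -1.2, 0.09),
                ExpressionRecord("r4", 2.0, 0.2),
            ]
        )
        up, down = select_responsive(table, ThresholdSpec(0.1, 1.5))
        assert up.gene_ids == {"r1"}
        assert down.gene_ids == {"r3"}
        assert not up.gene_ids & down.gene_ids

    def test_strict_inequalities_at_exact_threshold(self):
        table = ExpressionTable(
            [
                ExpressionRecord("at_q", 1.0, 0.1),                 # q not < 0.1
                ExpressionRecord("at_fc", float(np.log2(1.5)), 0.01),  # FC not > 1.5
            ]
        )
        up, down = select_responsive(table, ThresholdSpec(0.1, 1.5))
        assert len(up) == 0 and len(down) == 0


class TestDeriveRegulated:
    def test_disjoint_and_subset_cases(self):
        responsive = GeneSet.build("responsive", ["g1", "g2"])
        assert len(derive_regulated(responsive, GeneSet.build("bound", ["g9"])).genes) == 0
        full = derive_regulated(responsive, GeneSet.build("bound", ["g1", "g2", "g3"]))
        assert full.genes.gene_ids == {"g1", "g2"} and full.bound_fraction == 1.0

    def test_random_fixture_equals_set_intersection(self):
        rng = np.random.default_rng(1)
        ids = [f"g{i}" for i in range(40)]
        a = set(rng.choice(ids, 15, replace=False))
        b = set(rng.choice(ids, 20, replace=False))
        res = derive_regulated(GeneSet.build("resp", a), GeneSet.build("bound", b))
        assert res.genes.gene_ids == a & b
        assert res.bound_fraction == len(a & b) / len(a)


class TestRmjRegions:
    def test_identical_sets_one_cluster(self):
        a = rs("runx1", [(0, 10)])
        assert len(rmj_regions(a, rs("m", [(0, 10)]), rs("c", [(0, 10)]))) == 1

    def test_pairwise_only_overlaps_yield_empty(self):
        runx1 = rs("r", [(0, 10), (100, 110)])
        myod = rs("m", [(5, 15)])          # overlaps first cluster only
        cjun = rs("c", [(105, 115)])       # overlaps second cluster only
        assert len(rmj_regions(runx1, myod, cjun)) == 0

    def test_matches_venn3_triple_class(self):
        from regcascade.overlap import venn3

        rng = np.random.default_rng(9)
        from conftest import random_region_set

        for _ in range(100):
            a = random_region_set(rng, "A", n=int(rng.integers(0, 8)))
            b = random_region_set(rng, "B", n=int(rng.integers(0, 8)))
            c = random_region_set(rng, "C", n=int(rng.integers(0, 8)))
            assert len(rmj_regions(a, b, c)) == venn3(a, b, c).abc


class TestEnhancerState:
    def test_conjunction_of_both_marks(self):
        peaks = rs("p", [(0, 100), (200, 300)])
        me1 = rs("me1", [(50, 150), (250, 350)])
        ac = rs("ac", [(0, 60)])
        atac = rs("atac", [(400, 500)])
        state = annotate_enhancer_state(peaks, me1, ac, atac)
        flags = state.as_map()
        assert flags["p:0"].active_enhancer and not flags["p:0"].open_chromatin
        assert not flags["p:1"].active_enhancer  # H3K4me1 only
        assert state.fraction_active == 0.5 and state.fraction_open == 0.0

    def test_planted_mark_rate_recovered(self):
        ds = generate_dataset(
            SyntheticConfig(seed=21, n_runx1_peaks=800, n_genes=100,
                            chrom_length=4_000_000, write_fasta=False,
                            n_background_marks=0)
        )
        state = annotate_enhancer_state(
            ds.regions["runx1"], ds.regions["h3k4me1"], ds.regions["h3k27ac"], ds.regions["atac"]
        )
        sd = np.sqrt(0.7 * 0.3 / 800)
        assert abs(state.fraction_active - 0.7) <= 3 * sd


class TestHighConfidence:
    def make_inputs(self):
        genes = [GeneRecord("gA", "chr1", 100, "+"), GeneRecord("gB", "chr1", 5000, "+")]
        rmj = RegionSet(
            "RMJ",
            [GenomicInterval("chr1", 80, 120), GenomicInterval("chr1", 4950, 5050)],
            region_ids=["RMJ:0", "RMJ:1"],
        )
        rmj_reg = GeneSet.build("rmj_regulated", ["gA", "gB"])
        return genes, rmj, rmj_reg

    def state_for(self, rmj, marked_ids, open_ids):
        me1 = RegionSet("me1", [iv for rid, iv in zip(rmj.region_ids, rmj.intervals) if rid in marked_ids])
        ac = RegionSet("ac", [iv for rid, iv in zip(rmj.region_ids, rmj.intervals) if rid in marked_ids])
        atac = RegionSet("atac", [iv for rid, iv in zip(rmj.region_ids, rmj.intervals) if rid in open_ids])
        return annotate_enhancer_state(rmj, me1, ac, atac)

    def test_no_region_passes_both_flags(self):
        genes, rmj, rmj_reg = self.make_inputs()
        state = self.state_for(rmj, marked_ids={"RMJ:0"}, open_ids={"RMJ:1"})
        res = derive_high_confidence(rmj_reg, rmj, state, genes, window_bp=500)
        assert len(res.genes) == 0

    def test_all_regions_flagged_returns_everything(self):
        genes, rmj, rmj_reg = self.make_inputs()
        state = self.state_for(rmj, {"RMJ:0", "RMJ:1"}, {"RMJ:0", "RMJ:1"})
        res = derive_high_confidence(rmj_reg, rmj, state, genes, window_bp=500)
        assert res.genes.gene_ids == {"gA", "gB"}

    def test_gene_level_conjunction_is_looser(self):
        genes, rmj, rmj_reg = self.make_inputs()
        # gA is near both regions: one marked, the other open
        rmj2 = RegionSet(
            "RMJ",
            [GenomicInterval("chr1", 80, 120), GenomicInterval("chr1", 150, 250)],
            region_ids=["RMJ:0", "RMJ:1"],
        )
        state = self.state_for(rmj2, marked_ids={"RMJ:0"}, open_ids={"RMJ:1"})
        strict = derive_high_confidence(rmj_reg, rmj2, state, genes, window_bp=500,
                                        conjunction="region")
        loose = derive_high_confidence(rmj_reg, rmj2, state, genes, window_bp=500,
                                       conjunction="gene")
        assert len(strict.genes) == 0
        assert loose.genes.gene_ids == {"gA"}

    def test_mixed_fixture_equals_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            n_genes, n_regions = 6, 5
            genes = [GeneRecord(f"g{i}", "chr1", int(rng.integers(0, 3000)), "+")
                     for i in range(n_genes)]
            ivs, ids = [], []
            for j in range(n_regions):
                s = int(rng.integers(0, 2900))
                ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(10, 100))))
                ids.append(f"RMJ:{j}")
            rmj = RegionSet("RMJ", ivs, region_ids=ids)
            marked = {rid for rid in ids if rng.random() < 0.5}
            opened = {rid for rid in ids if rng.random() < 0.5}
            from regcascade.cascade import EnhancerState, EnhancerStateAnnotation

            flags = tuple(
                (rid, EnhancerState(rid in marked, rid in opened)) for rid in ids
            )
            state = EnhancerStateAnnotation(flags, 0.0, 0.0, 0.0)
            rmj_reg = GeneSet.build("rmj_regulated", [g.gene_id for g in genes])
            window = 400
            res = derive_high_confidence(rmj_reg, rmj, state, genes, window_bp=window)
            expected = set()
            for g in genes:
                for rid, iv in zip(rmj.region_ids, rmj.intervals):
                    mid = (iv.start + iv.end) // 2
                    if rid in marked and rid in opened and abs(mid - g.tss) <= window:
                        expected.add(g.gene_id)
            assert res.genes.gene_ids == expected


class TestRmjRegulatedAndInVivo:
    def test_no_rmj_regions_empty_with_p_one(self):
        genes = [GeneRecord("g0", "chr1", 100, "+")]
        responsive = GeneSet.build("responsive", ["g0"])
        res = derive_rmj_regulated(responsive, RegionSet("RMJ", []), genes)
        assert len(res.genes) == 0 and res.p_hypergeom == 1.0

    def test_planted_regions_at_tss_recover_all_responsive(self):
        genes = [GeneRecord(f"g{i}", "chr1", 10_000 * (i + 1), "+") for i in range(10)]
        responsive = GeneSet.build("responsive", ["g0", "g3", "g7"])
        ivs = [GenomicInterval("chr1", g.tss - 50, g.tss + 50)
               for g in genes if g.gene_id in responsive.gene_ids]
        res = derive_rmj_regulated(responsive, RegionSet("RMJ", ivs), genes, window_bp=1000)
        assert res.genes.gene_ids == responsive.gene_ids
        assert res.p_hypergeom < 0.05

    def test_in_vivo_is_plain_intersection_with_provenance(self):
        rmj_reg = GeneSet.build("rmj_regulated", ["g1", "g2", "g3"], stage="s")
        same = derive_in_vivo(rmj_reg, GeneSet.build("mdx", ["g1", "g2", "g3"]))
        assert same.gene_ids == rmj_reg.gene_ids
        assert derive_in_vivo(rmj_reg, GeneSet.build("mdx", ["g9"])).gene_ids == set()
        assert same.provenance[-1][0] == "derive_in_vivo"


class TestRunCascade:
    def test_missing_input_fails_before_computation(self, default_dataset):
        cfg = default_dataset.run_config(runx1="/nonexistent/peaks.bed")
        with pytest.raises(ValidationError, match="missing input"):
            run_cascade(cfg)

    def test_nesting_invariants_hold(self, default_dataset):
        report = run_cascade(default_dataset.run_config(n_iter_monte_carlo=50))
        gs = {k: set(v) for k, v in report.gene_sets.items()}
        assert gs["high_confidence"] <= gs["rmj_regulated"] <= gs["regulated"] <= gs["responsive"]
        assert gs["in_vivo"] <= gs["rmj_regulated"]

    def test_identical_config_is_bit_reproducible(self, default_dataset, tmp_path):
        cfg = default_dataset.run_config(n_iter_monte_carlo=100, n_iter_bootstrap=50)
        r1, r2 = run_cascade(cfg), run_cascade(cfg)
        p1, p2 = tmp_path / "r1.json", tmp_path / "r2.json"
        r1.to_json(p1)
        r2.to_json(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tightening_thresholds_never_enlarges_sets(self, default_dataset):
        loose = run_cascade(default_dataset.run_config(n_iter_monte_carlo=10))
        tight = run_cascade(
            default_dataset.run_config(
                n_iter_monte_carlo=10, q_max=0.05, fc_min=2.0, window_bp=100_000
            )
        )
        for stage in ("responsive", "regulated", "rmj_regulated", "high_confidence"):
            assert set(tight.gene_sets[stage]) <= set(loose.gene_sets[stage])

    def test_report_round_trip_and_schema_check(self, default_dataset, tmp_path):
        from regcascade.cascade import CascadeReport

        report = run_cascade(default_dataset.run_config(n_iter_monte_carlo=10))
        p = tmp_path / "report.json"
        report.to_json(p)
        back = CascadeReport.from_json(p)
        assert back.to_dict() == report.to_dict()
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps({"n_responsive": 3}))
        with pytest.raises(ValidationError, match="schema"):
            CascadeReport.from_json(bad)
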