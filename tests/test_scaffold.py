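"""Confidence scoring, placement, gap inference and scaffold emission."""

from types import SimpleNamespace

import pytest

from _util import make_block
from scafkit import fixtures as fx
from scafkit.formats_io import (
    AgpComponent,
    AgpGap,
    SequenceRecord,
    revcomp,
    validate_agp,
)
from scafkit.scaffold import (
    ScaffoldConfig,
    compute_confidences,
    emit_scaffolds,
    infer_gap_size,
    place_queries,
    scaffold_assembly,
)


class TestConfidences:
    def test_single_block_is_fully_confident(self):
        conf = compute_confidences([make_block()])
        assert (conf.grouping, conf.location, conf.orientation) == (1.0, 1.0, 1.0)

    def test_grouping_ratio(self):
        blocks = [
            make_block(r="chr1", qs=0, qe=900_000, bp=900_000),
            make_block(r="chr2", qs=900_000, qe=1_000_000, bp=100_000),
        ]
        assert compute_confidences(blocks).grouping == pytest.approx(0.9)

    def test_orientation_majority_ratio(self):
        blocks = [
            make_block(r="chr1", strand="+", qs=0, qe=600_000, bp=600_000,
                       rs=0, re=600_000),
            make_block(r="chr1", strand="-", qs=600_000, qe=900_000, bp=300_000,
                       rs=1_000_000, re=1_300_000),
        ]
        assert compute_confidences(blocks).orientation == pytest.approx(600 / 900)

    def test_no_blocks_rejected(self):
        with pytest.raises(ValueError):
            compute_confidences([])

    def test_invariant_under_uniform_scaling(self):
        def blocks(scale):
            return [
                make_block(r="chr1", qs=0, qe=60 * scale, bp=60 * scale,
                           rs=0, re=60 * scale, qlen=200 * scale, rlen=2000 * scale),
                make_block(r="chr1", strand="-", qs=60 * scale, qe=90 * scale,
                           bp=30 * scale, rs=500 * scale, re=530 * scale,
                           qlen=200 * scale, rlen=2000 * scale),
                make_block(r="chr2", qs=90 * scale, qe=100 * scale, bp=10 * scale,
                           qlen=200 * scale, rlen=2000 * scale),
            ]
        a, b = compute_confidences(blocks(1)), compute_confidences(blocks(1000))
        assert (a.grouping, a.location, a.orientation) == pytest.approx(
            (b.grouping, b.location, b.orientation)
        )


class TestPlacement:
    def test_order_indices_follow_reference_position(self):
        blocks = {
            "qa": [make_block(q="qa", rs=10_000, re=110_000, qlen=100_000)],
            "qb": [make_block(q="qb", rs=200_000, re=300_000, qlen=100_000)],
            "qc": [make_block(q="qc", rs=900_000, re=1_000_000, qlen=100_000)],
        }
        lengths = {q: 100_000 for q in blocks}
        placements, unplaced = place_queries(blocks, lengths)
        assert unplaced == []
        assert [(p.query_id, p.order_index) for p in placements] == [
            ("qa", 0), ("qb", 1), ("qc", 2)
        ]

    def test_low_grouping_confidence_unplaced(self):
        blocks = {
            "q1": [
                make_block(r=f"chr{i}", qs=i * 10_000, qe=(i + 1) * 10_000,
                           bp=15_000 if i == 0 else 12_000)
                for i in range(7)
            ]
        }
        placements, unplaced = place_queries(
            blocks, {"q1": 100_000}, ScaffoldConfig(min_grouping=0.2)
        )
        assert placements == [] and unplaced == ["q1"]

    def test_contained_primary_demoted_to_unplaced(self):
        blocks = {
            "big": [make_block(q="big", rs=0, re=500_000, qs=0, qe=500_000,
                               qlen=500_000)],
            "nested": [make_block(q="nested", rs=100_000, re=150_000,
                                  qs=0, qe=50_000, qlen=50_000)],
        }
        placements, unplaced = place_queries(
            blocks, {"big": 500_000, "nested": 50_000}
        )
        assert [p.query_id for p in placements] == ["big"]
        assert unplaced == ["nested"]

    def test_min_contig_len_and_excluded_refs(self):
        blocks = {
            "small": [make_block(q="small", qlen=1_000)],
            "excluded": [make_block(q="excluded", r="chr0", qlen=100_000)],
        }
        cfg = ScaffoldConfig(min_contig_len=10_000, excluded_refs=frozenset({"chr0"}))
        placements, unplaced = place_queries(
            blocks, {"small": 1_000, "excluded": 100_000}, cfg
        )
        assert placements == [] and unplaced == ["excluded", "small"]

    def test_orientation_from_primary_strand(self):
        blocks = {"q1": [make_block(strand="-", qlen=100_000)]}
        placements, _ = place_queries(blocks, {"q1": 100_000})
        assert placements[0].orientation == "-"


class TestGapInference:
    def test_printed_formula_hand_example(self):
        aln1 = SimpleNamespace(ref_start=0, ref_end=8_000, query_start=0, query_end=8_800)
        aln2 = SimpleNamespace(ref_start=10_000, ref_end=12_000, query_start=500, query_end=2_000)
        est = infer_gap_size(aln1, aln2, len_seq1=9_000)
        assert (est.size, est.known) == (1_300, True)

    @pytest.mark.parametrize("target,known", [(1, True), (0, False), (-5, False)])
    def test_minimum_one_bp(self, target, known):
        aln1 = SimpleNamespace(ref_start=0, ref_end=8_000, query_start=0, query_end=8_800)
        aln2 = SimpleNamespace(
            ref_start=8_700 + target, ref_end=10_000, query_start=500, query_end=2_000
        )
        est = infer_gap_size(aln1, aln2, len_seq1=9_000, g=1)
        assert est.known is known
        assert est.size == (target if known else 100)

    def test_oversized_gap_becomes_unknown(self):
        aln1 = SimpleNamespace(ref_start=0, ref_end=8_000, query_start=0, query_end=8_800)
        aln2 = SimpleNamespace(
            ref_start=8_700 + 100_001, ref_end=300_000, query_start=500, query_end=2_000
        )
        est = infer_gap_size(aln1, aln2, len_seq1=9_000, m=100_000)
        assert (est.size, est.known) == (100, False)


class TestEmitScaffolds:
    def _placements(self):
        blocks = {
            "qa": [make_block(q="qa", rs=0, re=10_000, qs=0, qe=10_000, qlen=10_000)],
            "qb": [make_block(q="qb", rs=50_000, re=60_000, qs=0, qe=10_000,
                              qlen=10_000)],
        }
        return place_queries(blocks, {"qa": 10_000, "qb": 10_000})

    def test_fixed_policy_inserts_100bp_unknown_gap(self):
        placements, unplaced = self._placements()
        queries = {
            "qa": SequenceRecord("qa", "A" * 10_000),
            "qb": SequenceRecord("qb", "C" * 10_000),
        }
        agp, fasta, report = emit_scaffolds(placements, unplaced, queries)
        (obj,) = agp
        assert obj.length == 20_100
        gap = obj.rows[1]
        assert isinstance(gap, AgpGap) and gap.gap_length == 100 and not gap.known
        assert fasta[0].sequence[10_000:10_100] == "N" * 100
        assert validate_agp(agp) == []

    def test_zero_placed_queries_pass_through(self):
        queries = {"q1": SequenceRecord("q1", "ACGT" * 100)}
        agp, fasta, report = emit_scaffolds([], ["q1"], queries)
        assert [o.object_id for o in agp] == ["q1"]
        assert fasta[0].sequence == queries["q1"].sequence

    def test_minus_component_emitted_reverse_complemented(self):
        blocks = {"q1": [make_block(strand="-", qs=0, qe=400, rs=0, re=400, qlen=400)]}
        placements, unplaced = place_queries(blocks, {"q1": 400})
        queries = {"q1": SequenceRecord("q1", "ACGT" * 100)}
        agp, fasta, _ = emit_scaffolds(placements, unplaced, queries)
        assert fasta[0].sequence == revcomp(queries["q1"].sequence)

    def test_concat_unplaced(self):
        queries = {
            "u1": SequenceRecord("u1", "A" * 50),
            "u2": SequenceRecord("u2", "C" * 50),
        }
        cfg = ScaffoldConfig(concat_unplaced=True)
        agp, fasta, _ = emit_scaffolds([], ["u1", "u2"], queries, cfg)
        (obj,) = agp
        assert obj.object_id == "unplaced_scaffold" and obj.length == 200
        assert validate_agp(agp) == []


class TestEndToEnd:
    def test_every_query_appears_exactly_once(self):
        genome = fx.simulate_genome(11, 2, 800_000)
        truth = fx.fragment_assembly(genome, 12, target_n50=80_000,
                                     inter_contig_bp=(100, 2_000))
        agp, fasta, placements, unplaced, _ = scaffold_assembly(
            truth.contigs, fx.exact_alignments(truth)
        )
        used = [
            row.component_id
            for obj in agp
            for row in obj.rows
            if isinstance(row, AgpComponent)
        ]
        assert sorted(used) == sorted(truth.contigs)
        assert validate_agp(agp) == []

    def test_recovers_truth_order_orientation_and_distances(self):
        genome = fx.simulate_genome(21, 2, 1_500_000)
        truth = fx.fragment_assembly(genome, 22, target_n50=150_000,
                                     inter_contig_bp=(200, 5_000))
        agp, _, placements, unplaced, _ = scaffold_assembly(
            truth.contigs, fx.exact_alignments(truth),
            ScaffoldConfig(gap_policy="inferred"),
        )
        assert unplaced == []
        recovered = {}
        for obj in agp:
            if not obj.object_id.endswith("_scaffold"):
                continue
            chain, gaps = [], []
            for row in obj.rows:
                if isinstance(row, AgpComponent):
                    chain.append((row.component_id, row.orientation))
                else:
                    gaps.append((row.gap_length, row.known))
            recovered[obj.object_id[: -len("_scaffold")]] = (chain, gaps)
        for chrom, entries in truth.layout().items():
            chain, gaps = recovered[chrom]
            assert chain == [(c, o) for c, o, _ in entries]
            assert [g for g, _ in gaps] == [d for _, _, d in entries[:-1]]
            assert all(known for _, known in gaps)
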