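"""AGP reconciliation: graph accumulation, Hi-C re-weighting, emission."""

import copy

import pytest

from scafkit import fixtures as fx
from scafkit.formats_io import AgpComponent, AgpGap, AgpObject, SequenceRecord
from scafkit.merge import (
    MergeConfig,
    adjacency_set,
    build_merge_graph,
    count_restriction_sites,
    emit_merged_agp,
    merge_agps,
    reweight_with_hic,
)
from scafkit.scaffold_graph import BEGIN, END, Terminus, edge_key


def agp_from_chains(chains, comp_len=200_000):
    """AGP objects from [(object_id, [(comp, orient), ...]), ...]."""
    objects = []
    for oid, comps in chains:
        rows = []
        pos = 0
        part = 0
        for i, (cid, orient) in enumerate(comps):
            if i:
                part += 1
                rows.append(AgpGap(pos + 1, pos + 100, part, 100, known=False))
                pos += 100
            part += 1
            rows.append(AgpComponent(pos + 1, pos + comp_len, part, cid, 1, comp_len, orient))
            pos += comp_len
        objects.append(AgpObject(oid, rows))
    return objects


def comp_seqs(ids, length=200_000):
    return {cid: SequenceRecord(cid, "A" * length) for cid in ids}


class TestBuildMergeGraph:
    def test_agreeing_sources_accumulate_weight(self):
        agp = agp_from_chains([("s1", [("A", "+"), ("B", "+")])])
        graph, small = build_merge_graph([agp, agp], min_component_len=0)
        edge = graph.get_edge(Terminus("A", END), Terminus("B", BEGIN))
        assert edge.weight == 2.0 and edge.support == ["agp0", "agp1"]
        assert small == set()

    def test_disagreeing_sources_create_separate_edges(self):
        agp1 = agp_from_chains([("s1", [("A", "+"), ("B", "+")]), ("s2", [("C", "+")])])
        agp2 = agp_from_chains([("s1", [("A", "+"), ("C", "+")]), ("s2", [("B", "+")])])
        graph, _ = build_merge_graph([agp1, agp2], min_component_len=0)
        assert len(graph.edges) == 2
        for edge in graph.edges.values():
            assert edge.weight == 1.0

    def test_component_set_mismatch_names_difference(self):
        agp1 = agp_from_chains([("s1", [("A", "+"), ("B", "+"), ("D", "+")])])
        agp2 = agp_from_chains([("s1", [("A", "+"), ("B", "+")])])
        with pytest.raises(ValueError, match="D"):
            build_merge_graph([agp1, agp2])

    def test_custom_weights(self):
        agp1 = agp_from_chains([("s1", [("A", "+"), ("B", "+")])])
        agp2 = agp_from_chains([("s1", [("A", "+"), ("B", "+")])])
        graph, _ = build_merge_graph([agp1, agp2], weights=[2.0, 0.5],
                                     min_component_len=0)
        edge = graph.get_edge(Terminus("A", END), Terminus("B", BEGIN))
        assert edge.weight == 2.5

    def test_short_components_are_singletons_and_do_not_bridge(self):
        agp = agp_from_chains(
            [("s1", [("A", "+"), ("tiny", "+"), ("B", "+")])], comp_len=200_000
        )
        # shrink "tiny" below the cutoff
        for obj in agp:
            for row in obj.rows:
                if isinstance(row, AgpComponent) and row.component_id == "tiny":
                    row.component_end = 5_000
        lengths = {"A": 200_000, "B": 200_000, "tiny": 5_000}
        graph, small = build_merge_graph(
            [agp], min_component_len=100_000, component_lengths=lengths
        )
        assert small == {"tiny"}
        assert graph.edges == {}  # adjacency never invented across the removed one

    def test_orientation_determines_termini(self):
        agp = agp_from_chains([("s1", [("A", "-"), ("B", "+")])])
        graph, _ = build_merge_graph([agp], min_component_len=0)
        assert graph.has_edge(Terminus("A", BEGIN), Terminus("B", BEGIN))


class TestRestrictionSites:
    @pytest.mark.parametrize("seq,patterns,expected", [
        ("GATCGATC", ["GATC"], 2),
        ("GAATCC", ["GA[ATCG]TC"], 1),
        ("GAATTC", ["GA[ATCG]TC"], 0),
        ("", ["GATC"], 0),
        ("TTTAA", ["TTAA"], 1),
        ("GATCGATC", ["GATC", "ATCG"], 3),  # overlapping motifs both counted
    ])
    def test_counts(self, seq, patterns, expected):
        assert count_restriction_sites(seq, patterns) == expected

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError, match="invalid restriction motif"):
            count_restriction_sites("ACGT", ["GA?C"])


class TestHiCReweighting:
    def _graph_and_seqs(self):
        agp = agp_from_chains([("s1", [("A", "+"), ("B", "+")])], comp_len=10_000)
        # 5 GATC sites inside each 1 kbp terminal window
        filler = "A" * 800
        window = "GATC" * 5 + "A" * 980
        seqs = {
            "A": SequenceRecord("A", "A" * 9_000 + "GATC" * 5 + filler[:980]),
            "B": SequenceRecord("B", window + "A" * 9_000),
        }
        seqs = {cid: SequenceRecord(cid, s.sequence[:10_000]) for cid, s in seqs.items()}
        graph, _ = build_merge_graph([agp], min_component_len=0,
                                     component_lengths={"A": 10_000, "B": 10_000})
        return graph, seqs

    def test_normalized_link_count(self):
        graph, seqs = self._graph_and_seqs()
        cfg = MergeConfig(terminal_window=1_000, restriction_patterns=("GATC",))
        contacts = [("A", 9_500, "B", 200)] * 10
        reweight_with_hic(graph, contacts, seqs, cfg)
        edge = graph.get_edge(Terminus("A", END), Terminus("B", BEGIN))
        assert edge.weight == pytest.approx(10 / 10)  # 10 links / (5+5 sites)

    def test_zero_contacts_zero_weight(self):
        graph, seqs = self._graph_and_seqs()
        cfg = MergeConfig(terminal_window=1_000, restriction_patterns=("GATC",))
        reweight_with_hic(graph, [], seqs, cfg)
        edge = graph.get_edge(Terminus("A", END), Terminus("B", BEGIN))
        assert edge.weight == 0.0

    def test_contacts_outside_windows_not_counted(self):
        graph, seqs = self._graph_and_seqs()
        cfg = MergeConfig(terminal_window=1_000, restriction_patterns=("GATC",))
        contacts = [("A", 5_000, "B", 5_000)] * 10  # mid-component
        reweight_with_hic(graph, contacts, seqs, cfg)
        edge = graph.get_edge(Terminus("A", END), Terminus("B", BEGIN))
        assert edge.weight == 0.0

    def test_out_of_range_contact_rejected(self):
        graph, seqs = self._graph_and_seqs()
        with pytest.raises(ValueError, match="outside component"):
            reweight_with_hic(graph, [("A", 10_000, "B", 0)], seqs,
                              MergeConfig(terminal_window=1_000))


class TestMergeEndToEnd:
    def test_single_input_idempotent(self):
        agp = agp_from_chains([
            ("s1", [("A", "+"), ("B", "-"), ("C", "+")]),
            ("s2", [("D", "+")]),
        ])
        seqs = comp_seqs("ABCD")
        merged, _ = merge_agps([agp], seqs, cfg=MergeConfig(min_component_len=0))
        assert adjacency_set(merged) == adjacency_set(agp)

    def test_agreeing_inputs_idempotent(self):
        agp = agp_from_chains([("s1", [("A", "+"), ("B", "+"), ("C", "+")])])
        seqs = comp_seqs("ABC")
        merged, _ = merge_agps([agp, copy.deepcopy(agp)], seqs,
                               cfg=MergeConfig(min_component_len=0))
        assert adjacency_set(merged) == adjacency_set(agp)

    def test_conflict_resolved_toward_heavier_source(self):
        agp1 = agp_from_chains([("s1", [("A", "+"), ("B", "+")]), ("s2", [("C", "+")])])
        agp2 = agp_from_chains([("s1", [("A", "+"), ("C", "+")]), ("s2", [("B", "+")])])
        seqs = comp_seqs("ABC")
        merged, _ = merge_agps([agp1, agp2], seqs, weights=[3.0, 1.0],
                               cfg=MergeConfig(min_component_len=0))
        assert edge_key(Terminus("A", END), Terminus("B", BEGIN)) in adjacency_set(merged)

    def test_hic_breaks_tie_between_equal_votes(self):
        agp1 = agp_from_chains([("s1", [("A", "+"), ("B", "+")]), ("s2", [("C", "+")])],
                               comp_len=10_000)
        agp2 = agp_from_chains([("s1", [("A", "+"), ("C", "+")]), ("s2", [("B", "+")])],
                               comp_len=10_000)
        seqs = comp_seqs("ABC", length=10_000)
        contacts = [("A", 9_900, "B", 50)] * 20  # strong A.end <-> B.begin signal
        merged, _ = merge_agps(
            [agp1, agp2], seqs,
            cfg=MergeConfig(min_component_len=0, hic_reweight=True,
                            terminal_window=1_000, restriction_patterns=("GATC",)),
            contacts=contacts,
        )
        assert edge_key(Terminus("A", END), Terminus("B", BEGIN)) in adjacency_set(merged)

    def test_conservatism_and_conservation_on_conflicting_inputs(self):
        genome = fx.simulate_genome(51, 2, 1_200_000)
        truth = fx.fragment_assembly(genome, 52, target_n50=200_000,
                                     inter_contig_bp=(100, 500))
        from scafkit.scaffold import ScaffoldConfig, scaffold_assembly

        agp1, _, _, _, _ = scaffold_assembly(truth.contigs, fx.exact_alignments(truth))
        # a conflicting second solution: reverse each object's component order
        agp2 = copy.deepcopy(agp1)
        for obj in agp2:
            comps = [r for r in obj.rows if isinstance(r, AgpComponent)]
            ids = [c.component_id for c in comps][::-1]
            for row, cid in zip(comps, ids):
                row.component_id = cid
        seqs = truth.contigs
        merged, _ = merge_agps([agp1, agp2], seqs, cfg=MergeConfig(min_component_len=0))
        union = adjacency_set(agp1) | adjacency_set(agp2)
        assert adjacency_set(merged) <= union
        used = [r.component_id for obj in merged for r in obj.rows
                if isinstance(r, AgpComponent)]
        assert sorted(used) == sorted(truth.contigs)

    def test_unmerged_components_pass_through(self):
        agp = agp_from_chains([("s1", [("A", "+")]), ("s2", [("B", "+")])])
        merged, _ = merge_agps([agp], comp_seqs("AB"),
                               cfg=MergeConfig(min_component_len=0))
        assert sorted(o.object_id for o in merged) == ["A", "B"]

    def test_hic_evidence_tag_in_gap_rows(self):
        agp = agp_from_chains([("s1", [("A", "+"), ("B", "+")])], comp_len=10_000)
        seqs = comp_seqs("AB", length=10_000)
        contacts = [("A", 9_900, "B", 50)] * 5
        merged, _ = merge_agps(
            [agp], seqs,
            cfg=MergeConfig(min_component_len=0, hic_reweight=True,
                            terminal_window=1_000),
            contacts=contacts,
        )
        gaps = [r for o in merged for r in o.rows if isinstance(r, AgpGap)]
        assert gaps and all(g.evidence == "proximity_ligation" for g in gaps)
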