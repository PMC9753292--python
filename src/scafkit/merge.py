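"""Reconciliation of multiple AGP scaffolding solutions ("merge").

Every input AGP orders and orients the same set of assembly components.
Each source is assigned a weight (1 by default) and, for every pair of
components adjacent in a source, an edge between the corresponding
component termini is added to a shared scaffold graph with its weight
incremented by the source weight (the CAMSA accumulation rule).  The
native weights can optionally be replaced by Hi-C scores: for each edge,
the number of Hi-C contacts linking the two terminal windows, normalized
by the restriction-site count of those windows (SALSA2-style).  The graph
is solved by maximum-weight matching with cycle breaking and each chain
becomes one merged AGP object with 100-bp unknown gaps; unmerged
components pass through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .formats_io import (
    AgpComponent,
    AgpGap,
    AgpObject,
    SequenceRecord,
)
from .scaffold_graph import (
    BEGIN,
    END,
    GraphSolution,
    ScaffoldGraph,
    Terminus,
    edge_key,
)

ARIMA_PATTERNS = ("GATC", "GA[ATCG]TC", "CT[ATCG]AG", "TTAA")
UNKNOWN_GAP_LEN = 100


@dataclass
class MergeConfig:
    """Merge policy.

    min_component_len
        Components shorter than this are unmergeable singletons (default
        100 kbp); their adjacencies contribute no edges and they are
        output unchanged.
    hic_reweight
        Replace accumulated AGP weights with Hi-C scores.
    restriction_patterns
        Degenerate-base motifs whose site counts normalize Hi-C link
        counts (default: the Arima two-enzyme motif set).
    terminal_window
        Window (bp) at each component end considered "terminal" for Hi-C
        counting; defaults per component to min(length // 2, 1 Mbp).
    """

    min_component_len: int = 100_000
    hic_reweight: bool = False
    restriction_patterns: Sequence[str] = ARIMA_PATTERNS
    terminal_window: int | None = None


def _component_rows(obj: AgpObject) -> list:
    return [r for r in obj.rows if isinstance(r, AgpComponent)]


def build_merge_graph(
    agps: Sequence[Sequence[AgpObject]],
    weights: Sequence[float] | None = None,
    min_component_len: int = 100_000,
    component_lengths: Mapping[str, int] | None = None,
) -> tuple:
    """Accumulate adjacency evidence from the input AGPs.

    Returns ``(graph, small_components)``.  All AGPs must carry the same
    component set; a mismatch raises with the symmetric difference.
    Adjacency is only recorded between directly consecutive retained
    components — dropping a short component does not bridge its
    neighbours, so the merge never invents adjacencies.
    """
    if not agps:
        raise ValueError("at least one AGP solution is required")
    weights = list(weights) if weights is not None else [1.0] * len(agps)
    if len(weights) != len(agps):
        raise ValueError("one weight per AGP solution is required")
    if any(w <= 0 for w in weights):
        raise ValueError("AGP weights must be positive")

    comp_sets = []
    for solution in agps:
        comp_sets.append({r.component_id for obj in solution for r in _component_rows(obj)})
    base = comp_sets[0]
    for i, cs in enumerate(comp_sets[1:], 1):
        if cs != base:
            diff = sorted(base.symmetric_difference(cs))
            raise ValueError(
                f"AGP solutions 0 and {i} order different component sets; "
                f"symmetric difference: {', '.join(diff)}"
            )

    if component_lengths is None:
        component_lengths = {}
        for solution in agps:
            for obj in solution:
                for r in _component_rows(obj):
                    component_lengths[r.component_id] = max(
                        component_lengths.get(r.component_id, 0), r.component_end
                    )
    small = {c for c in base if component_lengths.get(c, 0) < min_component_len}

    graph = ScaffoldGraph()
    for cid in base - small:
        graph.add_sequence(cid)
    for src_idx, (solution, w) in enumerate(zip(agps, weights)):
        label = f"agp{src_idx}"
        for obj in solution:
            prev = None
            for row in _component_rows(obj):
                if row.component_id in small:
                    prev = None
                    continue
                if prev is not None:
                    o1 = "+" if prev.orientation != "-" else "-"
                    o2 = "+" if row.orientation != "-" else "-"
                    t1 = Terminus(prev.component_id, END if o1 == "+" else BEGIN)
                    t2 = Terminus(row.component_id, BEGIN if o2 == "+" else END)
                    graph.add_edge(t1, t2, w, source=label, policy="increment")
                prev = row
    return graph, small


# ---------------------------------------------------------------------------
# Hi-C re-weighting


_MOTIF_OK = re.compile(r"^(?:[ACGT]|\[[ACGT]+\])+$")


def count_restriction_sites(sequence: str, patterns: Sequence[str]) -> int:
    """Forward-strand motif match positions, overlaps allowed, summed over
    motifs.  Motifs use degenerate-base character classes like GA[ATCG]TC."""
    total = 0
    seq = sequence.upper()
    for pat in patterns:
        if not _MOTIF_OK.match(pat):
            raise ValueError(f"invalid restriction motif {pat!r}")
        total += len(re.findall(f"(?={pat})", seq))
    return total


def _terminal_window(length: int, side: str, cfg: MergeConfig) -> tuple:
    w = cfg.terminal_window if cfg.terminal_window is not None else min(
        length // 2, 1_000_000
    )
    return (0, w) if side == BEGIN else (length - w, length)


def reweight_with_hic(
    graph: ScaffoldGraph,
    contacts: Sequence[tuple],
    component_seqs: Mapping[str, SequenceRecord],
    cfg: MergeConfig | None = None,
) -> ScaffoldGraph:
    """Replace native edge weights with SALSA2-style Hi-C scores.

    For an edge (t1, t2): h = links(t1 window, t2 window) /
    max(1, sites(t1 window) + sites(t2 window)), where a link is a contact
    with one end inside each terminal window.  Edges keep their support
    metadata; contacts are ``(component_a, pos_a, component_b, pos_b)``.
    """
    cfg = cfg or MergeConfig()
    lengths = {cid: len(rec) for cid, rec in component_seqs.items()}

    def touched(cid: str, pos: int) -> list:
        if cid not in lengths:
            return []
        if not (0 <= pos < lengths[cid]):
            raise ValueError(f"contact position {pos} outside component {cid}")
        out = []
        for side in (BEGIN, END):
            lo, hi = _terminal_window(lengths[cid], side, cfg)
            if lo <= pos < hi:
                out.append(Terminus(cid, side))
        return out

    links: dict = {}
    for ca, pa, cb, pb in contacts:
        for ta in touched(ca, int(pa)):
            for tb in touched(cb, int(pb)):
                if ta == tb or ta.sequence_id == tb.sequence_id:
                    continue
                key = edge_key(ta, tb)
                links[key] = links.get(key, 0) + 1

    site_cache: dict = {}

    def sites(t: Terminus) -> int:
        if t not in site_cache:
            lo, hi = _terminal_window(lengths[t.sequence_id], t.side, cfg)
            site_cache[t] = count_restriction_sites(
                component_seqs[t.sequence_id].sequence[lo:hi],
                cfg.restriction_patterns,
            )
        return site_cache[t]

    for key, edge in graph.edges.items():
        n_links = links.get(key, 0)
        edge.weight = n_links / max(1, sites(key[0]) + sites(key[1]))
    return graph


# ---------------------------------------------------------------------------
# Output


def emit_merged_agp(
    solution: GraphSolution,
    component_lengths: Mapping[str, int],
    small_components: Sequence[str] = (),
    hic_weighted: bool = False,
) -> list:
    """One AGP object per chain with 100-bp unknown gaps; singleton and
    short components are emitted unchanged."""
    evidence = "proximity_ligation" if hic_weighted else "align_genus"
    agp = []
    scf_index = 0
    for chain in solution.chains:
        if len(chain) == 1:
            cid, _ = chain.sequences[0]
            clen = component_lengths[cid]
            agp.append(AgpObject(cid, [AgpComponent(1, clen, 1, cid, 1, clen, "+")]))
            continue
        scf_index += 1
        rows = []
        pos = 0
        part = 0
        for i, (cid, orient) in enumerate(chain.sequences):
            clen = component_lengths[cid]
            if i > 0:
                part += 1
                rows.append(
                    AgpGap(
                        pos + 1, pos + UNKNOWN_GAP_LEN, part, UNKNOWN_GAP_LEN,
                        "scaffold", "yes", evidence, known=False,
                    )
                )
                pos += UNKNOWN_GAP_LEN
            part += 1
            rows.append(AgpComponent(pos + 1, pos + clen, part, cid, 1, clen, orient))
            pos += clen
        agp.append(AgpObject(f"scf{scf_index:05d}", rows))
    for cid in sorted(small_components):
        clen = component_lengths[cid]
        agp.append(AgpObject(cid, [AgpComponent(1, clen, 1, cid, 1, clen, "+")]))
    return agp


def adjacency_set(agp: Sequence[AgpObject]) -> set:
    """Orientation-aware adjacency fingerprint of an AGP solution.

    Each adjacency is the canonical terminus-pair key of two consecutive
    components, making the fingerprint invariant to whole-object reversal.
    """
    adjacencies = set()
    for obj in agp:
        comps = _component_rows(obj)
        for a, b in zip(comps, comps[1:]):
            o1 = "+" if a.orientation != "-" else "-"
            o2 = "+" if b.orientation != "-" else "-"
            t1 = Terminus(a.component_id, END if o1 == "+" else BEGIN)
            t2 = Terminus(b.component_id, BEGIN if o2 == "+" else END)
            adjacencies.add(edge_key(t1, t2))
    return adjacencies


def merge_agps(
    agps: Sequence[Sequence[AgpObject]],
    component_seqs: Mapping[str, SequenceRecord],
    weights: Sequence[float] | None = None,
    cfg: MergeConfig | None = None,
    contacts: Sequence[tuple] | None = None,
) -> tuple:
    """Full reconciliation pipeline.

    Returns ``(merged_agp, solution)``.  Pass ``contacts`` with
    ``cfg.hic_reweight`` to score adjacencies by Hi-C evidence instead of
    AGP vote weights.
    """
    cfg = cfg or MergeConfig()
    lengths = {cid: len(rec) for cid, rec in component_seqs.items()}
    graph, small = build_merge_graph(
        agps, weights, cfg.min_component_len, component_lengths=lengths
    )
    if cfg.hic_reweight:
        if contacts is None:
            raise ValueError("hic_reweight requires contacts")
        reweight_with_hic(graph, contacts, component_seqs, cfg)
    solution = graph.solve()
    merged = emit_merged_agp(solution, lengths, small, hic_weighted=cfg.hic_reweight)
    return merged, solution
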