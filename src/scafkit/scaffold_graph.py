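"""The shared weighted scaffold graph and its matching-based solver.

Every sequence contributes two nodes — its *begin* and *end* termini — and
weighted edges between termini of distinct sequences encode putative
adjacencies (an original gap, a patch-supporting query segment, AGP
adjacency support, or a Hi-C contact score).  The two termini of one
sequence are implicitly paired and never joined by an explicit edge.

Solving the graph means computing a maximum-weight matching over the
inter-sequence edges (networkx), overlaying the matched edges on the
implicit intra-sequence pairings, breaking any resulting cycle at its
lowest-weight matched edge, and reading off the resulting simple paths as
ordered, oriented chains of sequences.  Entering a sequence at its *end*
terminus means the chain carries it reverse-complemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, NamedTuple

import networkx as nx

BEGIN = "begin"
END = "end"


class Terminus(NamedTuple):
    """One of the two ends of a sequence."""

    sequence_id: str
    side: str  # "begin" | "end"


def opposite(t: Terminus) -> Terminus:
    return Terminus(t.sequence_id, END if t.side == BEGIN else BEGIN)


def edge_key(t1: Terminus, t2: Terminus) -> tuple:
    """Canonical unordered key for an edge."""
    return tuple(sorted((t1, t2)))


@dataclass
class Edge:
    t1: Terminus
    t2: Terminus
    weight: float
    metadata: Any = None
    support: list = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return edge_key(self.t1, self.t2)


@dataclass
class Chain:
    """An ordered, oriented walk of sequences.

    ``sequences`` is ``[(sequence_id, orientation), ...]``; ``joins`` holds
    one ``(Edge, forward)`` per adjacent pair, where ``forward`` is True iff
    the walk traverses the edge from its stored ``t1`` to ``t2``.
    """

    sequences: list
    joins: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class GraphSolution:
    chains: list
    dropped_edges: list  # [(edge_key, reason)], reason in {"unmatched", "cycle_break"}
    matched_weight: float


class ScaffoldGraph:
    """Weighted adjacency graph over sequence termini."""

    def __init__(self) -> None:
        self._sequences: set = set()
        self._edges: dict = {}

    # -- construction -------------------------------------------------------

    def add_sequence(self, sequence_id: str) -> None:
        self._sequences.add(sequence_id)

    def add_edge(
        self,
        t1: Terminus,
        t2: Terminus,
        weight: float = 1.0,
        metadata: Any = None,
        source: str | None = None,
        policy: str = "increment",
    ) -> Edge:
        """Add (or combine with) an edge between termini of distinct sequences.

        ``policy`` controls collisions with an existing edge on the same
        terminus pair: "increment" adds the weight and appends support
        (merge semantics); "replace" swaps weight and metadata in place
        (patch gap-replacement semantics); "error" refuses.
        """
        if weight < 0:
            raise ValueError("edge weights must be nonnegative")
        if t1.sequence_id == t2.sequence_id:
            raise ValueError(
                f"edge would join the two termini of {t1.sequence_id!r}"
            )
        self._sequences.add(t1.sequence_id)
        self._sequences.add(t2.sequence_id)
        key = edge_key(t1, t2)
        existing = self._edges.get(key)
        if existing is None:
            edge = Edge(t1, t2, weight, metadata, [source] if source else [])
            self._edges[key] = edge
            return edge
        if policy == "increment":
            existing.weight += weight
            if source:
                existing.support.append(source)
            return existing
        if policy == "replace":
            existing.t1, existing.t2 = t1, t2
            existing.weight = weight
            existing.metadata = metadata
            if source:
                existing.support.append(source)
            return existing
        raise ValueError(f"edge {key} already exists")

    def has_edge(self, t1: Terminus, t2: Terminus) -> bool:
        return edge_key(t1, t2) in self._edges

    def get_edge(self, t1: Terminus, t2: Terminus) -> Edge:
        return self._edges[edge_key(t1, t2)]

    def discard_edge(self, t1: Terminus, t2: Terminus) -> None:
        self._edges.pop(edge_key(t1, t2), None)

    @property
    def edges(self) -> dict:
        return self._edges

    @property
    def sequences(self) -> set:
        return self._sequences

    # -- solving ------------------------------------------------------------

    def solve(self) -> GraphSolution:
        """Maximum-weight matching + cycle breaking -> oriented chains.

        Every registered sequence appears in exactly one chain exactly
        once; sequences without matched edges come out as singleton
        chains.  Cycles are broken at their minimum-weight matched edge
        (ties: lexicographically smallest edge key).  Each chain direction
        is canonicalized deterministically.
        """
        G = nx.Graph()
        for sid in sorted(self._sequences):
            G.add_node(Terminus(sid, BEGIN))
            G.add_node(Terminus(sid, END))
        for key in sorted(self._edges):
            G.add_edge(key[0], key[1], weight=self._edges[key].weight)
        mate: dict = {}
        for a, b in nx.max_weight_matching(G):
            mate[a] = b
            mate[b] = a
        matched_keys = {edge_key(a, b) for a, b in mate.items()}
        matched_weight = sum(self._edges[k].weight for k in matched_keys)
        dropped = [(k, "unmatched") for k in sorted(self._edges) if k not in matched_keys]

        assigned: set = set()
        chains: list = []

        def walk(start: Terminus) -> Chain:
            sequences, joins = [], []
            node = start
            while True:
                assigned.add(node.sequence_id)
                sequences.append((node.sequence_id, "+" if node.side == BEGIN else "-"))
                exit_t = opposite(node)
                nxt = mate.get(exit_t)
                if nxt is None:
                    break
                edge = self._edges[edge_key(exit_t, nxt)]
                joins.append((edge, edge.t1 == exit_t))
                node = nxt
            return _canonical_chain(Chain(sequences, joins))

        for start in sorted(t for t in G.nodes if t not in mate):
            if start.sequence_id in assigned:
                continue
            chains.append(walk(start))

        # remaining sequences sit on cycles
        for sid in sorted(self._sequences):
            if sid in assigned:
                continue
            cycle_keys = []
            node = Terminus(sid, BEGIN)
            while True:
                exit_t = opposite(node)
                nxt = mate[exit_t]
                cycle_keys.append(edge_key(exit_t, nxt))
                node = nxt
                if node.sequence_id == sid:
                    break
            cut = min(cycle_keys, key=lambda k: (self._edges[k].weight, k))
            del mate[cut[0]]
            del mate[cut[1]]
            dropped.append((cut, "cycle_break"))
            chains.append(walk(min(cut)))

        chains.sort(key=lambda c: c.sequences)
        dropped.sort(key=lambda t: t[0])
        return GraphSolution(chains, dropped, matched_weight)


def _flip(orientation: str) -> str:
    return "-" if orientation == "+" else "+"


def _canonical_chain(chain: Chain) -> Chain:
    reversed_sequences = [(sid, _flip(o)) for sid, o in reversed(chain.sequences)]
    if reversed_sequences < chain.sequences:
        reversed_joins = [(e, not f) for e, f in reversed(chain.joins)]
        return Chain(reversed_sequences, reversed_joins)
    return chain
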