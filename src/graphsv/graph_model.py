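"""Undirected weighted assembly-graph model with motif enumeration.

The co-assembly graph G=(V,E) collapses each segment and its reverse
complement into a single node (the Bandage "single" view), so a link and
its reverse-complement twin describe the same undirected adjacency.  Edge
weight counts the number of *distinct* collapsed link classes between two
nodes; a segment linked to itself yields a self-loop.

Motifs drive SV calling: triangles (3-cycles) for indels, squares
(4-cycles, kept in cyclic order so opposite corners are recoverable) for
complex indels, and self-loops plus weight>=2 edges for tandem
duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .io_formats import LinkRecord, SegmentRecord

_FLIP = {"+": "-", "-": "+"}

EdgeKey = tuple[str, str]


def edge_key(a: str, b: str) -> EdgeKey:
    """Canonical unordered key for an edge (sorted endpoint pair)."""
    return (a, b) if a <= b else (b, a)


def canonicalize_link(link: LinkRecord) -> tuple[str, str, str, str]:
    """Canonical key identifying a link with its reverse-complement twin.

    A link (a, x) -> (b, y) and its twin (b, flip(y)) -> (a, flip(x))
    describe the same junction on opposite strands; the lexicographically
    smaller 4-tuple of the two is the class representative.
    """
    fwd = (link.from_seg, link.from_orient, link.to_seg, link.to_orient)
    rev = (link.to_seg, _FLIP[link.to_orient], link.from_seg, _FLIP[link.from_orient])
    return min(fwd, rev)


@dataclass
class AssemblyGraph:
    """Undirected weighted graph over collapsed segment pairs.

    Thin wrapper around :class:`networkx.Graph`; nodes carry ``length``
    and optional ``sequence`` attributes, edges carry integer ``weight``
    (number of distinct collapsed link classes, always >= 1).
    """

    g: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.g.nodes)

    def node_length(self, node: str) -> int:
        return self.g.nodes[node]["length"]

    def node_sequence(self, node: str) -> str | None:
        return self.g.nodes[node].get("sequence")

    @property
    def sequences(self) -> dict[str, str | None]:
        return {n: self.node_sequence(n) for n in self.g.nodes}

    def edge_weight(self, a: str, b: str) -> int:
        return self.g.edges[a, b]["weight"]

    @property
    def edges(self) -> list[EdgeKey]:
        return sorted(edge_key(a, b) for a, b in self.g.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return self.g.has_edge(a, b)


def build_graph(
    segments: Iterable[SegmentRecord], links: Iterable[LinkRecord]
) -> AssemblyGraph:
    """Build the collapsed undirected weighted graph from GFA records.

    One node per segment; links are deduplicated by canonical class and
    the weight of edge {i,j} is the number of distinct classes between i
    and j.  Segments without links become isolated nodes; self-links
    become self-loops.
    """
    g = nx.Graph()
    for seg in segments:
        g.add_node(seg.seg_id, length=seg.length, sequence=seg.sequence)
    classes: dict[EdgeKey, set[tuple[str, str, str, str]]] = {}
    for link in links:
        for seg in (link.from_seg, link.to_seg):
            if seg not in g:
                raise KeyError(f"link references unknown segment {seg!r}")
        key = edge_key(link.from_seg, link.to_seg)
        classes.setdefault(key, set()).add(canonicalize_link(link))
    for (a, b), cls in classes.items():
        g.add_edge(a, b, weight=len(cls))
    return AssemblyGraph(g)


@dataclass(frozen=True)
class Motifs:
    """SV-relevant graph patterns.

    ``triangles``: sorted 3-node tuples; ``squares``: 4-node tuples in
    cyclic adjacency order (canonical rotation/reflection); ``self_loops``:
    nodes with a loop edge; ``heavy_edges``: edges (incl. self-loops) with
    weight >= 2.
    """

    triangles: tuple[tuple[str, str, str], ...]
    squares: tuple[tuple[str, str, str, str], ...]
    self_loops: tuple[str, ...]
    heavy_edges: tuple[EdgeKey, ...]


def _canonical_cycle(cycle: Sequence[str]) -> tuple[str, ...]:
    """Canonical representative of a cyclic node sequence under rotation/reflection."""
    n = len(cycle)
    reps = []
    for seq in (list(cycle), list(reversed(cycle))):
        for i in range(n):
            reps.append(tuple(seq[i:] + seq[:i]))
    return min(reps)


def enumerate_motifs(graph: AssemblyGraph) -> Motifs:
    """Enumerate triangles, squares, self-loops and heavy edges.

    Uses :func:`networkx.simple_cycles` with ``length_bound=4``; each
    simple cycle is reported exactly once regardless of rotation or
    reflection.  Self-loops never participate in triangles/squares.
    """
    triangles: set[tuple[str, ...]] = set()
    squares: set[tuple[str, ...]] = set()
    for cycle in nx.simple_cycles(graph.g, length_bound=4):
        if len(cycle) == 3:
            triangles.add(tuple(sorted(cycle)))
        elif len(cycle) == 4:
            squares.add(_canonical_cycle(cycle))
    self_loops = tuple(sorted(n for n in graph.g.nodes if graph.g.has_edge(n, n)))
    heavy = tuple(
        sorted(
            edge_key(a, b)
            for a, b in graph.g.edges
            if graph.g.edges[a, b]["weight"] >= 2
        )
    )
    return Motifs(
        triangles=tuple(sorted(triangles)),
        squares=tuple(sorted(squares)),
        self_loops=self_loops,
        heavy_edges=heavy,
    )
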