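"""Per-sample coverage, depth normalization and log-fold-change series.

Node coverage is mean per-bp coverage: aligned bases landing in the node
divided by node length.  Edge coverage is the number of times read paths
traverse the edge in either direction.  Raw values are floored (default
1.0) so log ratios stay finite, then depth-normalized by each sample's
multiplier bp_n / m, where m is the median total base pairs across the
series.  Log fold change between consecutive samples is log2 of the
ratio of normalized values.

The floor is applied to edges as well as nodes: without it the LFC of an
edge absent in one sample is undefined, and the tandem-duplication
threshold would conflate sequencing depth with duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph_model import AssemblyGraph, EdgeKey, edge_key
from .io_formats import AlignmentRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleSeries:
    """Ordered sample series with total base-pair counts.

    ``multipliers[n] = bp[n] / m`` with m the median of ``bp``; dividing a
    sample's raw values by its multiplier corrects for sequencing depth.
    """

    labels: tuple[str, ...]
    bp: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.bp):
            raise ValueError("labels and bp must have equal length")
        if len(self.bp) < 2:
            raise ValueError("a series needs at least 2 samples")
        if any(v <= 0 for v in self.bp):
            raise ValueError("every sample must have bp > 0")

    @property
    def n_samples(self) -> int:
        return len(self.bp)

    @property
    def m(self) -> float:
        return float(np.median(self.bp))

    @property
    def multipliers(self) -> tuple[float, ...]:
        m = self.m
        return tuple(v / m for v in self.bp)

    @property
    def step_labels(self) -> tuple[str, ...]:
        return tuple(f"C{n}" for n in range(1, self.n_samples))


@dataclass(frozen=True)
class CoverageSeries:
    """Floored, depth-normalized node/edge coverage matrices (rows x samples)."""

    node_cov: pd.DataFrame
    edge_cov: pd.DataFrame
    series: SampleSeries


@dataclass(frozen=True)
class LfcSeries:
    """Node/edge log2 fold change between consecutive samples (columns C1..C(N-1))."""

    node_lfc: pd.DataFrame
    edge_lfc: pd.DataFrame


def node_coverage_raw(
    graph: AssemblyGraph, alignments: Iterable[AlignmentRecord]
) -> tuple[dict[str, float], int]:
    """Mean per-bp coverage per node for one sample.

    Each alignment's interval [path_start, path_end) is projected onto
    the concatenation of its path segments; every overlapped node
    accumulates covered bases.  Records whose offsets exceed the summed
    segment lengths are skipped and counted (second return value).
    """
    bases: dict[str, float] = {}
    skipped = 0
    for rec in alignments:
        lengths = [graph.node_length(seg) for seg, _ in rec.path]
        total = sum(lengths)
        if rec.path_end > total:
            skipped += 1
            continue
        offset = 0
        for (seg, _), seg_len in zip(rec.path, lengths):
            lo = max(rec.path_start, offset)
            hi = min(rec.path_end, offset + seg_len)
            if hi > lo:
                bases[seg] = bases.get(seg, 0.0) + (hi - lo)
            offset += seg_len
    if skipped:
        logger.warning("node_coverage_raw: %d records with out-of-range offsets skipped", skipped)
    return (
        {n: bases.get(n, 0.0) / graph.node_length(n) for n in graph.nodes},
        skipped,
    )


def edge_traversals_raw(
    graph: AssemblyGraph, alignments: Iterable[AlignmentRecord]
) -> tuple[dict[EdgeKey, int], int]:
    """Traversal count per undirected edge for one sample.

    Every consecutive oriented pair in a read path increments the
    undirected edge between the two nodes (identical consecutive
    segments increment the self-loop).  Pairs without a corresponding
    graph edge are tallied, not added (second return value).
    """
    counts: dict[EdgeKey, int] = {}
    unmatched = 0
    for rec in alignments:
        for (a, _), (b, _) in zip(rec.path, rec.path[1:]):
            if graph.has_edge(a, b):
                key = edge_key(a, b)
                counts[key] = counts.get(key, 0) + 1
            else:
                unmatched += 1
    if unmatched:
        logger.info("edge_traversals_raw: %d path adjacencies had no graph edge", unmatched)
    return counts, unmatched


def normalize(
    graph: AssemblyGraph,
    node_raw: Sequence[Mapping[str, float]],
    edge_raw: Sequence[Mapping[EdgeKey, float]],
    series: SampleSeries,
    floor: float = 1.0,
    direction: Literal["divide", "multiply"] = "divide",
) -> CoverageSeries:
    """Floor raw values, then depth-normalize each sample.

    Values below ``floor`` are set to ``floor`` first; then each sample's
    values are divided by its multiplier bp_n/m (``direction="multiply"``
    gives the literal multiply-by-the-multiplier reading instead).
    """
    if len(node_raw) != series.n_samples or len(edge_raw) != series.n_samples:
        raise ValueError("need one raw mapping per sample")
    nodes = graph.nodes
    edges = graph.edges
    node_mat = np.full((len(nodes), series.n_samples), 0.0)
    for j, sample in enumerate(node_raw):
        for i, n in enumerate(nodes):
            node_mat[i, j] = sample.get(n, 0.0)
    edge_mat = np.full((len(edges), series.n_samples), 0.0)
    for j, sample in enumerate(edge_raw):
        for i, e in enumerate(edges):
            edge_mat[i, j] = sample.get(e, 0.0)
    node_mat = np.maximum(node_mat, floor)
    edge_mat = np.maximum(edge_mat, floor)
    mult = np.asarray(series.multipliers)
    if direction == "divide":
        node_mat = node_mat / mult
        edge_mat = edge_mat / mult
    else:
        node_mat = node_mat * mult
        edge_mat = edge_mat * mult
    return CoverageSeries(
        node_cov=pd.DataFrame(node_mat, index=nodes, columns=list(series.labels)),
        edge_cov=pd.DataFrame(
            edge_mat,
            index=pd.MultiIndex.from_tuples(edges)
            if edges
            else pd.MultiIndex.from_arrays([[], []]),
            columns=list(series.labels),
        ),
        series=series,
    )


def lfc(cov: CoverageSeries) -> LfcSeries:
    """Log2 fold change of normalized coverage between consecutive samples."""
    steps = cov.series.step_labels
    node_vals = cov.node_cov.to_numpy()
    edge_vals = cov.edge_cov.to_numpy()
    node_lfc = np.log2(node_vals[:, 1:] / node_vals[:, :-1]) if node_vals.size else node_vals[:, 1:]
    edge_lfc = np.log2(edge_vals[:, 1:] / edge_vals[:, :-1]) if edge_vals.size else edge_vals[:, 1:]
    return LfcSeries(
        node_lfc=pd.DataFrame(node_lfc, index=cov.node_cov.index, columns=list(steps)),
        edge_lfc=pd.DataFrame(edge_lfc, index=cov.edge_cov.index, columns=list(steps)),
    )


def bp_from_alignments(alignments: Iterable[AlignmentRecord]) -> int:
    """Total base pairs of a sample from its GAF records (unique reads' query lengths)."""
    seen: dict[str, int] = {}
    for rec in alignments:
        seen[rec.read_id] = rec.read_length
    return int(sum(seen.values()))
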