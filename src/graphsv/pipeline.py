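"""End-to-end orchestration: GFA + per-sample GAF -> coverage -> LFC -> calls."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

from .coverage import (
    CoverageSeries,
    LfcSeries,
    SampleSeries,
    bp_from_alignments,
    edge_traversals_raw,
    lfc,
    node_coverage_raw,
    normalize,
)
from .graph_model import AssemblyGraph, Motifs, build_graph, enumerate_motifs
from .io_formats import parse_gaf, parse_gfa
from .sv_caller import CallConfig, SvCall, call_all
from .synthetic import SyntheticScenario


@dataclass
class CallResult:
    """Everything one calling run produced, for writers and inspection."""

    graph: AssemblyGraph
    motifs: Motifs
    series: SampleSeries
    coverage: CoverageSeries
    lfc: LfcSeries
    calls: list[SvCall]
    stats: dict = field(default_factory=dict)


def run_calling(
    graph: AssemblyGraph,
    alignments_per_sample: Sequence[list],
    labels: Sequence[str],
    bp: Sequence[float] | None = None,
    config: CallConfig = CallConfig(),
    floor: float = 1.0,
    direction: str = "divide",
) -> CallResult:
    """Core calling pass over parsed inputs.

    ``bp`` defaults to each sample's total unique-read query length from
    its GAF records.
    """
    if len(alignments_per_sample) < 2:
        raise ValueError("need at least 2 samples in series order")
    if bp is None:
        bp = [bp_from_alignments(alns) for alns in alignments_per_sample]
    series = SampleSeries(labels=tuple(labels), bp=tuple(float(v) for v in bp))
    node_raw, edge_raw = [], []
    stats: dict = {"samples": {}}
    for label, alns in zip(labels, alignments_per_sample):
        cov, skipped = node_coverage_raw(graph, alns)
        counts, unmatched = edge_traversals_raw(graph, alns)
        node_raw.append(cov)
        edge_raw.append(counts)
        n = len(alns)
        stats["samples"][label] = {
            "records": n,
            "records_used": n - skipped,
            "fraction_used": (n - skipped) / n if n else 0.0,
            "unmatched_adjacencies": unmatched,
        }
    cov_series = normalize(graph, node_raw, edge_raw, series, floor=floor, direction=direction)
    lfc_series = lfc(cov_series)
    motifs = enumerate_motifs(graph)
    calls = call_all(graph, motifs, lfc_series, config)
    return CallResult(
        graph=graph,
        motifs=motifs,
        series=series,
        coverage=cov_series,
        lfc=lfc_series,
        calls=calls,
        stats=stats,
    )


def call_from_files(
    gfa_path,
    gaf_paths: Sequence,
    labels: Sequence[str] | None = None,
    bp: Sequence[float] | None = None,
    min_mapq: int = 0,
    config: CallConfig = CallConfig(),
    floor: float = 1.0,
    direction: str = "divide",
) -> CallResult:
    """Parse a GFA and per-sample GAFs (series order) and call SVs."""
    segments, links = parse_gfa(gfa_path)
    graph = build_graph(segments, links)
    alignments = [parse_gaf(p, min_mapq=min_mapq) for p in gaf_paths]
    if labels is None:
        labels = [f"t{i}" for i in range(len(gaf_paths))]
    return run_calling(
        graph, alignments, labels, bp=bp, config=config, floor=floor, direction=direction
    )


def call_from_scenario(
    scenario: SyntheticScenario,
    config: CallConfig = CallConfig(),
    use_declared_bp: bool = True,
) -> CallResult:
    """Run the full pipeline on a synthetic scenario's serialized texts."""
    segments, links = parse_gfa(io.StringIO(scenario.gfa))
    graph = build_graph(segments, links)
    alignments = [parse_gaf(io.StringIO(text)) for text in scenario.gaf_per_sample]
    bp = scenario.bp_per_sample if use_declared_bp else None
    return run_calling(
        graph,
        alignments,
        scenario.sample_labels,
        bp=bp,
        config=config,
    )
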