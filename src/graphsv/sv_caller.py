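"""Motif + outlier rules that turn LFC vectors into SV calls.

Per consecutive step of the series:

* triangle with exactly one LFC outlier -> INS (outlier above the motif
  median) or DEL (below), called on the outlier node;
* square with a single outlier, or with two opposite-signed outliers on
  non-adjacent corners -> complex indel (CI-i above / CI-d below);
* self-loop edge LFC > 1 -> TD-i on the loop node; any weight>=2 edge
  with LFC > 1 -> TD-i on the endpoint with the greater node LFC; the
  mirrored declining rule (< -1) yields TD-d.  A tandem duplication is
  suppressed on nodes already called at the same step.

Outliers deviate from the motif *median* by more than one population
standard deviation (taken about the mean); the median gives robustness
against a single extreme value dragging the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coverage import LfcSeries
from .graph_model import AssemblyGraph, EdgeKey, Motifs, edge_key

SV_TYPES = ("INS", "DEL", "CI-i", "CI-d", "TD-i", "TD-d")

# lenient matching treats an insertion called inside a complex indel (and
# vice versa) as the same event class
_TYPE_CLASS = {
    "INS": "rise",
    "CI-i": "rise",
    "DEL": "fall",
    "CI-d": "fall",
    "TD-i": "td-rise",
    "TD-d": "td-fall",
}


@dataclass(frozen=True)
class SvCall:
    """One called structural variant.

    ``step`` indexes the consecutive pair (1..N-1, labeled C1..).  For
    triangle/square calls ``motif_median``/``motif_std`` summarize the
    motif's node LFCs; for tandem duplications ``motif_median`` carries
    the deciding edge LFC and ``motif_std`` is 0.
    """

    step: int
    sv_type: str
    node: str
    motif: tuple[str, ...]
    node_lfc: float
    motif_median: float
    motif_std: float


@dataclass(frozen=True)
class OutlierResult:
    values: tuple[float, ...]
    median: float
    std: float
    outliers: tuple[tuple[int, str], ...]  # (position, "above"|"below")


@dataclass(frozen=True)
class CallConfig:
    """Tunable thresholds of the calling rules.

    ``outlier_k``: multiple of the std a value must deviate from the
    motif median to be an outlier.  ``td_threshold``: edge LFC magnitude
    for tandem duplications (1.0 = a doubling in log2).  ``adjacency``:
    whether the square two-outlier rule checks the full graph's edge set
    or only the cycle's own edges.  ``enable_td_d``: call declining
    duplicates via the mirrored threshold.
    """

    outlier_k: float = 1.0
    td_threshold: float = 1.0
    adjacency: str = "graph"  # "graph" | "cycle"
    enable_td_d: bool = True


def find_outliers(values: Sequence[float], k: float = 1.0) -> OutlierResult:
    """Flag values deviating from the median by more than k population stds.

    The median is the standard sample median (mean of the middle two for
    four values); the standard deviation is the population std about the
    arithmetic mean.  Requires at least 3 values.
    """
    if len(values) < 3:
        raise ValueError("find_outliers requires at least 3 values")
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    std = float(np.std(arr))
    outliers = tuple(
        (i, "above" if v > med else "below")
        for i, v in enumerate(arr)
        if abs(v - med) > k * std
    )
    return OutlierResult(tuple(float(v) for v in arr), med, std, outliers)


def call_indels(
    triangles: Iterable[tuple[str, str, str]],
    node_lfc: Mapping[str, float],
    step: int,
    k: float = 1.0,
) -> list[SvCall]:
    """INS/DEL per triangle: exactly one outlier -> call on the outlier node."""
    calls = []
    for tri in triangles:
        values = [node_lfc[n] for n in tri]
        res = find_outliers(values, k)
        if len(res.outliers) != 1:
            continue
        i, direction = res.outliers[0]
        calls.append(
            SvCall(
                step=step,
                sv_type="INS" if direction == "above" else "DEL",
                node=tri[i],
                motif=tuple(tri),
                node_lfc=values[i],
                motif_median=res.median,
                motif_std=res.std,
            )
        )
    return calls


def call_complex_indels(
    squares: Iterable[tuple[str, str, str, str]],
    node_lfc: Mapping[str, float],
    step: int,
    graph: AssemblyGraph | None = None,
    adjacency: str = "graph",
    k: float = 1.0,
) -> list[SvCall]:
    """Complex indels per square (squares carry cyclic adjacency order).

    A single outlier yields one call; two outliers qualify only when they
    sit on non-adjacent corners AND straddle the median (one above, one
    below), yielding CI-i on the high node and CI-d on the low one.
    """
    if adjacency == "graph" and graph is None:
        raise ValueError("graph adjacency mode requires the graph")
    calls = []
    for sq in squares:
        values = [node_lfc[n] for n in sq]
        res = find_outliers(values, k)
        hits: list[tuple[int, str]] = []
        if len(res.outliers) == 1:
            hits = [res.outliers[0]]
        elif len(res.outliers) == 2:
            (i, di), (j, dj) = res.outliers
            if adjacency == "cycle":
                adjacent = (j - i) % 4 in (1, 3)
            else:
                adjacent = graph.has_edge(sq[i], sq[j])
            if di != dj and not adjacent:
                hits = [(i, di), (j, dj)]
        for i, direction in hits:
            calls.append(
                SvCall(
                    step=step,
                    sv_type="CI-i" if direction == "above" else "CI-d",
                    node=sq[i],
                    motif=tuple(sq),
                    node_lfc=values[i],
                    motif_median=res.median,
                    motif_std=res.std,
                )
            )
    return calls


def call_tandem_dups(
    self_loops: Iterable[str],
    heavy_edges: Iterable[EdgeKey],
    edge_lfc: Mapping[EdgeKey, float],
    node_lfc: Mapping[str, float],
    step: int,
    prior_calls: Iterable[SvCall] = (),
    threshold: float = 1.0,
    enable_td_d: bool = True,
) -> list[SvCall]:
    """Tandem duplications from self-loops and weight>=2 edges.

    A self-loop whose edge LFC exceeds the threshold calls TD-i on its
    node; a heavy edge exceeding it calls TD-i on the endpoint with the
    greater node LFC (ties break to the lexicographically smaller id).
    The mirrored rule below -threshold yields TD-d on the endpoint with
    the smaller node LFC.  Nodes already called at this step (prior
    indel/CI calls, or an earlier TD) are suppressed.
    """
    called = {c.node for c in prior_calls if c.step == step}
    calls = []

    def emit(node: str, sv_type: str, motif: tuple[str, ...], e_lfc: float) -> None:
        if node in called:
            return
        called.add(node)
        calls.append(
            SvCall(
                step=step,
                sv_type=sv_type,
                node=node,
                motif=motif,
                node_lfc=node_lfc[node],
                motif_median=e_lfc,
                motif_std=0.0,
            )
        )

    for v in sorted(self_loops):
        e = (v, v)
        val = edge_lfc[e]
        if val > threshold:
            emit(v, "TD-i", e, val)
        elif enable_td_d and val < -threshold:
            emit(v, "TD-d", e, val)

    for a, b in sorted(heavy_edges):
        if a == b:
            continue  # heavy self-loops already handled by the loop rule
        val = edge_lfc[(a, b)]
        if val > threshold:
            la, lb = node_lfc[a], node_lfc[b]
            node = a if la > lb or (la == lb and a < b) else b
            emit(node, "TD-i", (a, b), val)
        elif enable_td_d and val < -threshold:
            la, lb = node_lfc[a], node_lfc[b]
            node = a if la < lb or (la == lb and a < b) else b
            emit(node, "TD-d", (a, b), val)
    return calls


def call_all(
    graph: AssemblyGraph,
    motifs: Motifs,
    lfc_series: LfcSeries,
    config: CallConfig = CallConfig(),
) -> list[SvCall]:
    """Run the full rule cascade for every step of the series.

    Order per step: indels over triangles, complex indels over squares,
    then tandem duplications with suppression against the union of the
    earlier calls at that step.  Output is deterministically ordered by
    (step, sv_type, node, motif).
    """
    calls: list[SvCall] = []
    n_steps = lfc_series.node_lfc.shape[1]
    for step in range(1, n_steps + 1):
        col = lfc_series.node_lfc.columns[step - 1]
        node_lfc = lfc_series.node_lfc[col].to_dict()
        edge_lfc = dict(zip(lfc_series.edge_lfc.index, lfc_series.edge_lfc[col]))
        step_calls = call_indels(motifs.triangles, node_lfc, step, k=config.outlier_k)
        step_calls += call_complex_indels(
            motifs.squares,
            node_lfc,
            step,
            graph=graph,
            adjacency=config.adjacency,
            k=config.outlier_k,
        )
        step_calls += call_tandem_dups(
            motifs.self_loops,
            motifs.heavy_edges,
            edge_lfc,
            node_lfc,
            step,
            prior_calls=step_calls,
            threshold=config.td_threshold,
            enable_td_d=config.enable_td_d,
        )
        calls.extend(step_calls)
    return sorted(calls, key=lambda c: (c.step, c.sv_type, c.node, c.motif))


def dedupe_unique(
    calls: Iterable[SvCall],
) -> tuple[dict[tuple[str, int], int], dict[tuple[str, int], int]]:
    """Raw and unique call counts per (sv_type, step).

    Raw counts every call record; unique counts each distinct
    (node, sv_type) pair once per step, so one sequence called in many
    motifs contributes one.
    """
    raw: dict[tuple[str, int], int] = {}
    uniq_pairs: set[tuple[str, str, int]] = set()
    for c in calls:
        raw[(c.sv_type, c.step)] = raw.get((c.sv_type, c.step), 0) + 1
        uniq_pairs.add((c.node, c.sv_type, c.step))
    unique: dict[tuple[str, int], int] = {}
    for node, sv_type, step in uniq_pairs:
        unique[(sv_type, step)] = unique.get((sv_type, step), 0) + 1
    return raw, unique


def evaluate_calls(
    calls: Iterable[SvCall],
    truth: Iterable[tuple[str, str, int]],
    strict: bool = False,
) -> dict[str, dict[str, float]]:
    """Precision / recall / F1 per SV type against a planted truth table.

    Truth rows are (node, sv_type, step).  By default matching is
    lenient: an insertion and a complex-indel insertion on the same node
    count as the same event class (likewise deletions); ``strict=True``
    requires the exact type.  With zero calls of a type, precision is
    reported as 0.0 with a ``no_calls`` flag.
    """

    def cls(t: str) -> str:
        return t if strict else _TYPE_CLASS[t]

    truth = list(truth)
    uniq_calls = sorted({(c.node, c.sv_type, c.step) for c in calls})
    truth_keys = {(node, cls(t), step) for node, t, step in truth}
    call_keys = {(node, cls(t), step) for node, t, step in uniq_calls}

    result: dict[str, dict[str, float]] = {}
    types = sorted({t for _, t, _ in truth} | {t for _, t, _ in uniq_calls})
    for sv_type in types + ["overall"]:
        if sv_type == "overall":
            t_rows = truth
            c_rows = uniq_calls
        else:
            t_rows = [r for r in truth if r[1] == sv_type]
            c_rows = [r for r in uniq_calls if r[1] == sv_type]
        tp_truth = sum((n, cls(t), s) in call_keys for n, t, s in t_rows)
        tp_calls = sum((n, cls(t), s) in truth_keys for n, t, s in c_rows)
        recall = tp_truth / len(t_rows) if t_rows else float("nan")
        flags = []
        if c_rows:
            precision = tp_calls / len(c_rows)
        else:
            precision = 0.0
            flags.append("no_calls")
        if math.isnan(recall) or precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        result[sv_type] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "n_truth": float(len(t_rows)),
            "n_called": float(len(c_rows)),
        }
        if flags:
            result[sv_type]["flag"] = "no_calls"  # type: ignore[assignment]
    return result
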