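"""Calling-rule arithmetic, suppression ordering and symmetry properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphsv import (
    CallConfig,
    SvCall,
    build_graph,
    call_all,
    call_complex_indels,
    call_indels,
    call_tandem_dups,
    dedupe_unique,
    evaluate_calls,
    find_outliers,
)
from graphsv.io_formats import LinkRecord, SegmentRecord


def pop_std(values):
    mean = sum(values) / len(values)
    return math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))


class TestFindOutliers:
    def test_constant_values_no_outlier(self):
        assert find_outliers([1.0, 1.0, 1.0]).outliers == ()

    def test_three_value_oracle(self):
        res = find_outliers([0.0, 0.0, 5.0])
        assert res.median == 0.0
        assert res.std == pytest.approx(pop_std([0, 0, 5]))  # ~2.357
        assert res.outliers == ((2, "above"),)

    def test_four_value_oracle(self):
        res = find_outliers([0.0, 0.0, 4.0, -4.0])
        assert res.median == 0.0  # mean of middle two
        assert res.std == pytest.approx(pop_std([0, 0, 4, -4]))  # ~2.828
        assert res.outliers == ((2, "above"), (3, "below"))

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            find_outliers([1.0, 2.0])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(-40, 40).map(lambda i: i / 4), min_size=3, max_size=4),
        st.integers(-20, 20).map(lambda i: i / 4),
    )
    def test_shift_invariance(self, values, shift):
        """Adding a constant shifts median but leaves the outlier set unchanged."""
        base = find_outliers(values)
        shifted = find_outliers([v + shift for v in values])
        assert base.outliers == shifted.outliers


class TestCallIndels:
    def test_single_high_outlier_is_insertion(self):
        """(0.02, -0.01, 2.5): median 0.02, std~1.18, only 2.5 deviates."""
        lfc = {"u": 0.02, "v": -0.01, "x": 2.5}
        calls = call_indels([("u", "v", "x")], lfc, step=1)
        assert [(c.sv_type, c.node) for c in calls] == [("INS", "x")]
        assert calls[0].motif_median == pytest.approx(0.02)
        assert calls[0].motif_std == pytest.approx(pop_std([0.02, -0.01, 2.5]))

    def test_single_low_outlier_is_deletion(self):
        lfc = {"u": -2.2, "v": 0.1, "x": 0.0}
        calls = call_indels([("u", "v", "x")], lfc, step=1)
        assert [(c.sv_type, c.node) for c in calls] == [("DEL", "u")]

    def test_flat_triangle_no_call(self):
        assert call_indels([("u", "v", "x")], {"u": 0.0, "v": 0.0, "x": 0.0}, 1) == []

    def test_two_outliers_no_call(self):
        lfc = {"u": 4.0, "v": -4.0, "x": 0.0}
        assert call_indels([("u", "v", "x")], lfc, 1) == []


def square_graph(order):
    links = [
        LinkRecord(order[i], "+", order[(i + 1) % 4], "+") for i in range(4)
    ]
    return build_graph([SegmentRecord(n, None, 10) for n in order], links)


class TestCallComplexIndels:
    def test_adjacent_outliers_rejected(self):
        """Cycle (a,b,c,d) with c=+4, d=-4: outliers share the c-d edge."""
        g = square_graph(("a", "b", "c", "d"))
        lfc = {"a": 0.0, "b": 0.0, "c": 4.0, "d": -4.0}
        assert call_complex_indels([("a", "b", "c", "d")], lfc, 1, graph=g) == []

    def test_opposite_outliers_called_both_ways(self):
        """Cycle (a,c,b,d): +4/-4 on opposite corners -> CI-i and CI-d."""
        g = square_graph(("a", "c", "b", "d"))
        lfc = {"a": 0.0, "b": 0.0, "c": 4.0, "d": -4.0}
        calls = call_complex_indels([("a", "c", "b", "d")], lfc, 1, graph=g)
        assert sorted((c.sv_type, c.node) for c in calls) == [("CI-d", "d"), ("CI-i", "c")]

    def test_no_outliers_no_call(self):
        # symmetric pattern: every deviation from the median equals the std,
        # and the outlier test is strict, so nothing is flagged
        g = square_graph(("a", "b", "c", "d"))
        lfc = {"a": -1.0, "b": 1.0, "c": -1.0, "d": 1.0}
        assert call_complex_indels([("a", "b", "c", "d")], lfc, 1, graph=g) == []

    def test_single_outlier_square(self):
        g = square_graph(("a", "b", "c", "d"))
        lfc = {"a": 0.0, "b": 0.0, "c": 0.0, "d": -3.0}
        calls = call_complex_indels([("a", "b", "c", "d")], lfc, 1, graph=g)
        assert [(c.sv_type, c.node) for c in calls] == [("CI-d", "d")]

    def test_graph_adjacency_consults_chords(self):
        """A chord outside the cycle joins opposite corners under graph mode only."""
        g = square_graph(("a", "c", "b", "d"))
        g.g.add_edge("c", "d", weight=1)  # chord between the opposite outlier corners
        lfc = {"a": 0.0, "b": 0.0, "c": 4.0, "d": -4.0}
        sq = [("a", "c", "b", "d")]
        assert call_complex_indels(sq, lfc, 1, graph=g, adjacency="graph") == []
        assert len(call_complex_indels(sq, lfc, 1, adjacency="cycle")) == 2


class TestCallTandemDups:
    def test_self_loop_above_threshold(self):
        """Loop counts 5 -> 21 give edge LFC log2(4.2) ~ 2.07 -> TD-i."""
        e_lfc = {("x", "x"): math.log2(21 / 5)}
        calls = call_tandem_dups(["x"], [], e_lfc, {"x": 0.5}, 1)
        assert [(c.sv_type, c.node) for c in calls] == [("TD-i", "x")]
        assert calls[0].motif_median == pytest.approx(2.0704, abs=1e-4)

    def test_below_threshold_no_call(self):
        assert call_tandem_dups(["x"], [], {("x", "x"): 0.5}, {"x": 0.0}, 1) == []

    def test_heavy_edge_picks_greater_node_lfc(self):
        calls = call_tandem_dups(
            [], [("a", "b")], {("a", "b"): 1.5}, {"a": 0.8, "b": 0.3}, 1
        )
        assert [(c.sv_type, c.node) for c in calls] == [("TD-i", "a")]

    def test_suppressed_by_prior_call_same_step(self):
        prior = [SvCall(1, "INS", "a", ("a", "u", "v"), 0.8, 0.0, 0.1)]
        calls = call_tandem_dups(
            [], [("a", "b")], {("a", "b"): 1.5}, {"a": 0.8, "b": 0.3}, 1, prior_calls=prior
        )
        assert calls == []

    def test_prior_call_other_step_does_not_suppress(self):
        prior = [SvCall(2, "INS", "a", ("a", "u", "v"), 0.8, 0.0, 0.1)]
        calls = call_tandem_dups(
            [], [("a", "b")], {("a", "b"): 1.5}, {"a": 0.8, "b": 0.3}, 1, prior_calls=prior
        )
        assert len(calls) == 1

    def test_declining_duplicate_mirrored_rule(self):
        calls = call_tandem_dups(
            ["x"], [("a", "b")], {("x", "x"): -1.5, ("a", "b"): -2.0},
            {"x": 0.0, "a": -0.9, "b": -0.1}, 1,
        )
        assert sorted((c.sv_type, c.node) for c in calls) == [("TD-d", "a"), ("TD-d", "x")]

    def test_td_d_flag_disables(self):
        calls = call_tandem_dups(
            ["x"], [], {("x", "x"): -1.5}, {"x": 0.0}, 1, enable_td_d=False
        )
        assert calls == []

    def test_tie_breaks_to_smaller_id(self):
        calls = call_tandem_dups([], [("a", "b")], {("a", "b"): 1.5}, {"a": 0.5, "b": 0.5}, 1)
        assert calls[0].node == "a"


class TestSignSymmetry:
    def test_negating_lfc_swaps_call_types(self):
        """INS<->DEL, CI-i<->CI-d, TD-i<->TD-d with identical node sets."""
        swap = {"INS": "DEL", "DEL": "INS", "CI-i": "CI-d", "CI-d": "CI-i",
                "TD-i": "TD-d", "TD-d": "TD-i"}
        tri = [("u", "v", "x")]
        sq_g = square_graph(("a", "c", "b", "d"))
        sq = [("a", "c", "b", "d")]
        n_lfc = {"u": 0.1, "v": -0.05, "x": 2.4, "a": 0.0, "b": 0.1, "c": 3.0, "d": -3.1,
                 "s": 0.2, "p": 0.9, "q": 0.1}
        e_lfc = {("s", "s"): 1.7, ("p", "q"): 1.2}
        def run(nl, el):
            calls = call_indels(tri, nl, 1)
            calls += call_complex_indels(sq, nl, 1, graph=sq_g)
            calls += call_tandem_dups(["s"], [("p", "q")], el, nl, 1, prior_calls=calls)
            return calls
        pos = run(n_lfc, e_lfc)
        neg = run({k: -v for k, v in n_lfc.items()}, {k: -v for k, v in e_lfc.items()})
        assert {(swap[c.sv_type], c.node) for c in pos} == {(c.sv_type, c.node) for c in neg}
        assert len(pos) == 5


class TestDedupeAndEvaluate:
    def _ins(self, node, step=1, sv_type="INS", motif=None):
        return SvCall(step, sv_type, node, motif or (node,), 2.0, 0.0, 0.5)

    def test_repeat_motifs_collapse_to_one_unique(self):
        calls = [self._ins("x", motif=(f"u{i}", f"v{i}", "x")) for i in range(5)]
        raw, unique = dedupe_unique(calls)
        assert raw[("INS", 1)] == 5 and unique[("INS", 1)] == 1

    def test_empty_calls(self):
        assert dedupe_unique([]) == ({}, {})

    def test_same_node_counted_per_step(self):
        calls = [self._ins("x", step=1), self._ins("x", step=2)]
        _, unique = dedupe_unique(calls)
        assert unique == {("INS", 1): 1, ("INS", 2): 1}

    def test_perfect_recovery(self):
        calls = [self._ins("x"), self._ins("y", sv_type="DEL")]
        truth = [("x", "INS", 1), ("y", "DEL", 1)]
        ev = evaluate_calls(calls, truth)
        assert ev["overall"]["precision"] == 1.0 and ev["overall"]["recall"] == 1.0

    def test_partial_recall(self):
        calls = [self._ins(f"x{i}") for i in range(3)]
        truth = [(f"x{i}", "INS", 1) for i in range(4)]
        ev = evaluate_calls(calls, truth)
        assert ev["INS"]["recall"] == 0.75 and ev["INS"]["precision"] == 1.0

    def test_zero_calls_flagged(self):
        ev = evaluate_calls([], [("x", "INS", 1)])
        assert ev["INS"]["recall"] == 0.0
        assert ev["INS"]["precision"] == 0.0
        assert ev["INS"].get("flag") == "no_calls"

    def test_lenient_class_matches_ins_to_ci(self):
        calls = [self._ins("x", sv_type="CI-i")]
        truth = [("x", "INS", 1)]
        assert evaluate_calls(calls, truth)["INS"]["recall"] == 1.0
        assert evaluate_calls(calls, truth, strict=True)["INS"]["recall"] == 0.0


def test_call_all_ordering_and_suppression():
    """Indels run before CIs before TDs; TD suppression sees both; output sorted."""
    segments = [SegmentRecord(n, None, 10) for n in "uvx"]
    links = [
        LinkRecord("u", "+", "v", "+"),
        LinkRecord("u", "+", "x", "+"),
        LinkRecord("x", "+", "v", "+"),
        LinkRecord("x", "+", "x", "+"),
    ]
    graph = build_graph(segments, links)
    from graphsv import enumerate_motifs
    from graphsv.coverage import LfcSeries
    import pandas as pd

    motifs = enumerate_motifs(graph)
    node_lfc = pd.DataFrame({"C1": {"u": 0.0, "v": 0.1, "x": 2.5}})
    edge_lfc = pd.DataFrame(
        {"C1": {("u", "v"): 0.0, ("u", "x"): 1.2, ("v", "x"): 1.1, ("x", "x"): 2.0}}
    )
    edge_lfc.index = pd.MultiIndex.from_tuples(edge_lfc.index)
    calls = call_all(graph, motifs, LfcSeries(node_lfc, edge_lfc))
    # x is called INS by the triangle; the self-loop TD on x is suppressed
    assert [(c.sv_type, c.node) for c in calls] == [("INS", "x")]
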