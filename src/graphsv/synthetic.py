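"""Ground-truth scenario generator: graphs with planted SV motifs.

Variants are planted directly at graph level — a backbone chain of
segments plus, per planted SV, the motif its type produces in a
co-assembly graph:

* INS / DEL: a triangle (consecutive backbone pair u-v plus a variant
  node x linked u-x and x-v) whose variant node rises / falls;
* complex indel: a square u-x-v-y over a backbone pair two apart (so the
  cycle is chordless), with x rising and y falling;
* tandem duplication: either a variant node with a self-loop whose
  traversal count rises, or a variant node attached by a weight-2 double
  edge with rising traversals.

Per-sample GAF alignments realize a coverage plan in which planted
variants follow a geometric abundance trajectory (fold_change per
consecutive step, centered on coverage_mean) while backbone nodes stay
flat, so every step of the series is an event for every motif.  In
``exact`` mode read counts equal the plan and coverage values are
integers realizable by whole-node read paths; in ``poisson`` mode read
counts are Poisson draws and single-node reads become fixed-length
windows, emulating sampling noise.  Identical seeds give byte-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ScenarioParams:
    """Generator knobs; defaults are the package's standard study conditions."""

    n_backbone: int = 50
    node_length_range: tuple[int, int] = (2000, 4000)
    n_motifs_per_type: tuple[int, int, int, int] = (5, 5, 5, 5)  # INS, DEL, CI, TD
    n_samples: int = 3
    coverage_mean: float = 20.0
    fold_change: float = 4.0
    read_length: int = 500
    noise_model: str = "exact"  # "exact" | "poisson"
    jitter: float = 0.0  # uniform LFC jitter half-width on backbone nodes (log2)
    seed: int = 0


@dataclass(frozen=True)
class SyntheticScenario:
    """Planted-truth bundle: GFA text, per-sample GAF texts, bp totals, truth table."""

    params: ScenarioParams
    gfa: str
    gaf_per_sample: tuple[str, ...]
    bp_per_sample: tuple[int, ...]
    truth: tuple[tuple[str, str, int], ...]  # (node, sv_type, step)

    @property
    def sample_labels(self) -> tuple[str, ...]:
        return tuple(f"t{n}" for n in range(self.params.n_samples))

    def truth_tsv(self) -> str:
        lines = ["node\tsv_type\tstep\n"]
        for node, sv_type, step in self.truth:
            lines.append(f"{node}\t{sv_type}\tC{step}\n")
        return "".join(lines)

    def write(self, out_dir) -> None:
        """Write graph.gfa, one GAF per sample, bp table, truth table and params."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "graph.gfa").write_text(self.gfa)
        for label, gaf in zip(self.sample_labels, self.gaf_per_sample):
            (out / f"{label}.gaf").write_text(gaf)
        (out / "bp.tsv").write_text(
            "".join(f"{l}\t{bp}\n" for l, bp in zip(self.sample_labels, self.bp_per_sample))
        )
        (out / "truth.tsv").write_text(self.truth_tsv())
        (out / "params.json").write_text(
            json.dumps(
                {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self.params).items()},
                indent=2,
            )
            + "\n"
        )


@dataclass
class _Plan:
    """Internal coverage/traversal plan realized by the GAF emitter."""

    node_lengths: dict[str, int]
    links: list[tuple[str, str, str, str]]
    # single-node read counts per node per sample (exact-mode counts)
    singles: dict[str, list[float]]
    # multi-node read categories: (path, per-sample counts)
    specials: list[tuple[tuple[tuple[str, str], ...], list[float]]]
    truth: list[tuple[str, str, int]]


def _trajectory(params: ScenarioParams, rising: bool) -> list[float]:
    """Geometric abundance trajectory centered on coverage_mean."""
    center = (params.n_samples - 1) / 2
    vals = [
        params.coverage_mean * params.fold_change ** (n - center)
        for n in range(params.n_samples)
    ]
    return vals if rising else vals[::-1]


def plant_motifs(params: ScenarioParams, rng: np.random.Generator) -> _Plan:
    """Build the backbone chain, plant the motifs, and lay out the coverage plan.

    Motif regions are node-disjoint blocks along the backbone; the order
    of motif placement along the chain is shuffled by the RNG.
    """
    n_ins, n_del, n_ci, n_td = params.n_motifs_per_type
    blocks = (
        [("INS", 2)] * n_ins + [("DEL", 2)] * n_del + [("CI", 3)] * n_ci + [("TD", 1)] * n_td
    )
    needed = sum(size for _, size in blocks)
    if needed > params.n_backbone:
        raise ValueError(
            f"backbone of {params.n_backbone} nodes cannot host motifs needing {needed}"
        )
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    lo, hi = params.node_length_range
    backbone = [f"b{i:03d}" for i in range(params.n_backbone)]
    lengths = {b: int(rng.integers(lo, hi + 1)) for b in backbone}
    links: list[tuple[str, str, str, str]] = [
        (backbone[i], "+", backbone[i + 1], "+") for i in range(params.n_backbone - 1)
    ]

    flat = [params.coverage_mean] * params.n_samples
    singles: dict[str, list[float]] = {}
    for b in backbone:
        if params.jitter > 0:
            singles[b] = [
                v * 2.0 ** float(rng.uniform(-params.jitter, params.jitter)) for v in flat
            ]
        else:
            singles[b] = list(flat)
    specials: list[tuple[tuple[tuple[str, str], ...], list[float]]] = []
    truth: list[tuple[str, str, int]] = []
    steps = range(1, params.n_samples)

    cursor = 0
    counters = {"INS": 0, "DEL": 0, "CI": 0, "TD": 0}
    for kind, size in blocks:
        region = backbone[cursor : cursor + size]
        cursor += size
        k = counters[kind]
        counters[kind] += 1
        if kind in ("INS", "DEL"):
            u, v = region
            x = f"{kind.lower()}{k:02d}"
            lengths[x] = int(rng.integers(lo, hi + 1))
            links += [(u, "+", x, "+"), (x, "+", v, "+")]
            singles[x] = _trajectory(params, rising=(kind == "INS"))
            truth += [(x, kind, s) for s in steps]
        elif kind == "CI":
            u, _w, v = region
            x, y = f"cix{k:02d}", f"ciy{k:02d}"
            for node, rising in ((x, True), (y, False)):
                lengths[node] = int(rng.integers(lo, hi + 1))
                links += [(u, "+", node, "+"), (node, "+", v, "+")]
                singles[node] = _trajectory(params, rising)
            truth += [(x, "CI-i", s) for s in steps] + [(y, "CI-d", s) for s in steps]
        else:  # TD — alternate self-loop/double-edge and rising/falling subtypes
            (u,) = region
            x = f"td{k:02d}"
            lengths[x] = int(rng.integers(lo, hi + 1))
            rising = k % 4 < 2
            counts = _trajectory(params, rising=rising)
            if k % 2 == 0:
                # self-duplicate: variant node with a self-loop
                links += [(u, "+", x, "+"), (x, "+", x, "+")]
                specials.append((((x, "+"), (x, "+")), counts))
            else:
                # near-duplicate pair: weight-2 double edge u-x
                links += [(u, "+", x, "+"), (u, "+", x, "-")]
                specials.append((((u, "+"), (x, "+")), counts))
            singles[x] = [0.0] * params.n_samples
            truth += [(x, "TD-i" if rising else "TD-d", s) for s in steps]

    return _Plan(
        node_lengths=lengths,
        links=links,
        singles=singles,
        specials=specials,
        truth=truth,
    )


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode()


def _gfa_text(plan: _Plan, rng: np.random.Generator) -> str:
    lines = ["H\tVN:Z:1.0\n"]
    for node in sorted(plan.node_lengths):
        seq = _random_sequence(plan.node_lengths[node], rng)
        lines.append(f"S\t{node}\t{seq}\n")
    for a, oa, b, ob in plan.links:
        lines.append(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\n")
    return "".join(lines)


def emit_alignments(
    plan: _Plan, params: ScenarioParams, sample: int, rng: np.random.Generator
) -> tuple[str, int]:
    """Emit one sample's GAF stream realizing the coverage plan.

    Exact mode: per node, round(plan) whole-node reads; special paths get
    round(plan) full-span reads.  Poisson mode: special-path counts are
    Poisson(plan); single-node reads become Poisson(plan * L / read_length)
    windows of read_length bases at uniform offsets.
    """
    lines: list[str] = []
    bp = 0
    ridx = 0

    def gaf_line(path: tuple[tuple[str, str], ...], start: int, end: int) -> None:
        nonlocal bp, ridx
        plen = sum(plan.node_lengths[s] for s, _ in path)
        qlen = end - start
        path_str = "".join(("<" if o == "-" else ">") + s for s, o in path)
        lines.append(
            f"s{sample}_r{ridx:06d}\t{qlen}\t0\t{qlen}\t+\t{path_str}\t{plen}\t{start}\t{end}\t{qlen}\t{qlen}\t60\n"
        )
        bp += qlen
        ridx += 1

    for node in sorted(plan.singles):
        target = plan.singles[node][sample]
        length = plan.node_lengths[node]
        if params.noise_model == "poisson":
            rlen = min(params.read_length, length)
            count = int(rng.poisson(target * length / rlen))
            for _ in range(count):
                start = int(rng.integers(0, length - rlen + 1))
                gaf_line(((node, "+"),), start, start + rlen)
        else:
            for _ in range(int(round(target))):
                gaf_line(((node, "+"),), 0, length)

    for path, counts in plan.specials:
        target = counts[sample]
        count = (
            int(rng.poisson(target)) if params.noise_model == "poisson" else int(round(target))
        )
        span = sum(plan.node_lengths[s] for s, _ in path)
        for _ in range(count):
            gaf_line(path, 0, span)

    return "".join(lines), bp


def generate_scenario(params: ScenarioParams) -> SyntheticScenario:
    """Generate a full scenario bundle from the parameters' seed."""
    rng = np.random.default_rng(params.seed)
    plan = plant_motifs(params, rng)
    gfa = _gfa_text(plan, rng)
    gafs: list[str] = []
    bps: list[int] = []
    for sample in range(params.n_samples):
        text, bp = emit_alignments(plan, params, sample, rng)
        gafs.append(text)
        bps.append(bp)
    return SyntheticScenario(
        params=params,
        gfa=gfa,
        gaf_per_sample=tuple(gafs),
        bp_per_sample=tuple(bps),
        truth=tuple(plan.truth),
    )
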