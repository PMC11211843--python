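# Methods

## Model

`graphsv` assumes a series of long-read metagenome samples drawn from
the same community, co-assembled into one graph so that sequence shared
across samples and strains collapses into shared nodes. A structural
variant then leaves two correlated footprints: a *topological* one (the
variant sequence forms a characteristic motif against its flanking
backbone) and a *dynamic* one (its coverage trajectory diverges from its
neighbours' between consecutive samples). Calling on the conjunction of
both suppresses the two dominant error sources individually: assembly
artifacts create motifs without coherent coverage dynamics, and shifts
in species abundance move whole neighbourhoods' coverage together.

The graph is undirected; each segment and its reverse complement are one
node, so a GFA link and its reverse-complement twin are one adjacency.
Edge weight counts distinct collapsed link classes (1 for an ordinary
junction, 2 when two distinct junctions join the same node pair — the
signature of a near-identical duplicate looping between two nodes).

Coverage is computed per sample from graph alignments (GAF): node
coverage as aligned bases per node bp, projected from each alignment's
path-coordinate interval; edge coverage as direct i→j or j→i path
traversals. Both are floored at 1.0 — the node floor absorbs alignment
error on near-absent nodes and the edge floor keeps log ratios finite
for untraversed edges — then divided by the sample's depth multiplier
bp_n/m (m = series median of bp_n). Log fold change (LFC) between
consecutive samples is taken base 2, so the tandem-duplication threshold
of 1 corresponds to a doubling, the copy-number signature of one extra
tandem copy. The normalization's purpose is depth correction, hence the
division; a `direction="multiply"` switch preserves the literal
multiply-by-the-multiplier reading.

## Calling rules and numerical choices

Outliers within a motif are values deviating from the motif *median* by
more than one population standard deviation (taken about the arithmetic
mean; both the multiple and the definition are configurable). The median
reference keeps a single extreme value — the variant itself — from
dragging the reference toward itself.

Decisions that were genuinely open and how they were fixed:

* **Square adjacency.** When a square has two opposite-signed outliers,
  "no edge between them" is judged against the full graph's edge set by
  default (a chord outside the cycle disqualifies the pair);
  `adjacency="cycle"` restricts the check to the cycle's own edges.
* **Squares with chords** remain squares: cycle enumeration requires
  distinct vertices, not chordlessness. A 4-cycle cannot reuse a
  multi-edge pair; the weight ≥ 2 case belongs exclusively to the
  tandem-duplication rule.
* **Call ordering and suppression.** Indels, then complex indels, then
  tandem duplications; only TDs are suppressed (against every earlier
  call at that step and earlier TDs). Indel and CI calls on the same
  node coexist by design — both countings are exposed, raw and unique
  (node, type) pairs per step.
* **Declining duplicates.** The rising rule (edge LFC > 1) is mirrored
  at < −1 to call TD-d, flag-guarded (`enable_td_d`), since duplicates
  can also wash out of a community.
* **Ties** (equal node LFC at both heavy-edge endpoints) break to the
  lexicographically smaller node id, for determinism.
* **Degenerate motifs:** a motif whose values are all equal has std 0
  and deviation 0; the strict `>` comparison yields no outlier, hence
  no call. Isolated and degree-1 nodes can never be called.

Triangle and square detection uses networkx `simple_cycles` with a
length bound of 4; an independent brute-force subset enumeration backs
it in the test suite.

Evaluation against a planted truth table matches by node identity, step
and type class; by default an insertion called as the rising half of a
complex indel (or vice versa) counts as correct, `strict` mode requires
the exact label. Precision uses unique (node, type, step) calls so one
sequence called through many motifs is not over-counted.

## Synthetic scenarios

The generator emulates, at graph level, a community in which planted
variants rise or fall monotonically across the series: a backbone chain
of segments (random ACGT, lengths uniform in 2000–4000 bp) at flat 20×
coverage, plus per planted SV the motif its type produces — INS/DEL
triangles on consecutive backbone pairs, chordless CI squares on
backbone pairs two apart (one rising, one falling corner), and TDs as
either a self-loop node or a weight-2 double edge, alternating rising
(TD-i) and falling (TD-d) trajectories. Variant coverage follows a
geometric trajectory centered on the mean coverage (5×→20×→80× for fold
change 4 over three samples), so every consecutive step is an event and
the truth table lists each motif at every step. Motif regions are
node-disjoint along the backbone; placement order is randomized.

Emitted GAF reads realize the plan exactly in `exact` mode (whole-node
or whole-path reads, integer counts — coverage values are integers by
construction) or with Poisson-drawn counts in `poisson` mode, where
single-node reads become 500 bp windows at uniform offsets. The window
length makes per-node coverage noise realistic for long reads over
multi-kb nodes (~120 reads per backbone node at 20×), while junction
traversal counts stay at the coverage scale (~5–80 per loop), which is
the binding noise source for TD recall. Defaults (50 backbone nodes, 5
motifs per type, N = 3, 20×, fold 4) keep a full scenario plus pipeline
run under a second.

What passing on these fixtures does **not** show about real data: no
read errors or chimeras, no mis-assembly motifs, no strain mixtures
sharing variant nodes, no ambiguity in graph alignment, and abundance
shifts only through the global depth multiplier. Recovery rates on real
communities are bounded above by assembly and alignment quality —
variants absent from the co-assembly graph, or resolved into long nodes
rather than motifs, are invisible to the method by construction.

## Problem sizes

The default test and acceptance runs use the default scenario scale
(≈70 nodes, ≈20k reads across three samples) and 20 Poisson replicates;
motif-enumeration oracle checks run on 200 random graphs of ≤ 12 nodes
at edge probability 0.3. These sizes exercise every rule and invariant
while keeping a full suite run in seconds.

## Known limitations

Inversions and translocations are out of scope (they need orientation-
aware motifs; orientations are parsed and preserved for that future
use). Motifs longer than four nodes, breakpoint base-pair resolution,
and GC/mappability bias correction are not attempted. bp_n counts all
reads in a sample's input (aligned or not); with highly variable
alignment rates a user may prefer to supply aligned-bp totals via
`--bp-table`.
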