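"""Readers and writers for the formats the caller speaks.

Input: GFA 1.x co-assembly graphs (S/L lines, metaFlye dialect) and GAF
graph alignments (minigraph dialect, columns 1-12).  Output: a TSV call
table, a FASTA of called node sequences, and Bandage-loadable per-step
colour CSVs encoding log fold change.

GAF coordinates are 0-based half-open per the GAF standard.  Orientations
are preserved on parse even though the downstream graph is undirected.
"""

from __future__ import annotations

import io
import logging
import os
import re
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping, Sequence, Union

logger = logging.getLogger(__name__)

ORIENTATIONS = ("+", "-")

Source = Union[str, os.PathLike, IO[str], Iterable[str]]


class GraphFormatError(ValueError):
    """Raised for malformed GFA/GAF content; message names the line number."""


@dataclass(frozen=True)
class SegmentRecord:
    """One GFA segment: a sequence node of the assembly graph."""

    seg_id: str
    sequence: str | None
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise GraphFormatError(f"segment {self.seg_id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise GraphFormatError(f"segment {self.seg_id}: length != len(sequence)")


@dataclass(frozen=True)
class LinkRecord:
    """One GFA link: an oriented adjacency between two segments."""

    from_seg: str
    from_orient: str
    to_seg: str
    to_orient: str


@dataclass(frozen=True)
class AlignmentRecord:
    """One GAF record: a read's path through oriented graph segments."""

    read_id: str
    read_length: int
    path: tuple[tuple[str, str], ...]
    path_length: int
    path_start: int
    path_end: int
    mapq: int

    def __post_init__(self) -> None:
        if not self.path:
            raise GraphFormatError(f"read {self.read_id}: empty path")
        if not (0 <= self.path_start < self.path_end <= self.path_length):
            raise GraphFormatError(
                f"read {self.read_id}: bad path offsets "
                f"[{self.path_start},{self.path_end}) on length {self.path_length}"
            )


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt") as fh:
            yield from fh
    else:
        yield from source


def parse_gfa(source: Source) -> tuple[list[SegmentRecord], list[LinkRecord]]:
    """Parse a GFA 1.x stream into segment and link records.

    S lines may carry an explicit sequence or ``*`` plus an ``LN:i`` tag.
    Unknown line types (H, P, W, comments, ...) are skipped and counted.
    Links referencing unknown segments raise :class:`GraphFormatError`.
    """
    segments: list[SegmentRecord] = []
    links: list[LinkRecord] = []
    pending: list[tuple[int, LinkRecord]] = []
    seen: set[str] = set()
    skipped: Counter[str] = Counter()

    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        kind = line.split("\t", 1)[0]
        if kind == "S":
            fields = line.split("\t")
            if len(fields) < 3:
                raise GraphFormatError(f"GFA line {lineno}: S line needs >= 3 columns")
            seg_id, seq = fields[1], fields[2]
            if seg_id in seen:
                raise GraphFormatError(f"GFA line {lineno}: duplicate segment {seg_id!r}")
            seen.add(seg_id)
            if seq == "*":
                length = None
                for tag in fields[3:]:
                    if tag.startswith("LN:i:"):
                        length = int(tag[5:])
                if length is None:
                    raise GraphFormatError(
                        f"GFA line {lineno}: segment {seg_id!r} has no sequence and no LN tag"
                    )
                segments.append(SegmentRecord(seg_id, None, length))
            else:
                segments.append(SegmentRecord(seg_id, seq.upper(), len(seq)))
        elif kind == "L":
            fields = line.split("\t")
            if len(fields) < 5:
                raise GraphFormatError(f"GFA line {lineno}: L line needs >= 5 columns")
            a, oa, b, ob = fields[1], fields[2], fields[3], fields[4]
            if oa not in ORIENTATIONS or ob not in ORIENTATIONS:
                raise GraphFormatError(f"GFA line {lineno}: bad orientation {oa!r}/{ob!r}")
            pending.append((lineno, LinkRecord(a, oa, b, ob)))
        else:
            skipped[kind if kind else "?"] += 1

    for lineno, link in pending:
        for seg in (link.from_seg, link.to_seg):
            if seg not in seen:
                raise GraphFormatError(
                    f"GFA line {lineno}: link references unknown segment {seg!r}"
                )
        links.append(link)

    if skipped:
        logger.info("parse_gfa: skipped line types %s", dict(skipped))
    return segments, links


_PATH_RE = re.compile(r"([><])([^><\s]+)")


def parse_gaf(source: Source, min_mapq: int = 0) -> list[AlignmentRecord]:
    """Parse a GAF stream (columns 1-12) into alignment records.

    Records with mapq below ``min_mapq`` are dropped and counted; the
    default threshold 0 keeps everything.  cg/CIGAR tags beyond column 12
    are ignored: coverage is computed from path offsets alone.
    """
    records: list[AlignmentRecord] = []
    dropped = 0
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise GraphFormatError(f"GAF line {lineno}: needs >= 12 columns, got {len(fields)}")
        path_col = fields[5]
        steps = _PATH_RE.findall(path_col)
        if not steps or "".join(o + s for o, s in steps) != path_col:
            raise GraphFormatError(f"GAF line {lineno}: unparseable path {path_col!r}")
        path = tuple((seg, "+" if o == ">" else "-") for o, seg in steps)
        try:
            rec = AlignmentRecord(
                read_id=fields[0],
                read_length=int(fields[1]),
                path=path,
                path_length=int(fields[6]),
                path_start=int(fields[7]),
                path_end=int(fields[8]),
                mapq=int(fields[11]),
            )
        except ValueError as exc:
            raise GraphFormatError(f"GAF line {lineno}: {exc}") from exc
        if rec.mapq < min_mapq:
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.info("parse_gaf: dropped %d records below mapq %d", dropped, min_mapq)
    return records


# ---------------------------------------------------------------------------
# writers — all deterministic given identical inputs


def _step_label(step: int) -> str:
    return f"C{step}"


def write_sv_table(calls: Sequence, out: IO[str] | None = None) -> str:
    """Serialize SV calls as a TSV, one row per call.

    Rows are ordered by (step, sv_type, node) so identical call lists
    serialize byte-identically.
    """
    buf = io.StringIO()
    buf.write("step\tsv_type\tnode\tmotif_nodes\tnode_lfc\tmotif_median\tmotif_std\n")
    for c in sorted(calls, key=lambda c: (c.step, c.sv_type, c.node, c.motif)):
        buf.write(
            f"{_step_label(c.step)}\t{c.sv_type}\t{c.node}\t{','.join(c.motif)}\t"
            f"{c.node_lfc:.4f}\t{c.motif_median:.4f}\t{c.motif_std:.4f}\n"
        )
    text = buf.getvalue()
    if out is not None:
        out.write(text)
    return text


def write_sv_fasta(
    calls: Sequence, sequences: Mapping[str, str | None], out: IO[str] | None = None
) -> str:
    """Write one FASTA record per unique (node, type, step) call.

    The sequence is the called node's segment sequence verbatim; nodes
    whose segment carried ``*`` are skipped with a warning.
    """
    buf = io.StringIO()
    uniq = sorted({(c.step, c.sv_type, c.node) for c in calls})
    for step, sv_type, node in uniq:
        seq = sequences.get(node)
        if not seq:
            logger.warning("write_sv_fasta: node %s has no sequence; record skipped", node)
            continue
        buf.write(f">{node}|{sv_type}|{_step_label(step)}\n")
        for i in range(0, len(seq), 60):
            buf.write(seq[i : i + 60] + "\n")
    text = buf.getvalue()
    if out is not None:
        out.write(text)
    return text


def lfc_colour(value: float, limit: float = 2.0) -> str:
    """Diverging RGB hex for a log fold change: blue (<= -limit) via white (0) to red (>= +limit)."""
    x = max(-1.0, min(1.0, value / limit))
    if x >= 0:
        r, g, b = 255, round(255 * (1 - x)), round(255 * (1 - x))
    else:
        r, g, b = round(255 * (1 + x)), round(255 * (1 + x)), 255
    return f"#{r:02x}{g:02x}{b:02x}"


def write_bandage_csv(lfc, step: int, limit: float = 2.0, out: IO[str] | None = None) -> str:
    """Bandage-compatible node colour CSV for one series step.

    ``lfc`` is either an ``LfcSeries`` (its ``node_lfc`` column for the
    step is used) or a mapping node -> LFC value.  Header follows the
    Bandage ``Name,Colour`` convention so the file loads directly.
    """
    if hasattr(lfc, "node_lfc"):
        col = lfc.node_lfc[_step_label(step)]
        values = {str(k): float(v) for k, v in col.items()}
    else:
        values = {str(k): float(v) for k, v in lfc.items()}
    buf = io.StringIO()
    buf.write("Name,Colour,LFC\n")
    for node in sorted(values):
        v = values[node]
        buf.write(f"{node},{lfc_colour(v, limit)},{v:.4f}\n")
    text = buf.getvalue()
    if out is not None:
        out.write(text)
    return text
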