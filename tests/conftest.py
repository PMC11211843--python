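"""Shared fixtures: tiny hand-built graphs and alignment streams."""

import io

import pytest

from graphsv import build_graph, parse_gaf, parse_gfa


TRIANGLE_GFA = (
    "S\ta\t" + "A" * 100 + "\n"
    "S\tb\t" + "C" * 100 + "\n"
    "S\tc\t" + "G" * 100 + "\n"
    "L\ta\t+\tb\t+\t0M\n"
    "L\tb\t+\tc\t+\t0M\n"
    "L\tc\t+\ta\t+\t0M\n"
)


def gaf_line(read_id, path, plen, start, end, mapq=60, qlen=None):
    qlen = end - start if qlen is None else qlen
    return f"{read_id}\t{qlen}\t0\t{qlen}\t+\t{path}\t{plen}\t{start}\t{end}\t{end-start}\t{end-start}\t{mapq}\n"


@pytest.fixture
def triangle_records():
    return parse_gfa(io.StringIO(TRIANGLE_GFA))


@pytest.fixture
def triangle_graph(triangle_records):
    segments, links = triangle_records
    return build_graph(segments, links)


def parse_gaf_text(text, **kw):
    return parse_gaf(io.StringIO(text), **kw)


def parse_gfa_text(text):
    return parse_gfa(io.StringIO(text))
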