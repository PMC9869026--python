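"""Assembly-graph topology triage.

HiFi metagenome assembly graphs resolve most community members into one of
three shapes: a single self-linked segment (a complete circular replicon),
a multi-segment tangle (typically a strain mixture forming a big circular
or otherwise complex structure), or an isolated linear contig. This module
parses GFA1, classifies connected components into those three types,
extracts circular contigs (trimming the duplicated head/tail overlap),
emits tangle members for external re-assembly, and produces the linear
contig set that feeds binning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import networkx as nx

log = logging.getLogger(__name__)

TOPOLOGIES = ("circular", "tangled_circular", "linear")


@dataclass
class AssemblyGraph:
    segments: dict[str, str]  # id -> sequence
    links: list[tuple[str, str, str, str, str]]  # a, ao, b, bo, cigar
    depth: dict[str, float] = field(default_factory=dict)

    def length(self, seg: str) -> int:
        return len(self.segments[seg])


@dataclass(frozen=True)
class ComponentCall:
    component_id: str
    members: tuple[str, ...]
    topology: str
    total_bp: int
    has_cycle: bool


def parse_gfa(path: str | os.PathLike) -> AssemblyGraph:
    """Parse GFA1 S/L records; other record types are ignored with a
    warning. A link referencing a missing segment is a format error."""
    segments: dict[str, str] = {}
    depth: dict[str, float] = {}
    links: list[tuple[str, str, str, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise ValueError(f"line {lineno}: malformed S record")
                name, seq = fields[1], fields[2]
                segments[name] = seq.upper()
                for opt in fields[3:]:
                    if opt.startswith(("dp:f:", "DP:f:")):
                        depth[name] = float(opt.split(":")[2])
            elif tag == "L":
                if len(fields) < 6:
                    raise ValueError(f"line {lineno}: malformed L record")
                links.append(
                    (fields[1], fields[2], fields[3], fields[4], fields[5])
                )
            elif tag == "H":
                continue
            else:
                log.warning("ignoring GFA record type %r at line %d", tag,
                            lineno)
    for a, _, b, _, _ in links:
        for seg in (a, b):
            if seg not in segments:
                raise ValueError(
                    f"L record references unknown segment {seg!r}"
                )
    return AssemblyGraph(segments, links, depth)


def _is_circularising_self_link(ao: str, bo: str) -> bool:
    # (s,+,s,+) and (s,-,s,-) join head to tail; (s,+,s,-) is palindromic
    return ao == bo


def classify_components(graph: AssemblyGraph) -> list[ComponentCall]:
    """Partition segments into connected components and call topology.

    Single self-linked segment -> circular; any multi-segment component
    (cyclic or not) -> tangled_circular, with ``has_cycle`` recorded;
    isolated segment -> linear. A single segment whose only self-link is
    palindromic ((s,+,s,-)) is not circular and is forced to
    tangled_circular.
    """
    g = nx.MultiGraph()
    g.add_nodes_from(graph.segments)
    for a, ao, b, bo, _ in graph.links:
        g.add_edge(a, b, ao=ao, bo=bo)
    calls: list[ComponentCall] = []
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: c[0],
    )
    for i, members in enumerate(comps):
        total = sum(graph.length(m) for m in members)
        sub = g.subgraph(members)
        # a connected (multi)graph has a cycle iff edges >= nodes
        has_cycle = sub.number_of_edges() >= len(members)
        if len(members) == 1:
            s = members[0]
            self_links = [
                (ao, bo)
                for a, ao, b, bo, _ in graph.links
                if a == s and b == s
            ]
            if any(_is_circularising_self_link(ao, bo)
                   for ao, bo in self_links):
                topo = "circular"
            elif self_links:
                topo = "tangled_circular"
            else:
                topo = "linear"
        else:
            topo = "tangled_circular"
        calls.append(
            ComponentCall(f"comp{i:04d}", tuple(members), topo, total,
                          bool(has_cycle))
        )
    return calls


def _self_link_overlap(graph: AssemblyGraph, seg: str) -> int:
    """Overlap length (bases) of the circularising self-link of ``seg``."""
    for a, ao, b, bo, cigar in graph.links:
        if a == seg and b == seg and _is_circularising_self_link(ao, bo):
            cigar = cigar.strip()
            if cigar in ("*", "0M", ""):
                return 0
            if cigar.endswith("M") and cigar[:-1].isdigit():
                return int(cigar[:-1])
            raise ValueError(
                f"unsupported overlap CIGAR {cigar!r} on segment {seg}"
            )
    return 0


def extract_circular(
    graph: AssemblyGraph,
    calls: list[ComponentCall],
    min_length_bp: int = 0,
) -> list[tuple[str, str]]:
    """Circular contigs >= ``min_length_bp``, overlap-trimmed.

    The duplicated head/tail overlap recorded in the self-link's
    match-length CIGAR is removed, so the emitted sequence is exactly one
    traversal of the circle.
    """
    out = []
    for call in calls:
        if call.topology != "circular":
            continue
        seg = call.members[0]
        ov = _self_link_overlap(graph, seg)
        seq = graph.segments[seg]
        if ov:
            seq = seq[:-ov]
        if len(seq) >= min_length_bp:
            out.append((seg, seq))
    return out


def members_for_reassembly(
    graph: AssemblyGraph, calls: list[ComponentCall], component_id: str
) -> list[tuple[str, str]]:
    """Member sequences of a tangled component, for external re-assembly."""
    call = next((c for c in calls if c.component_id == component_id), None)
    if call is None:
        raise ValueError(f"no component {component_id!r}")
    if call.topology != "tangled_circular":
        raise ValueError(
            f"component {component_id} is {call.topology}, not tangled"
        )
    return [(m, graph.segments[m]) for m in call.members]


def prebinning_filter(
    graph: AssemblyGraph,
    calls: list[ComponentCall],
    min_contig_bp: int = 2000,
) -> list[tuple[str, str]]:
    """Linear contigs >= ``min_contig_bp``: the binning input set, with all
    circular and tangled components removed."""
    out = []
    for call in calls:
        if call.topology != "linear":
            continue
        seg = call.members[0]
        if graph.length(seg) >= min_contig_bp:
            out.append((seg, graph.segments[seg]))
    return out


def component_table(calls: list[ComponentCall]) -> str:
    lines = ["component_id\ttopology\thas_cycle\tn_segments\ttotal_bp"]
    for c in calls:
        lines.append(
            f"{c.component_id}\t{c.topology}\t{int(c.has_cycle)}\t"
            f"{len(c.members)}\t{c.total_bp}"
        )
    return "\n".join(lines) + "\n"
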