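"""Variation-graph data model and GFA1 reading/writing.

A variation graph is a sequence graph whose nodes carry nucleotide
sequences, whose edges connect oriented node ends, and whose paths embed
genomes as walks over oriented nodes.  The layout algorithms in this
package use the paths as a positional system, so graphs are expected to
carry at least one path (enforced where it matters, not here).

Coordinates within sequences are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GFAError",
    "GraphError",
    "Handle",
    "Edge",
    "Node",
    "Path",
    "VariationGraph",
    "reverse_complement",
    "parse_gfa",
    "write_gfa",
    "apply_node_order",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")
# rGFA-specific tags on S lines; their presence marks a dialect we reject.
_RGFA_TAGS = ("SN:Z:", "SO:i:", "SR:i:")


class GFAError(ValueError):
    """Malformed or unsupported GFA input."""


class GraphError(ValueError):
    """Structurally invalid variation graph."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Handle:
    """An oriented reference to a node: (node id, strand)."""

    node_id: int
    is_reverse: bool = False

    def flip(self) -> "Handle":
        return Handle(self.node_id, not self.is_reverse)

    def __str__(self) -> str:
        return f"{self.node_id}{'-' if self.is_reverse else '+'}"


@dataclass(frozen=True)
class Edge:
    """A directed link between two oriented node ends.

    The symmetric traversal (flip of both handles, in reverse order) is
    implicit and never stored.
    """

    src: Handle
    dst: Handle

    def key(self) -> tuple[int, bool, int, bool]:
        return (self.src.node_id, self.src.is_reverse, self.dst.node_id, self.dst.is_reverse)


@dataclass
class Node:
    """A graph node holding a non-empty nucleotide sequence."""

    id: int
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Path:
    """A named walk through the graph, as an ordered series of steps.

    Each step is a :class:`Handle`; consecutive steps must be connected
    by a (possibly implicitly reversed) edge.
    """

    name: str
    steps: list[Handle] = field(default_factory=list)


class VariationGraph:
    """Nodes with sequences, oriented edges, and embedded paths."""

    def __init__(
        self,
        nodes: Iterable[Node],
        edges: Iterable[Edge] = (),
        paths: Iterable[Path] = (),
        validate: bool = True,
    ) -> None:
        self.nodes: dict[int, Node] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise GraphError(f"duplicate node id {node.id}")
            self.nodes[node.id] = node
        self.edges: list[Edge] = list(edges)
        self.paths: list[Path] = list(paths)
        self._adjacency: frozenset[tuple[int, bool, int, bool]] | None = None
        if validate:
            self.validate()

    # -- basic accessors -------------------------------------------------

    @property
    def node_ids(self) -> list[int]:
        """Node ids in graph (insertion) order."""
        return list(self.nodes.keys())

    def node_length(self, node_id: int) -> int:
        return len(self.nodes[node_id].sequence)

    def total_sequence_length(self) -> int:
        return sum(len(n.sequence) for n in self.nodes.values())

    def path_by_name(self, name: str) -> Path:
        for p in self.paths:
            if p.name == name:
                return p
        raise GraphError(f"unknown path {name!r}")

    def step_sequence(self, step: Handle) -> str:
        seq = self.nodes[step.node_id].sequence
        return reverse_complement(seq) if step.is_reverse else seq

    def path_sequence(self, path: Path) -> str:
        """Concatenated nucleotides obtained by walking the path."""
        return "".join(self.step_sequence(s) for s in path.steps)

    # -- adjacency -------------------------------------------------------

    def _edge_keys(self) -> frozenset[tuple[int, bool, int, bool]]:
        if self._adjacency is None:
            self._adjacency = frozenset(e.key() for e in self.edges)
        return self._adjacency

    def has_edge(self, a: Handle, b: Handle) -> bool:
        """True if (a -> b) is an edge, stored directly or as the
        implicit reverse traversal (b̄ -> ā)."""
        keys = self._edge_keys()
        if (a.node_id, a.is_reverse, b.node_id, b.is_reverse) in keys:
            return True
        return (b.node_id, not b.is_reverse, a.node_id, not a.is_reverse) in keys

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for node in self.nodes.values():
            if node.id < 1:
                raise GraphError(f"node id {node.id} is not a positive integer")
            if not node.sequence:
                raise GraphError(f"node {node.id} has an empty sequence")
            bad = set(node.sequence) - _VALID_BASES
            if bad:
                raise GraphError(
                    f"node {node.id} sequence contains invalid characters {sorted(bad)}"
                )
        seen_edges: set[tuple[int, bool, int, bool]] = set()
        for edge in self.edges:
            for handle in (edge.src, edge.dst):
                if handle.node_id not in self.nodes:
                    raise GraphError(f"edge {edge} references unknown node {handle.node_id}")
            if edge.key() in seen_edges:
                raise GraphError(f"duplicate edge {edge.src}->{edge.dst}")
            seen_edges.add(edge.key())
        seen_names: set[str] = set()
        for path in self.paths:
            if path.name in seen_names:
                raise GraphError(f"duplicate path name {path.name!r}")
            seen_names.add(path.name)
            if not path.steps:
                raise GraphError(f"path {path.name!r} has no steps")
            for step in path.steps:
                if step.node_id not in self.nodes:
                    raise GraphError(
                        f"path {path.name!r} references unknown node {step.node_id}"
                    )
            for a, b in zip(path.steps, path.steps[1:]):
                if not self.has_edge(a, b):
                    raise GraphError(
                        f"path {path.name!r}: consecutive steps {a} -> {b} "
                        "are not connected by an edge"
                    )

    # -- equality (order-insensitive on edges) ---------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariationGraph):
            return NotImplemented
        if list(self.nodes) != list(other.nodes):
            return False
        for nid in self.nodes:
            if self.nodes[nid].sequence != other.nodes[nid].sequence:
                return False
        if sorted(e.key() for e in self.edges) != sorted(e.key() for e in other.edges):
            return False
        if len(self.paths) != len(other.paths):
            return False
        for pa, pb in zip(self.paths, other.paths):
            if pa.name != pb.name or pa.steps != pb.steps:
                return False
        return True


# -- GFA1 parsing --------------------------------------------------------


def _split_fields(line: str) -> list[str]:
    # GFA is tab-separated; tolerate space-separated test snippets.
    return line.split("\t") if "\t" in line else line.split()


def _parse_handle(token: str, lineno: int, context: str) -> Handle:
    if len(token) < 2 or token[-1] not in "+-":
        raise GFAError(f"line {lineno}: malformed oriented segment {token!r} in {context}")
    name = token[:-1]
    try:
        node_id = int(name)
    except ValueError:
        raise GFAError(
            f"line {lineno}: segment name {name!r} is not an integer id"
        ) from None
    return Handle(node_id, token[-1] == "-")


def parse_gfa(text: str) -> VariationGraph:
    """Parse a GFA1 document (S/L/P records) into a :class:`VariationGraph`.

    H lines and unknown record types are ignored; W lines and rGFA tags
    are rejected.  Link/path overlaps other than ``0M``/``*`` are rejected.
    """
    nodes: dict[int, Node] = {}
    raw_edges: list[tuple[int, Handle, Handle]] = []
    raw_paths: list[tuple[int, str, list[Handle]]] = []

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        rec = line[0]
        if rec == "H":
            continue
        if rec == "W":
            raise GFAError(f"line {lineno}: W lines (GFA1.1 walks) are not supported")
        fields = _split_fields(line)
        if rec == "S":
            if len(fields) < 3:
                raise GFAError(f"line {lineno}: S line needs a name and a sequence")
            name, seq = fields[1], fields[2]
            for tag in fields[3:]:
                if tag.startswith(_RGFA_TAGS):
                    raise GFAError(
                        f"line {lineno}: rGFA tag {tag.split(':')[0]} is not supported"
                    )
            try:
                node_id = int(name)
            except ValueError:
                raise GFAError(
                    f"line {lineno}: segment name {name!r} is not an integer id"
                ) from None
            if node_id in nodes:
                raise GFAError(f"line {lineno}: duplicate segment name {name}")
            if not seq or seq == "*":
                raise GFAError(f"line {lineno}: segment {name} has an empty sequence")
            nodes[node_id] = Node(node_id, seq.upper())
        elif rec == "L":
            if len(fields) < 5:
                raise GFAError(f"line {lineno}: L line needs from/to segments and strands")
            src = _parse_handle(fields[1] + fields[2], lineno, "L line")
            dst = _parse_handle(fields[3] + fields[4], lineno, "L line")
            overlap = fields[5] if len(fields) > 5 else "*"
            if overlap not in ("0M", "*"):
                raise GFAError(
                    f"line {lineno}: only 0M/* link overlaps are supported, got {overlap!r}"
                )
            raw_edges.append((lineno, src, dst))
        elif rec == "P":
            if len(fields) < 3:
                raise GFAError(f"line {lineno}: P line needs a name and a step list")
            name = fields[1]
            steps = [
                _parse_handle(tok, lineno, f"path {name!r}")
                for tok in fields[2].split(",")
                if tok
            ]
            if not steps:
                raise GFAError(f"line {lineno}: path {name!r} has no steps")
            if len(fields) > 3 and fields[3] not in ("*", ""):
                for ov in fields[3].split(","):
                    if ov not in ("0M", "*"):
                        raise GFAError(
                            f"line {lineno}: only 0M/* path overlaps are supported, "
                            f"got {ov!r}"
                        )
            raw_paths.append((lineno, name, steps))
        # other record types are silently ignored

    if not nodes:
        raise GFAError("document contains no S lines")

    edges: list[Edge] = []
    for lineno, src, dst in raw_edges:
        for handle in (src, dst):
            if handle.node_id not in nodes:
                raise GFAError(
                    f"line {lineno}: L line references unknown segment {handle.node_id}"
                )
        edges.append(Edge(src, dst))

    paths: list[Path] = []
    for lineno, name, steps in raw_paths:
        for step in steps:
            if step.node_id not in nodes:
                raise GFAError(
                    f"line {lineno}: path {name!r} references unknown segment "
                    f"{step.node_id}"
                )
        paths.append(Path(name, steps))

    try:
        return VariationGraph(nodes.values(), edges, paths)
    except GraphError as exc:
        raise GFAError(str(exc)) from exc


# -- GFA1 writing --------------------------------------------------------


def write_gfa(graph: VariationGraph) -> str:
    """Emit a canonical GFA1 document.

    Record order is deterministic: one H line, S lines by node id, L
    lines in lexicographic (src id, src strand, dst id, dst strand)
    order, P lines in path insertion order.  Link overlaps are written
    as ``0M`` and path overlaps as ``*``, so ``parse(write(g))`` equals
    ``g`` and writing is idempotent on canonical documents.
    """
    out = ["H\tVN:Z:1.0"]
    for nid in sorted(graph.nodes):
        out.append(f"S\t{nid}\t{graph.nodes[nid].sequence}")
    for edge in sorted(graph.edges, key=Edge.key):
        s, d = edge.src, edge.dst
        out.append(
            "L\t{}\t{}\t{}\t{}\t0M".format(
                s.node_id, "-" if s.is_reverse else "+", d.node_id, "-" if d.is_reverse else "+"
            )
        )
    for path in graph.paths:
        out.append("P\t{}\t{}\t*".format(path.name, ",".join(map(str, path.steps))))
    return "\n".join(out) + "\n"


# -- node reordering -----------------------------------------------------


def apply_node_order(graph: VariationGraph, order: Sequence[int]) -> VariationGraph:
    """Renumber nodes 1..N by their rank in ``order``.

    ``order`` must be a permutation of the graph's node ids.  Edges and
    path steps are rewritten consistently; sequences and per-path
    nucleotide content are unchanged.
    """
    if sorted(order) != sorted(graph.nodes):
        raise GraphError("order is not a permutation of the graph's node ids")
    remap = {old: rank + 1 for rank, old in enumerate(order)}
    nodes = [Node(remap[old], graph.nodes[old].sequence) for old in order]
    edges = [
        Edge(
            Handle(remap[e.src.node_id], e.src.is_reverse),
            Handle(remap[e.dst.node_id], e.dst.is_reverse),
        )
        for e in graph.edges
    ]
    paths = [
        Path(p.name, [Handle(remap[s.node_id], s.is_reverse) for s in p.steps])
        for p in graph.paths
    ]
    return VariationGraph(nodes, edges, paths)
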