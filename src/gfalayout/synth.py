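"""Seeded synthetic variation graphs for tests, demos, and benchmarks.

Every generator returns a validated :class:`VariationGraph` and is
bit-deterministic under a fixed seed.  Sequence composition is uniform
ACGT — only lengths matter to the layout.
"""

from __future__ import annotations

import numpy as np

from .graph import Edge, GraphError, Handle, Node, Path, VariationGraph, apply_node_order

__all__ = [
    "random_sequence",
    "make_linear",
    "make_snp_bubbles",
    "make_indel_bubbles",
    "make_inversion",
    "make_tandem_loop",
    "shuffle_ids",
    "make_graph",
]

_BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _lengths(rng: np.random.Generator, n: int, node_len: int | tuple[int, int]) -> list[int]:
    if isinstance(node_len, int):
        return [node_len] * n
    lo, hi = node_len
    return [int(v) for v in rng.integers(lo, hi + 1, size=n)]


def make_linear(
    n_nodes: int, node_len: int | tuple[int, int] = (4, 12), seed: int = 0
) -> VariationGraph:
    """Chain of forward-linked nodes with one path traversing all."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = [
        Node(i + 1, random_sequence(rng, ln))
        for i, ln in enumerate(_lengths(rng, n_nodes, node_len))
    ]
    edges = [Edge(Handle(i), Handle(i + 1)) for i in range(1, n_nodes)]
    path = Path("ref", [Handle(i) for i in range(1, n_nodes + 1)])
    return VariationGraph(nodes, edges, [path])


def make_snp_bubbles(
    n_anchors: int,
    bubble_rate: float = 0.5,
    n_paths: int = 2,
    node_len: int | tuple[int, int] = (4, 12),
    seed: int = 0,
) -> VariationGraph:
    """Anchor chain with biallelic single-node detours.

    Between consecutive anchors, with probability ``bubble_rate``, two
    alternative allele nodes are inserted (each bubble: 2 nodes, 4
    edges).  Each path picks one allele per bubble.
    """
    if n_anchors < 2:
        raise ValueError("n_anchors must be >= 2")
    rng = np.random.default_rng(seed)
    nodes: list[Node] = []
    edges: list[Edge] = []
    next_id = 1

    def new_node(length: int) -> int:
        nonlocal next_id
        nodes.append(Node(next_id, random_sequence(rng, length)))
        next_id += 1
        return next_id - 1

    anchor_lens = _lengths(rng, n_anchors, node_len)
    anchors = [new_node(anchor_lens[i]) for i in range(n_anchors)]
    # segments[i] is what sits between anchor i and anchor i+1
    bubbles: list[tuple[int, int] | None] = []
    for i in range(n_anchors - 1):
        if rng.random() < bubble_rate:
            alen = int(rng.integers(1, 4))
            blen = int(rng.integers(1, 4))
            a, b = new_node(alen), new_node(blen)
            bubbles.append((a, b))
            for alt in (a, b):
                edges.append(Edge(Handle(anchors[i]), Handle(alt)))
                edges.append(Edge(Handle(alt), Handle(anchors[i + 1])))
        else:
            bubbles.append(None)
            edges.append(Edge(Handle(anchors[i]), Handle(anchors[i + 1])))

    paths: list[Path] = []
    for p in range(n_paths):
        steps = [Handle(anchors[0])]
        for i in range(n_anchors - 1):
            bub = bubbles[i]
            if bub is not None:
                steps.append(Handle(bub[int(rng.integers(2))]))
            steps.append(Handle(anchors[i + 1]))
        paths.append(Path(f"hap{p + 1}", steps))
    return VariationGraph(nodes, edges, paths)


def make_indel_bubbles(
    n_anchors: int,
    indel_rate: float = 0.5,
    n_paths: int = 2,
    node_len: int | tuple[int, int] = (4, 12),
    seed: int = 0,
) -> VariationGraph:
    """Anchor chain where some gaps carry an optional insertion node;
    paths either traverse the insertion or skip straight to the next
    anchor (deletion allele)."""
    if n_anchors < 2:
        raise ValueError("n_anchors must be >= 2")
    rng = np.random.default_rng(seed)
    nodes: list[Node] = []
    edges: list[Edge] = []
    next_id = 1

    def new_node(length: int) -> int:
        nonlocal next_id
        nodes.append(Node(next_id, random_sequence(rng, length)))
        next_id += 1
        return next_id - 1

    anchor_lens = _lengths(rng, n_anchors, node_len)
    anchors = [new_node(anchor_lens[i]) for i in range(n_anchors)]
    inserts: list[int | None] = []
    for i in range(n_anchors - 1):
        edges.append(Edge(Handle(anchors[i]), Handle(anchors[i + 1])))
        if rng.random() < indel_rate:
            ins = new_node(int(rng.integers(1, 6)))
            inserts.append(ins)
            edges.append(Edge(Handle(anchors[i]), Handle(ins)))
            edges.append(Edge(Handle(ins), Handle(anchors[i + 1])))
        else:
            inserts.append(None)

    paths: list[Path] = []
    for p in range(n_paths):
        steps = [Handle(anchors[0])]
        for i in range(n_anchors - 1):
            ins = inserts[i]
            if ins is not None and rng.random() < 0.5:
                steps.append(Handle(ins))
            steps.append(Handle(anchors[i + 1]))
        paths.append(Path(f"hap{p + 1}", steps))
    return VariationGraph(nodes, edges, paths)


def make_inversion(
    n_nodes: int,
    inv_span: int,
    node_len: int | tuple[int, int] = (4, 12),
    seed: int = 0,
) -> VariationGraph:
    """Linear chain whose path traverses a middle block on the reverse
    strand (the block's steps walk backwards with is_reverse=True).

    inv_span = 0 degenerates to make_linear.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if inv_span < 0 or inv_span > n_nodes:
        raise ValueError("inv_span must lie in [0, n_nodes]")
    if inv_span == 0:
        return make_linear(n_nodes, node_len, seed)
    rng = np.random.default_rng(seed)
    nodes = [
        Node(i + 1, random_sequence(rng, ln))
        for i, ln in enumerate(_lengths(rng, n_nodes, node_len))
    ]
    start = max(1, (n_nodes - inv_span) // 2 + 1)  # first inverted node id
    stop = min(n_nodes, start + inv_span - 1)  # last inverted node id

    steps: list[Handle] = []
    for i in range(1, start):
        steps.append(Handle(i))
    for i in range(stop, start - 1, -1):
        steps.append(Handle(i, True))
    for i in range(stop + 1, n_nodes + 1):
        steps.append(Handle(i))

    edges = [Edge(a, b) for a, b in zip(steps, steps[1:])]
    return VariationGraph(nodes, edges, [Path("ref", steps)])


def make_tandem_loop(
    n_nodes: int,
    n_repeats: int = 3,
    loop_span: int | None = None,
    node_len: int | tuple[int, int] = (4, 12),
    seed: int = 0,
) -> VariationGraph:
    """Linear chain with a middle block traversed ``n_repeats`` times via
    a back edge — the path revisits the block's nodes, so no exact 1D/2D
    embedding exists for n_repeats > 1."""
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = [
        Node(i + 1, random_sequence(rng, ln))
        for i, ln in enumerate(_lengths(rng, n_nodes, node_len))
    ]
    span = loop_span if loop_span is not None else max(1, n_nodes // 3)
    start = max(2, (n_nodes - span) // 2 + 1)
    stop = min(n_nodes - 1, start + span - 1)

    edges = [Edge(Handle(i), Handle(i + 1)) for i in range(1, n_nodes)]
    if n_repeats > 1:
        edges.append(Edge(Handle(stop), Handle(start)))

    steps = [Handle(i) for i in range(1, start)]
    for _ in range(n_repeats):
        steps.extend(Handle(i) for i in range(start, stop + 1))
    steps.extend(Handle(i) for i in range(stop + 1, n_nodes + 1))
    return VariationGraph(nodes, edges, [Path("ref", steps)])


def shuffle_ids(graph: VariationGraph, seed: int = 0) -> VariationGraph:
    """Renumber nodes by a seeded random permutation (unsorted input for
    the 1D sorter)."""
    rng = np.random.default_rng(seed)
    ids = graph.node_ids
    order = [ids[i] for i in rng.permutation(len(ids))]
    return apply_node_order(graph, order)


_KINDS = {
    "linear": lambda n, seed, **kw: make_linear(n, seed=seed, **kw),
    "snp_bubbles": lambda n, seed, **kw: make_snp_bubbles(n, seed=seed, **kw),
    "indel_bubbles": lambda n, seed, **kw: make_indel_bubbles(n, seed=seed, **kw),
    "inversion": lambda n, seed, **kw: make_inversion(n, max(1, n // 3), seed=seed, **kw),
    "tandem_loop": lambda n, seed, **kw: make_tandem_loop(n, seed=seed, **kw),
}


def make_graph(kind: str, n: int, seed: int = 0, **kwargs) -> VariationGraph:
    """Dispatch by fixture kind (CLI entry point)."""
    if kind not in _KINDS:
        raise GraphError(f"unknown synthetic graph kind {kind!r}")
    return _KINDS[kind](n, seed, **kwargs)
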