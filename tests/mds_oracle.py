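"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (naive
scans, exhaustive pair enumeration, classic full-batch SGD MDS) and
never call into the package's sampling/engine internals.
"""

from __future__ import annotations

import numpy as np


def naive_step_offsets(graph, path):
    """Per-step cumulative nucleotide offsets by naive re-scan."""
    offsets = []
    total = 0
    for step in path.steps:
        offsets.append(total)
        total += len(graph.nodes[step.node_id].sequence)
    return offsets, total


def naive_end_offsets(graph, path, rank):
    """(sequence-start end, sequence-end end) path offsets of one step."""
    offsets, _ = naive_step_offsets(graph, path)
    step = path.steps[rank]
    length = len(graph.nodes[step.node_id].sequence)
    off = offsets[rank]
    if step.is_reverse:
        return off + length, off
    return off, off + length


def naive_term_nd(graph, path, rank_a, rank_b):
    """nd between two steps under the facing-ends rule, by direct scan."""
    offsets, _ = naive_step_offsets(graph, path)
    la = len(graph.nodes[path.steps[rank_a].node_id].sequence)
    lb = len(graph.nodes[path.steps[rank_b].node_id].sequence)
    if rank_a == rank_b:
        return la
    sa, ea = naive_end_offsets(graph, path, rank_a)
    sb, eb = naive_end_offsets(graph, path, rank_b)
    mid_a = offsets[rank_a] + la / 2.0
    mid_b = offsets[rank_b] + lb / 2.0
    oa = sa if abs(sa - mid_b) <= abs(ea - mid_b) else ea
    ob = sb if abs(sb - mid_a) <= abs(eb - mid_a) else eb
    return abs(oa - ob)


def all_end_points(graph, path):
    """Every node-end path offset of a single-path graph, as a flat list
    of (node_rank, which_end in {0, 1}, path_offset) triples.

    Node rank follows graph order; ends are listed for the first visit
    of each node only (matching a layout's 2 rows per node).
    """
    node_ids = list(graph.nodes)
    rank_of = {nid: i for i, nid in enumerate(node_ids)}
    offsets, _ = naive_step_offsets(graph, path)
    seen = set()
    out = []
    for r, step in enumerate(path.steps):
        if step.node_id in seen:
            continue
        seen.add(step.node_id)
        s, e = naive_end_offsets(graph, path, r)
        out.append((rank_of[step.node_id], 0, s))
        out.append((rank_of[step.node_id], 1, e))
    return out


def exhaustive_path_terms(graph):
    """All step-pair targets of a single-path graph, as (row_i, row_j, d)
    triples over layout rows (2 * node_rank + which_end).

    Enumerates every ordered step pair (a <= b), picks the facing node
    ends by direct scan, and adds each node's own two-end target once
    per visit.  This is the exhaustive counterpart of the stochastic
    term sampler, derived independently from the path walk.
    """
    path = graph.paths[0]
    node_rank = {nid: i for i, nid in enumerate(graph.nodes)}
    offs, _ = naive_step_offsets(graph, path)

    def end_row(rank, other_mid):
        step = path.steps[rank]
        length = len(graph.nodes[step.node_id].sequence)
        off = offs[rank]
        start, end = (off + length, off) if step.is_reverse else (off, off + length)
        if abs(start - other_mid) <= abs(end - other_mid):
            return 2 * node_rank[step.node_id], start
        return 2 * node_rank[step.node_id] + 1, end

    targets = []
    n = len(path.steps)
    for a in range(n):
        la = len(graph.nodes[path.steps[a].node_id].sequence)
        r = node_rank[path.steps[a].node_id]
        targets.append((2 * r, 2 * r + 1, la))
        for b in range(a + 1, n):
            lb = len(graph.nodes[path.steps[b].node_id].sequence)
            mid_a, mid_b = offs[a] + la / 2, offs[b] + lb / 2
            ia, oa = end_row(a, mid_b)
            ib, ob = end_row(b, mid_a)
            if ia != ib:
                targets.append((ia, ib, abs(oa - ob)))
    return targets


def full_batch_sgd_mds(targets, init, iter_max=60, eta_min=0.01, seed=0):
    """Classic full-batch SGD MDS on an explicit distance list.

    ``targets`` is a list of (i, j, d) triples over point indices into
    ``init`` (an (n, dims) array).  Every epoch visits all pairs in a
    shuffled order with the standard annealed, capped update:
    w = 1/max(d,1)^2, mu = min(eta*w, 1), both points moved by
    mu*(ld-d)/2 along their connecting line.
    """
    rng = np.random.default_rng(seed)
    pos = np.array(init, dtype=np.float64)
    dims = pos.shape[1]
    d_max = max(d for _, _, d in targets)
    eta_max = float(d_max) ** 2
    pairs = list(targets)
    for t in range(iter_max):
        eta = eta_max * (eta_min / eta_max) ** (t / (iter_max - 1))
        rng.shuffle(pairs)
        for i, j, d in pairs:
            delta = pos[j] - pos[i]
            ld = float(np.linalg.norm(delta))
            if ld < 1e-9:
                if dims == 1:
                    u = np.array([1.0 if rng.random() < 0.5 else -1.0])
                else:
                    ang = rng.random() * 2 * np.pi
                    u = np.array([np.cos(ang), np.sin(ang)])
            else:
                u = delta / ld
            mu = min(eta / max(d, 1.0) ** 2, 1.0)
            r = mu * (ld - d) / 2.0
            pos[i] += r * u
            pos[j] -= r * u
    return pos
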