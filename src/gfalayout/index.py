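"""Path-position index: nucleotide offsets of every path step.

Maps each step of each path to its cumulative nucleotide offset and
enumerates all steps flatly so the sampler can draw uniformly over the
whole step universe.  Stored as plain dense integer arrays; the query
contract (O(1) offset retrieval, uniform step sampling) is what the
layout algorithm depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import GraphError, VariationGraph

__all__ = [
    "StepRef",
    "PathIndex",
    "build_path_index",
    "step_offset",
    "sample_global_step",
    "step_end_offsets",
]


@dataclass(frozen=True)
class StepRef:
    """Reference to one step: (index of the path, 0-based rank within it)."""

    path_id: int
    step_rank: int


class PathIndex:
    """Dense-array index over all steps of all paths of a graph.

    Attributes
    ----------
    path_ptr : int64 array, shape (n_paths + 1,)
        Start of each path's slice in the flat step arrays (path-major,
        rank-minor enumeration).
    steps_per_path, path_lengths : int64 arrays, shape (n_paths,)
    f_off, f_len : int64 arrays, shape (total_steps,)
        Per-step cumulative nucleotide offset and node length.
    f_node : int64 array, shape (total_steps,)
        Per-step node rank (index into ``node_ids``).
    f_rev : int8 array, shape (total_steps,)
        Per-step strand flag (1 = reverse).
    node_ids : list of node ids in graph order; ``id_to_idx`` inverts it.
    """

    def __init__(self, graph: VariationGraph) -> None:
        if not graph.paths:
            raise GraphError("path-guided layout requires at least one embedded path")
        self.n_paths = len(graph.paths)
        self.node_ids = graph.node_ids
        self.id_to_idx = {nid: i for i, nid in enumerate(self.node_ids)}
        self.node_lengths = np.array(
            [len(graph.nodes[nid].sequence) for nid in self.node_ids], dtype=np.int64
        )

        counts = np.array([len(p.steps) for p in graph.paths], dtype=np.int64)
        self.steps_per_path = counts
        self.path_ptr = np.zeros(self.n_paths + 1, dtype=np.int64)
        np.cumsum(counts, out=self.path_ptr[1:])
        self.total_steps = int(self.path_ptr[-1])

        node_ranks = np.empty(self.total_steps, dtype=np.int64)
        revs = np.empty(self.total_steps, dtype=np.int8)
        pos = 0
        for path in graph.paths:
            for step in path.steps:
                node_ranks[pos] = self.id_to_idx[step.node_id]
                revs[pos] = 1 if step.is_reverse else 0
                pos += 1
        self.f_node = node_ranks
        self.f_rev = revs
        self.f_len = self.node_lengths[node_ranks]

        # per-path exclusive prefix sums of step lengths
        self.f_off = np.empty(self.total_steps, dtype=np.int64)
        self.path_lengths = np.empty(self.n_paths, dtype=np.int64)
        for p in range(self.n_paths):
            lo, hi = int(self.path_ptr[p]), int(self.path_ptr[p + 1])
            lens = self.f_len[lo:hi]
            self.f_off[lo] = 0
            np.cumsum(lens[:-1], out=self.f_off[lo + 1 : hi])
            self.path_lengths[p] = int(lens.sum())

    # -- flat <-> structured ---------------------------------------------

    def flat_of(self, ref: StepRef) -> int:
        if not (0 <= ref.path_id < self.n_paths):
            raise IndexError(f"path_id {ref.path_id} out of range")
        if not (0 <= ref.step_rank < self.steps_per_path[ref.path_id]):
            raise IndexError(
                f"step_rank {ref.step_rank} out of range for path {ref.path_id}"
            )
        return int(self.path_ptr[ref.path_id]) + ref.step_rank

    def ref_of(self, flat: int) -> StepRef:
        if not (0 <= flat < self.total_steps):
            raise IndexError(f"flat step {flat} out of range")
        p = int(np.searchsorted(self.path_ptr, flat, side="right")) - 1
        return StepRef(p, flat - int(self.path_ptr[p]))


def build_path_index(graph: VariationGraph) -> PathIndex:
    """Build the step/offset index; touches each step exactly once."""
    return PathIndex(graph)


def step_offset(index: PathIndex, ref: StepRef) -> int:
    """Cumulative nucleotide offset of a step from its path's start."""
    return int(index.f_off[index.flat_of(ref)])


def sample_global_step(index: PathIndex, rng: np.random.Generator) -> StepRef:
    """Draw one step uniformly from all steps of all paths."""
    return index.ref_of(int(rng.integers(index.total_steps)))


def step_end_offsets(
    graph: VariationGraph, index: PathIndex, ref: StepRef
) -> tuple[int, int]:
    """Path offsets of the two node ends at a step.

    Returns (sequence-start end, sequence-end end).  For a forward step
    these are (offset, offset + node length); for a reverse step they
    are swapped — the node's sequence-start end sits at the larger path
    coordinate.
    """
    flat = index.flat_of(ref)
    off = int(index.f_off[flat])
    length = int(index.f_len[flat])
    if index.f_rev[flat]:
        return off + length, off
    return off, off + length
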