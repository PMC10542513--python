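"""Path-guided SGD layout engine: 1D node sorting and 2D drawing.

Each sampled term pulls (or pushes) a pair of node ends so their layout
distance approaches the nucleotide distance measured along a shared
path.  The step size anneals geometrically from eta_max down to eta_min:
early iterations make global moves (learning rate capped at 1), late
iterations refine locally.

In 2D every node owns two movable points — its sequence-start and
sequence-end ends — so nodes render as segments.  In 1D a node is a
single scalar coordinate (a sortable rank).

Multi-threaded runs follow a coordination-free (HOGWILD-style) update
scheme: workers write interleaved element-wise updates into the shared
coordinate arrays without locking.  Single-threaded runs are
bit-deterministic under a fixed seed; threaded runs are only
statistically reproducible.
"""

from __future__ import annotations

import math
import threading
from dataclasses import dataclass, field
from typing import Callable, IO

import numpy as np

from .graph import GraphError, VariationGraph
from .index import PathIndex
from .sampling import SamplerConfig, Term, TermBatch, sample_term_batch

__all__ = [
    "Layout1D",
    "Layout2D",
    "SGDConfig",
    "eta_schedule",
    "apply_term_update_1d",
    "apply_term_update_2d",
    "init_layout_1d",
    "init_layout_2d",
    "run_layout",
    "node_order_from_layout",
    "write_layout_tsv",
    "read_layout_tsv",
]

_LD_FLOOR = 1e-9  # below this the update direction is RNG-derived


@dataclass
class SGDConfig:
    """Run parameters.  ``None`` fields are resolved against the graph:
    iter_max defaults to 30 (1D) / 100 (2D); min_term_updates to
    10 x total steps; eta_max to (longest path length)^2; eta_min to
    epsilon."""

    iter_max: int | None = None
    min_term_updates: int | None = None
    eta_max: float | None = None
    eta_min: float | None = None
    epsilon: float = 0.01
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    init_mode: str | None = None
    init_sigma: float = 1.0
    fix_path: str | None = None
    threads: int = 1
    seed: int = 0

    def resolved(self, index: PathIndex, dims: int) -> "SGDConfig":
        cfg = SGDConfig(**self.__dict__)
        if cfg.iter_max is None:
            cfg.iter_max = 30 if dims == 1 else 100
        if cfg.iter_max < 1:
            raise ValueError("iter_max must be >= 1")
        if cfg.min_term_updates is None:
            cfg.min_term_updates = 10 * index.total_steps
        if cfg.eta_max is None:
            cfg.eta_max = float(index.path_lengths.max()) ** 2
        if cfg.eta_min is None:
            cfg.eta_min = cfg.epsilon
        if not cfg.eta_max >= cfg.eta_min > 0:
            raise ValueError("requires eta_max >= eta_min > 0")
        if cfg.init_mode is None:
            cfg.init_mode = "input_order" if dims == 1 else "order_gaussian"
        return cfg


class Layout1D:
    """One scalar coordinate per node, in graph node order."""

    dims = 1

    def __init__(self, node_ids: list[int], x: np.ndarray) -> None:
        self.node_ids = node_ids
        self.id_to_idx = {nid: i for i, nid in enumerate(node_ids)}
        self.x = np.asarray(x, dtype=np.float64)
        if self.x.shape != (len(node_ids),):
            raise ValueError("coordinate array shape mismatch")

    def copy(self) -> "Layout1D":
        return Layout1D(self.node_ids, self.x.copy())


class Layout2D:
    """Two 2D points per node: row 2k is node k's sequence-start end,
    row 2k+1 its sequence-end end.  ``frozen`` marks rows that updates
    must never move."""

    dims = 2

    def __init__(
        self, node_ids: list[int], coords: np.ndarray, frozen: np.ndarray | None = None
    ) -> None:
        self.node_ids = node_ids
        self.id_to_idx = {nid: i for i, nid in enumerate(node_ids)}
        self.coords = np.asarray(coords, dtype=np.float64)
        if self.coords.shape != (2 * len(node_ids), 2):
            raise ValueError("coordinate array shape mismatch")
        self.frozen = (
            np.zeros(2 * len(node_ids), dtype=bool) if frozen is None else frozen
        )

    def copy(self) -> "Layout2D":
        return Layout2D(self.node_ids, self.coords.copy(), self.frozen.copy())


# -- annealing schedule --------------------------------------------------


def eta_schedule(config: SGDConfig, t: int) -> float:
    """Geometric decay from eta_max (t=0) to eta_min (t=iter_max-1)."""
    if config.iter_max is None or config.eta_max is None or config.eta_min is None:
        raise ValueError("config must be resolved before scheduling")
    if not 0 <= t < config.iter_max:
        raise ValueError(f"iteration {t} outside [0, {config.iter_max})")
    if config.iter_max == 1:
        return config.eta_max
    frac = t / (config.iter_max - 1)
    return config.eta_max * (config.eta_min / config.eta_max) ** frac


# -- single-term updates (reference implementations) ---------------------


def _mu(eta: float, nd: float) -> float:
    # written as eta / nd^2 (not eta * w) so the scalar and batched code
    # paths produce bit-identical learning rates
    return min(eta / max(nd, 1.0) ** 2, 1.0)


def apply_term_update_2d(
    layout: Layout2D, term: Term, eta: float, rng: np.random.Generator
) -> float:
    """Move the term's two node ends toward/away from each other so their
    distance contracts toward nd; returns the applied displacement r.

    With mu <= 1 the update never overshoots: |ld' - nd| = (1-mu)|ld - nd|.
    """
    ia = 2 * layout.id_to_idx[term.end_a.node_id] + (0 if term.end_a.which_end == "start" else 1)
    ib = 2 * layout.id_to_idx[term.end_b.node_id] + (0 if term.end_b.which_end == "start" else 1)
    return _update_pair_2d(layout.coords, layout.frozen, ia, ib, float(term.nd), eta, rng)


def _update_pair_2d(
    coords: np.ndarray,
    frozen: np.ndarray,
    ia: int,
    ib: int,
    nd: float,
    eta: float,
    rng: np.random.Generator,
) -> float:
    if ia == ib:
        return 0.0
    ax, ay = coords[ia]
    bx, by = coords[ib]
    if not (math.isfinite(ax) and math.isfinite(ay) and math.isfinite(bx) and math.isfinite(by)):
        raise FloatingPointError("non-finite layout coordinates")
    dx, dy = bx - ax, by - ay
    ld = math.hypot(dx, dy)
    if ld < _LD_FLOOR:
        ang = rng.random() * 2.0 * math.pi
        ux, uy = math.cos(ang), math.sin(ang)
    else:
        ux, uy = dx / ld, dy / ld
    r = _mu(eta, nd) * (ld - nd) / 2.0
    fa, fb = bool(frozen[ia]), bool(frozen[ib])
    if not fa:
        coords[ia, 0] = ax + r * ux
        coords[ia, 1] = ay + r * uy
    if not fb:
        coords[ib, 0] = bx - r * ux
        coords[ib, 1] = by - r * uy
    return r


def apply_term_update_1d(
    layout: Layout1D, term: Term, eta: float, rng: np.random.Generator
) -> float:
    """1D analogue: each node contributes its single coordinate."""
    ia = layout.id_to_idx[term.end_a.node_id]
    ib = layout.id_to_idx[term.end_b.node_id]
    return _update_pair_1d(layout.x, ia, ib, float(term.nd), eta, rng)


def _update_pair_1d(
    x: np.ndarray, ia: int, ib: int, nd: float, eta: float, rng: np.random.Generator
) -> float:
    if ia == ib:
        return 0.0
    xa, xb = x[ia], x[ib]
    if not (math.isfinite(xa) and math.isfinite(xb)):
        raise FloatingPointError("non-finite layout coordinates")
    d = xb - xa
    ld = abs(d)
    u = (1.0 if rng.random() < 0.5 else -1.0) if ld < _LD_FLOOR else d / ld
    r = _mu(eta, nd) * (ld - nd) / 2.0
    x[ia] = xa + r * u
    x[ib] = xb - r * u
    return r


# -- initialization ------------------------------------------------------


def _prefix_offsets(graph: VariationGraph) -> np.ndarray:
    lens = np.array([len(graph.nodes[n].sequence) for n in graph.nodes], dtype=np.float64)
    off = np.zeros(len(lens), dtype=np.float64)
    np.cumsum(lens[:-1], out=off[1:])
    return off


def init_layout_1d(
    graph: VariationGraph, mode: str = "input_order", rng: np.random.Generator | None = None
) -> Layout1D:
    """input_order: node k at the cumulative nucleotide offset of nodes
    before it; random: a uniform permutation of those offsets."""
    off = _prefix_offsets(graph)
    if mode == "random":
        if rng is None:
            raise ValueError("random init requires an rng")
        off = off[rng.permutation(len(off))]
    elif mode != "input_order":
        raise ValueError(f"unknown 1D init mode {mode!r}")
    return Layout1D(graph.node_ids, off)


def _hilbert_d2xy(order: int, d: int) -> tuple[int, int]:
    # standard Hilbert-curve index -> (x, y) on a 2^order grid
    x = y = 0
    t = d
    s = 1
    n = 1 << order
    while s < n:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        if ry == 0:
            if rx == 1:
                x = s - 1 - x
                y = s - 1 - y
            x, y = y, x
        x += s * rx
        y += s * ry
        t //= 4
        s *= 2
    return x, y


def init_layout_2d(
    graph: VariationGraph,
    mode: str = "order_gaussian",
    rng: np.random.Generator | None = None,
    sigma: float = 1.0,
    fix_path: str | None = None,
) -> Layout2D:
    """2D initialization.

    order_uniform / order_gaussian: X is the node's cumulative offset in
    graph order (a node's two ends separated by its length), Y is noise.
    hilbert: node ends traced along a Hilbert curve covering a square of
    side = total sequence length.  path_fixed: nodes on ``fix_path``
    pinned at their path offsets (frozen), the rest order_gaussian.
    """
    node_ids = graph.node_ids
    n = len(node_ids)
    off = _prefix_offsets(graph)
    lens = np.array([len(graph.nodes[i].sequence) for i in node_ids], dtype=np.float64)
    xs = np.empty(2 * n, dtype=np.float64)
    xs[0::2] = off
    xs[1::2] = off + lens
    coords = np.zeros((2 * n, 2), dtype=np.float64)
    frozen = np.zeros(2 * n, dtype=bool)

    if mode in ("order_uniform", "order_gaussian"):
        if rng is None:
            raise ValueError(f"{mode} init requires an rng")
        coords[:, 0] = xs
        if mode == "order_uniform":
            coords[:, 1] = rng.uniform(0.0, sigma, 2 * n) if sigma > 0 else 0.0
        else:
            coords[:, 1] = rng.normal(0.0, sigma, 2 * n) if sigma > 0 else 0.0
    elif mode == "hilbert":
        total = float(xs.max()) or 1.0
        order = max(1, math.ceil(math.log(total, 4)))
        cells = (1 << order) ** 2
        scale = total / (1 << order)
        for row, t in enumerate(xs):
            d = min(int(t / total * cells), cells - 1)
            hx, hy = _hilbert_d2xy(order, d)
            coords[row, 0] = hx * scale
            coords[row, 1] = hy * scale
    elif mode == "path_fixed":
        if fix_path is None:
            raise ValueError("path_fixed init requires a path name")
        path = graph.path_by_name(fix_path)  # raises on unknown name
        if rng is None:
            raise ValueError("path_fixed init requires an rng")
        coords[:, 0] = xs
        coords[:, 1] = rng.normal(0.0, sigma, 2 * n) if sigma > 0 else 0.0
        idx_of = {nid: i for i, nid in enumerate(node_ids)}
        cursor = 0
        seen: set[int] = set()
        for step in path.steps:
            length = len(graph.nodes[step.node_id].sequence)
            if step.node_id not in seen:
                seen.add(step.node_id)
                k = idx_of[step.node_id]
                start_off = cursor + length if step.is_reverse else cursor
                end_off = cursor if step.is_reverse else cursor + length
                coords[2 * k] = (start_off, 0.0)
                coords[2 * k + 1] = (end_off, 0.0)
                frozen[2 * k] = frozen[2 * k + 1] = True
            cursor += length
    else:
        raise ValueError(f"unknown 2D init mode {mode!r}")

    return Layout2D(node_ids, coords, frozen)


# -- main loop -----------------------------------------------------------


def _run_batch_2d(
    coords: np.ndarray,
    frozen: np.ndarray,
    batch: TermBatch,
    eta: float,
    rng: np.random.Generator,
) -> float:
    ia_arr = 2 * batch.node_a + batch.end_a
    ib_arr = 2 * batch.node_b + batch.end_b
    mu = np.minimum(eta / np.maximum(batch.nd, 1.0) ** 2, 1.0)
    nd = batch.nd
    max_r = 0.0
    hypot = math.hypot
    for k in range(len(nd)):
        ia = ia_arr[k]
        ib = ib_arr[k]
        if ia == ib:
            continue
        ax = coords[ia, 0]
        ay = coords[ia, 1]
        bx = coords[ib, 0]
        by = coords[ib, 1]
        dx = bx - ax
        dy = by - ay
        ld = hypot(dx, dy)
        if ld < _LD_FLOOR:
            ang = rng.random() * 6.283185307179586
            ux = math.cos(ang)
            uy = math.sin(ang)
        else:
            ux = dx / ld
            uy = dy / ld
        r = mu[k] * (ld - nd[k]) / 2.0
        if not frozen[ia]:
            coords[ia, 0] = ax + r * ux
            coords[ia, 1] = ay + r * uy
        if not frozen[ib]:
            coords[ib, 0] = bx - r * ux
            coords[ib, 1] = by - r * uy
        if r > max_r:
            max_r = r
        elif -r > max_r:
            max_r = -r
    return max_r


def _run_batch_1d(
    x: np.ndarray, batch: TermBatch, eta: float, rng: np.random.Generator
) -> float:
    ia_arr = batch.node_a
    ib_arr = batch.node_b
    mu = np.minimum(eta / np.maximum(batch.nd, 1.0) ** 2, 1.0)
    nd = batch.nd
    max_r = 0.0
    for k in range(len(nd)):
        ia = ia_arr[k]
        ib = ib_arr[k]
        if ia == ib:
            continue
        xa = x[ia]
        xb = x[ib]
        d = xb - xa
        ld = abs(d)
        if ld < _LD_FLOOR:
            u = 1.0 if rng.random() < 0.5 else -1.0
        else:
            u = d / ld
        r = mu[k] * (ld - nd[k]) / 2.0
        x[ia] = xa + r * u
        x[ib] = xb - r * u
        if r > max_r:
            max_r = r
        elif -r > max_r:
            max_r = -r
    return max_r


def run_layout(
    graph: VariationGraph,
    index: PathIndex,
    config: SGDConfig,
    dims: int = 2,
    rng: np.random.Generator | None = None,
    layout: Layout1D | Layout2D | None = None,
    callback: Callable[[int, float, float], None] | None = None,
    stop_delta: float | None = None,
) -> Layout1D | Layout2D:
    """Run the full annealed SGD layout.

    Per iteration: fix eta from the schedule, sample min_term_updates
    terms (cooling kicks in once t/iter_max crosses the sampler's
    cooling_start), and apply them sequentially (or split across
    lock-free workers when config.threads > 1).  ``callback(t, eta,
    max_abs_r)`` is invoked after each iteration; if ``stop_delta`` is
    set, the run ends early once an iteration's largest displacement
    falls below it.
    """
    if dims not in (1, 2):
        raise ValueError("dims must be 1 or 2")
    if not graph.paths:
        raise GraphError("path-guided layout requires at least one embedded path")
    cfg = config.resolved(index, dims)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if layout is None:
        if dims == 1:
            layout = init_layout_1d(graph, cfg.init_mode, rng)
        else:
            layout = init_layout_2d(
                graph, cfg.init_mode, rng, sigma=cfg.init_sigma, fix_path=cfg.fix_path
            )
    elif layout.dims != dims:
        raise ValueError("provided layout dimensionality does not match dims")

    n_workers = max(1, int(cfg.threads))
    for t in range(cfg.iter_max):
        eta = eta_schedule(cfg, t)
        progress = t / cfg.iter_max
        if n_workers == 1:
            batch = sample_term_batch(index, cfg.sampler, progress, rng, cfg.min_term_updates)
            if dims == 2:
                max_r = _run_batch_2d(layout.coords, layout.frozen, batch, eta, rng)
            else:
                max_r = _run_batch_1d(layout.x, batch, eta, rng)
        else:
            shares = [cfg.min_term_updates // n_workers] * n_workers
            shares[0] += cfg.min_term_updates % n_workers
            child_rngs = rng.spawn(n_workers)
            results = [0.0] * n_workers

            def worker(w: int) -> None:
                wrng = child_rngs[w]
                wbatch = sample_term_batch(index, cfg.sampler, progress, wrng, shares[w])
                if dims == 2:
                    results[w] = _run_batch_2d(layout.coords, layout.frozen, wbatch, eta, wrng)
                else:
                    results[w] = _run_batch_1d(layout.x, wbatch, eta, wrng)

            threads = [threading.Thread(target=worker, args=(w,)) for w in range(n_workers)]
            for th in threads:
                th.start()
            for th in threads:
                th.join()
            max_r = max(results)
        if callback is not None:
            callback(t, eta, max_r)
        if stop_delta is not None and max_r < stop_delta:
            break

    if dims == 1:
        # 1D layouts are mirror-symmetric; canonicalize so the longest
        # path runs in increasing coordinate order
        p = int(np.argmax(index.path_lengths))
        along = layout.x[index.f_node[index.path_ptr[p] : index.path_ptr[p + 1]]]
        if len(along) > 1 and np.ptp(along) > 0:
            if np.corrcoef(np.arange(len(along)), along)[0, 1] < 0:
                layout.x = -layout.x
    return layout


def node_order_from_layout(layout: Layout1D) -> list[int]:
    """Node ids sorted by their 1D coordinate (stable on ties)."""
    ranks = np.argsort(layout.x, kind="stable")
    return [layout.node_ids[i] for i in ranks]


# -- layout table I/O ----------------------------------------------------


def write_layout_tsv(layout: Layout2D, fh: IO[str]) -> None:
    """Write the 2-rows-per-node coordinate table (17 significant digits)."""
    fh.write("idx\tX\tY\n")
    for k, nid in enumerate(layout.node_ids):
        for row in (2 * k, 2 * k + 1):
            fh.write(
                "{}\t{:.17g}\t{:.17g}\n".format(
                    nid, layout.coords[row, 0], layout.coords[row, 1]
                )
            )


def read_layout_tsv(text: str) -> Layout2D:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != ["idx", "X", "Y"]:
        raise ValueError("layout TSV must start with an 'idx\\tX\\tY' header")
    rows = [ln.split("\t") for ln in lines[1:]]
    if len(rows) % 2 != 0:
        raise ValueError("layout TSV must have two rows per node")
    node_ids: list[int] = []
    coords = np.empty((len(rows), 2), dtype=np.float64)
    for i, (idx, xs, ys) in enumerate(rows):
        if i % 2 == 0:
            node_ids.append(int(idx))
        elif int(idx) != node_ids[-1]:
            raise ValueError(f"row {i + 2}: expected second row of node {node_ids[-1]}")
        coords[i, 0] = float(xs)
        coords[i, 1] = float(ys)
    return Layout2D(node_ids, coords)
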