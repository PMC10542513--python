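"""Term sampling: pairs of node ends with their path nucleotide distance.

One *term* is the unit of SGD work: two node ends that lie on the same
path plus the nucleotide distance ``nd`` between them measured in that
path's coordinate system.  The first step of a term is drawn uniformly
from all steps of all paths; the partner is drawn from the same path
either uniformly (global moves) or at a Zipf-distributed step-rank
offset (local refinement).  A cooling phase swaps in a sharper Zipf law
part-way through the run so late updates concentrate on short distances.

Zipf ranks count steps; the resulting ``nd`` is measured in nucleotides
via the path index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph import VariationGraph
from .index import PathIndex, StepRef, sample_global_step

__all__ = [
    "ZipfSpec",
    "SamplerConfig",
    "TermEnd",
    "Term",
    "TermBatch",
    "zipf_cdf",
    "zipf_sample",
    "sample_partner",
    "sample_term",
    "sample_term_batch",
]

# default training law: long-tailed; cooled law: concentrated locally
DEFAULT_THETA = 0.99
DEFAULT_WINDOW = 10_000
COOLED_THETA = 2.0
COOLED_WINDOW = 100


@dataclass(frozen=True)
class ZipfSpec:
    """Truncated Zipf law: P(k) ∝ k^(−theta) for ranks k in 1..window."""

    theta: float = DEFAULT_THETA
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass(frozen=True)
class SamplerConfig:
    """Knobs for term sampling.

    flip_probability is the chance a term uses a uniform (rather than
    Zipfian) partner draw; cooling_start is the fraction of total
    iterations after which cooled_zipf replaces zipf.
    """

    zipf: ZipfSpec = field(default_factory=ZipfSpec)
    flip_probability: float = 0.5
    cooling_start: float = 0.5
    cooled_zipf: ZipfSpec = field(default_factory=lambda: ZipfSpec(COOLED_THETA, COOLED_WINDOW))

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        if not 0.0 <= self.cooling_start <= 1.0:
            raise ValueError("cooling_start must lie in [0, 1]")

    def active_zipf(self, progress: float) -> ZipfSpec:
        return self.cooled_zipf if progress >= self.cooling_start else self.zipf


@dataclass(frozen=True)
class TermEnd:
    """One endpoint of a term: a step, the node it visits, which of the
    node's two ends participates, and that end's path offset."""

    step: StepRef
    node_id: int
    which_end: str  # "start" | "end" (of the node's sequence)
    offset: int


@dataclass(frozen=True)
class Term:
    end_a: TermEnd
    end_b: TermEnd
    nd: int

    def __post_init__(self) -> None:
        if self.end_a.step.path_id != self.end_b.step.path_id:
            raise ValueError("term endpoints must lie on the same path")


@dataclass
class TermBatch:
    """Structure-of-arrays form of many terms (engine fast path).

    node_a/node_b are node *ranks* (indices into the index's node
    order), end_a/end_b are 0 for the sequence-start end and 1 for the
    sequence-end end; uniform flags terms whose partner was drawn
    uniformly.
    """

    node_a: np.ndarray
    end_a: np.ndarray
    node_b: np.ndarray
    end_b: np.ndarray
    nd: np.ndarray
    uniform: np.ndarray
    flat_a: np.ndarray
    flat_b: np.ndarray

    def __len__(self) -> int:
        return len(self.nd)


# -- Zipf law ------------------------------------------------------------

_cdf_cache: dict[tuple[float, int], np.ndarray] = {}


def zipf_cdf(spec: ZipfSpec) -> np.ndarray:
    """Cumulative probabilities of the truncated Zipf law (ranks 1..N)."""
    key = (spec.theta, spec.window)
    cdf = _cdf_cache.get(key)
    if cdf is None:
        weights = np.arange(1, spec.window + 1, dtype=np.float64) ** (-spec.theta)
        cdf = np.cumsum(weights)
        cdf /= cdf[-1]
        if len(_cdf_cache) > 256:  # unbounded growth guard
            _cdf_cache.clear()
        _cdf_cache[key] = cdf
    return cdf


def zipf_sample(rng: np.random.Generator, spec: ZipfSpec) -> int:
    """One rank in [1, window] with P(k) = k^(−θ)/H_N (inverse CDF)."""
    cdf = zipf_cdf(spec)
    return int(np.searchsorted(cdf, rng.random(), side="right")) + 1


def _zipf_sample_many(rng: np.random.Generator, spec: ZipfSpec, n: int) -> np.ndarray:
    cdf = zipf_cdf(spec)
    return np.searchsorted(cdf, rng.random(n), side="right").astype(np.int64) + 1


# -- partner sampling ----------------------------------------------------


def _bounce_rank(rank_i: int, k: int, sign: int, n_steps: int) -> int:
    """Apply the direction-flip / boundary-clamp rule for a Zipf offset."""
    rank_j = rank_i + sign * k
    if 0 <= rank_j < n_steps:
        return rank_j
    rank_j = rank_i - sign * k  # flip direction
    if 0 <= rank_j < n_steps:
        return rank_j
    return min(max(rank_i + sign * k, 0), n_steps - 1)  # clamp to boundary


def sample_partner(
    index: PathIndex,
    si: StepRef,
    mode: str,
    spec: ZipfSpec,
    rng: np.random.Generator,
) -> StepRef:
    """Draw the partner step sj on the same path as si.

    ``mode`` is "uniform" (any step of the path, equiprobable) or "zipf"
    (a Zipf-distributed rank offset in a random direction, reflected at
    the path boundaries).  On a single-step path si itself is returned;
    the caller derives nd from the node length.
    """
    n_steps = int(index.steps_per_path[si.path_id])
    index.flat_of(si)  # validates
    if n_steps < 2:
        return si
    if mode == "uniform":
        return StepRef(si.path_id, int(rng.integers(n_steps)))
    if mode != "zipf":
        raise ValueError(f"unknown partner mode {mode!r}")
    eff = replace(spec, window=min(spec.window, n_steps - 1))
    k = zipf_sample(rng, eff)
    sign = 1 if rng.random() < 0.5 else -1
    return StepRef(si.path_id, _bounce_rank(si.step_rank, k, sign, n_steps))


# -- term construction ---------------------------------------------------


def _end_toward(off: int, length: int, rev: int, target_mid: float) -> tuple[str, int]:
    """Pick the node end nearer ``target_mid`` in path coordinates.

    Returns (which_end, end offset).  Tie goes to the sequence-start end.
    """
    start_off = off + length if rev else off
    end_off = off if rev else off + length
    if abs(start_off - target_mid) <= abs(end_off - target_mid):
        return "start", start_off
    return "end", end_off


def sample_term(
    graph: VariationGraph,
    index: PathIndex,
    config: SamplerConfig,
    progress: float,
    rng: np.random.Generator,
) -> Term:
    """Draw one term: uniform first step, uniform-or-Zipf partner, node
    ends chosen to face each other along the path."""
    si = sample_global_step(index, rng)
    mode = "uniform" if rng.random() < config.flip_probability else "zipf"
    sj = sample_partner(index, si, mode, config.active_zipf(progress), rng)

    fi, fj = index.flat_of(si), index.flat_of(sj)
    node_i = index.node_ids[index.f_node[fi]]
    node_j = index.node_ids[index.f_node[fj]]
    off_i, len_i, rev_i = int(index.f_off[fi]), int(index.f_len[fi]), int(index.f_rev[fi])
    off_j, len_j, rev_j = int(index.f_off[fj]), int(index.f_len[fj]), int(index.f_rev[fj])

    if fi == fj:
        # degenerate: the term spans the node's own two ends
        return Term(
            TermEnd(si, node_i, "start", off_i + len_i if rev_i else off_i),
            TermEnd(sj, node_j, "end", off_i if rev_i else off_i + len_i),
            len_i,
        )

    mid_i = off_i + len_i / 2.0
    mid_j = off_j + len_j / 2.0
    which_a, off_a = _end_toward(off_i, len_i, rev_i, mid_j)
    which_b, off_b = _end_toward(off_j, len_j, rev_j, mid_i)
    return Term(
        TermEnd(si, node_i, which_a, off_a),
        TermEnd(sj, node_j, which_b, off_b),
        abs(off_a - off_b),
    )


def sample_term_batch(
    index: PathIndex,
    config: SamplerConfig,
    progress: float,
    rng: np.random.Generator,
    n: int,
) -> TermBatch:
    """Vectorized equivalent of ``n`` independent ``sample_term`` draws.

    The draw order (first steps, then mode flags, then uniform partner
    draws, then per-path Zipf draws on sorted path ids) is fixed, so the
    batch is bit-reproducible for a given generator state.
    """
    ptr = index.path_ptr
    flat_i = rng.integers(0, index.total_steps, size=n)
    path = np.searchsorted(ptr, flat_i, side="right") - 1
    rank_i = flat_i - ptr[path]
    n_steps = index.steps_per_path[path]

    uniform = rng.random(n) < config.flip_probability
    rank_j = np.empty(n, dtype=np.int64)

    # uniform partners
    u_rows = np.flatnonzero(uniform)
    rank_j[u_rows] = (rng.random(len(u_rows)) * n_steps[u_rows]).astype(np.int64)

    # zipf partners, grouped by path so the window cap is per-path
    spec = config.active_zipf(progress)
    z_rows = np.flatnonzero(~uniform)
    for p in np.unique(path[z_rows]):
        rows = z_rows[path[z_rows] == p]
        m = int(index.steps_per_path[p]) - 1
        if m < 1:
            rank_j[rows] = rank_i[rows]
            continue
        eff = replace(spec, window=min(spec.window, m))
        k = _zipf_sample_many(rng, eff, len(rows))
        sign = rng.integers(0, 2, size=len(rows)) * 2 - 1
        ri = rank_i[rows]
        ns = int(index.steps_per_path[p])
        rj = ri + sign * k
        out = (rj < 0) | (rj >= ns)
        rj[out] = ri[out] - sign[out] * k[out]  # flip direction
        out = (rj < 0) | (rj >= ns)
        rj[out] = np.clip(ri[out] + sign[out] * k[out], 0, ns - 1)  # clamp
        rank_j[rows] = rj

    flat_j = ptr[path] + rank_j

    off_i, len_i = index.f_off[flat_i], index.f_len[flat_i]
    off_j, len_j = index.f_off[flat_j], index.f_len[flat_j]
    rev_i = index.f_rev[flat_i].astype(np.int64)
    rev_j = index.f_rev[flat_j].astype(np.int64)

    start_a = off_i + rev_i * len_i
    end_a = off_i + (1 - rev_i) * len_i
    start_b = off_j + rev_j * len_j
    end_b = off_j + (1 - rev_j) * len_j
    mid_i = off_i + len_i / 2.0
    mid_j = off_j + len_j / 2.0

    pick_a = (np.abs(start_a - mid_j) <= np.abs(end_a - mid_j)).astype(np.int64) ^ 1
    pick_b = (np.abs(start_b - mid_i) <= np.abs(end_b - mid_i)).astype(np.int64) ^ 1
    o_a = np.where(pick_a == 0, start_a, end_a)
    o_b = np.where(pick_b == 0, start_b, end_b)
    nd = np.abs(o_a - o_b)

    same = flat_i == flat_j
    pick_a[same] = 0
    pick_b[same] = 1
    nd[same] = len_i[same]

    return TermBatch(
        node_a=index.f_node[flat_i],
        end_a=pick_a,
        node_b=index.f_node[flat_j],
        end_b=pick_b,
        nd=nd.astype(np.float64),
        uniform=uniform,
        flat_a=flat_i,
        flat_b=flat_j,
    )
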