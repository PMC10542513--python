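"""Layout-quality diagnostics.

Stress is the sampled MDS objective: the mean over terms of the squared
relative residual ((ld - nd) / max(nd, 1))^2.  Evaluation terms use
uniform partner sampling only, decoupled from the Zipf-biased training
sampler, so the number reflects the layout rather than the training
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import Layout1D, Layout2D
from .graph import VariationGraph
from .index import PathIndex
from .sampling import SamplerConfig, sample_term_batch

__all__ = [
    "StressReport",
    "sampled_path_stress",
    "order_recovery",
    "linearity_2d",
]

_UNIFORM_SAMPLER = SamplerConfig(flip_probability=1.0)


@dataclass(frozen=True)
class StressReport:
    n_terms: int
    stress: float
    seed: int

    def to_tsv(self) -> str:
        return "n_terms\tstress\tseed\n{}\t{:.17g}\t{}\n".format(
            self.n_terms, self.stress, self.seed
        )


def sampled_path_stress(
    graph: VariationGraph,
    index: PathIndex,
    layout: Layout1D | Layout2D,
    n_terms: int,
    seed: int = 0,
) -> StressReport:
    """Mean normalized squared residual over uniformly sampled terms."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    batch = sample_term_batch(index, _UNIFORM_SAMPLER, 0.0, rng, n_terms)
    if isinstance(layout, Layout1D):
        ld = np.abs(layout.x[batch.node_b] - layout.x[batch.node_a])
    else:
        ia = 2 * batch.node_a + batch.end_a
        ib = 2 * batch.node_b + batch.end_b
        delta = layout.coords[ib] - layout.coords[ia]
        ld = np.hypot(delta[:, 0], delta[:, 1])
    resid = (ld - batch.nd) / np.maximum(batch.nd, 1.0)
    return StressReport(n_terms, float(np.mean(resid**2)), seed)


def _first_visit_nodes(graph: VariationGraph, path_name: str) -> list[int]:
    path = graph.path_by_name(path_name)
    seen: set[int] = set()
    order: list[int] = []
    for step in path.steps:
        if step.node_id not in seen:
            seen.add(step.node_id)
            order.append(step.node_id)
    return order


def order_recovery(layout: Layout1D, graph: VariationGraph, path_name: str) -> float:
    """Spearman correlation between 1D coordinates and first-visit path
    ranks of the path's nodes; 1.0 means the order was fully recovered."""
    nodes = _first_visit_nodes(graph, path_name)
    coords = [layout.x[layout.id_to_idx[n]] for n in nodes]
    rho = stats.spearmanr(coords, range(len(nodes))).statistic
    return float(rho)


def linearity_2d(layout: Layout2D, graph: VariationGraph, path_name: str) -> float:
    """|Pearson r| between path offsets of the path's node ends and their
    projection onto the layout's first principal axis.

    1.0 for a straight-line layout; rotation/translation invariant.
    """
    path = graph.path_by_name(path_name)
    pts: list[np.ndarray] = []
    offs: list[float] = []
    seen: set[int] = set()
    cursor = 0
    for step in path.steps:
        length = len(graph.nodes[step.node_id].sequence)
        if step.node_id not in seen:
            seen.add(step.node_id)
            k = layout.id_to_idx[step.node_id]
            start_off = cursor + length if step.is_reverse else cursor
            end_off = cursor if step.is_reverse else cursor + length
            pts.append(layout.coords[2 * k])
            offs.append(start_off)
            pts.append(layout.coords[2 * k + 1])
            offs.append(end_off)
        cursor += length
    points = np.asarray(pts) - np.mean(pts, axis=0)
    _, _, vt = np.linalg.svd(points, full_matrices=False)
    proj = points @ vt[0]
    r = np.corrcoef(proj, np.asarray(offs))[0, 1]
    return float(abs(r))
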