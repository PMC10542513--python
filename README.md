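# gfalayout

Path-guided stochastic gradient descent layout for pangenome variation
graphs in GFA1 format.

A variation graph embeds genomes as *paths*: walks over oriented,
sequence-labelled nodes. `gfalayout` uses those paths as a positional
system — it repeatedly samples pairs of node ends that share a path,
measures their nucleotide distance along that path, and nudges their
layout coordinates so the two distances agree. Because distances are
sampled from paths rather than precomputed for all node pairs, the cost
per update is O(1) and no quadratic distance matrix is ever built.

Features:

- **1D sorting** (`sort`): assigns each node a scalar coordinate and
  emits the induced node order (optionally a renumbered, sorted GFA).
- **2D drawing** (`layout` + `draw`): each node becomes a segment with
  two movable ends; output is a TSV coordinate table and an SVG
  rendering.
- **Sampling machinery**: uniform first-step draws over all path steps,
  uniform-or-Zipfian partner draws (the *flip*), and a *cooling* phase
  that sharpens the Zipf law late in the run to refine local structure.
- **Annealed updates**: learning rate `mu = min(eta / max(nd,1)^2, 1)`
  with a geometric `eta` schedule — global moves early, local
  refinement late; single updates never overshoot.
- **Lock-free parallelism**: optional multi-worker runs write
  interleaved updates into shared coordinate arrays without locks
  (single-threaded runs are bit-deterministic; threaded runs agree
  statistically).
- **Diagnostics** (`stats`): sampled normalized stress, 1D order
  recovery, 2D linearity.
- **Synthetic graphs** (`synth`): seeded linear / SNP-bubble /
  indel-bubble / inversion / tandem-loop fixtures, so nothing external
  is needed to try the tool.

## CLI

```sh
# make a small synthetic graph
gfalayout synth --kind snp_bubbles -n 50 --seed 1 --out graph.gfa

# 1D: sort the nodes along the embedded haplotypes
gfalayout sort graph.gfa --seed 1 --gfa-out sorted.gfa --out order.txt

# 2D: compute a layout, render it, and score it
gfalayout layout sorted.gfa --seed 1 --out layout.tsv
gfalayout draw sorted.gfa layout.tsv --out layout.svg
gfalayout stats sorted.gfa layout.tsv --terms 10000
```

Layout initialization modes (`--init`): `order-uniform` /
`order-gaussian` (graph-order X plus noise in Y), `hilbert`
(space-filling curve), `path-fixed` (pin the nodes of `--fix-path` at
their path offsets; pinned nodes never move).

Per-iteration `eta` and the largest applied displacement are logged to
stderr.

## Library

```python
import numpy as np, gfalayout as gl

graph = gl.parse_gfa(open("graph.gfa").read())
index = gl.build_path_index(graph)
layout = gl.run_layout(graph, index, gl.SGDConfig(seed=1), dims=2)
print(gl.sampled_path_stress(graph, index, layout, 10_000, seed=0))
```

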