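"""Interrogate the fitted gene network as a graph.

Cliques drive the MLE-existence condition; r-step neighbourhoods put a
gene of interest in its network context; clusters of flagged genes show
how differential expression organises along the network.
"""

import numpy as np

from ggmdx import (GeneGraph, SimConfig, flagged_clusters, generate_precision,
                   maximal_cliques, nearest_flagged, neighbourhood,
                   shortest_path)

model = generate_precision(SimConfig(p=200, n=100, q_per_row=2, seed=21))
G = GeneGraph.from_pattern(model.N_true,
                           labels=[f"g{j}" for j in range(200)])

cliques, sizes = maximal_cliques(G)
print("clique size distribution:",
      {k: sizes[k] for k in sorted(sizes)})

ball = neighbourhood(G, "g0", r=2)
print(f"genes within 2 edges of g0: {sorted(ball.labels)}")

rng = np.random.default_rng(0)
flagged = [f"g{j}" for j in rng.choice(200, 30, replace=False)]
comps, comp_sizes = flagged_clusters(G, flagged)
print(f"{len(comps)} clusters of flagged genes; size histogram:",
      {k: comp_sizes[k] for k in sorted(comp_sizes)})

print("closest flagged gene to g0:", nearest_flagged(G, "g0", flagged))
path = shortest_path(G, "g0", "g199")
print("shortest path g0 -> g199:", " -> ".join(path) if path else "none")
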