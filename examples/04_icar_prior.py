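"""The intrinsic CAR prior on the Guinea contiguity graph.

Shows the bundled region adjacency, the conditional law of one region's
effect given its neighbours (normal around the neighbour mean with variance
tau2 / neighbour count), and draws from the sum-to-zero-constrained joint.
"""

import numpy as np

from anemiamap import guinea_graph, icar_conditional, sample_icar

g = guinea_graph()
print("Guinea region adjacency (first-order contiguity):")
for j, label in enumerate(g.labels):
    nbs = ", ".join(g.labels[r] for r in g.neighbors[j])
    print(f"  {label:<10} ({g.m[j]} neighbours): {nbs}")

rng = np.random.default_rng(0)
tau2 = 0.04
u = sample_icar(g, tau2, rng)
print(f"\nOne ICAR draw with tau2 = {tau2} (sums to {u.sum():.2e}):")
for label, val in zip(g.labels, u):
    print(f"  {label:<10} {val:+.4f}")

j = list(g.labels).index("Faranah")
mean, var = icar_conditional(u, j, g, tau2)
print(f"\nConditional law of Faranah's effect given its {g.m[j]} neighbours:")
print(f"  N(mean={mean:+.4f}, var={var:.4f})  — the neighbour average, with")
print(f"  variance tau2/m = {tau2}/{g.m[j]}; smoothing is stronger for")
print("  regions with more neighbours.")
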