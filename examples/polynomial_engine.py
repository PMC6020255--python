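"""The x-polynomial engine on the classic worked bipartite instance.

Five overlapping embeddings (variables x1, x2, x3, x5, x6) depend on four
extra edges with polynomials Z1 = p1*x1 + q1, Z2 = p2*x1*x2*x3 + q2,
Z4 = p4*x1*x2*x3*x5 + q4 and Z8 = p8*x6 + q8.  Multiplying the polynomials
and collapsing each variable once its last polynomial arrives yields the
distribution of B_k, the number of overlapping embeddings that exist.
The multiplication order changes the work, never the answer.
"""

import numpy as np

from promote import BipartiteGraph, multiply_collapse, order_polynomials
from promote.oracle import exact_b_distribution

links = {1: [1], 2: [1, 2, 3], 4: [1, 2, 3, 5], 8: [6]}
probs = {1: 0.5, 2: 0.5, 4: 0.5, 8: 0.5}
bg = BipartiteGraph.build(
    v1=[1, 2, 3, 5, 6], v2=[1, 2, 4, 8], links=links, edge_probs=probs
)

dist, naive = multiply_collapse(bg, order=(1, 2, 4, 8), v1_precollapse=False)
_, reordered = multiply_collapse(bg, order=(4, 2, 8, 1), v1_precollapse=False)
greedy = order_polynomials(bg)
_, best = multiply_collapse(bg, order=greedy)

print("distribution of B_k (P[B=0..5]):", np.round(dist.probs, 4))
print("exact enumeration agrees:",
      np.allclose(dist.probs, exact_b_distribution(bg).probs))
print(f"collapse operations, naive order (Z1,Z2,Z4,Z8): {naive.collapse_ops}")
print(f"collapse operations, reordered (Z4,Z2,Z8,Z1):   {reordered.collapse_ops}")
print(f"greedy ordering found: {greedy}, "
      f"cost with degree-1 pre-collapse: {best.collapse_ops}")
# Ordering the product so that variables collapse early cuts the term-wise
# collapse work from 48 to 34 operations, and the degree-1 pre-collapse
# (folding x5 and x6 directly into t powers) cuts it further — while every
# variant returns the identical B_k distribution.
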