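# Methods

## Model and assumptions

A probabilistic network `G = (V, E, P)` assumes **independent** edge
existence: edge `e_i` is present with probability `p_i ∈ (0, 1]`,
independently of every other edge. Edges with `p = 1` are deterministic
and their absence branch (`q = 0`) is dropped everywhere. The motif `M`
is a small connected undirected pattern (2–5 edges); an *embedding* is a
subset of network edges whose subgraph is isomorphic to `M`, identified
by its edge set so that automorphic relabelings count once. The
existence probability of embedding `H_k` is its gain
`a_k = ∏_{e ∈ H_k} p_e`.

Overlap is measured per F2 (shared edge) or F3 (shared node). Under
either measure the objective — the expected number of realized
embeddings in an independent set — decomposes by linearity of
expectation into the sum of gains, which is the identity the oracle
tests verify exhaustively on small networks. The selection problem is a
maximum-weight independent set on the overlap graph and is solved
greedily; the packaged brute-force oracle gives the exact optimum on
instances with at most 20 embeddings so the heuristic's gap can be
measured.

## The x-polynomial and its collapse

For a focal embedding, V1 holds its overlapping embeddings and V2 the
edges those embeddings need beyond the focal embedding's own (edge
existence stays edge-driven under F3 as well; only the overlap adjacency
changes). Each V2 edge contributes `Z_j = p_j ∏ x_i + q_j`. A variable
collapses in the round where its last containing polynomial has been
multiplied: if its exponent equals its full V1 degree the term gains a
factor `t` (the neighbour exists), otherwise the variable is simply
removed. After all rounds the `t`-marginal is the exact distribution of
`B_k`; prefix marginals are valid distributions whose tail probabilities
`P(B ≥ τ)` and expectation are non-decreasing along the product, which
is what makes early termination sound.

Like terms (identical `t` exponent and variable exponents) are merged
after every round; total coefficient mass stays 1 throughout (checked to
1e-9 in the property tests).

## Cost accounting

`CostReport.collapse_ops` charges each round with
`(unmerged term count after the multiplication) × (variables collapsing)`,
where the unmerged count doubles with every two-branch multiplication.
This deliberately reflects the dense worst-case product rather than the
merged representation actually held in memory, because the collapse cost
of an ordering is a property of the product structure, not of the
merge-friendliness of particular probability values. On the classic
worked instance this convention yields 48 operations for the naive order
and 34 for the variable-collapsing-first order. `peak_terms` reports the
merged (actual) working-set maximum.

## Ordering heuristic (W/D matrices)

At each step, `W[r, s] = 1/deg(v_r)` for variables `x_r` contained in
candidate polynomial `Z_s`, with degrees taken in the *residual*
bipartite graph; `D[r, s]` multiplies the count of level-`1/s` entries in
`Z_r`'s column by `p_r`. Selection scans `D` columns left to right,
keeping the rows with the maximum entry and breaking remaining ties by
the next column; a final tie goes to the lowest edge id. The exact
minimization of collapse cost over all `|V2|!` orderings is intractable
and not attempted. Tie-breaking by id (rather than randomly) makes runs
bit-reproducible; since any order yields the identical distribution,
this affects only reported costs.

## Early termination

Candidates are visited in descending proxy order `Q_k = a_k / deg(H_k)`
(isolated embeddings first, ties by id). While a candidate's product
streams, `ρ_k^j = a_k / (1 + Exp(B_k | prefix j))` is a monotone upper
bound on its exact priority; the product is aborted when `ρ_k^j` falls
**strictly** below the best exact priority seen, so candidates tying the
incumbent are always fully evaluated and the winner (highest ρ, ties to
the lowest id) is identical with the strategy on or off. The incumbent
`ρ*` resets at every outer iteration, and distributions are rebuilt from
the surviving overlap graph after each removal so `B_k` always counts
only live conflicts.

`f(B) = 1 + Exp(B)` is the loss. Any monotone function of the
expectation preserves the bound; the `+1` keeps the loss finite at 1 for
isolated embeddings, making their priority equal to their gain.

## Memory-bounded products

With a term budget `max_terms ≥ 2`, the engine sets
`N1 = max(1, max_terms // (|V2| + 1))` and multiplies each polynomial
into an active batch of at most `N1` terms, deferring the surplus on a
LIFO stack tagged with the next unapplied polynomial index; deferred
batches are completed after the main pass. The in-progress working set
(active batch plus stack) stays within `(j+1)·N1 + N2` terms after `j`
multiplications (`N2 = max_terms − N1`); fully collapsed output terms —
at most `|V1| + 1` of them, the distribution itself — are not part of
the working set. The engine records whether the bound held
(`bound_respected`) rather than assuming it. Batch splits are made on
sorted term keys, so results are reproducible; the final distribution is
identical to the unbounded product (batch merging is an associative
re-grouping of the same sum). For finite budgets the collapse-op count
uses actual batch sizes, since the unmerged doubling convention is not
well defined across batch splits; with an infinite/absent budget the
bounded entry point delegates to the unbounded engine and reports are
identical.

## Synthetic networks

The generator emulates uncertain-network benchmarks: ER, WS or BA
topology with a target average degree (default 2 — ER edge probability
`d/(n−1)`, WS ring-lattice `k = round(d)` with rewiring probability 0.1,
BA attachment `m = max(1, round(d/2))`), then independent uniform(0, 1)
probabilities per edge, strictly inside the open interval. The WS
rewiring probability is a package choice (0.1, the conventional
small-world regime), as no canonical value exists for this protocol.
Replicate suites derive per-replicate seeds from one master seed and
aggregate with a trimmed mean/min/max dropping a fixed number of
extremes at each end (default 20 replicates, trim 2).

What the generator does **not** emulate: correlated edge probabilities
(real confidence scores cluster by evidence type), degree-probability
correlation, and the size/density of curated disease networks. Passing
tests therefore certify algorithmic correctness and invariances, not
biological effect sizes.

## Test problem sizes

Exhaustive oracles guard themselves: 2^|E| world enumeration at |E| ≤ 20,
exact `B_k` at |V2| ≤ 16, exact optima at ≤ 20 embeddings. The test
suite exercises the engine-vs-oracle equivalence on 100 random bipartite
instances (≤ 10 polynomials), strategy-invariance on 51 random ER/WS/BA
networks of 10–25 nodes, and the exhaustive objective identity on ~10-edge
networks — sizes chosen so the whole suite gives exact, reproducible
comparisons.

## Known limitations

- The greedy selection is a heuristic: it can be suboptimal on dense
  overlap graphs (the oracle tests report the gap on small instances but
  only assert the upper bound).
- The expected-maximum variant of the counting problem (per-world maximum
  independent sets) is intentionally not implemented.
- Real-data probability assignment (e.g. co-expression-derived
  confidences) is out of scope; inputs are plain probabilistic edge
  lists.
- Independence of edge existence is assumed throughout; correlated edges
  would invalidate both the gain products and the edge-polynomial model.
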