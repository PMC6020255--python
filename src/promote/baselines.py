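"""Deterministic-transform baselines.

Current practice for uncertain networks is to reduce them to a single
deterministic network first — by ignoring the probabilities (*binary*),
keeping only edges above a probability threshold (*threshold*, default
0.2), or drawing one Bernoulli realization per edge (*sampling*) — and to
count motifs there with a least-overlap greedy.  These are comparison
baselines, not part of the probabilistic counter.
"""

from __future__ import annotations

import numpy as np

from .motifs import Measure, build_overlap_graph, enumerate_embeddings
from .netio import MotifPattern, ProbabilisticNetwork

__all__ = [
    "binarize",
    "threshold_filter",
    "sample_network",
    "deterministic_count",
    "sampling_count",
]


def binarize(net: ProbabilisticNetwork) -> ProbabilisticNetwork:
    """Keep every edge, discarding its probability (edges become certain)."""
    return ProbabilisticNetwork(
        nodes=net.nodes,
        edges=tuple((u, v, 1.0) for u, v, _ in net.edges),
    )


def threshold_filter(
    net: ProbabilisticNetwork, theta: float = 0.2
) -> ProbabilisticNetwork:
    """Keep edges with probability strictly above ``theta`` as certain edges."""
    if not (0.0 <= theta < 1.0):
        raise ValueError(f"theta must lie in [0, 1), got {theta}")
    return ProbabilisticNetwork(
        nodes=net.nodes,
        edges=tuple((u, v, 1.0) for u, v, p in net.edges if p > theta),
    )


def sample_network(
    net: ProbabilisticNetwork, seed: int | np.random.Generator
) -> ProbabilisticNetwork:
    """One Bernoulli realization: keep each edge independently with its probability."""
    rng = np.random.default_rng(seed)
    draws = rng.random(net.n_edges)
    return ProbabilisticNetwork(
        nodes=net.nodes,
        edges=tuple(
            (u, v, 1.0)
            for (u, v, p), r in zip(net.edges, draws)
            if r < p
        ),
    )


def deterministic_count(
    g: ProbabilisticNetwork,
    motif: MotifPattern,
    measure: Measure = "F2",
) -> tuple[tuple[int, ...], int]:
    """Least-overlap greedy count on a deterministic network.

    Repeatedly picks the embedding with the fewest overlapping embeddings
    among the survivors (ties to the lowest id), removes it with its
    neighbours, and returns the chosen ids and their number.
    """
    embeds = enumerate_embeddings(g, motif)
    og = build_overlap_graph(embeds, measure)
    work = og.graph.copy()
    chosen: list[int] = []
    while work.number_of_nodes() > 0:
        k = min(work.nodes, key=lambda n: (work.degree(n), n))
        chosen.append(k)
        work.remove_nodes_from([k] + list(work.neighbors(k)))
    return tuple(chosen), len(chosen)


def sampling_count(
    net: ProbabilisticNetwork,
    motif: MotifPattern,
    measure: Measure = "F2",
    n_runs: int = 10,
    seed: int | np.random.Generator = 0,
) -> float:
    """Average least-overlap count over Bernoulli realizations of the network."""
    if n_runs < 1:
        raise ValueError("n_runs must be positive")
    seeds = np.random.SeedSequence(
        seed if isinstance(seed, int) else seed.integers(2**31)
    ).spawn(n_runs)
    counts = []
    for s in seeds:
        sampled = sample_network(net, np.random.default_rng(s))
        _, c = deterministic_count(sampled, motif, measure)
        counts.append(c)
    return float(np.mean(counts))
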