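"""Exhaustive references for small inputs.

A probabilistic network with ``|E|`` edges summarizes ``2^|E|`` deterministic
instances (possible worlds); the mass of a world is the product of ``p_i``
over present edges times ``q_i`` over absent ones.  These enumerators give
exact answers on small inputs and exist to validate the polynomial engine
and the greedy selection — hard size guards raise instead of running for
hours.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

from .motifs import (
    BipartiteGraph,
    Embedding,
    Measure,
    build_overlap_graph,
    enumerate_embeddings,
)
from .netio import MotifPattern, ProbabilisticNetwork
from .polyengine import BDistribution

__all__ = [
    "DeterministicInstance",
    "enum_deterministic",
    "expected_count_given_set",
    "exact_b_distribution",
    "exact_def1_solution",
    "best_independent_set",
]

MAX_ENUM_EDGES = 20
MAX_ENUM_V2 = 16
MAX_ENUM_EMBEDDINGS = 20


@dataclass(frozen=True)
class DeterministicInstance:
    """One possible world: which edges are present, and its probability mass."""

    present: tuple[bool, ...]
    mass: float


def enum_deterministic(
    net: ProbabilisticNetwork,
) -> Iterator[DeterministicInstance]:
    """Yield all 2^|E| deterministic instances with exact masses."""
    m = net.n_edges
    if m > MAX_ENUM_EDGES:
        raise ValueError(
            f"network has {m} edges; exhaustive enumeration is guarded "
            f"at {MAX_ENUM_EDGES}"
        )
    probs = net.probabilities()
    for bits in product((True, False), repeat=m):
        mass = 1.0
        for present, p in zip(bits, probs):
            mass *= p if present else (1.0 - p)
        yield DeterministicInstance(present=bits, mass=mass)


def expected_count_given_set(
    net: ProbabilisticNetwork, chosen: Iterable[Embedding]
) -> float:
    """Exact expected number of chosen embeddings present across all worlds.

    Sums, over every deterministic instance, the number of chosen
    embeddings whose edges are all present, weighted by the instance mass.
    By linearity of expectation this equals the sum of the embeddings'
    gains, which is what the identity tests assert.
    """
    chosen = list(chosen)
    total = 0.0
    for inst in enum_deterministic(net):
        count = sum(
            1 for e in chosen if all(inst.present[i] for i in e.edge_ids)
        )
        total += count * inst.mass
    return total


def exact_b_distribution(bg: BipartiteGraph) -> BDistribution:
    """Exact distribution of B_k by enumerating the 2^|V2| edge outcomes.

    An overlapping embedding exists in an outcome iff all of its V2-linked
    edges are present (its edges shared with the focal embedding are not in
    V2 and count as present).
    """
    v2 = list(bg.v2)
    if len(v2) > MAX_ENUM_V2:
        raise ValueError(
            f"|V2| = {len(v2)} exceeds the enumeration guard {MAX_ENUM_V2}"
        )
    needs = {i: set(bg.var_edges(i)) for i in bg.v1}
    probs = np.zeros(len(bg.v1) + 1)
    for bits in product((True, False), repeat=len(v2)):
        present = {j for j, b in zip(v2, bits) if b}
        mass = 1.0
        for j, b in zip(v2, bits):
            p = bg.edge_probs[j]
            mass *= p if b else (1.0 - p)
        count = sum(1 for i in bg.v1 if needs[i] <= present)
        probs[count] += mass
    return BDistribution(probs=probs, complete=True)


def best_independent_set(
    graph: nx.Graph, gains: dict[int, float]
) -> tuple[tuple[int, ...], float]:
    """Maximum-total-gain independent set of a small overlap graph.

    Enumerates maximal independent sets (gains are positive, so some
    maximal set attains the optimum); ties broken lexicographically on the
    sorted id tuple.
    """
    if graph.number_of_nodes() > MAX_ENUM_EMBEDDINGS:
        raise ValueError(
            f"{graph.number_of_nodes()} embeddings exceed the enumeration "
            f"guard {MAX_ENUM_EMBEDDINGS}"
        )
    if graph.number_of_nodes() == 0:
        return (), 0.0
    complement = nx.complement(graph)
    complement.add_nodes_from(graph.nodes)
    best: tuple[int, ...] | None = None
    best_value = -1.0
    for clique in nx.find_cliques(complement):
        ids = tuple(sorted(clique))
        value = sum(gains[i] for i in ids)
        if value > best_value or (value == best_value and ids < best):
            best, best_value = ids, value
    return best, best_value


def exact_def1_solution(
    net: ProbabilisticNetwork,
    motif: MotifPattern,
    measure: Measure = "F2",
) -> tuple[tuple[int, ...], float]:
    """Exact optimum of the maximum-expected-count independent embedding set.

    Enumerates independent sets of the overlap graph; the objective of a
    set is the sum of its embeddings' gains (exact by linearity of
    expectation).  Returns ``(embedding ids, value)``.
    """
    embeds = enumerate_embeddings(net, motif)
    og = build_overlap_graph(embeds, measure)
    gains = {e.id: e.gain for e in embeds}
    return best_independent_set(og.graph, gains)
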