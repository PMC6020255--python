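"""Motif embedding enumeration, overlap graphs and per-embedding bipartite graphs.

An *embedding* of a motif ``M`` in a network is a subset of network edges
whose subgraph is isomorphic to ``M``.  Embedding identity is the edge set:
automorphic relabelings collapse to a single embedding.  The probability
that an embedding exists — the product of its edge probabilities — is its
*gain* ``a_k``.

Two embeddings *overlap* under the F2 measure when they share an edge, and
under the stricter F3 measure when they share a node.  The *overlap graph*
has one node per embedding with adjacency given by the chosen measure, so
independent (non-overlapping) embedding sets are exactly its independent
sets.

For a focal embedding ``H_k`` the *bipartite graph* ``G_k = (V1, V2, E)``
pairs its overlapping embeddings (V1, one polynomial variable ``x_i`` each)
with the network edges those embeddings need beyond ``H_k``'s own edges
(V2, one edge polynomial each).  It is the input to the polynomial engine
that computes the distribution of the number ``B_k`` of overlapping
embeddings that materialize.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Literal, Mapping, Sequence

import networkx as nx
from networkx.algorithms import isomorphism

from .netio import MotifPattern, ProbabilisticNetwork

__all__ = [
    "Embedding",
    "OverlapGraph",
    "BipartiteGraph",
    "enumerate_embeddings",
    "build_overlap_graph",
    "build_bipartite",
]

Measure = Literal["F2", "F3"]


@dataclass(frozen=True)
class Embedding:
    """One occurrence of the motif: node set, edge-id set and gain a_k."""

    id: int
    node_set: frozenset[str]
    edge_ids: frozenset[int]
    gain: float

    def __post_init__(self) -> None:
        if not (0.0 < self.gain <= 1.0):
            raise ValueError(f"gain must lie in (0, 1], got {self.gain}")


@dataclass(frozen=True)
class OverlapGraph:
    """Embeddings as nodes; adjacency per the F2 (edge) or F3 (node) measure."""

    graph: nx.Graph
    measure: Measure

    def neighbors(self, embedding_id: int) -> list[int]:
        return sorted(self.graph.neighbors(embedding_id))

    def degree(self, embedding_id: int) -> int:
        return self.graph.degree(embedding_id)

    @property
    def embedding_ids(self) -> list[int]:
        return sorted(self.graph.nodes)


@dataclass(frozen=True)
class BipartiteGraph:
    """G_k = (V1, V2, E) for a focal embedding H_k.

    ``v1`` lists the overlapping embedding ids (variables x_i), ``v2`` the
    network edge ids those embeddings need beyond the focal embedding's own
    edges, ``links[j]`` the V1 members containing edge j, ``degrees[i]`` the
    number of V2 edges embedding i needs (deg(v_i | G_k)) and
    ``edge_probs[j]`` the existence probability of edge j.
    """

    v1: tuple[int, ...]
    v2: tuple[int, ...]
    links: Mapping[int, tuple[int, ...]]
    degrees: Mapping[int, int]
    edge_probs: Mapping[int, float]
    focal_id: int | None = None

    @classmethod
    def build(
        cls,
        v1: Sequence[int],
        v2: Sequence[int],
        links: Mapping[int, Sequence[int]],
        edge_probs: Mapping[int, float],
        focal_id: int | None = None,
    ) -> "BipartiteGraph":
        v1 = tuple(sorted(v1))
        v2 = tuple(sorted(v2))
        links_t = {j: tuple(sorted(links.get(j, ()))) for j in v2}
        degrees = {i: 0 for i in v1}
        for j in v2:
            for i in links_t[j]:
                if i not in degrees:
                    raise ValueError(f"link refers to unknown V1 node {i}")
                degrees[i] += 1
        probs = {j: float(edge_probs[j]) for j in v2}
        for j, p in probs.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"edge {j} probability out of range: {p}")
        return cls(
            v1=v1, v2=v2, links=links_t, degrees=degrees,
            edge_probs=probs, focal_id=focal_id,
        )

    def var_edges(self, var_id: int) -> tuple[int, ...]:
        """V2 edges linked to a given V1 variable."""
        return tuple(j for j in self.v2 if var_id in self.links[j])

    @property
    def n_links(self) -> int:
        return sum(len(v) for v in self.links.values())


def enumerate_embeddings(
    net: ProbabilisticNetwork, motif: MotifPattern
) -> list[Embedding]:
    """Enumerate all embeddings of ``motif`` in the deterministic skeleton.

    Returns one :class:`Embedding` per distinct edge subset of G' isomorphic
    to the motif, with deterministic ids assigned by sorted edge-id tuple.
    """
    skeleton = net.to_graph()
    if motif.n_nodes > net.n_nodes or motif.n_edges > net.n_edges:
        return []
    pattern = motif.to_graph()
    matcher = isomorphism.GraphMatcher(skeleton, pattern)
    edge_sets: set[frozenset[int]] = set()
    for mapping in matcher.subgraph_monomorphisms_iter():
        inv = {pv: gv for gv, pv in mapping.items()}
        ids = frozenset(
            skeleton[inv[a]][inv[b]]["edge_id"] for a, b in motif.edges
        )
        edge_sets.add(ids)
    embeddings = []
    for k, ids in enumerate(sorted(edge_sets, key=lambda s: tuple(sorted(s)))):
        nodes = frozenset(
            n for i in ids for n in (net.edges[i][0], net.edges[i][1])
        )
        gain = prod(net.edges[i][2] for i in ids)
        embeddings.append(
            Embedding(id=k, node_set=nodes, edge_ids=ids, gain=gain)
        )
    return embeddings


def build_overlap_graph(
    embeds: Sequence[Embedding], measure: Measure = "F2"
) -> OverlapGraph:
    """Build the overlap graph under the F2 (shared edge) or F3 (shared node) measure."""
    if measure not in ("F2", "F3"):
        raise ValueError(f"measure must be 'F2' or 'F3', got {measure!r}")
    g = nx.Graph()
    g.add_nodes_from(e.id for e in embeds)
    for a_pos, ea in enumerate(embeds):
        for eb in embeds[a_pos + 1:]:
            if measure == "F2":
                adjacent = bool(ea.edge_ids & eb.edge_ids)
            else:
                adjacent = bool(ea.node_set & eb.node_set)
            if adjacent:
                g.add_edge(ea.id, eb.id)
    return OverlapGraph(graph=g, measure=measure)


def build_bipartite(
    focal: Embedding,
    og: OverlapGraph,
    net: ProbabilisticNetwork,
    embeds: Sequence[Embedding] | Mapping[int, Embedding],
) -> BipartiteGraph:
    """Build G_k for a focal embedding from the overlap graph.

    V1 holds the focal embedding's overlap-graph neighbours; V2 the union of
    their edges minus the focal embedding's own edges (edge existence is
    edge-driven under both measures, so V2 is built from edges for F3 too).
    """
    if isinstance(embeds, Mapping):
        by_id = embeds
    else:
        by_id = {e.id: e for e in embeds}
    v1 = og.neighbors(focal.id)
    v2: set[int] = set()
    for i in v1:
        v2 |= by_id[i].edge_ids
    v2 -= focal.edge_ids
    links = {
        j: [i for i in v1 if j in by_id[i].edge_ids] for j in v2
    }
    probs = {j: net.probability(j) for j in v2}
    return BipartiteGraph.build(
        v1=v1, v2=sorted(v2), links=links, edge_probs=probs,
        focal_id=focal.id,
    )
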