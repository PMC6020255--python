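"""Reading and writing probabilistic networks and motif patterns.

A probabilistic network is an undirected graph ``G = (V, E, P)`` in which
every edge ``e_i`` exists independently with probability ``p_i = P(e_i)``
in ``(0, 1]``.  The on-disk dialect is a plain 3-column whitespace-separated
edge list (``u  v  p``) with ``#`` comment lines; node labels are arbitrary
strings.  Edges with ``p = 1`` are allowed and treated as deterministic.

The module also ships the catalog of the four small motif patterns used
throughout: the 2-edge path (M1), the triangle (M2), the 3-edge star (M3)
and the 3-edge path (M4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "ProbabilisticNetwork",
    "MotifPattern",
    "read_network",
    "write_network",
    "motif_catalog",
    "MOTIF_NAMES",
]

MAX_MOTIF_EDGES = 5


class NetworkFormatError(ValueError):
    """Raised for malformed probabilistic edge-list input."""


def _canon(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class ProbabilisticNetwork:
    """Undirected graph with an independent existence probability per edge.

    ``edges[i]`` is ``(u, v, p)`` and ``i`` is the stable dense edge id.
    """

    nodes: frozenset[str]
    edges: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        node_set = set()
        for u, v, p in self.edges:
            if u == v:
                raise NetworkFormatError(f"self-loop on node {u!r}")
            if not (0.0 < p <= 1.0):
                raise NetworkFormatError(
                    f"probability out of range for edge ({u!r}, {v!r}): {p}"
                )
            key = _canon(u, v)
            if key in seen:
                raise NetworkFormatError(f"duplicate edge {key}")
            seen.add(key)
            node_set.update(key)
        if not node_set <= set(self.nodes):
            raise NetworkFormatError("edge endpoints missing from node set")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "ProbabilisticNetwork":
        edges = tuple((str(u), str(v), float(p)) for u, v, p in edges)
        nodes = {n for u, v, _ in edges for n in (u, v)} | set(extra_nodes)
        return cls(nodes=frozenset(nodes), edges=edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def probability(self, edge_id: int) -> float:
        return self.edges[edge_id][2]

    def probabilities(self) -> list[float]:
        return [p for _, _, p in self.edges]

    def is_deterministic(self) -> bool:
        return all(p == 1.0 for _, _, p in self.edges)

    def to_graph(self) -> nx.Graph:
        """Deterministic skeleton G' = (V, E) with `edge_id`/`p` attributes."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, (u, v, p) in enumerate(self.edges):
            g.add_edge(u, v, edge_id=i, p=p)
        return g


@dataclass(frozen=True)
class MotifPattern:
    """A small connected undirected pattern graph on integer nodes."""

    edges: tuple[tuple[int, int], ...]
    name: str = "custom"
    nodes: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        if not (2 <= len(self.edges) <= MAX_MOTIF_EDGES):
            raise ValueError(
                f"motif must have between 2 and {MAX_MOTIF_EDGES} edges"
            )
        g = self.to_graph()
        if not nx.is_connected(g):
            raise ValueError("motif pattern must be connected")
        object.__setattr__(self, "nodes", frozenset(g.nodes))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for u, v in self.edges:
            if u == v:
                raise ValueError("motif pattern may not contain self-loops")
            g.add_edge(u, v)
        return g


# The two- and three-edge patterns: path of length 2, triangle (loop),
# 3-star, path of length 3.  M1 is a subgraph of each of M2, M3 and M4.
_CATALOG: dict[str, tuple[tuple[int, int], ...]] = {
    "M1": ((0, 1), (1, 2)),
    "M2": ((0, 1), (1, 2), (2, 0)),
    "M3": ((0, 1), (0, 2), (0, 3)),
    "M4": ((0, 1), (1, 2), (2, 3)),
}

MOTIF_NAMES = tuple(_CATALOG)


def motif_catalog(name: str) -> MotifPattern:
    """Return one of the built-in motif patterns M1..M4."""
    key = name.upper()
    if key not in _CATALOG:
        raise KeyError(f"unknown motif {name!r}; choose from {MOTIF_NAMES}")
    return MotifPattern(edges=_CATALOG[key], name=key)


def read_network(path: str | Path) -> ProbabilisticNetwork:
    """Read a probabilistic network from a 3-column edge list.

    Lines are ``u v p`` separated by whitespace; ``#`` starts a comment.
    Duplicate edges with an identical probability are collapsed with a
    warning; a conflicting probability is an error.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    index: dict[tuple[str, str], float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 'u v p', got {raw!r}"
            )
        u, v, ptxt = parts
        try:
            p = float(ptxt)
        except ValueError as exc:
            raise NetworkFormatError(
                f"{path}:{lineno}: bad probability {ptxt!r}"
            ) from exc
        if not (0.0 < p <= 1.0):
            raise NetworkFormatError(
                f"{path}:{lineno}: probability out of range: {p}"
            )
        if u == v:
            raise NetworkFormatError(f"{path}:{lineno}: self-loop on {u!r}")
        key = _canon(u, v)
        if key in index:
            if index[key] != p:
                raise NetworkFormatError(
                    f"{path}:{lineno}: duplicate edge {key} with "
                    f"conflicting probability {p} != {index[key]}"
                )
            warnings.warn(f"{path}:{lineno}: duplicate edge {key} ignored")
            continue
        index[key] = p
        edges.append((u, v, p))
    return ProbabilisticNetwork.from_edges(edges)


def write_network(net: ProbabilisticNetwork, path: str | Path) -> None:
    """Write a network in the edge-list dialect, sorted by edge id.

    Probabilities are printed with 17 significant digits so that a
    read/write round trip is exact.
    """
    path = Path(path)
    lines = ["# probabilistic edge list: u v p"]
    for u, v, p in net.edges:
        lines.append(f"{u}\t{v}\t{p:.17g}")
    path.write_text("\n".join(lines) + "\n")


def export_deterministic(net: ProbabilisticNetwork, path: str | Path) -> None:
    """Export the deterministic skeleton as a 2-column edge list."""
    path = Path(path)
    lines = ["# deterministic edge list: u v"]
    for u, v, _ in net.edges:
        lines.append(f"{u}\t{v}")
    path.write_text("\n".join(lines) + "\n")


def read_motif(path: str | Path) -> MotifPattern:
    """Read a custom motif as a 2-column integer edge list."""
    path = Path(path)
    edges = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        u, v = line.split()[:2]
        edges.append((int(u), int(v)))
    return MotifPattern(edges=tuple(edges), name=path.stem)
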