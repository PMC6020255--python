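"""Synthetic probabilistic network generation.

Random topologies come from three classic models — Erdős–Rényi (ER),
Watts–Strogatz (WS) and Barabási–Albert (BA) — parameterized through a
target average node degree (default 2).  Each edge then receives an
independent existence probability drawn uniformly from the open interval
(0, 1).  Replicate suites derive per-replicate seeds from a master seed
and aggregate with a trimmed mean/min/max that drops a fixed number of
extremes at each end (default suite: 20 replicates, trim 2).

Parameterization for a target average degree ``d`` on ``n`` nodes:
ER edge probability ``d/(n-1)``; WS ring-lattice neighbours ``k =
round(d)`` with rewiring probability 0.1; BA attachment ``m = max(1,
round(d/2))``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import networkx as nx
import numpy as np

from .netio import ProbabilisticNetwork

__all__ = [
    "GeneratorConfig",
    "generate",
    "replicate_suite",
    "trimmed_aggregate",
]

Model = Literal["ER", "WS", "BA"]

DEFAULT_AVG_DEGREE = 2.0
DEFAULT_WS_REWIRE = 0.1


@dataclass(frozen=True)
class GeneratorConfig:
    """Topology model, size, target average degree and seed."""

    model: Model
    n_nodes: int
    avg_degree: float = DEFAULT_AVG_DEGREE
    ws_rewire_prob: float = DEFAULT_WS_REWIRE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("ER", "WS", "BA"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if self.avg_degree <= 0:
            raise ValueError("avg_degree must be positive")
        if not (0.0 <= self.ws_rewire_prob <= 1.0):
            raise ValueError("ws_rewire_prob must lie in [0, 1]")
        if self.model == "BA" and self._ba_m() >= self.n_nodes:
            raise ValueError("BA attachment count must be below n_nodes")
        if self.model == "WS" and self._ws_k() >= self.n_nodes:
            raise ValueError("WS neighbour count must be below n_nodes")

    def _ba_m(self) -> int:
        return max(1, round(self.avg_degree / 2))

    def _ws_k(self) -> int:
        return max(2, round(self.avg_degree))


def _topology(config: GeneratorConfig, seed: int) -> nx.Graph:
    n = config.n_nodes
    if config.model == "ER":
        p = min(1.0, config.avg_degree / (n - 1))
        return nx.gnp_random_graph(n, p, seed=seed)
    if config.model == "WS":
        return nx.watts_strogatz_graph(
            n, config._ws_k(), config.ws_rewire_prob, seed=seed
        )
    return nx.barabasi_albert_graph(n, config._ba_m(), seed=seed)


def generate(config: GeneratorConfig) -> ProbabilisticNetwork:
    """Draw a topology from the configured model and assign uniform(0,1) edge probabilities."""
    ss = np.random.SeedSequence(config.seed)
    topo_seed_seq, prob_seed_seq = ss.spawn(2)
    topo_seed = int(topo_seed_seq.generate_state(1)[0] % (2**31))
    g = _topology(config, topo_seed)
    rng = np.random.default_rng(prob_seed_seq)
    edges = []
    for u, v in sorted((min(a, b), max(a, b)) for a, b in g.edges):
        p = rng.random()
        while p == 0.0:  # keep probabilities strictly inside (0, 1)
            p = rng.random()
        edges.append((f"n{u}", f"n{v}", p))
    return ProbabilisticNetwork.from_edges(
        edges, extra_nodes=(f"n{u}" for u in g.nodes)
    )


def replicate_suite(
    config: GeneratorConfig, n_replicates: int = 20, trim: int = 2
) -> tuple[list[ProbabilisticNetwork], Callable[[Sequence[float]], dict]]:
    """Generate a replicate suite plus its trimmed aggregation rule.

    Per-replicate seeds derive deterministically from the master seed.
    Returns the networks and a function aggregating one value per replicate
    into trimmed mean/min/max (dropping ``trim`` extremes at each end).
    """
    if trim < 0:
        raise ValueError("trim must be nonnegative")
    if n_replicates <= 2 * trim:
        raise ValueError("n_replicates must exceed 2 * trim")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(
        n_replicates
    )
    nets = [
        generate(replace(config, seed=int(s % (2**31))))
        for s in child_seeds
    ]

    def aggregate(values: Sequence[float]) -> dict:
        return trimmed_aggregate(values, trim)

    return nets, aggregate


def trimmed_aggregate(values: Sequence[float], trim: int) -> dict:
    """Mean/min/max after dropping ``trim`` smallest and ``trim`` largest values."""
    values = sorted(float(v) for v in values)
    if len(values) <= 2 * trim:
        raise ValueError("too few values for the requested trim")
    kept = values[trim:len(values) - trim] if trim else values
    return {
        "mean": float(np.mean(kept)),
        "min": float(min(kept)),
        "max": float(max(kept)),
        "n_kept": len(kept),
    }
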