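"""Greedy selection of a maximum-expected-count independent embedding set.

Each embedding ``H_k`` carries a gain ``a_k`` (its existence probability),
a loss ``f(B_k) = 1 + Exp(B_k)`` penalizing its expected number of existing
overlapping embeddings, and a priority ``rho_k = a_k / f(B_k)``.  The
driver repeatedly picks the highest-priority embedding, adds its gain to
the running expected count, and removes it with its overlap-graph
neighbours until no embedding remains.  The chosen set is independent by
construction and its expected count is the exact objective value for that
set (linearity of expectation).

Three optional accelerations, none of which changes the selected set:

* **Early termination** — candidates are visited in descending proxy order
  ``Q_k = a_k / deg(H_k)``; while a candidate's polynomial product streams,
  prefix distributions give monotonically shrinking upper bounds
  ``rho_k^j`` on its priority, and the product is aborted as soon as the
  bound drops strictly below the best exact priority seen.
* **Greedy polynomial ordering** — the V2 ordering of the engine.
* **Memory-bounded products** — a term budget for the engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .motifs import (
    BipartiteGraph,
    Embedding,
    Measure,
    OverlapGraph,
    build_bipartite,
    build_overlap_graph,
    enumerate_embeddings,
)
from .netio import MotifPattern, ProbabilisticNetwork
from .polyengine import (
    BDistribution,
    CostReport,
    multiply_collapse,
    multiply_collapse_bounded,
    order_polynomials,
)

__all__ = [
    "Strategies",
    "PriorityRecord",
    "SelectionResult",
    "loss",
    "priority",
    "proxy_order",
    "best_embedding",
    "count_independent",
]


@dataclass(frozen=True)
class Strategies:
    """Toggles for the three accelerations; all affect cost only, never the result."""

    early_termination: bool = True
    greedy_order: bool = True
    max_terms: int | None = None


@dataclass(frozen=True)
class PriorityRecord:
    """Gain / loss / priority bookkeeping for one candidate embedding.

    ``exact`` is False when the candidate was pruned early; ``rho`` is then
    a valid upper bound on its exact priority.
    """

    embedding_id: int
    gain: float
    loss: float
    rho: float
    exact: bool
    proxy: float


@dataclass(frozen=True)
class SelectionResult:
    """The chosen independent embedding set and its expected motif count."""

    chosen: tuple[int, ...]
    expected_count: float
    gains: Mapping[int, float]
    trace: tuple[dict, ...] = ()


def loss(dist: BDistribution) -> float:
    """Loss f(B_k) = 1 + Exp(B_k).

    Any monotone transform of the prefix-monotone expectation keeps the
    early-termination bound valid; the +1 keeps the loss at 1 for isolated
    embeddings so priorities never divide by zero.
    """
    return 1.0 + dist.expectation()


def priority(gain: float, loss_value: float) -> float:
    """Priority rho = gain / loss; finite and at most the gain."""
    if not (0.0 < gain <= 1.0):
        raise ValueError(f"gain must lie in (0, 1], got {gain}")
    if loss_value < 1.0:
        raise ValueError(f"loss must be >= 1, got {loss_value}")
    return gain / loss_value


def proxy_order(
    embeds: Mapping[int, Embedding], og: OverlapGraph
) -> list[int]:
    """Candidate visiting order: descending Q_k = a_k / deg(H_k).

    Zero-degree (isolated) embeddings rank first; ties break on embedding
    id ascending.
    """
    def q(k: int) -> float:
        d = og.graph.degree(k)
        return float("inf") if d == 0 else embeds[k].gain / d

    return sorted(og.graph.nodes, key=lambda k: (-q(k), k))


def _candidate_distribution(
    bg: BipartiteGraph,
    gain: float,
    rho_star: float,
    strategies: Strategies,
) -> tuple[BDistribution, CostReport]:
    order = order_polynomials(bg) if strategies.greedy_order else None
    on_prefix = None
    if strategies.early_termination:
        def on_prefix(dist: BDistribution) -> bool:
            # rho upper bound from the prefix expectation (a lower bound on
            # the final expectation); strict comparison so ties survive.
            return gain / (1.0 + dist.expectation()) < rho_star
    if strategies.max_terms is not None:
        return multiply_collapse_bounded(
            bg, order, strategies.max_terms, on_prefix=on_prefix
        )
    return multiply_collapse(bg, order, on_prefix=on_prefix)


def best_embedding(
    og: OverlapGraph,
    embeds: Mapping[int, Embedding] | Sequence[Embedding],
    net: ProbabilisticNetwork,
    strategies: Strategies = Strategies(),
) -> tuple[int, PriorityRecord, dict]:
    """Select the highest-priority embedding among the overlap graph's nodes.

    Visits candidates in proxy order; with early termination enabled a
    candidate is abandoned once its priority bound falls strictly below the
    best exact priority so far.  The winner (highest exact rho, ties to the
    lowest id) is identical with and without early termination.
    """
    if isinstance(embeds, Mapping):
        by_id = embeds
    else:
        by_id = {e.id: e for e in embeds}
    ids = list(og.graph.nodes)
    if not ids:
        raise ValueError("overlap graph is empty")
    rho_star = float("-inf")
    best_id: int | None = None
    best_record: PriorityRecord | None = None
    pruned = 0
    reports: list[CostReport] = []
    for k in proxy_order(by_id, og):
        emb = by_id[k]
        d = og.graph.degree(k)
        proxy = float("inf") if d == 0 else emb.gain / d
        if d == 0:
            dist = BDistribution([1.0])
            report = None
        else:
            bg = build_bipartite(emb, og, net, by_id)
            dist, report = _candidate_distribution(
                bg, emb.gain, rho_star, strategies
            )
            reports.append(report)
        f = loss(dist)
        rho = priority(emb.gain, f)
        if not dist.complete:
            pruned += 1
            continue
        if rho > rho_star or (rho == rho_star and k < best_id):
            rho_star = rho
            best_id = k
            best_record = PriorityRecord(
                embedding_id=k, gain=emb.gain, loss=f, rho=rho,
                exact=True, proxy=proxy,
            )
    trace = {
        "rho_star": rho_star,
        "pruned": pruned,
        "n_candidates": len(ids),
        "cost_reports": [r.to_dict() for r in reports],
    }
    return best_id, best_record, trace


def count_independent(
    net: ProbabilisticNetwork,
    motif: MotifPattern,
    measure: Measure = "F2",
    strategies: Strategies = Strategies(),
    keep_trace: bool = True,
) -> SelectionResult:
    """Greedy maximum-expected-count independent embedding set.

    Embedding distributions are rebuilt from the surviving overlap graph at
    each iteration, so ``B_k`` always counts only embeddings that can still
    conflict with ``H_k``.
    """
    embeds = enumerate_embeddings(net, motif)
    og = build_overlap_graph(embeds, measure)
    by_id = {e.id: e for e in embeds}
    work = og.graph.copy()
    chosen: list[int] = []
    total = 0.0
    trace: list[dict] = []
    while work.number_of_nodes() > 0:
        current = OverlapGraph(graph=work, measure=measure)
        k, record, step = best_embedding(current, by_id, net, strategies)
        chosen.append(k)
        total += by_id[k].gain
        if keep_trace:
            step["picked"] = k
            step["rho"] = record.rho
            trace.append(step)
        doomed = [k] + list(work.neighbors(k))
        work.remove_nodes_from(doomed)
    return SelectionResult(
        chosen=tuple(chosen),
        expected_count=total,
        gains={k: by_id[k].gain for k in chosen},
        trace=tuple(trace),
    )
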