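"""The x-polynomial engine.

For a focal embedding ``H_k`` with bipartite graph ``G_k = (V1, V2, E)``,
each V2 edge ``e_j`` carries an *edge polynomial*

    Z_j = p_j * prod_{(v_i, v_j) in E} x_i  +  q_j,        q_j = 1 - p_j,

whose two branches model the presence and absence of the edge.  The
x-polynomial ``Z_{H_k} = prod_j Z_j`` enumerates the deterministic outcomes
of the V2 edges; a variable ``x_i`` reaching exponent ``deg(v_i | G_k)``
marks that all edges of neighbouring embedding ``H_i`` are present.  The
*collapse operator* for variable ``x_r`` removes it from a term and
multiplies the term by ``t`` exactly when its exponent equals the full
degree of ``v_r``.  Once every variable has collapsed, the coefficient of
``t^j`` is ``P(B_k = j)``: the distribution of the number of overlapping
embeddings of ``H_k`` that materialize.

The engine implements three orthogonal accelerations:

* **V1 pre-collapse** — a degree-1 variable is folded into a ``t`` power of
  its single edge polynomial before any multiplication (``Z_j = p_j t^{|V1,j|}
  prod x_i + q_j``).
* **V2 ordering** — a greedy ordering of the edge polynomials that collapses
  variables as early as possible, driven by the W/D contribution matrices.
* **Memory-bounded products** — multiplication of arbitrarily long products
  within a fixed term budget, deferring term batches on a LIFO stack.

Cost accounting counts collapse-operator applications term-wise against the
*unmerged* term count (which doubles with every two-branch multiplication):
the cost of a round is (unmerged terms after the multiplication) x (number
of variables collapsing in that round).  Like terms are merged after every
round for the actual computation; the unmerged count exists only so that
reported costs reflect the worst-case dense product.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .motifs import BipartiteGraph

__all__ = [
    "EdgePolynomial",
    "XTerm",
    "BDistribution",
    "CostReport",
    "make_edge_polynomial",
    "collapse_term",
    "ordering_matrices",
    "order_polynomials",
    "multiply_collapse",
    "multiply_collapse_bounded",
]

PrefixCallback = Callable[["BDistribution"], bool | None]


@dataclass(frozen=True)
class EdgePolynomial:
    """Z_j = p * t^pre_collapsed_t * prod(x_i for i in var_ids) + q."""

    edge_id: int
    p: float
    var_ids: tuple[int, ...]
    pre_collapsed_t: int = 0

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class XTerm:
    """One x-polynomial term: coeff * t^t_exp * prod(x_i^c_i)."""

    coeff: float
    t_exp: int = 0
    x_exps: Mapping[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class BDistribution:
    """Distribution of B_k, the number of existing overlapping embeddings.

    ``probs[j] = P(B_k = j)``.  ``complete`` is False when the distribution
    was taken from a prefix of the edge-polynomial product, in which case
    the expectation is a lower bound on the final expectation.
    """

    probs: np.ndarray
    complete: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "probs", np.asarray(self.probs, dtype=float)
        )

    def expectation(self) -> float:
        return float(np.arange(len(self.probs)) @ self.probs)

    def sf(self, tau: int) -> float:
        """P(B_k >= tau)."""
        if tau <= 0:
            return float(self.probs.sum())
        return float(self.probs[tau:].sum())

    def total(self) -> float:
        return float(self.probs.sum())


@dataclass(frozen=True)
class CostReport:
    """Collapse-cost accounting for one edge-polynomial product."""

    collapse_ops: int
    peak_terms: int
    order_used: tuple[int, ...]
    n_applied: int
    batch_size: int | None = None   # N1 of the memory-bounded product
    bound_respected: bool = True    # live terms stayed within (j+1)N1+N2

    def to_dict(self) -> dict:
        return {
            "collapse_ops": self.collapse_ops,
            "peak_terms": self.peak_terms,
            "order_used": list(self.order_used),
            "n_applied": self.n_applied,
            "batch_size": self.batch_size,
            "bound_respected": self.bound_respected,
        }


def make_edge_polynomial(
    bg: BipartiteGraph, edge_id: int, v1_precollapse: bool = True
) -> EdgePolynomial:
    """Build the edge polynomial of a V2 edge.

    With ``v1_precollapse`` enabled, every linked degree-1 variable is
    folded into a direct ``t`` power instead of appearing as an ``x``
    variable, since its only edge polynomial is this one.
    """
    if edge_id not in bg.links:
        raise KeyError(f"edge {edge_id} is not in V2")
    linked = bg.links[edge_id]
    if v1_precollapse:
        var_ids = tuple(i for i in linked if bg.degrees[i] > 1)
        pre_t = len(linked) - len(var_ids)
    else:
        var_ids = tuple(linked)
        pre_t = 0
    return EdgePolynomial(
        edge_id=edge_id, p=bg.edge_probs[edge_id],
        var_ids=var_ids, pre_collapsed_t=pre_t,
    )


def collapse_term(term: XTerm, var_id: int, degree: int) -> XTerm:
    """Apply the collapse operator for ``x_{var_id}`` to one term.

    Removes the variable; increments the ``t`` exponent exactly when the
    variable's exponent equals its full degree (all edges of the
    corresponding embedding present).  The coefficient never changes.
    """
    exps = dict(term.x_exps)
    c = exps.pop(var_id, 0)
    bump = 1 if c == degree else 0
    return XTerm(coeff=term.coeff, t_exp=term.t_exp + bump, x_exps=exps)


# ---------------------------------------------------------------------------
# V2 ordering: W/D matrices and greedy selection
# ---------------------------------------------------------------------------

def ordering_matrices(
    bg: BipartiteGraph,
    v1: Sequence[int] | None = None,
    v2: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int], list[int]]:
    """Build the W and D contribution matrices for the (residual) bipartite graph.

    ``W[r, s] = 1/deg(v_r)`` if variable ``v1[r]`` appears in edge
    polynomial ``v2[s]``, else 0, with degrees taken in the residual graph.
    ``D[r, s]`` (s = 1..maxdeg, stored at column s-1) is ``p_r`` times the
    number of entries of value ``1/s`` in W's column for edge ``v2[r]``.
    Returns ``(W, D, v1_order, v2_order)``.
    """
    v2_order = sorted(v2 if v2 is not None else bg.v2)
    if v1 is None:
        active = sorted({i for j in v2_order for i in bg.links[j]})
    else:
        active = sorted(v1)
    deg = {
        i: sum(1 for j in v2_order if i in bg.links[j]) for i in active
    }
    active = [i for i in active if deg[i] > 0]
    w = np.zeros((len(active), len(v2_order)))
    for r, i in enumerate(active):
        for s, j in enumerate(v2_order):
            if i in bg.links[j]:
                w[r, s] = 1.0 / deg[i]
    maxdeg = max(deg.values(), default=1)
    d = np.zeros((len(v2_order), maxdeg))
    for r, j in enumerate(v2_order):
        for s in range(1, maxdeg + 1):
            count = int(np.sum(np.isclose(w[:, r], 1.0 / s)))
            d[r, s - 1] = bg.edge_probs[j] * count
    return w, d, active, v2_order


def order_polynomials(bg: BipartiteGraph) -> tuple[int, ...]:
    """Greedy V2 ordering: at each step pick the edge collapsing most variables.

    Scans the D matrix columns left to right (column s holds contributions
    at level 1/s), keeping the rows with the current maximum and breaking
    remaining ties by the next column; a final tie goes to the lowest edge
    id so runs are reproducible.  The chosen edge is removed and degrees
    recomputed before the next pick.
    """
    remaining = list(sorted(bg.v2))
    order: list[int] = []
    while remaining:
        _, d, _, v2_order = ordering_matrices(bg, v2=remaining)
        candidates = list(range(len(v2_order)))
        for s in range(d.shape[1]):
            col = d[candidates, s]
            best = col.max()
            narrowed = [r for r, val in zip(candidates, col) if val == best]
            candidates = narrowed
            if len(candidates) == 1:
                break
        pick = min(v2_order[r] for r in candidates)
        order.append(pick)
        remaining.remove(pick)
    return tuple(order)


# ---------------------------------------------------------------------------
# Products with collapse-as-you-go
# ---------------------------------------------------------------------------

TermKey = tuple[int, frozenset]


def _collapse_schedule(
    polys: Sequence[EdgePolynomial],
) -> list[tuple[int, ...]]:
    """For each position, the variables whose final polynomial is at that position."""
    last_seen: dict[int, int] = {}
    for idx, poly in enumerate(polys):
        for v in poly.var_ids:
            last_seen[v] = idx
    due: list[list[int]] = [[] for _ in polys]
    for v, idx in last_seen.items():
        due[idx].append(v)
    return [tuple(sorted(d)) for d in due]


def _multiply_batch(
    terms: dict[TermKey, float],
    poly: EdgePolynomial,
    due: tuple[int, ...],
    degrees: Mapping[int, int],
) -> dict[TermKey, float]:
    """Multiply a term batch by one edge polynomial, then collapse due variables."""
    out: dict[TermKey, float] = {}
    due_set = set(due)
    for (t, xs), coeff in terms.items():
        # presence branch
        xs_d = dict(xs)
        for v in poly.var_ids:
            xs_d[v] = xs_d.get(v, 0) + 1
        t_b = t + poly.pre_collapsed_t
        for branch_t, branch_xs, branch_coeff in (
            (t_b, xs_d, coeff * poly.p),
            (t, dict(xs), coeff * poly.q),
        ):
            if branch_coeff == 0.0:
                continue
            if due_set:
                for v in due:
                    c = branch_xs.pop(v, 0)
                    if c == degrees[v]:
                        branch_t += 1
            key = (branch_t, frozenset(branch_xs.items()))
            out[key] = out.get(key, 0.0) + branch_coeff
    return out


def _marginal(terms: Mapping[TermKey, float], size: int) -> np.ndarray:
    probs = np.zeros(size + 1)
    for (t, _), coeff in terms.items():
        probs[t] += coeff
    return probs


def _resolve_order(
    bg: BipartiteGraph, order: Sequence[int] | None
) -> tuple[int, ...]:
    if order is None:
        return tuple(sorted(bg.v2))
    order = tuple(order)
    if sorted(order) != sorted(bg.v2):
        raise ValueError("order must be a permutation of V2")
    return order


def multiply_collapse(
    bg: BipartiteGraph,
    order: Sequence[int] | None = None,
    *,
    v1_precollapse: bool = True,
    on_prefix: PrefixCallback | None = None,
) -> tuple[BDistribution, CostReport]:
    """Multiply all edge polynomials in ``order``, collapsing as soon as possible.

    A variable collapses in the round in which its final containing
    polynomial has been multiplied.  ``on_prefix`` is invoked after every
    round with the marginal distribution of the current ``t`` exponent — a
    valid prefix distribution of ``B_k`` whose expectation only grows with
    further rounds; returning a truthy value aborts the product (early
    termination), yielding an incomplete distribution.
    """
    order = _resolve_order(bg, order)
    polys = [make_edge_polynomial(bg, e, v1_precollapse) for e in order]
    due_at = _collapse_schedule(polys)
    degrees = bg.degrees
    size = len(bg.v1)

    terms: dict[TermKey, float] = {(0, frozenset()): 1.0}
    unmerged = 1
    cost = 0
    peak = 1
    for idx, poly in enumerate(polys):
        terms = _multiply_batch(terms, poly, due_at[idx], degrees)
        unmerged *= 2 if poly.q > 0.0 else 1
        cost += unmerged * len(due_at[idx])
        peak = max(peak, len(terms))
        if on_prefix is not None:
            dist = BDistribution(
                _marginal(terms, size), complete=(idx == len(polys) - 1)
            )
            if on_prefix(dist) and idx < len(polys) - 1:
                report = CostReport(cost, peak, order, idx + 1)
                return replace(dist, complete=False), report
    dist = BDistribution(_marginal(terms, size), complete=True)
    report = CostReport(cost, peak, order, len(polys))
    return dist, report


def multiply_collapse_bounded(
    bg: BipartiteGraph,
    order: Sequence[int] | None = None,
    max_terms: int | float | None = None,
    *,
    v1_precollapse: bool = True,
    on_prefix: PrefixCallback | None = None,
) -> tuple[BDistribution, CostReport]:
    """Memory-bounded edge-polynomial product.

    Each round multiplies the next edge polynomial with an active batch of
    at most ``N1 = max(1, max_terms // (|V2|+1))`` terms, deferring surplus
    terms on a last-in-first-out stack tagged with the next unapplied
    polynomial; deferred batches are completed after the main pass.  The
    live term count after ``j`` polynomials stays within ``(j+1)*N1 + N2``
    (``N2 = max_terms - N1``) for adequate budgets, and the final
    distribution is identical to the unbounded product.

    With ``max_terms`` None or infinite this delegates to
    :func:`multiply_collapse` (identical report and distribution).

    ``on_prefix`` receives the marginal of the ``t`` exponent over *all*
    live and finished terms after each multiplication; because total
    probability mass is conserved and ``t`` exponents only grow, its
    expectation is still a valid lower bound on the final ``Exp(B_k)``.
    """
    if max_terms is None or max_terms == float("inf"):
        return multiply_collapse(
            bg, order, v1_precollapse=v1_precollapse, on_prefix=on_prefix
        )
    max_terms = int(max_terms)
    if max_terms < 2:
        raise ValueError("max_terms must be at least 2 (one bifurcation)")
    order = _resolve_order(bg, order)
    polys = [make_edge_polynomial(bg, e, v1_precollapse) for e in order]
    due_at = _collapse_schedule(polys)
    degrees = bg.degrees
    size = len(bg.v1)
    n = len(order)
    n1 = max(1, max_terms // (n + 1))
    n2 = max_terms - n1

    done: dict[TermKey, float] = {}
    stack: list[tuple[dict[TermKey, float], int]] = []
    cost = 0
    peak = 1
    bound_ok = True

    def live_count(active: dict) -> int:
        # in-progress working set; `done` holds fully collapsed output terms
        # (at most |V1|+1 of them, the distribution itself)
        return len(active) + sum(len(b) for b, _ in stack)

    if n == 0:
        dist = BDistribution(_marginal({(0, frozenset()): 1.0}, size))
        return dist, CostReport(0, 1, order, 0, batch_size=n1)

    stack.append(({(0, frozenset()): 1.0}, 0))
    aborted = False
    while stack:
        batch, idx = stack.pop()
        while idx < n:
            if len(batch) > n1:
                items = sorted(batch.items())
                batch = dict(items[:n1])
                stack.append((dict(items[n1:]), idx))
            batch = _multiply_batch(batch, polys[idx], due_at[idx], degrees)
            cost += len(batch) * len(due_at[idx])
            idx += 1
            live = live_count(batch)
            peak = max(peak, live)
            if live > (idx + 1) * n1 + n2:
                bound_ok = False
            if on_prefix is not None:
                probs = _marginal(done, size) + _marginal(batch, size)
                for b, _ in stack:
                    probs += _marginal(b, size)
                complete = idx == n and not stack
                if on_prefix(BDistribution(probs, complete=complete)):
                    if not complete:
                        aborted = True
                        break
        if aborted:
            for key, coeff in batch.items():
                done[key] = done.get(key, 0.0) + coeff
            for b, _ in stack:
                for key, coeff in b.items():
                    done[key] = done.get(key, 0.0) + coeff
            report = CostReport(
                cost, peak, order, idx, batch_size=n1,
                bound_respected=bound_ok,
            )
            return (
                BDistribution(_marginal(done, size), complete=False),
                report,
            )
        for key, coeff in batch.items():
            done[key] = done.get(key, 0.0) + coeff
    dist = BDistribution(_marginal(done, size), complete=True)
    report = CostReport(
        cost, peak, order, n, batch_size=n1, bound_respected=bound_ok
    )
    return dist, report
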