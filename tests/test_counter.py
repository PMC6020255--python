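import numpy as np
import pytest

from promote import (
    BDistribution,
    ProbabilisticNetwork,
    Strategies,
    best_embedding,
    build_overlap_graph,
    count_independent,
    enumerate_embeddings,
    loss,
    motif_catalog,
    multiply_collapse,
    priority,
    proxy_order,
)
from promote.baselines import deterministic_count
from promote.oracle import (
    exact_b_distribution,
    exact_def1_solution,
    expected_count_given_set,
)
from promote.motifs import build_bipartite

from conftest import random_bipartite, random_small_network


class TestLossAndPriority:
    def test_point_mass_at_zero_gives_unit_loss(self):
        assert loss(BDistribution([1.0])) == 1.0

    def test_expectation_plus_one(self):
        assert loss(BDistribution([0.5, 0.0, 0.5])) == 2.0

    def test_loss_matches_brute_force_expectation(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            bg = random_bipartite(rng, max_v2=6)
            dist, _ = multiply_collapse(bg)
            exact = exact_b_distribution(bg)
            assert loss(dist) == pytest.approx(loss(exact), abs=1e-12)

    def test_isolated_embedding_priority_is_its_gain(self):
        assert priority(0.8, 1.0) == 0.8

    def test_priority_linear_in_gain(self):
        assert priority(0.4, 2.5) == pytest.approx(priority(0.8, 2.5) / 2)

    def test_priority_validates_inputs(self):
        with pytest.raises(ValueError):
            priority(0.0, 1.0)
        with pytest.raises(ValueError):
            priority(0.5, 0.5)

    def test_prefix_priority_upper_bounds_full_priority(self):
        """Streaming bounds rho_k^j never dip below the exact priority."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            bg = random_bipartite(rng)
            gain = float(rng.uniform(0.1, 1.0))
            final, _ = multiply_collapse(bg)
            rho_full = priority(gain, loss(final))
            bounds = []
            multiply_collapse(
                bg,
                on_prefix=lambda d: bounds.append(
                    priority(gain, loss(d))
                ),
            )
            assert all(b >= rho_full - 1e-12 for b in bounds)


class TestProxyOrder:
    def _embeds(self, net, motif="M1"):
        embeds = enumerate_embeddings(net, motif_catalog(motif))
        return {e.id: e for e in embeds}, embeds

    def test_isolated_embedding_ranked_first(self, two_triangles):
        # triangles are isolated; their 2-paths overlap within each triangle
        embeds = enumerate_embeddings(two_triangles, motif_catalog("M2"))
        og = build_overlap_graph(embeds, "F2")
        order = proxy_order({e.id: e for e in embeds}, og)
        assert og.graph.degree(order[0]) == 0

    def test_lower_degree_wins_at_equal_gain(self):
        # path a-b-c-d-e: 2-paths overlap in a chain, ends have degree 1
        edges = [(c1, c2, 0.5) for c1, c2 in zip("abcd", "bcde")]
        net = ProbabilisticNetwork.from_edges(edges)
        by_id, embeds = self._embeds(net)
        og = build_overlap_graph(embeds, "F2")
        order = proxy_order(by_id, og)
        degrees = [og.graph.degree(k) for k in order]
        assert degrees[0] == min(degrees)

    def test_matches_reference_sort(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            net = random_small_network(rng, n_nodes=10, avg_degree=2.5)
            by_id, embeds = self._embeds(net)
            if not embeds:
                continue
            og = build_overlap_graph(embeds, "F2")
            got = proxy_order(by_id, og)
            q = {
                k: (
                    float("inf")
                    if og.graph.degree(k) == 0
                    else by_id[k].gain / og.graph.degree(k)
                )
                for k in by_id
            }
            expect = sorted(by_id, key=lambda k: (-q[k], k))
            assert got == expect


class TestBestEmbedding:
    def test_single_embedding_selected_without_pruning(self):
        net = ProbabilisticNetwork.from_edges(
            [("a", "b", 0.9), ("b", "c", 0.8), ("c", "a", 0.7)]
        )
        embeds = enumerate_embeddings(net, motif_catalog("M2"))
        og = build_overlap_graph(embeds, "F2")
        k, record, trace = best_embedding(og, embeds, net)
        assert k == embeds[0].id
        assert record.exact and trace["pruned"] == 0

    def test_early_termination_does_not_change_selection(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            net = random_small_network(rng, n_nodes=12, avg_degree=2.8,
                                       max_edges=16)
            embeds = enumerate_embeddings(net, motif_catalog("M1"))
            if not embeds:
                continue
            og = build_overlap_graph(embeds, "F2")
            on_k, on_rec, _ = best_embedding(
                og, embeds, net, Strategies(early_termination=True)
            )
            off_k, off_rec, _ = best_embedding(
                og, embeds, net, Strategies(early_termination=False)
            )
            assert on_k == off_k
            assert on_rec.rho == pytest.approx(off_rec.rho, abs=1e-12)

    def test_pruning_happens_with_a_dominant_isolated_embedding(self):
        # one isolated high-gain triangle plus a dense clump of overlapping
        # low-gain 2-paths: the isolated candidate sets a high rho* first
        edges = [("a", "b", 0.99), ("b", "c", 0.99), ("c", "a", 0.99)]
        hub = [("h", x, 0.15) for x in "pqrstu"]
        net = ProbabilisticNetwork.from_edges(edges + hub)
        embeds = enumerate_embeddings(net, motif_catalog("M1"))
        og = build_overlap_graph(embeds, "F2")
        _, _, trace = best_embedding(og, embeds, net)
        assert trace["pruned"] > 0


class TestCountIndependent:
    def test_two_disjoint_triangles(self, two_triangles):
        result = count_independent(two_triangles, motif_catalog("M2"))
        assert len(result.chosen) == 2
        assert result.expected_count == pytest.approx(2 * 0.5**3)

    def test_chosen_set_is_independent(self):
        rng = np.random.default_rng(5)
        for measure in ("F2", "F3"):
            net = random_small_network(rng, n_nodes=12, avg_degree=2.5,
                                       max_edges=14)
            result = count_independent(net, motif_catalog("M1"), measure)
            embeds = {
                e.id: e
                for e in enumerate_embeddings(net, motif_catalog("M1"))
            }
            chosen = [embeds[k] for k in result.chosen]
            for i, a in enumerate(chosen):
                for b in chosen[i + 1:]:
                    if measure == "F2":
                        assert not (a.edge_ids & b.edge_ids)
                    else:
                        assert not (a.node_set & b.node_set)

    def test_all_deterministic_matches_least_overlap_greedy_count(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            base = random_small_network(rng, n_nodes=10, avg_degree=2.5)
            net = ProbabilisticNetwork(
                nodes=base.nodes,
                edges=tuple((u, v, 1.0) for u, v, _ in base.edges),
            )
            result = count_independent(net, motif_catalog("M1"))
            _, det = deterministic_count(net, motif_catalog("M1"))
            assert result.expected_count == pytest.approx(det)

    def test_expected_count_equals_exhaustive_objective(self):
        """Eq-of-objectives: greedy value = exhaustive expectation of its set."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            net = random_small_network(rng, max_edges=9)
            for motif in ("M1", "M2"):
                result = count_independent(net, motif_catalog(motif))
                embeds = {
                    e.id: e
                    for e in enumerate_embeddings(net, motif_catalog(motif))
                }
                chosen = [embeds[k] for k in result.chosen]
                exact = expected_count_given_set(net, chosen)
                assert result.expected_count == pytest.approx(
                    exact, abs=1e-12
                )

    def test_heuristic_bounded_by_exact_optimum(self):
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(10):
            net = random_small_network(rng, max_edges=9)
            result = count_independent(net, motif_catalog("M1"))
            ids, opt = exact_def1_solution(net, motif_catalog("M1"))
            if opt == 0:
                continue
            assert result.expected_count <= opt + 1e-12
            ratios.append(result.expected_count / opt)
        assert ratios  # at least one instance had embeddings

    def test_heuristic_exact_on_disjoint_instance(self, two_triangles):
        result = count_independent(two_triangles, motif_catalog("M2"))
        _, opt = exact_def1_solution(two_triangles, motif_catalog("M2"))
        assert result.expected_count == pytest.approx(opt)

    @pytest.mark.parametrize(
        "strategies",
        [
            Strategies(early_termination=False),
            Strategies(greedy_order=False),
            Strategies(early_termination=False, greedy_order=False),
            Strategies(max_terms=8),
            Strategies(early_termination=False, greedy_order=False,
                       max_terms=8),
        ],
        ids=["no-s1", "no-s2", "no-s1s2", "s3", "s3-only"],
    )
    def test_strategy_toggles_leave_result_unchanged(self, strategies):
        rng = np.random.default_rng(9)
        for _ in range(8):
            net = random_small_network(rng, n_nodes=12, avg_degree=2.6,
                                       max_edges=16)
            base = count_independent(
                net, motif_catalog("M1"), keep_trace=False
            )
            other = count_independent(
                net, motif_catalog("M1"), strategies=strategies,
                keep_trace=False,
            )
            assert other.chosen == base.chosen
            assert other.expected_count == pytest.approx(
                base.expected_count, abs=1e-12
            )
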