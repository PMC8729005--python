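import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairpath import (NoPathsError, PartialCorrMatrix, RandomGGMConfig,
                      correlation_from_partial, decompose_correlation, gamma,
                      max_pps, pps, random_ggm, tau)
from pairpath.pps import PairDecompositionPlan, plan_for_pair


def scalar_gamma_direct_edge(p12, p13, p23):
    """Oracle for the direct-edge contribution in a full 3-node model."""
    return p12 / math.sqrt((1 - p23 ** 2) * (1 - p13 ** 2))


def scalar_gamma_detour(p13, p23):
    """Oracle for the length-2 contribution in a full 3-node model."""
    return p13 * p23 / math.sqrt((1 - p23 ** 2) * (1 - p13 ** 2))


class TestTau:
    def test_single_edge(self, three_node):
        assert tau(three_node, ("a", "b")) == 0.3

    def test_two_edges(self, three_node):
        assert tau(three_node, ("a", "c", "b")) == pytest.approx(0.4 * 0.2)

    def test_zero_partial_warns(self, identity_p):
        with pytest.warns(UserWarning, match="zero partial"):
            assert tau(identity_p, ("a", "b")) == 0.0

    def test_abs_non_increasing_under_extension(self, sim_model10):
        from pairpath.paths import enumerate_paths, support_graph
        g = support_graph(sim_model10)
        for path in enumerate_paths(g, "x01", "x08", 5):
            for cut in range(2, len(path)):
                assert (abs(tau(sim_model10, path))
                        <= abs(tau(sim_model10, path[:cut])) + 1e-15)


class TestGamma:
    def test_two_node_network(self):
        p = PartialCorrMatrix(("a", "b"), [[1, 0.37], [0.37, 1]])
        assert gamma(p, ("a", "b")) == pytest.approx(0.37, abs=1e-15)

    def test_direct_edge_three_node(self, three_node):
        expected = scalar_gamma_direct_edge(0.3, 0.4, 0.2)
        assert expected == pytest.approx(0.33408, abs=5e-6)
        assert gamma(three_node, ("a", "b")) == pytest.approx(
            expected, rel=1e-12)

    def test_detour_three_node(self, three_node):
        expected = scalar_gamma_detour(0.4, 0.2)
        assert expected == pytest.approx(0.08909, abs=5e-6)
        assert gamma(three_node, ("a", "c", "b")) == pytest.approx(
            expected, rel=1e-12)

    def test_gammas_sum_to_marginal(self, three_node):
        total = (gamma(three_node, ("a", "b"))
                 + gamma(three_node, ("a", "c", "b")))
        c = correlation_from_partial(three_node)
        assert total == pytest.approx(c.entry("a", "b"), abs=1e-14)


class TestDecomposeCorrelation:
    @pytest.mark.parametrize("seed", range(8))
    def test_full_reconstruction_five_nodes(self, seed, model_factory):
        p = model_factory(5, seed)
        c = correlation_from_partial(p)
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = p.labels[i], p.labels[j]
                d = decompose_correlation(p, a, b, 4)
                assert d.reconstructed_correlation == pytest.approx(
                    c.entry(a, b), abs=1e-10)

    def test_disconnected_pair_is_empty(self, identity_p):
        d = decompose_correlation(identity_p, "a", "b", 2)
        assert len(d) == 0
        assert d.reconstructed_correlation == 0.0

    def test_worked_example_sum(self, three_node):
        d = decompose_correlation(three_node, "a", "b", 2)
        assert d.reconstructed_correlation == pytest.approx(0.4232, abs=5e-5)

    def test_plan_route_matches_direct_gamma(self, sim_model10):
        # the vectorized plan and the per-path determinant route are
        # independent implementations; they must agree
        d = decompose_correlation(sim_model10, "x01", "x08", 5)
        for path, g in zip(d.paths, d.gammas):
            assert g == pytest.approx(gamma(sim_model10, path), rel=1e-11,
                                      abs=1e-13)


class TestPPS:
    def test_single_path_scores_one(self, chain4):
        table = pps(chain4, "a", "d", 3)
        assert table.scores == (1.0,)
        assert table.paths == (("a", "b", "c", "d"),)

    def test_worked_example_scores(self, three_node):
        table = pps(three_node, "a", "b", 2)
        assert table.scores[0] == pytest.approx(0.7895, abs=5e-5)
        assert table.scores[1] == pytest.approx(0.2105, abs=5e-5)
        assert sum(table.scores) == pytest.approx(1.0, abs=1e-14)

    def test_disconnected_pair_has_no_paths_status(self, identity_p):
        table = pps(identity_p, "a", "b", 2)
        assert table.status == "no_paths"
        assert table.scores == ()
        with pytest.raises(NoPathsError):
            table.max_entry

    def test_truncation_zeroes_long_paths(self, chain4):
        table = pps(chain4, "a", "d", 2)  # unique path has length 3
        assert table.status == "no_paths"

    def test_cancellation_flagged(self):
        # two detours engineered so the marginal correlation vanishes
        # while individual contributions do not
        v = np.eye(4)
        v[0, 2] = v[2, 0] = 0.4
        v[2, 1] = v[1, 2] = 0.4
        v[0, 3] = v[3, 0] = 0.4
        v[3, 1] = v[1, 3] = -0.4
        p = PartialCorrMatrix(tuple("abcd"), v)
        table = pps(p, "a", "b", 3)
        assert table.status == "ok"
        assert table.cancellation
        assert table.decomposition.reconstructed_correlation == pytest.approx(
            0.0, abs=1e-14)
        assert sum(table.scores) == pytest.approx(1.0)


class TestMaxPPS:
    def test_single_path(self, chain4):
        path, score = max_pps(chain4, "a", "d", 3)
        assert path == ("a", "b", "c", "d")
        assert score == 1.0

    def test_worked_example_direct_edge_wins(self, three_node):
        path, score = max_pps(three_node, "a", "b", 2)
        assert path == ("a", "b")
        assert score == pytest.approx(0.7895, abs=5e-5)

    def test_no_paths_raises_specific_error(self, identity_p):
        with pytest.raises(NoPathsError):
            max_pps(identity_p, "a", "b", 2)

    def test_length_two_path_can_beat_direct_edge(self):
        # weak direct edge, strong detour: scores are not monotone in length
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.05
        v[0, 2] = v[2, 0] = 0.65
        v[1, 2] = v[2, 1] = 0.65
        p = PartialCorrMatrix(tuple("abc"), v)
        path, score = max_pps(p, "a", "b", 2)
        assert path == ("a", "c", "b")
        assert score > 0.5


class TestInvariants:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n_nodes=st.integers(3, 8))
    def test_exact_reconstruction_property(self, seed, n_nodes):
        p = random_ggm(RandomGGMConfig(n_nodes=n_nodes, seed=seed))
        c = correlation_from_partial(p)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                a, b = p.labels[i], p.labels[j]
                d = decompose_correlation(p, a, b, n_nodes - 1)
                assert abs(d.reconstructed_correlation
                           - c.entry(a, b)) < 1e-10

    @pytest.mark.parametrize("seed", range(6))
    def test_sign_rule(self, seed, model_factory):
        p = model_factory(7, seed)
        for i in range(7):
            for j in range(i + 1, 7):
                d = decompose_correlation(p, p.labels[i], p.labels[j], 6)
                for t, g in zip(d.taus, d.gammas):
                    assert np.sign(g) == np.sign(t)

    @pytest.mark.parametrize("seed", range(4))
    def test_ranking_invariance_in_cutoff(self, seed, model_factory):
        p = model_factory(7, seed, edge_prob=0.4)
        for i in range(7):
            for j in range(i + 1, 7):
                a, b = p.labels[i], p.labels[j]
                tables = {k: pps(p, a, b, k) for k in range(2, 7)}
                base = tables[2]
                if base.status != "ok":
                    continue
                ref = {q: s for q, s in zip(base.paths, base.scores)}
                for k in range(3, 7):
                    t = tables[k]
                    sub = {q: s for q, s in zip(t.paths, t.scores)
                           if q in ref}
                    ranked_ref = sorted(ref, key=lambda q: (ref[q],) + q)
                    ranked_sub = sorted(sub, key=lambda q: (sub[q],) + q)
                    assert ranked_ref == ranked_sub

    @pytest.mark.parametrize("seed", range(6))
    def test_scores_normalized(self, seed, model_factory):
        p = model_factory(6, seed)
        for i in range(6):
            for j in range(i + 1, 6):
                t = pps(p, p.labels[i], p.labels[j], 5)
                if t.status != "ok":
                    continue
                assert all(0.0 <= s <= 1.0 for s in t.scores)
                assert sum(t.scores) == pytest.approx(1.0, abs=1e-12)


class TestPlan:
    def test_plan_on_superset_support_is_exact(self, sim_model10):
        # a plan built over the complete graph gives the same nonzero
        # gammas as one built over the true support graph
        import networkx as nx
        from pairpath.paths import enumerate_paths
        full = nx.complete_graph(list(sim_model10.labels))
        plan_full = PairDecompositionPlan(
            sim_model10.labels, "x03", "x09",
            enumerate_paths(full, "x03", "x09", 4))
        plan_true = plan_for_pair(sim_model10, "x03", "x09", 4)
        g_full = plan_full.gammas(sim_model10.values)
        g_true = plan_true.gammas(sim_model10.values)
        nonzero = {p: g for p, g in zip(plan_full.paths, g_full) if g != 0}
        expected = {p: g for p, g in zip(plan_true.paths, g_true) if g != 0}
        assert set(nonzero) == set(expected)
        for q in nonzero:
            assert nonzero[q] == pytest.approx(expected[q], rel=1e-12)

    def test_empty_matrix_determinant_convention(self):
        # a path covering every node removes all of A; det(empty) = 1
        p = PartialCorrMatrix(("a", "b"), [[1, 0.6], [0.6, 1]])
        assert gamma(p, ("a", "b")) == pytest.approx(0.6, abs=1e-15)
        c = correlation_from_partial(p)
        assert c.entry("a", "b") == pytest.approx(0.6, abs=1e-12)
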