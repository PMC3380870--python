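"""Unit and property tests for the NEM core: prediction semantics, marginal
score, attachment posterior, pre-filtering and node merging."""

import numpy as np
import pytest
from conftest import brute_force_log_posterior, enumerate_graphs, random_instance

from mceminem.model import (
    NULL_TARGET,
    AttachmentPrior,
    EdgePrior,
    EffectsAttachment,
    LogOdds,
    SignalsGraph,
    attachment_posterior,
    filter_effects,
    log_posterior,
    merge_indistinguishable,
    predict_effects,
)


class TestTypes:
    def test_graph_requires_unit_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            SignalsGraph(np.zeros((2, 2), dtype=int))

    def test_graph_requires_binary_entries(self):
        with pytest.raises(ValueError, match="0 or 1"):
            SignalsGraph(np.array([[1, 2], [0, 1]]))

    def test_prior_rows_must_be_stochastic(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AttachmentPrior(np.array([[0.5, 0.4, 0.2]]))

    def test_edge_prior_rejects_boundary_probabilities(self):
        with pytest.raises(ValueError, match="strictly"):
            EdgePrior(np.array([[0.5, 1.0], [0.5, 0.5]]))

    def test_log_odds_must_be_finite(self):
        with pytest.raises(ValueError, match="finite"):
            LogOdds(np.array([[np.inf, 0.0]]))


class TestPredictEffects:
    def test_identity_graph_predicts_own_signal_only(self):
        g = SignalsGraph.identity(2)
        a = EffectsAttachment(np.array([0]), signal_labels=g.labels)
        F = predict_effects(g, a)
        assert F[:, 0].tolist() == [1, 0]

    def test_edge_creates_two_step_path(self):
        # s1 -> s2, effect on s2 responds to perturbing either signal
        g = SignalsGraph(np.array([[1, 1], [0, 1]]))
        a = EffectsAttachment(np.array([1]), signal_labels=g.labels)
        assert predict_effects(g, a)[:, 0].tolist() == [1, 1]

    def test_null_attachment_is_always_inactive(self):
        g = SignalsGraph(np.array([[1, 1], [1, 1]]))
        a = EffectsAttachment(np.array([NULL_TARGET]), signal_labels=g.labels)
        assert not predict_effects(g, a).any()

    def test_matches_matrix_indicator_form(self, rng):
        for _ in range(20):
            g, r, _, _ = random_instance(rng, n_effects=6)
            targets = rng.integers(-1, g.n_signals, size=6)
            a = EffectsAttachment(targets, signal_labels=g.labels)
            F = predict_effects(g, a)
            theta = a.as_matrix(g.n_signals)
            np.testing.assert_array_equal(F, (g.adjacency @ theta) >= 1)

    def test_label_mismatch_raises(self):
        g = SignalsGraph.identity(2)
        a = EffectsAttachment(np.array([0]), signal_labels=["x", "y"])
        with pytest.raises(ValueError, match="labels"):
            predict_effects(g, a)


class TestLogPosterior:
    def test_single_signal_hand_value(self):
        # nu = (1/2, 1/2) over {s1, null}, R = [ln 3]: marginal = 0.5*3 + 0.5*1
        g = SignalsGraph.identity(1)
        r = LogOdds(np.array([[np.log(3.0)]]), signal_labels=g.labels)
        nu = AttachmentPrior(np.array([[0.5, 0.5]]))
        ep = EdgePrior.uniform(1)
        assert log_posterior(g, r, nu, ep) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_zero_data_scores_depend_only_on_edge_prior(self, rng):
        # R == 0 makes the attachment term vanish for every graph
        S, E = 3, 4
        r = LogOdds(np.zeros((E, S)))
        nu = AttachmentPrior(rng.dirichlet(np.ones(S + 1), size=E))
        ep = EdgePrior(rng.uniform(0.2, 0.8, size=(S, S)))
        for adj in enumerate_graphs(S):
            g = SignalsGraph(adj, r.signal_labels)
            expected = sum(
                np.log(ep.values[k, s]) if adj[k, s] else np.log1p(-ep.values[k, s])
                for k in range(S)
                for s in range(S)
                if k != s
            )
            assert log_posterior(g, r, nu, ep) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_attachment_enumeration(self, rng):
        for _ in range(15):
            g, r, nu, ep = random_instance(rng)
            expected = brute_force_log_posterior(g.adjacency, r.values, nu.values, ep.values)
            assert log_posterior(g, r, nu, ep) == pytest.approx(expected, abs=1e-8)

    def test_supporting_edge_never_decreases_attachment_term(self, rng):
        # all log-odds positive: adding any edge can only raise the marginal
        S, E = 3, 5
        r = LogOdds(rng.uniform(0.2, 2.0, size=(E, S)))
        nu = AttachmentPrior(rng.dirichlet(np.ones(S + 1), size=E))
        ep = EdgePrior.uniform(S)  # p=0.5: edge prior identical for all graphs
        base = SignalsGraph.identity(S, r.signal_labels)
        base_score = log_posterior(base, r, nu, ep)
        for k in range(S):
            for s in range(S):
                if k == s:
                    continue
                adj = np.eye(S, dtype=int)
                adj[k, s] = 1
                more = log_posterior(SignalsGraph(adj, r.signal_labels), r, nu, ep)
                assert more >= base_score - 1e-12


class TestAttachmentPosterior:
    def test_uniform_prior_zero_row_gives_uniform_posterior(self):
        g = SignalsGraph.identity(2)
        r = LogOdds(np.zeros((1, 2)), signal_labels=g.labels)
        omega = attachment_posterior(g, r, AttachmentPrior.uniform(1, 2))
        np.testing.assert_allclose(omega.values, 1.0 / 3.0)

    def test_single_signal_hand_value(self):
        g = SignalsGraph.identity(1)
        r = LogOdds(np.array([[np.log(3.0)]]), signal_labels=g.labels)
        nu = AttachmentPrior(np.array([[0.5, 0.5]]))
        omega = attachment_posterior(g, r, nu)
        np.testing.assert_allclose(omega.values, [[0.75, 0.25]], atol=1e-12)

    def test_deterministic_null_prior_is_preserved(self, rng):
        g = SignalsGraph.identity(2)
        r = LogOdds(rng.normal(size=(1, 2)), signal_labels=g.labels)
        nu = AttachmentPrior(np.array([[0.0, 0.0, 1.0]]))
        omega = attachment_posterior(g, r, nu)
        np.testing.assert_allclose(omega.values, [[0.0, 0.0, 1.0]])

    def test_rows_sum_to_one_on_random_instances(self, rng):
        for _ in range(20):
            g, r, nu, _ = random_instance(rng, n_effects=8, scale=30.0)
            omega = attachment_posterior(g, r, nu)
            np.testing.assert_allclose(omega.values.sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_prior_row_raises(self):
        g = SignalsGraph.identity(2)
        r = LogOdds(np.zeros((1, 2)), signal_labels=g.labels)
        # bypass the dataclass validator to hit the workspace check directly
        bad = AttachmentPrior.uniform(1, 2)
        bad.values = np.zeros((1, 3))
        with pytest.raises(ValueError, match="all-zero"):
            attachment_posterior(g, r, bad)


class TestFilterEffects:
    @pytest.mark.parametrize(
        "row, kept",
        [((-1.2, -0.3), False), ((-1.2, 0.0), False), ((-1.2, 0.7), True)],
    )
    def test_strict_positivity_rule(self, row, kept):
        r = LogOdds(np.array([row]))
        reduced, idx = filter_effects(r)
        assert (reduced.n_effects == 1) is kept
        assert (0 in idx.tolist()) is kept

    def test_all_filtered_warns_and_returns_empty(self):
        r = LogOdds(np.full((2, 2), -1.0))
        with pytest.warns(UserWarning, match="filtered"):
            reduced, idx = filter_effects(r)
        assert reduced.n_effects == 0 and idx.size == 0

    def test_filtering_is_an_exact_constant_under_null_mass_priors(self, rng):
        # when the prior already sends inert genes to the null node their
        # marginal term is exp(0) = 1 for every graph: scores shift by 0
        S = 3
        values = np.vstack([rng.normal(0, 2, size=(3, S)), -rng.uniform(0.5, 2, size=(2, S))])
        r = LogOdds(values)
        nu_vals = rng.dirichlet(np.ones(S + 1), size=5)
        nu_vals[3:] = 0.0
        nu_vals[3:, S] = 1.0  # inert genes: all mass on null
        nu = AttachmentPrior(nu_vals)
        ep = EdgePrior(rng.uniform(0.2, 0.8, size=(S, S)))
        reduced, idx = filter_effects(r)
        nu_red = AttachmentPrior(nu.values[idx])
        for adj in enumerate_graphs(S):
            g = SignalsGraph(adj, r.signal_labels)
            assert log_posterior(g, r, nu, ep) == pytest.approx(
                log_posterior(g, reduced, nu_red, ep), abs=1e-9
            )


class TestMergeIndistinguishable:
    def test_mutual_pair_merges_to_single_node(self, rng):
        adj = np.eye(3, dtype=int)
        adj[1, 2] = adj[2, 1] = 1
        g = SignalsGraph(adj, ["a", "b", "c"])
        r = LogOdds(rng.normal(size=(4, 3)), None, g.labels)
        mg, mr, report = merge_indistinguishable(g, r)
        assert mg.n_signals == 2
        assert mg.labels == ["a", "bc"]
        assert report["bc"] == ["b", "c"]
        np.testing.assert_allclose(mr.values[:, 1], r.values[:, 1:].mean(axis=1))

    def test_no_mutual_edges_leaves_graph_unchanged(self, rng):
        adj = np.eye(3, dtype=int)
        adj[0, 1] = adj[1, 2] = 1
        g = SignalsGraph(adj)
        r = LogOdds(rng.normal(size=(2, 3)), None, g.labels)
        mg, mr, report = merge_indistinguishable(g, r)
        assert mg == g
        np.testing.assert_array_equal(mr.values, r.values)

    def test_transitive_mutual_chain_merges_all(self, rng):
        # mutual a<->b and b<->c: union-find closure puts all three together
        adj = np.eye(3, dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        adj[1, 2] = adj[2, 1] = 1
        g = SignalsGraph(adj, ["a", "b", "c"])
        r = LogOdds(rng.normal(size=(2, 3)), None, g.labels)
        mg, _, report = merge_indistinguishable(g, r)
        assert mg.n_signals == 1
        assert sorted(report[mg.labels[0]]) == ["a", "b", "c"]

    def test_merged_adjacency_is_elementwise_or(self):
        adj = np.eye(4, dtype=int)
        adj[1, 2] = adj[2, 1] = 1  # merge b, c
        adj[1, 0] = 1  # b -> a
        adj[3, 2] = 1  # d -> c
        g = SignalsGraph(adj, ["a", "b", "c", "d"])
        r = LogOdds(np.zeros((1, 4)), None, g.labels)
        mg, _, _ = merge_indistinguishable(g, r)
        assert mg.labels == ["a", "bc", "d"]
        assert mg.adjacency[1, 0] == 1  # from b -> a
        assert mg.adjacency[2, 1] == 1  # d -> c lands on the merged node
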