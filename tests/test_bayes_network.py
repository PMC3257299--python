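"""Discretization, BDeu scoring, search and consensus behaviour."""

import numpy as np
import pytest

from rootgrn import bayes_network as bn
from rootgrn.core_data import ExpressionMatrix, Sample, Site, Treatment


def two_node_dataset(x, y, clamp_x=None, arity=2):
    nodes = [bn.gene_node("X", arity), bn.gene_node("Y", arity)]
    states = np.array([x, y])
    clamped = np.zeros_like(states, dtype=bool)
    if clamp_x is not None:
        clamped[0] = clamp_x
    return bn.DiscreteDataset(nodes, states, clamped)


class TestDiscretization:
    def test_rank_tertiles_on_distinct_values(self):
        states = bn.equal_frequency_states(np.arange(1.0, 10.0), 3)
        assert states.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_value_clusters_on_distinct_levels(self):
        vals = np.array([6.1, 5.9, 12.0, 9.1, 8.9, 12.2, 6.0, 9.0, 11.8])
        states = bn.value_cluster_states(vals, 3)
        assert states.tolist() == [0, 0, 2, 1, 1, 2, 0, 1, 2]

    def test_value_clusters_handle_skewed_marginals(self, rng):
        # 50 low, 6 mid, 10 high: frequency binning would corrupt ~half the
        # labels, value clustering recovers the levels
        truth = np.array([0] * 50 + [1] * 6 + [2] * 10)
        vals = np.array([6.0, 9.0, 12.0])[truth] + rng.normal(0, 0.5, 66)
        states = bn.value_cluster_states(vals, 3, min_separation=1.5)
        assert np.mean(states == truth) > 0.95

    def test_merge_threshold_collapses_subnoise_splits(self, rng):
        # two genuine levels only: no third state should be invented
        truth = np.array([0] * 40 + [1] * 26)
        vals = np.array([6.0, 12.0])[truth] + rng.normal(0, 0.5, 66)
        states = bn.value_cluster_states(vals, 3, min_separation=1.5)
        assert set(states) == {0, 1}
        assert np.array_equal(states, truth)

    def test_constant_gene_all_state_zero_with_warning(self):
        expr = ExpressionMatrix(
            ["g1"], ["s1", "s2", "s3"], np.full((1, 3), 5.0)
        )
        samples = [
            Sample(f"s{i}", frozenset(), Site.SITE_A, i) for i in (1, 2, 3)
        ]
        with pytest.warns(UserWarning, match="constant"):
            data = bn.discretize_dataset(expr, samples, [bn.gene_node("g1")])
        assert np.all(data.states[0] == 0)

    def test_knockout_clamps_and_zeroes(self):
        expr = ExpressionMatrix(
            ["G5"], ["a", "b", "c", "d"], np.array([[12.0, 11.8, 6.1, 12.2]])
        )
        samples = [
            Sample("a", frozenset(), Site.SITE_A, 1),
            Sample("b", frozenset(), Site.SITE_A, 2),
            Sample("c", frozenset({"G5"}), Site.SITE_A, 1),
            Sample("d", frozenset(), Site.SITE_A, 3),
        ]
        data = bn.discretize_dataset(expr, samples, [bn.gene_node("G5")])
        j = expr.sample_ids.index("c")
        assert data.clamped[0, j] and data.states[0, j] == 0
        assert not data.clamped[0, [0, 1, 3]].any()

    def test_hormone_states_follow_treatment(self):
        expr = ExpressionMatrix(["g"], ["a", "b"], np.array([[1.0, 2.0]]))
        samples = [
            Sample("a", frozenset(), Site.SITE_A, 1, Treatment.IAA),
            Sample("b", frozenset(), Site.SITE_A, 1, Treatment.MS),
        ]
        data = bn.discretize_dataset(
            expr, samples, [bn.gene_node("g"), bn.hormone_node("IAA")]
        )
        assert data.states[1].tolist() == [1, 0]

    def test_missing_gene_is_error(self):
        expr = ExpressionMatrix(["g"], ["a", "b"], np.array([[1.0, 2.0]]))
        samples = [
            Sample("a", frozenset(), Site.SITE_A, 1),
            Sample("b", frozenset(), Site.SITE_A, 2),
        ]
        with pytest.raises(ValueError, match="missing"):
            bn.discretize_dataset(expr, samples, [bn.gene_node("nope")])


class TestBDeuScore:
    def test_closed_form_gamma_ratio(self):
        # binary parentless node, observations (0,0,1,1), alpha=1:
        # Gamma(1)/Gamma(5) * Gamma(2.5)^2/Gamma(0.5)^2 = 3/128
        data = two_node_dataset([0, 0, 1, 1], [0, 0, 0, 0])
        score = bn.bdeu_family_score("X", [], data)
        assert score == pytest.approx(np.log(3 / 128), abs=1e-9)

    def test_single_observation_uniform_predictive(self):
        data = two_node_dataset([0], [0])
        assert bn.bdeu_family_score("X", [], data) == pytest.approx(
            -np.log(2), abs=1e-12
        )

    def test_fully_clamped_node_scores_equal_for_any_parents(self):
        data = two_node_dataset([0, 1, 0, 1], [0, 1, 1, 0], clamp_x=[1, 1, 1, 1])
        assert bn.bdeu_family_score("X", [], data) == 0.0
        assert bn.bdeu_family_score("X", ["Y"], data) == 0.0

    def test_node_in_own_parent_set_rejected(self):
        data = two_node_dataset([0, 1], [0, 1])
        with pytest.raises(ValueError, match="parent set"):
            bn.bdeu_family_score("X", ["X"], data)

    def test_decomposability_of_network_score(self, rng):
        x = rng.integers(0, 2, 30)
        y = rng.integers(0, 2, 30)
        data = two_node_dataset(x, y)
        empty = bn.score_network([], data)
        assert empty == pytest.approx(
            bn.bdeu_family_score("X", [], data)
            + bn.bdeu_family_score("Y", [], data)
        )
        withedge = bn.score_network([("X", "Y")], data)
        assert withedge == pytest.approx(
            bn.bdeu_family_score("X", [], data)
            + bn.bdeu_family_score("Y", ["X"], data)
        )

    def test_caching_leaves_scores_identical(self, rng):
        x = rng.integers(0, 3, 40)
        y = rng.integers(0, 3, 40)
        data = two_node_dataset(x, y, arity=3)
        scorer = bn.BDeuScorer(data)
        first = scorer.family_score(1, (0,))
        again = scorer.family_score(1, (0,))
        fresh = bn.BDeuScorer(data).family_score(1, (0,))
        assert first == again == fresh

    def test_cyclic_structure_rejected(self):
        data = two_node_dataset([0, 1], [0, 1])
        with pytest.raises(ValueError, match="cycle"):
            bn.score_network([("X", "Y"), ("Y", "X")], data)


class TestInterventionalOrientation:
    @staticmethod
    def _xy_data(n=200, n_clamped=50, seed=5):
        """X -> Y with strong dependence; X clamped in the first n_clamped."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        x[:n_clamped] = 0
        flip = rng.random(n) < 0.1
        y = np.where(flip, 1 - x, x)
        clamp = np.zeros(n, bool)
        clamp[:n_clamped] = True
        return x, y, clamp

    def test_clamping_orients_the_edge(self):
        x, y, clamp = self._xy_data()
        data = two_node_dataset(x, y, clamp_x=clamp)
        forward = bn.score_network([("X", "Y")], data)
        backward = bn.score_network([("Y", "X")], data)
        assert forward > backward

    def test_observational_data_is_score_equivalent(self):
        x, y, _ = self._xy_data()
        data = two_node_dataset(x, y)  # no interventions
        forward = bn.score_network([("X", "Y")], data)
        backward = bn.score_network([("Y", "X")], data)
        assert forward == pytest.approx(backward, abs=1e-9)


class TestRolesAndSearch:
    @staticmethod
    def _random_dataset(n_nodes, n_samples, seed, dependent=True):
        rng = np.random.default_rng(seed)
        states = rng.integers(0, 2, size=(n_nodes, n_samples))
        if dependent:
            for i in range(1, n_nodes):
                mask = rng.random(n_samples) < 0.8
                states[i, mask] = states[i - 1, mask]
        nodes = [bn.gene_node(f"N{i}", 2) for i in range(n_nodes)]
        return bn.DiscreteDataset(
            nodes, states, np.zeros_like(states, dtype=bool)
        )

    def test_search_matches_exhaustive_enumeration_on_3_nodes(self):
        data = self._random_dataset(3, 120, seed=2)
        best_enum = bn.enumerate_dags(data)[0]
        topk = bn.learn_structures(
            data,
            search_cfg=bn.SearchConfig(restarts=10, top_k=25, seed=0),
        )
        assert topk.best.score == pytest.approx(best_enum.score, abs=1e-9)
        assert topk.best.edges == best_enum.edges

    def test_phenotype_never_a_source_hormone_never_a_target(self):
        rng = np.random.default_rng(3)
        n = 40
        states = np.vstack(
            [
                rng.integers(0, 2, n),
                rng.integers(0, 3, n),
                rng.integers(0, 2, n),
            ]
        )
        nodes = [
            bn.hormone_node("H"),
            bn.gene_node("G", 3),
            bn.phenotype_node("P", 2),
        ]
        data = bn.DiscreteDataset(nodes, states, np.zeros_like(states, bool))
        topk = bn.learn_structures(
            data, search_cfg=bn.SearchConfig(restarts=6, top_k=200, seed=1)
        )
        for dag in topk.structures():
            for a, b in dag.edges:
                assert a != "P" and b != "H"

    def test_role_violations_rejected_by_validator(self):
        nodes = [bn.hormone_node("H"), bn.phenotype_node("P", 2)]
        with pytest.raises(ValueError, match="leaf-only"):
            bn.validate_structure([("P", "H")], nodes)

    def test_search_is_deterministic_given_seed(self):
        data = self._random_dataset(4, 60, seed=4)
        cfg = bn.SearchConfig(restarts=5, top_k=50, seed=9)
        a = bn.learn_structures(data, search_cfg=cfg)
        b = bn.learn_structures(data, search_cfg=cfg)
        assert [(s.canonical(), s.score) for s in a.structures()] == [
            (s.canonical(), s.score) for s in b.structures()
        ]


class TestTopKList:
    def test_capacity_dedup_and_tie_rejection(self):
        top = bn.TopKList(2)
        e1 = frozenset({("a", "b")})
        e2 = frozenset({("b", "c")})
        e3 = frozenset({("a", "c")})
        assert top.offer(e1, -10.0)
        assert not top.offer(e1, -10.0)  # duplicate structure
        assert top.offer(e2, -5.0)
        assert not top.offer(e3, -10.0)  # tie with current minimum: rejected
        assert top.offer(e3, -9.0)
        assert {s.edges for s in top.structures()} == {e2, e3}


class TestConsensus:
    @staticmethod
    def _topk_from(structures):
        top = bn.TopKList(len(structures))
        for i, edges in enumerate(structures):
            top.offer(frozenset(edges), -float(i))
        return top

    def test_counting_support(self):
        # five distinct structures; an edge present in two has support 0.40
        # and is included exactly at the 40% threshold
        top = self._topk_from(
            [
                {("a", "b")},
                {("a", "b"), ("b", "c")},
                {("b", "c"), ("c", "d")},
                {("c", "d")},
                set(),
            ]
        )
        net = bn.consensus_network(top, 0.40)
        assert net.support_of("a", "b") == pytest.approx(0.4)
        assert net.support_of("b", "c") == pytest.approx(0.4)
        assert len(net.edges) == 3

    def test_f_one_is_the_intersection(self):
        top = self._topk_from(
            [{("a", "b"), ("b", "c")}, {("a", "b")}, {("a", "b"), ("c", "d")}]
        )
        net = bn.consensus_network(top, 1.0)
        assert net.edges.as_pairs() == {("a", "b")}

    def test_f_above_all_supports_gives_empty_network(self):
        top = self._topk_from([{("a", "b")}, {("b", "c")}, {("c", "d")}])
        net = bn.consensus_network(top, 0.9)
        assert len(net.edges) == 0

    def test_monotone_in_f(self):
        top = self._topk_from(
            [
                {("a", "b"), ("b", "c")},
                {("a", "b")},
                {("a", "b"), ("c", "d")},
                {("b", "c")},
            ]
        )
        sets = [
            bn.consensus_network(top, f).edges.as_pairs()
            for f in (0.25, 0.5, 0.75, 1.0)
        ]
        for tighter, looser in zip(sets[1:], sets):
            assert tighter <= looser

    def test_empty_topk_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            bn.consensus_network(bn.TopKList(5), 0.4)
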