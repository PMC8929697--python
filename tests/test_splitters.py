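from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from famsplit.similarity import AdjacencyGraph, make_graph_pair
from famsplit.splitters import (
    SplitConfig,
    SplitResult,
    best_of_n,
    check_split_graphs,
    greedy_sequential_bip,
    greedy_sequential_is,
    random_priority_bip,
    random_priority_is,
    run_until_n,
    split,
    split_cluster,
    split_cobalt,
    split_independent_selection,
    validate_split,
)
from famsplit.synthetic import generate_graph

from oracles import (
    adj_sets,
    greedy_is_distribution,
    is_maximal_independent_set,
    no_crossing_edges,
    total_variation,
)


def _er(n, prob, seed):
    return generate_graph("erdos_renyi", {"n": n, "prob": prob}, seed=seed)


def _adj(g):
    return adj_sets(g.n_vertices, g.edges)


LOOSE_CFG = SplitConfig(min_train=1, min_test=1)


class TestGreedySequentialIS:
    def test_edgeless_returns_everything(self, rng):
        g = generate_graph("edgeless", {"n": 5})
        assert greedy_sequential_is(g, rng) == (0, 1, 2, 3, 4)

    def test_path_center_alone_one_third_of_the_time(self):
        """On a path a-b-c the set {b} appears iff b is first: 1/3."""
        g = generate_graph("path", {"n": 3})
        exact = greedy_is_distribution(_adj(g))
        assert exact[frozenset({1})] == pytest.approx(1 / 3)
        runs = 30_000
        rng = np.random.default_rng(42)
        counts = Counter(frozenset(greedy_sequential_is(g, rng)) for _ in range(runs))
        assert total_variation(exact, counts, runs) < 0.02

    def test_complete_graph_single_uniform_vertex(self):
        g = generate_graph("complete", {"n": 3})
        rng = np.random.default_rng(0)
        counts = Counter(greedy_sequential_is(g, rng) for _ in range(9000))
        assert set(counts) == {(0,), (1,), (2,)}
        for c in counts.values():
            assert abs(c / 9000 - 1 / 3) < 0.03

    def test_restriction_to_subset(self, rng):
        g = generate_graph("path", {"n": 5})
        out = greedy_sequential_is(g, rng, vertices=[0, 1])
        assert out in ((0,), (1,))

    def test_star_inclusion_bound(self):
        """Leaf vertices (degree 1) enter the IS at least half the time;
        the center (degree d) at least 1/(d+1) of the time."""
        g = generate_graph("star", {"m": 4})
        rng = np.random.default_rng(3)
        hits = Counter()
        runs = 20_000
        for _ in range(runs):
            for v in greedy_sequential_is(g, rng):
                hits[v] += 1
        assert hits[0] / runs > 1 / 5 - 0.02
        for leaf in range(1, 5):
            assert hits[leaf] / runs > 1 / 2 - 0.02


class TestGreedySequentialBIP:
    def test_single_vertex_lands_in_train_side(self):
        g = generate_graph("edgeless", {"n": 1})
        for seed in range(10):
            assert greedy_sequential_bip(g, np.random.default_rng(seed)) == ((0,), ())

    def test_clique_collapses_to_one_side(self):
        # With no second side seeded, a clique member can always join the
        # side its peers are on (only opposite-side adjacency blocks entry),
        # so the whole clique ends up together and the other side is empty.
        for n in (2, 3, 4):
            g = generate_graph("complete", {"n": n})
            for seed in range(40):
                s, t = greedy_sequential_bip(g, np.random.default_rng(seed))
                assert s == tuple(range(n)) and t == ()

    def test_no_crossing_edges_and_size_order(self):
        for seed in range(150):
            g = _er(10, 0.3, seed)
            s, t = greedy_sequential_bip(g, np.random.default_rng(seed + 1))
            adj = _adj(g)
            assert no_crossing_edges(adj, s, t)
            assert len(s) >= len(t)
            assert not set(s) & set(t)


class TestRandomPriorityIS:
    def test_edgeless_one_round(self, rng):
        g = generate_graph("edgeless", {"n": 6})
        assert random_priority_is(g, rng) == tuple(range(6))

    def test_single_edge_each_endpoint_half(self):
        g = generate_graph("path", {"n": 2})
        rng = np.random.default_rng(8)
        counts = Counter(random_priority_is(g, rng) for _ in range(10_000))
        assert set(counts) == {(0,), (1,)}
        assert abs(counts[(0,)] / 10_000 - 0.5) < 0.02

    def test_maximal_on_random_graphs(self):
        for seed in range(200):
            g = _er(int(3 + seed % 10), 0.3, seed)
            out = random_priority_is(g, np.random.default_rng(seed))
            assert is_maximal_independent_set(_adj(g), out)


class TestRandomPriorityBIP:
    def test_single_vertex(self):
        g = generate_graph("edgeless", {"n": 1})
        for seed in range(10):
            assert random_priority_bip(g, np.random.default_rng(seed)) == ((0,), ())

    def test_edgeless_odd_everyone_placed(self):
        g = generate_graph("edgeless", {"n": 7})
        for seed in range(30):
            s, t = random_priority_bip(g, np.random.default_rng(seed))
            assert sorted(s + t) == list(range(7))

    def test_no_crossing_edges_and_size_order(self):
        for seed in range(150):
            g = _er(10, 0.3, seed)
            s, t = random_priority_bip(g, np.random.default_rng(seed + 7))
            assert no_crossing_edges(_adj(g), s, t)
            assert len(s) >= len(t)
            assert not set(s) & set(t)


class TestSplitAlgorithmsOnGraphs:
    """All four split procedures keep the split validity invariants on
    random abstract graphs, successful or not."""

    @pytest.mark.parametrize("algorithm", ["cobalt", "blue", "cluster", "indepsel"])
    def test_validity_on_random_graphs(self, algorithm):
        for seed in range(100):
            g = _er(int(4 + seed % 9), (0.1, 0.3, 0.6)[seed % 3], seed)
            cfg = replace(LOOSE_CFG, seed=seed)
            res = split(g, g, cfg, algorithm=algorithm)
            assert check_split_graphs(g, g, res)

    @pytest.mark.parametrize("algorithm", ["cobalt", "blue", "cluster", "indepsel"])
    def test_same_seed_identical_result(self, algorithm):
        g = _er(12, 0.3, 99)
        cfg = replace(LOOSE_CFG, seed=4, mode="best", n_reps=5)
        assert split(g, g, cfg, algorithm=algorithm) == split(g, g, cfg, algorithm=algorithm)


class TestSplitCluster:
    def test_largest_component_trains_rest_tested(self, rng):
        # p-components {0,1,2}, {3}, {4}; no q-edges between 3 and 4
        g_p = AdjacencyGraph(5, [(0, 1), (1, 2)])
        g_q = AdjacencyGraph(5, [])
        res = split_cluster(g_p, g_q, LOOSE_CFG, rng)
        assert res.train == (0, 1, 2) and res.test == (3, 4)
        assert res.success

    def test_single_component_cannot_split(self, rng):
        g = generate_graph("complete", {"n": 6})
        res = split_cluster(g, g, LOOSE_CFG, rng)
        assert res.test == () and not res.success

    def test_q_components_one_representative_each(self):
        # remainder {3,4,5} has q-edge 3-4: two q-components -> 2 test seqs
        g_p = AdjacencyGraph(6, [(0, 1), (1, 2)])
        g_q = AdjacencyGraph(6, [(3, 4)])
        res = split_cluster(g_p, g_q, LOOSE_CFG, np.random.default_rng(0))
        assert len(res.test) == 2 and 5 in res.test
        assert res.test[0] in (3, 4)


class TestSplitIndependentSelection:
    def test_training_size_binomial_on_edgeless(self):
        g = generate_graph("edgeless", {"n": 1000})
        res = split_independent_selection(g, g, LOOSE_CFG, np.random.default_rng(5))
        # Binomial(1000, 0.7): mean 700, sd ~14.5; 4 sd window
        assert abs(len(res.train) - 700) < 58

    def test_complete_graph_test_empty_unless_train_empty(self):
        g = generate_graph("complete", {"n": 12})
        for seed in range(50):
            res = split_independent_selection(
                g, g, LOOSE_CFG, np.random.default_rng(seed)
            )
            if res.train:
                assert res.test == ()
            else:
                assert len(res.test) == 1


class TestSplitOnFamilies:
    def test_cobalt_splits_two_disjoint_clusters(self, two_cluster_family):
        gp, gq = make_graph_pair(two_cluster_family, 25, 50)
        res = split(gp, gq, SplitConfig(mode="until", n_reps=40, seed=1), "cobalt")
        assert res.success
        assert validate_split(two_cluster_family, res, 25, 50).passed

    def test_blue_splits_two_disjoint_clusters(self, two_cluster_family):
        gp, gq = make_graph_pair(two_cluster_family, 25, 50)
        res = split(gp, gq, SplitConfig(mode="until", n_reps=40, seed=1), "blue")
        assert res.success
        assert validate_split(two_cluster_family, res, 25, 50).passed

    def test_single_sequence_family_fails_minima(self, rng):
        g = generate_graph("edgeless", {"n": 1})
        res = split_cobalt(g, g, SplitConfig(min_train=1, min_test=1), rng)
        assert res.train == (0,) and res.test == () and not res.success

    def test_isolated_outlier_in_test_half_the_time(self, outlier_family):
        """A sequence below the p threshold to everything is assigned to the
        test set by Cobalt and Blue about half the time (its side coin is
        independent of where the big cluster lands)."""
        gp, gq = make_graph_pair(outlier_family, 25, 50)
        outlier = outlier_family.n_rows - 1
        from famsplit.splitters import split_blue

        for fn in (split_cobalt, split_blue):
            hits = sum(
                outlier in fn(gp, gq, LOOSE_CFG, np.random.default_rng(s)).test
                for s in range(2000)
            )
            assert abs(hits / 2000 - 0.5) < 0.04


class TestRepetitionDrivers:
    def test_first_success_stops_early(self, two_cluster_family):
        gp, gq = make_graph_pair(two_cluster_family, 25, 50)
        res = run_until_n(split_cobalt, gp, gq, SplitConfig(mode="until", n_reps=40, seed=2))
        assert res.success and res.runs_used == res.iteration + 1

    def test_impossible_minima_exhaust_all_runs(self):
        g = generate_graph("edgeless", {"n": 4})
        cfg = SplitConfig(min_train=10, min_test=1, mode="until", n_reps=7, seed=0)
        res = run_until_n(split_cobalt, g, g, cfg)
        assert not res.success and res.runs_used == 7

    def test_expected_runs_geometric_on_coin_flip_fixture(self):
        # Edgeless K_2: the two vertices land on opposite sides with
        # probability 1/2, so run-until-n behaves geometrically, mean ~2.
        g = generate_graph("edgeless", {"n": 2})
        cfg = SplitConfig(min_train=1, min_test=1, mode="until", n_reps=200)
        used = [
            run_until_n(split_cobalt, g, g, replace(cfg, seed=s)).runs_used
            for s in range(400)
        ]
        assert abs(np.mean(used) - 2.0) < 0.25

    def test_best_of_n_argmax_with_earliest_tie(self):
        objectives = iter([20, 44, 44, 30])

        def stub(g_p, g_q, cfg, rng):
            obj = next(objectives)
            train = tuple(range(obj))  # |train| * |test=1 vertex| = obj
            return SplitResult(train, (99,), (), "stub", None, 0, True, obj)

        g = generate_graph("edgeless", {"n": 1})
        cfg = SplitConfig(min_train=1, min_test=1, mode="best", n_reps=4, seed=0)
        res = best_of_n(stub, g, g, cfg)
        assert res.objective == 44 and res.iteration == 1

    def test_best_of_one_equals_single_run(self, two_cluster_family):
        gp, gq = make_graph_pair(two_cluster_family, 25, 50)
        cfg = SplitConfig(seed=9, mode="best", n_reps=1)
        best = best_of_n(split_cobalt, gp, gq, cfg)
        single = split(gp, gq, replace(cfg, mode="single"), "cobalt")
        assert (best.train, best.test) == (single.train, single.test)

    def test_best_of_n_dominates_each_replay(self):
        g = _er(14, 0.25, 3)
        cfg = SplitConfig(min_train=3, min_test=2, mode="best", n_reps=10, seed=6)
        best = best_of_n(split_cobalt, g, g, cfg)
        for i in range(10):
            rng = np.random.default_rng([cfg.seed, i])
            replay = split_cobalt(g, g, cfg, rng)
            if replay.success:
                assert best.objective >= replay.objective

    def test_no_success_returns_failure(self):
        g = generate_graph("complete", {"n": 5})
        cfg = SplitConfig(min_train=2, min_test=2, mode="best", n_reps=5, seed=0)
        assert not best_of_n(split_cobalt, g, g, cfg).success


class TestValidateSplit:
    def test_violating_pair_reported(self, tiny_alignment):
        # s1 vs s2 are 80% identical: a train/test violation at p=25
        res = SplitResult((0,), (1,), (2,), "hand", None, 0, True, 1)
        report = validate_split(tiny_alignment, res, 25, 50)
        assert not report.passed
        assert (0, 1) in {(u, v) for u, v, _ in report.violations}
        assert report.max_train_test_pid == pytest.approx(0.8)

    def test_empty_test_passes_vacuously(self, tiny_alignment):
        res = SplitResult((0, 1, 2), (), (), "hand", None, 0, False, 0)
        assert validate_split(tiny_alignment, res, 25, 50).passed

    def test_out_of_range_vertex_errors(self, tiny_alignment):
        res = SplitResult((0,), (7,), (), "hand", None, 0, True, 1)
        with pytest.raises(IndexError):
            validate_split(tiny_alignment, res, 25, 50)

    @pytest.mark.parametrize("algorithm", ["cobalt", "blue", "cluster", "indepsel"])
    def test_every_returned_split_validates(self, two_cluster_family, algorithm):
        gp, gq = make_graph_pair(two_cluster_family, 25, 50)
        for seed in range(10):
            res = split(gp, gq, replace(LOOSE_CFG, seed=seed), algorithm)
            assert validate_split(two_cluster_family, res, 25, 50).passed


class TestSplitConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p": -1},
            {"q": 101},
            {"min_train": 0},
            {"min_test": 0},
            {"n_reps": 0},
            {"p_select": 0.0},
            {"p_select": 1.0},
            {"mode": "forever"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SplitConfig(**kwargs)
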