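"""MDL scoring and the pruned dynamic-programming exact search."""

from itertools import combinations

import numpy as np
import pytest

import blockbn as bb
from blockbn.dp import BlockSizeError, _score_ties

from conftest import make_chain_net, make_random_net


def _data(cols, cards=None):
    cols = np.asarray(cols).T
    if cards is None:
        cards = cols.max(axis=0) + 1
    return bb.DataMatrix(cols, np.asarray(cards),
                         [f"c{i}" for i in range(cols.shape[1])])


class TestMdlNode:
    def test_hand_worked_binary_marginal(self):
        """Counts (3,1), N=4: H = -(3 ln 3/4 + ln 1/4), K = 1,
        MDL = H + (ln 4 / 2)."""
        d = _data([[0, 0, 0, 1]])
        st = bb.mdl_node(d, 0)
        h_expect = -(3 * np.log(0.75) + 1 * np.log(0.25))
        assert st.entropy == pytest.approx(h_expect, abs=1e-9)
        assert st.complexity == 1
        assert st.mdl == pytest.approx(h_expect + 0.5 * np.log(4) * 1,
                                       abs=1e-9)

    def test_deterministic_child_zero_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 200)
        d = _data([x, x.copy()])
        assert bb.mdl_node(d, 1, (0,)).entropy == pytest.approx(0.0,
                                                                abs=1e-12)

    def test_parameter_count_two_ternary_parents(self):
        rng = np.random.default_rng(1)
        d = _data([rng.integers(0, 2, 60), rng.integers(0, 3, 60),
                   rng.integers(0, 3, 60)], cards=[2, 3, 3])
        assert bb.mdl_node(d, 0, (1, 2)).complexity == (2 - 1) * 3 * 3

    def test_self_parent_rejected(self):
        d = _data([[0, 1]])
        with pytest.raises(ValueError):
            bb.mdl_node(d, 0, (0,))

    def test_entropy_monotone_under_conditioning(self):
        """Adding a parent never increases empirical conditional entropy."""
        for seed in range(5):
            net = make_random_net(4, seed)
            data = bb.forward_sample(net, 500, seed=seed)
            for i in range(4):
                others = [j for j in range(4) if j != i]
                for size in range(len(others)):
                    for pa in combinations(others, size):
                        for extra in others:
                            if extra in pa:
                                continue
                            h0 = bb.mdl_node(data, i, pa).entropy
                            h1 = bb.mdl_node(data, i, pa + (extra,)).entropy
                            assert h1 <= h0 + 1e-9


class TestBestParents:
    def test_empty_candidates(self):
        d = _data([[0, 1, 0, 1]])
        entry = bb.best_parents(d, 0, ())
        assert entry.best_subset == ()
        assert entry.best_mdl == pytest.approx(bb.mdl_node(d, 0).mdl)

    def test_strong_dependence_beats_penalty(self):
        net = make_chain_net(("A", "X"), strength=0.95)
        data = bb.forward_sample(net, 5000, seed=0)
        entry = bb.best_parents(data, 1, (0,))
        assert entry.best_subset == (0,)
        assert bb.mdl_node(data, 1, (0,)).mdl < bb.mdl_node(data, 1).mdl

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_subset_minimisation(self, seed):
        net = make_random_net(7, seed, edge_prob=0.5)
        data = bb.forward_sample(net, 400, seed=seed)
        cands = tuple(range(1, 7))
        entry = bb.best_parents(data, 0, cands)
        scores = {}
        for size in range(len(cands) + 1):
            for S in combinations(cands, size):
                scores[S] = bb.mdl_node(data, 0, S).mdl
        best = min(scores.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))
        assert entry.best_mdl == pytest.approx(best[1], abs=1e-9)
        assert scores[entry.best_subset] == pytest.approx(best[1], abs=1e-9)

    def test_forced_present_in_every_evaluated_set(self):
        net = make_random_net(4, 3)
        data = bb.forward_sample(net, 300, seed=1)
        entry = bb.best_parents(data, 0, (1, 2), forced=(3,))
        assert 3 in entry.best_subset
        assert entry.best_mdl == pytest.approx(
            min(bb.mdl_node(data, 0, tuple(sorted(set(S) | {3}))).mdl
                for size in range(3)
                for S in combinations((1, 2), size)), abs=1e-9)

    def test_best_mdl_monotone_in_candidate_pool(self):
        net = make_random_net(5, 4)
        data = bb.forward_sample(net, 500, seed=2)
        small = bb.best_parents(data, 0, (1, 2)).best_mdl
        large = bb.best_parents(data, 0, (1, 2, 3, 4)).best_mdl
        assert large <= small + 1e-9


class TestDpLearn:
    def test_single_variable(self):
        d = _data([[0, 1, 1, 0]])
        res = bb.dp_learn(d, [0])
        assert res.edges == set()
        assert res.score == pytest.approx(bb.mdl_node(d, 0).mdl)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exhaustive_oracle(self, seed):
        p = 4
        net = make_random_net(p, seed)
        data = bb.forward_sample(net, 1000, seed=seed)
        res = bb.dp_learn(data, list(range(p)))
        _, oracle_score = bb.exhaustive_oracle(data, list(range(p)))
        assert abs(res.score - oracle_score) <= 1e-9 * (1 + abs(oracle_score))
        # the DP structure itself must attain the oracle optimum
        assert _score_ties(_structure_score(data, res.edges), oracle_score)

    def test_order_graph_expands_two_to_the_n(self):
        net = make_random_net(5, 1)
        data = bb.forward_sample(net, 300, seed=0)
        assert bb.dp_learn(data, list(range(5))).n_subsets == 2 ** 5

    def test_pruning_with_complete_skeleton_is_noop(self):
        net = make_random_net(5, 2)
        data = bb.forward_sample(net, 800, seed=3)
        free = bb.dp_learn(data, list(range(5)))
        sk = bb.Skeleton.complete(data.names)
        pruned = bb.dp_learn(data, list(range(5)), skeleton=sk)
        assert pruned.score == pytest.approx(free.score, abs=1e-9)
        assert pruned.edges == free.edges

    def test_skeleton_restricts_edges(self):
        net = make_random_net(4, 5, edge_prob=0.8)
        data = bb.forward_sample(net, 2000, seed=4)
        sk = bb.Skeleton.from_edges(data.names, [(0, 1), (2, 3)])
        res = bb.dp_learn(data, list(range(4)), skeleton=sk)
        allowed = {frozenset(e) for e in [(0, 1), (2, 3)]}
        assert all(frozenset(e) in allowed for e in res.edges)

    def test_decomposability_of_returned_score(self):
        net = make_random_net(5, 6)
        data = bb.forward_sample(net, 700, seed=5)
        res = bb.dp_learn(data, list(range(5)))
        assert res.score == pytest.approx(
            _structure_score(data, res.edges), abs=1e-9)

    def test_forced_external_parent_is_scored_not_structural(self):
        net = make_chain_net(("A", "B", "C"), strength=0.9)
        data = bb.forward_sample(net, 3000, seed=6)
        res = bb.dp_learn(data, [1, 2], forced={1: (0,)})
        assert all(u in (1, 2) for u, v in res.edges)
        # score includes the forced parent's contribution for node 1
        pm = {1: [0], 2: []}
        for u, v in res.edges:
            pm[v].append(u)
        expect = sum(bb.mdl_node(data, v, tuple(sorted(pm[v]))).mdl
                     for v in (1, 2))
        assert res.score == pytest.approx(expect, abs=1e-9)

    def test_cap_enforced(self):
        net = make_random_net(4, 7)
        data = bb.forward_sample(net, 100, seed=0)
        with pytest.raises(BlockSizeError, match="increase k"):
            bb.dp_learn(data, list(range(4)), cap=3)


def _structure_score(data, edges):
    pm = {i: [] for i in range(data.p)}
    for u, v in edges:
        pm[v].append(u)
    return sum(bb.mdl_node(data, i, tuple(sorted(pm[i]))).mdl
               for i in range(data.p))


class TestExhaustiveOracle:
    def test_empty_problem(self):
        d = _data([[0, 1]])
        edges, score = bb.exhaustive_oracle(d, [])
        assert edges == set() and score == 0.0

    def test_dag_count_sequence(self):
        assert bb.count_dags(0) == 1
        assert bb.count_dags(1) == 1
        assert bb.count_dags(2) == 3
        assert bb.count_dags(3) == 25
        assert bb.count_dags(4) == 543

    def test_size_cap(self):
        net = make_random_net(6, 0)
        data = bb.forward_sample(net, 50, seed=0)
        with pytest.raises(BlockSizeError):
            bb.exhaustive_oracle(data, list(range(6)))
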