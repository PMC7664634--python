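"""Shared fixtures: programmatic network builders and the 20-seed
three-block recovery study reused across pipeline-level tests."""

from __future__ import annotations

import numpy as np
import pytest

import blockbn as bb
from blockbn.netcore import DiscreteBayesNet


def make_random_net(p, seed, edge_prob=0.4, card_range=(2, 3)):
    """Random DAG (edges oriented low -> high index) with Dirichlet(0.5)
    CPTs; the workhorse for oracle-equivalence fixtures."""
    rng = np.random.default_rng(seed)
    names = [f"V{i}" for i in range(p)]
    lo, hi = card_range
    cards = {v: int(rng.integers(lo, hi + 1)) for v in names}
    parents = {v: () for v in names}
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_prob:
                parents[names[j]] = parents[names[j]] + (names[i],)
    cpts = {}
    for v in names:
        rows = int(np.prod([cards[q] for q in parents[v]], dtype=int)) \
            if parents[v] else 1
        cpts[v] = rng.dirichlet(np.full(cards[v], 0.5), size=rows)
    return DiscreteBayesNet(names, cards, parents, cpts).validate()


def make_chain_net(labels=("A", "B", "C"), strength=0.9, cards=None):
    """A chain X1 -> X2 -> ... with strong 'copy with noise' CPTs."""
    names = list(labels)
    cards = cards or {v: 2 for v in names}
    parents = {v: () for v in names}
    cpts = {names[0]: np.array([[0.5, 0.5]])}
    for a, b in zip(names, names[1:]):
        parents[b] = (a,)
        s = strength
        cpts[b] = np.array([[s, 1 - s], [1 - s, s]])
    return DiscreteBayesNet(names, cards, parents, cpts).validate()


def index_edges(net):
    """Truth edges as index pairs under the net's own variable order."""
    pos = {v: i for i, v in enumerate(net.variables)}
    return {(pos[u], pos[v]) for u, v in net.edges}


@pytest.fixture(scope="session")
def three_block_study():
    """20 seeded runs of the learner on its reference synthetic fixture:
    3 blocks x 4 nodes, intra-block density 0.6, 2 cross-block edges,
    n = 10000.  Returns a list of dicts with the run, the truth and the
    Hamming decomposition."""
    runs = []
    for seed in range(20):
        spec = bb.SyntheticSpec(n_blocks=3, nodes_per_block=4,
                                intra_density=0.6, n_inter_edges=2,
                                seed=seed)
        net = bb.generate_block_network(spec)
        truth = index_edges(net)
        data = bb.forward_sample(net, 10000, seed=1000 + seed)
        res = bb.blmkm(data, 3, seed=seed)
        runs.append({
            "seed": seed,
            "net": net,
            "truth": truth,
            "result": res,
            "hamming": bb.hamming(res.edges, truth),
        })
    return runs


TOY_BIF_ONE = """\
network toy {
}
variable A {
  type discrete [ 2 ] { a0, a1 };
}
probability ( A ) {
  table 0.5, 0.5;
}
"""

TOY_BIF_TWO = """\
network toy {
}
variable A {
  type discrete [ 2 ] { a0, a1 };
}
variable B {
  type discrete [ 2 ] { b0, b1 };
}
probability ( A ) {
  table 0.3, 0.7;
}
probability ( B | A ) {
  (a0) 0.9, 0.1;
  (a1) 0.2, 0.8;
}
"""


@pytest.fixture
def toy_bif_one(tmp_path):
    path = tmp_path / "one.bif"
    path.write_text(TOY_BIF_ONE)
    return path


@pytest.fixture
def toy_bif_two(tmp_path):
    path = tmp_path / "two.bif"
    path.write_text(TOY_BIF_TWO)
    return path
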