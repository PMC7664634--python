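"""MDL scoring and pruned dynamic-programming exact structure search.

The node score is the minimum-description-length criterion

    MDL(X | PA) = H(X | PA) + (log N / 2) * K(X | PA)
    H(X | PA)   = - sum_{x, pa} N_{x,pa} log(N_{x,pa} / N_{pa})       (nats)
    K(X | PA)   = (r_X - 1) * prod_{L in PA} r_L

with counts from the data (0 log 0 := 0, no smoothing).  The total
structure score is the sum of node scores (decomposability), minimised.

The search walks the *order graph* -- the subset lattice of the
variables, where reaching subset O u {X} from O means X is added as a
leaf with parents drawn from O -- and per variable a *parent graph*,
the subset lattice of its candidate parents caching

    BestMDL(X, P) = min_{S subseteq P} MDL(X | S).

Candidate parents are pruned to the skeleton neighbours of X (the MMPC
skeleton), and a block's variables may carry *forced external parents*
from the cross-block orientation: these appear in every evaluated
parent configuration and are scored, but are not nodes of the
subproblem's DAG.

``exhaustive_oracle`` re-derives the optimum by brute force (all
topological orders x all admissible parent subsets) for cross-checking
on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

from .infotheory import joint_counts

__all__ = [
    "ScoreTerms",
    "ParentGraphEntry",
    "mdl_node",
    "best_parents",
    "dp_learn",
    "exhaustive_oracle",
    "count_dags",
    "DPResult",
    "BlockSizeError",
]


class BlockSizeError(RuntimeError):
    pass


@dataclass
class ScoreTerms:
    """Decomposed node score for X_i with parent set PA."""

    variable: int
    parents: tuple
    entropy: float        # H(X|PA), count-scaled, nats
    complexity: int       # K(X|PA), free-parameter count
    mdl: float            # H + (log N / 2) * K
    n: int

    def __post_init__(self):
        assert self.entropy >= -1e-9
        assert self.complexity >= 1


def mdl_node(data, i, PA=()) -> ScoreTerms:
    """MDL score terms of variable ``i`` with parent set ``PA``.

    A single counting pass builds the (parent-config x state) table;
    zero-count cells contribute nothing to the entropy term.
    """
    PA = tuple(sorted(PA))
    if i in PA:
        raise ValueError("a variable cannot parent itself")
    n = data.n
    ri = int(data.cardinalities[i])
    counts = joint_counts(data, [i, *PA]).astype(float).reshape(ri, -1)
    npa = counts.sum(axis=0)
    nz = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -float(np.sum(counts[nz] * (np.log(counts, where=nz,
                                               out=np.zeros_like(counts))
                                        - np.log(npa)[None, :])[nz]))
    h = max(h, 0.0)
    k = int((ri - 1) * np.prod([data.cardinalities[q] for q in PA],
                               dtype=np.int64))
    mdl = h + 0.5 * np.log(n) * k
    return ScoreTerms(i, PA, h, k, float(mdl), n)


@dataclass
class ParentGraphEntry:
    """BestMDL cache entry: optimum over all subsets of the candidates."""

    variable: int
    candidates: tuple
    best_mdl: float
    best_subset: tuple    # includes forced parents
    forced: tuple


# Scores of Markov-equivalent structures are equal in exact arithmetic
# (entropy sums telescope, parameter counts coincide) but differ by float
# rounding, so ties are detected with a relative tolerance; otherwise the
# secondary tie-breaks would be decided by summation noise.
_TIE_RTOL = 1e-9


def _score_ties(a, b):
    return abs(a - b) <= _TIE_RTOL * (1.0 + max(abs(a), abs(b)))


def _subset_key(score, members):
    """Shared tie-break: smaller score, then smaller set, then lexicographic."""
    return (score, len(members), tuple(sorted(members)))


def _key_better(cand, incumbent):
    """True when ``cand`` beats ``incumbent`` under the fuzzy-score
    (smaller score, then smaller set, then lexicographic) ordering."""
    if _score_ties(cand[0], incumbent[0]):
        return cand[1:] < incumbent[1:]
    return cand[0] < incumbent[0]


class _ParentGraph:
    """Bottom-up memoised BestMDL lattice for one variable.

    ``best[mask]`` is the optimal (score, parents) over subsets of the
    candidate list indexed by ``mask`` bits; forced parents are part of
    every evaluated configuration.
    """

    def __init__(self, data, i, candidates, forced=()):
        self.variable = i
        self.candidates = tuple(sorted(candidates))
        self.forced = tuple(sorted(forced))
        if i in self.candidates or i in self.forced:
            raise ValueError("variable cannot be its own parent candidate")
        c = len(self.candidates)
        self.best = np.empty(1 << c)
        self.best_set = [None] * (1 << c)
        for mask in range(1 << c):
            members = tuple(self.candidates[b] for b in range(c)
                            if (mask >> b) & 1)
            pa = tuple(sorted(set(members) | set(self.forced)))
            raw = mdl_node(data, i, pa).mdl
            key = _subset_key(raw, pa)
            for b in range(c):
                if (mask >> b) & 1:
                    sub = mask ^ (1 << b)
                    cand = _subset_key(self.best[sub], self.best_set[sub])
                    if _key_better(cand, key):
                        key = cand
            self.best[mask] = key[0]
            self.best_set[mask] = key[2]

    def query(self, mask):
        return self.best[mask], self.best_set[mask]

    def full_entry(self):
        full = (1 << len(self.candidates)) - 1
        s, pa = self.query(full)
        return ParentGraphEntry(self.variable, self.candidates, float(s),
                                tuple(pa), self.forced)


def best_parents(data, i, candidates, forced=()) -> ParentGraphEntry:
    """Optimal parent set of ``i``: minimise MDL(i | forced u S) over
    S subseteq candidates, ties broken by smaller set then lexicographic."""
    return _ParentGraph(data, i, candidates, forced).full_entry()


@dataclass
class DPResult:
    variables: tuple
    edges: set            # within-subproblem directed (u, v) index pairs
    external_edges: set   # selected optional external parents (u, v)
    score: float          # total MDL including forced-parent contributions
    order: tuple          # leaf-addition order (first added .. last added)
    n_subsets: int        # order-graph size expanded (2^p)


def dp_learn(data, variables, skeleton=None, forced=None, cap=25,
             optional_ext=None) -> DPResult:
    """Globally MDL-optimal DAG over ``variables`` via order-graph DP.

    Candidate parents of each variable are its skeleton neighbours
    inside ``variables`` (everything, when ``skeleton`` is None);
    ``forced`` maps a variable to external parents that are scored in
    every configuration but are not part of this DAG.  ``optional_ext``
    maps a variable to external parents that *compete* as ordinary
    candidates instead of being mandatory; the chosen ones are reported
    in ``external_edges``.  Exact search is exponential in
    ``len(variables)``; beyond ``cap`` variables a
    :class:`BlockSizeError` asks for a finer blocking instead of an
    open-ended run.
    """
    variables = sorted(variables)
    p = len(variables)
    if p > cap:
        raise BlockSizeError(
            f"{p} variables exceed the exact-search cap {cap}; "
            f"increase k so blocks are smaller")
    if p == 0:
        return DPResult((), set(), set(), 0.0, (), 1)
    forced = forced or {}
    optional_ext = optional_ext or {}
    for v, ext in list(forced.items()) + list(optional_ext.items()):
        if set(ext) & set(variables):
            raise ValueError("external parents must lie outside the subproblem")
    pos = {v: b for b, v in enumerate(variables)}
    inset = set(variables)

    # candidate parents per variable: skeleton neighbours within the set,
    # plus any optional external candidates (always available)
    pgs = [None] * p
    cand_masks = [0] * p
    ext_masks = [0] * p
    for b, v in enumerate(variables):
        if skeleton is None:
            cands = [u for u in variables if u != v]
        else:
            cands = [u for u in skeleton.neighbors(v) if u in inset and u != v]
        cands = sorted(set(cands) | set(optional_ext.get(v, ())))
        pgs[b] = _ParentGraph(data, v, cands, forced.get(v, ()))
        m = e = 0
        for ci, u in enumerate(pgs[b].candidates):
            if u in inset:
                m |= 1 << pos[u]
            else:
                e |= 1 << ci
        cand_masks[b] = m
        ext_masks[b] = e

    # map a variable-set mask to the local mask of b's candidate list
    def local_mask(b, varmask):
        inter = varmask & cand_masks[b]
        lm = ext_masks[b]          # externals are always available
        for ci, u in enumerate(pgs[b].candidates):
            if u in inset and (inter >> pos[u]) & 1:
                lm |= 1 << ci
        return lm

    full = (1 << p) - 1
    score = np.full(1 << p, np.inf)
    score[0] = 0.0
    back = [None] * (1 << p)
    for target in range(1, full + 1):
        best = np.inf
        best_bp = None
        # descending leaf index: on exact ties the larger-index variable
        # stays the later leaf, a fixed deterministic preference
        for b in range(p - 1, -1, -1):
            if not (target >> b) & 1:
                continue
            prev = target ^ (1 << b)
            s_leaf, pa = pgs[b].query(local_mask(b, prev))
            s = score[prev] + s_leaf
            if best_bp is None or (not _score_ties(s, best) and s < best):
                best = s
                best_bp = (b, pa)
        score[target] = best
        back[target] = best_bp

    # reconstruct: peel leaves from the full set
    edges = set()
    ext_edges = set()
    order_rev = []
    mask = full
    while mask:
        b, pa = back[mask]
        v = variables[b]
        order_rev.append(v)
        for u in pa:
            if u in inset:
                edges.add((u, v))
            elif u not in forced.get(v, ()):   # chosen optional external
                ext_edges.add((u, v))
            # forced externals are score-level only, never DAG edges here
        mask ^= 1 << b
    order = tuple(reversed(order_rev))
    _assert_acyclic(edges, variables)
    return DPResult(tuple(variables), edges, ext_edges, float(score[full]),
                    order, 1 << p)


def _assert_acyclic(edges, variables):
    import networkx as nx
    g = nx.DiGraph()
    g.add_nodes_from(variables)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise AssertionError("reconstructed subnetwork is cyclic")


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def exhaustive_oracle(data, variables, skeleton=None, forced=None,
                      max_vars=5):
    """Brute-force optimum over every admissible DAG on ``variables``.

    Enumerates all topological orders and, per order and variable, every
    parent subset drawn from the variable's admissible candidates among
    its predecessors; scores each assembled DAG by the decomposable MDL
    sum and returns ``(edges, score)`` for the minimum, tie-broken by
    (score, lexicographic sorted edge list).  Independent of the DP
    recurrences by construction; capped at ``max_vars`` variables.
    """
    variables = sorted(variables)
    p = len(variables)
    if p > max_vars:
        raise BlockSizeError(f"oracle capped at {max_vars} variables")
    if p == 0:
        return set(), 0.0
    forced = forced or {}
    inset = set(variables)
    cands = {}
    for v in variables:
        if skeleton is None:
            cands[v] = [u for u in variables if u != v]
        else:
            cands[v] = sorted(u for u in skeleton.neighbors(v)
                              if u in inset and u != v)

    raw = {}

    def node_score(v, members):
        key = (v, tuple(sorted(members)))
        if key not in raw:
            pa = tuple(sorted(set(members) | set(forced.get(v, ()))))
            raw[key] = mdl_node(data, v, pa).mdl
        return raw[key]

    best_score = np.inf
    best_edges = None
    seen = set()
    for perm in permutations(variables):
        pred = set()
        choices = []      # per variable: list of (subset, score)
        for v in perm:
            allowed = [u for u in cands[v] if u in pred]
            opts = []
            for size in range(len(allowed) + 1):
                for S in combinations(allowed, size):
                    opts.append((S, node_score(v, S)))
            choices.append((v, opts))
            pred.add(v)
        # expand the cartesian product iteratively
        stack = [((), 0.0, 0)]
        while stack:
            edges_acc, score_acc, depth = stack.pop()
            if depth == p:
                canon = tuple(sorted(edges_acc))
                if canon in seen:
                    continue
                seen.add(canon)
                take = (best_edges is None
                        or (_score_ties(score_acc, best_score)
                            and canon < tuple(sorted(best_edges)))
                        or (not _score_ties(score_acc, best_score)
                            and score_acc < best_score))
                if take:
                    best_score, best_edges = score_acc, set(edges_acc)
                continue
            v, opts = choices[depth]
            for S, s in opts:
                stack.append((edges_acc + tuple((u, v) for u in S),
                              score_acc + s, depth + 1))
    return best_edges, float(best_score)


def count_dags(p):
    """Number of labelled DAGs on ``p`` nodes by direct enumeration
    (1, 1, 3, 25, 543, 29281, ...); a structural sanity check."""
    variables = list(range(p))
    seen = set()
    for perm in permutations(variables):
        pred = []
        per_var = []
        for v in perm:
            per_var.append((v, list(pred)))
            pred.append(v)
        stack = [((), 0)]
        while stack:
            edges_acc, depth = stack.pop()
            if depth == p:
                seen.add(tuple(sorted(edges_acc)))
                continue
            v, allowed = per_var[depth]
            for size in range(len(allowed) + 1):
                for S in combinations(allowed, size):
                    stack.append((edges_acc + tuple((u, v) for u in S),
                                  depth + 1))
    return len(seen)
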