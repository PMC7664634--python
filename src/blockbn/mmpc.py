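"""MMPC (max-min parents and children) skeleton discovery.

Per variable X, a forward phase greedily adds the candidate whose
*weakest* association with X -- minimised over conditioning subsets of
the current PC set -- is strongest ("max-min"), stopping when no
remaining candidate is dependent at level alpha.  A backward phase then
drops any PC member that some conditioning subset renders independent
of X.  The per-variable PC sets are symmetrised with an AND rule into a
0-1 adjacency matrix: the network skeleton.

Association is measured by the G-squared test: smaller p-value =
stronger association, ties broken by larger statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .infotheory import ci_test

__all__ = ["Skeleton", "mmpc_pc", "mmpc_skeleton"]

logger = logging.getLogger(__name__)


@dataclass
class Skeleton:
    """Symmetric 0-1 adjacency matrix over the variables (zero diagonal)."""

    adjacency: np.ndarray
    names: list

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=np.int8)
        if not np.array_equal(a, a.T) or np.any(np.diag(a)):
            raise ValueError("skeleton must be symmetric with zero diagonal")
        self.adjacency = a

    @property
    def p(self):
        return self.adjacency.shape[0]

    def neighbors(self, i):
        return [int(j) for j in np.flatnonzero(self.adjacency[i])]

    def pc_sets(self):
        return {i: set(self.neighbors(i)) for i in range(self.p)}

    def edges(self):
        """Undirected edges as sorted (i, j) pairs, i < j."""
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return [(int(a), int(b)) for a, b in zip(ii, jj)]

    @classmethod
    def complete(cls, names):
        p = len(names)
        return cls(np.ones((p, p), dtype=np.int8) - np.eye(p, dtype=np.int8),
                   list(names))

    @classmethod
    def from_edges(cls, names, edges):
        p = len(names)
        a = np.zeros((p, p), dtype=np.int8)
        for u, v in edges:
            a[u, v] = a[v, u] = 1
        np.fill_diagonal(a, 0)
        return cls(a, list(names))

    def to_tsv(self, path):
        pd.DataFrame(self.adjacency, columns=self.names).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path):
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=np.int8), [str(c) for c in df.columns])


def _min_association(data, i, j, pc, max_cond):
    """Weakest association of (i, j) over conditioning subsets of ``pc``.

    Returns ``(max_p, -max_g2_at_max_p)`` -- the subset that best
    explains the pair away.  Larger tuple = weaker association.
    """
    worst = (-1.0, 0.0)
    for size in range(0, min(max_cond, len(pc)) + 1):
        for S in combinations(sorted(pc), size):
            res = ci_test(data, i, j, S)
            key = (res.p_value, -res.statistic)
            if key > worst:
                worst = key
    return worst


def mmpc_pc(data, i, alpha=0.05, max_cond=3, pc_cap=10):
    """Parents-and-children candidates of variable ``i``.

    Forward: add the candidate with the strongest min-association while
    that min-association is significant at ``alpha``.  Backward: remove
    any member that becomes independent of ``i`` given some subset of
    the remaining members.  ``pc_cap`` bounds the forward phase (a
    warning is logged when it bites).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    pc = []
    candidates = [j for j in range(data.p) if j != i]
    while candidates:
        if len(pc) >= pc_cap:
            logger.warning("PC(%d) reached cap %d; stopping forward phase",
                           i, pc_cap)
            break
        scored = []
        for j in candidates:
            max_p, neg_g2 = _min_association(data, i, j, pc, max_cond)
            scored.append(((max_p, neg_g2, j), j))
        # strongest min-association: smallest worst-case p-value
        (best_p, _, _), best_j = min(scored)
        if best_p >= alpha:
            break
        pc.append(best_j)
        candidates.remove(best_j)

    # backward: try to explain each member away by subsets of the others
    kept = list(pc)
    for y in list(kept):
        others = [z for z in kept if z != y]
        removed = False
        for size in range(0, min(max_cond, len(others)) + 1):
            for S in combinations(others, size):
                if ci_test(data, i, y, S).p_value >= alpha:
                    removed = True
                    break
            if removed:
                break
        if removed:
            kept.remove(y)
    return set(kept)


def mmpc_skeleton(data, alpha=0.05, max_cond=3, pc_cap=10) -> Skeleton:
    """Whole-network skeleton: edge (i, j) iff j in PC(i) AND i in PC(j).

    The AND symmetry rule keeps the skeleton conservative, which is what
    lets downstream structure search add no edge outside it.
    """
    pcs = [mmpc_pc(data, i, alpha=alpha, max_cond=max_cond, pc_cap=pc_cap)
           for i in range(data.p)]
    p = data.p
    adj = np.zeros((p, p), dtype=np.int8)
    for i in range(p):
        for j in pcs[i]:
            if i in pcs[j]:
                adj[i, j] = adj[j, i] = 1
    return Skeleton(adj, list(data.names))
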