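"""Mutual-information K-medoid blocking of network variables.

Variables are partitioned into k blocks by a K-means-style alternation,
with two changes that suit Bayesian-network nodes: similarity is mutual
information (higher = more dependent) instead of Euclidean distance, and
cluster centres are medoids -- actual member variables -- updated by
cost-improving replacement, since a "mean node" has no meaning in a
network.  The clustering cost of a block is the sum of MI between each
member and the medoid; total cost is maximised and is non-decreasing
across iterations, which guarantees termination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .infotheory import mi_matrix

__all__ = ["Blocking", "cluster_cost", "mkm", "suggest_k"]


@dataclass
class Blocking:
    """A partition of variable indices into k blocks with one medoid each."""

    k: int
    clusters: list            # list of sorted index lists
    medoids: list             # medoids[c] is a member of clusters[c]
    cost: float
    seed: int | None = None
    n_iter: int = 0
    history: list = field(default_factory=list, repr=False)

    def validate(self, p=None):
        seen = [i for c in self.clusters for i in c]
        if len(seen) != len(set(seen)):
            raise ValueError("clusters overlap")
        if p is not None and sorted(seen) != list(range(p)):
            raise ValueError("clusters do not cover all variables")
        for c, m in zip(self.clusters, self.medoids):
            if m not in c:
                raise ValueError("medoid outside its cluster")
        if self.k != sum(1 for c in self.clusters if c):
            raise ValueError("k != number of nonempty clusters")
        return self

    def block_of(self):
        """Map variable index -> block index."""
        out = {}
        for b, members in enumerate(self.clusters):
            for i in members:
                out[i] = b
        return out

    def to_json(self, path=None):
        doc = {"k": self.k, "clusters": [list(map(int, c)) for c in self.clusters],
               "medoids": list(map(int, self.medoids)),
               "cost": self.cost, "seed": self.seed, "n_iter": self.n_iter}
        if path is None:
            return json.dumps(doc, indent=2)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            doc = json.load(fh)
        return cls(doc["k"], doc["clusters"], doc["medoids"], doc["cost"],
                   doc.get("seed"), doc.get("n_iter", 0))


def cluster_cost(mi, cluster, medoid):
    """Sum of MI between the medoid and every other member.

    A singleton cluster costs 0 (empty sum).
    """
    if medoid not in set(cluster):
        raise ValueError("medoid must belong to the cluster")
    return float(sum(mi[x, medoid] for x in cluster if x != medoid))


def total_cost(mi, clusters, medoids):
    return float(sum(cluster_cost(mi, c, m) for c, m in zip(clusters, medoids)))


def _assign(mi, medoids, p):
    """Assign every non-medoid to the medoid of maximal MI.

    Ties, and variables with zero MI to every medoid, go to the
    lowest-index medoid (deterministic).
    """
    order = sorted(medoids)
    clusters = {m: [m] for m in medoids}
    for x in range(p):
        if x in clusters:
            continue
        best = max(order, key=lambda m: (mi[x, m], -m))
        clusters[best].append(x)
    return [sorted(clusters[m]) for m in order], order


def mkm(data, k, seed=0, max_iter=100, mi=None, plusplus_init=False):
    """MI K-medoid blocking of the columns of ``data`` into ``k`` blocks.

    Alternates (a) assignment of each variable to its max-MI medoid and
    (b) a full sweep of medoid replacement: within each block, any
    member whose promotion to medoid strictly increases the block cost
    replaces the current medoid.  Stops when a sweep changes no medoid
    or after ``max_iter`` iterations.

    Parameters
    ----------
    mi : ndarray, optional
        Precomputed MI matrix (else computed from ``data``).
    plusplus_init : bool
        Spread the initial medoids (greedy farthest-in-MI choice) instead
        of uniform random choice.
    """
    p = data.p
    if not (1 <= k <= p):
        raise ValueError(f"k={k} out of range [1, {p}]")
    if mi is None:
        mi = mi_matrix(data)
    rng = np.random.default_rng(seed)
    if plusplus_init:
        medoids = [int(rng.integers(p))]
        while len(medoids) < k:
            # farthest-point analogue: pick the variable with the lowest
            # maximal MI to existing medoids (weakest attachment)
            rest = [x for x in range(p) if x not in medoids]
            medoids.append(min(rest, key=lambda x: (max(mi[x, m] for m in medoids), x)))
    else:
        medoids = sorted(int(m) for m in rng.choice(p, size=k, replace=False))

    history = []
    clusters = None
    for it in range(1, max_iter + 1):
        clusters, medoids = _assign(mi, medoids, p)
        changed = False
        new_medoids = []
        for c, m in zip(clusters, medoids):
            best_m, best_cost = m, cluster_cost(mi, c, m)
            for x in c:
                if x == m:
                    continue
                cand = cluster_cost(mi, c, x)
                if cand > best_cost + 1e-15:
                    best_m, best_cost = x, cand
            if best_m != m:
                changed = True
            new_medoids.append(best_m)
        medoids = new_medoids
        history.append(total_cost(mi, clusters, medoids))
        if not changed:
            break
    # final assignment under the settled medoids
    clusters, medoids = _assign(mi, medoids, p)
    cost = total_cost(mi, clusters, medoids)
    history.append(cost)
    return Blocking(k, clusters, list(medoids), cost, seed=seed,
                    n_iter=len(history) - 1, history=history).validate(p)


def suggest_k(p):
    """Rule-of-thumb block count, round(sqrt(p/2)); never applied silently."""
    return max(1, int(round(np.sqrt(p / 2.0))))
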