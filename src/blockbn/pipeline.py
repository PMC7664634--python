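"""End-to-end block learner: block the variables, learn the skeleton,
enumerate cross-block orientations, solve each block's constrained exact
search, assemble, and keep the BIC-best acyclic candidate.  Also the
structural evaluation (added / missing / inverted edge decomposition of
the Hamming distance) against a known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .combiner import build_candidate, enumerate_orientations, find_interblock_edges
from .dp import dp_learn, mdl_node
from .mkm import mkm
from .mmpc import Skeleton, mmpc_skeleton

__all__ = [
    "BlmkmConfig",
    "LearnedNetwork",
    "BicScore",
    "HammingDecomposition",
    "blmkm",
    "bic_score",
    "hamming",
]

logger = logging.getLogger(__name__)


@dataclass
class BlmkmConfig:
    """Tunable knobs of the block learner.

    alpha : CI-test significance for skeleton discovery (default 0.05).
    max_cond : largest conditioning-set size in MMPC tests.
    pc_cap : forward-phase cap on a PC set's size.
    orientation_cap : maximum number of cross-block edges (2^m candidates).
    dp_cap : largest block solvable by exact search.
    mkm_max_iter : medoid-replacement iteration cap (monotone cost makes
        this a safety net only).
    forced_mandatory : cross-block parents are mandatory in their child's
        score (False downgrades them to optional candidates).
    """

    alpha: float = 0.05
    max_cond: int = 3
    pc_cap: int = 10
    orientation_cap: int = 16
    dp_cap: int = 25
    mkm_max_iter: int = 100
    forced_mandatory: bool = True

    def validate(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("max_cond", "pc_cap", "orientation_cap", "dp_cap",
                     "mkm_max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        return self


@dataclass
class BicScore:
    """BIC: log-likelihood at ML parameters minus (d/2) log m.

    ``raw = loglik - (d/2) log m`` exactly; ``per_sample = raw / m`` is
    also reported because published magnitudes are often normalised.
    """

    loglik: float
    d: int
    m: int
    raw: float
    per_sample: float


@dataclass
class HammingDecomposition:
    """A = added, M = missing, I = inverted, H = A + M + I."""

    A: int
    M: int
    I: int

    @property
    def H(self):
        return self.A + self.M + self.I

    def as_dict(self):
        return {"A": self.A, "M": self.M, "I": self.I, "H": self.H}


@dataclass
class LearnedNetwork:
    """Result bundle of one block-learning run."""

    names: list
    edges: set                    # directed (i, j) index pairs
    mdl: float                    # decomposable MDL of the selected network
    bic: BicScore
    blocking: object
    skeleton: Skeleton
    interblock_edges: list
    candidate_scores: list        # (bitmask, total MDL, acyclic) per candidate
    selected_bitmask: int
    n_cyclic_discarded: int
    provenance: dict = field(default_factory=dict)

    @property
    def named_edges(self):
        return {(self.names[u], self.names[v]) for u, v in self.edges}

    def parent_map(self):
        pm = {i: [] for i in range(len(self.names))}
        for u, v in self.edges:
            pm[v].append(u)
        return {v: sorted(us) for v, us in pm.items()}


def bic_score(data, edges) -> BicScore:
    """BIC of a structure under maximum-likelihood count parameters.

    Decomposable: ``loglik = -sum_i H(X_i | PA_i)`` (count-scaled
    entropies), ``d = sum_i K(X_i | PA_i)``.
    """
    p = data.p
    parents = {i: [] for i in range(p)}
    for u, v in edges:
        parents[v].append(u)
    loglik = 0.0
    d = 0
    for i in range(p):
        st = mdl_node(data, i, tuple(parents[i]))
        loglik -= st.entropy
        d += st.complexity
    m = data.n
    raw = loglik - 0.5 * d * np.log(m)
    return BicScore(float(loglik), int(d), int(m), float(raw),
                    float(raw / m))


def total_mdl(data, edges):
    """Decomposable MDL of a full structure (sum of node scores)."""
    p = data.p
    parents = {i: [] for i in range(p)}
    for u, v in edges:
        parents[v].append(u)
    return float(sum(mdl_node(data, i, tuple(parents[i])).mdl
                     for i in range(p)))


def hamming(learned_edges, truth_edges, n_variables=None) -> HammingDecomposition:
    """Structural Hamming decomposition of ``learned`` against ``truth``.

    Pairs adjacent in both but with opposite direction count as
    inverted; adjacencies only in the learned (resp. true) network count
    as added (resp. missing).
    """
    learned = set(learned_edges)
    truth = set(truth_edges)
    lu = {frozenset(e) for e in learned}
    tu = {frozenset(e) for e in truth}
    inverted = sum(1 for (u, v) in learned
                   if (v, u) in truth and (u, v) not in truth)
    added = len(lu - tu)
    missing = len(tu - lu)
    return HammingDecomposition(added, missing, inverted)


def blmkm(data, k, seed=0, config: BlmkmConfig | None = None,
          skeleton: Skeleton | None = None,
          blocking=None) -> LearnedNetwork:
    """Learn a Bayesian-network structure by block decomposition.

    Steps: (1) MI K-medoid blocking into ``k`` blocks; (2) MMPC skeleton;
    (3) enumerate all 2^m orientations of the cross-block skeleton edges;
    (4) per orientation, exact MDL search inside each block with the
    oriented cross edges as forced external parents (block results are
    cached on (block, forced-parents) so orientations share work);
    (5) assemble each candidate, discard cyclic assemblies, and keep the
    candidate with maximal BIC (equivalently minimal total MDL).

    ``skeleton``/``blocking`` may be supplied to bypass stages (e.g. the
    true skeleton in calibration studies).
    """
    config = (config or BlmkmConfig()).validate()
    if blocking is None:
        blocking = mkm(data, k, seed=seed, max_iter=config.mkm_max_iter)
    if skeleton is None:
        skeleton = mmpc_skeleton(data, alpha=config.alpha,
                                 max_cond=config.max_cond,
                                 pc_cap=config.pc_cap)

    inter = find_interblock_edges(skeleton, blocking)
    orientations = enumerate_orientations(inter, cap=config.orientation_cap)
    logger.info("blocks=%d inter-block edges=%d candidates=%d",
                blocking.k, len(inter), len(orientations))

    cache = {}

    def solve_block(block, forced_map, optional_map):
        key = (tuple(block),
               tuple(sorted((v, forced_map[v]) for v in forced_map)),
               tuple(sorted((v, optional_map[v]) for v in optional_map)))
        if key not in cache:
            cache[key] = dp_learn(data, block, skeleton=skeleton,
                                  forced=forced_map, cap=config.dp_cap,
                                  optional_ext=optional_map)
        return cache[key]

    candidate_scores = []
    best = None           # (mdl, bitmask, edges)
    n_cyclic = 0
    for orientation in orientations:
        cand = build_candidate(blocking, skeleton, orientation)
        edges = set()
        score = 0.0
        for block in cand.blocks:
            ext = {v: cand.forced_for(v) for v in block
                   if cand.forced_for(v)}
            if config.forced_mandatory:
                fmap, omap = ext, {}
            else:
                # downgraded: cross parents compete as ordinary candidates
                fmap, omap = {}, ext
            res = solve_block(block, fmap, omap)
            score += res.score
            edges |= res.edges
            edges |= res.external_edges
        if config.forced_mandatory:
            edges |= set(orientation)
        g = nx.DiGraph()
        g.add_nodes_from(range(data.p))
        g.add_edges_from(edges)
        acyclic = nx.is_directed_acyclic_graph(g)
        if not acyclic:
            n_cyclic += 1
            logger.info("candidate %d discarded: cyclic assembly",
                        cand.bitmask)
        candidate_scores.append((cand.bitmask, float(score), acyclic))
        if acyclic and (best is None or (score, cand.bitmask) < best[:2]):
            best = (score, cand.bitmask, edges)
    if best is None:
        raise RuntimeError(
            f"all {len(orientations)} candidates produced cyclic assemblies; "
            f"inter-block edges: {[(e.i, e.j) for e in inter]}")

    score, bitmask, edges = best
    full_mdl = total_mdl(data, edges)
    bic = bic_score(data, edges)
    return LearnedNetwork(
        names=list(data.names),
        edges=edges,
        mdl=full_mdl,
        bic=bic,
        blocking=blocking,
        skeleton=skeleton,
        interblock_edges=[(e.i, e.j) for e in inter],
        candidate_scores=candidate_scores,
        selected_bitmask=bitmask,
        n_cyclic_discarded=n_cyclic,
        provenance={"k": k, "seed": seed, "alpha": config.alpha,
                    "max_cond": config.max_cond,
                    "orientation_cap": config.orientation_cap,
                    "dp_cap": config.dp_cap,
                    "forced_mandatory": config.forced_mandatory,
                    "n_candidates": len(orientations),
                    "n_cyclic_discarded": n_cyclic},
    )
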