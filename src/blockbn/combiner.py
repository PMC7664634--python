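"""Cross-block edge handling: find the skeleton edges that straddle two
blocks, enumerate every orientation of them (2^m assignments), and build
the per-block constrained learning problems.

Because cross-block connectivity is sparse by construction of the
blocking, m is small and exhaustive orientation is affordable; each
orientation turns the head of every cross edge into a *forced external
parent* of its tail's block problem, so no parent outside a block is
ever missed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "InterBlockEdge",
    "CandidateProblem",
    "OrientationCapError",
    "find_interblock_edges",
    "enumerate_orientations",
    "build_candidate",
]


@dataclass(frozen=True, order=True)
class InterBlockEdge:
    """Undirected skeleton edge whose endpoints lie in different blocks."""

    i: int
    j: int

    def oriented(self, forward: bool):
        """Directed pair: (i -> j) if forward else (j -> i)."""
        return (self.i, self.j) if forward else (self.j, self.i)


class OrientationCapError(RuntimeError):
    pass


@dataclass
class CandidateProblem:
    """One orientation of the cross-block edges plus its per-block
    constrained subproblems."""

    orientation: tuple            # directed (u, v) per inter-block edge
    bitmask: int                  # bit e set <=> edge e reversed (j -> i)
    blocks: list                  # list of sorted member-index lists
    forced: dict = field(default_factory=dict)  # child -> sorted ext parents

    def forced_for(self, v):
        return self.forced.get(v, ())


def find_interblock_edges(skeleton, blocking):
    """Skeleton edges with endpoints in different blocks, in lexicographic
    order."""
    if skeleton.p != sum(len(c) for c in blocking.clusters):
        raise ValueError("skeleton and blocking cover different variables")
    block_of = blocking.block_of()
    return [InterBlockEdge(i, j) for i, j in skeleton.edges()
            if block_of[i] != block_of[j]]


def enumerate_orientations(edges, cap=16):
    """All 2^m direction assignments of the cross-block edges.

    Deterministic binary-counting order over the lexicographic edge
    list: bit e of the assignment index reverses edge e.  Raises
    :class:`OrientationCapError` beyond ``cap`` edges.
    """
    m = len(edges)
    if m > cap:
        raise OrientationCapError(
            f"{m} inter-block edges exceed the orientation cap {cap} "
            f"(2^{m} candidates); raise the cap or use a coarser blocking "
            f"(smaller k)")
    edges = sorted(edges)
    out = []
    for mask in range(1 << m):
        out.append(tuple(e.oriented(forward=not (mask >> b) & 1)
                         for b, e in enumerate(edges)))
    return out


def build_candidate(blocking, skeleton, orientation) -> CandidateProblem:
    """Per-block constrained problems for one orientation assignment.

    For each directed cross edge u -> v, u becomes a forced external
    parent in v's block problem; within-block structure remains
    restricted to the skeleton by the downstream search.
    """
    expected = {frozenset((e.i, e.j))
                for e in find_interblock_edges(skeleton, blocking)}
    got = {frozenset(uv) for uv in orientation}
    if got != expected:
        raise ValueError("orientation does not cover the inter-block edges")
    forced = {}
    for u, v in orientation:
        forced.setdefault(v, set()).add(u)
    mask = 0
    directed = {frozenset(uv): uv for uv in orientation}
    for b, e in enumerate(sorted(expected, key=lambda e: tuple(sorted(e)))):
        u, v = sorted(e)
        if directed[e] == (v, u):
            mask |= 1 << b
    return CandidateProblem(
        orientation=tuple(orientation),
        bitmask=mask,
        blocks=[list(c) for c in blocking.clusters],
        forced={v: tuple(sorted(s)) for v, s in forced.items()},
    )


def dump_candidates(candidates, path=None):
    """Audit dump: orientation bitmask -> forced-parent map, as JSON."""
    doc = [{"bitmask": c.bitmask,
            "orientation": [list(uv) for uv in c.orientation],
            "forced": {str(k): list(v) for k, v in c.forced.items()}}
           for c in candidates]
    if path is None:
        return json.dumps(doc, indent=2)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
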