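"""Network and data containers: discrete Bayesian networks, BIF I/O,
ancestral sampling, and the synthetic sparse-block network generator.

A discrete Bayesian network is a DAG over categorical variables plus one
conditional probability table (CPT) per variable.  The joint distribution
factorises as ``P(X_1..X_n) = prod_i P(X_i | pa(X_i))``.  States are coded
as 0-based contiguous integers throughout; BIF state labels are kept as
metadata only.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DiscreteBayesNet",
    "DataMatrix",
    "SyntheticSpec",
    "read_bif",
    "write_bif",
    "forward_sample",
    "generate_block_network",
    "BifParseError",
]

_CPT_ATOL = 1e-6


class BifParseError(ValueError):
    """Raised on malformed BIF input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class DiscreteBayesNet:
    """DAG + CPTs over discrete variables.

    Parameters
    ----------
    variables : list of str
        Variable names in declaration order.
    cardinalities : dict str -> int
        Number of states (>= 2) per variable.
    parents : dict str -> tuple of str
        Ordered parent list per variable (defines CPT row indexing).
    cpts : dict str -> ndarray, shape (prod parent cards, r_i)
        Row ``k`` is P(X_i | parent configuration k) where ``k`` is the
        C-order (last parent fastest) mixed-radix index of the parent
        states in ``parents[v]`` order.
    state_names : dict str -> list of str, optional
        Original state labels (BIF metadata).
    """

    variables: list
    cardinalities: dict
    parents: dict
    cpts: dict
    state_names: dict = field(default_factory=dict)

    # -- derived views ------------------------------------------------
    @property
    def edges(self):
        """Set of directed (parent, child) pairs."""
        return {(p, v) for v in self.variables for p in self.parents.get(v, ())}

    @property
    def n_variables(self):
        return len(self.variables)

    def to_digraph(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self):
        return list(nx.topological_sort(self.to_digraph()))

    def validate(self):
        """Check the structural invariants; raise ValueError on violation."""
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge relation is cyclic")
        for v in self.variables:
            r = self.cardinalities[v]
            if r < 2:
                raise ValueError(f"{v}: cardinality {r} < 2")
            pa = self.parents.get(v, ())
            expect_rows = int(np.prod([self.cardinalities[p] for p in pa], dtype=np.int64)) if pa else 1
            cpt = np.asarray(self.cpts[v], dtype=float)
            if cpt.shape != (expect_rows, r):
                raise ValueError(
                    f"{v}: CPT shape {cpt.shape} != ({expect_rows}, {r})")
            if np.any(cpt < -1e-12) or np.any(cpt > 1 + 1e-12):
                raise ValueError(f"{v}: CPT entries outside [0,1]")
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{v}: CPT rows do not sum to 1")
        return self

    def states_of(self, v):
        return self.state_names.get(
            v, [str(s) for s in range(self.cardinalities[v])])


@dataclass
class DataMatrix:
    """Complete-case n x p matrix of 0-based integer state codes."""

    values: np.ndarray
    cardinalities: np.ndarray
    names: list

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.int64)
        self.cardinalities = np.asarray(self.cardinalities, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one sample")
        if self.values.shape[1] != len(self.cardinalities) or \
                self.values.shape[1] != len(self.names):
            raise ValueError("column metadata length mismatch")
        if np.any(self.values < 0) or np.any(self.values >= self.cardinalities):
            raise ValueError("state code out of range for its cardinality")

    @property
    def n(self):
        return self.values.shape[0]

    @property
    def p(self):
        return self.values.shape[1]

    def column(self, i):
        return self.values[:, i]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cardinalities=None):
        """Build from an integer-coded DataFrame.

        Missing values are rejected; cardinalities default to per-column
        ``max + 1``.
        """
        if df.isna().any().any():
            raise ValueError("missing entries are not supported")
        values = df.to_numpy(dtype=np.int64)
        if cardinalities is None:
            cardinalities = values.max(axis=0) + 1 if len(values) else None
        return cls(values, cardinalities, [str(c) for c in df.columns])

    @classmethod
    def read_csv(cls, path, delimiter=None, cardinalities=None):
        """Read a delimited text file with a header row.

        The delimiter is sniffed from the header when not given.
        """
        if delimiter is None:
            with open(path) as fh:
                header = fh.readline()
            delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
        df = pd.read_csv(path, sep=delimiter)
        return cls.from_dataframe(df, cardinalities=cardinalities)

    def to_csv(self, path, delimiter=","):
        pd.DataFrame(self.values, columns=self.names).to_csv(
            path, sep=delimiter, index=False)

    def subset(self, columns):
        idx = list(columns)
        return DataMatrix(self.values[:, idx], self.cardinalities[idx],
                          [self.names[i] for i in idx])


@dataclass
class SyntheticSpec:
    """Recipe for a sparse block-structured ground-truth network: several
    densely connected blocks joined by a handful of cross-block edges."""

    n_blocks: int = 3
    nodes_per_block: int = 4
    intra_density: float = 0.6
    n_inter_edges: int = 2
    cardinality_range: tuple = (2, 3)
    seed: int = 0

    def validate(self):
        if self.n_blocks < 1 or self.nodes_per_block < 1:
            raise ValueError("block counts must be positive")
        if not (0 < self.intra_density <= 1):
            raise ValueError("intra_density must lie in (0, 1]")
        lo, hi = self.cardinality_range
        if lo < 2 or hi < lo:
            raise ValueError("cardinality range must satisfy 2 <= lo <= hi")
        if self.n_inter_edges < 0:
            raise ValueError("n_inter_edges must be >= 0")
        if self.n_blocks == 1 and self.n_inter_edges > 0:
            raise ValueError("cannot place inter-block edges with one block")
        return self


# ---------------------------------------------------------------------------
# BIF reading / writing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"//[^\n]*|/\*.*?\*/|[A-Za-z0-9_.\-]+|[{}()\[\];,|]", re.S)


def _tokenize(text):
    """Yield (token, line) pairs, skipping comments."""
    line = 1
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        line += text.count("\n", pos, m.start())
        pos = m.start()
        tok = m.group(0)
        if tok.startswith("//") or tok.startswith("/*"):
            continue
        yield tok, line


class _TokenStream:
    def __init__(self, text):
        self.toks = list(_tokenize(text))
        self.i = 0

    def peek(self):
        return self.toks[self.i] if self.i < len(self.toks) else (None, -1)

    def next(self, expect=None):
        tok, line = self.peek()
        if tok is None:
            raise BifParseError("unexpected end of file")
        self.i += 1
        if expect is not None and tok != expect:
            raise BifParseError(f"expected '{expect}', got '{tok}'", line)
        return tok, line

    def skip_block(self):
        """Consume a balanced { ... } block."""
        self.next("{")
        depth = 1
        while depth:
            tok, line = self.next()
            if tok == "{":
                depth += 1
            elif tok == "}":
                depth -= 1


def read_bif(source) -> DiscreteBayesNet:
    """Parse a Bayesian Interchange Format (BIF) file.

    ``source`` may be a path or a file-like object.  Variable order is
    file order; CPT rows follow the parent order declared in each
    ``probability`` block.  Rows failing normalisation beyond 1e-6 raise
    :class:`BifParseError` with the line number.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    ts = _TokenStream(text)

    variables, cards, states = [], {}, {}
    parents, cpts = {}, {}

    while ts.peek()[0] is not None:
        tok, line = ts.next()
        if tok == "network":
            ts.next()  # name
            ts.skip_block()
        elif tok == "variable":
            name, _ = ts.next()
            ts.next("{")
            ts.next("type")
            ts.next("discrete")
            ts.next("[")
            ns_tok, nline = ts.next()
            try:
                n_states = int(ns_tok)
            except ValueError:
                raise BifParseError(f"bad state count '{ns_tok}'", nline)
            ts.next("]")
            ts.next("{")
            labels = []
            while True:
                t, _ = ts.next()
                if t == "}":
                    break
                if t != ",":
                    labels.append(t)
            ts.next(";")
            ts.next("}")
            if len(labels) != n_states:
                raise BifParseError(
                    f"variable {name}: {len(labels)} labels, declared {n_states}",
                    line)
            if n_states < 2:
                raise BifParseError(f"variable {name}: needs >= 2 states", line)
            variables.append(name)
            cards[name] = n_states
            states[name] = labels
        elif tok == "probability":
            ts.next("(")
            child, cline = ts.next()
            if child not in cards:
                raise BifParseError(f"unknown variable '{child}'", cline)
            pa = []
            t, _ = ts.next()
            if t == "|":
                while True:
                    t, pl = ts.next()
                    if t == ")":
                        break
                    if t == ",":
                        continue
                    if t not in cards:
                        raise BifParseError(f"unknown parent '{t}'", pl)
                    pa.append(t)
            elif t != ")":
                raise BifParseError(f"expected '|' or ')', got '{t}'", cline)
            parents[child] = tuple(pa)
            pa_cards = [cards[p] for p in pa]
            n_rows = int(np.prod(pa_cards, dtype=np.int64)) if pa else 1
            cpt = np.full((n_rows, cards[child]), np.nan)
            ts.next("{")
            while True:
                t, tline = ts.next()
                if t == "}":
                    break
                if t == "table":
                    vals = _read_numbers_until(ts, ";", tline)
                    if len(vals) != cards[child] or pa:
                        raise BifParseError(
                            f"table for {child}: expected {cards[child]} "
                            f"unconditional values", tline)
                    cpt[0, :] = vals
                elif t == "(":
                    cfg = []
                    while True:
                        s, sline = ts.next()
                        if s == ")":
                            break
                        if s == ",":
                            continue
                        cfg.append((s, sline))
                    if len(cfg) != len(pa):
                        raise BifParseError(
                            f"{child}: {len(cfg)} parent states for "
                            f"{len(pa)} parents", tline)
                    idx = []
                    for (lbl, sline), p in zip(cfg, pa):
                        try:
                            idx.append(states[p].index(lbl))
                        except ValueError:
                            raise BifParseError(
                                f"'{lbl}' is not a state of {p}", sline)
                    row = int(np.ravel_multi_index(idx, pa_cards)) if pa else 0
                    vals = _read_numbers_until(ts, ";", tline)
                    if len(vals) != cards[child]:
                        raise BifParseError(
                            f"{child}: row has {len(vals)} entries, "
                            f"expected {cards[child]}", tline)
                    cpt[row, :] = vals
                else:
                    raise BifParseError(f"unexpected token '{t}'", tline)
            if np.isnan(cpt).any():
                raise BifParseError(f"{child}: CPT rows missing", cline)
            bad = np.abs(cpt.sum(axis=1) - 1.0) > _CPT_ATOL
            if bad.any():
                raise BifParseError(
                    f"{child}: CPT row {int(np.flatnonzero(bad)[0])} sums to "
                    f"{cpt.sum(axis=1)[bad][0]:.8f}", cline)
            # renormalise away sub-1e-6 rounding from the file
            cpt /= cpt.sum(axis=1, keepdims=True)
            cpts[child] = cpt
        else:
            raise BifParseError(f"unexpected token '{tok}'", line)

    missing = [v for v in variables if v not in cpts]
    if missing:
        raise BifParseError(f"no probability block for {missing}")
    net = DiscreteBayesNet(variables, cards, parents, cpts, states)
    return net.validate()


def _read_numbers_until(ts, stop, line):
    vals = []
    while True:
        t, tl = ts.next()
        if t == stop:
            return vals
        if t == ",":
            continue
        try:
            vals.append(float(t))
        except ValueError:
            raise BifParseError(f"expected a number, got '{t}'", tl)


def write_bif(net: DiscreteBayesNet, path_or_buf):
    """Serialise a network to BIF.  Round-trips through :func:`read_bif`
    reproduce variables, edges and CPTs to 1e-9."""
    buf = io.StringIO()
    buf.write("network unknown {\n}\n")
    for v in net.variables:
        labels = net.states_of(v)
        buf.write(f"variable {v} {{\n")
        buf.write(f"  type discrete [ {net.cardinalities[v]} ] "
                  f"{{ {', '.join(labels)} }};\n}}\n")
    for v in net.variables:
        pa = net.parents.get(v, ())
        cpt = np.asarray(net.cpts[v])
        if not pa:
            buf.write(f"probability ( {v} ) {{\n")
            buf.write("  table " + ", ".join(f"{x:.12g}" for x in cpt[0]) + ";\n}\n")
        else:
            buf.write(f"probability ( {v} | {', '.join(pa)} ) {{\n")
            pa_cards = [net.cardinalities[p] for p in pa]
            for row in range(cpt.shape[0]):
                idx = np.unravel_index(row, pa_cards)
                labels = [net.states_of(p)[i] for p, i in zip(pa, idx)]
                buf.write("  (" + ", ".join(labels) + ") "
                          + ", ".join(f"{x:.12g}" for x in cpt[row]) + ";\n")
            buf.write("}\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Forward (ancestral) sampling
# ---------------------------------------------------------------------------

def forward_sample(net: DiscreteBayesNet, n: int, seed: int) -> DataMatrix:
    """Draw ``n`` complete records by ancestral sampling.

    Each variable is sampled given its parents in a fixed topological
    order from a single seeded generator stream, so identical
    ``(net, n, seed)`` calls are bit-identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = net.topological_order()
    col = {v: i for i, v in enumerate(net.variables)}
    out = np.zeros((n, net.n_variables), dtype=np.int64)
    for v in order:
        pa = net.parents.get(v, ())
        cpt = np.asarray(net.cpts[v], dtype=float)
        if pa:
            pa_cards = [net.cardinalities[p] for p in pa]
            cfg = np.ravel_multi_index(
                tuple(out[:, col[p]] for p in pa), pa_cards)
            probs = cpt[cfg]
        else:
            probs = np.broadcast_to(cpt[0], (n, cpt.shape[1]))
        u = rng.random(n)
        out[:, col[v]] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    cards = np.array([net.cardinalities[v] for v in net.variables])
    return DataMatrix(out, cards, list(net.variables))


# ---------------------------------------------------------------------------
# Synthetic sparse block networks
# ---------------------------------------------------------------------------

def _dependent_row(rng, r):
    """Dirichlet(0.5) row resampled until total-variation distance from
    the uniform distribution is >= 0.1, so parent-child signal exists."""
    while True:
        row = rng.dirichlet(np.full(r, 0.5))
        if 0.5 * np.abs(row - 1.0 / r).sum() >= 0.1:
            return row


def generate_block_network(spec: SyntheticSpec) -> DiscreteBayesNet:
    """Generate a ground-truth network with dense blocks and sparse
    cross-block edges (the community structure the block learner targets).

    Within each block, ``round(intra_density * C(nb, 2))`` edges are
    drawn uniformly among the in-block pairs, oriented from lower to
    higher node index.  Exactly ``n_inter_edges`` cross-block edges are
    drawn among distinct cross-block pairs, oriented from the lower to
    the higher block, so the result is acyclic by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nb, b = spec.nodes_per_block, spec.n_blocks
    p = nb * b
    names = [f"X{i}" for i in range(p)]
    blocks = [list(range(i * nb, (i + 1) * nb)) for i in range(b)]

    max_intra = nb * (nb - 1) // 2
    n_intra = int(round(spec.intra_density * max_intra))
    if n_intra > max_intra:
        raise ValueError("requested density exceeds maximum DAG edges")

    edges = []
    for blk in blocks:
        pairs = [(blk[i], blk[j]) for i in range(nb) for j in range(i + 1, nb)]
        if n_intra:
            chosen = rng.choice(len(pairs), size=n_intra, replace=False)
            edges.extend(pairs[c] for c in sorted(chosen))

    cross_pairs = [(u, v) for bi in range(b) for bj in range(bi + 1, b)
                   for u in blocks[bi] for v in blocks[bj]]
    if spec.n_inter_edges > len(cross_pairs):
        raise ValueError("more inter-block edges than cross-block pairs")
    if spec.n_inter_edges:
        chosen = rng.choice(len(cross_pairs), size=spec.n_inter_edges,
                            replace=False)
        edges.extend(cross_pairs[c] for c in sorted(chosen))

    lo, hi = spec.cardinality_range
    cards = {names[i]: int(rng.integers(lo, hi + 1)) for i in range(p)}
    parents = {v: () for v in names}
    for u, v in edges:
        parents[names[v]] = parents[names[v]] + (names[u],)

    cpts = {}
    for v in names:
        r = cards[v]
        pa = parents[v]
        rows = int(np.prod([cards[q] for q in pa], dtype=np.int64)) if pa else 1
        cpts[v] = np.vstack([_dependent_row(rng, r) for _ in range(rows)])

    net = DiscreteBayesNet(names, cards, parents, cpts)
    net.blocks = blocks  # ground-truth partition, kept for evaluation
    return net.validate()


def edge_list_frame(net_or_edges):
    """Edge list as a two-column DataFrame (parent, child), sorted."""
    edges = net_or_edges.edges if hasattr(net_or_edges, "edges") else net_or_edges
    rows = sorted(edges)
    return pd.DataFrame(rows, columns=["parent", "child"])
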