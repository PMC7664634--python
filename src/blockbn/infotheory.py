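"""Plug-in information measures and the G-squared conditional-independence
test on discrete data.

All quantities are in nats (natural log).  Empirical probabilities are
raw frequencies with the 0*log(0) := 0 convention and no smoothing, so
they agree exactly with the count-based MDL entropy used by the scorer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = [
    "joint_counts",
    "mutual_information",
    "entropy",
    "mi_matrix",
    "ci_test",
    "CITestResult",
]


def _encode(data, cols):
    """Mixed-radix joint code of the given columns; returns (codes, size)."""
    codes = np.zeros(data.n, dtype=np.int64)
    mult = 1
    for c in cols:
        codes += data.column(c) * mult
        mult *= int(data.cardinalities[c])
    return codes, mult


def joint_counts(data, cols):
    """Contingency counts over the joint states of ``cols``.

    Returns an array of shape ``(r_c1, r_c2, ...)`` whose entries sum to
    ``n``; margins are the corresponding axis sums.
    """
    codes, size = _encode(data, cols)
    counts = np.bincount(codes, minlength=size)
    shape = tuple(int(data.cardinalities[c]) for c in cols)
    # first column is the fastest-varying digit -> Fortran order
    return counts.reshape(shape, order="F")


def _xlogx(a):
    out = np.zeros_like(a, dtype=float)
    nz = a > 0
    out[nz] = a[nz] * np.log(a[nz])
    return out


def entropy(data, i):
    """Empirical marginal entropy of column ``i`` in nats."""
    counts = joint_counts(data, [i]).astype(float)
    n = counts.sum()
    p = counts / n
    return float(-_xlogx(p).sum())


def mutual_information(data, i, j):
    """Plug-in mutual information I(X_i; X_j) in nats.

    ``I = sum_xy p(x,y) log[p(x,y) / (p(x) p(y))]`` with empty cells
    contributing zero.  Symmetric in (i, j) and >= 0 up to float slack.
    """
    if i == j:
        raise ValueError("i and j must differ; use entropy() for I(X;X)")
    i, j = min(i, j), max(i, j)   # canonical order => exact symmetry
    nxy = joint_counts(data, [i, j]).astype(float)
    n = nxy.sum()
    pxy = nxy / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * (np.log(pxy[nz])
                                 - np.log((px * py)[nz]))))
    return max(mi, 0.0) if mi > -1e-12 else mi


def mi_matrix(data):
    """Full symmetric p x p mutual-information matrix (zero diagonal)."""
    p = data.p
    m = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            m[i, j] = m[j, i] = mutual_information(data, i, j)
    return m


@dataclass
class CITestResult:
    """Outcome of one G-squared test of X_i independent of X_j given S."""

    statistic: float
    df: int
    p_value: float
    conditioning: tuple

    def __post_init__(self):
        assert self.df >= 1
        assert 0.0 <= self.p_value <= 1.0


def ci_test(data, i, j, S=(), max_cond=None) -> CITestResult:
    """G-squared conditional-independence test.

    The statistic is ``2 N * I(X_i; X_j | S)`` (conditional mutual
    information estimated from counts, in nats).  Degrees of freedom are
    ``(r_i - 1)(r_j - 1) * (# conditioning configurations with nonzero
    count)``; configurations never observed contribute neither to the
    statistic nor to the df.  The p-value is the chi-square upper tail.
    """
    S = tuple(S)
    if i == j or i in S or j in S:
        raise ValueError("require i != j and i, j not in S")
    if max_cond is not None and len(S) > max_cond:
        raise ValueError(f"conditioning set larger than cap {max_cond}")

    ri = int(data.cardinalities[i])
    rj = int(data.cardinalities[j])
    counts = joint_counts(data, [i, j, *S]).astype(float)
    n3 = counts.reshape(ri, rj, -1)          # (x, y, s-config)
    ns = n3.sum(axis=(0, 1))                 # per-config totals
    nxs = n3.sum(axis=1)                     # (x, s)
    nys = n3.sum(axis=0)                     # (y, s)

    nz = n3 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = (np.log(n3, where=nz, out=np.zeros_like(n3))
                    + np.log(ns)[None, None, :]
                    - np.log(nxs)[:, None, :]
                    - np.log(nys)[None, :, :])
    g2 = float(2.0 * np.sum(n3[nz] * log_term[nz]))
    g2 = max(g2, 0.0)

    df = (ri - 1) * (rj - 1) * int(np.count_nonzero(ns))
    df = max(df, 1)
    p_value = float(chi2.sf(g2, df))
    return CITestResult(g2, df, p_value, S)
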