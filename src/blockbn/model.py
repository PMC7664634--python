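"""Model / Results objects wrapping the block structure learner.

``BlockStructureModel`` holds the data and configuration;  ``fit``
runs blocking, skeleton discovery, orientation enumeration and the
per-block exact search, and returns a ``BlockStructureResults`` carrying
the selected network, its scores, the per-candidate ledger and a
``summary()`` table.  Simulation (``simulate``) and evaluation against
a ground truth (``evaluate``) hang off these objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .netcore import DataMatrix, DiscreteBayesNet, edge_list_frame, forward_sample
from .pipeline import BlmkmConfig, blmkm, hamming

__all__ = ["BlockStructureModel", "BlockStructureResults"]


class BlockStructureModel:
    """Discrete Bayesian-network structure learner with block decomposition.

    Parameters
    ----------
    data : DataMatrix
        Complete-case integer-coded sample matrix.
    k : int
        Number of variable blocks for the MI K-medoid step.  Required;
        see :func:`blockbn.mkm.suggest_k` for a rule of thumb.
    alpha : float
        CI-test significance for the MMPC skeleton.
    **config_kwargs
        Remaining :class:`~blockbn.pipeline.BlmkmConfig` fields.

    Examples
    --------
    >>> model = BlockStructureModel.from_dataframe(df, k=3)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(self, data: DataMatrix, k: int, alpha: float = 0.05,
                 **config_kwargs):
        self.data = data
        self.k = int(k)
        self.config = BlmkmConfig(alpha=alpha, **config_kwargs).validate()
        if not (1 <= self.k <= data.p):
            raise ValueError(f"k={k} out of range [1, {data.p}]")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, k: int, cardinalities=None,
                       **kwargs):
        return cls(DataMatrix.from_dataframe(df, cardinalities=cardinalities),
                   k, **kwargs)

    @classmethod
    def from_net(cls, net: DiscreteBayesNet, k: int, n: int = 5000,
                 seed: int = 0, **kwargs):
        """Convenience: forward-sample ``n`` records from a reference
        network and build the model on them."""
        return cls(forward_sample(net, n, seed), k, **kwargs)

    def fit(self, seed: int = 0, skeleton=None, blocking=None):
        learned = blmkm(self.data, self.k, seed=seed, config=self.config,
                        skeleton=skeleton, blocking=blocking)
        return BlockStructureResults(self, learned)


class BlockStructureResults:
    """Fitted block-learning result.

    Attributes
    ----------
    learned : LearnedNetwork
        Full result bundle (edges, scores, provenance).
    edges : set of (str, str)
        Learned directed edges by variable name.
    mdl, bic : float, BicScore
        Selected network's decomposable MDL and BIC.
    """

    def __init__(self, model, learned):
        self.model = model
        self.learned = learned

    # -- views ---------------------------------------------------------
    @property
    def edges(self):
        return self.learned.named_edges

    @property
    def edge_indices(self):
        return set(self.learned.edges)

    @property
    def mdl(self):
        return self.learned.mdl

    @property
    def bic(self):
        return self.learned.bic

    @property
    def blocking(self):
        return self.learned.blocking

    @property
    def skeleton(self):
        return self.learned.skeleton

    def edge_frame(self):
        return edge_list_frame(sorted(self.edges))

    def evaluate(self, truth):
        """Structural Hamming decomposition against a reference network.

        ``truth`` may be a DiscreteBayesNet or an iterable of named or
        index edge pairs.
        """
        names = self.learned.names
        idx = {v: i for i, v in enumerate(names)}
        t_edges = truth.edges if hasattr(truth, "edges") else set(truth)
        t_idx = set()
        for u, v in t_edges:
            if isinstance(u, str):
                if u not in idx or v not in idx:
                    raise ValueError(f"truth variable {u!r}/{v!r} unknown")
                t_idx.add((idx[u], idx[v]))
            else:
                t_idx.add((u, v))
        return hamming(self.learned.edges, t_idx, len(names))

    def to_net(self, smoothing=0.0) -> DiscreteBayesNet:
        """Materialise the learned structure as a network with
        maximum-likelihood CPTs (optional additive smoothing)."""
        data = self.model.data
        names = self.learned.names
        parents = {v: () for v in names}
        for u, v in sorted(self.learned.edges):
            parents[names[v]] = parents[names[v]] + (names[u],)
        cards = {v: int(c) for v, c in zip(names, data.cardinalities)}
        cpts = {}
        from .infotheory import joint_counts
        for i, v in enumerate(names):
            pa = parents[v]
            pa_idx = [names.index(q) for q in pa]
            cnt = joint_counts(data, [i, *pa_idx]).astype(float)
            # axis 0 is the child; CPT rows are C-order parent configs
            rows = np.moveaxis(cnt, 0, -1).reshape(-1, cards[v]) + smoothing
            zero = rows.sum(axis=1) == 0
            rows[zero, :] = 1.0          # unobserved configs -> uniform
            cpts[v] = rows / rows.sum(axis=1, keepdims=True)
        return DiscreteBayesNet(list(names), cards, parents, cpts).validate()

    def simulate(self, n, seed=0):
        """Forward-sample from the learned network (ML parameters)."""
        return forward_sample(self.to_net(), n, seed)

    def summary(self):
        ln = self.learned
        cfg = self.model.config
        lines = []
        lines.append("Block Bayesian-network structure learning results")
        lines.append("=" * 58)
        lines.append(f"{'No. variables:':<28}{len(ln.names)}")
        lines.append(f"{'No. samples:':<28}{self.model.data.n}")
        lines.append(f"{'Blocks (k):':<28}{ln.blocking.k}")
        lines.append(f"{'Skeleton edges:':<28}{len(ln.skeleton.edges())}")
        lines.append(f"{'Inter-block edges (m):':<28}{len(ln.interblock_edges)}")
        lines.append(f"{'Candidates (2^m):':<28}{len(ln.candidate_scores)}")
        lines.append(f"{'Cyclic discarded:':<28}{ln.n_cyclic_discarded}")
        lines.append(f"{'Selected orientation:':<28}0b{ln.selected_bitmask:b}")
        lines.append(f"{'alpha / max_cond:':<28}{cfg.alpha} / {cfg.max_cond}")
        lines.append("-" * 58)
        lines.append(f"{'Learned edges:':<28}{len(ln.edges)}")
        lines.append(f"{'MDL (total, nats):':<28}{ln.mdl:.4f}")
        lines.append(f"{'BIC (raw):':<28}{ln.bic.raw:.4f}")
        lines.append(f"{'BIC (per sample):':<28}{ln.bic.per_sample:.4f}")
        lines.append(f"{'Free parameters d:':<28}{ln.bic.d}")
        lines.append("-" * 58)
        lines.append("Edges (parent -> child):")
        for u, v in sorted(self.edges):
            lines.append(f"  {u} -> {v}")
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - visual aid
        """Draw the learned DAG (requires matplotlib)."""
        import matplotlib.pyplot as plt
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.learned.names)
        g.add_edges_from(self.edges)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        nx.draw_networkx(g, ax=ax, node_color="#9ecae1", arrows=True)
        ax.set_axis_off()
        return ax
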