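"""Thresholded Pearson coexpression networks.

A gene is a node; an edge joins two genes whose expression profiles
correlate at or above a threshold ``t`` (``r >= t`` in ``positive``
mode, ``|r| >= t`` in ``absolute`` mode).  Genes with zero expression
variance have no defined correlation and are excluded from the node
set rather than silently given ``r = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats

from .errors import ValidationError, ZeroVarianceError
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

MODES = ("positive", "absolute")


@dataclass
class CoexpressionNetwork:
    """Undirected weighted graph over genes, stored as index arrays.

    ``edge_index`` holds ``(i, j)`` node-index pairs with ``i < j``;
    ``weights`` the corresponding correlation coefficients at full
    precision.  The array representation keeps construction and
    clustering fast at compendium scale (~5.5k genes, ~1e6 candidate
    edges); conversion helpers provide networkx / igraph views.
    """

    nodes: list[str]
    edge_index: np.ndarray
    weights: np.ndarray
    threshold: float
    mode: str = "positive"
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.mode not in MODES:
            raise ValidationError(f"mode: must be one of {MODES}")
        if len(self.weights) != len(self.edge_index):
            raise ValidationError("weights: length mismatch with edge_index")
        if len(self.edge_index) and (
            self.edge_index.min() < 0 or self.edge_index.max() >= len(self.nodes)
        ):
            raise ValidationError("edge_index: node index out of range")
        if np.any(self.edge_index[:, 0] == self.edge_index[:, 1]):
            raise ValidationError("edge_index: self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edge_index[:, 0], 1)
            np.add.at(deg, self.edge_index[:, 1], 1)
        return deg

    def iter_edges(self) -> Iterator[tuple[str, str, float]]:
        for (i, j), w in zip(self.edge_index, self.weights):
            yield self.nodes[i], self.nodes[j], float(w)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.iter_edges())
        return g

    def to_igraph(self):
        import igraph as ig

        return ig.Graph(
            n=self.n_nodes,
            edges=[(int(i), int(j)) for i, j in self.edge_index],
            directed=False,
        )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length profiles.

    Raises :class:`ZeroVarianceError` for constant vectors — callers
    exclude such genes instead of fabricating a coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("pearson: length mismatch")
    if x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson: need 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("pearson: constant input vector")
    r = stats.pearsonr(x, y).statistic
    return float(min(1.0, max(-1.0, r)))


def build_network(
    em: ExpressionMatrix,
    t: float,
    mode: str = "positive",
    condition_label: str | None = None,
) -> CoexpressionNetwork:
    """All-pairs correlation of the matrix rows, thresholded at ``t``.

    Node order follows the matrix row order (minus excluded
    zero-variance genes); the edge set is therefore deterministic and,
    up to relabeling, independent of gene input order.
    """
    if not 0.0 < t <= 1.0:
        raise ValidationError("t: threshold must lie in (0, 1]")
    if mode not in MODES:
        raise ValidationError(f"mode: must be one of {MODES}")
    if em.n_samples < 3:
        raise ValidationError("em: need >= 3 samples for correlation")

    sd = em.values.std(axis=1)
    keep = sd > 0
    dropped = [t_ for t_, k in zip(em.locus_tags, keep) if not k]
    if dropped:
        logger.warning("build_network: excluding %d zero-variance genes: %s",
                       len(dropped), ",".join(dropped[:10]) +
                       ("..." if len(dropped) > 10 else ""))
    nodes = [tag for tag, k in zip(em.locus_tags, keep) if k]
    values = em.values[keep]
    if len(nodes) >= 2:
        corr = np.corrcoef(values)
        np.clip(corr, -1.0, 1.0, out=corr)
        sel = corr >= t if mode == "positive" else np.abs(corr) >= t
        sel &= np.triu(np.ones_like(sel, dtype=bool), k=1)
        ii, jj = np.nonzero(sel)
        edge_index = np.column_stack([ii, jj])
        weights = corr[ii, jj]
    else:
        edge_index = np.empty((0, 2), dtype=np.int64)
        weights = np.empty(0)
    return CoexpressionNetwork(
        nodes=nodes,
        edge_index=edge_index,
        weights=weights,
        threshold=float(t),
        mode=mode,
        condition_label=em.condition_label if condition_label is None else condition_label,
    )


def isolated_genes(net: CoexpressionNetwork) -> frozenset[str]:
    """Degree-0 nodes: genes with no connection to any other gene."""
    deg = net.degrees()
    return frozenset(n for n, d in zip(net.nodes, deg) if d == 0)
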