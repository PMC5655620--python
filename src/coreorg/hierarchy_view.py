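"""Agglomerative ordering of the category matrix: dendrograms, Newick
export, and a render-ready binned heatmap table.

Hierarchical clustering is agglomerative on Euclidean distances with
average (default), complete or single linkage, implemented with
Lance-Williams updates and a deterministic tie rule: among equally
close pairs, the pair whose (smallest-leaf, smallest-leaf) label pair
is lexicographically smallest merges first.  Merge heights are the
inter-cluster distances; leaves of a cluster merged at height ``h`` sit
at depth ``h/2`` (UPGMA convention), which fixes the Newick branch
lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import isclose

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

LINKAGES = ("average", "complete", "single")

#: Heatmap colour bins, lowest to highest count.
BIN_LABELS = ("red", "orange", "yellow", "green", "blue", "indigo", "violet")


@dataclass
class DendroNode:
    """One merge (or leaf) of the tree; leaves carry ``label``."""

    height: float
    children: tuple["DendroNode", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Dendrogram:
    """Binary merge tree with heights; leaf order = traversal order."""

    root: DendroNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def approx_equal(self, other: "Dendrogram", tol: float = 1e-9) -> bool:
        def eq(a: DendroNode, b: DendroNode) -> bool:
            if a.is_leaf != b.is_leaf:
                return False
            if not isclose(a.height, b.height, rel_tol=tol, abs_tol=tol):
                return False
            if a.is_leaf:
                return a.label == b.label
            return len(a.children) == len(b.children) and all(
                eq(x, y) for x, y in zip(a.children, b.children)
            )

        return eq(self.root, other.root)


def _axis_vectors(matrix, axis: str) -> tuple[list[str], np.ndarray]:
    df: pd.DataFrame = getattr(matrix, "data", matrix)
    if axis == "rows":
        return [str(i) for i in df.index], df.to_numpy(dtype=float)
    if axis == "columns":
        return [str(c) for c in df.columns], df.to_numpy(dtype=float).T
    raise ValidationError("axis: must be 'rows' or 'columns'")


def hcluster(
    matrix,
    axis: str = "rows",
    metric: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of one axis of a category matrix.

    Accepts a :class:`~coreorg.category_analysis.CategoryMatrix` or a
    plain DataFrame.  Requires >= 2 labels on the chosen axis;
    all-equal vectors yield a valid tree with zero heights.
    """
    if metric != "euclidean":
        raise ValidationError("metric: only 'euclidean' is supported")
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage: must be one of {LINKAGES}")
    labels, vectors = _axis_vectors(matrix, axis)
    if len(labels) < 2:
        raise ValidationError("axis: need >= 2 labels to cluster")
    if len(set(labels)) != len(labels):
        raise ValidationError("axis: duplicate labels")

    # Active clusters: id -> (node, size, smallest leaf label).
    nodes: dict[int, DendroNode] = {
        i: DendroNode(0.0, label=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in nodes}
    minleaf = {i: lab for i, lab in enumerate(labels)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[(i, j)] = float(np.linalg.norm(vectors[i] - vectors[j]))

    next_id = len(labels)
    while len(nodes) > 1:
        # Deterministic pick: smallest distance, ties by the sorted
        # (minleaf_i, minleaf_j) label pair.
        best = min(
            dist,
            key=lambda ij: (dist[ij], tuple(sorted((minleaf[ij[0]], minleaf[ij[1]])))),
        )
        i, j = best
        h = dist[best]
        if minleaf[j] < minleaf[i]:  # smaller-leaf cluster on the left
            i, j = j, i
        merged = DendroNode(h, children=(nodes[i], nodes[j]))
        ni, nj = sizes[i], sizes[j]
        new_dist: dict[int, float] = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            if linkage == "average":
                new_dist[k] = (ni * dik + nj * djk) / (ni + nj)
            elif linkage == "complete":
                new_dist[k] = max(dik, djk)
            else:
                new_dist[k] = min(dik, djk)
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        del nodes[i], nodes[j], sizes[i], sizes[j], minleaf[i], minleaf[j]
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        minleaf[next_id] = min(merged.leaves())
        for k, d in new_dist.items():
            dist[(min(k, next_id), max(k, next_id))] = d
        next_id += 1
    return Dendrogram(root=next(iter(nodes.values())))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEEDS_QUOTES = set(" \t(),:;[]'\"")


def _quote(label: str) -> str:
    if any(c in _NEEDS_QUOTES for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(d: Dendrogram) -> str:
    """Newick string with branch lengths from merge heights.

    A node merged at height ``h`` under a parent merged at ``H`` gets
    branch length ``(H - h) / 2``; the root carries ``:0.0``.  Two
    leaves merged at 2 therefore render as ``(a:1.0,b:1.0):0.0;``.
    """

    def fmt(node: DendroNode, parent_height: float) -> str:
        bl = (parent_height - node.height) / 2.0
        if node.is_leaf:
            return f"{_quote(node.label)}:{bl!r}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{bl!r}"

    return fmt(d.root, d.root.height) + ";"


def from_newick(s: str) -> Dendrogram:
    """Parse a Newick string written by :func:`to_newick`.

    Heights are reconstructed from the ultrametric branch lengths
    (``height(parent) = height(child) + 2 * branch(child)``).
    """
    s = s.strip()
    if not s.endswith(";"):
        raise ParseError("from_newick: missing terminating ';'")
    text = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            out = []
            while pos < len(text):
                if text[pos] == "'":
                    if pos + 1 < len(text) and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(text[pos])
                pos += 1
            raise ParseError("from_newick: unterminated quoted label")
        start = pos
        while pos < len(text) and text[pos] not in "(),:;":
            pos += 1
        return text[start:pos]

    def parse_branch_length() -> float:
        nonlocal pos
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in "(),;":
                pos += 1
            return float(text[start:pos])
        return 0.0

    def parse_node() -> tuple[DendroNode, float]:
        """Returns (node-with-height, branch length to parent)."""
        nonlocal pos
        if pos < len(text) and text[pos] == "(":
            pos += 1
            children: list[tuple[DendroNode, float]] = []
            while True:
                children.append(parse_node())
                if pos < len(text) and text[pos] == ",":
                    pos += 1
                    continue
                break
            if pos >= len(text) or text[pos] != ")":
                raise ParseError(f"from_newick: expected ')' at position {pos}")
            pos += 1
            parse_label()  # internal node labels (unused) permitted
            bl = parse_branch_length()
            height = max(child.height + 2.0 * b for child, b in children)
            node = DendroNode(height, children=tuple(c for c, _ in children))
            return node, bl
        label = parse_label()
        if not label:
            raise ParseError(f"from_newick: empty leaf label at position {pos}")
        bl = parse_branch_length()
        return DendroNode(0.0, label=label), bl

    root, _ = parse_node()
    if pos != len(text):
        raise ParseError(f"from_newick: trailing characters at position {pos}")
    return Dendrogram(root=root)


# ---------------------------------------------------------------------------
# Heatmap table
# ---------------------------------------------------------------------------

def heatmap_table(
    matrix,
    row_tree: Dendrogram,
    col_tree: Dendrogram,
    n_bins: int = len(BIN_LABELS),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reorder the matrix by the trees' leaf orders and bin each cell.

    Bins divide ``[0, max cell value]`` into ``n_bins`` equal intervals
    (bin 1 = lowest = "red" ... bin 7 = highest = "violet"); the
    maximum cell lands in the top bin, and an all-zero matrix is
    entirely bin 1.  Cell values themselves are never changed.
    """
    df: pd.DataFrame = getattr(matrix, "data", matrix)
    row_order = row_tree.leaves()
    col_order = col_tree.leaves()
    bad_rows = set(row_order) ^ set(str(i) for i in df.index)
    bad_cols = set(col_order) ^ set(str(c) for c in df.columns)
    if bad_rows or bad_cols:
        raise ValidationError(
            f"tree/matrix label mismatch; rows: {sorted(bad_rows)}, "
            f"columns: {sorted(bad_cols)}"
        )
    ordered = df.reindex(index=row_order, columns=col_order)
    vmax = float(ordered.to_numpy().max()) if ordered.size else 0.0
    if vmax <= 0:
        bins = pd.DataFrame(1, index=row_order, columns=col_order, dtype=int)
    else:
        frac = ordered.to_numpy(dtype=float) / vmax
        binned = np.minimum(n_bins, np.floor(frac * n_bins).astype(int) + 1)
        bins = pd.DataFrame(binned, index=row_order, columns=col_order, dtype=int)
    return ordered, bins
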