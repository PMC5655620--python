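"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately take a different route than the package:
set partitions are enumerated recursively and scored with
networkx's modularity; hierarchical clustering is re-agglomerated
naively, recomputing every inter-cluster distance from the raw vectors
at each step instead of using running updates.
"""

from __future__ import annotations

import numpy as np
import pytest

from coreorg.network_construction import CoexpressionNetwork


def all_set_partitions(items):
    """Every partition of ``items`` into non-empty blocks (brute force)."""
    items = list(items)
    if not items:
        yield []
        return
    head, tail = items[0], items[1:]
    for rest in all_set_partitions(tail):
        for i in range(len(rest)):
            yield rest[:i] + [rest[i] | {head}] + rest[i + 1:]
        yield [{head}] + rest


def max_modularity_bruteforce(graph):
    """Exhaustive maximum modularity of a networkx graph (oracle)."""
    import networkx as nx

    best = -np.inf
    for parts in all_set_partitions(graph.nodes):
        q = nx.community.modularity(graph, parts)
        best = max(best, q)
    return best


def network_from_edges(nodes, edges, threshold=0.5, mode="positive", label=""):
    """Build a CoexpressionNetwork directly from an explicit edge list."""
    nodes = list(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    pairs = sorted(
        (min(index[a], index[b]), max(index[a], index[b])) for a, b in edges
    )
    weights = np.ones(len(pairs))
    return CoexpressionNetwork(
        nodes=nodes,
        edge_index=np.array(pairs, dtype=np.int64).reshape(-1, 2),
        weights=weights,
        threshold=threshold,
        mode=mode,
        condition_label=label,
    )


def naive_hcluster(labels, vectors, linkage="average"):
    """O(n^3) agglomeration oracle, recomputing distances from scratch.

    Returns the merge tree as nested tuples
    ``(height, left, right) | label`` using the same tie rule as the
    package (smallest distance; ties by sorted smallest-leaf labels;
    smaller-leaf cluster on the left).
    """
    vec = {lab: np.asarray(v, dtype=float) for lab, v in zip(labels, vectors)}
    clusters = [(frozenset([lab]), lab) for lab in labels]  # (members, tree)

    def cluster_dist(a, b):
        d = [np.linalg.norm(vec[x] - vec[y]) for x in a for y in b]
        if linkage == "average":
            return float(np.mean(d))
        return float(max(d)) if linkage == "complete" else float(min(d))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                key = (
                    cluster_dist(a[0], b[0]),
                    tuple(sorted((min(a[0]), min(b[0])))),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        (h, _), i, j = best
        a, b = clusters[i], clusters[j]
        if min(b[0]) < min(a[0]):
            a, b = b, a
        merged = (a[0] | b[0], (h, a[1], b[1]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters[0][1]


def tree_as_tuples(node):
    """Convert a package Dendrogram node to the oracle's tuple form."""
    if node.is_leaf:
        return node.label
    left, right = node.children
    return (node.height, tree_as_tuples(left), tree_as_tuples(right))


def tuples_equal(a, b, tol=1e-9):
    if isinstance(a, str) or isinstance(b, str):
        return a == b
    ha, la, ra = a
    hb, lb, rb = b
    return abs(ha - hb) <= tol * max(1.0, abs(ha), abs(hb)) and \
        tuples_equal(la, lb, tol) and tuples_equal(ra, rb, tol)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
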