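"""Modularity-based community detection with separate isolated-gene
accounting.

Degree-0 genes are set aside before optimization (the analysis treats
them as their own first-class group).  The remaining graph is
partitioned by maximizing Newman-Girvan modularity

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(c_i, c_j)

on the unweighted thresholded graph.  Small node sets (<= 8) are solved
exactly by enumerating all set partitions; larger graphs use the fast
greedy agglomerative (CNM) algorithm from igraph's C core, cut at the
maximum-modularity level.  Both paths are deterministic: node order is
canonicalized (sorted locus tags) before optimization, so the result is
invariant to gene insertion order.

Communities that end up with a single (connected) member are reported
as "singletons", distinct both from clusters (size >= 2) and from
isolated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError
from .network_construction import CoexpressionNetwork

logger = logging.getLogger(__name__)

#: Node sets at or below this size are partitioned by exhaustive search.
EXACT_SEARCH_MAX_NODES = 8


@dataclass
class GenePartition:
    """Cluster labels plus the isolated and singleton residual classes.

    ``assignment`` maps genes in clusters of size >= 2 to small-integer
    cluster ids, assigned in decreasing cluster-size order (ties broken
    by the lexicographically smallest member tag).  ``quality`` is the
    modularity Q of the partition that produced the labels.
    """

    assignment: dict[str, int]
    isolated: frozenset[str]
    singletons: frozenset[str]
    condition_label: str = ""
    quality: float = 0.0

    def __post_init__(self) -> None:
        domains = [set(self.assignment), set(self.isolated), set(self.singletons)]
        total = sum(len(d) for d in domains)
        if len(set().union(*domains)) != total:
            raise ValidationError("assignment/isolated/singletons must be disjoint")
        sizes: dict[int, int] = {}
        for cid in self.assignment.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        if any(s < 2 for s in sizes.values()):
            raise ValidationError("assignment: every cluster id needs >= 2 members")

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.assignment) | self.isolated | self.singletons

    def clusters(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for gene, cid in self.assignment.items():
            out.setdefault(cid, set()).add(gene)
        return {cid: frozenset(members) for cid, members in out.items()}

    def members(self, cid: int) -> frozenset[str]:
        return frozenset(g for g, c in self.assignment.items() if c == cid)

    def status_key(self, gene: str) -> tuple:
        """Membership key used for stayer/mover logic: a cluster id, or
        the ISOLATED / SINGLETON pseudo-class."""
        if gene in self.assignment:
            return ("CLUSTER", self.assignment[gene])
        if gene in self.isolated:
            return ("ISOLATED",)
        if gene in self.singletons:
            return ("SINGLETON",)
        raise KeyError(gene)


def modularity(net: CoexpressionNetwork, communities: Iterable[Iterable[str]]) -> float:
    """Newman-Girvan modularity of a node grouping on the unweighted graph."""
    m = net.n_edges
    if m == 0:
        return 0.0
    index = {n: i for i, n in enumerate(net.nodes)}
    deg = net.degrees()
    label = np.full(net.n_nodes, -1, dtype=np.int64)
    for cid, group in enumerate(communities):
        for gene in group:
            label[index[gene]] = cid
    within = np.sum(
        (label[net.edge_index[:, 0]] >= 0)
        & (label[net.edge_index[:, 0]] == label[net.edge_index[:, 1]])
    )
    q = within / m
    two_m = 2.0 * m
    n_comms = int(label.max()) + 1 if label.size else 0
    for cid in range(n_comms):
        d = deg[label == cid].sum()
        q -= (d / two_m) ** 2
    return float(q)


def _set_partitions(items: list[str]):
    """Yield all set partitions of ``items`` (restricted-growth order)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def _exact_partition(net: CoexpressionNetwork, nodes: list[str]) -> list[set[str]]:
    """Exhaustive maximum-modularity partition for small node sets.

    Ties (within 1e-12 in Q) resolve to the lexicographically smallest
    canonical form, making the result unique.
    """
    best_q = -np.inf
    best_canon = None
    best: list[set[str]] = []
    for parts in _set_partitions(sorted(nodes)):
        q = modularity(net, parts)
        canon = sorted(tuple(sorted(p)) for p in parts)
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and
                                  (best_canon is None or canon < best_canon)):
            best_q, best_canon, best = q, canon, [set(p) for p in parts]
    return best


def _fastgreedy_partition(
    net: CoexpressionNetwork, nodes: list[str]
) -> list[set[str]]:
    """CNM greedy modularity agglomeration via igraph, cut at max Q."""
    import igraph as ig

    order = {n: i for i, n in enumerate(nodes)}
    keep = set(nodes)
    edges = sorted(
        (order[a], order[b])
        for a, b, _ in net.iter_edges()
        if a in keep and b in keep
    )
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    clustering = g.community_fastgreedy().as_clustering()
    return [set(nodes[i] for i in comm) for comm in clustering]


def _louvain_partition(
    net: CoexpressionNetwork, nodes: list[str], seed: int
) -> list[set[str]]:
    import random

    import igraph as ig

    order = {n: i for i, n in enumerate(nodes)}
    keep = set(nodes)
    edges = sorted(
        (order[a], order[b])
        for a, b, _ in net.iter_edges()
        if a in keep and b in keep
    )
    ig.set_random_number_generator(random.Random(seed))
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    clustering = g.community_multilevel()
    ig.set_random_number_generator(random)  # restore default
    return [set(nodes[i] for i in comm) for comm in clustering]


def detect_communities(
    net: CoexpressionNetwork,
    seed: int = 0,
    method: str = "greedy",
) -> GenePartition:
    """Partition a network into clusters, singletons and isolated genes.

    ``method`` is ``"greedy"`` (default; exact for <= 8 connected
    nodes, CNM beyond) or ``"louvain"`` (igraph multilevel, seeded).
    The empty graph yields 0 clusters with every gene isolated.
    """
    deg = net.degrees()
    isolated = frozenset(n for n, d in zip(net.nodes, deg) if d == 0)
    connected = sorted(n for n, d in zip(net.nodes, deg) if d > 0)

    if not connected:
        return GenePartition({}, isolated, frozenset(),
                             net.condition_label, quality=0.0)

    if method == "louvain":
        communities = _louvain_partition(net, connected, seed)
    elif method == "greedy":
        if len(connected) <= EXACT_SEARCH_MAX_NODES:
            communities = _exact_partition(net, connected)
        else:
            communities = _fastgreedy_partition(net, connected)
    else:
        raise ValidationError(f"method: unknown community method {method!r}")

    quality = modularity(net, communities)

    clusters = [c for c in communities if len(c) >= 2]
    singles = frozenset(g for c in communities if len(c) == 1 for g in c)
    # Decreasing size; ties by smallest member tag.
    clusters.sort(key=lambda c: (-len(c), min(c)))
    assignment = {gene: cid for cid, comm in enumerate(clusters) for gene in comm}
    return GenePartition(
        assignment=assignment,
        isolated=isolated,
        singletons=singles,
        condition_label=net.condition_label,
        quality=quality,
    )


def count_clusters(p: GenePartition) -> int:
    """Number of clusters of size >= 2 (isolated/singletons excluded)."""
    return p.n_clusters


def cluster_sizes(p: GenePartition) -> list[tuple[int, int]]:
    """(cluster id, size) pairs in decreasing-size / id order."""
    sizes: dict[int, int] = {}
    for cid in p.assignment.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    return sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))


def adjusted_rand(labels_a: Mapping[str, object], labels_b: Mapping[str, object]) -> float:
    """Adjusted Rand index between two labelings over their common genes."""
    from sklearn.metrics import adjusted_rand_score

    genes = sorted(set(labels_a) & set(labels_b))
    if not genes:
        raise ValidationError("adjusted_rand: no common genes")
    return float(adjusted_rand_score(
        [str(labels_a[g]) for g in genes],
        [str(labels_b[g]) for g in genes],
    ))
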