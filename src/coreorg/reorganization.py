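"""Cross-condition partition alignment and gene reorganization calls.

This is the analytical core: given the control and stress partitions of
the same gene universe, after-clusters are aligned one-to-one to
before-clusters by greedy Jaccard matching; genes are then classified
as *stayers* (matched cluster identity preserved) or *movers*; for each
focal gene the *co-movers* (genes sharing both its source and target
cluster) and *joiners* (sharing only the target) are collected; and
pairs of focal genes with coincident standardized expression profiles
are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .community_detection import GenePartition
from .io_formats import ExpressionMatrix, FocalGeneList

logger = logging.getLogger(__name__)

#: Sentinel for an after-cluster with no acceptable before-counterpart.
NEW = "NEW"


@dataclass
class ClusterMatch:
    """One-to-one greedy Jaccard alignment of after- onto before-clusters.

    ``mapping`` sends each after-cluster id to a before-cluster id or
    :data:`NEW`; ``jaccard`` records the accepted overlap score per
    matched after-cluster (for NEW clusters, the best score available
    at decision time, kept for diagnostics).
    """

    mapping: dict[int, object]
    jaccard: dict[int, float]
    j_min: float


@dataclass
class ReorganizationReport:
    """Everything the condition-pair comparison produced."""

    match: ClusterMatch
    stayers: frozenset[str]
    movers: frozenset[str]
    comovers: dict[str, frozenset[str]]
    joiners: dict[str, frozenset[str]]
    same_profile_pairs: frozenset[tuple[str, str]]
    condition_pair_label: str = ""


def match_clusters(
    before: GenePartition, after: GenePartition, j_min: float = 0.25
) -> ClusterMatch:
    """Align after-clusters to before-clusters by greedy Jaccard.

    All (after, before) pairs are scored by ``|A & B| / |A | B|`` and
    accepted in decreasing score order (ties: smaller after id, then
    smaller before id) subject to one-to-one use.  After-clusters left
    unaccepted, or whose best score falls below ``j_min``, map to NEW.
    Pairs with zero overlap are never matched, whatever ``j_min``.
    """
    diff = before.genes ^ after.genes
    if diff:
        logger.warning("match_clusters: %d genes present in only one "
                       "partition: %s", len(diff),
                       ",".join(sorted(diff)[:10]))
    b_clusters = before.clusters()
    a_clusters = after.clusters()
    scored: list[tuple[float, int, int]] = []
    for aid, amem in a_clusters.items():
        for bid, bmem in b_clusters.items():
            inter = len(amem & bmem)
            if inter:
                scored.append((inter / len(amem | bmem), aid, bid))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping: dict[int, object] = {}
    jaccard: dict[int, float] = {}
    used_before: set[int] = set()
    for j, aid, bid in scored:
        if aid in mapping or bid in used_before:
            continue
        if j < j_min:
            continue
        mapping[aid] = bid
        jaccard[aid] = j
        used_before.add(bid)
    best_any = {}
    for j, aid, bid in scored:
        best_any.setdefault(aid, j)
    for aid in a_clusters:
        if aid not in mapping:
            mapping[aid] = NEW
            jaccard[aid] = best_any.get(aid, 0.0)
    return ClusterMatch(mapping=mapping, jaccard=jaccard, j_min=float(j_min))


def classify_genes(
    before: GenePartition, after: GenePartition, match: ClusterMatch
) -> tuple[frozenset[str], frozenset[str]]:
    """Split the common gene universe into stayers and movers.

    A gene in clusters under both conditions is a stayer iff its
    after-cluster maps back to its before-cluster.  Genes isolated or
    singleton in either condition are stayers iff their status class is
    identical on both sides, movers otherwise — the pseudo-classes are
    treated uniformly as clusters of their own.
    """
    common = before.genes & after.genes
    only = (before.genes | after.genes) - common
    if only:
        logger.warning("classify_genes: %d genes unassignable (present in "
                       "one condition only)", len(only))
    stayers: set[str] = set()
    movers: set[str] = set()
    for gene in common:
        kb = before.status_key(gene)
        ka = after.status_key(gene)
        if kb[0] == "CLUSTER" and ka[0] == "CLUSTER":
            stayed = match.mapping.get(ka[1]) == kb[1]
        else:
            stayed = kb[0] == ka[0]
        (stayers if stayed else movers).add(gene)
    return frozenset(stayers), frozenset(movers)


def comovers(
    before: GenePartition,
    after: GenePartition,
    match: ClusterMatch,
    focal: FocalGeneList | Iterable[str],
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Per-focal-gene co-mover and joiner sets.

    For a focal mover ``f``: co-movers share both f's before-membership
    and after-membership (other focal genes included, ``f`` itself
    excluded); joiners share only the after-membership.  Focal stayers
    get an empty co-mover set.  Focal genes absent from either
    partition are logged and skipped.
    """
    stayers, _ = classify_genes(before, after, match)
    common = before.genes & after.genes
    by_before: dict[tuple, set[str]] = {}
    by_after: dict[tuple, set[str]] = {}
    for gene in common:
        by_before.setdefault(before.status_key(gene), set()).add(gene)
        by_after.setdefault(after.status_key(gene), set()).add(gene)

    co: dict[str, frozenset[str]] = {}
    join: dict[str, frozenset[str]] = {}
    for f in focal:
        if f not in common:
            logger.warning("comovers: focal gene %r absent from one or both "
                           "partitions; skipped", f)
            continue
        kb, ka = before.status_key(f), after.status_key(f)
        sharing_after = by_after[ka] - {f}
        sharing_both = sharing_after & by_before[kb]
        co[f] = frozenset() if f in stayers else frozenset(sharing_both)
        join[f] = frozenset(sharing_after - by_before[kb])
    return co, join


def same_profile_pairs(
    em: ExpressionMatrix,
    genes: Iterable[str],
    epsilon: float = 1e-9,
) -> frozenset[tuple[str, str]]:
    """Pairs of genes with coincident standardized expression profiles.

    Profiles are z-scored (zero mean, unit variance), so affine copies
    ``b = c*a + d`` with ``c > 0`` coincide exactly; a pair is reported
    when the standardized vectors differ by at most ``epsilon`` in any
    coordinate (equivalently ``r >= 1 - O(eps^2)``).  With
    ``epsilon = 0`` the relation is exact equality and transitive.
    Zero-variance genes are excluded and logged.
    """
    tags = [g for g in genes if g in set(em.locus_tags)]
    absent = [g for g in genes if g not in set(em.locus_tags)]
    if absent:
        logger.warning("same_profile_pairs: genes absent from matrix: %s",
                       ",".join(sorted(absent)))
    z: dict[str, np.ndarray] = {}
    for g in tags:
        x = em.row(g)
        sd = x.std()
        if sd == 0:
            logger.warning("same_profile_pairs: zero-variance gene %r excluded", g)
            continue
        z[g] = (x - x.mean()) / sd
    pairs = set()
    for a, b in combinations(sorted(z), 2):
        if np.max(np.abs(z[a] - z[b])) <= epsilon:
            pairs.add((a, b))
    return frozenset(pairs)


def compare_conditions(
    before: GenePartition,
    after: GenePartition,
    focal: FocalGeneList,
    em_after: ExpressionMatrix | None = None,
    j_min: float = 0.25,
    epsilon: float = 1e-9,
    condition_pair_label: str = "",
) -> ReorganizationReport:
    """Convenience composition of the full condition-pair comparison."""
    match = match_clusters(before, after, j_min=j_min)
    stayers, movers = classify_genes(before, after, match)
    co, join = comovers(before, after, match, focal)
    profiles = (same_profile_pairs(em_after, list(focal), epsilon)
                if em_after is not None else frozenset())
    return ReorganizationReport(
        match=match,
        stayers=stayers,
        movers=movers,
        comovers=co,
        joiners=join,
        same_profile_pairs=profiles,
        condition_pair_label=condition_pair_label,
    )
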