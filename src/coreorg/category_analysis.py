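"""Functional-category cross-tabulation of co-movers and cluster
composition tables.

The category matrix counts, for each focal gene, how many of its
co-movers (or joiners) fall in each functional category — the raw-count
summary behind the category-by-focal-gene heatmap.  Composition tables
break each target-partition cluster into the percentage contributed by
every source-partition cluster (plus the isolated/singleton buckets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .community_detection import GenePartition, cluster_sizes
from .errors import ValidationError, VocabularyMismatchError
from .io_formats import UNCLASSIFIED, GeneAnnotation
from .reorganization import ReorganizationReport

logger = logging.getLogger(__name__)

ISOLATED_BUCKET = "ISOLATED"
SINGLETON_BUCKET = "SINGLETON"


@dataclass
class CategoryMatrix:
    """Category x focal-gene co-mover counts.

    Rows are functional-category names (closed vocabulary, with
    ``unclassified`` reserved for unannotated genes), columns focal
    locus tags, cells non-negative integer gene counts.  ``scope``
    names the condition pair, or the aggregate of several.
    """

    data: pd.DataFrame
    scope: str = ""

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("data: counts must be non-negative")
        self.data = self.data.astype(int)

    @property
    def categories(self) -> list[str]:
        return list(self.data.index)

    @property
    def focal_tags(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CompositionTable:
    """Per-target-cluster percentage breakdown by source cluster.

    ``percentages[target_id][source_bucket]`` is a 2-decimal percentage;
    buckets are source cluster ids (as strings) plus the ISOLATED and
    SINGLETON classes.  Each pie sums to 100 within rounding tolerance.
    """

    percentages: dict[int, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target_cluster": tid, "source_cluster": src, "percent": pct}
            for tid, comp in sorted(self.percentages.items())
            for src, pct in sorted(comp.items())
        ]
        return pd.DataFrame(rows, columns=["target_cluster", "source_cluster", "percent"])


def _category_of(gene: str, ann: Mapping[str, GeneAnnotation | str]) -> str:
    entry = ann.get(gene)
    if entry is None:
        return UNCLASSIFIED
    return entry.category if isinstance(entry, GeneAnnotation) else str(entry)


def _vocabulary(ann: Mapping[str, GeneAnnotation | str]) -> list[str]:
    seen: list[str] = []
    for entry in ann.values():
        cat = entry.category if isinstance(entry, GeneAnnotation) else str(entry)
        if cat not in seen:
            seen.append(cat)
    if UNCLASSIFIED not in seen:
        seen.append(UNCLASSIFIED)
    return seen


def categorize_comovers(
    report: ReorganizationReport,
    ann: Mapping[str, GeneAnnotation | str],
    source: str = "comovers",
) -> CategoryMatrix:
    """Count co-movers (or joiners) of each focal gene per category.

    ``cell(c, f) = |{g in comovers(f) : category(g) = c}|``; genes with
    no annotation count under ``unclassified``.  Row order follows the
    annotation table's first-appearance order, column order the focal
    order of the report; any reordering is left to the dendrogram stage.
    """
    if source not in ("comovers", "joiners"):
        raise ValidationError("source: must be 'comovers' or 'joiners'")
    sets = report.comovers if source == "comovers" else report.joiners
    vocab = _vocabulary(ann)
    data = pd.DataFrame(0, index=vocab, columns=list(sets), dtype=int)
    for f, genes in sets.items():
        for g in genes:
            data.loc[_category_of(g, ann), f] += 1
    return CategoryMatrix(data=data, scope=report.condition_pair_label)


def aggregate(matrices: Iterable[CategoryMatrix]) -> CategoryMatrix:
    """Cellwise sum over condition pairs (columns unioned, missing = 0).

    The category vocabulary must be identical across inputs; a mismatch
    raises, listing the differing labels.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValidationError("matrices: need at least one category matrix")
    vocab = list(matrices[0].data.index)
    for cm in matrices[1:]:
        if set(cm.data.index) != set(vocab):
            diff = set(cm.data.index) ^ set(vocab)
            raise VocabularyMismatchError(
                f"category vocabularies differ on: {sorted(diff)}"
            )
    columns: list[str] = []
    for cm in matrices:
        for col in cm.data.columns:
            if col not in columns:
                columns.append(col)
    total = pd.DataFrame(0, index=vocab, columns=columns, dtype=int)
    for cm in matrices:
        total = total.add(cm.data.reindex(index=vocab), fill_value=0).astype(int)
    total = total[columns].reindex(vocab)
    scope = "+".join(cm.scope or "?" for cm in matrices)
    return CategoryMatrix(data=total, scope=scope)


@dataclass
class IntersectionTable:
    """Focal x named-list overlap of co-mover sets.

    ``counts`` is a focal-by-list DataFrame of intersection sizes;
    ``sets`` holds the actual gene sets; ``independent`` flags focal
    genes whose co-movers miss every supplied list.
    """

    counts: pd.DataFrame
    sets: dict[tuple[str, str], frozenset[str]]
    independent: frozenset[str]


def intersect_lists(
    report: ReorganizationReport,
    lists: Mapping[str, Iterable[str]],
) -> IntersectionTable:
    """Intersect each focal gene's co-movers with named gene lists
    (e.g. externally determined up-/down-regulated sets)."""
    named = {name: frozenset(genes) for name, genes in lists.items()}
    focal_tags = list(report.comovers)
    counts = pd.DataFrame(0, index=focal_tags, columns=list(named), dtype=int)
    sets: dict[tuple[str, str], frozenset[str]] = {}
    for f in focal_tags:
        co = report.comovers[f]
        for name, members in named.items():
            inter = co & members
            sets[(f, name)] = inter
            counts.loc[f, name] = len(inter)
    independent = frozenset(
        f for f in focal_tags if named and counts.loc[f].sum() == 0
    )
    return IntersectionTable(counts=counts, sets=sets, independent=independent)


def composition(
    source: GenePartition,
    target: GenePartition,
    top_k: int,
) -> CompositionTable:
    """Percentage make-up of the top_k largest target clusters by source
    cluster (plus ISOLATED/SINGLETON buckets), 2-decimal rendering."""
    if top_k < 1:
        raise ValidationError("top_k: must be >= 1")
    ordered = cluster_sizes(target)
    if top_k > len(ordered):
        logger.warning("composition: top_k=%d exceeds %d target clusters; "
                       "using all", top_k, len(ordered))
        top_k = len(ordered)
    out: dict[int, dict[str, float]] = {}
    for tid, _size in ordered[:top_k]:
        members = target.members(tid)
        buckets: dict[str, int] = {}
        for gene in members:
            try:
                key = source.status_key(gene)
            except KeyError:
                logger.warning("composition: gene %r absent from source "
                               "partition; skipped", gene)
                continue
            if key[0] == "CLUSTER":
                label = str(key[1])
            elif key[0] == "ISOLATED":
                label = ISOLATED_BUCKET
            else:
                label = SINGLETON_BUCKET
            buckets[label] = buckets.get(label, 0) + 1
        n = sum(buckets.values())
        out[tid] = _round_percentages(buckets, n)
    return CompositionTable(percentages=out)


def _round_percentages(buckets: dict[str, int], n: int) -> dict[str, float]:
    """2-decimal percentages by largest-remainder rounding, so each pie
    sums to exactly 100.00 regardless of the number of buckets."""
    hundredths = {lab: 10_000 * c / n for lab, c in buckets.items()}
    floored = {lab: int(v) for lab, v in hundredths.items()}
    shortfall = 10_000 - sum(floored.values())
    by_remainder = sorted(buckets, key=lambda lab: (floored[lab] - hundredths[lab], lab))
    for lab in by_remainder[:shortfall]:
        floored[lab] += 1
    return {lab: floored[lab] / 100.0 for lab in buckets}
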