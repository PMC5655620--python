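"""Readers and writers for every external artifact of the pipeline.

Expression matrices travel as plain genes x samples TSV (first column =
locus tag, header row = sample ids); a convenience reader handles the
GEO series-matrix text dialect.  Networks are written as edge-list TSV
or GraphML, partitions and category matrices as TSV, reorganization
reports as a single JSON document.  Every writer has a reader that
round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - type-only imports avoid cycles
    from .category_analysis import CategoryMatrix
    from .community_detection import GenePartition
    from .network_construction import CoexpressionNetwork
    from .reorganization import ReorganizationReport

logger = logging.getLogger(__name__)

#: Cell contents treated as missing during expression-matrix cleaning.
MISSING_TOKENS = frozenset({"NA", "null", ""})

#: Reserved functional-category label for genes without an annotation.
UNCLASSIFIED = "unclassified"

#: Sentinel cluster labels used in partition TSV files.
ISOLATED_LABEL = "ISOLATED"
SINGLETON_LABEL = "SINGLETON"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix for one experimental condition.

    Rows are genes identified by locus tags (e.g. ``"PA0153"``), columns
    are arrays/samples.  Values are expression intensities, unitless
    after any log transform.  Invariants (unique tags and sample ids,
    matching dimensions, finite values) are enforced at construction.
    """

    locus_tags: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.locus_tags = [str(t) for t in self.locus_tags]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.locus_tags)) != len(self.locus_tags):
            raise ValidationError("locus_tags: duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids: duplicate sample identifiers")
        if self.values.shape != (len(self.locus_tags), len(self.sample_ids)):
            raise ValidationError(
                f"values: shape {self.values.shape} does not match "
                f"{len(self.locus_tags)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("values: non-finite entries after cleaning")

    @property
    def n_genes(self) -> int:
        return len(self.locus_tags)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, tag: str) -> np.ndarray:
        return self.values[self.locus_tags.index(tag)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.locus_tags, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition_label: str = "") -> "ExpressionMatrix":
        return cls(
            locus_tags=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            condition_label=condition_label,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Functional annotation for one gene: locus tag, one category, product."""

    locus_tag: str
    category: str
    product_name: str | None = None


@dataclass
class FocalGeneList:
    """An ordered set of genes whose reorganization is tracked.

    The packaged default is the 46 PAH-degradation locus tags of
    P. aeruginosa PAO1 (:func:`default_focal_genes`).
    """

    locus_tags: tuple[str, ...]
    label: str = "PAH degradation genes"

    def __post_init__(self) -> None:
        tags = tuple(str(t) for t in self.locus_tags)
        if len(set(tags)) != len(tags):
            raise ValidationError("locus_tags: duplicate focal genes")
        self.locus_tags = tags

    def __len__(self) -> int:
        return len(self.locus_tags)

    def __iter__(self):
        return iter(self.locus_tags)

    def coverage(self, em: ExpressionMatrix) -> tuple[list[str], list[str]]:
        """Report which focal genes are present/absent in a matrix.

        Membership is reported, never assumed: returns
        ``(present, missing)`` in focal-list order.
        """
        have = set(em.locus_tags)
        present = [t for t in self.locus_tags if t in have]
        missing = [t for t in self.locus_tags if t not in have]
        if missing:
            logger.warning(
                "%d/%d focal genes absent from matrix %r: %s",
                len(missing), len(self.locus_tags),
                em.condition_label, ",".join(missing),
            )
        return present, missing


def default_focal_genes() -> FocalGeneList:
    """The packaged 46 PAH-degradation locus tags (PA0153 ... PA5427)."""
    text = resources.files("coreorg").joinpath("data/pah46.txt").read_text()
    tags = [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
    return FocalGeneList(locus_tags=tuple(tags))


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _clean_rows(
    tags: list[str],
    raw: list[list[str]],
    sample_ids: list[str],
    path: str,
) -> tuple[list[str], np.ndarray]:
    """Apply the missing-value and duplicate-tag policies.

    Missing cells (``NA``/``null``/empty) are imputed by the gene's row
    mean when under 25% of the row is missing, otherwise the gene is
    dropped with a warning.  For duplicated locus tags (multiple probes
    per gene) the highest-variance row is kept.
    """
    n_samples = len(sample_ids)
    kept_tags: list[str] = []
    kept_rows: list[np.ndarray] = []
    for i, (tag, cells) in enumerate(zip(tags, raw)):
        vals = np.empty(n_samples, dtype=float)
        missing = np.zeros(n_samples, dtype=bool)
        for j, cell in enumerate(cells):
            token = cell.strip()
            if token in MISSING_TOKENS:
                missing[j] = True
                vals[j] = np.nan
            else:
                try:
                    vals[j] = float(token)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} for gene "
                        f"{tag!r} (row {i + 2}), sample {sample_ids[j]!r}"
                    ) from None
        if missing.any():
            frac = missing.mean()
            if frac >= 0.25 or (~missing).sum() == 0:
                logger.warning(
                    "%s: dropping gene %r (%.0f%% missing values)",
                    path, tag, 100 * frac,
                )
                continue
            vals[missing] = vals[~missing].mean()
        kept_tags.append(tag)
        kept_rows.append(vals)

    # Duplicate locus tags: keep the most variable probe, preserve the
    # row order of the first occurrence.
    first_index: dict[str, int] = {}
    best: dict[str, np.ndarray] = {}
    for idx, (tag, row) in enumerate(zip(kept_tags, kept_rows)):
        if tag not in best:
            first_index[tag] = idx
            best[tag] = row
        else:
            logger.warning("%s: duplicate locus tag %r; keeping the "
                           "higher-variance probe", path, tag)
            if np.var(row) > np.var(best[tag]):
                best[tag] = row
    ordered = sorted(best, key=first_index.__getitem__)
    if not ordered:
        raise ParseError(f"{path}: no usable gene rows after cleaning")
    return ordered, np.vstack([best[t] for t in ordered])


def read_expression_tsv(
    path: str | Path,
    condition_label: str = "",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, column 1 = tags).

    ``log2_transform`` applies ``log2(x + 1)`` after cleaning; values
    are otherwise used as stored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise ParseError(f"{path}: malformed header (line 1 is empty)")
    header = lines[0].rstrip("\r\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: malformed header (line 1 has no sample columns)")
    sample_ids = [h.strip() for h in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample id in header (line 1)")
    tags: list[str] = []
    raw: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\r\n").split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {len(header)}"
            )
        tags.append(cells[0].strip())
        raw.append(cells[1:])
    kept, values = _clean_rows(tags, raw, sample_ids, str(path))
    if log2_transform:
        values = np.log2(values + 1.0)
    return ExpressionMatrix(kept, sample_ids, values, condition_label)


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    em.to_frame().to_csv(path, sep="\t", index_label="locus_tag")


def read_series_matrix(
    path: str | Path,
    condition_label: str = "",
    probe_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read the GEO series-matrix text dialect.

    Lines starting with ``!`` are metadata; the expression table sits
    between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``
    with quoted identifiers.  When ``probe_map`` is given, probe ids are
    replaced by their mapped locus tags; unmapped probes keep their
    verbatim identifier.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    begin = end = None
    for i, line in enumerate(lines):
        key = line.strip().strip('"').lower()
        if key == "!series_matrix_table_begin":
            begin = i
        elif key == "!series_matrix_table_end":
            end = i
    if begin is None or end is None or end <= begin:
        raise ParseError(f"{path}: missing series-matrix table begin/end markers")
    table = [ln for ln in lines[begin + 1:end] if ln.strip()]
    if len(table) < 2:
        raise ParseError(f"{path}: empty series-matrix table")

    def dequote(cell: str) -> str:
        cell = cell.strip()
        if len(cell) >= 2 and cell[0] == '"' and cell[-1] == '"':
            cell = cell[1:-1]
        return cell

    header = [dequote(c) for c in table[0].split("\t")]
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample id in series-matrix header")
    tags: list[str] = []
    raw: list[list[str]] = []
    for line in table[1:]:
        cells = [dequote(c) for c in line.split("\t")]
        if len(cells) != len(header):
            raise ParseError(f"{path}: ragged series-matrix table row {cells[0]!r}")
        probe = cells[0]
        tags.append(probe_map.get(probe, probe) if probe_map else probe)
        raw.append(cells[1:])
    kept, values = _clean_rows(tags, raw, sample_ids, str(path))
    return ExpressionMatrix(kept, sample_ids, values, condition_label)


# ---------------------------------------------------------------------------
# Annotations and gene lists
# ---------------------------------------------------------------------------

def read_annotation_tsv(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read an annotation TSV (locus_tag, category[, product_name]).

    One category per gene: for multi-category cells (``;``-separated)
    and repeated locus tags the first listed category wins; the rest is
    logged.  Insertion order of the file is preserved, which downstream
    fixes the category-vocabulary row order.
    """
    path = Path(path)
    out: dict[str, GeneAnnotation] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if len(header) < 2 or header[0].strip().lower() != "locus_tag":
            raise ParseError(f"{path}: annotation header must start with 'locus_tag'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\r\n").split("\t")
            if len(cells) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >= 2 fields")
            tag = cells[0].strip()
            cats = [c.strip() for c in cells[1].split(";") if c.strip()]
            if not cats:
                cats = [UNCLASSIFIED]
            if len(cats) > 1:
                logger.info("%s: gene %r lists extra categories %s; keeping %r",
                            path, tag, cats[1:], cats[0])
            product = cells[2].strip() if len(cells) > 2 and cells[2].strip() else None
            if tag in out:
                logger.info("%s: repeated annotation for %r ignored", path, tag)
                continue
            out[tag] = GeneAnnotation(tag, cats[0], product)
    return out


def write_annotation_tsv(annotations: Mapping[str, GeneAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("locus_tag\tcategory\tproduct_name\n")
        for ann in annotations.values():
            fh.write(f"{ann.locus_tag}\t{ann.category}\t{ann.product_name or ''}\n")


def read_gene_list(path: str | Path, label: str | None = None) -> FocalGeneList:
    """Read a plain-text gene list (one tag per line, ``#`` comments)."""
    path = Path(path)
    tags = []
    for line in path.read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            tags.append(token)
    return FocalGeneList(tuple(tags), label=label or path.stem)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def write_network(net: "CoexpressionNetwork", path: str | Path, format: str = "edge_tsv") -> None:
    """Write a network as ``edge_tsv`` or ``graphml``.

    edge_tsv rows are ``gene_a  gene_b  weight`` with ``gene_a < gene_b``
    lexicographically; leading ``#`` lines record the condition label,
    threshold, mode and the full node list so that re-reading
    reproduces the network exactly (including degree-0 nodes).
    """
    path = Path(path)
    if format == "edge_tsv":
        with path.open("w") as fh:
            fh.write(f"# condition_label: {net.condition_label}\n")
            fh.write(f"# threshold: {net.threshold!r}\n")
            fh.write(f"# mode: {net.mode}\n")
            fh.write(f"# nodes: {','.join(net.nodes)}\n")
            fh.write("gene_a\tgene_b\tweight\n")
            rows = sorted(
                (min(a, b), max(a, b), w) for a, b, w in net.iter_edges()
            )
            for a, b, w in rows:
                fh.write(f"{a}\t{b}\t{w!r}\n")
    elif format == "graphml":
        import networkx as nx

        g = net.to_networkx()
        g.graph["condition_label"] = net.condition_label
        g.graph["threshold"] = float(net.threshold)
        g.graph["mode"] = net.mode
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"format: unknown network format {format!r}")


def read_network(path: str | Path, format: str | None = None) -> "CoexpressionNetwork":
    """Read a network written by :func:`write_network`.

    ``format`` defaults from the file suffix (``.graphml`` vs TSV).
    """
    from .network_construction import CoexpressionNetwork

    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "edge_tsv"
    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        nodes = sorted(g.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        pairs = sorted(
            (min(index[a], index[b]), max(index[a], index[b]), float(d["weight"]))
            for a, b, d in g.edges(data=True)
        )
        return CoexpressionNetwork(
            nodes=nodes,
            edge_index=np.array([(i, j) for i, j, _ in pairs], dtype=np.int64).reshape(-1, 2),
            weights=np.array([w for *_, w in pairs], dtype=float),
            threshold=float(g.graph.get("threshold", 0.0)),
            mode=str(g.graph.get("mode", "positive")),
            condition_label=str(g.graph.get("condition_label", "")),
        )
    meta: dict[str, str] = {}
    edges: list[tuple[str, str, float]] = []
    header_seen = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            continue
        if not line.strip():
            continue
        if not header_seen:
            if line.split("\t")[:3] != ["gene_a", "gene_b", "weight"]:
                raise ParseError(f"{path}: line {lineno}: expected edge_tsv header")
            header_seen = True
            continue
        a, b, w = line.split("\t")
        edges.append((a, b, float(w)))
    nodes = ([n for n in meta.get("nodes", "").split(",") if n]
             or sorted({n for a, b, _ in edges for n in (a, b)}))
    index = {n: i for i, n in enumerate(nodes)}
    pairs = sorted((min(index[a], index[b]), max(index[a], index[b]), w)
                   for a, b, w in edges)
    return CoexpressionNetwork(
        nodes=nodes,
        edge_index=np.array([(i, j) for i, j, _ in pairs], dtype=np.int64).reshape(-1, 2),
        weights=np.array([w for *_, w in pairs], dtype=float),
        threshold=float(meta.get("threshold", "0.0")),
        mode=meta.get("mode", "positive"),
        condition_label=meta.get("condition_label", ""),
    )


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

def write_partition(p: "GenePartition", path: str | Path) -> None:
    """Partition TSV: gene, cluster_id (or ISOLATED/SINGLETON), condition."""
    with Path(path).open("w") as fh:
        fh.write(f"# quality: {p.quality!r}\n")
        fh.write("gene\tcluster_id\tcondition_label\n")
        for gene in sorted(p.assignment):
            fh.write(f"{gene}\t{p.assignment[gene]}\t{p.condition_label}\n")
        for gene in sorted(p.singletons):
            fh.write(f"{gene}\t{SINGLETON_LABEL}\t{p.condition_label}\n")
        for gene in sorted(p.isolated):
            fh.write(f"{gene}\t{ISOLATED_LABEL}\t{p.condition_label}\n")


def read_partition(path: str | Path) -> "GenePartition":
    from .community_detection import GenePartition

    quality = 0.0
    assignment: dict[str, int] = {}
    isolated: set[str] = set()
    singletons: set[str] = set()
    label = ""
    header_seen = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            if key.strip() == "quality":
                quality = float(val)
            continue
        if not line.strip():
            continue
        if not header_seen:
            header_seen = True
            continue
        cells = line.split("\t")
        if len(cells) != 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields")
        gene, cid, label = cells
        if cid == ISOLATED_LABEL:
            isolated.add(gene)
        elif cid == SINGLETON_LABEL:
            singletons.add(gene)
        else:
            assignment[gene] = int(cid)
    return GenePartition(
        assignment=assignment,
        isolated=frozenset(isolated),
        singletons=frozenset(singletons),
        condition_label=label,
        quality=quality,
    )


# ---------------------------------------------------------------------------
# Reorganization reports
# ---------------------------------------------------------------------------

def write_report(report: "ReorganizationReport", path: str | Path) -> None:
    """Serialize a report as one JSON object with deterministic ordering."""
    doc = {
        "condition_pair_label": report.condition_pair_label,
        "match": {
            "j_min": report.match.j_min,
            "mapping": {str(k): v for k, v in report.match.mapping.items()},
            "jaccard": {str(k): v for k, v in report.match.jaccard.items()},
        },
        "stayers": sorted(report.stayers),
        "movers": sorted(report.movers),
        "comovers": {f: sorted(s) for f, s in report.comovers.items()},
        "joiners": {f: sorted(s) for f, s in report.joiners.items()},
        "same_profile_pairs": sorted(list(p) for p in report.same_profile_pairs),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> "ReorganizationReport":
    from .reorganization import NEW, ClusterMatch, ReorganizationReport

    doc = json.loads(Path(path).read_text())
    mapping = {int(k): (NEW if v == NEW else int(v))
               for k, v in doc["match"]["mapping"].items()}
    jaccard = {int(k): float(v) for k, v in doc["match"]["jaccard"].items()}
    return ReorganizationReport(
        match=ClusterMatch(mapping=mapping, jaccard=jaccard,
                           j_min=float(doc["match"]["j_min"])),
        stayers=frozenset(doc["stayers"]),
        movers=frozenset(doc["movers"]),
        comovers={f: frozenset(s) for f, s in doc["comovers"].items()},
        joiners={f: frozenset(s) for f, s in doc["joiners"].items()},
        same_profile_pairs=frozenset(tuple(p) for p in doc["same_profile_pairs"]),
        condition_pair_label=doc["condition_pair_label"],
    )


# ---------------------------------------------------------------------------
# Category matrices
# ---------------------------------------------------------------------------

def write_category_matrix(cm: "CategoryMatrix", path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# scope: {cm.scope}\n")
        cm.data.to_csv(fh, sep="\t", index_label="category")


def read_category_matrix(path: str | Path) -> "CategoryMatrix":
    from .category_analysis import CategoryMatrix

    scope = ""
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            if key.strip() == "scope":
                scope = val.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[body_start:])), sep="\t",
                     index_col=0)
    df.index.name = None
    return CategoryMatrix(data=df.astype(int), scope=scope)
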