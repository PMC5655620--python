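"""Planted-module expression simulator with known reorganization.

The generator emulates the structure of small-replicate two-channel /
Affymetrix microarray compendia: thousands of genes, a handful of
samples per condition, block-correlated coexpression modules, a set of
uncorrelated ("isolated") genes, and a stress condition in which
designated gene sets — including focal genes — migrate between modules.
Ground truth (module membership before/after, the planted mover set and
per-focal co-mover sets) is returned alongside the matrices so every
downstream stage can be validated without external downloads.

Model: each module ``k`` carries one latent factor per sample,
``f_k ~ N(0, 1)``; gene ``i`` in module ``k`` has expression
``a * f_k + noise``, with ``a`` chosen so the expected pairwise Pearson
correlation inside a module equals ``within_module_corr``
(``a^2 / (a^2 + noise_sd^2) = within_module_corr``).  Isolated genes
are pure noise.  The stress condition redraws factors and noise
independently and applies the planted reassignments; only membership
carries over between conditions, mirroring the fact that a control and
a stress experiment are distinct array sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

#: Module label for genes outside every correlation module.
ISOLATED = "ISOLATED"

#: Cluster sizes of the 19 baseline modules at full compendium scale.
COMPENDIUM_MODULE_SIZES: tuple[int, ...] = (
    521, 506, 398, 368, 361, 356, 343, 321, 302, 280,
    253, 252, 245, 243, 225, 181, 168, 140, 85,
)

#: Total genes on the Affymetrix P. aeruginosa PAO1 array (GPL84).
COMPENDIUM_N_GENES = 5549

#: COG-style functional categories used by the synthetic annotation
#: generator; the vocabulary of real runs comes from the annotation file.
COG_CATEGORIES: tuple[str, ...] = (
    "amino acid transport and metabolism",
    "inorganic ion transport and metabolism",
    "energy production and conversion",
    "lipid transport and metabolism",
    "transcription",
    "posttranslational modification, protein turnover, chaperones",
    "coenzyme transport and metabolism",
    "signal transduction mechanisms",
    "cell wall-membrane-envelope biogenesis",
    "carbohydrate transport and metabolism",
    "replication, recombination and repair",
    "nucleotide transport and metabolism",
    "cell motility",
    "secondary metabolites biosynthesis, transport and catabolism",
    "translation, ribosomal structure and biogenesis",
    "defense mechanisms",
    "intracellular trafficking, secretion, and vesicular transport",
    "cell cycle control, cell division, chromosome partitioning",
    "chromatin structure and dynamics",
    "RNA processing and modification",
    "general function prediction only",
    "unclassified",
)


@dataclass
class MoverSet:
    """A planted migration: ``genes`` leave ``source`` for ``target``."""

    genes: tuple[int, ...]
    source: int
    target: int


@dataclass
class SyntheticSpec:
    """Full description of one synthetic condition pair.

    ``movers`` entries are ``(gene index set, source module, target
    module)``; ``focal_assignment`` pins focal locus tags onto gene
    indices so the generated matrices contain them verbatim.
    """

    n_genes: int
    n_samples: int
    module_sizes: tuple[int, ...]
    within_module_corr: float = 0.9
    n_isolated: int = 0
    movers: tuple[MoverSet, ...] = ()
    focal_assignment: dict[str, int] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        self.movers = tuple(
            m if isinstance(m, MoverSet) else MoverSet(tuple(m[0]), m[1], m[2])
            for m in self.movers
        )
        if self.n_genes <= 0:
            raise ValidationError("n_genes: must be positive")
        if self.n_samples <= 0:
            raise ValidationError("n_samples: must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ValidationError("module_sizes: all sizes must be positive")
        if self.n_isolated < 0:
            raise ValidationError("n_isolated: must be non-negative")
        if sum(self.module_sizes) + self.n_isolated != self.n_genes:
            raise ValidationError(
                "module_sizes: sum(module_sizes) + n_isolated must equal n_genes"
            )
        if not 0.0 < self.within_module_corr < 1.0:
            raise ValidationError("within_module_corr: must lie strictly in (0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd: must be > 0")
        seen: set[int] = set()
        for m in self.movers:
            if m.source == m.target:
                raise ValidationError("movers: source must differ from target")
            for k in (m.source, m.target):
                if not (0 <= k < len(self.module_sizes)):
                    raise ValidationError(f"movers: module index {k} out of range")
            overlap = seen.intersection(m.genes)
            if overlap:
                raise ValidationError(f"movers: gene sets overlap on {sorted(overlap)}")
            seen.update(m.genes)
        for tag, idx in self.focal_assignment.items():
            if not (0 <= idx < self.n_genes):
                raise ValidationError(f"focal_assignment: index {idx} for {tag!r} out of range")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "module_sizes": list(self.module_sizes),
            "within_module_corr": self.within_module_corr,
            "n_isolated": self.n_isolated,
            "movers": [
                {"genes": list(m.genes), "source": m.source, "target": m.target}
                for m in self.movers
            ],
            "focal_assignment": dict(self.focal_assignment),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["movers"] = tuple(
            MoverSet(tuple(m["genes"]), m["source"], m["target"])
            for m in doc.get("movers", [])
        )
        doc["module_sizes"] = tuple(doc["module_sizes"])
        return cls(**doc)


@dataclass
class GroundTruth:
    """Planted memberships and the implied mover/co-mover answers."""

    partition_before: dict[str, object]
    partition_after: dict[str, object]
    true_movers: frozenset[str]
    true_comovers: dict[str, frozenset[str]]


def _gene_names(spec: SyntheticSpec) -> list[str]:
    width = max(4, len(str(spec.n_genes)))
    names = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    for tag, idx in spec.focal_assignment.items():
        names[idx] = tag
    if len(set(names)) != len(names):
        raise ValidationError("focal_assignment: collides with generated gene names")
    return names


def _memberships(spec: SyntheticSpec) -> tuple[list[object], list[object]]:
    """Module id (or ISOLATED) per gene index, before and after."""
    before: list[object] = []
    for k, size in enumerate(spec.module_sizes):
        before.extend([k] * size)
    before.extend([ISOLATED] * spec.n_isolated)
    after = list(before)
    for m in spec.movers:
        for g in m.genes:
            if before[g] != m.source:
                raise ValidationError(
                    f"movers: gene {g} is in module {before[g]}, not source {m.source}"
                )
            after[g] = m.target
    return before, after


def _sample_condition(
    membership: list[object],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    rho = spec.within_module_corr
    a = spec.noise_sd * np.sqrt(rho / (1.0 - rho))
    factors = rng.standard_normal((len(spec.module_sizes), spec.n_samples))
    noise = rng.standard_normal((spec.n_genes, spec.n_samples)) * spec.noise_sd
    values = noise
    for i, mem in enumerate(membership):
        if mem is not ISOLATED and mem != ISOLATED:
            values[i] += a * factors[int(mem)]
    return values


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Draw the control/stress matrix pair plus ground truth.

    Fully reproducible from ``spec.seed``: the same spec yields bitwise
    identical matrices.
    """
    names = _gene_names(spec)
    before_mem, after_mem = _memberships(spec)
    rng = np.random.default_rng(spec.seed)
    values_before = _sample_condition(before_mem, spec, rng)
    values_after = _sample_condition(after_mem, spec, rng)

    em_before = ExpressionMatrix(names, [f"S{j + 1}" for j in range(spec.n_samples)],
                                 values_before, condition_label="before")
    em_after = ExpressionMatrix(names, [f"S{j + 1}" for j in range(spec.n_samples)],
                                values_after, condition_label="after")

    part_before = dict(zip(names, before_mem))
    part_after = dict(zip(names, after_mem))
    movers = frozenset(n for n in names if part_before[n] != part_after[n])
    comovers: dict[str, frozenset[str]] = {}
    for tag in spec.focal_assignment:
        comovers[tag] = frozenset(
            g for g in names
            if g != tag
            and part_before[g] == part_before[tag]
            and part_after[g] == part_after[tag]
        )
    truth = GroundTruth(part_before, part_after, movers, comovers)
    return em_before, em_after, truth


def default_compendium_spec(seed: int) -> SyntheticSpec:
    """The full-compendium baseline: 5549 genes, 19 modules, 4 samples.

    Module sizes follow :data:`COMPENDIUM_MODULE_SIZES`; the one gene
    left over is isolated.  Four samples per condition emulates typical
    GEO replicate counts; analyses that need stable correlations
    override ``n_samples`` upward.
    """
    return SyntheticSpec(
        n_genes=COMPENDIUM_N_GENES,
        n_samples=4,
        module_sizes=COMPENDIUM_MODULE_SIZES,
        within_module_corr=0.9,
        n_isolated=COMPENDIUM_N_GENES - sum(COMPENDIUM_MODULE_SIZES),
        seed=seed,
    )


def synthetic_annotation(
    locus_tags: list[str],
    seed: int = 0,
    categories: tuple[str, ...] = COG_CATEGORIES,
) -> dict[str, GeneAnnotation]:
    """Assign each gene a random COG-style category (synthetic stand-in
    for a genome-database annotation table)."""
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(categories), size=len(locus_tags))
    return {
        tag: GeneAnnotation(tag, categories[int(k)])
        for tag, k in zip(locus_tags, picks)
    }


def write_ground_truth_tsv(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmodule_before\tmodule_after\n")
        for gene in truth.partition_before:
            fh.write(f"{gene}\t{truth.partition_before[gene]}\t"
                     f"{truth.partition_after[gene]}\n")
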