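# Methods

This note documents the models, defaults and numerical choices behind
`coreorg`, and what the synthetic benchmarks do and do not demonstrate
about real microarray data.

## Network model

A coexpression network is built per condition from a genes × samples
matrix: all-pairs Pearson correlation, then a hard threshold.  Two
parameters matter and both are mandatory, logged run parameters:

- `t` (dimensionless, default **0.9**): the edge threshold.  With the
  few samples typical of array experiments (2–6 replicates), sample
  correlations are noisy and only high thresholds control edge density;
  0.9 is a conventional "strong correlation" default, not an estimate.
- `mode` (`positive` default, or `absolute`): whether anti-correlated
  profiles also form edges.  Coexpression in the "same pathway" sense
  is usually taken as positive co-variation, so positive is the
  default; `absolute` is available when co-regulation in either
  direction is of interest.

Genes with zero variance across samples have no defined correlation
and are excluded from the node set (with a logged warning) rather than
being assigned r = 0, which would silently suppress or fabricate
edges.  Correlation requires ≥ 3 samples; fewer is an error, not a
warning.  Expression values are used as stored; an optional
`log2(x+1)` transform is provided because array submissions vary in
whether they are already log scale, and the pipeline makes no attempt
to guess.

Missing-value policy at load time: cells equal to `NA`, `null` or the
empty string are imputed by the gene's row mean when less than 25% of
the row is missing, otherwise the gene is dropped with a warning —
Pearson correlation needs complete vectors, and a row more than a
quarter absent is not worth imputing.  When several probes map to one
locus tag, the highest-variance probe is kept (the most informative
profile); the discard is logged.

## Community detection

Degree-0 (isolated) genes are set aside before optimization and
reported as their own class, mirroring how the analysis treats
unconnected genes as a first-class group.  The remaining graph is
partitioned by maximizing Newman–Girvan modularity on the unweighted
thresholded graph — the edges are binary "good correlation" relations;
correlation weights are retained as metadata only.

Two solvers sit behind one interface:

- **Exhaustive** when at most 8 connected nodes remain: all set
  partitions (Bell(8) = 4140) are scored and the maximum taken, with
  ties (ΔQ ≤ 1e-12) resolved to the lexicographically smallest
  canonical partition.  Greedy agglomeration cannot guarantee the
  modularity optimum even on tiny graphs, and on graphs this small
  exactness is cheap, so the package simply is exact there.
- **Fast-greedy (CNM)** agglomeration from igraph's C core otherwise,
  cut at the maximum-modularity level.  At compendium scale (5549
  genes, ~5·10⁵ edges) this runs in about a second.

Both paths are deterministic; node order is canonicalized (sorted
locus tags) first, so results are invariant to gene input order.  An
igraph multilevel ("louvain") alternative is available behind
`method="louvain"` with a seeded RNG.  Communities that end with a
single connected member are reported as **singletons**, distinct from
clusters (size ≥ 2) and from isolated genes.  Cluster ids are assigned
in decreasing size order, ties broken by smallest member tag.  The
reported Q is recomputed from the final assignment by the package's
own modularity function (and cross-checked against networkx in tests).

## Cluster matching and reorganization calls

After-clusters are aligned to before-clusters by greedy one-to-one
Jaccard matching: score all pairs, accept in decreasing score (ties:
smaller after id, then smaller before id), subject to one-to-one use.
Maximum-weight assignment was considered and rejected: in the
high-overlap regime this analysis assumes, greedy and optimal
assignments coincide, and greedy is simpler to reason about and to
trace.  `j_min` (default **0.25**) is the floor below which a "match"
no longer means identity of the cluster across conditions; below it,
and for zero-overlap pairs at any `j_min`, after-clusters map to NEW.

Stayer/mover classification treats ISOLATED and SINGLETON as
pseudo-clusters: a gene is a stayer iff its membership class is
preserved (for clustered genes, via the match mapping), applied
uniformly.  Consequently the co-movers of a focal gene that moved
between pseudo-classes (e.g. into the isolated pool) are all genes
making the same class transition.  Both **co-movers** (shared source
and target) and **joiners** (shared target only) are emitted, since
"found together in a new cluster" admits either reading; category
matrices can be built from either set.

"Same-profile" pairs are defined on standardized (z-scored) vectors
with max-coordinate tolerance `epsilon` (default **1e-9**): affine
copies of one another — the most plausible origin of identical printed
profiles in array data — coincide exactly after standardization, and
at `epsilon = 0` the relation is a genuine equivalence.

## Category tables and dendrograms

Category vocabularies come from the annotation file (first-appearance
row order preserved), never from code; `unclassified` is reserved for
unannotated genes, so category column sums always equal co-mover set
sizes.  Aggregation over condition pairs is a cellwise sum with
unioned focal columns and requires identical vocabularies.

Composition tables (the per-target-cluster percentage pies) use
largest-remainder rounding to 2 decimals so every pie sums to exactly
100.00 regardless of bucket count; naive per-bucket rounding can drift
by 0.005 per bucket, which breaches the 0.05 conservation tolerance
once a pie has more than ten source buckets.

Hierarchical clustering is agglomerative with Euclidean distance and
average linkage by default (complete and single are available),
implemented directly with Lance–Williams updates because the package
guarantees a specific deterministic tie rule — among equally close
pairs, merge the one whose sorted (smallest-leaf, smallest-leaf) label
pair is lexicographically smallest — that library implementations do
not expose.  Heights are monotone for all three linkages.  Newick
branch lengths follow the UPGMA convention fixed by the two-leaf case
`(a:1.0,b:1.0):0.0;`: a cluster merged at height h places its leaves
at depth h/2, i.e. branch = (parent height − child height)/2.  Labels
with spaces, commas or quotes are single-quoted with doubled internal
quotes.  Heatmap bins divide [0, max cell] into 7 equal intervals
(red → violet), the maximum falling in the top bin; an all-zero matrix
is entirely bin 1.

## Synthetic data: what it emulates and what it does not

The generator draws one latent factor per module per sample
(standard normal) and sets gene i of module k to `a·f_k + ε`,
ε ~ N(0, σ²), with `a = σ·sqrt(ρ/(1−ρ))` so the expected within-module
Pearson correlation is exactly ρ (`within_module_corr`).  Isolated
genes are pure noise.  The stress condition redraws factors and noise
independently and applies the planted membership reassignments — only
membership carries over, as in distinct array sets.  Defaults: the
full-compendium baseline is 5549 genes in 19 modules with the size
profile (521, 506, …, 85) plus one isolated gene, 4 samples per
condition (typical GEO replicate counts) and ρ = 0.9.  Analyses that
need stable correlation estimates override `n_samples` upward (the
benchmarks use 20); `noise_sd` must be strictly positive since σ = 0
degenerates every profile to an exact copy of the factor.

A deliberate property of this model, worth understanding when reading
benchmark results: all pairwise correlations within a module share one
factor realization, so an unlucky factor draw (low empirical variance
across samples) depresses a whole module's sample correlations
together.  With a hard threshold at t = ρ = 0.9 roughly half of the
within-module pairs clear the threshold in any draw — ample for dense,
connected modules at sizes 85–521 (planted-partition ARI ≥ 0.97 on
every benchmark seed) — but at small module sizes an occasional gene
can drop below the threshold with all partners and leave its cluster.
The exact mover/co-mover recovery benchmark therefore thresholds at
t = 0.8 with ρ = 0.9 and 20 samples (modules of 30, ten planted
movers), where within-module edges are near-certain and between-module
edges (|r| ≥ 0.8 under the null at n = 20) have probability ~10⁻⁶.

The simulator does not model probe-level effects, array batches,
dye bias, heavy-tailed intensity distributions, or overlapping /
hierarchical modules.  Passing benchmarks therefore demonstrate that
the pipeline's inference is correct when its assumptions hold — not
that a particular threshold will recover biological pathways from any
given real compendium, where the unknown true correlation structure
and normalization dominate.

## Benchmark problem sizes

The recovery benchmarks run at 5549 genes × 20 samples × 10 seeds
(module recovery), 95 genes × 20 samples × 20 replicates (exact
mover/co-mover recovery), 200 connected graphs of ≤ 7 nodes against
exhaustive search, partitions of 10–5000 genes for the conservation
laws, and 50 random matrices of ≤ 8 labels against a naive O(n³)
agglomeration oracle.  These sizes keep the whole validation suite in
the tens of seconds on one CPU while exercising every code path at or
above the scales the analysis targets.

## Known limitations

- Hard thresholding makes cluster membership sensitive near t; no
  soft-threshold (WGCNA-style) or partial-correlation networks.
- Greedy Jaccard matching is not globally optimal when overlaps are
  weak and ambiguous; in that regime "same cluster across conditions"
  is ill-defined regardless of matcher.
- No significance testing of co-movement is performed or implied;
  counts are descriptive.
- The GEO series-matrix reader handles the common text dialect
  (metadata `!` lines, begin/end table markers, quoted identifiers)
  only; CEL-file processing and normalization pipelines are out of
  scope.
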