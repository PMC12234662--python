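# Methods

This note documents the statistical model implemented by `markerscore`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Marker integration

A marker record is the claim, by one annotation source, that a gene is a
positive or negative marker of a cell type in a given species, tissue and
category (physiological, disease, or cell-cycle). Records are deduplicated
on the identity tuple (species, tissue, celltype, gene, polarity, source)
before any counting, so a source can contribute at most one vote per claim.
All scores are computed within the user-selected (species, tissue,
category) scope, after deduplication and before any top-N selection.

**Conflict resolution.** Sources can disagree on polarity. For each
(gene, cell type) pair the number of distinct sources per polarity is
counted and the difference `d = n_pos − n_neg` taken; the marker is kept as
positive (`d > 0`) or negative (`d < 0`) with evidence consistency
`ECs = |d|`, or discarded when the votes cancel exactly. This rule is
antisymmetric: relabelling every positive record as negative and vice versa
flips every resolved polarity and preserves every ECs (a property test
asserts this).

**Specificity.** `SPs = 1/N` where `N` is the number of cell types a gene
marks with a given polarity inside the scope. Positive and negative
specificities are computed independently, since a gene can legitimately be
a broad negative marker and an exclusive positive one.

**Regularization.** Raw ECs values are long-tailed, and raw `1/N` values
live on a different scale, so both are compressed before being multiplied:

- `ECs_reg = 1 + log10(ECs)`, which maps a single-source marker to exactly
  1 and grows slowly (ECs = 10 → 2).
- For specificity, `N` is reverse-scaled within its polarity,
  `r = N_max + N_min − N`, then mapped affinely from `[N_min, N_max]` onto
  `[1, ECs_max]` and transformed identically: `SPs_reg = 1 + log10(m(r))`.
  The affine rescale onto `[1, ECs_max]` is what gives the two factors the
  same dynamic range, so neither dominates the product. When every gene of
  a polarity is equally specific (`N_max = N_min`) the map is the constant
  `ECs_max`: uniform specificity carries no discriminating information and
  must not penalize.

The closed forms are constrained by two analytic endpoints: a marker with
`ECs = 1` from the least specific gene weighs exactly 1, and a marker with
maximal consistency and specificity weighs `(1 + log10 ECs_max)²` — 5.58
(≈ 5.6) when `ECs_max = 23`. `scripts/acceptance.py` recomputes both from
scratch. Within this constraint other monotone transforms are conceivable;
the affine-log form is the simplest one hitting both endpoints.

**Top-N selection.** With `max_n_marker` set (default 30 in the pipeline),
each cell type retains its top-N positive and, independently, top-N
negative markers by descending weight, ties broken alphabetically by gene
symbol for determinism. Gene symbols are matched case-sensitively after
whitespace trimming; a `case_insensitive` flag exists but is off by
default, since silent case folding can merge distinct symbols (human vs
mouse conventions).

## Expression preprocessing

Counts are normalized per cell as `ln(1 + c/total × scale_factor)` with
`scale_factor = 10⁴`, the convention of the mainstream scRNA-seq toolkits
this package is meant to slot into. The scaled-expression (SE) layer is a
per-gene z-score across **all** cells, restricted to marker genes, using
the sample standard deviation and clipped to ±10 (the default `clip`).
Zero-variance genes get all-zero rows rather than errors — they simply
contribute nothing to any score. Cells with zero total counts are an error
naming the barcode; quality filtering is the caller's job. Whether
normalization/scaling has already been performed is communicated by an
explicit `se_provided` flag, never guessed from the data.

**log2 fold-change filter.** The optional per-cluster filter computes, for
each positive marker, `(mean normalized expression in cluster − mean in all
other cells)/ln 2` and removes markers below the threshold (default 1) from
that cluster's candidate set. Negative markers are never removed — absence
of expression is their signal. `threshold = −inf` disables the filter; a
single cluster skips it with a warning. The exact semantics of this filter
are a reconstruction: the threshold parameter is standard in this family of
tools but its published definition is loose, and cluster-vs-rest mean
difference on the log scale is the conventional reading.

## Impact scoring

Gene impact is the product `SE × ECs_reg × SPs_reg`; cell-type impact is
the weighted sum of positive-marker impacts minus that of negative-marker
impacts, each normalized by the square root of its summed weights. The
√-normalization keeps scores comparable between cell types with 3 markers
and cell types with 30: under independent unit-variance SE values the
score's variance is independent of the marker-set size. Consequences that
are property-tested: the positive term is linear in SE, and adding an
expressed negative marker strictly decreases a cell type's score.

Cell types whose markers are entirely absent from the matrix are excluded
from the score matrix (and listed in a warning) rather than scored 0 — a
structural zero would silently compete in the argmax.

**Aggregation and winners.** Cluster scores are the per-cluster quantile of
member-cell scores with linear interpolation, default `q = 0.75` (third
quartile) — robust to the skewed tail of non-member cells that leak into
real clusters while still rewarding the bulk. The winner is the argmax;
ties break lexicographically by cell-type id. With `allow_unknown`, a row
whose maximum score is ≤ 0 is labelled `unknown`: a non-positive impact
score means no net positive marker evidence, which is the natural reading
of "cannot be assigned". The quantile and tie rules are exposed as
parameters.

**Reports.** For each cluster the report lists the top-k (default 3)
competing cell types by cluster score, the fraction of member cells whose
per-cell winner is each label (interpreted as support; fractions sum to 1),
and the winner's genes ranked by the q-quantile of their gene impact across
member cells. Support is defined as per-cell winner fractions, not score
shares — it answers "how many cells individually agree with the cluster
call".

**Cell cycle and signatures.** Phases (including G0/quiescence) are
ordinary labels with their own positive/negative marker sets, scored by the
same engine at cell resolution. A custom signature is a single
pseudo-cell-type; unweighted signatures get weight 1 per gene, so a
one-gene signature's score is exactly that gene's SE.

## Ontology similarity

Cell-type terms form a DAG with child → parent `is_a` edges (multiple
parents supported). Information content is corpus-free:
`IC(t) = −ln(|descendants(t) ∪ {t}|/|terms|)`, so the root of a connected
graph has IC 0. Similarity is Lin's ratio scaled to 0–100:
`100·2·IC(MICA)/(IC(a)+IC(b))` with the most-informative common ancestor,
ties broken by lexicographic term id; identical terms score exactly 100,
terms in disconnected components 0. The log base cancels in the ratio.
A corpus-based IC (annotation frequencies) would be an alternative, but it
requires an external annotation corpus and breaks determinism of the
evaluation; descendant-count IC preserves the 0–100 contract (0 = maximal
distance, 100 = perfect match) that the benchmark metric needs. Published
evaluations using other similarity implementations may differ numerically
while agreeing on that contract.

## Evaluation

Benchmarking is cluster-level by default (each cluster mapped to the truth
label of the largest fraction of its cells, ties to the lexicographically
smallest label); per-cell evaluation is available by treating each cell as
a singleton cluster. Detection metrics use the standard precision/recall/F1
on the aberrant class with 0 on zero denominators. The one-tailed Wilcoxon
rank-sum test uses the exact null distribution whenever both samples have
≤ 10 observations — closed form without ties, exhaustive permutation
enumeration (all rank splits) with ties — and the normal approximation with
tie and continuity corrections otherwise; `alternative="greater"` tests
whether the second sample tends to exceed the first.

## Synthetic data

The generator emulates the study conditions every end-to-end check runs
under: 4 planted cell types × 200 cells, 5 positive marker genes per type,
100 background genes, marker elevation fold 8, and a 5-source marker
database with perfect agreement and no polarity conflicts (each varied per
test as needed). Counts are negative binomial in the (mean, dispersion)
parameterization, `var = μ + μ²/dispersion`, with `nb_mean = 2` (a
moderately expressed gene at typical 10x depth), `nb_dispersion = 2`
(substantial overdispersion, biologically realistic), and multiplicative
per-cell library-size factors uniform on (0.75, 1.25). All randomness flows
from a single integer seed through one PCG64 generator; identical
(params, seed) give bit-identical outputs.

Under these conditions the full pipeline recovers ≥ 95% of planted per-cell
labels at fold 8 (every seed of ten), collapses to the 1/n_types chance
level at fold 1, and improves monotonically in between — and recovered ECs
equals the planted source count exactly under perfect agreement. What this
does **not** show: robustness to ambient RNA, doublets, batch effects,
dropout beyond NB sampling, imperfect clustering, or marker databases whose
errors are correlated across sources. The generator deliberately omits
those; results on real tissue depend on marker quality in ways no synthetic
benchmark can certify.

## Numerical and degenerate-input conventions

- Quantiles: linear interpolation everywhere (numpy/pandas default),
  exposed as a parameter.
- Jaccard of two empty sets is 0; database concordance with no shared cell
  types is an error, not 0.
- Empty scopes, zero-total cells, absent marker genes (all of them), cyclic
  or empty ontologies, empty samples: explicit errors naming the offender.
- Marker genes missing from a matrix, excluded cell types, skipped filters:
  logged warnings, collected into the run report.
- Scores are float64 throughout; the loop-oracle equivalence tests pin the
  vectorized implementations to 1e−9.

## Known limitations

- The specificity rescaling depends on the scope-wide `N_min/N_max`, so a
  gene's weight can change when unrelated genes enter the scope; this is
  inherent to range-matching the two factors.
- Cluster-level annotation with the log2FC filter scores each cluster
  against its own filtered candidate set, so cluster score rows are not
  directly comparable across clusters (winners are unaffected).
- The OBO reader honors only `id`, `name` and `is_a`; obsolete terms are
  skipped, other relationship types ignored.
- No spatial-specific logic: spatial transcriptomics is handled exactly
  like scRNA-seq, one observation per cell/spot.
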