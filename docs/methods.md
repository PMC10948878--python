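# Methods

This note documents the models and procedures implemented in `uromet`,
the assumptions behind them, the parameters that matter, what the
synthetic-data generators do and do not emulate, and the design choices
made where the underlying analysis left the design open.

## Somatic variant consensus

**Model.** Four callers (MuTect2, Strelka, VarScan, SomaticSniper) are
treated as exchangeable witnesses of a somatic event. Variant identity is
the key (chrom, pos, ref, alt) after trimming shared suffix then prefix
bases of the alleles (advancing the position), because callers report the
same indel with different amounts of redundant context. Retention
requires ≥2 SNV callers, or both of Strelka and VarScan for indels (the
only two callers that report them).

**Filters**, applied in order on retained candidates, first failure
recorded: depth (tumor and normal ≥30 reads), tumor VAF (≥10% *and* >5
alt reads), normal contamination (normal VAF ≤1% *or* ≤1 alt read — the
"just one read" clause is read as ≤1), dbSNP membership unless the site
is also in COSMIC, and a platform artifact blocklist. The PASS set is
invariant to the order of the database filter relative to the quality
filters (statuses are re-derivable); the tests assert this.

**Parameters.** All thresholds live in `FilterConfig` (defaults above).
When callers disagree on depth/VAF for one key, the values come from the
caller with the highest tumor depth, ties broken by the fixed order
mutect2 < somaticsniper < strelka < varscan — a deterministic rule chosen
because no aggregation convention is canonical. The TMB-high threshold is
a required argument with no default: it is cancer-type-specific and has
no universal value. TMB counts all PASS somatic variants; the
nonsynonymous restriction is applied only by the concordance statistics.
The MSI score is the percentage of microsatellite sites called unstable;
MSI-high requires score strictly greater than 3.5, so a score of exactly
3.5 is MSS.

## Copy-number segmentation and calling

**Region filter.** A capture region is dropped only when *both* tumor and
normal have <100 reads — the literal reading of the rule; the
either-sample reading would be more conservative and is configurable via
`min_reads` only in its threshold, not its logic.

**Normalization.** Counts become fractions of the per-sample total
aligned reads. Explicit totals may accompany the region table (the
synthetic generator emits them, mirroring pipelines that normalize by
genome-wide alignment totals); otherwise column sums are used. The log₂
ratio is invariant to global scaling of either track.

**CBS.** Per chromosome (karyotypic order 1..22, X, Y, then lexical), a
recursive circular change-point search: every arc (i, j) with both arc
and complement of at least `min_width = 2` regions is scored, and the
split maximizing the two-sample |t| statistic is tested by permutation.
For fixed data the |t| over a split is a monotone function of the
between-group sum of squares B = (S·n − L·T)² / (n·L·(n−L)) (S = arc sum,
L = arc length, T = total), so the search maximizes B — this makes both
the observed scan and the `n_perm = 1000` within-segment permutations
vectorizable over all arc lengths. A split is accepted when the
add-one permutation p-value (1 + #{perm ≥ obs}) / (1 + n_perm) is below
`alpha = 0.01`; recursion continues on the resulting sub-segments.
`n_perm < 100` is rejected as giving unstable p-values. There is **no
post-hoc merge/prune ("undo") pass**: the recursion's output is final.
This is a deliberate simplification — it keeps the algorithm fully
specified and testable against brute force — and a known limitation: on
very noisy tracks it can retain marginally supported breakpoints that a
pruning pass would remove.

**Calls.** Amplified iff mean segment log₂ > 1, deleted iff < −0.5, both
strict; a segment at exactly 1.0 is neutral. Gene calls are emitted per
(gene, overlapping non-neutral segment) using 0-based half-open
coordinates; a gene spanning segments with conflicting non-neutral calls
yields one row per call with a `conflict` flag, since no single-call rule
is defensible.

## Concordance statistics

The sharing denominator is the union of the two PASS nonsynonymous
variant sets — chosen because the three reported percentages (shared,
primary-private, metastasis-private) must sum to 100. Indels are included
alongside SNVs. For a patient with several metastases, each
primary–metastasis pair is computed separately and the patient
contributes the unweighted mean; cohort means are unweighted over
patients, optionally stratified by prior-chemotherapy status. Pathogenic
overlap restricts alteration sets to entries labeled oncogenic or likely
oncogenic in a static file-based lookup — live database queries were
rejected for reproducibility.

## Transcriptomic classification

All log transforms are log₂(FPKM + 1), the dominant convention where the
base is unstated.

**Subtype.** Nearest centroid over six consensus classes using Pearson
correlation computed on the intersection of classifier genes; the label
is the argmax centroid, or "unclassified" when the best r < `min_cor`
(default 0.15). Pearson correlation makes the classifier invariant to
positive affine transforms of a sample's log-expression.

**Immune contexture.** Expression restricted to the signature genes,
log-transformed and median-centered per gene, then PAM with k = 2 over
samples. PAM is the classical BUILD + SWAP k-medoids on Euclidean
distances (no metric is canonical here; Euclidean on centered
log-expression was chosen), fully deterministic with ties broken by
lowest index; the SWAP phase strictly decreases the objective, so it
terminates. The cluster with the higher mean transformed signature
expression is labeled T-cell inflamed — labels derive from expression,
never from cluster indices, making them invariant to sample order. An
optional reference cohort can be co-clustered to stabilize the two-group
structure; calls are returned for query samples only.

**ssGSEA.** Per sample, genes are ranked by expression descending (ties
broken by gene order for determinism). The running sum gains
w(r) = r^α (normalized over in-set genes; r = N..1 is the rank position)
at in-set genes and loses 1/(N−|S|) at out-of-set genes; the enrichment
score is the *integral* (sum) of the running sum, with `alpha = 0.25`.
Both the form and α are configurable since neither is pinned down by
convention. Scores are z-standardized per set across samples (population
sd, so sd is exactly 1). Group comparison defaults to the unpaired
Mann–Whitney test — a signed-rank test strictly requires pairing, which
unequal primary/metastatic groups do not have — with `paired=True`
switching to the Wilcoxon signed-rank; q-values are Benjamini–Hochberg
and significance is q ≤ 0.25.

## Single-cell phenotyping

The cell table (one row per segmented cell: marker intensities +
morphology) is the interface; pixel-level processing and segmentation are
upstream concerns. Cells with solidity exactly 1 — perfectly convex
objects, typical of segmentation artifacts — are excluded first.

**Standardization.** log(1+x) on intensities; z-score per marker within
each image (a single-cell image gets z = 0 with a warning); cap at ±3;
then center and scale each marker globally. The cap bounds the influence
of bright artifacts before global statistics are computed. The order is
scale → batch-correct → (implicit) rescale via the correction's
standardization step.

**Batch correction.** Parametric empirical-Bayes location/scale
adjustment (ComBat): standardize each feature, estimate per-batch
per-feature means and variances, shrink them toward across-feature
moment-based hyperpriors by the standard iterative solution, remove, and
restore the global scale. A final per-feature re-centering guarantees the
global mean of every feature is preserved exactly. Single-batch input is
returned unchanged; batches of one cell are rejected.

**Graph and clustering.** PCA to `n_pcs = 30` (truncated with a warning
when there are fewer features), then a batch-balanced kNN graph: each
cell takes its `neighbors_within_batch = 3` nearest neighbors *from every
batch*, which stitches batches together even when a global kNN would stay
batch-pure. Leiden community detection (RB-configuration quality) at
`resolution = 0.5` with a fixed seed makes the pipeline deterministic
end to end. A 2-D UMAP (repulsion strength 25) is available for
visualization only and is deliberately untested.

**Metaclusters.** Clusters are aggregated into named lineages by an
ordered, editable rule table (first match wins): a rule lists markers
that must be high (mean standardized intensity ≥ threshold, default 0.5)
and markers that must not be (< threshold). The shipped table
(`data/metacluster_rules.yaml`) reconstructs the tumor basal/luminal,
T-cell (CD4/CD8/Treg), immunosuppressive-myeloid, macrophage, fibroblast
and endothelial logic; it is a reconstruction, not a canonical mapping,
which is why it ships as config rather than code. Unmatched clusters are
"unassigned" rather than force-labeled.

**Plasticity.** Per cell, log₂((KRT5 + ε)/(GATA3 + ε)) on *raw*
intensities with ε = 0.01 intensity units (a pseudocount is needed
because IMC intensities can be 0; 0.01 is well below biological signal).
Zero means equal basal and luminal marker expression; swapping the two
channels negates every ratio. Per-sample five-number summaries and
matched-pair median deltas support primary-vs-metastasis comparisons.

**Infiltration.** Cell counts per (image, metacluster), averaged per
sample (a metacluster absent from a sample counts 0), compared between
immune-inflamed and immune-depleted samples with the Mann–Whitney test.

## Statistics core

Implemented from first principles so every result is checkable against
enumeration:

- **Fisher exact (2×2, two-sided):** probability-mass rule — the sum of
  hypergeometric point masses ≤ the observed one, computed in exact
  integer arithmetic with a 10⁻⁷ relative tolerance guarding ties.
- **Mann–Whitney U:** exact rank-distribution enumeration when both
  n ≤ 8 and there are no ties; otherwise normal approximation with tie
  correction and a 0.5 continuity correction. Under the null the
  empirical size at α = 0.05 is 0.05 ± 0.01 (10,000-replicate seeded
  check in the suite).
- **Wilcoxon signed-rank:** zeros dropped; exact enumeration over 2ⁿ sign
  assignments (honoring tied ranks) for n ≤ 12, normal approximation with
  tie and continuity corrections above.
- **Benjamini–Hochberg:** step-up with monotonicity enforcement.

## Synthetic data: what it emulates, and what it does not

The generators produce the exact file formats the readers consume, carry
a complete truth table (every record in exactly one truth class), and are
bit-identical under a fixed seed.

- **Variant layer.** True variants are planted as shared / primary-private /
  metastasis-private at chosen counts (positions drawn without replacement
  from a 10,000-site toy exome over 22 chromosomes, guaranteeing key
  uniqueness); depths are Poisson around mean 100 (floored at 33 so the
  depth rule is passed with margin) and tumor VAFs uniform on [0.15, 0.6],
  clear of the 10% threshold. Artifact decoys each violate exactly one
  retention rule (low depth, low VAF, germline contamination, dbSNP-only,
  blocklisted, or single-caller), at a configurable rate per true variant.
  Callers are exchangeable apart from the indel-caller contract — no
  per-caller sensitivity profile is modeled, and neither are mutational
  signatures or read-level errors.
- **Copy-number layer.** Regions take expectation mean·2^(true log₂)
  inside planted segments; counts are Poisson draws (or the expectations
  themselves with noise off). Per-sample totals are emitted explicitly and
  set equal so the expected normalized ratio inside a segment is exactly
  2^(true log₂); with column-sum normalization alone, any genome-wide
  imbalance of the planted profile would shift all ratios by a constant —
  a real phenomenon the explicit totals deliberately remove so that truth
  is exact.
- **Expression layer.** Sample log-expression = subtype centroid +
  Gaussian noise, back-transformed to FPKM; immune-inflamed samples get a
  configurable additive shift on signature genes. Centroids are a fixed
  random matrix (150 genes, 6 classes) — they are *not* the published
  classifier's centroids, which are external data; the classifier itself
  is agnostic to which centroid file it is given.
- **Cell layer.** Per-population log-normal marker models and morphology
  draws, per-batch multiplicative marker factors, and a configurable rate
  of solidity-1 artifacts (default 2%, a realistic segmentation-artifact
  fraction). There is no spatial structure, no marker spillover, and no
  intensity drift within images.

Passing tests on these cohorts demonstrates that every algorithm recovers
known truth under its stated assumptions; it does not demonstrate
robustness to the failure modes real data adds (caller-specific error
profiles, GC waves in coverage, subtype mixtures, spatial autocorrelation
of cells).

## Problem sizes and numerical choices

The test suite and the acceptance script run the variant layer at 1,000
variants (30% artifacts), CBS at 1,000 regions with 1,000 permutations,
expression cohorts at 60 samples, the null-calibration of the
Mann–Whitney test at 10,000 replicates, and the single-cell benchmark at
30,000 cells — sizes chosen to exercise the asymptotic code paths while
keeping a full run in the tens of seconds. Seeds are threaded explicitly
through every stochastic step; segment means are exact member means
(asserted to 10⁻¹²); floating-point tie tolerances are 10⁻⁷ (Fisher) and
10⁻¹² (CBS permutation comparisons).
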