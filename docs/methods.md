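# Methods

## The problem and the pipeline

A tumor cell line panel annotated as SCLC is re-examined along three axes:
(i) which of the four lineage transcription factors dominates each line's
expression (the molecular subtype call), (ii) which genes are recurrently
mutated within one subtype and no other, and (iii) whether the suspicious
subtype's transcriptome resembles SCLC at all once it is co-embedded with a
reference cohort of SMARCA4-deficient tumors. The package implements each
stage as a pure function over validated containers (expression matrix,
mutation table, gene signature, annotation table) and chains them in
`run_pipeline`.

## Subtype assignment

A sample's subtype is the arg-max of the raw log-abundance of ASCL1, NEUROD1,
POU2F3 and YAP1, in that declared order. No per-gene standardisation is
applied: the call compares the four genes within one sample, so adding a
constant to a sample leaves the call unchanged (tested), whereas z-scoring
genes across samples would make the call cohort-dependent. Exact ties take
the first maximal gene in the declared order and are flagged; ties are
measure-zero for continuous data and indicate degenerate input when they
occur.

## Mutation screen

`classify_variant` maps MAF-style terms: nonsense, frameshift (insertion or
deletion), splice-site and nonstop variants are TRUNCATING; missense is
MISSENSE; all other coding terms — and unknown terms, with a warning — are
OTHER; absence of any record for a (sample, gene) pair is WT. Per-sample
genotype summaries take the worst class with precedence
TRUNCATING > MISSENSE > OTHER > WT.

Prevalence counts a sample once per gene regardless of how many variants it
carries. The threshold comparison defaults to `>= 0.5` with a `strict` flag
for `> 0.5`; both conventions appear in practice and the choice is stamped
into outputs. Exclusive sets are the singleton cells of the Venn
decomposition of the per-subtype prevalent sets; the decomposition partitions
the union exactly (property-tested), so no gene is double-counted.

Pathogenicity annotation, when wanted, is a join against a user-supplied
static table (gene, protein change, flag); the package performs no live
database queries.

## Neuroendocrine score

For a signature whose genes carry NE / non-NE classes and two reference mean
profiles, a sample's score is

    score = (r_NE − r_nonNE) / 2

with `r_NE` (`r_nonNE`) the Pearson correlation between the sample's vector
over available signature genes and the NE (non-NE) reference profile.
Pearson is the default (Spearman available). Genes absent from the matrix are
dropped from the sample and from both reference vectors symmetrically —
imputation would distort the correlation — and at least 80% of the classed
signature genes must be present (configurable floor; the run errors below it,
listing the missing genes). A zero-variance sample vector has no defined
correlation and is reported as missing with a warning. Consequences that are
tested: the score is invariant to positive affine transforms of the sample,
swapping the two reference profiles negates it exactly, and when the
references are perfectly anti-correlated the score of a sample equal to the
NE profile is exactly 1. The score's scale depends on the expression unit of
the matrix; scores should be compared only within one unit.

The package ships no real signature gene list — the 50-gene set is an
external input — but the simulator provides a shape-matched synthetic one.

## Integration

Cohorts are merged on the intersection of their gene sets (first cohort's
order) with source labels recorded per sample; duplicate sample ids across
cohorts are an error. Quantile normalization is applied jointly across the
merged matrix: each sample's values are replaced by the cross-sample mean of
order statistics at their rank, and tied values receive the mean of the
reference values across every sorted position the tie group spans (the
convention of the standard microarray implementations; the tie rule is not
dictated by the definition and is therefore stated here). QN is idempotent
and rank-preserving within samples (both property-tested). Gene z-scores use
the population (n) standard deviation — the common heatmap convention,
configurable — and zero-variance rows are dropped with a warning. The default
order is QN then z-score.

## Clustering and the batch-PC workaround

Clustering operates on the signature-restricted, gene-z-scored matrix with
Euclidean distance and Ward linkage by default (both configurable; parameters
are stamped into the model). Samples are sorted lexicographically before the
linkage is computed, which makes the output invariant to input column order.
Flat clusters come from cutting the tree at an explicit `k` (default 2 for
anchor detection): an explicit cut is reproducible where visual heatmap-block
reading is not. The anchor cluster is the one holding a strict majority of
the designated reference-class samples; with no strict majority the plurality
cluster is labelled and a warning raised (ties take the smallest cluster id).

When two cohorts are merged, one principal component of the z-scored matrix
is typically dominated by the data source. The screen formalises the manual
fix: PCA over samples, each of the first `n_pcs` (default 4) components
tested for source association — two sources: two-sided rank-sum test with
rank-biserial effect |1 − 2U/(n₁n₂)|; more: Kruskal–Wallis with ε² = H/(n−1)
— and components with p < 0.05 and effect ≥ 0.5 are excluded. Clustering
genes are the union (duplicates collapsed) of the `n_top` (default 50)
largest-|loading| genes of each retained component. The automatic rule can be
overridden with an explicit exclusion list to reproduce a known source-driven
component verbatim. If every screened component is source-associated the run
errors rather than silently clustering on nothing.

A regime note: the screen assumes the source axis is separable from the
biological axes. When a planted batch effect is made exactly as strong as the
planted biology, the two variance axes are degenerate, PCA mixes them and the
screen can flag a mixed component; the generator's batch-dominant regime
(shift 5 on 30% of genes against 2-log biology blocks) is the phenomenon the
workaround targets and is where its benefit is measured.

## Statistics

Two-group comparisons are gated on per-group Shapiro–Wilk normality (normal
means p > 0.05). If any group fails, a two-sided Mann–Whitney test is used:
exact when both groups have n ≤ 20 and the pooled values are tie-free,
otherwise asymptotic with tie and continuity correction. If both groups pass,
a two-sided Welch t-test is used and flagged `parametric=True` — the
parametric branch is this package's documented fallback choice, and
`force="nonparametric"` bypasses the gate entirely. Groups with n < 3 cannot
be gated and force the nonparametric branch with a warning. The exact branch
is validated against full enumeration of rank assignments; the asymptotic
branch agrees with the exact one to within a few percent under the null at
n = 15 per group, but the continuity correction inflates the *relative*
discrepancy when p itself is very small.

Multi-group comparisons use tie-corrected Kruskal–Wallis followed by Dunn's
pairwise z-tests on the pooled ranks (tie-corrected pooled variance),
adjusted by Bonferroni (Prism-compatible default) or Holm, with star codes
`* < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001`. Dunn's test is implemented
directly from the rank algebra and verified against a hand computation.

Pearson correlation reports the sample r with the two-sided p from the
t-distribution on n − 2 degrees of freedom; zero-variance input is an error.

## H-scores

`H = 1·pct₁ + 2·pct₂ + 3·pct₃` over the percentages of cells at staining
intensities 0–3; inputs are accepted as percentages or fractions with an
explicit unit flag and must sum to 100 (±1e−9). The score is linear in the
distribution and monotone under shifting mass upward (property-tested).

## Synthetic cohort generator

The generator defines the study conditions for every planted-truth check.
Defaults: 16 A, 12 N, 8 P and 8 Y samples (an A-dominant panel with eight
YAP1-high lines); dominant-TF effect +3 log-units; NE-block effect 2
log-units (+NE/−non-NE for subtypes A and N, the reverse for P and Y);
three quarters of Y samples SMARCA4-deficient with a 2-log-unit expression
drop *and* a guaranteed truncating SMARCA4 record, so genotype and expression
deficiency coincide per sample; Gaussian noise sd 1 on the log scale; 200
background genes alongside the 4 TF genes, SMARCA4 and a 25+25-gene
synthetic NE signature whose reference profiles equal the configured block
means; a two-source batch shift of 2 log-units on a seeded random 30% of
genes; and per-subtype Bernoulli mutation prevalences (TP53/RB1 ≈ 0.9 in
A/N/P, TP53 0.85 and RB1 absent in Y), from which the planted
subtype-exclusive gene sets are derived as the genes above the exclusivity
threshold in exactly one subtype.

Design choices worth knowing:

* All draws come from child generators spawned from one seed in a fixed
  order (expression noise, batch genes, deficient subset, mutations), so
  enlarging the gene panel never perturbs the mutation draws and identical
  seeds give byte-identical outputs.
* Sources alternate within each subtype — balanced and deterministic —
  keeping the technical axis orthogonal to biology by construction.
* The batch shift hits background genes only, never the four TF-caller
  genes, SMARCA4 or the signature blocks. Real batch effects are not so
  polite; the restriction keeps the planted biology identifiable (e.g. the
  zero-noise limit recovers every subtype call exactly) and is the main
  deliberate non-realism of the generator.
* Because the deficient subset always carries a SMARCA4 record, the
  effective SMARCA4 prevalence in Y is `f + (1−f)·p` for configured
  prevalence p and deficient fraction f; convergence-to-prevalence checks
  therefore use other genes.
* The generator emulates log-scale bulk abundance with additive effects and
  homoscedastic noise. It does not model counts, length/depth biases,
  isoforms, copy number, proteomics, or correlated noise between genes —
  so passing planted-truth tests demonstrates the pipeline's correctness on
  its stated assumptions, not robustness to every artefact of real RNA-seq.

## Problem sizes

The test suite and the acceptance script run entirely on simulated cohorts of
44–80 samples × ~255 genes across 10–20 seeds per check, and on closed-form
fixtures; the whole battery completes in seconds. The published full-cohort
analyses (hundreds of cell lines, 19k genes) are reachable through the same
functions via `sclcy.external` given local copies of the pinned public
releases.

## Known limitations

* The revised-classification flag in the pipeline summary is a transparent
  three-condition heuristic (non-WT SMARCA4, below-median NE score, anchor
  cluster membership); a real reclassification additionally requires
  histopathology, which is out of scope.
* Cross-dataset reconciliation of discordant subtype calls for the same line
  is left to the caller.
* The PC-exclusion rule is a formalisation of a manual judgement; near the
  degenerate regime described above it should be overridden with an explicit
  component list.
* Exact cluster memberships on real merged cohorts can be sensitive to
  distance/linkage choices; the external checks therefore allow a small
  documented parameter grid.
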