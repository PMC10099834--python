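# Methods

This note records the models, conventions and numerical choices behind
`crossexpr`, and what the synthetic-data tests do and do not establish.

## The comparative design

The package asks a three-tissue question: given a focal tissue (venom gland)
and two candidate relatives (silk gland, salivary gland) sampled across
species, which relative shares more transcriptional organization with the
focal tissue?  Three largely independent lines of evidence are computed on a
common cross-species ortholog expression matrix:

1. **Module preservation** — is the focal tissue's co-expression module
   structure present in the candidate tissue's data?
2. **DUG similarity** — do the tissues upregulate the same genes relative to
   non-secretory references (ovary, brain)?
3. **GO semantic similarity** — do the tissues' highly expressed genes enrich
   semantically related biological processes?

Supporting analyses: tissue-specificity (τ) classification with
orthogroup-level overlap, ISA transcription modules and their tissue
specificity, and sample-space views (PCA, correlation clustering, NJ
expression trees).

## Synthetic studies and their ground truth

`synthdata.generate_study` emits a complete study whose statistical structure
matches what the pipeline assumes, with every planted feature recorded in a
`TruthRecord`.

**Design.** Ten species (`sp01`…`sp10`, `sp01` the anchor), seven tissue
classes (venom/silk/salivary/other gland, ovary, brain, fat body), six
replicate libraries per tissue per species.  Six libraries — not the minimum
three — because the SI resampling scheme draws 3 without replacement per
tissue; with exactly 3 every draw is identical and the resampling distribution
degenerates to a point.

**Genes.** 2000 one-to-one ortholog slots shared by all species; 150
multi-paralog orthogroups (1–8 paralogs per species, small families most
probable); 150 species-specific genes per species.  Gene lengths are
log-uniform on 500–10000 bp.

**Expression model.** Per gene and sample a log2 mean is assembled from:

* a baseline log2 TPM, uniform on [0, 8] for unstructured genes and on
  [4, 8] for program members (co-regulated secretory machinery is
  well-expressed; a top-500 expression comparison cannot see genes that are
  not),
* program effects: a member of a program active in tissue T gains
  `effect_size` log2 units in T's samples,
* a per-sample latent factor per program with per-gene loadings
  `correlation_strength × 1.5 × U(0.5, 1.5)`.  The 1.5 log2-unit scale makes
  the loading approximately equal the realized member–member correlation
  under the default dispersion; the per-gene multipliers create hub
  structure, so intramodular connectivity is a preserved, testable quantity
  and not pure noise.  The factor is centered within each species × tissue
  cell so that the tissue-level elevation is exactly `effect_size` — the
  factor carries only sample-level co-variation,
* an additive per-(gene, batch) offset, N(−0.25, 0.1) / N(+0.25, 0.1) for the
  two default batches, applied on the log scale before counts are drawn
  (exactly the additive model the batch correction removes),
* divergent paralogs: each orthogroup paralog independently (p = 0.5) adopts
  one glandular tissue with a +5 log2 elevation there.

Counts are negative binomial with mean `2^μ × length_kb × depth` (depth
log-normal around 3) and a single study-wide dispersion φ = 0.3
(var = m + φm²).

**Planted programs (the default scenario).** A 150-gene secretion program
shared by all four gland classes (effect 1.5, correlation 0.5); a 300-gene
venom+silk core program (effect 2.0, correlation 0.8) absent from salivary
tissue; single-tissue programs for venom, silk (100 genes each) and salivary
glands (150 genes) at effect 4.5.  The true tissue-similarity ordering is
therefore venom~silk > venom~salivary.  Single-tissue effects sit at 4.5–5
log2 units because the τ > 0.8 rule needs a >5× expression ratio *after*
within-sample TPM renormalization, which compresses ratios by roughly 2× in
gland samples; real tissue-specific secretory genes are one to two orders of
magnitude elevated, so this is the realistic regime, and weaker "specific"
genes would be ambiguous by the index's own definition.

**Hit tables.** 12-column (outfmt-6 dialect) tables for every ordered species
pair plus within-species tables.  True ortholog pairs (matching paralog
indices) score ~400 bits, cross-paralog hits ~250, within-family
within-species hits ~300, decoys ~90, with σ = 5 noise — margins large enough
that reciprocal best hits recover the truth exactly.  E-values are
10^(−bits/10), monotone in the score.

**Ontology and annotations.** A random single-rooted DAG of 500 terms
(depth ≤ 10; 80% is_a, 20% part_of edges).  Each program owns a disjoint
"theme": a *closed* subtree of 8–20 terms (all descendants included), so
theme terms are not ancestors of unrelated annotation terms and enrichment
signals stay sharp.  Program genes draw 3–6 annotations from their theme;
background genes draw 3–6 terms uniformly.

**What the generator does not emulate.** Read-level artifacts (GC/length
bias within a sample, positional bias), isoforms, unbalanced tissue
availability across species (every synthetic species has every tissue),
phylogenetic correlation of expression evolution, and contamination between
tissues.  Passing the planted-recovery tests therefore shows the pipeline's
statistics recover the structure they are designed for at realistic noise;
it does not show robustness to mapping artifacts or confounded designs.

## Normalization

TPM from counts and lengths (rate = count/length, scaled to 10⁶ per sample);
log2(x+1); quantile normalization with the limma tie rule (ties share the
mean of the reference quantiles they span).  With ties present, quantile
normalization is not exactly idempotent and columns do not share an exact
multiset — both properties hold exactly for tie-free columns, which is what
the invariant tests assert.

Batch correction is a two-way location/scale adjustment: fit per-tissue means,
centre and rescale per-batch residuals to the pooled variance, restore the
tissue means.  No empirical-Bayes shrinkage: the generating model's batch
effects are additive per (gene, batch), which this adjustment removes exactly;
on real data with few samples per batch a shrinkage estimator (ComBat) would
be preferable.  The correction refuses to run when batch and tissue are
perfectly confounded, and protects `tissue` by default.

## Networks, modules, preservation

Unsigned adjacency |cor|^β with Pearson correlation; the standard TOM.
`pick_soft_threshold` implements the scale-free criterion (10 connectivity
bins, signed R² of log-frequency on log-connectivity, smallest power reaching
R² ≥ 0.85, else the argmax).  The end-to-end pipeline restricts the candidate
grid to β ∈ {6,…,12}: on block-structured data the scale-free criterion is
satisfied already at β ≈ 3, where module contrast against the correlation
background is too weak for separation; β ≥ 6 is the standard recommendation
for unsigned networks at these sample sizes.

Module detection: average-linkage clustering of 1 − TOM with a static cut at
0.995 × the dendrogram's maximum merge height (relative, so it adapts to the
TOM's dynamic range), minimum module size 30, then iterative merging of
modules whose eigengene dissimilarity is below 0.25.  This is a deliberate
simplification of the dynamic tree-cut algorithm; it recovers well-separated
planted modules and keeps the cut's semantics in one parameter.  Eigengenes
are the first PC of the gene-standardized module, oriented to correlate
positively with the module mean; kME is the gene–eigengene Pearson
correlation; hubs require kME > 0.8 and |gene–trait correlation| > 0.2, both
strict.

Preservation uses three statistics — within-module mean test adjacency
(density), the ref-vs-test correlation of intramodular connectivity, and the
ref-vs-test correlation of the within-module correlation structures
(connectivity) — standardized against a size-preserving permutation of module
labels over the shared genes (default 100 permutations, label-0 genes in the
pool).  Z_connectivity is the median of the two connectivity Z's; Z_summary
their mean with Z_density.  This keeps the full framework's
density+connectivity semantics at a tractable statistic count; the reduction
is recorded in the result objects.

## DUGs and the similarity index

The upregulation test is a Welch two-sample t-test on log2(TPM+1) between the
target tissue and pooled ovary+brain references — a distribution-light
substitute for a count-model ANOVA, recorded in every result's `method`
field.  Fold change uses pseudocount 1 on TPM means, strict > 2.  Cross-tissue
SI calls use raw p ≤ 0.05 (the resampling supplies the robustness); the
within-species variant exposes BH FDR via `use_fdr`.  SI resampling draws 3
libraries per tissue type without replacement, 100 replicates; the pipeline
pools four rotating species pairs per tissue-pair group so no single species'
sampling luck dominates a group, mirroring how multi-species comparisons are
pooled in practice.  Group differences: two-sided Mann–Whitney U (exact for
small untied groups), BH across pairs, significance at FDR < 0.01.

## τ classification

τ is computed on per-tissue mean TPM (raw scale, before quantile
normalization); assignment requires τ > 0.8 (strict) and the gene's top three
samples — ties broken by sample id — to come from one tissue.  Family-level
overlaps lift gene sets to orthogroup images, so a venom-specific gene and a
silk-specific paralog of the same family count in both sets and the
intersection.

## Semantic similarity

Enrichment: annotations propagated to ancestors over is_a and part_of;
hypergeometric upper-tail per term over the annotated background; BH ≤ 0.05.
Term similarity: Wang's measure with edge weights 0.8 (is_a) / 0.6 (part_of),
chosen because it needs no information-content corpus — appropriate for
synthetic annotation sets; set similarity by best-match average.  The
permutation null draws term sets of the observed sizes uniformly from the
full term pool, 1000 draws; significance is one-sided above the 95th
percentile.

## ISA

Row- and column-standardized copies of the matrix; random 10-gene seeds;
alternating thresholded scoring (keep |score| > t·sd, defaults
t_g = t_c = 2.0); convergence when membership repeats or successive gene
scores correlate > 0.99, at most 50 iterations; non-converged seeds dropped;
deduplication at 0.9 membership correlation keeping the more robust module
(robustness = product of converged score norms).  A module is tissue-specific
when all (min_frac = 1.0) of its member samples are one tissue class.

## Sample space

PCA on the 500 most-variable genes, gene-centered (the DESeq2 plotPCA
convention).  Sample clustering: Spearman ρ, distance 1 − ρ, "ward.D"
agglomeration — obtained exactly by running the squared-distance Ward update
on √d and squaring the merge heights.  NJ trees via scikit-bio's Saitou–Nei
implementation; negative branch lengths are clamped with the deficit moved to
the adjacent branch, and the tree is flagged when that happened.

## Problem sizes

The shipped configurations are scaled so a complete study analysis (2000
ortholog slots, 10 species, 420 samples, 100 preservation permutations, 100
SI replicates, 1000 semantic-similarity draws, 100 ISA seeds) runs in about
half a minute, and the five-seed planted-recovery suite in about three; these
sizes were chosen to make the statistics stable (permutation sds well
resolved, resampling distributions non-degenerate) while keeping the full
test cycle interactive.

## Known limitations

* The DE substitute is a t-test on log TPM; genuine count-model inference
  (edgeR/DESeq2-style NB GLMs) will differ at very low counts.
* The preservation composite uses 3 statistics, not the 20+ of the full
  framework; absolute Z values are comparable in spirit, not numerically,
  with the full implementation.
* Module counts and sizes depend on the static cut; only well-separated
  modules are guaranteed recovered.
* Orthogroups by connected components over best-hit edges can chain distinct
  families through promiscuous hits in noisy real data; the generator's
  margins avoid this regime.
* With heavy ties (many zero-TPM genes), quantile normalization's tie
  averaging means columns share a value multiset only approximately.
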