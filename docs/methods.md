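# Methods

This note records the models behind each stage, the parameters that
matter, the design decisions taken where more than one reasonable choice
existed, and what the synthetic benchmark does and does not demonstrate.

## Expansion screen

Per orthogroup, AM and NM per-species gene counts are compared with a
Mann–Whitney *U* test, alternative "AM stochastically larger". *U* counts
AM-over-NM wins with ties as ½. The exact null distribution is used for
small tie-free samples (min group size ≤ 8, no ties); otherwise the
tie-corrected normal approximation with continuity correction. Families
with zero genes in every species are dropped before testing, and
Benjamini–Hochberg runs over exactly the tested set. The expansion call
additionally requires median(AM) > median(NM): with heavily tied counts a
rank test can reach small p without the direction of interest, and the
median guard removes that artefact.

Sidedness is a design choice — the target is families *larger* in AM
plants, so one-sided "greater" is the default and a two-sided alternative
is exposed for sensitivity analysis. The screen cannot distinguish
selective expansion in AM lineages from loss in NM lineages; no function
here claims to.

`binomial_enrichment(k, n, baseline)` reports fold = (k/n)/baseline and
the exact upper tail P(X ≥ k), X ~ Binomial(n, baseline). It is the
validator used for candidate gene sets (e.g., the Common Symbiosis
Pathway membership check).

## Context-dependent expression

The interaction test fits, per gene,

    log mu_j = b0 + b1*myc_j + b2*stress_j + b3*myc_j*stress_j + log s_j

with negative-binomial (NB2) errors and fixed per-gene dispersion, and
compares against the model without b3 by a likelihood-ratio test
(chi-square, 1 df). This is a deliberately transparent approximation of
the DESeq2-style analysis a practitioner would run on real data: no
dispersion shrinkage, no outlier filtering, no independent filtering.
The trade is calibration-for-simplicity and it is acceptable here because
the benchmark is synthetic data whose generating model is known.

* **Size factors** are DESeq-style median-of-ratios, rescaled to
  geometric mean 1; the LRT is invariant to rescaling them by a constant.
* **Dispersion** is method-of-moments per design cell on normalised
  counts, alpha = (s^2 − m)/m^2, taking the max over cells, clipped to
  [1e-8, 10]. With 3 replicates per cell this estimator is noisy and
  upward-biased (max over four noisy cell estimates), which makes the
  per-gene test conservative; the family-level proportions inherit that
  conservatism. Genes with total count < 10 or zero mean in every cell
  are excluded before testing.
* **Fitting** is iteratively reweighted least squares with the working
  weights mu/(1 + alpha*mu), vectorised across all genes (batched 3×3/4×4
  solves), with steps damped to ±5 on the log scale and the linear
  predictor capped at ±50. Convergence tolerance is 1e-10 on the
  coefficients; non-converged genes are flagged and excluded from BH.
  The fitter agrees with statsmodels' NB GLM to ~1e-4 in the LR statistic
  (cross-checked in the test suite); it exists because the benchmark
  suites fit two models to every gene of a genome across dozens of
  simulated studies, which a per-gene GLM loop would make impractically
  slow.

The family metric is (number significant)/(number tested) per family,
with family size defaulting to the focal species' gene count. Whether
"family size" should be the focal-species count or the family's total
size across species is genuinely ambiguous; focal count is the default
because both the expression experiment and the SNP panel are
single-species measurements, and `--size-mode total` switches to the
cross-species sum.

## Fitness-associated SNP density

Filters keep SNPs with MAF ≥ 0.05 and missingness ≤ 0.10 — boundary
values survive, i.e., "less than 5%" is read strictly, so exactly-5% sites
are kept. Major-allele imputation replaces missing calls with the site's
modal allele, breaking ties to the allele that sorts first
(deterministic), and recomputes MAF. The association model itself (e.g.,
a latent-factor GWAS) is out of scope: per-SNP significance arrives as an
input column, either a boolean flag or a q-value dichotomised at 0.05.

A SNP belongs to a gene when the chromosome matches and
start ≤ position ≤ end (1-based closed intervals, matching GFF3). A
family's normalised density is (significant SNPs in its gene bodies) /
(summed gene-body lengths, end − start + 1). Gene-body length is used —
not CDS, not flanks — because the family's "sequence length" is taken as
the concatenated gene sequences; whether introns/UTRs should count is
unresolved in general, and the gene-body convention is the simplest
defensible reading. The density is invariant to splitting a gene into
abutting records of the same family, and a SNP overlapping genes of two
families counts once in each.

## Permutation enrichment

The engine answers one question for any per-family metric: is the
Spearman correlation between family size and metric stronger in the focal
(expanded) set than in random family sets of the same size? The null
draws k families without replacement from all eligible families —
expanded families are *not* excluded from the pool — and records the
subsample's rank correlation (midranks for ties). Empirical p-values use
the plain counting formula, p_greater = #{rho_null ≥ rho_obs}/N, with no
+1 correction; a `conservative_p` flag adds (x+1)/(N+1) for users who
need strictly positive p. Comparisons use a 1e-12 tolerance so that
"or equal" survives floating-point differences between the scalar and
vectorised rho routes. Draws with a constant side are redrawn up to 100
times, then recorded as 0 with a warning. No asymptotic p-values are
offered — the permutation null is the contract.

Note the null distribution centres at the *pool's realised* correlation,
not at exactly zero; for a large pool with independent size and metric
the two coincide closely.

Reproducibility: one root seed; each pipeline stage derives its own
generator from (seed, fixed stage tag), so stages are independently
reproducible and the full run report is byte-identical across reruns.

## Duplication-origin classification

Duplicate pairs are co-members of one orthogroup — the classifier
deliberately leverages gene families rather than raw sequence hits. Gene
ranks are 0-based per chromosome, ordered by start, ties broken by end
then gene ID. Classes, in priority order (a gene qualifying for several
gets the first): **wgd** (anchors a collinear block), **tandem**
(co-member at rank distance exactly 1), **proximal** (co-member with
1–20 intervening genes, i.e., rank distance 2–21), **dispersed** (other
co-members only), **singleton** (no co-member). Strand is ignored
throughout.

Collinear blocks come from a longest-chain dynamic programme per
chromosome pair and orientation: anchors sorted by rank on the first
chromosome chain when both rank steps are ≤ 25 (forward on the first,
forward/backward for same/inverted orientation), chains need ≥ 5 anchors,
and an anchor joins at most one block (longest chain first). Defaults
follow the common collinearity-scanner settings. Three plausibility rules
complete the chainer:

1. **Near-diagonal exclusion.** Intra-chromosomal anchors with
   |Δrank| ≤ 25 are not chainable — tandem/proximal arrays otherwise seed
   fake diagonal "blocks".
2. **Chain significance.** A chain must have e-value ≤ 1e-8 — the
   expected number of equally long, equally tight chains under uniform
   random anchors on the chromosome pair's rank grid — *or* tightness
   score Σ log(max_gap²/(Δa·Δb)) ≥ 20, a scale-free route that keeps
   genuinely contiguous segments in tiny inputs where no e-value can get
   small. Family-based anchors are dense (~750 per chromosome pair at the
   default genome size), and without this rule random diagonals at gap 25
   produce hundreds of spurious blocks; planted segments have near-unit
   steps and clear either route by many orders of magnitude.
3. **Segment disjointness.** An intra-chromosomal block's two rank
   intervals must not overlap: a duplicated segment lies elsewhere on the
   chromosome, while overlapping intervals are self-similarity bands
   (typically thrown off by 3+-copy proximal families whose outer pairs
   exceed the diagonal exclusion).

Per-class enrichment in the expanded set subsamples the matched number of
families (not genes) from all families with ≥ 1 focal gene, recomputes
class proportions over their genes, and reports
p_two_sided = min(1, 2·min(#null ≥ obs, #null ≤ obs)/N). Counting ties in
both tails makes this mildly conservative (level ≈ 0.03 at nominal 0.05
on the default benchmark). BH runs across the class tests of the species
analysed; when several species are analysed the caller can pool before
correcting.

## Synthetic study generator

The generator emulates the study's input structure with planted,
recoverable effects; its defaults are the benchmark conditions.

* **Family sizes**: 32 AM + 10 NM species, 2,000 orthogroups, 1.5%
  planted as AM-expanded. Counts are Poisson-like (negative binomial
  parameterised by a variance-to-mean ratio, default 1.0) with means 8
  (expanded, AM side), 2 (expanded, NM side) and 3 (background). The
  variance-to-mean parameterisation is deliberate: it is the natural
  overdispersion dial for count matrices of this kind, and at the default
  the screen's planted signal is strong (AM/NM AUC ≈ 0.97), giving
  sensitivity ≈ 1 at BH 0.05.
* **Genome**: 5 chromosomes; genes are fixed 1 kb bodies with 200 bp
  intergenic spacing, non-overlapping. Multi-copy families are laid out
  as tandem arrays (probability 0.5 in expanded families, 0.05
  background), proximal runs with 1–20 filler genes between copies
  (0.2/0.05), anchors of 3 planted 10-family duplicated segments (drawn
  from background families so the expanded set's class mix stays exactly
  as stated), or dispersed copies spread across chromosomes. Filler pools
  are shuffled before weaving so fillers carry no family-order structure.
  Planted classes are recovered by the classifier at ≈ 99% at defaults.
* **Expression**: 2×2 factorial, 3 replicates per cell, baseline mean
  100, NB dispersion 0.1, log-normal library-size factors (sd 0.2).
  A gene's interaction is non-zero with probability
  logistic(−3.5 + 0.55·size) inside expanded families and 0.02 elsewhere;
  the effect magnitude is ±log 8. These effect-size defaults were
  calibrated once, at design time, so that the conservative
  moments-based dispersion estimator still leaves the downstream
  enrichment with near-complete power across seeds; they are the
  generator's definition of a "clearly context-dependent" gene family.
* **SNPs**: one SNP per ~100 bp of gene body plus ~10% intergenic;
  MAF ~ U(0.01, 0.5) and missingness ~ U(0, 0.2), so both filters have
  real work; significance is Bernoulli with probability
  logistic(−3.0 + 0.35·size) in expanded-family genes and 0.05 elsewhere.
* **Null switches** (`null_expansion`, `null_interaction`, `null_snp`)
  turn each planted effect off, enabling the calibration suites.

One root seed makes every emitted file byte-identical across runs; the
membership table carries real gene IDs for the focal species and
synthesised IDs elsewhere (only their counts matter downstream).

What passing on this benchmark shows — and does not. It shows the
statistics are calibrated under their own null, recover planted effects
of the stated size, and that the classifier implements its definition
exactly. It does not show robustness to the things real data add:
phylogenetic non-independence among species (the screen treats species
as exchangeable; the study's phylogenetically corrected variant is out
of scope), annotation-pipeline heterogeneity, isoform collapsing, count
outliers, linkage disequilibrium among SNPs, or population structure in
the association evidence (assumed handled upstream of the significance
flags).

## Problem sizes in the test suite

The suites run at the default study scale (2,000 families, ~6,000 focal
genes, ~65,000 SNPs): calibration over 200 null-mode datasets at 1,000
permutations; power over 50 seeded studies per metric stage; classifier
oracle-equivalence over 500 random toy genomes (≤ 200 genes); and the
duplication-calibration estimate over 800 replicate focal draws (the
two-sided test's conservatism makes a precise estimate necessary to place
its level inside the uniformity band). The pipeline's own defaults
(n_perm = 10,000) are used for single-run checks; repeated-run suites use
1,000 permutations, which bounds their empirical p resolution at 0.001.

## Known limitations

* The NB-LRT's moments-based dispersion makes it conservative at 3
  replicates; with real data and many replicates, or a shrinkage
  estimator, per-gene power would be higher.
* The collinearity chainer has no gap-extension scoring and no synteny
  across species; it is a within-genome segmental-duplication detector
  tuned for family-derived anchors, not a replacement for a full synteny
  tool.
* Ks/Ka dating of duplications is not implemented, so "tandem" vs
  "proximal" is purely positional, and old tandem arrays interrupted by
  insertions are (correctly, per the definitions) called proximal.
* The empirical p-value without the +1 correction can be exactly 0; use
  `--conservative-p` when downstream consumers cannot accept that.
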