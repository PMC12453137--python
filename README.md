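# amexpand

Tools for asking how gene-family expansions shape the context-dependent
regulation of arbuscular mycorrhizal (AM) symbiosis — written for
comparative genomicists and molecular ecologists who have an orthogroup
table, a genome annotation, a factorial RNA-seq experiment and a SNP
association table, and want the full inference chain from "which families
are larger in AM-associating plants?" to "how did those families grow?".

Most land plants trade carbon for phosphorus with AM fungi, and the
benefit of that trade depends on environmental context. `amexpand`
implements the genomic side of that question as four linked analyses:

1. **Expansion screen.** For each orthogroup *g*, per-species gene counts
   of AM-associating species are tested against non-mycorrhizal (NM)
   species with a one-sided Mann–Whitney *U* (alternative: AM
   stochastically larger), followed by Benjamini–Hochberg correction.
   A family is *AM-expanded* when q < α and median(AM) > median(NM).
2. **Context-dependent expression.** In a 2×2 factorial experiment
   (±mycorrhizae × ±stressor), each gene's counts are fit by a
   negative-binomial GLM, log μ = β₀ + β₁·myc + β₂·stress +
   β₃·myc·stress + log s_j, and the interaction is tested by a
   likelihood-ratio test (χ², 1 df; FDR < 0.05). Per family the metric is
   the *proportion* of tested genes with significant β₃ — a proportion,
   so large families are not trivially favoured.
3. **Fitness-associated variation.** SNPs are filtered (MAF ≥ 5%,
   missingness ≤ 10%), optionally imputed with the site's major allele,
   and each family's *normalised SNP density* is the count of
   significantly trait-associated SNPs inside its gene bodies divided by
   its summed gene length.
4. **Permutation enrichment & duplication origins.** For either metric
   *m*, the observed Spearman ρ(size, m) over the AM-expanded set is
   compared with ρ in 10,000 random same-size family subsamples;
   p = #{ρ_null ≥ ρ_obs}/N. Each focal-species gene is also classified by
   duplication origin — singleton, dispersed, proximal (1–20 intervening
   genes), tandem (adjacent), or WGD/segmental (anchor of a collinear
   block), with priority WGD > tandem > proximal > dispersed > singleton —
   and per-class frequencies in expanded families are compared with the
   same subsample null.

A synthetic-data generator produces all five inputs with planted ground
truth (expanded families, per-gene duplication classes, size-dependent
interaction and SNP effects), so the whole chain is testable end to end
without any downloads.

## Worked example

Simulate a study at the default conditions (32 AM + 10 NM species, 2,000
orthogroups, ~1.5% planted expansions) and run every stage:

```bash
amexpand simulate --outdir demo --seed 42
amexpand run-all \
  --species demo/species.tsv --orthogroups demo/orthogroups.tsv \
  --gff demo/genome.gff3 --counts demo/counts.tsv --design demo/design.tsv \
  --snps demo/snps.tsv --outdir demo/results --seed 42 --n-perm 1000
```

Output (abridged):

```
screen: {"n_families_tested": 2000, "n_expanded": 34, "frac_expanded": 0.017}
ctx:    {"n_significant_genes": 270, "enrichment": {"rho_obs": 0.647,
         "null_mean": 0.193, "p_greater": 0.0, "fold": 3.35}}
snp:    {"n_snps": 68222, "n_snps_filtered": 31332, "enrichment":
         {"rho_obs": 0.894, "null_mean": 0.218, "p_greater": 0.0}}
dup:    {"n_blocks": 3, "enrichment": [... {"dup_class": "tandem",
         "prop_obs": 0.475, "null_mean": 0.079, "fold": 6.00,
         "p_two_sided": 0.0, "q": 0.0} ...]}
```

Reading this: the screen called 34 of 2,000 families AM-expanded (1.7%,
close to the planted 1.5%). Within that set, family size correlates with
the proportion of context-dependently expressed genes at ρ = 0.647
against a subsample null centred at 0.193 — none of 1,000 random subsets
matched it (p = 0.0) — and with normalised SNP density at ρ = 0.894.
Genes in expanded families are six times more often tandem duplicates
than random family sets (47.5% vs 7.9%, q < 0.05), while
WGD/segmental origins show no enrichment: in this simulated genome, as in
real ones, expanded families grow locally. Full tables land in
`demo/results/` alongside a `report.json` that records every parameter,
seed and library version; the same report is byte-identical when rerun
with the same seed.

Every stage is also a plain Python call (`screen_expanded`,
`run_interaction_tests`, `family_snp_density`, `enrichment_test`,
`classify_duplications`, …) operating on pandas/dataclass inputs — see
the module docstrings.

## Layout

```
src/amexpand/
  models.py      domain types (family-size matrix, gene/SNP records, results)
  io.py          OrthoFinder-dialect, GFF3, counts/design, SNP TSV/VCF readers
  screen.py      Mann–Whitney screen, BH, binomial enrichment
  expression.py  NB interaction LRT (vectorised IRLS), family proportions
  snp_density.py SNP filters, imputation, normalised family SNP density
  enrichment.py  Spearman + subsample permutation null
  duplication.py gene ranks, anchor pairs, collinear blocks, classes, enrichment
  simulate.py    synthetic study generator with planted ground truth
  pipeline.py    stage orchestration + JSON run report
  cli.py         `amexpand` command-line entry point
docs/methods.md  model assumptions, parameter choices, limitations
```
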