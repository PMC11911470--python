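# npscreen

Genetics-driven prioritization of natural products (NPs) and herbal
ingredients for a disease of interest, from summary statistics alone.

Drug-repurposing screens over natural-medicine catalogues face a gap: herbal
ingredients act through many compounds hitting many targets, while human
genetic evidence for disease genes lives in GWAS and molecular-QTL summary
statistics. `npscreen` bridges the two with a three-stage, fully inspectable
pipeline:

1. **Gene–disease association by SMR.** For each gene, significant QTL SNPs
   (FDR < 0.05) are extracted, LD-clumped, and harmonized against the outcome
   GWAS. With `z_x = b_x/se_x` (top cis-QTL effect on the gene's
   expression/protein level) and `z_y = b_y/se_y` (the same SNP's effect on
   the trait), summary-data-based Mendelian randomization gives

   `b_SMR = b_y / b_x`,  `T_SMR = z_x² z_y² / (z_x² + z_y²) ~ χ²₁`,

   and genes are ranked by `−log10 p_SMR`, one ranking per QTL × GWAS
   dataset pair.
2. **NP prioritization by preranked GSEA.** Each NP is a gene set (its
   targets); the weighted Kolmogorov–Smirnov enrichment score is tested
   against a permutation null of random same-size sets
   (`scoreType = pos`, adaptive permutation escalation in place of `eps = 0`).
   Per-pair p-values are pooled with Stouffer's method,
   `Z = Σᵢ Φ⁻¹(1−pᵢ)/√k`, and NPs are ranked by `−log10` of the meta-p.
3. **Herb screening.** Each herb is a set of NPs; a second preranked GSEA on
   the consensus NP ranking yields per-herb NES and p-values, reported with
   BH-FDR and Bonferroni adjustment. Candidates satisfy Bonferroni-adjusted
   p < 0.05 (strict).

A seeded synthetic benchmark generator (`npscreen.synthetic`) emits GWAS/QTL
summary statistics with planted causal genes and two-layer NP/herb networks
with planted effective sets, in exactly the file dialects the pipeline
reads, so every stage is testable without any external download.

## Worked example

Generate a default synthetic benchmark (500 genes / 50 causal, 2 QTL × 2
GWAS datasets, 200 NPs / 40 effective, 200 herbs / 20 planted) and run the
full pipeline:

```sh
npscreen simulate -o demo --seed 3
npscreen validate -c demo/config.yaml
npscreen run -c demo/config.yaml
```

The run log reports each stage:

```
[smr] qtl_1: 500 genes with instruments after FDR filter + clumping
[gsea-np] qtl_1__gwas_1: 200 NPs tested
[consensus] 200 NPs pooled over 4 analyses
[gsea-herb] 200 herbs tested, 14 selected (Bonferroni p < 0.05)
```

and `demo/results/herbs.tsv` begins:

```
INGREDIENT  NES          P_VALUE         P_FDR          P_BONFERRONI  N_NP_TARGETS  SELECTED
HB0125      1.396111703  9.999900001e-06 0.0005714228572 0.00199998   30            True
HB0089      1.377621695  1.99998e-05     0.0005714228572 0.00399996   30            True
```

Here 14 of 200 herbs pass the Bonferroni screen; the top rows are planted
herbs whose NPs target the planted causal genes (compare against
`demo/truth.tsv`). `N_NP_TARGETS` is the herb's NP-set size intersected with
the ranked NP universe, `NES` the enrichment score normalized by the mean
positive permutation-null score.

Intermediate tables (`genes_<pair>.tsv`, `np_<pair>.tsv`,
`np_consensus.tsv`) are always written, so every stage of a screen can be
audited. The `gsea` verb runs standalone preranked enrichment — including
signed rankings (`--score-type std`), e.g. log-fold-change signatures —
against two-column or GMT set files.

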