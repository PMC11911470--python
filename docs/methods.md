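# Methods

## Model and procedure

`npscreen` estimates gene–disease associations from two-sample summary
statistics and propagates them through two levels of set enrichment to a
screened table of herbal-ingredient candidates.

**SMR statistic.** For a gene instrumented by a single cis-QTL SNP, the Wald
ratio `b_SMR = b_y/b_x` estimates the effect of the gene's molecular level on
the trait. Its test statistic is `T_SMR = z_x² z_y² / (z_x² + z_y²)` with
`z = b/se`, referred to a χ² distribution with 1 df. `T_SMR` is symmetric in
`(z_x, z_y)`, bounded by `min(z_x², z_y²)`, and strictly increasing in
`|z_y|` for fixed `z_x ≠ 0`; because the instrument is required to be a
strong QTL (FDR < 0.05, |z_x| typically ≫ 2), the test is close to — and
never more liberal than — the outcome association test. The assumptions are
the usual ones for two-sample MR with one instrument: a strong, correctly
harmonized instrument, no horizontal pleiotropy at the top SNP, and shared
ancestry (LD structure) between cohorts. No heterogeneity (HEIDI-style) test
and no multi-instrument estimators (IVW, Egger) are provided; one statistic
per (gene, QTL dataset, GWAS dataset) triple.

**Instrument handling.** Instruments are significant QTL SNPs (`fdr <
0.05`; Benjamini–Hochberg is applied across the whole table when no FDR
column is supplied). Greedy LD clumping (sort by p, retain the best, discard
r² ≥ 0.001 within 10 Mb — the defaults of standard clumping tools) thins
each gene's instruments; LD always comes from a user-supplied table, never
from genotypes or a remote service. The SMR call uses the top (smallest
exposure p) SNP, falling through to the next-best instrument when the top
SNP cannot be matched or harmonized, so genes are not silently lost; a
`min_p_over_instruments` switch evaluates every instrument instead and keeps
the smallest SMR p (non-default, since single-top-SNP is the canonical
behavior).

**Harmonization.** Outcome records are aligned to the exposure's effect
allele: allele swaps negate the outcome beta and reflect EAF; strand
complements are resolved for unambiguous SNVs; indel alleles are compared as
exact strings with no complementing. Palindromic (A/T, G/C) SNPs carry no
strand information in their alleles, so they are aligned by effect-allele
frequency, and dropped whenever either EAF is missing or falls within
0.5 ± 0.08 (the ambiguity window, configurable). Harmonization is idempotent
and invariant to double flips (swapped alleles + negated beta on input).
Combinations requiring both complement and swap are reported under the
`strand_complement` action. LD-proxy lookup (off by default, min r² = 0.8)
substitutes the best available outcome SNP, re-phasing its alleles onto the
query SNP via the LD table's phase column; without phase information the
proxy's own alleles are kept under an explicit shared-coding assumption.

**Preranked GSEA.** Genes are ranked by `−log10 p_SMR` (p floored at 1e-300
so the statistic stays finite). For a set S in a universe of N ranked items,
`P_hit` accumulates member weights `|s|^q` (q = 1 by default), `P_miss`
accumulates `1/(N−|S|)`, and the enrichment score is the extremum of
`P_hit − P_miss` — the positive extremum under `score_type="pos"`
(appropriate for non-negative rankings), the larger-magnitude signed
extremum under `"std"` (for signed rankings such as log-fold-changes; ties
favor the positive side). When all member weights are zero the hit
increments fall back to uniform `1/|S|`. The implementation is vectorized
over candidate positions and agrees with both a direct running-sum oracle
and the R fgsea package's `calcGseaStat` to machine precision.

The permutation null draws random same-size member sets without replacement
from the universe — the only exchangeable unit for preranked input — and
`p = (b+1)/(n+1)` with `b` the count of null scores at least as extreme
(sign-stratified under `"std"`). NES divides the observed score by the mean
positive (resp. |negative|) null score. With `eps = 0` (default), a set
whose p hits the resolution floor (`b = 0`) escalates permutations tenfold
up to `n_perm_max`; the reached floor is recorded per result in the
`N_PERM` column. This adaptive escalation stands in for exact tail
refinement: downstream consensus ranking needs finite `−log10 p`, not exact
extreme tails. Defaults are `n_perm = 1000` and `n_perm_max = 100000`
(floor `−log10 p ≈ 5` per analysis), which keeps a full benchmark run in
seconds; raise `n_perm_max` for deeper tails. Null distributions depend
only on set size for a fixed ranking, so they are cached per (size,
n_perm) within a call and shared across same-size sets; the cache is
seeded independently of set order, preserving reproducibility. Ties in the
ranking are ordered by identifier so runs are exactly repeatable.

**Consensus and screening.** Per-analysis NP p-values are pooled with
equal-weight Stouffer combination, `Z = Σ Φ⁻¹(1−pᵢ)/√k`,
`meta-p = 1 − Φ(Z)`; an NP missing from some analyses is combined over the
k analyses in which it was tested. Small p ⇒ large positive z, consistent
with one-sided positive enrichment. Boundary p-values are clamped to
[1e-300, 1−1e-16] before the quantile transform. The herb-level GSEA runs
on the `−log10 meta-p` ranking; Bonferroni and BH adjustments use m = the
number of herbs actually tested (post size-filter), which the log records.
Herbs are reported sorted by p (ties by descending NES, then id) with
`selected = (Bonferroni-adjusted p < 0.05)`, strict. Genes absent from a
given SMR ranking are excluded from that analysis's universe (treated as
missing, not as zeros); each QTL input file is one exposure dataset keyed
by gene id, with any tissue collapsing left to upstream preparation.

## Synthetic benchmark

The generator emulates the statistical structure the pipeline assumes,
with defaults acting as the benchmark's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_causal | 500 / 50 | universe and planted causal genes |
| n_snps_per_gene | 3 | cis instruments per gene |
| qtl_z_scale | 8 | mean \|z\| of true instrument effects |
| gene_effect (δ) | 0.5 | outcome effect per unit exposure, causal genes |
| n_qtl × n_gwas | 2 × 2 | dataset pairs (4 analyses) |
| n_nps / n_effective | 200 / 40 | NP universe and planted effective NPs |
| targets_per_np / ρ | 20 / 0.6 | NP set size; causal fraction for effective NPs |
| n_herbs / n_planted | 200 / 20 | herb universe and planted herbs |
| nps_per_herb / eff. fraction | 30 / 0.6 | herb set size; effective-NP fraction |
| maf_range | (0.05, 0.5) | uniform allele-frequency range |
| qtl_n / gwas_n | 31,684 / 487,511 | cohort scales for the SE model |

Each SNP gets one latent true exposure effect (`|z| ~ N(qtl_z_scale, 1)`
truncated positive, random sign); each QTL dataset observes it with its own
sampling noise and each GWAS dataset observes δ times it (causal genes
only) with independent noise, using the standard GWAS standard-error model
`se = 1/√(2·n·maf·(1−maf))` with per-dataset sample sizes — the two-sample
structure SMR assumes. Cohort scales mirror large eQTL and case-control
GWAS consortia. Herb set sizes are in the tens because BATMAN-TCM-style
catalogues link an ingredient to tens-to-hundreds of compounds; with only a
handful of NPs per herb the weighted KS statistic cannot separate planted
from background herbs even in a reference implementation, and the benchmark
would not exercise recovery. A random 30% of outcome records are presented
with swapped allele orientation so harmonization does real work on every
run. Allele pairs are drawn from non-palindromic SNV combinations only —
palindromic variants would be dropped by the EAF-window policy under the
generator's frequency range — so the palindrome path is exercised by
dedicated tests instead. LD is independent by default (`ld.tsv` empty,
clumping a pass-through); `ld_mode="block"` writes constant within-gene r²
to exercise clumping.

Not emulated: realistic LD structure and allele-frequency spectra,
genome-wide SNP density, pleiotropy, sample overlap between exposure and
outcome cohorts, interaction-confidence scores of curated NP catalogues,
and tissue-specific QTL heterogeneity. Passing the benchmark therefore
demonstrates the statistical machinery and its calibration under the
generative model, not robustness to those real-data complications.

## Numerical choices

- p-value floors: 1e-300 before `−log10` (gene, NP rankings) and before
  normal quantiles; χ²₁ tails floored likewise so p stays in (0, 1].
- Permutation p is `(b+1)/(n+1)` — never zero; minimum attainable p is
  `1/(n_perm_max+1)` per analysis.
- Sorting ties: rankings break ties by identifier; herb tables by
  (p, −NES, id); clumping by (p, snp_id); proxy candidates by (−r², snp_id).
- Degenerate sets (empty intersection or full universe) are skipped with a
  log entry; a universe smaller than 2, an empty relationship file, or an
  empty harmonized universe aborts with a stage-named error.
- `b_x = 0` makes the Wald ratio undefined: the instrument is flagged and
  skipped.
- Seeding: one top-level seed; per-stage streams are derived from
  (seed, stage name, dataset-pair id) via a CRC mix, so adding a dataset
  never perturbs unrelated stages. Repeated runs with identical config and
  seed are byte-identical.

## Limitations

- Single-instrument SMR only; no HEIDI, colocalization, or multi-SNP MR.
- The permutation GSEA resolves p only to `1/(n_perm_max+1)`; exact
  multilevel tail refinement is not implemented.
- Nulls shared across same-size sets make p-values of equal-size sets on
  the same ranking dependent (their ordering equals the ES ordering);
  this is immaterial for ranking but worth knowing when interpreting
  many p-values from a single call.
- Inputs must share a genome build and ancestry; no liftover, no LD
  computation, no remote data access.
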