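# uromet

Concordance analysis of **primary and metastatic upper tract urothelial
carcinoma (UTUC)** across three molecular layers: whole-exome somatic
variants and copy number, bulk transcriptomes, and single-cell imaging
mass cytometry (IMC). The package asks one question at three scales: *how
much of a patient's tumor biology is conserved between the primary tumor
and its metastases?* — and answers it with consensus variant filtering,
mutation-sharing statistics, copy-number segmentation, molecular subtype
and immune-contexture classification, and single-cell phenotyping.

Because matched primary/metastatic cohorts are controlled-access, every
input layer can be generated synthetically with known ground truth
(`uromet.synthetic_data`), so the full pipeline is testable end to end on
any machine.

## What it computes

- **Consensus somatic variants** (`variant_consensus`). An SNV is retained
  when called by ≥2 of {MuTect2, Strelka, VarScan, SomaticSniper}; an indel
  when called by both Strelka and VarScan. Retained calls must satisfy
  depth ≥30 in tumor and normal, tumor VAF ≥10% with >5 alt reads, and
  normal VAF ≤1% (or at most one alt read), then survive a
  dbSNP-unless-COSMIC filter and a platform artifact blocklist.
  TMB = mutations / covered bases × 10⁶; MSI score = % unstable
  microsatellite sites, MSI-high iff score > 3.5.
- **Copy number** (`cna_calling`). Capture-region read counts (dropped when
  <100 reads in *both* samples) are normalized per sample; the log₂
  tumor/normal ratio track is segmented with circular binary segmentation
  (recursive circular change-point search; splits accepted at a
  within-segment permutation p < α). Segments with log₂ > 1 are amplified,
  < −0.5 deleted; calls are projected onto gene intervals by overlap, and
  group frequencies compared with Fisher's exact test.
- **Concordance** (`concordance`). For each matched pair, the shared /
  primary-private / metastasis-private percentages of the union of PASS
  nonsynonymous mutations; cohort means stratified by prior chemotherapy;
  overlap of OncoKB-style oncogenic alterations.
- **Expression** (`expression_class`). Consensus molecular subtype (LumP,
  LumNS, LumU, Stroma-rich, Ba/Sq, NE-like) by nearest centroid on Pearson
  r over log₂(FPKM+1), unclassified below minCor = 0.15; T-cell
  inflamed/depleted by PAM (k = 2) on a log-transformed, median-centered
  immune gene signature; ssGSEA with z-standardized scores and rank-based
  group comparison with Benjamini–Hochberg correction.
- **Single cells** (`singlecell_phenotype`). Solidity-1 cells excluded;
  log(1+x), per-image z-scores capped at ±3, global standardization;
  ComBat-style empirical-Bayes batch correction; PCA + batch-balanced kNN +
  Leiden (resolution 0.5); marker-rule metaclusters; per-cell
  log₂(KRT5/GATA3) plasticity ratio; immune-infiltration statistics.
- **Statistics** (`stats_core`). Self-contained two-sided Fisher exact
  (probability-mass rule), Mann–Whitney U and Wilcoxon signed-rank (exact
  at small n, tie/continuity-corrected normal approximation otherwise),
  Benjamini–Hochberg q-values — all validated against brute-force
  enumeration oracles in the test suite.

## Worked example

Simulate a matched primary/metastatic pair with planted truth, then run
consensus filtering on the primary tumor's four caller VCFs:

```sh
$ uromet simulate --layer variants --seed 3 --out-dir sim
wrote variants layer to sim
$ uromet variants \
    --caller-vcf mutect2=sim/primary.mutect2.vcf \
    --caller-vcf strelka=sim/primary.strelka.vcf \
    --caller-vcf varscan=sim/primary.varscan.vcf \
    --caller-vcf somaticsniper=sim/primary.somaticsniper.vcf \
    --blocklist sim/blocklist.tsv \
    --coverage-bases 30000000 --tmb-threshold 10 \
    --out primary.consensus.tsv
PASS variants: 70; TMB 2.33/Mb (low)
```

The simulated pair plants 70 clean variants in the primary tumor (20
shared with the metastasis, 50 private) plus artifact decoys; all 70 —
and only those 70 — survive the filters, giving a TMB of
70/30 Mb × 10⁶ = 2.33 mutations per megabase, below the chosen TMB-high
threshold. The single-cell stage runs the same way:

```sh
$ uromet simulate --layer cells --seed 4 --out-dir simc
$ uromet cells --cells simc/cells.csv --panel simc/panel.yaml \
    --n-pcs 10 --seed 0 --out-prefix pheno
3929 cells in 8 clusters / 8 metaclusters
```

of the 4,000 simulated cells, 71 solidity-1 segmentation artifacts are
excluded, and the eight planted populations are recovered as eight
clusters whose marker profiles map onto eight named metaclusters.
`pheno.plasticity.tsv` holds each sample's KRT5/GATA3 log-ratio summary
(median ≈ 0 here, since the simulated tumor mixes basal and luminal
populations evenly).

The library API mirrors the CLI; see the module docstrings and
`docs/methods.md` for the underlying models and their assumptions.

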