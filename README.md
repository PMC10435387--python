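# phylopop

A population-phylogeography pipeline toolkit for range-wide resequencing
studies of clonal marine plants (and similar systems). It re-implements, as
tested and reusable components:

- **`phylopop.simulate`** — an internal Hudson-style coalescent engine
  (independent non-recombining loci, infinite-sites mutation, population
  splits and single-generation admixture pulses) producing diploid genotype
  tables with clean INFO/FORMAT metrics, plus generators that inject
  clonemate copies, selfed offspring, filter-failing records (exact
  truth-tagged counts per filter), chloroplast pileups with artifact
  positions, and pangenome presence/absence alignment summaries.
- **`phylopop.qc`** — the post-calling SNP filter cascade: indel-proximity
  masking (|Δ| ≤ 20 bp), hard filters (MQ < 40, FS > 60, QD < 10,
  |rank sums| > 2.5, SOR > 3, DP > 2 × mean; strict inequalities, missing
  INFO passes), genotype masking (GQ < 30, DP < 10, conflicting allele
  depths), biallelic selection, BED intersection, annotation subsetting,
  3-kb greedy thinning and the per-sample missing-rate filter.
- **`phylopop.clonality`** — clonemate groups and selfed parent–descendant
  pairs from shared heterozygosity (Jaccard of heterozygous site sets),
  with a priority-ordered exclusion ledger (selfing > clone > missing).
- **`phylopop.pav`** — gene presence calling from alignment summaries
  (single-hit >60/60 rule, or >85/85 aggregated over ≤ 3 scaffolds),
  sample QC (> 17,500 genes) and deterministic 1-D k-means cloud/shell/core
  classification.
- **`phylopop.popstats`** — per-SNP nucleotide diversity, individual
  heterozygosity, multi-locus Weir–Cockerham F_ST (ratio of sums, bootstrap
  p across loci), the four-taxon ABBA–BABA D with delete-one block
  jackknife (Student-t p with g−1 df), and the max-significance trio
  heatmap summarisation.
- **`phylopop.cpdna`** — organelle variant calling from pileups
  (variant-read fraction > 0.5 and coverage > 0.3 × median), artifact mask
  application, haplotype collapsing, parsimony-informative site selection
  and a deterministic median-joining network (ε ∈ {0, 1}).
- **`phylopop.clock`** — molecular-clock arithmetic (k/(2μL),
  generation→year conversion, N_e-trajectory minima, lognormal calibration
  priors) and a net-divergence (d_a) split-time estimator used for
  simulation-based parameter recovery.
- **`phylopop.pipeline` / CLI** — YAML-configured end-to-end orchestration
  with a deterministic seed hierarchy.

## CLI

```bash
phylopop run-all --demo --seed 1 --out demo_run   # synthetic end-to-end demo
phylopop qc --vcf in.vcf --bed core.bed --out-prefix qc
phylopop clones --vcf qc.vcf --threshold 0.9
phylopop pav --hits hits.tsv --min-genes 17500
phylopop stats --vcf qc.vcf --pops pops.tsv --outgroup OUT
phylopop cpdna --pileups pileup_dir/ --masks masks.bed --epsilon 0
phylopop date --k 30 --mu 2e-9 --sites 19000
phylopop validate --config run.yaml
```

The demo run simulates a 190-sample dataset (17 clonemate duplicates, 10
selfed offspring, 10 high-missing samples) and reproduces the 153-sample
retained ledger.

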