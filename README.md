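# broadscan

Some enhancers drive gene expression in a single cellular context; others
are active across hundreds. `broadscan` is an analysis pipeline for asking
how much of that *breadth of activity* is readable from enhancer sequence
alone: are dinucleotide repeat motifs (DRMs) general drivers of broad
activity, or is the signal carried by wider sequence patterns — in
particular GC-rich ones — and by the binding preferences of broadly
expressed transcription factors?

It is written for computational regulatory genomicists who want each stage
of that question as a tested, reusable component, exercised end to end on
synthetic enhancer catalogs with known planted structure (no downloads
required).

## What the pipeline computes

**Motif detection.** DRMs (CACACA, GAGAGA, GCGCGC, TATATA) are modeled as
probability-one PWMs, scored as log2 odds against a non-uniform i.i.d.
background (42% GC by default). A match cutoff is a P-value α: the score
threshold s\* is the smallest achievable score with

    P(score(W) >= s*) < α,   W a random background word,

computed **exactly** by dynamic programming (never by sampling). This
calibration has real consequences: at α = 1/4096 the perfect TATATA word,
with background probability 0.29⁶ ≈ 5.9e-4, clears no threshold at all,
while at α = 1/1024 all four perfect repeat words pass. Scanning covers
both strands, so the palindromic GC and TA repeats are counted twice per
genomic site.

**Enrichment.** Fold enrichment of a motif between region sets is
FE = mean(count | positives) / mean(count | negatives), reported as
log2(FE) with mean ± SD over four independent negative sets and a
Wilcoxon rank-sum P (exact for small samples). Depletion is displayed as
−1/FE.

**Classification.** Linear SVMs on three feature schemes — per-bp DRM
densities, the full 4096-dimensional 6-mer spectrum (the spectrum kernel
realized as explicit counts), and per-bp densities of a TF motif
collection — separate broadly active enhancers from length-matched
background, GC-matched background, or single-context enhancers, all
recentered to 600 bp. Evaluation is stratified 10-fold cross-validation
with ROC/PR curves averaged on fixed grids. Per-6-mer weights are read off
the primal coefficients and correlated with 6-mer GC fraction.

**TF expression.** TFs carry a tissue specificity score (TSPS; 0 =
uniform, ~5 = single tissue; TSPS ≥ 1 = "specific"). Per-TF mean motif GC
and CpG content are compared between broad and specific groups, and a
squared semipartial correlation asks whether CpG adds information about
expression breadth beyond GC.

**Synthetic catalogs.** One seed generates a background genome, an
enhancer catalog with a specific-heavy breadth distribution (15%
single-context, 5% above 45 contexts), length and GC coupled to breadth,
DRMs planted at class-dependent densities with a verbatim truth table, and
a TF table with a configurable GC–TSPS association.

## Worked example

The numbered scripts under `analysis/` run the study on a default
catalog (4 × 1.5 Mb genome, 3000 enhancers). `python analysis/02_drm_enrichment.py 1`
prints:

```
drm  log2_fe_vs_background  sd_over_4_replicates  p_vs_background  signed_fold_vs_narrow  p_vs_narrow  density_breadth_rho
 CA               0.458558              0.109613     4.233828e-06               1.274286 2.066432e-03             0.024123
 GA               0.479136              0.050898     9.185768e-07               1.210938 2.731538e-02             0.057258
 GC               1.681468              0.194675     7.167245e-35               2.653659 1.168651e-17             0.124176
 TA              -0.972922              0.064691     7.717526e-04              -1.928571 4.879241e-03            -0.031117

GC content vs breadth: Spearman rho = 0.302 (P = 2.4e-64)
```

Reading: the GC repeat is strongly enriched in broadly active enhancers
(log2 FE 1.68 vs background, 2.7× vs single-context enhancers) and its
per-bp density rises with breadth (ρ = 0.124); the TA repeat is depleted
(−1.9× vs narrow); CA and GA are modest. `analysis/03_classifiers.py`
then shows the classifier ordering (6-mer spectrum ROC AUC 0.98 > TF
motifs 0.91 > DRMs 0.86 against background, all pulled toward chance by
GC-matched negatives), `analysis/04_kmer_gc.py` the attenuation of the
weight/GC and enrichment/GC correlations under GC matching, and
`analysis/05_tf_motifs.py` the TF-level contrast:

```
motif GC: broad 50.6% vs specific 40.4% (rank-sum P = 9.8e-69)
motif CpG/bp: broad 0.065 vs specific 0.042 (P = 4.1e-63)
sr2 of CpG beyond GC: TSPS response 0.0050 (P = 0.034), ...
positive control: planted sr2 0.1 recovered as 0.099 +/- 0.019 over 50 seeds
```

## Layout

```
src/broadscan/
  synthetic_data.py     catalog generator (genome, enhancers, TF table)
  regions.py            intervals, 600 bp recentering, class splits,
                        matched negative sets
  motif_scan.py         PWM scoring, exact P-value calibration, scanning
  enrichment.py         fold enrichment, rank-sum tests, breadth correlations
  spectrum_classifier.py  k-mer spectra, linear SVM, CV, weight extraction
  tf_expression.py      motif GC/CpG vs TSPS, semipartial correlation
  experiments.py        the controlled experiments the analyses run
analysis/01..05_*.py    narrative drivers writing tables under results/
tests/                  unit, property, and end-to-end acceptance tests
docs/methods.md         models, parameters, and design choices in detail
```
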