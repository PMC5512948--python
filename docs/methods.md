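# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the design was open.

## PWM scoring and exact P-value calibration

A motif of length L is a matrix of per-position nucleotide probabilities
p(i, b). Scores are log2 odds against an i.i.d. background bg(b):

    score(i, b) = log2( p'(i, b) / bg(b) ),
    p'(i, b)    = (p(i, b) + c · bg(b)) / (1 + c),

with pseudocount c = 0.001 added in proportion to the background (the
convention of the MOODS family of scanners; the regularization form is a
visible `ScanParams` field). The default background is 42% GC
(A = T = 0.29, C = G = 0.21), the human genome-wide value; a uniform
background misprices AT-rich words.

A match cutoff is a P-value α. The threshold is the smallest *achievable*
score s\* with P(score(W) ≥ s\*) < α (strict), where W is a random
background word. The score distribution is computed exactly: for motifs up
to 8 columns, a dynamic program over positions accumulates the distinct
partial score sums as floats in left-to-right order, so the resulting
values coincide bit-for-bit with full 4^L enumeration (the test suite
verifies agreement to 1e-12 on all DRMs and random PWMs). Longer matrices
(TF motifs) use a lattice convolution at 1e-3-bit granularity, far below
any decision-relevant score gap; a length-10 spot check against vectorized
enumeration agrees to ~1e-6 in tail probability.

Calibration consequences on the 42% GC background:

* α = 1/1024 — all four perfect DRM words pass; the thresholds sit just
  below the one-mismatch score band, so a small set of single-mismatch
  words also passes (tail at threshold ≈ 7.8e-4 for CA/GA, 7.3e-4 for GC,
  5.9e-4 for TA).
* α = 1/4096 — the perfect TATATA word (background probability
  0.29⁶ ≈ 5.9e-4 ≥ α) clears no threshold: scanning returns zero TA hits.
  CA, GA, GC still pass. This asymmetry is why 1/1024 is the default.

Scanning evaluates every window on both strands (reverse-strand scores via
the reverse-complemented matrix). GC and TA repeats are their own reverse
complements, so one genomic site yields one hit per strand — counted
twice by design, with a `dedupe_palindromes` flag to collapse. Windows
containing ambiguous bases are disqualified. Scores accumulate in
strand-dependent order, so the match comparison allows a 1e-9-bit slack
against the threshold; without it a word exactly at threshold can flip on
a rounding ulp between strands.

Threshold calibrations are memoized per (motif, background, c, α) since a
motif is typically scanned over thousands of regions, and per-region
counting is vectorized over a padded region matrix (verified equal to the
hit-listing scanner).

## Negative-set construction

* Length-matched: uniform placement among feasible positions (rejection
  sampling; chromosomes weighted by available starts), excluding the
  positive set, the full catalog, and any further exclusion intervals,
  with outputs mutually disjoint. Overlap with an exclusion by ≥ 1 bp
  disqualifies. By default placement is not constrained to the source
  chromosome (`same_chrom` pins it).
* GC-matched: per input region, a same-chromosome, same-length window
  with |ΔGC| ≤ 0.02. Candidate starts are enumerated exactly from
  per-window GC prefix sums and sampled uniformly, so the sampler is
  uniform over feasible candidates rather than try-limited. Regions with
  no candidate are per-region failures; the run aborts when more than 1%
  fail (both the tolerance and the failure budget are `NegativeSetSpec`
  fields).

The ±0.02 default keeps the residual GC difference below the composition
noise of a single 600 bp window (SD ≈ 0.02 at 42% GC). One desk-scale
caveat: the synthetic background genome is i.i.d., with none of the
isochore-scale GC heterogeneity of a real genome, so the highest-GC broad
enhancers (4–5 SD above background) can be genuinely unmatchable at
±0.02. The catalog-scale analysis scripts therefore run the matcher at
±0.03 with a 5% failure budget; the classifier experiments at milder GC
shifts use the defaults.

## Enhancer classes and length control

Breadth classes follow quantile semantics: the broad cutoff b\* is the
smallest breadth with |{breadth > b\*}| ≤ 0.05·n ("active in more than b\*
contexts"), and the narrow class is a uniform random sample of breadth-1
enhancers sized to the broad set. The sample is drawn from a canonically
sorted candidate list, so the split is invariant to input order given the
seed. All classified regions are recentered to 600 bp (center preserved;
an odd remainder extends rightward) because length correlates with
breadth and would otherwise leak into any feature scheme.

## Enrichment statistics

FE = mean(pos) / mean(neg) on per-region counts; log2(FE) is the working
scale, with the signed −1/FE form presentation-only. Against genomic
background, four independent negative replicates give mean ± SD of
log2(FE) (the SE is also emitted, since either spread convention appears
in practice). Significance is the two-sided Wilcoxon rank-sum test: exact
enumeration of the rank-sum null over all assignments of pooled mid-ranks
when the smaller sample has ≤ 8 observations (valid under ties), else the
tie- and continuity-corrected normal approximation. Zero negative means
produce explicit NaN/inf sentinels excluded from summaries; an optional
FE pseudocount exists for small runs. No multiple-testing layer is
applied — per-motif P-values are reported raw.

The all-6-mer analysis computes per-k-mer log2(FE) from forward-strand
sliding-window counts (matching the classifier features) and flags k-mers
beyond 1 or 2 SD of the finite enrichment distribution.

## Classifiers

The spectrum kernel for k = 6 is realized as explicit 4096 count features
with a linear model — mathematically the same decision function, and
weight extraction becomes a direct read of primal coefficients. Counts are
used raw (regions are fixed at 600 bp, so counts ≈ densities); DRM and TF
features are per-bp densities. Spectra use the forward strand of each
region; a `collapse_revcomp` option merges reverse-complement pairs.

Training is hinge-loss linear SVM (liblinear dual) with C = 1.0 default
and the intercept inside the regularizer; the tests verify the solution
against an independent SLSQP quadratic program of the same objective.
Evaluation is stratified 10-fold CV; ROC curves are vertically averaged on
a fixed 101-point FPR grid (PR curves on a recall grid) with min/max
bands, and the summary AUC is the mean of per-fold AUCs (within 0.01 of
the averaged-curve AUC on all fixtures). TF-motif features are scanned at
α = 1e-4, the customary default of general-purpose motif scanners.

Classifier comparisons use a two-sided paired t-test across per-fold ROC
AUCs. This is a labeled stand-in — the appropriate test for correlated CV
folds is genuinely unsettled — and requires identical fold structure;
identical inputs return P = 1 by convention.

## TF motif composition and the semipartial analysis

Motif GC and CpG content are probability-weighted expectations,

    gc  = (1/L) Σᵢ [pᵢ(C) + pᵢ(G)],
    cpg = (1/(L−1)) Σᵢ pᵢ(C) · pᵢ₊₁(G),

equal to the expected composition of a realization of the motif model
(enumeration-verified); consensus-string counting is available as a mode,
since either convention is defensible. Per-TF values average over that
TF's motifs; a TF complex inherits the maximum TSPS of its components
(a complex cannot be expressed more broadly than its most specific
member). TSPS = 1 classifies as specific. Group comparisons are rank-sum
tests.

Whether CpG informs expression breadth beyond GC is measured by the
squared semipartial correlation sr² = R²(y ~ GC + CpG) − R²(y ~ GC), with
the incremental F-test F = sr²(n−3)/(1−R²_full) on (1, n−3) df, for both
the continuous-TSPS and broad/specific-dummy responses. Fits go through
least squares, so an exactly collinear CpG (a linear function of GC)
yields sr² = 0 rather than an error; NaN is reserved for constant inputs.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed and
the analyses run against them.

* **Genome**: i.i.d. bases at 42% GC. Not emulated: isochores, CpG
  islands, repeats, assembly gaps, chromosome-scale heterogeneity.
* **Breadth distribution**: anchored at 15% single-context mass and 5%
  above 45 contexts (of a 60-context ceiling). A single geometric law
  cannot meet both anchors — with P(1) = 0.15 a geometric body leaves
  ~7e-4 above 45 — so the body over 1..45 is geometric carrying 95% and
  the tail spreads 5% uniformly over 46..60. The true breadth law between
  the anchors is unknown; the decay shape is a modeling choice and fully
  overridable.
* **Length**: 280 + 5.5·breadth + N(0, 40) bp, truncated at 60 bp —
  single-context enhancers average ~285 bp (the transcribed-catalog mean
  is ~297) and the broadest reach ~600 bp, giving the positive
  length–breadth correlation that motivates the 600 bp control.
* **GC coupling**: each enhancer's bases are resampled at
  0.42 + 0.0012·breadth *before* motif planting, so compositional and
  motif effects stay separable by construction; the catalog-level
  GC–breadth Spearman ρ lands near 0.3.
* **Planting**: motifs overwrite background bases in place (no indels) at
  class-dependent per-bp Poisson densities, with ≥ 2 bp guard gaps so
  repeat instances cannot chain into longer repeats carrying extra
  matching windows; positions are recorded verbatim in a truth table and
  are fully recoverable by rescanning. Defaults keep DRMs rare (median 0
  per 600 bp region) with GC planted 4× denser in broad than narrow
  classes and TA depleted in broad — the directional pattern the
  enrichment stage should detect.
* **TF table**: 563 TFs, 313 broad (TSPS ~ U(0,1)) and 250 specific
  (TSPS ~ U(1,5)); motif target GC is Normal(0.455 ± association/2, 0.07)
  with association 0.11, i.e. group means 0.51 vs 0.40 — the contrast
  magnitude reported for real TF collections, used here as a generator
  parameter. Dirichlet-concentrated columns (concentration 10) make
  motifs realistically fuzzy. CpG content is whatever composition
  implies, so CpG carries no information beyond GC in the generator —
  the semipartial analysis should and does come out null, and a separate
  generator plants a known sr² for positive control.

Because all structure is planted, passing tests demonstrate correct
recovery of known signal under idealized composition — not performance on
real enhancers, where motif grammar, chromatin context, and assay noise
all intrude.

## Experiment scales and seeds

One integer seed drives everything; generator stages draw from fixed
substreams so each stage is independently reproducible, and reruns are
bit-identical. Desk scales chosen for the experiments: catalogs of
3000–4000 enhancers on 6–8 Mb genomes; enrichment recovery at 200+200
regions × 20 replicate seeds per density ratio; classifier ordering at
1000 regions per class (600 bp); weight/GC null over 10 seeds at 400 per
class; semipartial recovery at n = 500 × 50 seeds. Statistical
calibration checks (null rank-sum rates, null AUC) run at 20–60 replicate
seeds with binomial slack on the expected rate.

## Known limitations

* The DRM classifier on fully planted catalogs is stronger than on real
  data, where repeat occurrences are rarer relative to catalog size; the
  orderings (spectrum > TF motifs > DRMs; GC matching attenuates) are the
  meaningful desk-scale observables, not absolute AUCs.
* The exact rank-sum path enumerates C(n₁+n₂, n₁) assignments and is
  capped at min(n) ≤ 8; beyond that the corrected normal approximation is
  used without a permutation fallback.
* The lattice score distribution is not exact; its 1e-3-bit granularity
  is validated against enumeration only up to length 10.
* `compare_classifiers` pairs folds by index; it is not valid across CV
  runs with different seeds or fold counts.
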