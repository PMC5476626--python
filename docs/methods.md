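# Methods

## Scope and design

The package implements a two-population selection scan (windowed Z(Fst) and
Tajima's D with empirical-tail overlap), a bulk RNA-seq differential-
expression arm, their intersection into candidate genes, and the phenotype
formulas used alongside them (fibre morphometry, 2^−ΔΔCt).  Read alignment,
variant calling, genotype QC, enrichment analysis and network figures are
out of scope: the pipeline starts from a multi-sample VCF, a scaffold index,
a gene annotation and a count matrix.

## Windowed statistics

* **Windows.** 0-based half-open, starting at 0 with a fixed step; only full
  windows are emitted, so a scaffold of length L yields
  ⌊(L−W)/s⌋+1 windows (0 when L < W).  Defaults W = 40 kb, s = 20 kb.
  Scaffolds are used only when strictly longer than 60 kb, matching the
  strict reading of the length filter.
* **Diversity.** Per-site unbiased pairwise diversity 2c(n−c)/(n(n−1)),
  summed over in-window sites; sites with fewer than 4 called alleles in
  either population are excluded from all statistics (the minimum for the
  pairwise terms; configurable).
* **Tajima's D.** The 1989 constants assume one sample size per window, but
  missing genotypes make n vary by site.  Rule: use the window's modal
  n_called and drop deviating sites from that window's S and π.  D is
  flagged undefined (NaN) when S = 0 — a zero-SNP window carries no
  frequency-spectrum evidence — and such windows never satisfy the D
  criterion by default (a flag can invert this).
* **Fst.** Default estimator is Weir & Cockerham (1984) variance components
  (a, b, c from allele frequencies, sample sizes and observed heterozygote
  frequencies), combined per window as Σa/Σ(a+b+c) (ratio of averages).  The
  alternative is the sample-corrected Hudson estimator,
  num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) over
  den = p₁(1−p₂)+p₂(1−p₁).  The correction makes the estimator unbiased
  under the Balding–Nichols model (the null-calibration tests rely on this);
  its exact value on two *identical* polymorphic count tables is −1/(n−1),
  i.e. zero differentiation up to the within-sample term, which the
  closed-form tests assert.  Windows with an empty denominator are flagged
  undefined.

## Scan calling

Z(Fst) standardises window Fst by the genome-wide mean and sample standard
deviation (n−1) over all retained scaffolds pooled — the scan treats the
genome as one empirical distribution.  Tail thresholds are nearest-rank
percentiles (no interpolation dialect to disagree about), computed after
removing undefined windows.  A window is called when Z(Fst) ≥ the upper 5%
threshold and Tajima's D ≤ the lower 5% threshold.  Which population's D is
consulted is configurable (`pop1`, `pop2`, `pooled`, or the default
`either`, where each breed's D is compared against its own distribution);
the study design does not pin this down, and `either` is the most sensitive
symmetric choice.  Called windows that overlap or abut merge into regions;
genes overlap a region with ≥ 1 bp.  Both window counts and merged-region
counts are reported, since the two are easily conflated.

## Differential expression

DE is a reimplementation of the classic NB count-model test, not a wrapper:

* median-of-ratios size factors over genes with nonzero counts in every
  sample, normalised to unit geometric mean (relative factors are what the
  test consumes; the convention only fixes the overall scale);
* method-of-moments dispersion on normalized counts with variance pooled
  within the two groups, floored at 1e−8, then averaged 50/50 with a
  log-linear mean–dispersion trend fitted across genes (genes at the floor
  are excluded from the fit).  With two replicates per group the per-gene
  estimate alone is far too noisy; the trend supplies the stabilising
  information;
* Wald test on the log fold change with the delta-method standard error
  under Var = μ + αμ², two-sided normal p-values, BH adjustment per
  contrast (the four contrasts are separate questions);
* the reported fold change adds a pseudocount of 0.5 to both normalized
  group means so zero-count groups stay finite; the DEG rule is
  padj < 0.05 and FC > 2 or < 0.5, both strict.

Because this test is not numerically identical to any specific historical
implementation, its validation is by operating characteristics on simulated
data (recall, false-discovery proportion, null rate), not by matching a
published DEG count.

## Synthetic data

The genotype generator draws, per site, an ancestral frequency
p ~ U(0.05, 0.95) (bounded away from 0/1 so sites are rarely monomorphic in
both populations) and per-population frequencies from the Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F), whose expected Fst is F — the simplest
standard divergence model with a tunable expectation.  Sweep windows use an
elevated F and push the target population's frequency to the nearer of 0/1
with probability `sweep_fix_prob`, jointly raising Fst and depressing π and
Tajima's D.  Genotypes are binomial per diploid; sites monomorphic in the
combined sample are dropped, as a variant caller would.  Defaults emulate
the study design at desk scale: 9 diploids per breed, baseline F = 0.05,
ten 4.02-Mb scaffolds (2,000 windows), ten planted 40-kb sweeps at F = 0.4
with fixation push 0.8.

The expression generator draws per-gene baseline means log10-uniform over
[0.5, 3] (≈ 3–1000 counts, spanning the RPKM-detectable range of a bulk
muscle library), assigns each planted DE gene one contrast (round-robin)
and a random sign, multiplies the first group of that contrast by
2^(±log2FC), and draws NB counts at the configured dispersion.  Because a
shifted group participates in other contrasts, the truth records, per
contrast, every gene whose group means actually differ.  Defaults: 2,000
genes, four groups × 2 replicates, 10% DE at |log2FC| = 2, dispersion 0.05.

What the generators do **not** emulate: linkage and recombination (sites are
independent), demography and drift history, genotyping error and depth-
dependent missingness, GC/length biases in counts, and library-preparation
batch effects.  Passing tests therefore demonstrate correctness of the
statistics and calling logic under a clean generative model, not robustness
to every artefact of real sequencing data.

## Numerical choices and degenerate inputs

* Nearest-rank percentiles; sample (n−1) standard deviations.
* Z-scoring refuses degenerate input (all window Fst equal, or < 2 defined
  windows).
* Tajima's D raises for modal n < 4; per-site statistics skip n < 2.
* Multi-allelic records and indels are dropped at VCF read (counts logged),
  not decomposed.
* Missing alleles reduce n_called; they are never imputed.
* Technical qPCR replicates are averaged on the Ct scale before ΔCt.
* Pairwise phenotype comparisons default to Welch's t-test with Bonferroni
  correction across the stated comparisons; the historical
  "Duncan-with-Bonferroni" hybrid is not reproducible as described, so it is
  deliberately not offered.

## Problem sizes

Simulation-based checks use 2,000 windows × 20 seeds for the scan and
2,000 genes × 4 contrasts × 20 seeds for DE; both finish in well under a
minute on one CPU, and the acceptance script uses 5 seeds per block.  These
sizes give binomial standard errors of ≈ 1–3 percentage points on the
reported rates, which is the package's chosen precision/runtime trade-off.

## Known limitations

* The scan is window-based only: no haplotype statistics (iHS, XP-EHH), no
  composite-likelihood sweep model, and no significance calibration against
  a coalescent null — thresholds are empirical tails, so some flagged
  windows are expected under the null by construction.
* The NB test's normal Wald p-values are approximate at two replicates per
  group; the BH-adjusted operating characteristics (not per-gene p-value
  calibration) are the supported guarantee.
* With very sparse windows the modal-n rule can discard a large share of
  sites; the per-window site counts in the output table make this visible.
* The candidate classification is a fixed function of the contrast pattern;
  genes with patterns spanning both between-breed ages receive both labels
  rather than a special "complex" class.
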