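# Methods

## Model and estimands

The package fits the stratified LD score regression model. Effect sizes on
the standardized-genotype scale are mean-zero with annotation-additive
variances, `Var(beta_j) = sum_c a_cj tau_c`; marginal GWAS chi-square
statistics then satisfy `E[chi2_j] = N sum_c l(j,c) tau_c + 1`, where the
partitioned LD score `l(j,c) = sum_k a_ck r2_jk` sums squared genotypic
correlations with annotation-c SNPs near j. The regression of observed
chi2 on `{N l(j,c)}_c` estimates the `tau_c` jointly; all derived
quantities (%h2, enrichment, tau*, expected enrichment) are deterministic
functions of the tau vector and of annotation cross-products over the
heritability SNPs, so each is recomputed per leave-one-block-out tau for
jackknife standard errors.

Per annotation c, over heritability SNPs (MAF >= 0.05 in the reference
panel, M of them):

* observed h2(c) = `sum_j a_jc (sum_c' a_jc' tau_c')`; %h2(c) = h2(c)/h2_g
  with h2_g = total over all heritability SNPs. Disjoint annotations'
  %h2 values are exactly additive.
* enrichment = %h2(c) / %SNPs(c), with %SNPs(c) = `sum_j a_jc / M` (the
  SNP fraction for binary annotations, its natural generalization
  otherwise). Estimates below 0 or above 1 are reported as-is, never
  truncated.
* tau*_c = `tau_c sd(c) / (h2_g / M)` with sd(c) the annotation SD over
  heritability SNPs. Its significance uses a standard-normal reference for
  tau*/se(tau*); the enrichment p-value tests enrichment = 1 with a
  jackknife-t (n_blocks - 1 degrees of freedom).
* expected %h2 / enrichment of a focal annotation: per-SNP variances from a
  conditioning model fitted *without* the focal annotation (equivalently,
  setting its tau to zero), summed over focal SNPs. A focal name already in
  the conditioning model is rejected; a value-duplicate under a fresh name
  legitimately reproduces that annotation's model-implied enrichment.

## Regression details

* **Weights** (the literature leaves them unstated; switchable to
  unweighted): product of an LD overcounting term `1/max(1, l_w(j))`, with
  `l_w` the LD score restricted to regression SNPs, and a
  heteroskedasticity term `1/(2 (N l_tot(j) taubar + 1)^2)`. `taubar`
  starts from the moment estimate `(mean chi2 - 1)/(N mean l_tot)` and is
  refreshed once from the fitted h2 (one re-weighting iteration).
  Weighting choices do not move the estimates on noiseless data (the fit is
  exact there for any weights); they matter only for efficiency.
* **Intercept**: free by default, recovering the "+1" as a fitted value;
  constrainable to 1. Simulation studies constrain it: the generator has no
  confounding or stratification, so 1 is the true value, and at 2,000
  regression SNPs a free intercept is weakly identified and mostly adds
  variance.
* **Jackknife**: contiguous blocks with equal regression-SNP counts, 200 by
  default (an equal-bp split is a one-line change). Validity requires each
  block to span the local correlation length; at the synthetic scale
  (2,000 SNPs in 40 independent LD blocks) the studies therefore use 40
  jackknife blocks — one per LD block — rather than 200 blocks of 10
  correlated SNPs. SE calibration is checked over 50 replicates (empirical
  SD of enrichment estimates against the mean jackknife SE; the two agree
  to a few percent at the study conditions).
* **Filters**: regression SNPs drop chi2 > max(80, 0.001 N) and the MHC
  region (chr6:25-34 Mb, configurable); heritability SNPs are reference
  SNPs with MAF >= 0.05. Annotations spanning < 0.4% of common SNPs are
  refused an observed-enrichment estimate (expected enrichment only)
  unless forced.
* **Degenerate cases**: rank-deficient designs are rejected naming the
  collinear pair; a leave-one-out design that loses an annotation entirely
  (possible only below the size gate) falls back to a minimal-norm
  solution; zero jackknife SE yields p = 1 at the null value and p = 0
  away from it.

## LD scores

`l(j,c)` sums the small-sample-adjusted squared correlation
`r2_adj = r2 - (1 - r2)/(n_ref - 2)` over reference SNPs within a physical
window (default 1 Mb, standing in for 1 cM when no genetic map exists) of
each scored SNP. Without the adjustment, every pair inflates the score by
~1/n_ref and null calibration fails at reference panels of a few hundred
samples; with it, the all-SNPs score of an LD-free panel averages 1.
Scores are computed at regression SNPs but sum over all polymorphic
reference SNPs in the window; a sensitivity mode drops (e.g.,
non-uniquely-mappable) SNPs from the panel first. The whole path is
float64; agreement with a naive O(M^2) double loop is ~3e-14 on a 500-SNP
panel.

## Annotation construction

Coordinates: intervals are BED-style 0-based half-open, SNP positions
1-based; a SNP at position p is inside [start, end) iff start < p <= end.
Flanks are `[start - w, start) u [end, end + w)` minus all element bodies,
clipped at the chromosome start; the default width is 500 bp with a
{100, 200, 500, 1000} sensitivity grid. Element age uses the milliDiv
divergence score (mutations per kilobase against the element consensus —
older elements have diverged more); SNPs inherit their element's score
(ties to the older element by default; younger/mean by flag) and quintile
boundaries are the 20/40/60/80 percentiles of the per-SNP distribution
(per-element by flag; the choice of distribution is genuinely open and
per-SNP matches how the annotations enter the regression). K-mer motif
annotations mark every genomic window within Hamming distance 0-1 of the
query on either strand; ambiguity codes never match. Random controls
resample the template's interval-length multiset uniformly over the
covered chromosomes until the control's SNP fraction is within 10%
relative of the template's (<= 100 tries, keeping the closest attempt);
they match length only — not GC or gap content.

## The synthetic cohort generator

Haplotypes follow a copying Markov chain within independent LD blocks: the
first allele of a block is Bernoulli(MAF), each later allele copies its
left neighbour with probability `ld_decay` and is redrawn otherwise. This
keeps marginal frequencies exact and gives dosage correlation
`ld_decay^|j-k|` within a block and 0 across blocks — closed-form LD
control in the spirit of a haplotype-copying model. MAF is drawn once per
block (copying between different marginals would distort them). Phenotypes
are `Y = X beta + e` on standardized genotypes with
`e ~ N(0, 1 - h2_g)`; summary statistics are per-SNP marginal-regression
Wald chi-squares. Architectures: annotation-driven
(`beta_j ~ N(0, sum_c a_cj tau_c)`) or flat polygenic (n_c causal SNPs
with variance h2_g/n_c each, summing to h2_g exactly).

What the generator does *not* emulate: minor-allele-frequency-dependent
architectures, genetic maps and recombination-rate variation, population
structure and relatedness, imputation error, and cross-block long-range
LD. Passing studies therefore demonstrate the *statistical* correctness of
the estimator chain under its own model, not robustness to those
real-data complications.

### Study conditions

The simulation studies run at 2,000 SNPs (40 LD blocks, within-block
correlation 0.9 per step, MAF uniform on [0.05, 0.5]), GWAS N = 20,000
(the middle of the {2,000, 20,000, 40,000} preset grid), h2_g = 0.5, with
LD scores from an n_ref = 1,000 cohort subsample. Recovery uses a
10%-of-SNPs annotation whose SNPs carry 5x the background per-SNP
variance; null calibration uses size-matched random controls under a flat
architecture, with a template of 100 short (2 kb) elements covering 10% of
the chromosome — numerous short elements, like real TE families. (A
template of a few large clumps would concentrate the annotation inside
single LD blocks, leave the jackknife too few effective units, and
measurably degrade SE calibration.) Problem
sizes were chosen so a full 20-replicate study completes in a few minutes
on one CPU while leaving every estimand identified.

## Meta-analysis and contrasts

Cross-trait pooling is DerSimonian–Laird random effects (the standard
moment estimator; the specific routine behind published analyses is not
documented, so DL is assumed and stated). The between-trait variance
estimate is truncated at zero, where the pooling reduces exactly to
inverse-variance fixed effects. Duplicate traits keep the largest-N
dataset. Class contrasts compare two disjoint classes' pooled means with
an unpaired two-sided z-test (a design choice; the underlying per-trait
estimates are independent across traits, so unpaired is the natural
model). Multiple testing uses Bonferroni against the full *designed*
family — e.g., 281 Alu-consensus 9-mers x 27 one-mismatch neighbours
= 7,587 hypotheses — not just the tests actually run.

## Known limitations

* No genetic-map support: the LD-score window is physical bp only.
* No MAF-bin expected-enrichment denominator and no liability-scale
  (case/control) phenotypes.
* The annotation matrix is dense in memory; genome-scale runs should
  process per chromosome (the file formats already split naturally).
* Real-data mode consumes PLINK/BED/RepeatMasker/sumstats files but has no
  liftover, consensus-sequence construction, or fine-mapping integration.
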