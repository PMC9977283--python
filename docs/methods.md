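# Methods

This note documents the statistical procedures implemented in `dosagescreen`,
the synthetic-data model they are validated against, and the numerical and
design choices made where more than one convention was defensible.

## The screen

The screen looks for genes whose expression tracks the dosage of a regulator
protein. Its motivating use case is a methyl-CpG-binding regulator (MeCP2)
whose acute knockdown and recovery — for example by an antisense
oligonucleotide (ASO) in an overexpressing mouse — produces a protein
trajectory against which gene fold-changes can be correlated.

**Dynamic correlation.** For each gene with log2 fold-change series
x(t1),...,x(tn) (perturbed vs control) and the protein trajectory
y(t1),...,y(tn) on the identical time axis, we compute Spearman's rho: both
series are converted to ranks (average ranks for ties, the tie-corrected
definition, not the 6*sum(d^2) shortcut) and Pearson's correlation is taken
on the ranks. At least three timepoints are required. A constant series has
no rank ordering; its rho is reported as undefined (NaN) rather than 0,
because silently mapping a degenerate input to "no correlation" hides data
problems. Genes with |rho| strictly greater than the threshold (default
0.75) are selected; the strict inequality follows the ">" convention and is
configurable.

**Constraint filter.** Selected genes are intersected with a
loss-of-function-intolerance table (pLI in [0,1]); genes with pLI strictly
greater than 0.9 are kept. Genes missing from the table cannot pass the
filter and are dropped with a logged warning — absence from a constraint
resource is not evidence of tolerance, so the drop is always surfaced.

**Cross-study tally.** Each candidate is looked up in a panel of per-study
differential-expression tables (log2FC and BH-adjusted p per gene, each
study labeled LOF for loss-of-function models or GOF for
gain-of-function models). A study is *significant* for the gene when
padj < 0.1 (strict, per the usual "FDR below 0.1" rule); it is
*concordant* when additionally the fold-change sign matches the model class
under the positive-regulation convention (down in LOF, up in GOF).
Studies lacking the gene or its padj count as untested: missing evidence
changes the denominator, never the numerator. Significance-only counting is
the primary statistic (`n_significant`/`n_tested`); direction concordance is
reported as a clearly separate, supplementary column. Candidates are ranked
by (n_significant desc, n_concordant desc, |rho| desc, gene id), a total
order with no ties.

## Cell-type correlation

Given single-cell counts and an external cell-type annotation, Spearman
correlation between a focal gene pair is computed per annotated class on raw
counts. No normalization is applied: rank correlation is invariant to any
per-gene monotone scaling, and per-cell scaling would require a normalization
model the procedure does not otherwise need. Cells with zero counts are
retained — they carry rank information as ties. Neurons are split into
excitatory and inhibitory classes by a marker rule (Slc17a7/Vglut1 counts
>= 5 per cell denotes excitatory; the threshold is inclusive). The "overall"
value is defined as the pooled correlation across all annotated cells; an
alternative reading — a correlation of per-type summary values — would
measure across-type covariation instead, and is deliberately not what this
package computes.

## Spike-calibrated occupancy quantification

Fragments carry a genome-of-origin label (`primary` or `spike`); spike
fragments come from an exogenous genome added at fixed mass per sample and
serve as a cross-sample calibration anchor. All coordinates are 0-based
half-open (BED convention); any 1-based input dialect must be converted at
the reader.

**Windows.** Called peaks arrive as BED3; each is expanded to a symmetric
window of center +- halfwidth (default 3500 bp, i.e. a 7 kb window), clipped
at position 0. Integrating over a wide window is appropriate for broadly
binding factors whose occupancy is not confined to the narrow peak call.

**Counting.** A fragment counts in a window iff it overlaps by >= 1 bp under
half-open arithmetic; a fragment spanning two windows counts in both
(windows are quantified independently). The implementation sorts fragment
starts and ends per (chromosome, sample) and uses two binary searches per
window; the test suite checks it against an explicit all-pairs overlap scan.

**Calibration.** A sample's calibrated signal is raw counts x C /
spike_count with C = 10000 by default. C is arbitrary — it cancels in any
between-sample comparison — and exists only to put browser tracks on a
convenient scale. The multiplication is evaluated as `(counts * C) /
spike_count` in one rounding step so that duplicating a sample's primary and
spike fragments k-fold leaves its calibrated signal bit-for-bit unchanged.

**Differential occupancy.** Between two genotype groups (>= 2 samples
each), counts are normalized by spike-derived size factors
(spike_s / geometric mean of spikes, DESeq-style, so factors multiply to 1).
Per window:

* log2FC = log2((mean_perturbed + c0) / (mean_ref + c0)) with pseudo-count
  c0 = 0.5, keeping the estimate finite for empty windows;
* the NB dispersion alpha (variance = mu + alpha mu^2) is estimated per
  window by method of moments from the pooled within-group variance, floored
  at 0 (Poisson when underdispersed), then **moderated** toward the
  across-window median with 10 pseudo-observations of prior weight
  (empirical-Bayes shrinkage in the limma/DESeq2 tradition);
* the Wald statistic is the log-ratio over its delta-method standard error
  from the NB variance function, referred to a t distribution with
  prior + residual degrees of freedom (10 + n1 + n2 - 2).

The moderation is the one place this module departs from a strictly
per-window dispersion. With three samples per group a per-window variance
estimate carries ~4 degrees of freedom; a test honest about that uncertainty
(t with 4 df) gives up roughly a fifth of its power against a 2-fold change,
while a test that ignores it (normal reference) roughly doubles its nominal
type-I error. Sharing dispersion information across windows resolves the
dilemma exactly as the field's standard engines do, and the simulation suite
verifies the resulting operating characteristics directly (null type-I
error, p-value uniformity, and power against a planted 2-fold change at the
design point of mean 100, dispersion 0.05, 3 vs 3). With very few windows
the prior collapses toward the per-window estimate of those same windows and
the calibration guarantee weakens; single-region p-values should be read
accordingly. Raw per-window p-values are reported; any panel-wide multiple
testing adjustment is the caller's decision.

## Closed-form estimators

**Optical fractionator.** N = [sum(Q) * (t/h) * (1/asf) * (1/ssf)] * 2,
with Q the per-section counts, t section thickness (um), h dissector height,
asf and ssf the area and section sampling fractions, and the final factor 2
converting the single sectioned hemisphere to a bilateral total. The
estimator is linear in sum(Q) and in 1/ssf and is design-unbiased under
uniform systematic sampling, which the simulation suite verifies. Density
is reported against a Cavalieri-style reference volume V = (sum of sampled
section areas x t) / ssf converted to mm^3 — the denominator construction is
this package's own convention and is labeled as such, since reporting
density requires a reference volume that the counting protocol itself does
not define.

**ddCt.** Per sample, technical-replicate Ct values are averaged; dCt =
Ct_target - Ct_reference (reference gene, e.g. Ppia); ddCt = dCt minus the
arithmetic mean dCt of the control group; relative expression = 2^(-ddCt).
Centering on the arithmetic mean of control dCt (the Livak formulation)
forces the geometric mean of control-group expression to exactly 1, which
the tests exploit as an invariant. Adding any constant to every Ct value
cancels. Not-detected wells propagate as explicit flags: a sample whose
target is undetected is reported as not-detected (never as zero expression);
a sample whose reference is undetected is excluded with a warning. Primer
efficiency correction is out of scope (the 2^-ddCt form assumes perfect
doubling).

## Synthetic data: what it emulates, what it does not

All validation runs on generator output with planted truth; every generator
is deterministic given its seed and never emits non-finite values.

* **Time course.** The protein trajectory is piecewise linear: a drop from 0
  to a nadir (default -2.5 log2 units, i.e. ~82% knockdown) over the first
  quarter of the time span, a plateau through ~55% of the span, then linear
  recovery to 0 — the sustained-suppression-then-washout shape of a bolus
  knockdown. Eight biweekly timepoints (2-16 weeks) are the default; the
  number and spacing are parameters, not constants. Tracking genes follow
  gene(t) = slope x protein(t) + N(0, noise_sd) with |slope| uniform in
  [0.5, 1.5] and random sign; non-tracking genes are i.i.d. N(0, 0.1 by
  default). Real fold-change series have correlated errors across timepoints
  and amplitude that varies with expression level; the generator does not
  model either, so recovery rates here are an upper bound on real-data
  performance.
* **Constraint table.** pLI is bimodal in real resources; the generator
  draws ~15% of background genes from Beta(9, 1) (constrained mode) and the
  rest from Beta(1, 9), and planted dosage-sensitive genes from U(0.92, 1) —
  by hypothesis the screen's targets are loss-intolerant.
* **Study panel.** Differential expression is simulated at the summary level
  (log2FC estimate + known SE -> Wald p -> BH within study), not at the
  count level: the screen consumes DE tables, and count-level modeling is
  exercised in the occupancy module instead. The default universe is 50
  genes — a candidate shortlist, which is what such panels carry — with one
  planted robust gene at |log2FC| = 1, SE 0.2, signed by model class
  (14 LOF + 6 GOF studies by default).
* **Cells.** Focal-pair counts are negative-binomial marginals (mean 4,
  dispersion 0.3 — moderately expressed genes in brain single-nucleus data)
  coupled by a Gaussian copula with latent correlation r = 2 sin(pi rho_S/6),
  the exact inverse of the Spearman/Pearson relation for bivariate normals.
  NB discretization attenuates the realized rank correlation slightly
  (about 0.006 at the default marginals and rho 0.7); the closed-form
  calibration is used as is and the residual error is accepted. Sparser
  marginals (mean ~1) would attenuate substantially more. The marker gene is
  >= 5 counts with probability 0.6 among neurons (threshold plus Poisson
  overshoot) and capped below 5 elsewhere.
* **Fragments.** Window and background fragment counts are Poisson at a
  background rate of 0.5 fragments/kb scaled by the planted per-window,
  per-genotype fold; spike fragments are Poisson(5000) per sample; lengths
  are uniform in [120, 180] bp (a plausible sub-nucleosomal range — the
  value is irrelevant to >= 1 bp overlap counting). Truth windows must not
  overlap so the planted fold is unambiguous. GC structure, duplicate reads,
  and blacklist artifacts are not modeled.
* **Sections.** Half of the planted bilateral total is distributed uniformly
  (multinomially) across the sectioned hemisphere's sections; every
  1/ssf-th section is sampled from a uniformly random start; within-section
  counting is Binomial thinning with probability (h/t) x asf. Real tissue
  has rostro-caudal density gradients; uniformity makes the unbiasedness
  check a pure test of the estimator algebra.
* **Ct table.** Reference Ct ~20 with biological scatter 0.15 cycles,
  planted group fold-changes enter as -log2(fold) on the target dCt,
  technical duplicates add 0.1-cycle noise.

## Pipeline

A YAML config names stages, thresholds, seed, and output directory; unknown
keys and out-of-range thresholds are rejected before anything runs (exit
code 2 at the CLI, vs 1 for runtime failures). The single global seed is
fanned out to per-stage child seeds via `SeedSequence([seed, stage_index])`,
so each stage's randomness is reproducible independent of which other stages
run. The simulate stage writes all inputs in the same formats the analysis
stages read; floats are written at 17 significant digits and parsed with
round-trip precision, making identical-seed reruns byte-identical — the
property the determinism tests assert. On error, files written during the
failed run are removed.

## Problem sizes used in validation

The simulation suite uses 20 generator seeds for screen recovery, 50 for the
study-panel and fractionator checks, 2000 windows for the null calibration
of the occupancy test and 500 for its power check, and 2000-6500 cells for
correlation recovery. These sizes put Monte-Carlo error comfortably inside
the asserted tolerances while keeping the suite quick to run.

## Known limitations

* The screen correlates over the shared treated-vs-control fold-change axis
  only; it does not use control-arm trajectories as extra observations.
* The occupancy test targets the single-region / small-panel use case; it
  reports raw p-values and leaves FDR across a genome-scale window set to
  the caller, and its small-sample calibration rests on the dispersion
  prior (see above).
* ddCt assumes perfect amplification efficiency; the fractionator assumes
  the dissector height and guard zones were handled upstream in Q.
* Generator realism bounds what passing tests demonstrate: they validate the
  estimators' algebra and operating characteristics under the stated models,
  not robustness to batch effects, correlated noise, or annotation error in
  real data.
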