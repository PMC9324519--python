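# Methods

## Pathway activation level

The score for pathway *p* is

PAL(p) = Σₙ ARR(n,p) · log_b CNR(n) / Σₙ |ARR(n,p)|,

summing over pathway members measured in the expression matrix. CNR(n) is
the ratio of gene *n*'s mean expression in the case samples to its mean in
the control samples; membership of a gene outside the pathway contributes
nothing, and neutral members (ARR = 0) cancel from numerator and denominator
both. The denominator normalizes by the total absolute role weight so that
PAL is a weighted *mean* log-ratio, comparable across pathways of different
sizes; without it the score would scale with pathway size and pathway-to-
pathway comparisons (counts of up/down-regulated pathways, heatmaps) would
be dominated by large pathways.

Conventions and degenerate cases:

* **Log base.** Base 10 by default, configurable. Changing the base rescales
  every PAL by a constant, so all order-based and sign-based conclusions are
  base-invariant; log10 units mean "PAL = 1 ⇔ an average member moved
  ten-fold in the activating direction".
* **Norm definition.** `control_arith_mean` (default) takes the arithmetic
  mean of the control samples gene-wise — the literal "average value in the
  control group". `control_geom_mean` is offered because intensities are
  roughly log-normal and the geometric mean is the natural center on the log
  scale; for per-sample PAS, `cohort_mean` uses the per-gene arithmetic mean
  over all samples as the norm profile.
* **Unmeasured genes** are removed from both sums rather than imputed to
  CNR = 1. Imputation would shrink every score toward 0 by an amount
  depending on platform coverage, not on biology.
* **Flooring.** Means are floored at ε = 1e−8 before division so CNR is
  always positive and finite; floored genes are recorded on the CNR vector.
  ε only matters for genes with essentially zero signal, where any ratio is
  unreliable anyway — such genes should be filtered upstream when possible.
* **Unscorable pathways.** A pathway with no measured member is reported
  "unmeasured"; one whose measured members are all neutral is "unscorable"
  (denominator 0). Batch scoring skips and lists both instead of aborting.

Exact properties the tests assert: antisymmetry under case/control swap
(log(1/x) = −log x), invariance under global intensity rescaling (ratios
cancel), neutrality of ARR = 0 members, and agreement with a naive per-gene
loop to 1e−10.

## Expression preprocessing

Replicate probe signals are combined by geometric mean per replicate group —
the right average for multiplicative intensity noise — with zeros floored at
ε = 1e−8 first (the geometric mean is undefined at 0; flooring events are
counted and logged). Replicate groups with no gene assignment are dropped;
groups mapping to one gene are collapsed by arithmetic mean *after*
aggregation and normalization-ready output is produced on the linear scale.

Quantile normalization maps every sample column onto the common reference
distribution formed by row-wise means of the column-sorted matrix. Tied
values within a column receive the arithmetic mean of the reference values
at the tied positions (the standard convention). Two consequences worth
knowing: on tie-free data the transform is exactly idempotent and all
output columns share a bit-identical sorted value multiset; with ties, tie-
averaging replaces two distinct reference values by their mean, so those
identities hold only up to the tie correction. The tests assert the exact
identities on tie-free data and the tie convention separately.

## Cohort distributions and the high-expressor flag

Single-gene, pan-cancer analyses work on the log2(x+1) scale with 64
equal-width bins spanning the pooled 0.5th–99.5th percentile range
(both configurable and recorded); out-of-range values are clipped into the
terminal bins and counted. Cohort histograms are clustered with Ward
linkage on Euclidean distances between frequency vectors — the Ward.D2
variant, in which merge heights are square-rooted cluster-update distances;
`scipy.cluster.hierarchy.linkage(method="ward")` on the raw frequency
vectors is exactly this procedure. Cohorts are sorted by label before
linkage so results do not depend on input order.

A cohort is flagged a "high expressor" of the gene when strictly more than
5% of its samples exceed the arithmetic-mean expression of a designated
reference cohort (in the motivating application, mean KIT expression in
AML), with the threshold computed on the same analysis scale as the cohort
values. The boundary is strict: a fraction of exactly 0.05 is not flagged.

## Correlation screens and two-stage FDR

Signature scores are the mean of squared expression over a signature's
measured genes — literally mean-of-squares, not root-mean-square; an `rms`
mode is provided since the phrase is ambiguous in the literature, but the
default follows the literal reading. Pearson r with the two-sided p-value
from the t transform (n−2 df) is computed on pairwise-complete pairs, with
a minimum of 3; constant vectors are excluded from screens with a count of
undefined correlations rather than failing the run.

Multiplicity is handled by the Benjamini–Krieger–Yekutieli two-stage
adaptive step-up: stage 1 runs the BH step-up at α′ = α/(1+α) and uses its
rejection count r₁ to estimate the number of true nulls m₀ = m − r₁; stage 2
reruns BH at α′·m/m₀ (all hypotheses rejected if r₁ = m). The
implementation delegates to `statsmodels` (`fdr_tsbky`); the test suite
checks its rejection sets against an independent brute-force transcription
of the two-stage definition on an exhaustive battery of small p-vectors and
random vectors, and checks null calibration (any-false-rejection rate ≈ α
under 2000-feature complete nulls).

Two correction-family conventions are used, matching the two screens'
published forms: the signature screen corrects within each cohort across
features and calls significance at q < α **and** |r| > 0.2 (effect floor);
the PAS-vs-driver screen corrects across pathways within the single cohort
and applies no effect floor by default. The family and floor are explicit
parameters.

## Dependency and drug-sensitivity analysis

Dependency panels (one per screen channel, RNAi/DEMETER2-like and
CRISPR/Chronos-like) keep the convention "more negative = stronger
dependency"; no sign flip is applied anywhere. Per-tumor-type summaries
keep only types with strictly more than `min_lines` (default 5) cell lines.
For each drug–target pair, Pearson r between drug AUC and target dependency
is computed per channel over the shared cell lines (≥ 3 required, else that
channel is recorded missing) and the cell value is the mean over available
channels — a pair present in one channel yields that channel's r. Targets
are ranked by the mean of their available cells; drugs are clustered with
Ward.D2, for which (and only for which) missing cells are column-mean
imputed, with the imputation count reported.

## Synthetic data: what it emulates, what it does not

The generators produce log-normal expression (positive, roughly normal on a
log scale, like microarray intensities) with effects planted on the log
scale, so every recovery target is closed-form:

* **Cohort generator** — per cohort, the driver gene follows a two-component
  log-normal mixture (fraction π from a component shifted by a set number of
  base SDs); other genes are i.i.d. log-normal. Emulates the pan-cancer
  situation where some cancer types carry a high-expressor subpopulation.
* **Pathway generator** — control samples at a log-normal baseline; case
  samples shift the chosen pathway's activators by +δ and repressors by −δ
  (log10), plus N(0, σ) log noise per gene and sample. With σ = 0 the
  planted pathway's PAL is exactly δ and all others are exactly 0. Defaults
  δ = 1, σ = 0.2, 3 cases vs 3 controls — a typical small two-arm microarray
  design with a strong perturbation.
* **Signature generator** — a standard-normal latent z drives the driver
  gene (nearly linearly); each signature shares a latent u = ρz + √(1−ρ²)ε
  and its gene values are constructed so the mean-square score is linear in
  u up to per-gene noise, putting the population score-vs-driver correlation
  at ≈ ρ (slightly attenuated by the driver's mild log-normality; observed r
  for ρ = 0.9 at n = 500 lands within ±0.1).
* **Pharm generator** — per true-target gene, a latent per-line dependency
  t ~ N(−0.5, 0.4) shared by both channels (the planted ground truth);
  decoy genes are independent N(−0.1, 0.3) per channel; AUC = slope·t + ε
  with SD(ε) = noise_ratio·|slope|·SD(t). Default 60 lines,
  noise_ratio = 0.5 — a clearly detectable but noisy pharmacogenomic signal.

All generators draw from `numpy.random.default_rng(seed)` in a fixed order:
identical arguments and seed give bit-identical output.

What the synthetic data deliberately does **not** model: gene–gene
covariance beyond the planted structure, batch and platform effects across
cohorts, probe-level physics, missing-at-random dropout patterns, and the
heavy-tailed outliers of real tumor panels. Passing tests therefore
demonstrate that the *statistical machinery* is correct and calibrated
under its stated model, not that any particular biological finding
reproduces on real data; real-data counts of significant pathways or
regulated fractions depend on the cohort and the pathway collection used.

## Problem sizes

The shipped tests and the acceptance script use desk-scale problem sizes
chosen to make every planted effect decisively detectable while keeping the
whole suite fast: 100 random instances for oracle checks, 2000-feature
nulls × 200 replicates for FDR calibration, 200 null features + 1 planted
(n = 100 samples, 50 seeds) for screen operating characteristics, 10+10
cohorts × 150 samples × 100 seeds for clustering recovery, and 60 cell
lines × 100 seeds for target deconvolution. These sizes are in the regime
of the motivating applications (tens of samples per cohort arm, tens of
cell lines per tumor type) and the recovery rates are already saturated at
them; larger sizes change nothing but runtime.
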