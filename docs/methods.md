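# Methods

This note documents the statistical procedures the package implements, the
modelling choices behind the synthetic-cohort generator, and the numerical
conventions that matter for reproducing published-style results.

## Setting

The target design is a two-annual-visit observational cohort of older
adults in three diagnostic groups — cognitively normal (CN), amnestic mild
cognitive impairment (aMCI) and Alzheimer's disease (AD) — assessed at both
visits with two informant-based instruments (AQ, 0–27; FAQ, 0–30; higher =
worse) and one objective cognitive screen (MMSE, 0–30; lower = worse),
plus three ordinal global staging scales (FAST and GDS, categories 1–7;
CDR global score in {0, 0.5, 1, 2, 3}). All analyses operate on the change
score `year2 − year1`; with this sign convention positive change means
worsening on every measure except the MMSE, where worsening is negative.
Change scores are complete-case per instrument: a subject missing either
visit is dropped for that instrument only.

The package was calibrated and validated against the published group-level
summaries of a 202-subject cohort (101 CN / 62 aMCI / 39 AD); those
summaries ship in `cogchange.reference` and double as the generator's
default parameters.

## Sensitivity to change

For each (group, instrument) cell the chain is

* mean change with a two-sided **t interval** (`mean ± t_{0.975, n−1}·sd/√n`;
  the t, not z, quantile is required to reproduce published intervals);
* pooled SD over the two visits, `√((sd₁² + sd₂²)/2)` — the correlated-design
  denominator;
* uncorrected effect size `ES = |mean change| / pooled SD` (reported as an
  absolute value);
* test–retest reliability `r` = Spearman correlation of the two visits,
  computed within the analysis group;
* corrected effect size `d = ES / √(2(1 − r))`, banded as
  trivial < 0.20 ≤ small < 0.50 ≤ moderate < 0.80 ≤ large (each boundary
  assigned to the higher band, which matches how published values of 0.43,
  0.52 and 0.84 are labelled).

Full precision is carried through the whole chain and rounding happens only
at display. This is a contract, not a nicety: chaining the display-rounded
ES of 0.27 with r = 0.65 gives d = 0.32, while the unrounded chain gives
the published 0.33.

Two caveats about the published table the defaults are calibrated to:

* The FAQ rows are internally inconsistent (e.g. the aMCI FAQ pooled SD of
  3.29 does not reproduce the printed ES of 0.30, and the same 3.29 appears
  for two different groups) — almost certainly a typesetting error in the
  source. FAQ rows therefore carry `es_consistent=False` and are excluded
  from exact cross-checks.
* The CN AQ interval upper bound computes to 1.0089 from the printed
  mean/SD/n, versus a printed 1.00 — the published value came from
  unrounded subject-level data. Tests assert it to within one unit in the
  last printed digit.

## Trial sample size

The projection assumes a two-arm placebo-controlled trial whose endpoint is
the cumulative change score over the trial. The treatment effect is a
fraction (default 25%) of the expected cumulative change,
`Δ = 0.25 · years · |annual mean change|`, with trial lengths of 2 years
(AD), 3 years (aMCI) and 5 years (CN) — faster-progressing groups get
shorter trials. The endpoint SD is the SD of the *annual* change score,
taken as constant over the horizon (an assumption inherited from the
design being reconstructed; it ignores the √t growth a random-walk model
would imply). With δ = Δ/SD, the per-arm n is the corrected normal
approximation for the two-sample t test,

    n = ceil( 2 (z_{0.975} + z_{0.80})² / δ²  +  z_{0.975}² / 4 ),

always rounded up. This exact rule was reconstructed by matching published
per-arm numbers: it reproduces 8 of the 9 published cells exactly (251,
224, 597 for aMCI AQ/FAQ/MMSE; 232, 119, 157 for AD; 340, 300 for CN
AQ/FAQ). The ninth (CN MMSE, printed 660) is not reproducible under this —
or any convention we tested — from its printed inputs (0.05 points/year
against SD 1.71 implies ≈ 11,750 per arm) and is excluded from
cross-checks. `exact_power` provides the noncentral-t power
(df = 2n−2, noncentrality δ√(n/2)) as an independent oracle; the
approximation tracks the exact minimal n within ±1 subject over
δ ∈ [0.1, 1.0].

## Reliable change

RCI parameters are estimated from the CN reference group:
`SEm = SD_ref·√(1−r)` with SD_ref the CN **Year-1** SD (the standard
Jacobson–Truax reference; the source does not specify which SD it used),
r the CN Spearman test–retest reliability, `SEdiff = √2·SEm`, and
`RCI = (change − practice)/SEdiff`. The practice effect is the CN mean
retest change, applied only in the practice-corrected variant used for the
MMSE (performance-based tests improve on re-exposure); the informant
instruments use the classic variant (practice ≡ 0). The default
variant-to-instrument mapping is overridable. A subject with |RCI| ≥ 1.645
(boundary included) lies outside the two-sided 90% band and counts as
clinically significantly changed.

On exactly bivariate-normal CN data the classic RCI flags ≈10% of stable
subjects by construction. Estimating r by Spearman rather than Pearson
biases the flag rate slightly low (Spearman of a bivariate normal is
(6/π)·asin(ρ/2) < ρ), worth roughly half a percentage point at the
reliabilities involved — visible in the calibration checks, which land
near 9.2–9.8% at n = 10,000.

## Global-stage progression

Each staging scale is dichotomized per subject: 1 if the Year-2 category is
more severe than Year-1 (any one-category move; improvement counts as 0).
Each of the 3 instruments × 3 scales cells gets a univariate
maximum-likelihood logistic fit of the indicator on the change score
(statsmodels), reported as the odds ratio per 1-point change with a Wald
95% CI and two-sided Wald p — Wald rather than profile-likelihood
inference, matching the OR-with-CI reporting style. Complete separation is
detected up front (univariate check: all cases strictly to one side of all
controls) and reported as an error rather than a divergent estimate;
quasi-separation is caught by an SE-magnitude guard. Fits run per group
and for the pooled sample. Multiplicity within each block uses a fixed
per-comparison threshold of 0.006 by default (≈ 0.05 spread over nine
tests, which is how the published analysis behaves); true Benjamini–
Hochberg step-up is available as an alternative mode.

## Synthetic cohort generator

The generator's job is to produce cohorts with the first- and
second-moment structure the analyses assume, with known ground truth.

**Scores.** Per group and instrument, (Year-1, Year-2) pairs are latent
bivariate normal with means (μ₁, μ₂), SDs (σ₁, σ₂) and correlation ρ,
then rounded to integers and clipped to the instrument range. The default
calibration takes each published row and sets μ₂ − μ₁ = published mean
change, σ₁ = σ₂ = published pooled SD, and ρ from the change-variance
identity `sd_change² = σ₁² + σ₂² − 2ρσ₁σ₂` (e.g. aMCI AQ:
ρ = 1 − 4.96²/(2·6.10²) = 0.669, consistent with the published Spearman
0.65). Where that identity yields ρ < 0 — only the internally inconsistent
aMCI FAQ row — the SDs are instead back-solved from the change SD and the
published reliability (σ = sd_change/√(2(1−r)), ρ = r), since a negative
test–retest correlation is not a credible generating mechanism.

**Discretization.** Rounding and clipping would bias observed means, so
latent means are pre-calibrated: the exact mean of the
rounded-and-clipped normal is computed on the integer grid and inverted
(Brent) so that the *observed* means — and hence the mean change — hit
their targets. Second moments are not re-calibrated; discretization
perturbs change SDs by up to ≈4% and Spearman reliabilities by ≲0.035 at
the default parameters, bounded in tests. A `latent=True` mode skips
discretization for checks whose theory assumes exact normality (RCI null
calibration, moment-convergence tests).

**Baseline levels.** Only change scores enter the analyses, so Year-1 means
are free parameters. They are ordered by clinical severity
(AQ 8/12/15, FAQ 6/12/15, MMSE 26/24.5/19 for CN/aMCI/AD) and placed away
from the scale boundaries so discretization preserves the configured
moments. Deliberately **not** emulated: the floor/ceiling effects and
skewness of real instrument distributions (real CN AQ scores pile up near
0). Passing tests therefore demonstrate correctness of the estimators
under the generating model, not robustness to real-data non-normality —
the analyses are non-parametric where that matters (Spearman, Kruskal–
Wallis) precisely because real data fail normality.

**Demographics.** Ages and education are normal (published group means/SDs,
e.g. CN age 81.76 ± 7.23), rounded to whole years and clipped to
plausible ranges; gender is Bernoulli with the published male fraction.
The three groups are generated demographically homogeneous, as the
matched design intends.

**Staging.** Each subject draws a baseline category per scale from a
group-specific distribution (CN in the normal/earliest stages, aMCI at
the MCI stages, AD across the dementia stages). Top categories are left
unoccupied at baseline so every subject has a next-worse category and the
worsening model is exactly specified. Year-2 worsening is a one-category
move drawn independently per scale with probability
`logistic(α + Σ βᵢ·changeᵢ)`; the default couples AQ change only, with
β = ln(1.20) (the published pooled CDR-GS association) and a 20% per-year
base rate (α = logit(0.2), a typical annual progression rate for a mixed
cohort of this composition). FAQ/MMSE coupling is available through the
config but off by default.

**Seeding.** One master seed feeds a `SeedSequence` tree with per-group,
per-component substreams: cohorts are bit-reproducible and adding an
instrument does not perturb the other streams.

## Matching

Case–control matching (aMCI/AD → CN) is greedy and without replacement:
cases in sorted subject-id order, candidate controls filtered to the same
gender and to |Δage| ≤ 2 and |Δeducation| ≤ 2 years, the nearest by
|Δage| chosen, ties broken by |Δeducation| then control id. The greedy
order and tie-breaks are this package's own determinism choices — the
procedure being emulated specified only the tolerances — so a different
valid matching could be produced by other implementations. Unmatchable
cases are reported, never silently dropped.

## Problem sizes used in checks

Moment-convergence and RCI-calibration checks use 10,000 subjects per
group (Monte-Carlo SEs small enough to resolve the documented biases);
odds-ratio recovery uses 500 replicates at the study's own n = 202;
matching invariants are exercised over 300 random cohorts; the Spearman
brute-force cross-check uses 1,000 random tied vectors; the power oracle
scans δ ∈ [0.1, 1.0]. These sizes are the package's validation design and
are fixed in the test suite.

## Known limitations

* Exactly two visits; no trajectories, attrition or missing-data modelling
  beyond complete-case per instrument.
* Item-level instrument content is out of scope (total scores only).
* The generator's latent-normal scores understate real-data skew and
  floor effects (see above).
* Percent-outside RCI rates, per-group odds ratios and correlation-table
  magnitudes for the real validation cohort depend on its raw data and are
  checked only as calibration/recovery properties on synthetic data, plus
  sign/ordering anchors.
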