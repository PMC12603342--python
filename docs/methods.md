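# Methods

This note records the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the
procedure left room.

## Stimuli and trial sequences

A session presents `n_once + 2·n_twice` trials (default 100 + 200 = 300)
drawn from a 200-word pool, 100 odor-related and 100 control.  Words are
assigned to the once/twice groups uniformly at random; first
presentations are shuffled uniformly; each repeat is then inserted
uniformly among the slots after its first presentation (configurable
minimum/maximum lag; lag structure is otherwise unconstrained).  Onsets
advance by the 0.5-s display plus a uniform 1.7–2.3 s jitter.
Slow-response delays can be added per trial but default to zero: all
analyses are stimulus-locked, so the delay only stretches inter-trial
baseline time.  Old/new recognition behavior is not modeled.

The packaged word-property table is **synthetic**.  It encodes the target
group means and SDs per property with deterministic constructions chosen
to respect the domain constraints:

- bounded 1–10 ratings: a symmetric two-point set (half the group at
  m − d, half at m + d, d = s·√(99/100)), giving the exact sample mean
  and SD;
- word frequency (non-negative, right-skewed): an asymmetric 90/10
  two-point set, since the symmetric construction would produce negative
  occurrence rates;
- syllable counts (integers ≥ 1): exact integer compositions, e.g.
  28·1 + 42·2 + 22·3 + 8·4 for mean 2.1 and SD 0.90.  The n−1 sample SD
  then deviates from the target by ~0.5%, which moves the matching
  p-values by well under 0.01.

Category flags are fixed: 60% / 40% (odor / control) of words tagged
living and 50% / 10% tagged food, food being a subset of living — odor
words lean living and food-related, which is what the LIVING and FOOD
control analyses are meant to disentangle.

Property matching uses two-sided unpaired t-tests on item values with no
multiplicity correction (a matching check, not inference).  The pooled
(Student) variant is the default, with df = n₁ + n₂ − 2, because the item
counts are equal and the historical toolchains default to it; Welch is a
switch.  Degenerate inputs (both SDs zero) return t = 0, p = 1 for equal
means and p = 0 with a warning otherwise.

## Synthetic recording sessions

Spiking is an inhomogeneous Poisson process with piecewise-constant
rates.  This is the weakest model on which a t-test/z-score pipeline can
be calibrated: counts in disjoint windows are independent Poisson,
trial-to-trial variability is irreducible, and no distributional claim
stronger than the original analysis needs is smuggled in.  Refractory
periods, bursting, waveform shape and sorting noise are deliberately not
modeled; passing tests therefore say nothing about sorting quality or
non-Poisson count dispersion in real data.

Per-unit generative parameters (`SimUnitSpec`):

- `baseline_rate_hz` — drawn log-normal, median 4 Hz, log-SD 0.5, so most
  units clear the 2 Hz inclusion filter while a realistic minority does
  not; only the ≥ 2 Hz criterion is documented for the reference data, so
  the distribution is a package choice.
- `response_window_s` — one of the four 500-ms post windows, drawn with
  probabilities (0.2, 0.5, 0.2, 0.1): response latencies concentrate on
  500–1000 ms, the most frequent observed interval.
- `response_gain` — multiplies the rate inside the window on every trial;
  default 2.0 for increasing and 0.5 for decreasing units, with 10/33 of
  responsive units decreasing (the observed split).
- `odor_gain` — additionally multiplies the in-window rate on odor-word
  trials only; default 2.0 / 0.5 with 4/11 decreasing.

Effect magnitudes are free simulation parameters, not estimates: the
reference data report only which units were flagged, not their gains.
Default unit counts per region are 57/54/22/29/33 (195 total) and default
responsive / odor-associated fractions per region equal the observed
prevalences (e.g. 11/57 and 7/57 in the amygdala).  Flag assignment uses
`round(fraction × n)` per region so the default session encodes the
observed counts exactly; responsive and odor-associated sets are drawn
independently and may overlap.  A consequence worth noting: an
odor-associated unit raises its mean in-window rate across all trials, so
it also tends to screen as stimulus-responsive — the generator makes no
attempt to produce "purely" odor-modulated units.

`poisson_window_counts` and `null_ensemble_rate_series` are exact
count-level shortcuts (Poisson counts drawn directly per window or per
time bin, and per-condition trial sums drawn as a single Poisson) used by
the repeated-simulation calibration studies; they are distributionally
identical to sampling and binning spike times for piecewise-constant
rates.

## Rates and z-scores

Windows are half-open `[start, end)` relative to stimulus onset; the
boundary convention is undocumented in the reference description, so a
spike exactly at +0.5 s counts toward the second post window.  Only
first-presentation trials enter the analysis.

Rates divide counts by the true window duration: the 200-ms baseline uses
a factor of 5, not the factor of 2 that converts 500-ms counts.  The
reference text describes a uniform ×2 conversion; applied to the baseline
window it would understate baseline rates 2.5-fold and change who passes
the 2 Hz filter, so the duration-correct reading is the default and the
literal uniform-×2 behavior is available as
`apply_rate_filter(..., uniform_half_second_conversion=True)`.

The inclusion filter keeps a unit if its across-trial mean rate reaches
2 Hz in at least one of the five windows, pooling all first-presentation
trials (not per condition).  z-scores use the per-unit baseline mean and
sample SD (n−1 denominator; unspecified in the reference) across all
first-presentation trials; units with zero baseline SD cannot be
z-scored and are excluded from z-based analyses with a logged reason.
For every retained unit the baseline z-scores have mean 0 and SD 1 to
1e-10 by construction, and the paired post-vs-baseline contrast is
invariant to this per-unit affine transform, so screening decisions on
raw and z-scored rates coincide exactly.

## Screening and multiplicity

Each unit's family is four tests (one per post window).  Both screening
contrasts are two-sided; sidedness is stated only for the odor contrast
in the reference description, and adopting it uniformly matches the fact
that both increases and decreases are reported.  Unpaired tests default
to pooled variance (Welch switchable).  Zero-variance windows get p = 1
(never flagged) rather than NaN.

Bonferroni flags at p < α/4 = 0.0125; Benjamini–Hochberg applies the
step-up rule within the same four-test family (an across-unit family mode
exists but is off by default — the four-interval family is what the
correction is defined over).  BH rejections are a superset of Bonferroni
rejections at the same level, which the tests assert as a property.

`direction` is the sign of the mean contrast in the most significant
window; if several windows are significant with conflicting signs, the
smallest-p window wins and a note is logged.

## Prevalence tests

Per region, p = P(X ≥ k) for X ~ Binomial(n, 0.05), computed by exact
tail summation (scipy's regularized-beta survival function; verified
against a rational-arithmetic product-ratio recursion to 1e-12 for all
n ≤ 200).  The upper-tail convention reproduces the published per-region
values at printed precision in nine of ten table entries.  The tenth (1
odor-associated unit of 33 piriform units, printed p = 0.50) matches the
*lower* tail P(X ≤ 1) ≈ 0.504 rather than the upper tail ≈ 0.82; the
package treats this as an inconsistency in the published table and keeps
the uniform upper-tail convention.  Display rounding mirrors the
published style (2 decimals above 0.2, 3 between 0.01 and 0.2, 4 below);
raw p-values are kept in machine output.

## Split-plot mixed ANOVA

Observations are unit-level cell means: each unit contributes a complete
2 × T matrix (CATEGORY level × TIME window, averaged across its
first-presentation trials), consistent with units as the random factor
and with the published df (e.g. F₄,₁₉₀ for CATEGORY × REGION with 195
units in five regions).  The univariate decomposition works on orthonormal
contrast scores of the 2T cell space:

- between stratum — REGION tested against units-within-region,
  df = (a − 1, N − a);
- each within stratum — the within effect and its ×REGION interaction
  tested against the effect × units-within-region error,
  df = (q, q(N − a)) and (q(a − 1), q(N − a)).

Unbalanced regions are handled Type III style: within main effects test
the **unweighted** mean of region means (verified to match SPSS-style
Type III output from `car::Anova` exactly; the interaction and between
tests agree with `pingouin.mixed_anova` to 1e-10, whose weighted main
effect differs slightly under imbalance).  No sphericity correction is
applied by default — the published df are uncorrected — but
Greenhouse–Geisser epsilon adjustment of the p-value is available.
Sums of squares below 1e-12 of the total data scale are treated as exact
zeros so that degenerate designs (identical cells) return F = 0 rather
than a ratio of rounding noise.  Partial η² = SS_eff / (SS_eff + SS_err),
identical to F·df₁/(F·df₁ + df₂).

Averaging the 100-ms windows reproduces the 500-ms category marginals
exactly, so the CATEGORY and CATEGORY × REGION F values are identical at
both resolutions — asserted as a test.

LSD post-hocs compare unit-level category marginals (time-averaged cell
means) within each region with an uncorrected paired t-test; Cohen's d
uses the paired-difference SD.  The published d values come with no
formula; the paired-difference convention is the package's choice, and
the classic pooled-error LSD (difference variance pooled across regions,
df = N − a) is available as an option.  The FOOD-within-odor-words
control is the same machinery with a single group: a two-within-factor
repeated-measures ANOVA over amygdala units, FOOD df = (1, N − 1).

The ensemble analyses do not attempt to reproduce the published F, p, d
or cluster values — those require the patient recordings.  Their
acceptance is structural (df, algebraic identities, oracle equivalence)
and calibration-based (type-I rates under null simulation).

## Cluster permutation tests

Instantaneous rates: 10-ms bins convolved with a Gaussian kernel (50-ms
SD, truncated at ±4 SD, renormalized), computed on a padded axis so
smoothing mass is conserved within the analysis span; the reference
figures do not state their estimator, so both parameters are exposed.
Per-bin two-sided t statistics (paired or pooled-variance unpaired) are
thresholded at the sample alpha (0.05); maximal contiguous supra-threshold
runs form clusters separately for positive and negative t; the cluster
statistic is the summed t (max-size optional).  The null is the maximum
absolute cluster mass over n_perm permutations — sign flips of the
per-observation difference series when paired (the ensemble test across
units), label shuffles across trials when unpaired (the per-unit test;
odor/control trials are unpaired at trial level, so "paired" applies only
at the ensemble level).  Cluster p = (1 + #{null ≥ |mass|}) / (n_perm + 1),
with resolution 1/(n_perm + 1).  Zero-variance bins get t = 0 and can
never be supra-threshold.  The result carries both the cluster list and
the raw supra-threshold mask, so plots can distinguish cluster-level
significance from mere alpha-threshold exceedance.

## Problem sizes and calibration

The repeated-simulation studies use count-level sampling at these sizes,
chosen to give tight Monte-Carlo error while keeping the default runs
fast: 1,000 null units for the family-wise screening rate (binomial SE
≈ 0.7% at p = 0.05), 500 simulated 195-unit sessions for the ANOVA
interaction type-I rate, 500 null ensemble runs at n_perm = 1,000 for the
cluster false-positive rate, and five full spike-level sessions (fixed
4 Hz baseline, odor gain 2.0) for ground-truth recovery.  Observed rates
sit near the nominal 5% (e.g. 0.035 / 0.050 / 0.042 at seed 1) and
recovery is complete; `analysis/06_calibration.py` and
`scripts/acceptance.py` recompute all of them.

## Known limitations

- Poisson spiking understates count dispersion of real units; calibration
  results transfer to real data only insofar as window counts are
  approximately Poisson at these rates.
- Units are treated as independent and pooled across (virtual)
  participants; no hierarchical patient-level structure is modeled.
- The generator's effect sizes are conventions, so power numbers
  (recovery rates) characterize the pipeline at those gains, not the
  biology.
- Second presentations are generated for paradigm fidelity but never
  analyzed (no old/new memory contrast), and behavioral responses are not
  simulated.
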