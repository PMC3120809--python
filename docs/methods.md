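# Methods

This note documents the statistical content of `ordagree`: the estimators
and their exact conventions, the synthetic-data model, numerical choices,
and the limits of what the test suite demonstrates.

## Data model and sign convention

Ratings are integers `1..K` on an ordered scale; K ≥ 2.  Orientation
(whether 1 is the most or least favourable category) is carried as
metadata on `RatingScale` and never enters a formula.  All derived
quantities use the fixed convention **d = a − b** (rater A minus
rater B).  In the motivating setting rater A is the physician and 1 is
the best category, so d > 0 means the physician rated the encounter
*less* favourably than the patient.  Every downstream sign — the mean
difference, the Wilcoxon Z, the standardized marginal-homogeneity
statistic — inherits this convention; transposing the contingency table
negates them all (a property the suite checks on random tables).

Pair lists, K×K contingency tables and difference distributions are
interconvertible without loss (up to encounter order); the difference
distribution is the anti-diagonal sum of the table.  Category collapsing
is restricted to ordered partitions into *contiguous* blocks: arbitrary
regrouping would scramble the ordering that τ-b, the MH test and the
within-±k summaries rely on.  Rows with a missing rating in either rater
are dropped pairwise per item, with the count logged; no imputation is
attempted.

## The battery

**Percent agreement** is 100·trace/n; **percent within ±k** generalises
it to |d| ≤ k.  On a 5-point satisfaction item the ±1 summary is usually
the clinically meaningful one: a one-category near-miss between "totally
agree" and "agree" rarely reflects a real difference of opinion.

**Cohen's kappa** is (Po_w − Pe_w)/(1 − Pe_w) with agreement weights
w_ii = 1 and, for the weighted variants, w_ij = 1 − |i−j|/(K−1) (linear)
or 1 − (i−j)²/(K−1)² (quadratic); custom weight matrices are accepted.
On a table concentrated in one category Pe_w → 1 and kappa is reported
as undefined (a marker with an explanatory note, not an exception, so a
batch over many items survives a degenerate one).  Reports always name
the scheme, because the schemes legitimately disagree: on the built-in
example the unweighted, linear and quadratic estimates are 0.013, 0.025
and 0.054 — all "no agreement", all defensible, and not interchangeable.

**Kendall's τ-b** is computed from cell-block sums over the table:
each cell's count multiplies the total count in the block below-right
(concordant) and below-left (discordant), giving
τ-b = (C − D)/√((n0 − n1)(n0 − n2)) with n0 = n(n−1)/2 and n1, n2 the
tied pairs on each margin.  The result object exposes C, D, n0, n1, n2
so the arithmetic is auditable.  The p-value uses the asymptotic normal
approximation for C − D with the standard tie-corrected variance; the
test suite verifies both estimate and p against an O(n²) brute-force
enumeration and against an independent library implementation.

**Marginal homogeneity.**  The default statistic is the directional
standardized score statistic with category scores s (default 1..K'):
Z = Σ_{i≠j} c_ij (s_i − s_j) / √(Σ_{i≠j} c_ij (s_i − s_j)²).
Conditionally on the discordant totals c_ij + c_ji each pair splits
Binomial(·, ½) under the null, which makes Z asymptotically standard
normal; on 2×2 tables Z² is exactly the uncorrected McNemar chi-square.
Diagonal cells never enter: the test weighs only disagreement and says
nothing about its size — which is precisely why it can be enormous on
data whose raters are never more than a category apart.  The
Stuart-Maxwell chi-square is available as a labelled, omnidirectional
alternative.  In the full battery the MH test runs on the collapsed
table when a collapse is requested, since pooling near-empty categories
is what makes its normal approximation trustworthy.

**Wilcoxon signed-rank.**  Mid-ranks for tied |d|, tie-corrected
variance, and a signed Z = (T⁺ − μ)/σ so the direction of the shift is
preserved.  Zero differences are discarded by default; Pratt's method
(rank zeros, then drop their contribution, with the zero block removed
from μ and σ² in full) is available.  A continuity correction (0.5
toward the mean) is applied by default: exhaustive comparison against
the exact permutation distribution shows the corrected p is within 0.02
of the exact p for every attainable statistic once n ≥ 9, and for every
statistic with exact p ≤ 0.25 at n = 5..8; in the lumpy centre of the
smallest null distributions no normal approximation does better than
about 0.035.  At the sample sizes of real rating studies the correction
is negligible.  When all differences are zero the statistic is an
undefined marker and the median difference (0) is still reported —
on ceiling-effect data the combination "median difference 0, Z highly
significant" is the central interpretive trap, so both numbers always
travel together.  The effect size r = |Z|/√N takes N explicitly; the
cluster workflow passes the number of clusters, since using the number
of individuals makes r a nearly mechanical function of sample size.

**Bonferroni.**  Raw p-values are adjusted family-by-family across items
(each p multiplied by the number of defined tests in its family, capped
at 1); every reported p carries its adjusted twin.

## Bland-Altman analysis for lattice data

Limits of agreement are d̄ ± 1.96·s with s the sample SD (denominator
n − 1).  The multiplier is fixed at 1.96 — not 2.0 and not a t quantile —
because the limits estimate the 2.5th/97.5th percentiles of the
difference distribution, not a mean.  Two 95% CI conventions for the
limits are implemented and always named in output:

* `bland_altman_1986`: limit ± 1.96·√(3s²/n) (the classic large-sample
  variance of a limit);
* `medcalc_t`: limit ± t₀.₉₇₅,ₙ₋₁ · s·√(1/n + 1.96²/(2(n−1))), the
  t-based convention several commercial packages print.

On the built-in example the two differ only in the third decimal
(−1.124/−1.123 for the lower bound of the lower limit), but the t-based
variant is what reproduces published MedCalc output.  "Within limits"
uses closed-interval comparison; for integer differences a tie with a
limit can only occur when a limit is an exact integer, in which case the
difference counts as inside.

With fewer than two differences, or zero spread, the limits collapse to
the mean and the CIs become undefined markers.

The skewness flag fires when |d̄| < s.  For a difference distribution
concentrated on {−1, 0, +1} with a small bias this is the expected
signature, and it warns that the normal-theory reading of the limits
("95% of differences inside") rests on an assumption the data visibly
violates; the empirical coverage is reported alongside so the claim can
be checked rather than assumed.

Plot data keeps the (average, difference) lattice explicit: one point
per occupied cell with its multiplicity, no jitter.  On the built-in
example 12 cells carry 506 observations and one cell carries 264 of
them — information a jittered scatter destroys.  The "trumpet" narrowing
at the extremes is structural (two raters at category 1 can only differ
by 0) and must not be read as variance depending on the mean.

## Cluster-aware comparison

For cluster-randomised designs (patients nested in physicians) the
package reduces each cluster to its pair of mean ratings and applies the
Wilcoxon comparison at cluster level, with N = number of clusters for
effect sizes.  The overall means average cluster means *unweighted* by
default — one vote per physician, which is the aggregation that matches
reporting means "per physician" — with a size-weighted option that
reproduces the individual-level grand means exactly (an identity the
suite checks).  No mixed-model or GEE adjustment is offered: the target
workflow is aggregation, and modelling the intra-cluster correlation is
out of scope.

## Synthetic-data generator

Per cluster c: u_c ~ N(0, σ_c²).  Per encounter: (z_A, z_B) standard
bivariate normal with correlation ρ; latent_A = z_A + u_c + δ,
latent_B = z_B + u_c; each rater's latent value is cut at their own
strictly increasing thresholds into `1..K`.  A single seeded
`numpy.random.Generator` drives each call; identical seeds give
identical samples.

The latent formulation makes the four data features independently
tunable — skew via thresholds, association via ρ, systematic bias via δ,
clustering via σ_c — which direct multinomial sampling of table cells
cannot do.  `calibrate_thresholds` inverts a target marginal through the
standard-normal quantile function, so the expected category frequencies
equal the target exactly (verified empirically to within 0.5 percentage
points per category at n = 10⁶).

`ceiling_preset()` freezes the canonical study-like configuration:
44 clusters × 12 encounters, K = 5, patient thresholds calibrated to a
(90.5, 7.5, 1.6, 0.2, 0.2)% marginal, physician thresholds to
(57.1, 40.5, 1.2, 1.0, 0.2)% (the observed physician marginal, with the
empty worst category given a token 1/506 mass because a zero-probability
category has no finite threshold), δ = 0.35, σ_c = 0.2, ρ = 0.1.
Threshold calibration accounts for δ and the total latent SD √(1+σ_c²),
so the realised marginals match the targets regardless of the bias and
cluster settings.  On this preset the cluster-level Wilcoxon detects the
positive shift (p < .05) in essentially every replicate, and the kappa
paradox — κ < 0.10 with > 90% of differences within one point — emerges
in ≈ 99% of replicates.

What the generator does *not* emulate: multi-item correlation within an
encounter (items are generated independently; no item-response
structure), heterogeneous cluster sizes, rater-specific cluster effects,
and any form of missingness.  Passing tests on generator data therefore
demonstrate the statistical machinery and the qualitative ceiling-effect
phenomenology, not the full dependence structure of real multi-item
questionnaire data.

## Numerical and reporting conventions

* Percentages are displayed to one decimal and coefficients to two,
  rounded half-up (ties away from zero, matching the major statistical
  packages rather than Python's banker's rounding); machine-readable
  output keeps full precision.  Note that published tables rounded this
  way cannot always be reproduced cell-by-cell — e.g. a cell percentage
  of 264/506 = 52.17% printed as 52.1% — so exact checks in the suite
  target recomputed full-precision values, rounded last.
* Undefined statistics (degenerate tables, all-zero differences, zero
  variance) are always markers with a reason, rendered as "n/a", never
  as 0 or an exception mid-batch.
* Monte-Carlo problem sizes: limit-coverage at n = 10⁵ (tolerance ±0.5
  points), marginal calibration at n = 10⁶ (±0.5 points per category),
  power/paradox rates over 200 preset replicates — sizes at which the
  binomial noise of the checked proportion is well below the asserted
  tolerance.

## Known limitations

* Exactly two raters; multi-rater generalisations (Fleiss-type kappa,
  Kendall's W) are out of scope.
* No exact/network p-values for the marginal homogeneity test; the
  normal approximation assumes the collapsed table has adequate
  discordant counts.
* τ-b p-values use the asymptotic variance; published small-sample
  p-values computed by other software with exact or jackknife methods
  will differ.
* The Bland-Altman machinery deliberately omits regression-based
  (proportional-bias) and log-transformed variants; on a 5-point lattice
  neither is estimable in a meaningful way.
* Items are analysed singly; scale scores (sums across items) are not
  constructed.
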