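# ordagree

**Agreement statistics for paired ordinal (Likert) ratings.**

When two raters — in the motivating application a physician and their
patient — score the same encounters on a short ordered scale, "do they
agree?" can be asked on three different dimensions: do their rating
*distributions* differ, are their ratings *associated*, and how far apart
are they on the *scale of measurement*?  On heavily skewed data (a
satisfaction item where ~90% of one rater's answers sit in the best
category) the standard answers contradict each other: difference tests
are wildly significant, association coefficients are near zero, yet
almost every rating pair is at most one category apart.  `ordagree`
implements the full battery so the contradiction can be seen, quantified
and explained, with first-class support for the Bland-Altman analysis
that resolves it.

## What is implemented

For a K-point scale coded `1..K` and paired ratings (a, b) with the fixed
sign convention **d = a − b**:

* **Containers** — pair lists, K×K contingency tables and difference
  distributions, with lossless conversions, contiguous category
  collapsing, and long-format CSV I/O (`ordagree.core`).
* **Difference tests** — Wilcoxon signed-rank (mid-ranks, tie-corrected
  variance, continuity correction, discard/Pratt zero handling) with the
  effect size r = |Z|/√N; the directional standardized marginal
  homogeneity test

  Z = Σ_{i≠j} c_ij (s_i − s_j) / √( Σ_{i≠j} c_ij (s_i − s_j)² ),

  plus the Stuart–Maxwell chi-square as the omnidirectional alternative
  (`ordagree.stats`).
* **Association / chance-corrected agreement** — Cohen's kappa
  (unweighted, linear 1 − |i−j|/(K−1), quadratic, or custom weights) and
  Kendall's τ-b from cell-block sums with explicit concordant/discordant
  and tie bookkeeping.
* **Raw agreement** — percent agreement and percent within ±k scale
  points.
* **Bland-Altman** — limits of agreement d̄ ± 1.96·s with two CI
  conventions (the classic large-sample formula and the t-based variant
  used by MedCalc), coverage percentages, a skewness flag
  (|d̄| < s), and three multiplicity-aware plots for lattice-valued data.
* **Clustered designs** — per-cluster rater means and the cluster-level
  Wilcoxon comparison for patients nested in physicians.
* **Synthetic data** — a latent bivariate-normal threshold generator with
  independently controllable skew, association, bias and cluster effect,
  including a calibrated ceiling-effect preset.
* **Reports** — the whole battery per item, Bonferroni-adjusted across
  items, rendered as schema-stable JSON or markdown.

## Worked example

The built-in dataset is a published 5×5 table of physician-versus-patient
ratings on one participation item after 506 primary-care consultations
(1 = totally agree … 5 = totally disagree).  Running
`python examples/01_item_battery.py` prints:

```
n = 506 paired ratings
physician marginal: [289, 205, 6, 6, 0]
patient marginal:   [458, 38, 8, 1, 1]

percent agreement        :  55.3 %
percent within +/-1 point:  96.8 %
kappa (unweighted)       :  0.013
kappa (linear weights)   :  0.025
Kendall tau-b            :  0.038  (p = 0.38)
standardized MH (3 cat.) :  10.47  (p < .001)

mean (SD) of differences : 0.34 (0.70), median 0
limits of agreement      : -1.02 / +1.71
within limits            :  96.8 %
```

Every dimension tells a different story.  The margins differ massively
(MH Z = 10.47: physicians systematically choose the less favourable of
the top two categories), association is absent (κ ≈ 0.01, τ-b ≈ 0.04 —
the ceiling effect leaves no variance to correlate), raw agreement looks
mediocre (55.3%), yet the Bland-Altman summary shows the raters are never
far apart: the mean difference is a third of a scale point and 96.8% of
differences are within one point.  The kappa paradox in one screen.

The other examples render the three Bland-Altman views
(`02_bland_altman_views.py`), simulate and analyse a clustered trial arm
end to end (`03_simulate_cluster_analysis.py`), and reproduce the paradox
across 50 simulated replicates (`04_kappa_paradox.py`).

A thin CLI wraps the same library:

```bash
ordagree simulate ratings.csv --seed 3
ordagree analyze ratings.csv --collapse 3:5 --md-out report.md
ordagree plot ratings.csv --prefix figures/ba
```

## Documentation

`docs/methods.md` describes the statistical model behind every estimator,
the conventions that change numbers (weight schemes, CI variants, zero
policies, the sign convention), what the synthetic-data generator does
and does not emulate, and known limitations.
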