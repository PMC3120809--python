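"""Bland-Altman agreement analysis for discrete ordinal data.

The Bland-Altman method summarises agreement between two raters by the
mean and standard deviation of their paired differences: the 95% limits
of agreement, mean +/- 1.96 s, are expected to bracket about 95% of
differences.  Unlike correlation or kappa it quantifies *how far apart*
the raters are on the scale of measurement, which is exactly the question
clinical users of a 5-point satisfaction item care about.

On integer ratings the classic mean-difference scatter plot degenerates:
all points fall on a small lattice of (average, difference) cells whose
multiplicities differ by orders of magnitude, so the visual "trumpet"
shape is an artefact of the scale boundaries, not of the data.  The plot
helpers here therefore keep the multiplicities explicit (sized points, a
3-D bar chart, and a bar chart of the difference distribution) instead of
jittering the lattice away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ContingencyTable, DifferenceDistribution, PairedRatings, \
    build_contingency, difference_distribution
from .stats import percent_within_k

__all__ = [
    "BAResult",
    "BAPlotData",
    "ba_limits",
    "ba_plot_data",
    "skewness_flag",
    "plot_mean_difference",
    "plot_difference_bars",
    "plot_grid_3d",
]

Z_95 = 1.96  # fixed multiplier for the limits themselves


@dataclass(frozen=True)
class BAResult:
    """Limits of agreement with confidence intervals and coverage.

    All quantities are in scale points.  ``ci_lower_limit`` and
    ``ci_upper_limit`` are 95% confidence intervals for the lower and
    upper limit of agreement; they are ``None`` when undefined (n < 2 or
    zero spread).  ``pct_within_loa`` is the percentage of differences
    inside the closed interval [loa_lower, loa_upper]; ``pct_within_1``
    the percentage with |d| <= 1.
    """

    mean_d: float
    sd_d: float
    loa_lower: float
    loa_upper: float
    ci_lower_limit: tuple[float, float] | None
    ci_upper_limit: tuple[float, float] | None
    pct_within_loa: float
    pct_within_1: float
    n: int
    ci_method: str
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "mean_d": self.mean_d,
            "sd_d": self.sd_d,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "ci_lower_limit": list(self.ci_lower_limit) if self.ci_lower_limit else None,
            "ci_upper_limit": list(self.ci_upper_limit) if self.ci_upper_limit else None,
            "pct_within_loa": self.pct_within_loa,
            "pct_within_1": self.pct_within_1,
            "n": self.n,
            "ci_method": self.ci_method,
            "note": self.note,
        }


@dataclass(frozen=True)
class BAPlotData:
    """Lattice representation of a mean-difference plot for integer ratings.

    ``points`` are (average, difference, multiplicity) triples, one per
    occupied lattice cell; the same triples serve as the grid of the 3-D
    bar chart.  ``histogram`` is the distribution of differences.
    """

    points: tuple[tuple[float, int, int], ...]
    histogram: DifferenceDistribution
    n: int

    @property
    def grid(self) -> tuple[tuple[float, int, int], ...]:
        return self.points


def ba_limits(
    diffs: DifferenceDistribution | np.ndarray,
    ci_method: str = "bland_altman_1986",
    K: int | None = None,
) -> BAResult:
    """Limits of agreement mean_d +/- 1.96 sd_d with 95% CIs.

    ``diffs`` is a :class:`DifferenceDistribution` or a raw vector of
    differences.  Two CI conventions are offered:

    * ``"bland_altman_1986"`` — limit +/- 1.96 sqrt(3 s^2 / n), the
      classic large-sample formula;
    * ``"medcalc_t"`` — limit +/- t(0.975, n-1) s sqrt(1/n + 1.96^2/(2(n-1))),
      the t-based convention used by MedCalc and several other packages.

    ``pct_within_loa`` uses closed-interval comparison; for integer
    differences a tie with a limit can only occur when the limit is an
    exact integer, in which case the difference counts as inside.
    """
    if isinstance(diffs, DifferenceDistribution):
        dist = diffs
    else:
        d = np.asarray(diffs)
        if K is None:
            K = int(np.abs(d).max()) + 1 if len(d) else 2
        counts = np.zeros(2 * K - 1, dtype=np.int64)
        np.add.at(counts, d.astype(np.int64) + K - 1, 1)
        dist = DifferenceDistribution(counts, K)
    n = dist.n
    mean_d = dist.mean
    sd_d = dist.sd
    if n < 2 or sd_d == 0.0:
        inside = 100.0 if n else 0.0
        return BAResult(
            mean_d, sd_d, mean_d, mean_d, None, None,
            pct_within_loa=inside,
            pct_within_1=percent_within_k(dist, min(1, dist.K - 1)),
            n=n, ci_method=ci_method,
            note="fewer than 2 differences or zero spread; limits collapse to the mean",
        )
    half = Z_95 * sd_d
    lo, hi = mean_d - half, mean_d + half
    if ci_method == "bland_altman_1986":
        se = math.sqrt(3.0 * sd_d**2 / n)
        ci_half = Z_95 * se
    elif ci_method == "medcalc_t":
        t = float(sps.t.ppf(0.975, n - 1))
        ci_half = t * sd_d * math.sqrt(1.0 / n + Z_95**2 / (2.0 * (n - 1)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    support = dist.support
    inside = int(dist.counts[(support >= lo) & (support <= hi)].sum())
    return BAResult(
        mean_d, sd_d, lo, hi,
        (lo - ci_half, lo + ci_half),
        (hi - ci_half, hi + ci_half),
        pct_within_loa=100.0 * inside / n,
        pct_within_1=percent_within_k(dist, 1),
        n=n, ci_method=ci_method,
    )


def ba_plot_data(pairs: PairedRatings) -> BAPlotData:
    """Tally (average, difference) lattice cells with multiplicities.

    Averages are (a + b)/2 with no jitter; the multiplicity at each cell
    is what a faithful plot must encode, because on ceiling-effect data a
    single cell can hold the majority of all observations.
    """
    table = build_contingency(pairs)
    idx_a, idx_b = np.nonzero(table.counts)
    pts = sorted(
        (float(i + j + 2) / 2.0, int(i - j), int(table.counts[i, j]))
        for i, j in zip(idx_a, idx_b)
    )
    return BAPlotData(tuple(pts), difference_distribution(table), pairs.n)


def skewness_flag(mean_d: float, sd_d: float) -> bool:
    """True when |mean of differences| < SD of differences.

    On a bounded short scale this pattern signals a skewed difference
    distribution: the normality reasoning behind the 95% limits of
    agreement is then strained and the limits should be read together
    with the bar chart of differences.
    """
    if sd_d < 0:
        raise ValueError("sd_d must be >= 0")
    return abs(mean_d) < sd_d


# ---------------------------------------------------------------------------
# plotting (matplotlib; all return the Axes/Figure for further styling)


def plot_mean_difference(pairs: PairedRatings, ba: BAResult | None = None, ax=None):
    """Mean-difference plot with point areas encoding multiplicity."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    data = ba_plot_data(pairs)
    if ba is None:
        ba = ba_limits(data.histogram)
    avgs = [p[0] for p in data.points]
    ds = [p[1] for p in data.points]
    mult = np.array([p[2] for p in data.points], dtype=float)
    ax.scatter(avgs, ds, s=20 + 400 * mult / mult.max(), alpha=0.7,
               edgecolor="black", linewidth=0.5, zorder=3)
    for x, d, m in data.points:
        ax.annotate(str(m), (x, d), textcoords="offset points", xytext=(6, 6),
                    fontsize=7)
    ax.axhline(ba.mean_d, color="tab:blue", label=f"mean d = {ba.mean_d:.2f}")
    for lim in (ba.loa_lower, ba.loa_upper):
        ax.axhline(lim, color="tab:red", linestyle="--")
    if ba.ci_lower_limit:
        ax.axhspan(*ba.ci_lower_limit, color="tab:red", alpha=0.15)
    if ba.ci_upper_limit:
        ax.axhspan(*ba.ci_upper_limit, color="tab:red", alpha=0.15)
    ax.set_xlabel("average of the two ratings (a+b)/2")
    ax.set_ylabel("difference d = a − b")
    ax.set_title(f"Mean-difference plot ({pairs.item_id}, n={pairs.n})")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_difference_bars(diffs: DifferenceDistribution, ax=None, percent=True):
    """Bar chart of the difference distribution (the recommended companion

    to the mean-difference plot on short scales)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    y = diffs.counts.astype(float)
    if percent:
        y = 100.0 * y / diffs.n
    ax.bar(diffs.support, y, color="tab:gray", edgecolor="black")
    ax.set_xlabel("difference d = a − b (scale points)")
    ax.set_ylabel("% of encounters" if percent else "count")
    ax.set_xticks(diffs.support)
    return ax


def plot_grid_3d(pairs: PairedRatings, ax=None):
    """Three-dimensional bar chart over the (average, difference) lattice."""
    import matplotlib.pyplot as plt

    data = ba_plot_data(pairs)
    if ax is None:
        fig = plt.figure(figsize=(7, 5))
        ax = fig.add_subplot(projection="3d")
    xs = np.array([p[0] for p in data.points])
    ys = np.array([p[1] for p in data.points], dtype=float)
    zs = np.array([p[2] for p in data.points], dtype=float)
    ax.bar3d(xs - 0.2, ys - 0.2, np.zeros_like(zs), 0.4, 0.4, zs, shade=True)
    ax.set_xlabel("average (a+b)/2")
    ax.set_ylabel("difference a − b")
    ax.set_zlabel("count")
    return ax
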