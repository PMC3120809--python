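"""Difference and association statistics for paired ordinal ratings.

The battery implemented here is the one recommended for inter-rater data
when no single gold-standard index exists: raw percentage agreement,
agreement within +/-k scale points, Cohen's kappa (unweighted, linear or
quadratic weights), Kendall's tau-b with tie correction, the standardized
marginal-homogeneity test, the Wilcoxon signed-rank test with its effect
size r = |Z|/sqrt(N), and Bonferroni adjustment across items.

Degenerate inputs (e.g. a one-category table, all differences zero) yield
an *undefined marker* — ``nan`` statistics with an explanatory note — not
an exception, so that a batch report over many items never aborts on one
pathological item.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import SquareTable
from statsmodels.stats.multitest import multipletests

from .core import ContingencyTable, DifferenceDistribution, difference_distribution

__all__ = [
    "TestResult",
    "KappaResult",
    "TauBResult",
    "percent_agreement",
    "percent_within_k",
    "cohen_kappa",
    "kappa_weight_matrix",
    "kendall_tau_b",
    "marginal_homogeneity_test",
    "stuart_maxwell_test",
    "wilcoxon_signed_rank",
    "wilcoxon_effect_size",
    "bonferroni_adjust",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention of most

    statistical packages), rather than Python's banker's rounding."""
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its two-sided p-value.

    ``statistic`` is ``nan`` and ``p_value`` is ``None`` when the test is
    undefined on the data; ``note`` then says why.
    """

    statistic: float
    p_value: float | None
    method_label: str
    n_effective: int
    median_diff: float | None = None
    note: str | None = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.statistic)

    def to_dict(self) -> dict:
        return {
            "statistic": None if not self.defined else self.statistic,
            "p_value": self.p_value,
            "method_label": self.method_label,
            "n_effective": self.n_effective,
            "median_diff": self.median_diff,
            "note": self.note,
        }


@dataclass(frozen=True)
class KappaResult:
    """Chance-corrected agreement: kappa = (Po_w - Pe_w) / (1 - Pe_w)."""

    estimate: float
    po_w: float
    pe_w: float
    weight_scheme: str
    n: int
    note: str | None = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.estimate)

    def to_dict(self) -> dict:
        return {
            "estimate": None if not self.defined else self.estimate,
            "observed_agreement": self.po_w,
            "expected_agreement": self.pe_w,
            "weight_scheme": self.weight_scheme,
            "n": self.n,
            "note": self.note,
        }


@dataclass(frozen=True)
class TauBResult:
    """Kendall's tau-b with the tie bookkeeping made explicit.

    ``concordant``/``discordant`` count observation pairs; ``n0`` is the
    total number of pairs n(n-1)/2 and ``n1``/``n2`` the pairs tied on
    rater A's and rater B's margin respectively.
    """

    estimate: float
    concordant: int
    discordant: int
    n0: int
    n1: int
    n2: int
    p_value: float | None
    n: int
    note: str | None = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.estimate)

    def to_dict(self) -> dict:
        return {
            "estimate": None if not self.defined else self.estimate,
            "concordant": self.concordant,
            "discordant": self.discordant,
            "n0": self.n0,
            "n1": self.n1,
            "n2": self.n2,
            "p_value": self.p_value,
            "n": self.n,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# agreement percentages


def percent_agreement(table: ContingencyTable) -> float:
    """Raw percentage of exact agreement: 100 * trace / n."""
    n = table.n
    if n < 1:
        raise ValueError("empty table")
    return 100.0 * float(np.trace(table.counts)) / n


def percent_within_k(diffs: DifferenceDistribution, k: int) -> float:
    """Percentage of paired differences with |d| <= k scale points.

    ``k = 0`` equals :func:`percent_agreement`; ``k = K-1`` is always 100.
    On a short scale this is often the clinically meaningful agreement
    summary: a one-category near-miss on a 5-point satisfaction item is
    rarely a relevant disagreement.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= diffs.K:
        raise ValueError(f"k must be < K = {diffs.K}")
    inside = int(diffs.counts[np.abs(diffs.support) <= k].sum())
    return 100.0 * inside / diffs.n


# ---------------------------------------------------------------------------
# kappa


def kappa_weight_matrix(K: int, scheme: str = "linear") -> np.ndarray:
    """Agreement weights w_ij in [0, 1]; w_ii = 1.

    unweighted: identity; linear: 1 - |i-j|/(K-1); quadratic:
    1 - (i-j)^2/(K-1)^2.
    """
    i, j = np.indices((K, K))
    if scheme == "unweighted":
        return (i == j).astype(float)
    if scheme == "linear":
        return 1.0 - np.abs(i - j) / (K - 1)
    if scheme == "quadratic":
        return 1.0 - (i - j) ** 2 / (K - 1) ** 2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def cohen_kappa(
    table: ContingencyTable,
    scheme: str | np.ndarray = "linear",
) -> KappaResult:
    """Cohen's kappa on a K x K table, optionally distance-weighted.

    ``scheme`` is ``"unweighted"``, ``"linear"``, ``"quadratic"`` or a
    custom K x K weight matrix.  On a one-category table (expected
    agreement 1) kappa is undefined and the result carries a note instead
    of raising.

    Note the well-known paradox on skewed marginals: with nearly all mass
    in one category, chance agreement Pe is already close to 1 and kappa
    collapses toward 0 no matter how close the raters are.
    """
    n = table.n
    if n < 1:
        raise ValueError("empty table")
    if isinstance(scheme, str):
        w = kappa_weight_matrix(table.K, scheme)
        scheme_name = scheme
    else:
        w = np.asarray(scheme, dtype=float)
        if w.shape != (table.K, table.K):
            raise ValueError("custom weight matrix has wrong shape")
        scheme_name = "custom"
    p = table.counts / n
    po = float((w * p).sum())
    pe = float((w * np.outer(table.row_totals, table.col_totals)).sum()) / n**2
    if pe >= 1.0 - 1e-12:
        return KappaResult(
            math.nan, po, pe, scheme_name, n,
            note="expected agreement is 1 (single occupied category); kappa undefined",
        )
    return KappaResult((po - pe) / (1.0 - pe), po, pe, scheme_name, n)


# ---------------------------------------------------------------------------
# Kendall's tau-b


def kendall_tau_b(table: ContingencyTable) -> TauBResult:
    """Kendall's tau-b from cell-block sums over the contingency table.

    For grouped ordinal data every pair of observations falls in a pair of
    cells; concordant and discordant pair counts are obtained by summing,
    for each cell, the counts in the block below-right (concordant) and
    below-left (discordant):

        tau-b = (C - D) / sqrt((n0 - n1)(n0 - n2))

    with n0 = n(n-1)/2 and n1, n2 the numbers of pairs tied on each
    margin.  The p-value uses the standard asymptotic normal
    approximation for C - D with tie-corrected variance.
    """
    c = table.counts
    K = table.K
    n = table.n
    if n < 2:
        raise ValueError("tau-b needs at least two observations")
    C = 0
    D = 0
    for i in range(K):
        for j in range(K):
            if c[i, j] == 0:
                continue
            C += int(c[i, j]) * int(c[i + 1 :, j + 1 :].sum())
            D += int(c[i, j]) * int(c[i + 1 :, :j].sum())
    rt = table.row_totals
    ct = table.col_totals
    n0 = n * (n - 1) // 2
    n1 = int((rt * (rt - 1) // 2).sum())
    n2 = int((ct * (ct - 1) // 2).sum())
    denom_sq = (n0 - n1) * (n0 - n2)
    if denom_sq <= 0:
        return TauBResult(
            math.nan, C, D, n0, n1, n2, None, n,
            note="all observations tied on a margin; tau-b undefined",
        )
    tau = (C - D) / math.sqrt(denom_sq)

    # tie-corrected variance of C - D (Kendall/Stuart), as used by the
    # standard asymptotic significance test
    rt_ = rt.astype(float)
    ct_ = ct.astype(float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((rt_ * (rt_ - 1) * (2 * rt_ + 5)).sum())
    vu = float((ct_ * (ct_ - 1) * (2 * ct_ + 5)).sum())
    v1 = (
        float((rt_ * (rt_ - 1)).sum())
        * float((ct_ * (ct_ - 1)).sum())
        / (2.0 * n * (n - 1))
    )
    v2 = 0.0
    if n > 2:
        v2 = (
            float((rt_ * (rt_ - 1) * (rt_ - 2)).sum())
            * float((ct_ * (ct_ - 1) * (ct_ - 2)).sum())
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var = (v0 - vt - vu) / 18.0 + v1 + v2
    if var <= 0:
        p = None
    else:
        z = (C - D) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return TauBResult(tau, C, D, n0, n1, n2, p, n)


# ---------------------------------------------------------------------------
# marginal homogeneity


def marginal_homogeneity_test(
    table: ContingencyTable, scores: np.ndarray | None = None
) -> TestResult:
    """Standardized marginal-homogeneity (score) test for paired ordinal data.

    Tests whether the two raters' category distributions (the row and
    column margins) differ systematically.  With category scores s (default
    1..K) the statistic is

        Z = sum_{i != j} c_ij (s_i - s_j) / sqrt(sum_{i != j} c_ij (s_i - s_j)^2),

    the conditional score statistic: given the off-diagonal totals
    c_ij + c_ji, each pair splits Binomial(., 1/2) under the null, so Z is
    asymptotically standard normal.  The sign follows d = A - B: positive Z
    means rater A uses systematically higher (less favourable) categories.
    Transposing the table flips the sign.  Diagonal cells do not enter:
    the test ignores the extent of agreement and weighs only disagreement.
    """
    K = table.K
    if scores is None:
        scores = np.arange(1, K + 1, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (K,):
        raise ValueError(f"need {K} category scores")
    diff = scores[:, None] - scores[None, :]
    off = ~np.eye(K, dtype=bool)
    num = float((table.counts * diff)[off].sum())
    den_sq = float((table.counts * diff**2)[off].sum())
    if den_sq <= 0:
        return TestResult(
            math.nan, None, "standardized marginal homogeneity", 0,
            note="no discordant pairs; marginal homogeneity statistic undefined",
        )
    z = num / math.sqrt(den_sq)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    n_disc = int(table.counts[off].sum())
    return TestResult(z, p, "standardized marginal homogeneity", n_disc)


def stuart_maxwell_test(table: ContingencyTable) -> TestResult:
    """Stuart-Maxwell chi-square test of marginal homogeneity.

    The omnidirectional (chi-square) alternative to the directional
    standardized statistic; it detects any difference between the margins
    rather than an ordered shift.  Delegates to the square-table machinery
    in statsmodels.
    """
    res = SquareTable(table.counts, shift_zeros=False).homogeneity()
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        f"Stuart-Maxwell chi-square (df={int(res.df)})",
        table.n,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, zero_policy: str = "discard",
    correction: bool = True,
) -> TestResult:
    """Wilcoxon signed-rank matched-pairs test on d = x - y.

    Tests whether the median of the paired differences is zero.  Ranks of
    |d| use mid-ranks for ties; the normal approximation Z uses the
    tie-corrected variance.  ``zero_policy="discard"`` drops zero
    differences before ranking (the default of most statistical
    packages); ``"pratt"`` ranks them and then drops their contribution.
    ``correction`` applies the continuity correction (0.5 toward the
    mean), which keeps the approximate p close to the exact permutation p
    in small samples and is negligible in large ones.

    The result also carries the median of the differences: on heavily
    skewed short-scale data the test can be highly significant while that
    median is exactly zero, which is the central interpretive trap this
    package exists to surface.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 1:
        raise ValueError("need at least one pair")
    if zero_policy not in ("discard", "pratt"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    d = x - y
    median = float(np.median(d))
    nz = int(np.count_nonzero(d))
    label = f"Wilcoxon signed-rank (zeros: {zero_policy})"
    if nz == 0:
        return TestResult(
            math.nan, None, label, 0, median_diff=median,
            note="all paired differences are zero; statistic undefined",
        )
    if zero_policy == "discard":
        dd = d[d != 0]
        n0 = 0
    else:  # Pratt: rank the zeros, then drop their contribution
        dd = d
        n0 = len(d) - nz
    n = len(dd)
    r = sps.rankdata(np.abs(dd))
    t_plus = float(r[dd > 0].sum())
    mu = (n * (n + 1) - n0 * (n0 + 1)) / 4.0
    # tie correction over tied groups of nonzero |d|; the zero block is
    # already removed in full by the n0 terms
    rep = np.unique(r[dd != 0], return_counts=True)[1].astype(float)
    tie = float((rep**3 - rep).sum()) / 48.0
    var = (
        n * (n + 1) * (2 * n + 1) / 24.0
        - n0 * (n0 + 1) * (2 * n0 + 1) / 24.0
        - tie
    )
    if var <= 0:
        return TestResult(
            math.nan, None, label, nz, median_diff=median,
            note="zero variance after tie correction; statistic undefined",
        )
    dev = t_plus - mu
    if correction:
        dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev)
    z = dev / math.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    n_eff = nz if zero_policy == "discard" else len(x)
    return TestResult(z, min(p, 1.0), label, n_eff, median_diff=median)


def wilcoxon_effect_size(z: float, n: int) -> float:
    """Effect size r = |Z| / sqrt(N) for the Wilcoxon signed-rank test.

    r >= .30 is conventionally read as a medium effect and r >= .50 as
    large.  N must be chosen deliberately (individuals or clusters): the
    cluster-level workflow passes the number of clusters.
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    return abs(z) / math.sqrt(n)


# ---------------------------------------------------------------------------
# multiplicity


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni adjustment: each p multiplied by m, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]
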