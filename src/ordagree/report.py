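"""Full analysis battery and report rendering.

`run_analysis` applies, per item: cross-tabulation, optional category
collapsing, percentage agreement and within-one-point agreement, kappa
under every weight scheme, Kendall's tau-b, the standardized marginal
homogeneity test (on the collapsed table when a collapse is given, since
that is where near-empty categories are pooled), the Wilcoxon signed-rank
test at individual and — when cluster labels are present — at cluster
level, and the Bland-Altman limits of agreement.  Raw p-values get
Bonferroni-adjusted twins across items, family by family.

Conventions that change numbers (kappa weight scheme, CI method, zero
policy, collapse mapping) are always recorded next to the value they
produced.
"""

from __future__ import annotations

import datetime
import json
import logging
import math
from typing import Sequence

import numpy as np

from . import __version__
from .blandaltman import ba_limits, ba_plot_data, skewness_flag
from .clusters import clustered_wilcoxon
from .core import (
    ContingencyTable,
    PairedRatings,
    build_contingency,
    collapse_categories,
    difference_distribution,
)
from .stats import (
    bonferroni_adjust,
    cohen_kappa,
    kendall_tau_b,
    marginal_homogeneity_test,
    percent_agreement,
    percent_within_k,
    round_half_up,
    stuart_maxwell_test,
    wilcoxon_effect_size,
    wilcoxon_signed_rank,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
KAPPA_SCHEMES = ("unweighted", "linear", "quadratic")

__all__ = ["run_analysis", "analyze_item", "render_report", "SCHEMA_VERSION"]


def analyze_item(
    pairs: PairedRatings,
    collapse: Sequence[Sequence[int]] | None = None,
    ci_method: str = "bland_altman_1986",
    zero_policy: str = "discard",
) -> dict:
    """The complete statistic battery for a single item; returns a plain dict."""
    table = build_contingency(pairs)
    diffs = difference_distribution(table)
    collapsed = collapse_categories(table, collapse) if collapse else None
    mh_table = collapsed if collapsed is not None else table

    for label, margin in (("rater A", table.row_totals), ("rater B", table.col_totals)):
        top = 100.0 * margin.max() / table.n
        if top > 80.0:
            logger.warning(
                "item %s: %s puts %.1f%% of ratings in one category "
                "(ceiling/floor effect); chance-corrected coefficients will be "
                "hard to interpret", pairs.item_id, label, top,
            )

    wil = wilcoxon_signed_rank(pairs.a, pairs.b, zero_policy=zero_policy)
    block: dict = {
        "item": pairs.item_id,
        "n": pairs.n,
        "table": table.counts.tolist(),
        "collapse": [list(g) for g in collapse] if collapse else None,
        "collapsed_table": collapsed.counts.tolist() if collapsed is not None else None,
        "mean_a": float(pairs.a.mean()),
        "sd_a": float(pairs.a.std(ddof=1)) if pairs.n > 1 else 0.0,
        "mean_b": float(pairs.b.mean()),
        "sd_b": float(pairs.b.std(ddof=1)) if pairs.n > 1 else 0.0,
        "mean_d": diffs.mean,
        "sd_d": diffs.sd,
        "median_d": diffs.median,
        "percent_agreement": percent_agreement(table),
        "percent_within_1": percent_within_k(diffs, min(1, diffs.K - 1)),
        "kappa": {s: cohen_kappa(table, s).to_dict() for s in KAPPA_SCHEMES},
        "tau_b": kendall_tau_b(table).to_dict(),
        "mh": marginal_homogeneity_test(mh_table).to_dict(),
        "stuart_maxwell": stuart_maxwell_test(mh_table).to_dict(),
        "wilcoxon": wil.to_dict(),
        "wilcoxon_effect_size": (
            wilcoxon_effect_size(wil.statistic, pairs.n) if wil.defined else None
        ),
        "bland_altman": ba_limits(diffs, ci_method=ci_method).to_dict(),
        "skewness_flag": skewness_flag(diffs.mean, diffs.sd),
        "plot_points": [list(p) for p in ba_plot_data(pairs).points],
    }
    if block["skewness_flag"]:
        logger.warning(
            "item %s: |mean difference| (%.2f) < SD (%.2f) — skewed differences; "
            "read the limits of agreement together with the difference bar chart",
            pairs.item_id, diffs.mean, diffs.sd,
        )
    if pairs.cluster is not None:
        cw = clustered_wilcoxon(pairs, zero_policy=zero_policy)
        n_clusters = len(np.unique(np.asarray(pairs.cluster)))
        block["clustered_wilcoxon"] = cw.to_dict()
        block["n_clusters"] = n_clusters
        block["clustered_effect_size"] = (
            wilcoxon_effect_size(cw.statistic, n_clusters) if cw.defined else None
        )
    else:
        block["clustered_wilcoxon"] = None
        block["n_clusters"] = None
        block["clustered_effect_size"] = None
    return block


# p-value families that get Bonferroni twins across items
_P_FAMILIES = (
    ("mh", "p_value"),
    ("stuart_maxwell", "p_value"),
    ("tau_b", "p_value"),
    ("wilcoxon", "p_value"),
    ("clustered_wilcoxon", "p_value"),
)


def _adjust_across_items(items: list[dict]) -> None:
    for family, key in _P_FAMILIES:
        holders = [
            it[family] for it in items
            if it.get(family) and it[family].get(key) is not None
        ]
        if not holders:
            continue
        adj = bonferroni_adjust([h[key] for h in holders])
        for h, a in zip(holders, adj):
            h[key + "_bonferroni"] = float(a)
        # items where the statistic was undefined still get the twin slot
        for it in items:
            if it.get(family) is not None:
                it[family].setdefault(key + "_bonferroni", None)


def run_analysis(
    items: dict[str, PairedRatings],
    collapse: Sequence[Sequence[int]] | None = None,
    ci_method: str = "bland_altman_1986",
    zero_policy: str = "discard",
    alpha: float = 0.05,
    input_path: str | None = None,
    timestamp: bool = True,
) -> dict:
    """Run the per-item battery over all items and assemble the report."""
    if not items:
        raise ValueError("no items to analyse")
    blocks = [
        analyze_item(pairs, collapse=collapse, ci_method=ci_method,
                     zero_policy=zero_policy)
        for _, pairs in sorted(items.items())
    ]
    _adjust_across_items(blocks)
    report = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "metadata": {
            "input": input_path,
            "n_items": len(blocks),
            "alpha": alpha,
            "options": {
                "collapse": [list(g) for g in collapse] if collapse else None,
                "ci_method": ci_method,
                "zero_policy": zero_policy,
            },
            "timestamp": (
                datetime.datetime.now(datetime.timezone.utc).isoformat()
                if timestamp else None
            ),
        },
        "items": blocks,
    }
    return report


# ---------------------------------------------------------------------------
# rendering


def _fmt(x, nd=2, pct=False):
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "n/a"
    return f"{round_half_up(float(x), 1 if pct else nd):.{1 if pct else nd}f}"


def _fmt_p(p):
    if p is None:
        return "n/a"
    return "< .001" if p < 0.001 else f"= {round_half_up(p, 2):.2f}"


def render_report(report: dict, format: str = "json") -> str:
    """Serialise a report as schema-stable JSON or as markdown tables.

    The markdown view rounds to presentation precision (one decimal for
    percentages, two for coefficients, round-half-up); the JSON view keeps
    full precision.  Undefined statistics render as ``n/a`` with their
    reason, never as 0.
    """
    if format == "json":
        return json.dumps(report, indent=2, allow_nan=False)
    if format != "markdown":
        raise ValueError(f"unknown format {format!r}")

    lines = [
        "# Paired-rating agreement report",
        "",
        f"n items: {report['metadata']['n_items']}; "
        f"options: {report['metadata']['options']}",
        "",
        "## Marginal homogeneity (standardized MH)",
        "",
        "| Item | stand. MH | p | p (Bonferroni) |",
        "|---|---|---|---|",
    ]
    for it in report["items"]:
        mh = it["mh"]
        lines.append(
            f"| {it['item']} | {_fmt(mh['statistic'])} | {_fmt_p(mh['p_value'])} "
            f"| {_fmt_p(mh.get('p_value_bonferroni'))} |"
        )
    lines += [
        "",
        "## Differences (Wilcoxon signed-rank)",
        "",
        "| Item | mean (SD) A | mean (SD) B | mean (SD) of differences "
        "| median of differences | Z | p | p (Bonferroni) |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for it in report["items"]:
        w = it["clustered_wilcoxon"] or it["wilcoxon"]
        note = " (cluster level)" if it["clustered_wilcoxon"] else ""
        stat = _fmt(w["statistic"])
        if w["statistic"] is None and w.get("note"):
            stat = f"n/a ({w['note']})"
        lines.append(
            f"| {it['item']}{note} | {_fmt(it['mean_a'])} ({_fmt(it['sd_a'])}) "
            f"| {_fmt(it['mean_b'])} ({_fmt(it['sd_b'])}) "
            f"| {_fmt(it['mean_d'])} ({_fmt(it['sd_d'])}) | {_fmt(it['median_d'])} "
            f"| {stat} | {_fmt_p(w['p_value'])} "
            f"| {_fmt_p(w.get('p_value_bonferroni'))} |"
        )
    lines += [
        "",
        "## Association and raw agreement",
        "",
        "| Item | kappa (unweighted) | kappa (linear) | % agreement | tau-b | p |",
        "|---|---|---|---|---|---|",
    ]
    for it in report["items"]:
        ku = it["kappa"]["unweighted"]["estimate"]
        kl = it["kappa"]["linear"]["estimate"]
        tb = it["tau_b"]
        lines.append(
            f"| {it['item']} | {_fmt(ku)} | {_fmt(kl)} "
            f"| {_fmt(it['percent_agreement'], pct=True)} "
            f"| {_fmt(tb['estimate'])} | {_fmt_p(tb['p_value'])} |"
        )
    lines += [
        "",
        "## Bland-Altman limits of agreement",
        "",
        "| Item | lower limit (95% CI) | upper limit (95% CI) "
        "| % within limits | % within ±1 point |",
        "|---|---|---|---|---|",
    ]
    for it in report["items"]:
        ba = it["bland_altman"]
        lo_ci = ba["ci_lower_limit"]
        hi_ci = ba["ci_upper_limit"]
        lo = f"{_fmt(ba['loa_lower'])}"
        hi = f"{_fmt(ba['loa_upper'])}"
        if lo_ci:
            lo += f" ({_fmt(lo_ci[0])} to {_fmt(lo_ci[1])})"
        if hi_ci:
            hi += f" ({_fmt(hi_ci[0])} to {_fmt(hi_ci[1])})"
        flag = " ⚠ skewed differences" if it["skewness_flag"] else ""
        lines.append(
            f"| {it['item']} | {lo} | {hi} "
            f"| {_fmt(ba['pct_within_loa'], pct=True)} "
            f"| {_fmt(ba['pct_within_1'], pct=True)}{flag} |"
        )
    lines.append("")
    return "\n".join(lines)
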