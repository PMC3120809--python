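"""Cluster-aware aggregation for nested rating data.

In a cluster-randomised design patients are nested in physicians, so the
rating pairs within a physician are not independent.  The aggregation
strategy implemented here reduces each cluster to its pair of mean
ratings (mean of rater A, mean of rater B over the cluster's encounters)
and runs the paired comparison at cluster level, with the number of
clusters as the effective sample size for effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PairedRatings
from .stats import TestResult, wilcoxon_signed_rank

__all__ = ["ClusterSummary", "cluster_means", "clustered_wilcoxon", "overall_means"]


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: object
    n_members: int
    mean_a: float
    mean_b: float

    @property
    def mean_diff(self) -> float:
        return self.mean_a - self.mean_b


def cluster_means(pairs: PairedRatings) -> list[ClusterSummary]:
    """Per-cluster mean ratings of each rater.

    Size-weighted recombination of the cluster means reproduces the grand
    means exactly (see :func:`overall_means`).
    """
    if pairs.cluster is None:
        raise ValueError("pairs carry no cluster labels")
    cluster = np.asarray(pairs.cluster)
    out = []
    for cid in _unique_sorted(cluster):
        mask = cluster == cid
        out.append(
            ClusterSummary(
                cluster_id=cid,
                n_members=int(mask.sum()),
                mean_a=float(pairs.a[mask].mean()),
                mean_b=float(pairs.b[mask].mean()),
            )
        )
    return out


def _unique_sorted(values: np.ndarray) -> np.ndarray:
    # np.unique sorts, which keeps output deterministic for mixed label types
    return np.unique(values)


def overall_means(summaries: list[ClusterSummary], weighted: bool = False):
    """Overall (mean_a, mean_b) across clusters.

    Unweighted averaging of cluster means is the default: every physician
    contributes equally regardless of how many patients they recruited.
    ``weighted=True`` weights by cluster size, which reproduces the
    individual-level grand means instead.
    """
    ma = np.array([s.mean_a for s in summaries])
    mb = np.array([s.mean_b for s in summaries])
    if weighted:
        w = np.array([s.n_members for s in summaries], dtype=float)
        w /= w.sum()
        return float(ma @ w), float(mb @ w)
    return float(ma.mean()), float(mb.mean())


def clustered_wilcoxon(pairs: PairedRatings, zero_policy: str = "discard") -> TestResult:
    """Wilcoxon signed-rank test on the per-cluster mean ratings.

    One observation pair per cluster, so the test respects the nesting;
    downstream effect sizes should use the number of clusters as N.
    """
    summaries = cluster_means(pairs)
    if len(summaries) < 2:
        raise ValueError("need at least 2 clusters for a cluster-level test")
    ma = np.array([s.mean_a for s in summaries])
    mb = np.array([s.mean_b for s in summaries])
    res = wilcoxon_signed_rank(ma, mb, zero_policy=zero_policy)
    label = res.method_label + ", on cluster means"
    return TestResult(res.statistic, res.p_value, label, res.n_effective,
                      median_diff=res.median_diff, note=res.note)
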