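"""Canonical containers for paired ordinal ratings.

Two raters (here called A and B; in the motivating application, physician
and patient) score the same encounters on a K-point ordered scale coded
``1..K``.  The same data can be viewed three ways, and the statistics in
this package each want a different view:

* :class:`PairedRatings` — the raw aligned vectors, optionally with a
  cluster label per encounter (patients nested in physicians);
* :class:`ContingencyTable` — the K x K cross-tabulation of (A, B) pairs;
* :class:`DifferenceDistribution` — the counts of ``d = a - b`` over
  ``-(K-1) .. +(K-1)``.

The sign convention is fixed throughout the package: ``d = a - b`` (rater A
minus rater B).  With a scale where 1 is the most favourable category and
rater A the physician, a *negative* difference means the physician rated
the encounter better than the patient.  All downstream signs (mean
difference, the standardized marginal-homogeneity statistic) inherit this
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RatingScale",
    "PairedRatings",
    "ContingencyTable",
    "DifferenceDistribution",
    "build_contingency",
    "collapse_categories",
    "difference_distribution",
    "read_long_csv",
    "read_table_csv",
    "write_table_csv",
]


@dataclass(frozen=True)
class RatingScale:
    """An ordered category system with K levels coded ``1..K``.

    ``lower_is_better`` is metadata only: it records the orientation of
    the instrument (e.g. 1 = "totally agree" ... 5 = "totally disagree",
    so low scores mean high satisfaction) but no formula in this package
    depends on it.
    """

    K: int
    labels: tuple[str, ...] | None = None
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"a rating scale needs K >= 2 categories, got K={self.K}")
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
            if len(self.labels) != self.K:
                raise ValueError(
                    f"got {len(self.labels)} labels for a {self.K}-point scale"
                )

    @property
    def categories(self) -> np.ndarray:
        return np.arange(1, self.K + 1)

    def label(self, category: int) -> str:
        if self.labels is None:
            return str(category)
        return self.labels[category - 1]


def _validate_ratings(values: np.ndarray, K: int, name: str) -> None:
    bad = np.flatnonzero((values < 1) | (values > K))
    if bad.size:
        raise ValueError(
            f"rating outside 1..{K} in column {name!r} at row index {bad[0]} "
            f"(value {values[bad[0]]})"
        )


@dataclass(frozen=True)
class PairedRatings:
    """Aligned integer ratings by two raters on one item.

    Parameters
    ----------
    a, b
        Ratings by rater A and rater B, same length, each in ``1..K``.
    cluster
        Optional cluster identifier per encounter (e.g. the physician a
        patient is nested under).
    """

    a: np.ndarray
    b: np.ndarray
    scale: RatingScale
    cluster: np.ndarray | None = None
    item_id: str = "item"

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.int64)
        b = np.asarray(self.b, dtype=np.int64)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
            raise ValueError("a and b must be 1-d vectors of equal length")
        if len(a) < 1:
            raise ValueError("need at least one rating pair")
        _validate_ratings(a, self.scale.K, "rater_a")
        _validate_ratings(b, self.scale.K, "rater_b")
        if self.cluster is not None:
            cluster = np.asarray(self.cluster)
            object.__setattr__(self, "cluster", cluster)
            if len(cluster) != len(a):
                raise ValueError("cluster vector length must match the ratings")

    @property
    def n(self) -> int:
        return len(self.a)

    @property
    def differences(self) -> np.ndarray:
        """Signed differences ``d = a - b`` per encounter."""
        return self.a - self.b


@dataclass(frozen=True)
class ContingencyTable:
    """K x K cross-tabulation of paired ratings.

    Rows index rater A's category, columns rater B's.  Transposing the
    table swaps the rater roles.
    """

    counts: np.ndarray
    scale: RatingScale
    item_id: str = "item"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        K = self.scale.K
        if counts.shape != (K, K):
            raise ValueError(f"expected a {K}x{K} count matrix, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def K(self) -> int:
        return self.scale.K

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        """Swap the rater roles (rows <-> columns)."""
        return ContingencyTable(self.counts.T.copy(), self.scale, self.item_id)

    def to_pairs(self) -> PairedRatings:
        """Expand back to a pair list (encounter order is not recoverable)."""
        idx_a, idx_b = np.nonzero(self.counts)
        reps = self.counts[idx_a, idx_b]
        a = np.repeat(idx_a + 1, reps)
        b = np.repeat(idx_b + 1, reps)
        return PairedRatings(a=a, b=b, scale=self.scale, item_id=self.item_id)

    def to_frame(self) -> pd.DataFrame:
        cats = self.scale.categories
        return pd.DataFrame(self.counts, index=cats, columns=cats)


@dataclass(frozen=True)
class DifferenceDistribution:
    """Counts of the signed difference ``d = a - b`` on a K-point scale.

    ``counts[i]`` holds the count for ``d = i - (K-1)``; the support is
    ``-(K-1) .. +(K-1)``.
    """

    counts: np.ndarray
    K: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (2 * self.K - 1,):
            raise ValueError(
                f"expected {2 * self.K - 1} difference counts for K={self.K}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def support(self) -> np.ndarray:
        return np.arange(-(self.K - 1), self.K)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def count(self, d: int) -> int:
        return int(self.counts[d + self.K - 1])

    def mirror(self) -> "DifferenceDistribution":
        """The distribution of ``-d`` (rater roles swapped)."""
        return DifferenceDistribution(self.counts[::-1].copy(), self.K)

    def expand(self) -> np.ndarray:
        """All individual differences as a flat vector (sorted)."""
        return np.repeat(self.support, self.counts)

    @property
    def mean(self) -> float:
        return float(self.support @ self.counts) / self.n

    @property
    def sd(self) -> float:
        """Sample standard deviation of the differences (denominator n-1)."""
        if self.n < 2:
            return 0.0
        m = self.mean
        ss = float(((self.support - m) ** 2) @ self.counts)
        return float(np.sqrt(ss / (self.n - 1)))

    @property
    def median(self) -> float:
        return float(np.median(self.expand()))


def build_contingency(pairs: PairedRatings) -> ContingencyTable:
    """Cross-tabulate paired ratings into a K x K count matrix.

    ``counts[i-1, j-1]`` is the number of encounters with rater A giving
    category ``i`` and rater B category ``j``.
    """
    K = pairs.scale.K
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (pairs.a - 1, pairs.b - 1), 1)
    return ContingencyTable(counts, pairs.scale, pairs.item_id)


def collapse_categories(
    table: ContingencyTable, groups: Sequence[Sequence[int]]
) -> ContingencyTable:
    """Merge contiguous blocks of ordinal categories.

    ``groups`` must be an ordered partition of ``1..K`` into at least two
    contiguous blocks, e.g. ``[(1,), (2,), (3, 4, 5)]`` pools the three
    worst categories of a 5-point scale into one.  Non-contiguous
    regroupings are rejected: they would scramble the category order that
    every ordinal statistic downstream relies on.
    """
    K = table.K
    flat = [c for g in groups for c in g]
    if flat != list(range(1, K + 1)):
        raise ValueError(
            "groups must be an ordered partition of 1..K into contiguous blocks; "
            f"got {list(map(list, groups))} for K={K}"
        )
    if len(groups) < 2:
        raise ValueError("collapsing to a single category is not meaningful")
    edges = np.cumsum([0] + [len(g) for g in groups])
    Kp = len(groups)
    new = np.add.reduceat(np.add.reduceat(table.counts, edges[:-1], axis=0),
                          edges[:-1], axis=1)
    if table.scale.labels is not None:
        labels = tuple(
            "+".join(table.scale.labels[c - 1] for c in g) for g in groups
        )
    else:
        labels = None
    new_scale = RatingScale(Kp, labels, table.scale.lower_is_better)
    return ContingencyTable(new, new_scale, table.item_id)


def parse_collapse_spec(spec: str, K: int) -> list[tuple[int, ...]]:
    """Parse a collapse directive like ``"3:5"`` into a full partition.

    ``"3:5"`` on a 5-point scale means "pool categories 3..5", yielding
    ``[(1,), (2,), (3, 4, 5)]``.  Several ranges may be separated by
    commas; unmentioned categories stay singletons.
    """
    merged: list[tuple[int, int]] = []
    for part in spec.split(","):
        lo_s, _, hi_s = part.partition(":")
        lo, hi = int(lo_s), int(hi_s or lo_s)
        if not (1 <= lo <= hi <= K):
            raise ValueError(f"collapse range {part!r} outside 1..{K}")
        merged.append((lo, hi))
    merged.sort()
    groups: list[tuple[int, ...]] = []
    c = 1
    for lo, hi in merged:
        while c < lo:
            groups.append((c,))
            c += 1
        if c != lo:
            raise ValueError(f"overlapping collapse ranges in {spec!r}")
        groups.append(tuple(range(lo, hi + 1)))
        c = hi + 1
    while c <= K:
        groups.append((c,))
        c += 1
    return groups


def difference_distribution(table: ContingencyTable) -> DifferenceDistribution:
    """Anti-diagonal sums of the table: the distribution of ``d = a - b``."""
    K = table.K
    counts = np.zeros(2 * K - 1, dtype=np.int64)
    i, j = np.indices((K, K))
    np.add.at(counts, (i - j).ravel() + K - 1, table.counts.ravel())
    return DifferenceDistribution(counts, K)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_long_csv(
    path,
    scale: RatingScale,
    *,
    item_col: str = "item",
    a_col: str = "rater_a",
    b_col: str = "rater_b",
    cluster_col: str | None = "cluster_id",
) -> dict[str, PairedRatings]:
    """Read long-format paired ratings: one row per encounter per item.

    Required columns: ``item``, ``rater_a``, ``rater_b``; optional
    ``cluster_id``.  Rows with a missing rating in either rater are
    dropped pairwise per item, with the dropped count logged.
    """
    df = pd.read_csv(path)
    for col in (item_col, a_col, b_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    has_cluster = cluster_col is not None and cluster_col in df.columns
    out: dict[str, PairedRatings] = {}
    for item, sub in df.groupby(item_col, sort=True):
        ok = sub[a_col].notna() & sub[b_col].notna()
        dropped = int((~ok).sum())
        if dropped:
            logger.info("item %s: dropped %d row(s) with missing ratings", item, dropped)
        sub = sub[ok]
        if sub.empty:
            raise ValueError(f"item {item!r} has no complete rating pairs")
        out[str(item)] = PairedRatings(
            a=sub[a_col].to_numpy(dtype=np.int64),
            b=sub[b_col].to_numpy(dtype=np.int64),
            scale=scale,
            cluster=sub[cluster_col].to_numpy() if has_cluster else None,
            item_id=str(item),
        )
    if not out:
        raise ValueError(f"no rating data found in {path}")
    return out


def write_long_csv(path, items: dict[str, PairedRatings]) -> None:
    frames = []
    for item_id, pairs in items.items():
        frame = pd.DataFrame(
            {
                "encounter_id": np.arange(1, pairs.n + 1),
                "item": item_id,
                "rater_a": pairs.a,
                "rater_b": pairs.b,
            }
        )
        if pairs.cluster is not None:
            frame.insert(1, "cluster_id", pairs.cluster)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_table_csv(path, scale: RatingScale | None = None) -> ContingencyTable:
    """Read a K x K contingency table stored as a plain CSV matrix."""
    df = pd.read_csv(path, index_col=0)
    counts = df.to_numpy(dtype=np.int64)
    if scale is None:
        scale = RatingScale(counts.shape[0])
    return ContingencyTable(counts, scale)


def write_table_csv(path, table: ContingencyTable) -> None:
    table.to_frame().to_csv(path)
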