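import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ordagree import ContingencyTable, RatingScale
from ordagree.datasets import participation_item1, participation_item1_pairs

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def item1_table():
    """The built-in 5x5 physician-vs-patient example table (n=506)."""
    return participation_item1()


@pytest.fixture
def item1_pairs():
    return participation_item1_pairs()


def random_table(rng: np.random.Generator, K: int | None = None,
                 n_max: int = 60) -> ContingencyTable:
    """A random K x K contingency table with at least 2 observations."""
    if K is None:
        K = int(rng.integers(2, 6))
    n = int(rng.integers(2, n_max + 1))
    cells = rng.multinomial(n, np.full(K * K, 1.0 / (K * K))).reshape(K, K)
    return ContingencyTable(cells, RatingScale(K))


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)


def brute_force_tau_b(a: np.ndarray, b: np.ndarray) -> float:
    """tau-b by O(n^2) enumeration of all observation pairs."""
    n = len(a)
    C = D = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_a += 1
                ties_b += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif (da > 0) == (db > 0):
                C += 1
            else:
                D += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt(float(n0 - ties_a) * float(n0 - ties_b))
    return (C - D) / denom


def wilcoxon_null_distribution(n: int) -> np.ndarray:
    """Exact null pmf of the signed-rank sum W+ for n untied ranks,

    by polynomial convolution over the 2^n equiprobable sign vectors."""
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[k:] = counts[:-k] if k else counts
        counts = counts + shifted
    return counts / counts.sum()


def signed_ranks_for_statistic(n: int, w: int) -> np.ndarray:
    """A vector of distinct differences whose positive ranks sum to w."""
    d = -np.arange(1.0, n + 1)
    remaining = w
    for k in range(n, 0, -1):
        if remaining >= k:
            d[k - 1] = k
            remaining -= k
    assert remaining == 0
    return d


def exact_wilcoxon_p(d: np.ndarray) -> float:
    """Two-sided exact permutation p for the signed-rank test.

    Enumerates all 2^n sign assignments of the ranked absolute
    differences; p = P(|W - mu| >= |W_obs - mu|) under the null.
    Assumes no zero differences.
    """
    from itertools import product

    r = np.argsort(np.argsort(np.abs(d))) + 1.0  # ranks, no ties assumed
    w_obs = r[d > 0].sum()
    mu = r.sum() / 2.0
    hits = total = 0
    for signs in product((0.0, 1.0), repeat=len(d)):
        w = float(np.dot(signs, r))
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total
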