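"""Difference and association statistics, checked against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import mcnemar

from ordagree import (
    ContingencyTable,
    RatingScale,
    bonferroni_adjust,
    cohen_kappa,
    collapse_categories,
    difference_distribution,
    kendall_tau_b,
    marginal_homogeneity_test,
    percent_agreement,
    percent_within_k,
    stuart_maxwell_test,
    wilcoxon_effect_size,
    wilcoxon_signed_rank,
)
from ordagree.stats import kappa_weight_matrix, round_half_up

from conftest import (
    brute_force_tau_b,
    exact_wilcoxon_p,
    random_table,
    signed_ranks_for_statistic,
    wilcoxon_null_distribution,
)


class TestPercentAgreement:
    def test_example_table(self, item1_table):
        assert percent_agreement(item1_table) == pytest.approx(100 * 280 / 506)
        assert round_half_up(percent_agreement(item1_table), 1) == 55.3

    def test_diagonal_table_is_100(self):
        t = ContingencyTable(np.diag([5, 5, 5]), RatingScale(3))
        assert percent_agreement(t) == 100.0

    def test_uniform_2x2_is_50(self):
        t = ContingencyTable([[1, 1], [1, 1]], RatingScale(2))
        assert percent_agreement(t) == 50.0

    def test_empty_table_rejected(self):
        t = ContingencyTable(np.zeros((2, 2), dtype=int), RatingScale(2))
        with pytest.raises(ValueError):
            percent_agreement(t)


class TestPercentWithinK:
    def test_example_within_one(self, item1_table):
        d = difference_distribution(item1_table)
        assert percent_within_k(d, 1) == pytest.approx(100 * 490 / 506)
        assert round_half_up(percent_within_k(d, 1), 1) == 96.8

    def test_k0_equals_percent_agreement(self, item1_table):
        d = difference_distribution(item1_table)
        assert percent_within_k(d, 0) == pytest.approx(percent_agreement(item1_table))

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_k_and_reaches_100(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng)
        d = difference_distribution(table)
        vals = [percent_within_k(d, k) for k in range(table.K)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(100.0)

    def test_negative_k_rejected(self, item1_table):
        with pytest.raises(ValueError):
            percent_within_k(difference_distribution(item1_table), -1)


class TestCohenKappa:
    def test_example_unweighted(self, item1_table):
        # Po = 280/506, Pe = (289*458 + 205*38 + 6*8 + 6*1)/506^2
        res = cohen_kappa(item1_table, "unweighted")
        po = 280 / 506
        pe = 140206 / 506**2
        assert res.po_w == pytest.approx(po)
        assert res.pe_w == pytest.approx(pe)
        assert res.estimate == pytest.approx((po - pe) / (1 - pe))
        assert round_half_up(res.estimate, 2) == 0.01

    def test_example_linear(self, item1_table):
        res = cohen_kappa(item1_table, "linear")
        assert res.estimate == pytest.approx(0.0248057, abs=1e-4)

    def test_perfect_agreement_is_1(self):
        t = ContingencyTable(np.diag([7, 3, 2]), RatingScale(3))
        for scheme in ("unweighted", "linear", "quadratic"):
            assert cohen_kappa(t, scheme).estimate == pytest.approx(1.0)

    def test_single_category_table_undefined(self):
        t = ContingencyTable([[9, 0], [0, 0]], RatingScale(2))
        res = cohen_kappa(t, "unweighted")
        assert not res.defined
        assert res.note is not None

    @pytest.mark.parametrize("scheme,sk_weights", [
        ("unweighted", None), ("linear", "linear"), ("quadratic", "quadratic"),
    ])
    def test_matches_sklearn_on_random_tables(self, scheme, sk_weights):
        rng = np.random.default_rng(20260920)
        for _ in range(25):
            table = random_table(rng)
            pairs = table.to_pairs()
            expected = cohen_kappa_score(
                pairs.a, pairs.b, labels=list(range(1, table.K + 1)),
                weights=sk_weights,
            )
            got = cohen_kappa(table, scheme).estimate
            if math.isnan(expected):
                assert not math.isfinite(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_custom_weight_matrix_matches_named_scheme(self, item1_table):
        w = kappa_weight_matrix(5, "quadratic")
        assert cohen_kappa(item1_table, w).estimate == pytest.approx(
            cohen_kappa(item1_table, "quadratic").estimate
        )


class TestKendallTauB:
    def test_example_pair_counts(self, item1_table):
        res = kendall_tau_b(item1_table)
        assert res.concordant == 6596
        assert res.discordant == 5140
        assert res.n0 == 506 * 505 // 2
        assert res.estimate == pytest.approx(0.0381125, abs=1e-5)
        assert round_half_up(res.estimate, 2) == 0.04

    def test_staircase_table_is_1(self):
        t = ContingencyTable(np.diag([4, 6, 2, 8]), RatingScale(4))
        assert kendall_tau_b(t).estimate == pytest.approx(1.0)

    def test_tied_margin_undefined(self):
        t = ContingencyTable([[3, 4], [0, 0]], RatingScale(2))
        res = kendall_tau_b(t)
        assert not res.defined

    def test_matches_brute_force_enumeration(self):
        """Cell-block sums equal naive O(n^2) pair counting."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 50:
            table = random_table(rng, n_max=60)
            pairs = table.to_pairs()
            res = kendall_tau_b(table)
            if not res.defined:
                continue
            assert res.estimate == pytest.approx(
                brute_force_tau_b(pairs.a, pairs.b), abs=1e-12
            )
            checked += 1

    def test_matches_scipy_estimate_and_p(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 20:
            table = random_table(rng)
            if table.n < 3:  # scipy's asymptotic variance needs n >= 3
                continue
            checked += 1
            res = kendall_tau_b(table)
            pairs = table.to_pairs()
            ref = sps.kendalltau(pairs.a, pairs.b, method="asymptotic")
            if not res.defined:
                assert math.isnan(ref.statistic)
                continue
            assert res.estimate == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestMarginalHomogeneity:
    def test_example_collapsed_z(self, item1_table):
        coll = collapse_categories(item1_table, [(1,), (2,), (3, 4, 5)])
        res = marginal_homogeneity_test(coll)
        # numerator 171, denominator sqrt(267) from the collapsed counts
        assert res.statistic == pytest.approx(171 / math.sqrt(267))
        assert round_half_up(res.statistic, 2) == 10.47
        assert res.p_value < 0.001

    def test_symmetric_table_is_zero(self):
        t = ContingencyTable([[5, 2, 1], [2, 9, 4], [1, 4, 3]], RatingScale(3))
        assert marginal_homogeneity_test(t).statistic == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_under_transpose(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng)
        res = marginal_homogeneity_test(table)
        res_t = marginal_homogeneity_test(table.transpose())
        if res.defined:
            assert res_t.statistic == pytest.approx(-res.statistic)
        else:
            assert not res_t.defined

    def test_2x2_squares_to_uncorrected_mcnemar(self):
        """On 2x2 tables Z^2 = (b-c)^2/(b+c), the uncorrected McNemar chi2."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = random_table(rng, K=2)
            res = marginal_homogeneity_test(t)
            if not res.defined:
                continue
            ref = mcnemar(t.counts, exact=False, correction=False)
            assert res.statistic**2 == pytest.approx(ref.statistic)

    def test_no_discordance_undefined(self):
        t = ContingencyTable(np.diag([5, 3]), RatingScale(2))
        res = marginal_homogeneity_test(t)
        assert not res.defined
        assert "discordant" in res.note

    def test_stuart_maxwell_alternative_labelled(self, item1_table):
        coll = collapse_categories(item1_table, [(1,), (2,), (3, 4, 5)])
        res = stuart_maxwell_test(coll)
        assert "Stuart-Maxwell" in res.method_label
        assert res.p_value < 0.001


class TestWilcoxon:
    def test_all_zero_differences_undefined(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert not res.defined
        assert res.median_diff == 0.0
        assert res.p_value is None

    @pytest.mark.parametrize("n", range(5, 13))
    def test_normal_approx_close_to_exact_permutation(self, n):
        """Approximate vs exact permutation p, exhaustively over every

        attainable statistic for small untied samples.  The approximation
        is within 0.02 of the exact p wherever the p-value carries
        decision information (exact p <= 0.25) and, from n = 9 on,
        everywhere; in the lumpy centre of the tiniest null
        distributions it stays within 0.04."""
        pmf = wilcoxon_null_distribution(n)
        mu = n * (n + 1) / 4.0
        support = np.arange(len(pmf))
        for w in support:
            p_exact = float(pmf[np.abs(support - mu) >= abs(w - mu) - 1e-9].sum())
            d = signed_ranks_for_statistic(n, int(w))
            x = np.zeros(n) + d  # x - y = d with y = 0
            res = wilcoxon_signed_rank(x, np.zeros(n))
            gap = abs(res.p_value - p_exact)
            assert gap <= 0.04
            if p_exact <= 0.25 or n >= 9:
                assert gap <= 0.02

    def test_null_distribution_oracle_self_consistent(self):
        """The convolution pmf agrees with direct 2^n enumeration."""
        n = 8
        pmf = wilcoxon_null_distribution(n)
        mu = n * (n + 1) / 4.0
        support = np.arange(len(pmf))
        for w in (3, 10, 18):
            d = signed_ranks_for_statistic(n, w)
            p_direct = exact_wilcoxon_p(d)
            p_pmf = float(pmf[np.abs(support - mu) >= abs(w - mu) - 1e-9].sum())
            assert p_direct == pytest.approx(p_pmf, abs=1e-12)

    def test_pratt_counts_zeros_in_n_effective(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 1, 1, 6, 5])
        assert wilcoxon_signed_rank(x, y, "discard").n_effective == 3
        assert wilcoxon_signed_rank(x, y, "pratt").n_effective == 5

    @pytest.mark.parametrize("zero_policy", ["discard", "pratt"])
    def test_matches_scipy_p_values(self, zero_policy):
        rng = np.random.default_rng(55)
        zero_method = {"discard": "wilcox", "pratt": "pratt"}[zero_policy]
        for _ in range(20):
            n = int(rng.integers(8, 40))
            x = rng.integers(1, 6, n).astype(float)
            y = rng.integers(1, 6, n).astype(float)
            if not np.any(x != y):
                continue
            res = wilcoxon_signed_rank(x, y, zero_policy, correction=False)
            ref = sps.wilcoxon(x, y, zero_method=zero_method,
                               correction=False, method="approx")
            if not res.defined:
                continue
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert abs(res.statistic) == pytest.approx(abs(ref.zstatistic), abs=1e-10)

    def test_sign_follows_a_minus_b(self):
        x = np.arange(1.0, 11)
        res = wilcoxon_signed_rank(x + 1, x)  # x+1 > x everywhere
        assert res.statistic > 0
        assert res.median_diff == 1.0


class TestEffectSize:
    @pytest.mark.parametrize("z,n,expected", [
        (3.0, 100, 0.30),
        (0.0, 17, 0.0),
        (-4.56, 44, 0.687),
    ])
    def test_closed_form(self, z, n, expected):
        assert wilcoxon_effect_size(z, n) == pytest.approx(expected, abs=5e-4)

    def test_rejects_n_zero(self):
        with pytest.raises(ValueError):
            wilcoxon_effect_size(1.0, 0)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.06, 0.09]
        )
        assert bonferroni_adjust([1.0]) == pytest.approx([1.0])
        assert bonferroni_adjust([0.4] * 4) == pytest.approx([1.0] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5, 1.2])


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (0.125, 2, 0.13),   # half-up, not banker's
        (55.335968, 1, 55.3),
        (-0.915, 2, -0.92),  # ties away from zero
        (10.465, 2, 10.47),
    ])
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected
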