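"""Chi-square / Fisher risk-factor association and the test-selection rule."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from miascreen.association_tests import (
    ContingencyTable,
    DegenerateTableError,
    TestKind,
    UnsupportedShapeError,
    associate,
    chi_square_test,
    crosstab,
    expected_counts,
    fisher_exact_2x2,
    select_test,
)

# Published risk-factor tables: (malignant, benign) counts per category.
MENOPAUSE = [[6, 106], [24, 14]]
PARITY = [[8, 40], [4, 50], [18, 30]]
FAMILY_HISTORY = [[29, 113], [1, 7]]
OCP = [[27, 114], [3, 6]]
FERTILITY = [[28, 112], [2, 8]]
SMOKING = [[29, 116], [1, 4]]
BREASTFEEDING = [[8, 42], [22, 78]]
BMI = [[0, 18], [14, 38], [16, 64]]


def _t(counts):
    return ContingencyTable.from_array(counts)


def _fisher_oracle(counts):
    """Brute-force two-sided Fisher p by exact rational enumeration of every
    table with the observed margins (sum-of-small-point-probabilities)."""
    (a, b), (c, d) = counts
    row0, col0, n = a + b, a + c, a + b + c + d

    def point_prob(x):
        if x < 0 or x > row0 or col0 - x < 0 or col0 - x > n - row0:
            return Fraction(0)
        return Fraction(
            math.comb(row0, x) * math.comb(n - row0, col0 - x), math.comb(n, col0)
        )

    p_obs = point_prob(a)
    return float(
        sum(p for x in range(n + 1) if (p := point_prob(x)) <= p_obs)
    )


class TestExpectedCounts:
    def test_family_history_smallest_cell(self):
        expected = expected_counts(_t(FAMILY_HISTORY))
        assert expected.min() == pytest.approx(8 * 30 / 150)  # 1.6

    def test_menopause_smallest_cell(self):
        assert expected_counts(_t(MENOPAUSE)).min() == pytest.approx(38 * 30 / 150)

    def test_uniform_table(self):
        assert np.allclose(expected_counts(_t([[5, 5], [5, 5]])), 5.0)

    def test_margins_preserved(self):
        observed = np.array(PARITY)
        expected = expected_counts(_t(PARITY))
        assert np.allclose(expected.sum(axis=0), observed.sum(axis=0))
        assert np.allclose(expected.sum(axis=1), observed.sum(axis=1))


class TestSelectTest:
    @pytest.mark.parametrize(
        "counts, expected_kind",
        [
            (FAMILY_HISTORY, TestKind.FISHER_EXACT),
            (OCP, TestKind.FISHER_EXACT),
            (FERTILITY, TestKind.FISHER_EXACT),
            (SMOKING, TestKind.FISHER_EXACT),
            (MENOPAUSE, TestKind.CHI_SQUARE),
            (PARITY, TestKind.CHI_SQUARE),
            (BREASTFEEDING, TestKind.CHI_SQUARE),
            # one of six expected counts (16.7%) below 5 does not exceed 20%
            (BMI, TestKind.CHI_SQUARE),
        ],
    )
    def test_published_selection_pattern(self, counts, expected_kind):
        assert select_test(_t(counts)) is expected_kind

    def test_exactly_20_percent_small_cells_keeps_chi_square(self):
        # 5x2 table with exactly 2 of 10 expected counts below 5
        counts = [[2, 2], [20, 20], [20, 20], [20, 20], [20, 20]]
        expected = expected_counts(_t(counts))
        assert (expected < 5).mean() == pytest.approx(0.2)
        assert select_test(_t(counts)) is TestKind.CHI_SQUARE

    def test_large_sparse_table_unsupported(self):
        with pytest.raises(UnsupportedShapeError):
            select_test(_t([[1, 1, 1], [1, 1, 1]]))


class TestChiSquare:
    @pytest.mark.parametrize(
        "counts, expected_p",
        [(BREASTFEEDING, 0.386), (PARITY, 0.001), (BMI, 0.048)],
    )
    def test_published_p_values(self, counts, expected_p):
        assert round(chi_square_test(_t(counts)).p_value, 3) == expected_p

    def test_menopause_highly_significant(self):
        result = chi_square_test(_t(MENOPAUSE))
        assert result.p_value < 0.001
        assert result.df == 1

    def test_no_continuity_correction(self):
        """The statistic is the raw Pearson sum, matching scipy without
        Yates correction."""
        result = chi_square_test(_t(BREASTFEEDING))
        scipy_stat = stats.chi2_contingency(BREASTFEEDING, correction=False)[0]
        yates_stat = stats.chi2_contingency(BREASTFEEDING, correction=True)[0]
        assert result.statistic == pytest.approx(scipy_stat)
        assert result.statistic != pytest.approx(yates_stat)

    def test_proportional_rows_give_null(self):
        result = chi_square_test(_t([[10, 20], [20, 40]]))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_permutation_invariance_and_scaling(self):
        base = chi_square_test(_t(PARITY))
        permuted = chi_square_test(_t([PARITY[2], PARITY[0], PARITY[1]]))
        assert permuted.statistic == pytest.approx(base.statistic)
        flipped = chi_square_test(_t([row[::-1] for row in PARITY]))
        assert flipped.statistic == pytest.approx(base.statistic)
        tripled = chi_square_test(_t([[3 * c for c in row] for row in PARITY]))
        assert tripled.statistic == pytest.approx(3 * base.statistic)

    def test_zero_expected_count_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test(_t([[0, 5], [0, 5]]))


class TestFisherExact:
    @pytest.mark.parametrize(
        "counts, expected_p",
        [(OCP, 0.384), (FAMILY_HISTORY, 1.0), (FERTILITY, 1.0), (SMOKING, 1.0)],
    )
    def test_published_p_values(self, counts, expected_p):
        assert round(fisher_exact_2x2(_t(counts)).p_value, 3) == expected_p

    def test_zero_margin_single_table(self):
        assert fisher_exact_2x2(_t([[0, 0], [3, 7]])).p_value == pytest.approx(1.0)

    def test_non_2x2_rejected(self):
        with pytest.raises(UnsupportedShapeError):
            fisher_exact_2x2(_t(PARITY))

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    def test_agrees_with_rational_enumeration_oracle(self, a, b, c, d):
        """Exact-fraction enumeration of all margin-preserving tables
        (n <= 60) matches to floating-point accuracy."""
        if a + b + c + d == 0:
            return
        counts = [[a, b], [c, d]]
        ours = fisher_exact_2x2(_t(counts)).p_value
        assert ours == pytest.approx(_fisher_oracle(counts), rel=1e-9, abs=1e-12)

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    def test_agrees_with_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        counts = [[a, b], [c, d]]
        theirs = stats.fisher_exact(counts, alternative="two-sided")[1]
        assert fisher_exact_2x2(_t(counts)).p_value == pytest.approx(theirs, rel=1e-7)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_two_sided_at_least_smaller_one_sided_tail(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        counts = [[a, b], [c, d]]
        two = fisher_exact_2x2(_t(counts)).p_value
        less = stats.fisher_exact(counts, alternative="less")[1]
        greater = stats.fisher_exact(counts, alternative="greater")[1]
        assert two >= min(less, greater) - 1e-12

    def test_hypergeometric_pmf_sums_to_one(self):
        """Support mass of the conditional distribution for random margins."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 501))
            row0 = int(rng.integers(1, n))
            col0 = int(rng.integers(1, n))
            lo = max(0, row0 + col0 - n)
            hi = min(row0, col0)
            support = np.arange(lo, hi + 1)
            total = stats.hypergeom(n, col0, row0).pmf(support).sum()
            assert total == pytest.approx(1.0, abs=1e-12)


class TestAssociateAndCrosstab:
    def test_associate_dispatches_by_rule(self):
        assert associate(_t(OCP)).test_used is TestKind.FISHER_EXACT
        assert associate(_t(PARITY)).test_used is TestKind.CHI_SQUARE

    def test_crosstab_reproduces_published_tables(self, reference_cohort):
        for variable, counts in [
            ("menopausal_status", MENOPAUSE),
            ("parity", PARITY),
            ("family_history_ca", FAMILY_HISTORY),
            ("ocp_use", OCP),
            ("fertility_drugs", FERTILITY),
            ("smoking", SMOKING),
            ("breastfeeding", BREASTFEEDING),
            ("bmi", BMI),
        ]:
            table = crosstab(reference_cohort, variable)
            assert [list(row) for row in table.counts] == counts, variable

    def test_unknown_variable_rejected(self, reference_cohort):
        with pytest.raises(KeyError):
            crosstab(reference_cohort, "coffee")
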