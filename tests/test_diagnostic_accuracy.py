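"""Confusion tables, accuracy metrics, exact McNemar, reconstruction."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from miascreen.cohort_model import Histopathology
from miascreen.diagnostic_accuracy import (
    ConfusionTable,
    InconsistentSummaryError,
    StageGroup,
    accuracy_metrics,
    confusion_table,
    evaluate_test,
    mcnemar_exact,
    reconstruct_confusion,
    stage_subset,
)


def _mcnemar_oracle(b, c):
    """Exact rational two-sided binomial tail, independent of scipy."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(Fraction(math.comb(n, i), 2**n) for i in range(k + 1))
    return float(min(Fraction(1), 2 * tail))


class TestConfusionTable:
    def test_counts_joint_outcomes(self):
        calls = [True, True, False, False, True]
        truth = [True, False, True, False, True]
        ct = confusion_table(calls, truth)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (2, 1, 1, 1)
        assert ct.total == 5

    def test_accepts_histopathology_enum(self):
        ct = confusion_table(
            [True, False], [Histopathology.MALIGNANT, Histopathology.BENIGN]
        )
        assert (ct.tp, ct.tn) == (1, 1)

    def test_degenerate_tests(self):
        truth = [True] * 3 + [False] * 7
        all_neg = confusion_table([False] * 10, truth)
        assert (all_neg.tp, all_neg.fp, all_neg.fn, all_neg.tn) == (0, 0, 3, 7)
        identity = confusion_table(truth, truth)
        assert (identity.tp, identity.fp, identity.fn, identity.tn) == (3, 0, 0, 7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            confusion_table([True], [True, False])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(tp=-1, fp=0, fn=0, tn=0)


class TestAccuracyMetrics:
    def test_early_stage_study_cells(self):
        report = accuracy_metrics(ConfusionTable(tp=8, fp=4, fn=0, tn=116))
        assert report.sensitivity == pytest.approx(100.0)
        assert report.specificity == pytest.approx(96.7, abs=0.05)

    def test_study_mia_cells(self):
        report = accuracy_metrics(ConfusionTable(tp=21, fp=4, fn=9, tn=116))
        assert report.sensitivity == pytest.approx(70.0)
        assert report.ppv == pytest.approx(84.0)
        assert report.npv == pytest.approx(92.8, abs=0.05)
        assert report.total_agreement == pytest.approx(91.3, abs=0.05)

    def test_zero_denominator_is_absent_not_zero(self):
        report = accuracy_metrics(ConfusionTable(tp=0, fp=0, fn=0, tn=10))
        assert report.sensitivity is None
        assert report.ppv is None
        assert report.specificity == pytest.approx(100.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy_metrics(ConfusionTable(tp=0, fp=0, fn=0, tn=0))


class TestMcnemarExact:
    @pytest.mark.parametrize(
        "b, c, expected",
        [(4, 9, 0.267), (20, 5, 0.004), (17, 9, 0.169), (0, 0, 1.0), (4, 0, 0.125)],
    )
    def test_reference_values(self, b, c, expected):
        p = mcnemar_exact(ConfusionTable(tp=0, fp=b, fn=c, tn=0))
        assert round(p, 3) == expected

    def test_agrees_with_rational_oracle_all_small_tables(self):
        """Brute-force exact-fraction binomial tail for every b + c <= 20."""
        for n in range(21):
            for b in range(n + 1):
                c = n - b
                p = mcnemar_exact(ConfusionTable(tp=1, fp=b, fn=c, tn=2))
                assert p == pytest.approx(_mcnemar_oracle(b, c), rel=1e-12)

    def test_agrees_with_statsmodels(self):
        """Independent cross-check against the exact McNemar of statsmodels."""
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(4, 9), (20, 5), (17, 9), (1, 0), (10, 10)]:
            ours = mcnemar_exact(ConfusionTable(tp=0, fp=b, fn=c, tn=0))
            theirs = float(sm_mcnemar([[0, b], [c, 0]], exact=True).pvalue)
            assert ours == pytest.approx(theirs, rel=1e-9)

    @given(st.integers(0, 40), st.integers(0, 40))
    def test_symmetric_in_discordant_cells(self, b, c):
        p1 = mcnemar_exact(ConfusionTable(tp=0, fp=b, fn=c, tn=0))
        p2 = mcnemar_exact(ConfusionTable(tp=0, fp=c, fn=b, tn=0))
        assert p1 == p2
        if b == c:
            assert p1 == 1.0


class TestStageSubset:
    def test_study_cohort_sizes(self, reference_cohort):
        assert len(stage_subset(reference_cohort, StageGroup.EARLY)) == 128
        assert len(stage_subset(reference_cohort, StageGroup.LATE)) == 142
        assert len(stage_subset(reference_cohort, StageGroup.ALL)) == 150

    def test_retains_full_benign_arm(self, reference_cohort):
        early = stage_subset(reference_cohort, StageGroup.EARLY)
        assert sum(not r.malignant for r in early) == 120
        assert all(r.figo_stage.value in ("I", "II") for r in early if r.malignant)

    def test_no_malignant_cases(self, reference_cohort):
        benign_only = [r for r in reference_cohort if not r.malignant]
        assert stage_subset(benign_only, StageGroup.EARLY) == benign_only


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "summary, cells",
        [
            ((150, 30, 25, 91.3), (21, 4, 9, 116)),   # index assay
            ((150, 30, 45, 83.3), (25, 20, 5, 100)),  # CA 125
            ((150, 30, 38, 82.7), (21, 17, 9, 103)),  # clinician
            ((100, 20, 20, 100.0), (20, 0, 0, 80)),   # perfect test
        ],
    )
    def test_recovers_unique_integer_solution(self, summary, cells):
        ct = reconstruct_confusion(*summary)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == cells

    def test_study_mia_summaries_verify_against_all_printed_metrics(self):
        ct = reconstruct_confusion(150, 30, 25, 91.3)
        report = accuracy_metrics(ct)
        assert round(report.sensitivity, 1) == 70.0
        assert round(report.specificity, 1) == 96.7
        assert round(report.ppv, 1) == 84.0
        assert round(report.npv, 1) == 92.8

    def test_inconsistent_summaries_rejected(self):
        with pytest.raises(InconsistentSummaryError):
            reconstruct_confusion(150, 30, 25, 40.0)  # agreement too low
        with pytest.raises(InconsistentSummaryError):
            reconstruct_confusion(10, 20, 5, 50.0)  # marginal exceeds total

    @given(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    )
    def test_round_trip_identity(self, tp, fp, fn, tn):
        """accuracy_metrics then reconstruct_confusion recovers the cells."""
        if tp + fp + fn + tn == 0:
            return
        ct = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
        agreement = round(accuracy_metrics(ct).total_agreement, 1)
        recovered = reconstruct_confusion(
            ct.total, ct.n_malignant, ct.n_test_positive, agreement
        )
        assert recovered == ct

    def test_round_trip_identity_random_tables(self):
        """1000 random tables with n <= 500 survive the summary round-trip."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            cells = rng.multinomial(int(rng.integers(1, 501)), [0.25] * 4)
            ct = ConfusionTable(*(int(c) for c in cells))
            agreement = round(accuracy_metrics(ct).total_agreement, 1)
            assert (
                reconstruct_confusion(
                    ct.total, ct.n_malignant, ct.n_test_positive, agreement
                )
                == ct
            )


class TestEvaluateTest:
    def test_combines_metrics_and_mcnemar(self):
        truth = [True] * 30 + [False] * 120
        calls = [True] * 21 + [False] * 9 + [True] * 4 + [False] * 116
        report = evaluate_test(calls, truth)
        assert round(report.sensitivity, 1) == 70.0
        assert round(report.mcnemar_p, 3) == 0.267
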