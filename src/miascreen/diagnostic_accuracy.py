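"""Screening-test accuracy against the histopathology gold standard.

Confusion tables, the standard accuracy metrics (sensitivity, specificity,
predictive values, total agreement), the exact McNemar test on the
discordant cells, FIGO-stage-stratified subsets, and reconstruction of a
2x2 table's integer cells from published summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

from scipy import stats

from .cohort_model import FigoStage, Histopathology, PatientRecord

__all__ = [
    "ConfusionTable",
    "AccuracyReport",
    "StageGroup",
    "InconsistentSummaryError",
    "confusion_table",
    "accuracy_metrics",
    "mcnemar_exact",
    "evaluate_test",
    "stage_subset",
    "reconstruct_confusion",
]


class InconsistentSummaryError(ValueError):
    """Published summary statistics admit no non-negative integer 2x2 table."""


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cells of a screening test scored against histopathology.

    tp: test-positive & malignant; fp: test-positive & benign;
    fn: test-negative & malignant; tn: test-negative & benign.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_malignant(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.fp + self.tn

    @property
    def n_test_positive(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy metrics as percentages; None marks an undefined ratio
    (zero denominator), never silently 0 or 100."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    total_agreement: float
    mcnemar_p: float | None = None


class StageGroup(str, Enum):
    EARLY = "early"  # FIGO I-II
    LATE = "late"    # FIGO III-IV
    ALL = "all"


_EARLY_STAGES = frozenset({FigoStage.I, FigoStage.II})
_LATE_STAGES = frozenset({FigoStage.III, FigoStage.IV})


def confusion_table(
    test_calls: Sequence[bool],
    truth: Sequence[Histopathology | bool],
) -> ConfusionTable:
    """Cross-tabulate paired test calls against the gold standard.

    ``truth`` entries may be Histopathology values or booleans
    (True = malignant).
    """
    if len(test_calls) != len(truth):
        raise ValueError(
            f"test_calls ({len(test_calls)}) and truth ({len(truth)}) "
            f"must have equal length"
        )
    tp = fp = fn = tn = 0
    for call, outcome in zip(test_calls, truth):
        malignant = (
            outcome is Histopathology.MALIGNANT
            if isinstance(outcome, Histopathology)
            else bool(outcome)
        )
        if call and malignant:
            tp += 1
        elif call:
            fp += 1
        elif malignant:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _pct(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator


def accuracy_metrics(ct: ConfusionTable) -> AccuracyReport:
    """Sensitivity TP/(TP+FN), specificity TN/(FP+TN), PPV TP/(TP+FP),
    NPV TN/(FN+TN), total agreement (TP+TN)/n — all x100."""
    if ct.total == 0:
        raise ValueError("empty confusion table")
    return AccuracyReport(
        sensitivity=_pct(ct.tp, ct.tp + ct.fn),
        specificity=_pct(ct.tn, ct.fp + ct.tn),
        ppv=_pct(ct.tp, ct.tp + ct.fp),
        npv=_pct(ct.tn, ct.fn + ct.tn),
        total_agreement=100.0 * (ct.tp + ct.tn) / ct.total,
    )


def mcnemar_exact(ct: ConfusionTable) -> float:
    """Exact two-sided McNemar test on the discordant cells.

    Against the gold standard the discordant cells are the false positives
    (b) and false negatives (c).  Under the null the smaller count is
    binomial(b + c, 1/2); the two-sided p is twice the smaller tail, capped
    at 1.  With no discordant pairs p = 1.
    """
    b, c = ct.fp, ct.fn
    n = b + c
    if n == 0:
        return 1.0
    return min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))


def evaluate_test(
    test_calls: Sequence[bool],
    truth: Sequence[Histopathology | bool],
) -> AccuracyReport:
    """Confusion table, accuracy metrics and exact McNemar p in one step."""
    ct = confusion_table(test_calls, truth)
    return replace(accuracy_metrics(ct), mcnemar_p=mcnemar_exact(ct))


def stage_subset(
    cohort: Sequence[PatientRecord], group: StageGroup
) -> list[PatientRecord]:
    """Stage-restricted analysis set: malignant cases of the requested FIGO
    group pooled with ALL benign cases (never a case-only subset)."""
    if group is StageGroup.ALL:
        return list(cohort)
    stages = _EARLY_STAGES if group is StageGroup.EARLY else _LATE_STAGES
    return [
        r
        for r in cohort
        if r.histopathology is Histopathology.BENIGN or r.figo_stage in stages
    ]


def reconstruct_confusion(
    n_total: int,
    n_disease_pos: int,
    n_test_pos: int,
    agreement_pct: float,
) -> ConfusionTable:
    """Recover the integer 2x2 cells from published summary counts.

    Given the cohort size, the number of malignant cases, the number of
    test positives and the printed total agreement percentage, the cells
    are determined by the linear system

        tp + fp = n_test_pos,  tp + fn = n_disease_pos,
        tp + tn = round(agreement_pct / 100 * n_total),
        tp + fp + fn + tn = n_total,

    which gives tp = (agree + n_test_pos + n_disease_pos - n_total) / 2.
    Because the printed agreement is rounded, the integer agreement count is
    searched in a +/-1 neighborhood of the naive rounding; the solution
    whose recomputed agreement matches the printed value to 1 decimal place
    is returned.
    """
    if n_total <= 0:
        raise InconsistentSummaryError("n_total must be positive")
    if not (0 <= n_disease_pos <= n_total and 0 <= n_test_pos <= n_total):
        raise InconsistentSummaryError("marginals exceed the cohort size")
    target = agreement_pct / 100.0 * n_total
    violations: list[str] = []
    for agree in sorted(
        {int(round(target)) + d for d in (-1, 0, 1)}
    ):
        if not 0 <= agree <= n_total:
            continue
        numerator = agree + n_test_pos + n_disease_pos - n_total
        if numerator % 2 != 0:
            violations.append(f"agreement count {agree} gives non-integer tp")
            continue
        tp = numerator // 2
        fp = n_test_pos - tp
        fn = n_disease_pos - tp
        tn = n_total - tp - fp - fn
        if min(tp, fp, fn, tn) < 0:
            violations.append(
                f"agreement count {agree} gives negative cell "
                f"(tp={tp}, fp={fp}, fn={fn}, tn={tn})"
            )
            continue
        recomputed = round(100.0 * (tp + tn) / n_total, 1)
        if recomputed == round(agreement_pct, 1):
            return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
        violations.append(
            f"agreement count {agree} recomputes to {recomputed}% "
            f"!= printed {round(agreement_pct, 1)}%"
        )
    raise InconsistentSummaryError(
        "no consistent non-negative integer table: " + "; ".join(violations)
    )
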