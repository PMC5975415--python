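"""Risk-factor association tests on r x c contingency tables.

Pearson chi-square (no continuity correction) with the small-expected-count
rule: when more than 20% of the cells have expected count below 5, the 2x2
chi-square approximation is replaced by Fisher's exact test (two-sided,
sum-of-small-point-probabilities convention).  A significance level of
p <= 0.05 is used for report flagging.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import expected_freq

from .cohort_model import (
    Histopathology,
    PatientRecord,
    classify_breastfeeding,
)

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "TestKind",
    "UnsupportedShapeError",
    "DegenerateTableError",
    "expected_counts",
    "select_test",
    "chi_square_test",
    "fisher_exact_2x2",
    "associate",
    "crosstab",
    "RISK_FACTOR_VARIABLES",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05
SMALL_EXPECTED_CUTOFF = 5.0
SMALL_CELL_FRACTION = 0.20  # strictly more than 20% of cells -> exact test
_FISHER_REL_TOL = 1e-7  # guard on the <= comparison of point probabilities


class TestKind(str, Enum):
    __test__ = False  # not a pytest class

    CHI_SQUARE = "chi_square"
    FISHER_EXACT = "fisher_exact"


class UnsupportedShapeError(ValueError):
    """Fisher's exact test is only provided for 2x2 tables."""


class DegenerateTableError(ValueError):
    """A zero expected count makes the chi-square statistic undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts with axis labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"table must be at least 2x2, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("grand total must be positive")
        if self.row_labels and len(self.row_labels) != arr.shape[0]:
            raise ValueError("row_labels length does not match row count")
        if self.col_labels and len(self.col_labels) != arr.shape[1]:
            raise ValueError("col_labels length does not match column count")

    @classmethod
    def from_array(
        cls,
        counts: Sequence[Sequence[int]],
        row_labels: Sequence[str] = (),
        col_labels: Sequence[str] = (),
    ) -> "ContingencyTable":
        return cls(
            counts=tuple(tuple(int(c) for c in row) for row in counts),
            row_labels=tuple(row_labels),
            col_labels=tuple(col_labels),
        )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.to_array().shape


@dataclass(frozen=True)
class AssociationResult:
    p_value: float
    test_used: TestKind
    statistic: float | None = None  # chi-square value; absent for Fisher
    df: int | None = None           # (r-1)(c-1); absent for Fisher

    @property
    def significant(self) -> bool:
        return self.p_value <= SIGNIFICANCE_LEVEL


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts E[i][j] = row_total[i] * col_total[j] / n."""
    return expected_freq(table.to_array())


def select_test(table: ContingencyTable) -> TestKind:
    """The small-sample rule: Fisher's exact test when strictly more than
    20% of expected counts fall below 5, otherwise Pearson chi-square."""
    expected = expected_counts(table)
    small_fraction = float((expected < SMALL_EXPECTED_CUTOFF).mean())
    if small_fraction > SMALL_CELL_FRACTION:
        if table.shape != (2, 2):
            raise UnsupportedShapeError(
                f"exact test required (expected counts below "
                f"{SMALL_EXPECTED_CUTOFF} in {small_fraction:.0%} of cells) "
                f"but table shape {table.shape} is not 2x2"
            )
        return TestKind.FISHER_EXACT
    return TestKind.CHI_SQUARE


def chi_square_test(table: ContingencyTable) -> AssociationResult:
    """Pearson chi-square of association, without Yates correction."""
    observed = table.to_array()
    expected = expected_counts(table)
    if (expected == 0).any():
        raise DegenerateTableError(
            "a zero expected count makes the chi-square statistic undefined"
        )
    statistic = float(((observed - expected) ** 2 / expected).sum())
    r, c = observed.shape
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(statistic, df))
    return AssociationResult(
        p_value=p, test_used=TestKind.CHI_SQUARE, statistic=statistic, df=df
    )


def fisher_exact_2x2(table: ContingencyTable) -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Conditioning on both margins, the first cell follows a hypergeometric
    distribution; the two-sided p sums the point probabilities of every
    table (with the observed margins) no more probable than the observed
    one.  A small relative tolerance on that comparison avoids excluding
    ties through floating-point error.  A zero margin leaves a single
    possible table, so p = 1.
    """
    if table.shape != (2, 2):
        raise UnsupportedShapeError(
            f"Fisher exact test supports only 2x2 tables, got {table.shape}"
        )
    observed = table.to_array()
    n = int(observed.sum())
    row0 = int(observed[0].sum())
    col0 = int(observed[:, 0].sum())
    a = int(observed[0, 0])
    dist = stats.hypergeom(n, col0, row0)
    lo = max(0, row0 + col0 - n)
    hi = min(row0, col0)
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_REL_TOL)].sum())
    return AssociationResult(p_value=min(1.0, p), test_used=TestKind.FISHER_EXACT)


def associate(table: ContingencyTable) -> AssociationResult:
    """Apply the small-expected-count rule and run the selected test."""
    if select_test(table) is TestKind.FISHER_EXACT:
        return fisher_exact_2x2(table)
    return chi_square_test(table)


# (label, category labels, extractor returning a category label)
RISK_FACTOR_VARIABLES: dict[str, tuple[tuple[str, ...], object]] = {
    "menopausal_status": (
        ("premenopausal", "postmenopausal"),
        lambda r: r.menopausal_status.value,
    ),
    "parity": (
        ("nulliparous", "multiparous", "grand_multiparous"),
        lambda r: r.parity_class.value,
    ),
    "family_history_ca": (
        ("negative", "positive"),
        lambda r: "positive" if r.family_history_ca else "negative",
    ),
    "ocp_use": (
        ("negative", "positive"),
        lambda r: "positive" if r.ocp_use else "negative",
    ),
    "fertility_drugs": (
        ("negative", "positive"),
        lambda r: "positive" if r.fertility_drugs else "negative",
    ),
    "smoking": (
        ("negative", "positive"),
        lambda r: "positive" if r.smoking else "negative",
    ),
    "breastfeeding": (
        ("< 6 months", ">= 6 months"),
        lambda r: classify_breastfeeding(r.breastfeeding_months),
    ),
    "bmi": (
        ("normal", "overweight", "obese"),
        lambda r: r.bmi_class.value,
    ),
}


def crosstab(records: Sequence[PatientRecord], variable: str) -> ContingencyTable:
    """Build the <variable categories> x <malignant, benign> table for one
    of the named risk factors."""
    if variable not in RISK_FACTOR_VARIABLES:
        raise KeyError(
            f"unknown variable {variable!r}; expected one of "
            f"{sorted(RISK_FACTOR_VARIABLES)}"
        )
    categories, extract = RISK_FACTOR_VARIABLES[variable]
    counts = {cat: [0, 0] for cat in categories}
    for record in records:
        column = 0 if record.histopathology is Histopathology.MALIGNANT else 1
        counts[extract(record)][column] += 1
    return ContingencyTable.from_array(
        [counts[cat] for cat in categories],
        row_labels=categories,
        col_labels=("malignant", "benign"),
    )
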