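"""One-command reproduction of the full study analysis.

Given a cohort CSV (or records in memory), computes the risk-factor
association table, the histopathology subtype distribution, per-test
positive/negative marginals, accuracy reports against histopathology,
stage-stratified accuracy (early = FIGO I-II, late = III-IV, each pooled
with the full benign arm), and the stage distribution of malignant cases.

All internal computation is full precision; rounding (percentages to 1
decimal place, p-values to 3, rendered as "< 0.001" below 0.0005) happens
only at render time.  Every association row logs its expected-count matrix
and which test the small-expected-count rule selected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association_tests import (
    AssociationResult,
    RISK_FACTOR_VARIABLES,
    associate,
    crosstab,
    expected_counts,
    select_test,
)
from .cohort_model import Histopathology, PatientRecord, read_cohort
from .diagnostic_accuracy import (
    AccuracyReport,
    ConfusionTable,
    StageGroup,
    accuracy_metrics,
    confusion_table,
    evaluate_test,
    mcnemar_exact,
    stage_subset,
)
from .marker_rules import (
    DEFAULT_THRESHOLDS,
    MarkerThresholds,
    ca125_classify,
    combine_parallel,
    mia_classify,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StudyReport",
    "TEST_NAMES",
    "classify_cohort",
    "build_study_report",
    "run_study",
    "stage_distribution",
    "subtype_frequencies",
    "format_percent",
    "format_p_value",
    "report_to_json",
    "render_text",
    "write_report",
]

TEST_NAMES = ("mia", "ca125", "gynecologist", "mia_or_clinical")

_TEST_LABELS = {
    "mia": "MIA",
    "ca125": "CA 125",
    "gynecologist": "Gynecologist's assessment",
    "mia_or_clinical": "MIA and/or Clinical",
}


def format_percent(value: float | None) -> str:
    return "-" if value is None else f"{value:.1f}"


def format_p_value(p: float | None) -> str:
    if p is None:
        return "-"
    if p < 0.0005:
        return "< 0.001"
    return f"{p:.3f}"


@dataclass(frozen=True)
class RunConfig:
    """Inputs of one pipeline run."""

    input_path: str | Path
    thresholds_path: str | Path | None = None
    tests: tuple[str, ...] = TEST_NAMES
    output_dir: str | Path | None = None
    formats: tuple[str, ...] = ("text", "json")

    def __post_init__(self) -> None:
        unknown = set(self.tests) - set(TEST_NAMES)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}")
        if not self.tests:
            raise ValueError("at least one test must be selected")
        bad_formats = set(self.formats) - {"text", "json", "csv"}
        if bad_formats:
            raise ValueError(f"unknown report formats {sorted(bad_formats)}")
        if not self.formats:
            raise ValueError("at least one report format must be selected")


@dataclass(frozen=True)
class RiskFactorRow:
    variable: str
    categories: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]  # (malignant, benign) per category
    result: AssociationResult


@dataclass(frozen=True)
class StageStratumReport:
    """Accuracy of each test on one stage stratum (malignant cases of the
    stratum pooled with all benign cases)."""

    group: StageGroup
    n_malignant: int
    n_benign: int
    tables: Mapping[str, ConfusionTable]
    reports: Mapping[str, AccuracyReport]


@dataclass(frozen=True)
class StudyReport:
    n_patients: int
    n_malignant: int
    risk_factors: tuple[RiskFactorRow, ...]
    subtype_distribution: tuple[tuple[str, int, float], ...]
    test_marginals: Mapping[str, tuple[int, int]]  # test -> (positive, negative)
    confusions: Mapping[str, ConfusionTable]
    test_accuracy: Mapping[str, AccuracyReport]
    early_stage: StageStratumReport
    late_stage: StageStratumReport
    stage_percentages: tuple[float, float, float, float]


def classify_cohort(
    records: Sequence[PatientRecord],
    thresholds: MarkerThresholds = DEFAULT_THRESHOLDS,
    tests: Sequence[str] = TEST_NAMES,
) -> dict[str, list[bool]]:
    """Per-patient boolean calls for each requested test.

    The parallel combination is computed from the per-patient OR of the
    index assay and the clinician impression, never from marginal algebra.
    """
    calls: dict[str, list[bool]] = {}
    mia_calls = [
        mia_classify(r.markers, r.menopausal_status, thresholds).high_risk
        for r in records
    ]
    if "mia" in tests:
        calls["mia"] = mia_calls
    if "ca125" in tests:
        calls["ca125"] = [
            ca125_classify(r.markers.ca125, r.menopausal_status, thresholds)
            for r in records
        ]
    if "gynecologist" in tests:
        calls["gynecologist"] = [r.gynecologist_malignant for r in records]
    if "mia_or_clinical" in tests:
        calls["mia_or_clinical"] = [
            combine_parallel(m, r.gynecologist_malignant)
            for m, r in zip(mia_calls, records)
        ]
    return calls


def stage_distribution(
    records: Sequence[PatientRecord], decimals: int | None = None
) -> tuple[float, float, float, float]:
    """Percentage of malignant cases per FIGO stage I-IV."""
    staged = [r.figo_stage for r in records if r.figo_stage is not None]
    if not staged:
        raise ValueError("stage distribution requires at least one malignant case")
    from .cohort_model import FigoStage

    pcts = tuple(
        100.0 * sum(s is stage for s in staged) / len(staged)
        for stage in (FigoStage.I, FigoStage.II, FigoStage.III, FigoStage.IV)
    )
    if decimals is not None:
        pcts = tuple(round(p, decimals) for p in pcts)
    return pcts  # type: ignore[return-value]


def subtype_frequencies(
    records: Sequence[PatientRecord],
) -> list[tuple[str, int, float]]:
    """Histopathology subtype counts, descending, alphabetical tie-break;
    percentages of the whole cohort."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.histopathology_subtype] = counts.get(r.histopathology_subtype, 0) + 1
    total = len(records)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, n, 100.0 * n / total) for name, n in ordered]


def _stage_stratum(
    records: Sequence[PatientRecord],
    calls: Mapping[str, Sequence[bool]],
    group: StageGroup,
    tests: Sequence[str],
) -> StageStratumReport:
    index = {id(r): i for i, r in enumerate(records)}
    subset = stage_subset(records, group)
    truth = [r.malignant for r in subset]
    tables: dict[str, ConfusionTable] = {}
    reports: dict[str, AccuracyReport] = {}
    for test in tests:
        subset_calls = [calls[test][index[id(r)]] for r in subset]
        ct = confusion_table(subset_calls, truth)
        tables[test] = ct
        report = accuracy_metrics(ct)
        reports[test] = AccuracyReport(
            sensitivity=report.sensitivity,
            specificity=report.specificity,
            ppv=report.ppv,
            npv=report.npv,
            total_agreement=report.total_agreement,
            mcnemar_p=mcnemar_exact(ct),
        )
    return StageStratumReport(
        group=group,
        n_malignant=sum(truth),
        n_benign=len(truth) - sum(truth),
        tables=tables,
        reports=reports,
    )


def build_study_report(
    records: Sequence[PatientRecord],
    thresholds: MarkerThresholds = DEFAULT_THRESHOLDS,
    tests: Sequence[str] = TEST_NAMES,
) -> StudyReport:
    """Compute every study table from per-patient records."""
    if not records:
        raise ValueError("empty cohort")
    truth = [r.malignant for r in records]
    calls = classify_cohort(records, thresholds, tests)

    risk_rows = []
    for variable in RISK_FACTOR_VARIABLES:
        table = crosstab(records, variable)
        expected = expected_counts(table)
        chosen = select_test(table)
        logger.info(
            "risk factor %s: expected counts %s -> %s",
            variable,
            np.round(expected, 2).tolist(),
            chosen.value,
        )
        risk_rows.append(
            RiskFactorRow(
                variable=variable,
                categories=table.row_labels,
                counts=tuple((row[0], row[1]) for row in table.counts),
                result=associate(table),
            )
        )

    confusions = {t: confusion_table(calls[t], truth) for t in tests}
    accuracy = {t: evaluate_test(calls[t], truth) for t in tests}
    marginals = {
        t: (confusions[t].n_test_positive, len(records) - confusions[t].n_test_positive)
        for t in tests
    }
    stage_tests = tuple(t for t in ("ca125", "mia") if t in tests) or tuple(tests)
    return StudyReport(
        n_patients=len(records),
        n_malignant=sum(truth),
        risk_factors=tuple(risk_rows),
        subtype_distribution=tuple(subtype_frequencies(records)),
        test_marginals=marginals,
        confusions=confusions,
        test_accuracy=accuracy,
        early_stage=_stage_stratum(records, calls, StageGroup.EARLY, stage_tests),
        late_stage=_stage_stratum(records, calls, StageGroup.LATE, stage_tests),
        stage_percentages=stage_distribution(records),
    )


def run_study(config: RunConfig) -> StudyReport:
    """Read a cohort CSV, compute the report, and (optionally) write it."""
    thresholds = (
        MarkerThresholds.from_yaml(config.thresholds_path)
        if config.thresholds_path
        else DEFAULT_THRESHOLDS
    )
    records = read_cohort(config.input_path)
    report = build_study_report(records, thresholds, config.tests)
    if config.output_dir is not None:
        write_report(report, config.output_dir, config.formats)
    return report


# --------------------------------------------------------------------------
# rendering


def _accuracy_dict(report: AccuracyReport) -> dict[str, str]:
    return {
        "sensitivity": format_percent(report.sensitivity),
        "specificity": format_percent(report.specificity),
        "ppv": format_percent(report.ppv),
        "npv": format_percent(report.npv),
        "total_agreement": format_percent(report.total_agreement),
        "p": format_p_value(report.mcnemar_p),
    }


def report_to_json(report: StudyReport) -> str:
    """Deterministic JSON rendering (sorted keys, rounded at render time)."""
    payload = {
        "n_patients": report.n_patients,
        "n_malignant": report.n_malignant,
        "risk_factors": [
            {
                "variable": row.variable,
                "categories": list(row.categories),
                "counts": [list(c) for c in row.counts],
                "test_used": row.result.test_used.value,
                "statistic": (
                    None
                    if row.result.statistic is None
                    else round(row.result.statistic, 3)
                ),
                "df": row.result.df,
                "p": format_p_value(row.result.p_value),
                "significant": row.result.significant,
            }
            for row in report.risk_factors
        ],
        "subtype_distribution": [
            {"subtype": name, "n": n, "percent": round(pct, 1)}
            for name, n, pct in report.subtype_distribution
        ],
        "test_marginals": {
            test: {"positive": pos, "negative": neg}
            for test, (pos, neg) in report.test_marginals.items()
        },
        "confusions": {test: asdict(ct) for test, ct in report.confusions.items()},
        "test_accuracy": {
            test: _accuracy_dict(acc) for test, acc in report.test_accuracy.items()
        },
        "early_stage": _stratum_payload(report.early_stage),
        "late_stage": _stratum_payload(report.late_stage),
        "stage_percentages": [round(p) for p in report.stage_percentages],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def _stratum_payload(stratum: StageStratumReport) -> dict:
    return {
        "group": stratum.group.value,
        "n_malignant": stratum.n_malignant,
        "n_benign": stratum.n_benign,
        "confusions": {t: asdict(ct) for t, ct in stratum.tables.items()},
        "accuracy": {t: _accuracy_dict(a) for t, a in stratum.reports.items()},
    }


def render_text(report: StudyReport) -> str:
    """Plain-text rendering mirroring the published table layout."""
    lines: list[str] = []
    lines.append(
        f"Cohort: {report.n_patients} patients, "
        f"{report.n_malignant} malignant "
        f"({format_percent(100 * report.n_malignant / report.n_patients)}%)"
    )
    lines.append("")
    lines.append("Risk-factor association with histopathology")
    for row in report.risk_factors:
        flag = "*" if row.result.test_used.value == "fisher_exact" else ""
        lines.append(
            f"  {row.variable}: p = {format_p_value(row.result.p_value)}{flag}"
        )
        for cat, (mal, ben) in zip(row.categories, row.counts):
            total = mal + ben
            mal_pct = format_percent(100 * mal / total) if total else "-"
            lines.append(f"    {cat}: malignant {mal} ({mal_pct}%), benign {ben}")
    lines.append("  (* by Fisher's exact test)")
    lines.append("")
    lines.append("Histopathological diagnoses")
    for name, n, pct in report.subtype_distribution:
        lines.append(f"  {name}: {n} ({format_percent(pct)}%)")
    lines.append("")
    lines.append("Test results (positive / negative)")
    for test, (pos, neg) in report.test_marginals.items():
        pct = format_percent(100 * pos / report.n_patients)
        lines.append(f"  {_TEST_LABELS[test]}: {pos} ({pct}%) / {neg}")
    lines.append("")
    lines.append(
        "Validity vs histopathology "
        "(sensitivity / specificity / PPV / NPV / agreement / McNemar p)"
    )
    for test, acc in report.test_accuracy.items():
        d = _accuracy_dict(acc)
        lines.append(
            f"  {_TEST_LABELS[test]}: {d['sensitivity']} / {d['specificity']} / "
            f"{d['ppv']} / {d['npv']} / {d['total_agreement']} / {d['p']}"
        )
    for stratum, label in (
        (report.early_stage, "Early stage (FIGO I-II)"),
        (report.late_stage, "Late stage (FIGO III-IV)"),
    ):
        lines.append("")
        lines.append(
            f"{label}: {stratum.n_malignant} malignant + "
            f"{stratum.n_benign} benign"
        )
        for test, acc in stratum.reports.items():
            d = _accuracy_dict(acc)
            ct = stratum.tables[test]
            lines.append(
                f"  {_TEST_LABELS[test]}: tp {ct.tp}, fp {ct.fp}, fn {ct.fn}, "
                f"tn {ct.tn}; sensitivity {d['sensitivity']}%, "
                f"specificity {d['specificity']}%, p {d['p']}"
            )
    lines.append("")
    stage_pct = " / ".join(f"{round(p)}%" for p in report.stage_percentages)
    lines.append(f"Stage distribution of malignant cases (I/II/III/IV): {stage_pct}")
    return "\n".join(lines) + "\n"


def write_report(
    report: StudyReport,
    output_dir: str | Path,
    formats: Sequence[str] = ("text", "json"),
) -> list[Path]:
    """Write the report to disk; returns the paths written."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = output_dir / "report.json"
        path.write_text(report_to_json(report), encoding="utf-8")
        written.append(path)
    if "text" in formats:
        path = output_dir / "report.txt"
        path.write_text(render_text(report), encoding="utf-8")
        written.append(path)
    if "csv" in formats:
        frames = {
            "risk_factors.csv": pd.DataFrame(
                [
                    {
                        "variable": row.variable,
                        "category": cat,
                        "malignant": mal,
                        "benign": ben,
                        "test_used": row.result.test_used.value,
                        "p": row.result.p_value,
                    }
                    for row in report.risk_factors
                    for cat, (mal, ben) in zip(row.categories, row.counts)
                ]
            ),
            "subtypes.csv": pd.DataFrame(
                report.subtype_distribution,
                columns=["subtype", "n", "percent"],
            ),
            "test_accuracy.csv": pd.DataFrame(
                [
                    {
                        "test": test,
                        "tp": report.confusions[test].tp,
                        "fp": report.confusions[test].fp,
                        "fn": report.confusions[test].fn,
                        "tn": report.confusions[test].tn,
                        "sensitivity": acc.sensitivity,
                        "specificity": acc.specificity,
                        "ppv": acc.ppv,
                        "npv": acc.npv,
                        "total_agreement": acc.total_agreement,
                        "mcnemar_p": acc.mcnemar_p,
                    }
                    for test, acc in report.test_accuracy.items()
                ]
            ),
        }
        for name, frame in frames.items():
            path = output_dir / name
            frame.to_csv(path, index=False)
            written.append(path)
    return written
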