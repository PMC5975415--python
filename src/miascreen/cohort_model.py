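"""Typed cohort records, categorical derivations, and CSV input/output.

The unit of analysis is one enrolled woman with an ovarian mass scheduled
for surgery: demographics and risk factors, the five serum biomarkers of
the multivariate index assay, the gynecologist's pre-operative impression,
and the surgical histopathology that serves as the gold standard.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MenopausalStatus",
    "Histopathology",
    "FigoStage",
    "ParityClass",
    "BmiClass",
    "MarkerPanel",
    "PatientRecord",
    "CohortValidationError",
    "CohortSchemaError",
    "derive_menopausal_status",
    "classify_parity",
    "classify_bmi",
    "classify_breastfeeding",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]


class MenopausalStatus(str, Enum):
    PREMENOPAUSAL = "premenopausal"
    POSTMENOPAUSAL = "postmenopausal"


class Histopathology(str, Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class FigoStage(str, Enum):
    """FIGO surgical stage of ovarian cancer; I-II early, III-IV late."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class ParityClass(str, Enum):
    NULLIPAROUS = "nulliparous"          # parity 0
    MULTIPAROUS = "multiparous"          # parity 1-4
    GRAND_MULTIPAROUS = "grand_multiparous"  # parity >= 5


class BmiClass(str, Enum):
    NORMAL = "normal"        # BMI < 25
    OVERWEIGHT = "overweight"  # 25 <= BMI < 30
    OBESE = "obese"          # BMI >= 30


class CohortValidationError(ValueError):
    """A record (or CSV row) violates the cohort invariants."""


class CohortSchemaError(ValueError):
    """A cohort CSV file does not match the documented column schema."""


MARKER_NAMES = ("ca125", "b2m", "transferrin", "apoa1", "prealbumin")


@dataclass(frozen=True)
class MarkerPanel:
    """The five serum markers of the index assay, as measured.

    ca125 in IU/L (numerically identical to the U/ml convention for CA 125);
    the four protein markers in g/L.  Any marker may be missing (None).
    """

    ca125: float | None = None
    b2m: float | None = None
    transferrin: float | None = None
    apoa1: float | None = None
    prealbumin: float | None = None

    def __post_init__(self) -> None:
        for name in MARKER_NAMES:
            value = getattr(self, name)
            if value is not None and not value >= 0:
                raise CohortValidationError(
                    f"marker {name} must be non-negative, got {value!r}"
                )

    def missing(self) -> tuple[str, ...]:
        """Names of markers without a measured value."""
        return tuple(n for n in MARKER_NAMES if getattr(self, n) is None)


def derive_menopausal_status(
    months_since_last_menses: int | None,
    age: int,
    unsure: bool = False,
) -> MenopausalStatus:
    """Menopausal status from the reported menstrual history.

    Postmenopausal means absence of menses for at least 12 months; when the
    woman is unsure of her menses, age >= 50 years is used instead.  A record
    with unknown months but the unsure flag not set is contradictory and
    rejected rather than imputed.
    """
    if age < 18:
        raise CohortValidationError(f"age must be >= 18, got {age}")
    if months_since_last_menses is None and not unsure:
        raise CohortValidationError(
            "months_since_last_menses is unknown but menses_unsure is false"
        )
    post = (
        months_since_last_menses is not None and months_since_last_menses >= 12
    ) or (unsure and age >= 50)
    return MenopausalStatus.POSTMENOPAUSAL if post else MenopausalStatus.PREMENOPAUSAL


def classify_parity(parity: int) -> ParityClass:
    """Nulliparous (0), multiparous (1-4), grand multiparous (>= 5)."""
    if parity < 0:
        raise CohortValidationError(f"parity must be >= 0, got {parity}")
    if parity == 0:
        return ParityClass.NULLIPAROUS
    if parity <= 4:
        return ParityClass.MULTIPAROUS
    return ParityClass.GRAND_MULTIPAROUS


def classify_bmi(bmi: float) -> BmiClass:
    """WHO-style classes: <25 normal, [25, 30) overweight, >=30 obese."""
    if not bmi > 0:
        raise CohortValidationError(f"bmi must be positive, got {bmi}")
    if bmi < 25:
        return BmiClass.NORMAL
    if bmi < 30:
        return BmiClass.OVERWEIGHT
    return BmiClass.OBESE


def classify_breastfeeding(months: float) -> str:
    """Dichotomy used in the risk-factor analysis; 6.0 falls in '>= 6'."""
    if months < 0:
        raise CohortValidationError(f"breastfeeding months must be >= 0, got {months}")
    return ">= 6 months" if months >= 6 else "< 6 months"


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: int
    months_since_last_menses: int | None
    menses_unsure: bool
    parity: int
    bmi: float
    family_history_ca: bool
    ocp_use: bool
    fertility_drugs: bool
    smoking: bool
    breastfeeding_months: float
    markers: MarkerPanel
    gynecologist_malignant: bool
    histopathology: Histopathology
    histopathology_subtype: str = ""
    figo_stage: FigoStage | None = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise CohortValidationError(
                f"patient {self.patient_id}: age must be >= 18, got {self.age}"
            )
        if self.parity < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: parity must be >= 0"
            )
        if not self.bmi > 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: bmi must be positive"
            )
        if self.breastfeeding_months < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: breastfeeding_months must be >= 0"
            )
        malignant = self.histopathology is Histopathology.MALIGNANT
        if malignant != (self.figo_stage is not None):
            raise CohortValidationError(
                f"patient {self.patient_id}: figo_stage must be present iff "
                f"histopathology is malignant"
            )
        # fail fast on contradictory menstrual history
        derive_menopausal_status(
            self.months_since_last_menses, self.age, self.menses_unsure
        )

    @property
    def menopausal_status(self) -> MenopausalStatus:
        return derive_menopausal_status(
            self.months_since_last_menses, self.age, self.menses_unsure
        )

    @property
    def parity_class(self) -> ParityClass:
        return classify_parity(self.parity)

    @property
    def bmi_class(self) -> BmiClass:
        return classify_bmi(self.bmi)

    @property
    def malignant(self) -> bool:
        return self.histopathology is Histopathology.MALIGNANT


COHORT_COLUMNS = (
    "patient_id",
    "age",
    "months_since_last_menses",
    "menses_unsure",
    "parity",
    "bmi",
    "family_history_ca",
    "ocp_use",
    "fertility_drugs",
    "smoking",
    "breastfeeding_months",
    "ca125",
    "b2m",
    "transferrin",
    "apoa1",
    "prealbumin",
    "gynecologist_malignant",
    "histopathology",
    "subtype",
    "figo_stage",
)

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(text: str, column: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise CohortValidationError(f"column {column}: invalid boolean {text!r}")


def _fmt_bool(value: bool) -> str:
    return "true" if value else "false"


def _fmt_float(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def _record_from_row(row: dict[str, str]) -> PatientRecord:
    def opt_float(col: str) -> float | None:
        text = row[col].strip()
        return None if text == "" else float(text)

    months_text = row["months_since_last_menses"].strip()
    stage_text = row["figo_stage"].strip()
    histo_text = row["histopathology"].strip().lower()
    try:
        histopathology = Histopathology(histo_text)
    except ValueError:
        raise CohortValidationError(
            f"invalid histopathology value {row['histopathology']!r}"
        ) from None
    if stage_text:
        try:
            figo_stage: FigoStage | None = FigoStage(stage_text.upper())
        except ValueError:
            raise CohortValidationError(
                f"invalid figo_stage value {row['figo_stage']!r}"
            ) from None
    else:
        figo_stage = None
    return PatientRecord(
        patient_id=row["patient_id"].strip(),
        age=int(row["age"]),
        months_since_last_menses=None if months_text == "" else int(months_text),
        menses_unsure=_parse_bool(row["menses_unsure"], "menses_unsure"),
        parity=int(row["parity"]),
        bmi=float(row["bmi"]),
        family_history_ca=_parse_bool(row["family_history_ca"], "family_history_ca"),
        ocp_use=_parse_bool(row["ocp_use"], "ocp_use"),
        fertility_drugs=_parse_bool(row["fertility_drugs"], "fertility_drugs"),
        smoking=_parse_bool(row["smoking"], "smoking"),
        breastfeeding_months=float(row["breastfeeding_months"]),
        markers=MarkerPanel(
            ca125=opt_float("ca125"),
            b2m=opt_float("b2m"),
            transferrin=opt_float("transferrin"),
            apoa1=opt_float("apoa1"),
            prealbumin=opt_float("prealbumin"),
        ),
        gynecologist_malignant=_parse_bool(
            row["gynecologist_malignant"], "gynecologist_malignant"
        ),
        histopathology=histopathology,
        histopathology_subtype=row["subtype"].strip(),
        figo_stage=figo_stage,
    )


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV (schema in COHORT_COLUMNS).

    Raises CohortSchemaError if columns are missing, or a
    CohortValidationError listing every invalid row with its 1-based data
    row number.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise CohortSchemaError(f"{path}: empty file, header row required")
        missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortSchemaError(f"{path}: missing required columns {missing}")
        records: list[PatientRecord] = []
        problems: list[str] = []
        for index, row in enumerate(reader, start=1):
            try:
                records.append(_record_from_row(row))
            except (CohortValidationError, ValueError) as exc:
                problems.append(f"row {index}: {exc}")
        if problems:
            raise CohortValidationError(
                f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems)
            )
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to CSV; floats use shortest round-trip representation."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.age,
                    "" if r.months_since_last_menses is None else r.months_since_last_menses,
                    _fmt_bool(r.menses_unsure),
                    r.parity,
                    repr(float(r.bmi)),
                    _fmt_bool(r.family_history_ca),
                    _fmt_bool(r.ocp_use),
                    _fmt_bool(r.fertility_drugs),
                    _fmt_bool(r.smoking),
                    repr(float(r.breastfeeding_months)),
                    _fmt_float(r.markers.ca125),
                    _fmt_float(r.markers.b2m),
                    _fmt_float(r.markers.transferrin),
                    _fmt_float(r.markers.apoa1),
                    _fmt_float(r.markers.prealbumin),
                    _fmt_bool(r.gynecologist_malignant),
                    r.histopathology.value,
                    r.histopathology_subtype,
                    "" if r.figo_stage is None else r.figo_stage.value,
                ]
            )
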