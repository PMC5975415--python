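"""Synthetic reconstruction of the modelled 150-patient study cohort.

The study this package models published only summary tables — risk-factor
contingency counts, per-test positive/negative marginals, accuracy
percentages, and stage-stratified cells — never per-patient data.  Those
summaries, however, pin down the integer 2x2 cells of every test (via
:func:`miascreen.diagnostic_accuracy.reconstruct_confusion`), and this
module builds a fully explicit SYNTHETIC cohort of 150 patient records
whose per-patient pipeline results reproduce every published count exactly:

* 30 malignant / 120 benign, FIGO stages 4/4/11/11 (I/II/III/IV);
* index-assay confusion (tp 21, fp 4, fn 9, tn 116), all 8 early-stage
  cancers assay-positive, 13 of 22 late-stage;
* CA 125 confusion (25, 20, 5, 100) with 6/8 early and 19/22 late positive;
* gynecologist confusion (21, 17, 9, 103), overlapping the assay on
  14 malignant and 0 benign patients so the parallel combination scores
  28/30 sensitivity and 99/120 specificity;
* every risk-factor row (menopause 24/30 vs 14/120 postmenopausal, parity
  8/4/18 vs 40/50/30, BMI 0/14/16 vs 18/38/64, ...) and the subtype
  frequency table.

Joint structure the summaries do not constrain (e.g. which individual
benign patients are clinician false positives) is fixed by an arbitrary
deterministic assignment; marker values are synthetic round numbers chosen
on the correct side of each patient's thresholds, not measured levels.
"""

from __future__ import annotations

from .cohort_model import (
    FigoStage,
    Histopathology,
    MarkerPanel,
    MenopausalStatus,
    PatientRecord,
)
from .marker_rules import DEFAULT_THRESHOLDS, MarkerThresholds

__all__ = [
    "STUDY_N",
    "STUDY_N_MALIGNANT",
    "TEST_POSITIVES",
    "TOTAL_AGREEMENT_PCT",
    "RISK_FACTOR_COUNTS",
    "build_reference_cohort",
]

STUDY_N = 150
STUDY_N_MALIGNANT = 30

# Published per-test positive counts (of 150) and total agreement (%),
# from which the 2x2 cells are uniquely reconstructible.
TEST_POSITIVES = {"gynecologist": 38, "ca125": 45, "mia": 25}
TOTAL_AGREEMENT_PCT = {
    "gynecologist": 82.7,
    "ca125": 83.3,
    "mia": 91.3,
    "mia_or_clinical": 84.7,
}

# Published risk-factor table: variable -> (category -> (malignant, benign)).
RISK_FACTOR_COUNTS = {
    "menopausal_status": {"premenopausal": (6, 106), "postmenopausal": (24, 14)},
    "parity": {
        "nulliparous": (8, 40),
        "multiparous": (4, 50),
        "grand_multiparous": (18, 30),
    },
    "family_history_ca": {"negative": (29, 113), "positive": (1, 7)},
    "ocp_use": {"negative": (27, 114), "positive": (3, 6)},
    "fertility_drugs": {"negative": (28, 112), "positive": (2, 8)},
    "smoking": {"negative": (29, 116), "positive": (1, 4)},
    "breastfeeding": {"< 6 months": (8, 42), ">= 6 months": (22, 78)},
    "bmi": {"normal": (0, 18), "overweight": (14, 38), "obese": (16, 64)},
}

_MALIGNANT_STAGES = (
    [FigoStage.I] * 4 + [FigoStage.II] * 4 + [FigoStage.III] * 11 + [FigoStage.IV] * 11
)
_MALIGNANT_SUBTYPES = (
    ["serous cystadenocarcinoma"] * 14
    + ["endometrioid adenocarcinoma"] * 8
    + ["mucinous cystadenocarcinoma"] * 3
    + ["Krukenberg's tumor"] * 3
    + ["granulosa cell cancer"] * 2
)
_BENIGN_SUBTYPES = (
    ["serous cystadenoma"] * 45
    + ["dermoid"] * 28
    + ["endometrioma"] * 18
    + ["mucinous cystadenoma"] * 16
    + ["hemorrhagic luteal cyst"] * 7
    + ["follicular cyst"] * 6
)


def _panel(
    mia_positive: bool,
    ca125_positive: bool,
    status: MenopausalStatus,
    thresholds: MarkerThresholds,
) -> MarkerPanel:
    """Synthetic marker values that force the requested calls.

    CA 125 sits at 1.5x (positive) or 0.5x (negative) the patient's own
    menopause-specific cutoff; the protein markers are placed just outside
    or inside their limits so the panel vote lands exactly at 3 positives
    (high risk) or at most 1 (low risk).
    """
    cutoff = thresholds.ca125_upper(status)
    ca125 = cutoff * (1.5 if ca125_positive else 0.5)
    normal = dict(b2m=2.0, transferrin=3.0, apoa1=1.6, prealbumin=0.25)
    if mia_positive:
        normal["b2m"] = 3.0          # above upper limit -> positive
        normal["transferrin"] = 1.5  # below lower limit -> positive
        if not ca125_positive:
            normal["apoa1"] = 1.0    # third vote when CA 125 is negative
    return MarkerPanel(ca125=ca125, **normal)


def _record(
    patient_id: str,
    *,
    malignant: bool,
    stage: FigoStage | None,
    subtype: str,
    postmenopausal: bool,
    parity: int,
    bmi: float,
    family_history: bool,
    ocp: bool,
    fertility: bool,
    smoking: bool,
    breastfeeding: float,
    mia_positive: bool,
    ca125_positive: bool,
    gyn_positive: bool,
    thresholds: MarkerThresholds,
) -> PatientRecord:
    status = (
        MenopausalStatus.POSTMENOPAUSAL
        if postmenopausal
        else MenopausalStatus.PREMENOPAUSAL
    )
    return PatientRecord(
        patient_id=patient_id,
        age=55 if postmenopausal else 35,
        months_since_last_menses=24 if postmenopausal else 3,
        menses_unsure=False,
        parity=parity,
        bmi=bmi,
        family_history_ca=family_history,
        ocp_use=ocp,
        fertility_drugs=fertility,
        smoking=smoking,
        breastfeeding_months=breastfeeding,
        markers=_panel(mia_positive, ca125_positive, status, thresholds),
        gynecologist_malignant=gyn_positive,
        histopathology=(
            Histopathology.MALIGNANT if malignant else Histopathology.BENIGN
        ),
        histopathology_subtype=subtype,
        figo_stage=stage,
    )


def build_reference_cohort(
    thresholds: MarkerThresholds = DEFAULT_THRESHOLDS,
) -> list[PatientRecord]:
    """The deterministic synthetic cohort matching every published summary.

    Running the full pipeline (marker classification, accuracy evaluation,
    stage stratification, risk-factor association) on these records
    reproduces the published tables cell for cell.
    """
    records: list[PatientRecord] = []
    # --- malignant arm (index i = 0..29) -------------------------------
    # MIA positive: all 8 early + first 13 late (i < 21).
    # CA 125 positive: first 6 early + late i in 8..26 (19 of 22).
    # Gynecologist positive: i < 14 (14 of the 21 MIA+) and 21 <= i < 28
    # (7 of the 9 MIA-) -> union with MIA covers 28 of 30.
    for i in range(30):
        early = i < 8
        mia_pos = i < 21
        ca_pos = (i < 6) if early else (8 <= i < 27)
        gyn_pos = i < 14 or 21 <= i < 28
        records.append(
            _record(
                f"M{i + 1:03d}",
                malignant=True,
                stage=_MALIGNANT_STAGES[i],
                subtype=_MALIGNANT_SUBTYPES[i],
                postmenopausal=i < 24,
                parity=0 if i < 8 else (2 if i < 12 else 6),
                bmi=27.0 if i < 14 else 32.0,
                family_history=i < 1,
                ocp=i < 3,
                fertility=i < 2,
                smoking=i < 1,
                breastfeeding=12.0 if i < 22 else 3.0,
                mia_positive=mia_pos,
                ca125_positive=ca_pos,
                gyn_positive=gyn_pos,
                thresholds=thresholds,
            )
        )
    # --- benign arm (index j = 0..119) ---------------------------------
    # MIA false positives: j < 4 (also CA 125 positive); CA 125 false
    # positives: j < 20; gynecologist false positives: 4 <= j < 21
    # (disjoint from the MIA false positives, so the parallel combination
    # is positive on 21 benign patients).
    for j in range(120):
        records.append(
            _record(
                f"B{j + 1:03d}",
                malignant=False,
                stage=None,
                subtype=_BENIGN_SUBTYPES[j],
                postmenopausal=j < 14,
                parity=0 if j < 40 else (2 if j < 90 else 6),
                bmi=22.0 if j < 18 else (27.0 if j < 56 else 32.0),
                family_history=j < 7,
                ocp=j < 6,
                fertility=j < 8,
                smoking=j < 4,
                breastfeeding=12.0 if j < 78 else 3.0,
                mia_positive=j < 4,
                ca125_positive=j < 20,
                gyn_positive=4 <= j < 21,
                thresholds=thresholds,
            )
        )
    return records
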