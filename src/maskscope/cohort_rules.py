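"""Reference standard: inclusion rules and the four masking categories.

Included examinations fall in two groups.  Screen-detected: positive
screen with diagnosis within 12 months and a negative prior screen less
than 30 months before.  Interval: negative screen with an interval cancer
diagnosed within 24 months.  In situ, micro-invasive, metachronous and
bilateral cancers are excluded, as are first-round screenings, positives
without a known negative prior, and exams with breast implants.

Retrospective mass visibility then defines four masking categories:

    1  screen-detected, mass visible       -> low risk
    2  screen-detected, no visible mass    -> unknown risk
    3  interval cancer, mass visible       -> intermediate risk
    4  interval cancer, no visible mass    -> high risk

Analysis 1 contrasts categories {1,2} vs {3,4}; analysis 2 is the ordinal
contrast 1 < 3 < 4 with category 2 excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .errors import ValidationError

__all__ = [
    "CohortRecord",
    "MaskingCategory",
    "months_between",
    "classify_exam",
    "assign_masking_category",
    "build_analysis_sets",
    "CATEGORY_RISK_LABELS",
]

CATEGORY_RISK_LABELS = {1: "low", 2: "unknown", 3: "intermediate", 4: "high"}

#: Inclusion windows in whole months (boundary inclusive).
SCREEN_DETECTED_DX_WINDOW = 12
INTERVAL_DX_WINDOW = 24
PRIOR_NEGATIVE_WINDOW = 30
SUPPLEMENT_B_WINDOW = 12

_MEAN_MONTH_DAYS = 30.44


@dataclass
class CohortRecord:
    """One screening examination's metadata, timing and outcome."""

    exam_id: str
    screen_result: str                  # "positive" | "negative"
    months_to_diagnosis: int | None
    cancer_invasiveness: str = "invasive"   # invasive | in_situ | micro_invasive
    laterality_cancer: str = "unilateral"   # unilateral | bilateral
    metachronous: bool = False
    months_prior_negative: int | None = None  # months before exam; None = unknown
    first_round: bool = False
    mass_visible: str | bool | None = None    # yes | no | unknown
    age: float | None = None
    implant: bool = False


@dataclass(frozen=True)
class MaskingCategory:
    category: int
    risk_label: str


def months_between(earlier: date, later: date) -> int:
    """Whole-month difference, floor of day difference / 30.44."""
    days = (later - earlier).days
    if days < 0:
        raise ValidationError("dates out of order")
    return int(days // _MEAN_MONTH_DAYS)


def classify_exam(record: CohortRecord) -> str:
    """Classify a record as included group or an exclusion reason.

    Returns ``"screen_detected"``, ``"interval"`` or an exclusion reason
    string prefixed ``"excluded:"``.
    """
    if record.implant:
        return "excluded:implant"
    if record.cancer_invasiveness in ("in_situ", "micro_invasive"):
        return f"excluded:{record.cancer_invasiveness}"
    if record.metachronous:
        return "excluded:metachronous"
    if record.laterality_cancer == "bilateral":
        return "excluded:bilateral"
    m = record.months_to_diagnosis
    if m is not None and m < 0:
        raise ValidationError("diagnosis precedes the examination")
    if record.screen_result == "positive":
        if record.first_round:
            return "excluded:first_round"
        if record.months_prior_negative is None:
            return "excluded:no_known_prior"
        if not 0 < record.months_prior_negative < PRIOR_NEGATIVE_WINDOW:
            return "excluded:prior_too_old"
        if m is None or m > SCREEN_DETECTED_DX_WINDOW:
            return "excluded:late_diagnosis"
        return "screen_detected"
    if record.screen_result == "negative":
        if m is None or m > INTERVAL_DX_WINDOW:
            return "excluded:not_interval_window"
        return "interval"
    raise ValidationError(f"unknown screen_result: {record.screen_result!r}")


def assign_masking_category(group: str, mass_visible) -> MaskingCategory | None:
    """Four-category masking classification; None when visibility unknown."""
    if isinstance(mass_visible, str):
        if mass_visible == "unknown":
            return None
        visible = mass_visible == "yes"
    else:
        visible = bool(mass_visible)
    if group == "screen_detected":
        cat = 1 if visible else 2
    elif group == "interval":
        cat = 3 if visible else 4
    else:
        raise ValidationError(f"not an included group: {group!r}")
    return MaskingCategory(category=cat, risk_label=CATEGORY_RISK_LABELS[cat])


def build_analysis_sets(
    records: pd.DataFrame, supplement_b: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition records into the two analysis sets plus an exclusion log.

    Analysis 1: binary label (0 = screen-detected / assumed-low risk,
    1 = interval / assumed-high risk), all included exams.  Analysis 2:
    ordinal label in {1, 3, 4} (category 2 and unknown-visibility exams
    dropped).  ``supplement_b`` additionally restricts interval exams to
    diagnoses within 12 months.  Every input record lands in exactly one
    of {analysis 1, exclusion log}.
    """
    rows1, rows2, excl = [], [], []
    for _, row in records.iterrows():
        rec = CohortRecord(
            exam_id=row["exam_id"],
            screen_result=row["screen_result"],
            months_to_diagnosis=_maybe_int(row.get("months_to_diagnosis")),
            cancer_invasiveness=row.get("cancer_invasiveness", "invasive"),
            laterality_cancer=row.get("laterality_cancer", "unilateral"),
            metachronous=bool(row.get("metachronous", False)),
            months_prior_negative=_maybe_int(row.get("months_prior_negative")),
            first_round=bool(row.get("first_round", False)),
            mass_visible=row.get("mass_visible"),
            implant=bool(row.get("implant", False)),
        )
        outcome = classify_exam(rec)
        if outcome.startswith("excluded:"):
            excl.append({"exam_id": rec.exam_id, "reason": outcome.split(":", 1)[1]})
            continue
        if (
            supplement_b
            and outcome == "interval"
            and rec.months_to_diagnosis > SUPPLEMENT_B_WINDOW
        ):
            excl.append({"exam_id": rec.exam_id, "reason": "supplement_b_window"})
            continue
        label1 = 0 if outcome == "screen_detected" else 1
        cat = (
            assign_masking_category(outcome, rec.mass_visible)
            if rec.mass_visible is not None
            else None
        )
        entry = dict(row)
        entry.update(group=outcome, label=label1,
                     category=cat.category if cat else None,
                     risk_label=cat.risk_label if cat else None)
        rows1.append(entry)
        if cat is not None and cat.category != 2:
            rows2.append(entry)
    analysis1 = pd.DataFrame(rows1)
    analysis2 = pd.DataFrame(rows2)
    exclusion_log = pd.DataFrame(excl, columns=["exam_id", "reason"])
    return analysis1, analysis2, exclusion_log


def _maybe_int(value):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return int(value)
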