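"""Phenotype ground truth and per-patient DMD/BMD prediction rules.

Ground truth follows the ambulation-based operational definition: loss of
independent walking before 16 years is Duchenne (DMD); remaining ambulant
at or beyond 16 years is Becker (BMD).  Patients still walking but younger
than the cutoff cannot be labelled and are ``indeterminate``.

Three predictors are implemented:

* frame rule — out-of-frame events predict DMD, in-frame BMD;
* milestone rule — first independent walking at or after 18 months
  (a delayed walking-alone milestone) predicts DMD, earlier walking BMD;
* combined rule — predict DMD if *either* rule predicts DMD (logical OR
  on the DMD flags), BMD only when both defined rules say BMD.

The OR combination can only gain sensitivity and only lose specificity
relative to its components; in a cohort where no mild (BMD) case walks
late, specificity is untouched while frame-rule false negatives who walked
late are recovered.
"""

from __future__ import annotations

import enum
from collections import OrderedDict
from dataclasses import dataclass, field

from .gene_model import ExonTable, FrameStatus, VariantEvent, frame_status

__all__ = [
    "POINT_MUTATION",
    "PatientRecord",
    "PhenotypeLabel",
    "Prediction",
    "Rule",
    "apply_eligibility",
    "milestone_delayed",
    "phenotype_from_followup",
    "predict_cohort",
    "predict_combined",
    "predict_frame",
    "predict_milestone",
    "predict_patient",
]

#: Marker used in place of a :class:`VariantEvent` for point-mutation cases,
#: which the exon-level frame rule cannot score (they are excluded upstream).
POINT_MUTATION = "point_mutation"

DEFAULT_MILESTONE_THRESHOLD_MONTHS = 18.0
DEFAULT_PHENOTYPE_CUTOFF_YEARS = 16.0


class PhenotypeLabel(str, enum.Enum):
    DMD = "DMD"
    BMD = "BMD"
    INDETERMINATE = "indeterminate"


class Rule(str, enum.Enum):
    FRAME = "frame"
    MILESTONE = "milestone"
    COMBINED = "combined"


@dataclass(frozen=True)
class PatientRecord:
    """One study subject.

    Ages are in the units clinicians record them: the walking-alone
    milestone in months, everything else in years.  ``None`` means missing.
    ``variant`` is either an exon-level :class:`VariantEvent` or the
    :data:`POINT_MUTATION` marker.
    """

    patient_id: str
    sex: str  # "male" | "female"
    variant: VariantEvent | str
    first_walking_age_months: float | None = None
    onset_age_years: float | None = None
    diagnosis_age_years: float | None = None
    ck_u_per_l: float | None = None
    ambulation_lost: bool = False
    age_at_ambulation_loss_years: float | None = None
    age_at_last_followup_years: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (isinstance(self.variant, VariantEvent) or self.variant == POINT_MUTATION):
            raise ValueError(
                f"variant must be a VariantEvent or {POINT_MUTATION!r}, "
                f"got {self.variant!r}"
            )
        if self.ambulation_lost:
            if self.age_at_ambulation_loss_years is None:
                raise ValueError(
                    f"{self.patient_id}: ambulation_lost without age_at_ambulation_loss_years"
                )
            if self.age_at_ambulation_loss_years > self.age_at_last_followup_years:
                raise ValueError(
                    f"{self.patient_id}: ambulation loss at "
                    f"{self.age_at_ambulation_loss_years} y after last follow-up "
                    f"{self.age_at_last_followup_years} y"
                )
        walk = self.first_walking_age_months
        if walk is not None and not 6.0 < walk < 72.0:
            raise ValueError(
                f"{self.patient_id}: first_walking_age_months={walk} outside the "
                "plausible (6, 72) month window"
            )


@dataclass(frozen=True)
class Prediction:
    """A per-patient predicted label under one named rule."""

    patient_id: str
    rule: Rule
    predicted: PhenotypeLabel
    frame_status: FrameStatus
    milestone_delayed: bool | None


def phenotype_from_followup(
    record: PatientRecord,
    cutoff_years: float = DEFAULT_PHENOTYPE_CUTOFF_YEARS,
) -> PhenotypeLabel:
    """Ground-truth label from ambulation follow-up.

    DMD when ambulation was lost before ``cutoff_years``; BMD when the
    patient is still ambulant and has been followed to at least the cutoff;
    otherwise indeterminate (still walking, too young to call).
    """
    if record.ambulation_lost:
        if record.age_at_ambulation_loss_years < cutoff_years:
            return PhenotypeLabel.DMD
        return PhenotypeLabel.BMD
    if record.age_at_last_followup_years >= cutoff_years:
        return PhenotypeLabel.BMD
    return PhenotypeLabel.INDETERMINATE


def milestone_delayed(
    first_walking_age_months: float | None,
    threshold_months: float = DEFAULT_MILESTONE_THRESHOLD_MONTHS,
) -> bool | None:
    """Whether the walking-alone milestone is delayed (not walking by 18 mo).

    "Unable to walk alone until 18 months" is read inclusively: first
    walking at exactly the threshold counts as delayed.  A missing age
    returns ``None`` — unknown, never silently "not delayed".
    """
    if first_walking_age_months is None:
        return None
    if first_walking_age_months <= 0:
        raise ValueError(f"first_walking_age_months must be positive, got {first_walking_age_months}")
    return first_walking_age_months >= threshold_months


def predict_frame(status: FrameStatus) -> PhenotypeLabel:
    """Frame rule: out-of-frame events predict DMD, in-frame BMD."""
    if status is FrameStatus.OUT_OF_FRAME:
        return PhenotypeLabel.DMD
    if status is FrameStatus.IN_FRAME:
        return PhenotypeLabel.BMD
    return PhenotypeLabel.INDETERMINATE


def predict_milestone(delayed: bool | None) -> PhenotypeLabel:
    """Milestone rule: delayed walking predicts DMD, timely walking BMD."""
    if delayed is None:
        return PhenotypeLabel.INDETERMINATE
    return PhenotypeLabel.DMD if delayed else PhenotypeLabel.BMD


def predict_combined(
    frame_pred: PhenotypeLabel, milestone_pred: PhenotypeLabel
) -> PhenotypeLabel:
    """OR combination: DMD if either rule says DMD; BMD only if both
    defined rules say BMD; indeterminate when neither rule is defined."""
    preds = (frame_pred, milestone_pred)
    if PhenotypeLabel.DMD in preds:
        return PhenotypeLabel.DMD
    defined = [p for p in preds if p is not PhenotypeLabel.INDETERMINATE]
    if not defined:
        return PhenotypeLabel.INDETERMINATE
    return PhenotypeLabel.BMD


def predict_patient(
    record: PatientRecord,
    table: ExonTable,
    rule: Rule,
    milestone_threshold_months: float = DEFAULT_MILESTONE_THRESHOLD_MONTHS,
) -> Prediction:
    """Score one patient under one rule."""
    if isinstance(record.variant, VariantEvent):
        status = frame_status(table, record.variant)
    else:
        status = FrameStatus.INDETERMINATE
    delayed = milestone_delayed(record.first_walking_age_months, milestone_threshold_months)

    rule = Rule(rule)
    if rule is Rule.FRAME:
        label = predict_frame(status)
    elif rule is Rule.MILESTONE:
        label = predict_milestone(delayed)
    else:
        label = predict_combined(predict_frame(status), predict_milestone(delayed))
    return Prediction(
        patient_id=record.patient_id,
        rule=rule,
        predicted=label,
        frame_status=status,
        milestone_delayed=delayed,
    )


def predict_cohort(
    records: list[PatientRecord],
    table: ExonTable,
    rule: Rule,
    milestone_threshold_months: float = DEFAULT_MILESTONE_THRESHOLD_MONTHS,
) -> list[Prediction]:
    return [
        predict_patient(r, table, rule, milestone_threshold_months) for r in records
    ]


def apply_eligibility(
    manifest: list[PatientRecord],
    cutoff_years: float = DEFAULT_PHENOTYPE_CUTOFF_YEARS,
) -> tuple[list[PatientRecord], "OrderedDict[str, int]"]:
    """Study-entry filters, applied in order, with a per-filter exclusion tally.

    1. ``female`` — only male probands enter (X-linked disease);
    2. ``point_mutation`` — the exon-level frame rule needs a del/dup;
    3. ``ambulant_under_cutoff`` — still-walking patients younger than the
       cutoff carry no ground-truth label and are excluded.

    Returns the surviving records and an ordered ``filter name -> excluded
    count`` map mirroring a study-profile flow chart.
    """
    flow: "OrderedDict[str, int]" = OrderedDict(
        (name, 0) for name in ("female", "point_mutation", "ambulant_under_cutoff")
    )
    eligible: list[PatientRecord] = []
    for record in manifest:
        if record.sex != "male":
            flow["female"] += 1
            continue
        if not isinstance(record.variant, VariantEvent):
            flow["point_mutation"] += 1
            continue
        if phenotype_from_followup(record, cutoff_years) is PhenotypeLabel.INDETERMINATE:
            flow["ambulant_under_cutoff"] += 1
            continue
        eligible.append(record)
    return eligible, flow
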