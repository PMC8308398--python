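"""Per-visit diabetes status adjudication: T2D, reversal, or remission.

Status is decided from the visit's HbA1c and fasting plasma glucose
together with a comparison of the visit's glucose-lowering medication
against the reference (baseline) visit:

* **remission** — fasting glucose <= 6.9 mmol/L AND HbA1c < 48 mmol/mol
  AND no glucose-lowering medication of any class at the visit;
* **reversal** — HbA1c <= 53 mmol/mol AND fasting glucose < 8.0 mmol/L
  on reduced (or fully stopped) medication, OR HbA1c < 48 AND fasting
  glucose <= 6.9 on unchanged medication;
* **T2D** otherwise.

The boundary semantics (<= 6.9, < 48, <= 53, < 8.0) are honored
strictly; remission takes precedence over reversal.  Only
glucose-lowering drug classes enter the comparison — blood-pressure and
lipid medication is tracked elsewhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .indices import Visit

__all__ = [
    "DrugClass",
    "medication_states",
    "adjudicate_cohort",
    "MedRelation",
    "MedicationItem",
    "MedicationState",
    "VisitLabs",
    "StatusCall",
    "compare_medication",
    "classify_status",
    "status_counts",
]


class DrugClass(str, enum.Enum):
    """Glucose-lowering drug classes tracked by the adjudicator."""

    metformin = "metformin"
    SU_derivative = "SU_derivative"
    insulin = "insulin"
    GLP1_agonist = "GLP1_agonist"
    other_glucose_lowering = "other_glucose_lowering"


class MedRelation(str, enum.Enum):
    """Ordering of a visit's medication against the reference visit."""

    stopped_all = "stopped_all"
    reduced = "reduced"
    equal = "equal"
    increased = "increased"


@dataclass(frozen=True)
class MedicationItem:
    drug_class: DrugClass
    daily_dose: float
    dose_unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_class", DrugClass(self.drug_class))
        if not self.daily_dose > 0:
            raise ValueError("daily_dose must be positive")


@dataclass(frozen=True)
class MedicationState:
    """Set of glucose-lowering drugs with doses at one visit."""

    visit: Visit
    items: tuple[MedicationItem, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "visit", Visit(self.visit))
        object.__setattr__(self, "items", tuple(self.items))
        classes = [item.drug_class for item in self.items]
        if len(classes) != len(set(classes)):
            raise ValueError("at most one item per drug class")

    @property
    def classes(self) -> frozenset[DrugClass]:
        return frozenset(item.drug_class for item in self.items)

    @property
    def empty(self) -> bool:
        return not self.items

    def dose(self, drug_class: DrugClass) -> tuple[float, str]:
        for item in self.items:
            if item.drug_class == drug_class:
                return item.daily_dose, item.dose_unit
        raise KeyError(drug_class)


@dataclass(frozen=True)
class VisitLabs:
    """HbA1c (mmol/mol) and fasting plasma glucose (mmol/L) at a visit."""

    hba1c: float
    fpg: float

    def __post_init__(self) -> None:
        if not (self.hba1c > 0 and self.fpg > 0):
            raise ValueError("hba1c and fpg must be positive")


@dataclass(frozen=True)
class StatusCall:
    status: str  # "T2D" | "reversal" | "remission"
    med_relation: MedRelation
    visit: Visit | None = field(default=None)

    def __post_init__(self) -> None:
        if self.status not in ("T2D", "reversal", "remission"):
            raise ValueError(f"unknown status {self.status!r}")
        object.__setattr__(self, "med_relation", MedRelation(self.med_relation))
        if self.status == "remission" and self.med_relation != MedRelation.stopped_all:
            raise ValueError("remission requires all glucose-lowering drugs stopped")


def compare_medication(
    baseline: MedicationState, current: MedicationState
) -> MedRelation:
    """Order a visit's glucose-lowering medication against baseline.

    ``stopped_all`` — current is empty and baseline was not; ``reduced``
    — a strict subset of the baseline classes (doses ignored once a
    class is dropped), or identical classes with every dose <= baseline
    and at least one strictly lower; ``equal`` — identical classes and
    doses; ``increased`` — anything else (a new class, a higher dose, or
    a mixed up/down change, which is treated conservatively).

    Dose comparison is only defined within an identical (class, unit)
    pair; a unit mismatch raises rather than guessing a conversion.
    """
    if current.empty:
        return MedRelation.stopped_all if not baseline.empty else MedRelation.equal
    if not current.classes <= baseline.classes:
        return MedRelation.increased
    if current.classes < baseline.classes:
        # fewer drug classes counts as reduced unless a retained dose rose
        for item in current.items:
            base_dose, base_unit = baseline.dose(item.drug_class)
            if item.dose_unit != base_unit:
                raise ValueError(
                    f"dose unit mismatch for {item.drug_class.value}: "
                    f"{base_unit!r} vs {item.dose_unit!r}"
                )
            if item.daily_dose > base_dose:
                return MedRelation.increased
        return MedRelation.reduced
    # identical class sets: compare dose vectors
    any_lower = False
    for item in current.items:
        base_dose, base_unit = baseline.dose(item.drug_class)
        if item.dose_unit != base_unit:
            raise ValueError(
                f"dose unit mismatch for {item.drug_class.value}: "
                f"{base_unit!r} vs {item.dose_unit!r}"
            )
        if item.daily_dose > base_dose:
            return MedRelation.increased
        if item.daily_dose < base_dose:
            any_lower = True
    return MedRelation.reduced if any_lower else MedRelation.equal


def classify_status(
    labs: VisitLabs,
    relation: MedRelation,
    current: MedicationState,
) -> StatusCall:
    """Adjudicate remission / reversal / T2D for one visit."""
    relation = MedRelation(relation)
    if labs.fpg <= 6.9 and labs.hba1c < 48 and current.empty:
        # current is empty here, so "no medication present" holds; a
        # never-medicated participant (relation equal) is recorded as
        # stopped_all to keep the remission invariant unambiguous
        return StatusCall("remission", MedRelation.stopped_all, current.visit)
    on_target = labs.hba1c <= 53 and labs.fpg < 8.0
    normalized = labs.hba1c < 48 and labs.fpg <= 6.9
    if on_target and relation in (MedRelation.reduced, MedRelation.stopped_all):
        return StatusCall("reversal", relation, current.visit)
    if normalized and relation == MedRelation.equal:
        return StatusCall("reversal", relation, current.visit)
    return StatusCall("T2D", relation, current.visit)


def status_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-visit counts of T2D / reversal / remission calls.

    ``calls`` needs columns ``participant_id``, ``visit``, ``status``
    with one row per participant per visit; counts sum to n per visit.
    """
    required = {"participant_id", "visit", "status"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls must have columns {sorted(required)}")
    dup = calls.duplicated(subset=["participant_id", "visit"])
    if dup.any():
        raise ValueError("expected one status call per participant per visit")
    visits = [v.value for v in Visit]
    statuses = ["T2D", "reversal", "remission"]
    table = (
        pd.crosstab(calls["status"], calls["visit"])
        .reindex(index=statuses, columns=visits, fill_value=0)
        .fillna(0)
        .astype(int)
    )
    table.index.name = "status"
    return table


def medication_states(
    medications: pd.DataFrame, participant_id: str
) -> dict[str, MedicationState]:
    """Assemble per-visit :class:`MedicationState` for one participant.

    Rows with ``drug_class == "none"`` are explicit markers for a
    medication-free visit and yield an empty state; a visit with no row
    at all is simply absent from the result (unrecorded).
    """
    states: dict[str, MedicationState] = {}
    sub = medications[medications["participant_id"] == participant_id]
    for visit in (v.value for v in Visit):
        rows = sub[sub["visit"] == visit]
        if rows.empty:
            continue
        items = tuple(
            MedicationItem(
                DrugClass(r.drug_class), float(r.daily_dose), str(r.dose_unit)
            )
            for r in rows.itertuples()
            if r.drug_class != "none"
        )
        states[visit] = MedicationState(visit=visit, items=items)
    return states


def adjudicate_cohort(
    labs: pd.DataFrame,
    medications: pd.DataFrame,
    *,
    reference_visit: str = "baseline",
) -> pd.DataFrame:
    """Status calls for every participant-visit in a labs table.

    Each visit's medication is compared against the participant's
    ``reference_visit`` state (the trial start by default).  A
    participant without a medication record at the reference visit (not
    even an explicit none-marker) raises, as does a visit with labs but
    no medication record.
    """
    rows = []
    for pid, sub in labs.groupby("participant_id", sort=True):
        states = medication_states(medications, str(pid))
        if reference_visit not in states:
            raise ValueError(
                f"participant {pid!r} has no medication record at the "
                f"reference visit {reference_visit!r}"
            )
        baseline = states[reference_visit]
        for row in sub.itertuples():
            visit = str(row.visit)
            if visit not in states:
                raise ValueError(
                    f"participant {pid!r} has labs but no medication record "
                    f"at visit {visit!r}"
                )
            current = states[visit]
            relation = compare_medication(baseline, current)
            call = classify_status(
                VisitLabs(hba1c=float(row.hba1c_mmol_mol), fpg=float(row.fpg_mmol_l)),
                relation,
                current,
            )
            rows.append(
                {
                    "participant_id": str(pid),
                    "visit": visit,
                    "status": call.status,
                    "med_relation": call.med_relation.value,
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "visit", "status", "med_relation"]
    )
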