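"""Eight-subtype T2D classification ("diabetyping") and cutoff calibration.

A participant-visit is flagged on three pathophysiological axes from
the OGTT index panel:

* hepatic insulin resistance  — HIRI *above* its cutoff,
* muscle insulin resistance   — MISI *above* its cutoff,
* impaired beta-cell function — disposition index *below* its cutoff.

Under the default span-slope convention MISI is a non-positive number
whose magnitude is the OGTT glucose decay per unit insulin, so a large
negative MISI means efficient insulin-mediated disposal: muscle IR is
flagged when MISI sits *near zero*, i.e. above the cutoff.  (This is
the direction published participant trajectories follow: values move
away from zero as muscle insulin sensitivity improves.)

The three flags map bijectively onto eight labels: healthy, HIR,
MIR, CIR (combined liver + muscle IR) and their impaired-beta-cell
variants IB, IB-HIR, IB-MIR, IB-CIR.  Boundary equality always resolves
to the healthy side, so the healthy cell is closed.

The numeric cutoffs used by the original study were derived from
unavailable reference cohorts and never published, so they are a
required configuration input here; :func:`calibrate_cutoffs` provides a
per-index ROC / Youden-J procedure to derive them from any labeled
healthy-vs-T2D reference panel set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .indices import IndexPanel, Visit

__all__ = [
    "SUBTYPE_LABELS",
    "CutoffConfig",
    "SubtypeCall",
    "label_from_flags",
    "flags_from_label",
    "classify_subtype",
    "youden_threshold",
    "calibrate_cutoffs",
    "subtype_flow",
]

#: All eight reachable subtype labels.
SUBTYPE_LABELS: tuple[str, ...] = (
    "healthy",
    "HIR",
    "MIR",
    "CIR",
    "IB",
    "IB-HIR",
    "IB-MIR",
    "IB-CIR",
)


@dataclass(frozen=True)
class CutoffConfig:
    """Per-index decision thresholds for diabetyping.

    Directions are fixed: HIRI above ``hiri_cutoff`` flags hepatic IR,
    MISI above ``misi_cutoff`` flags muscle IR (the span-slope MISI is
    non-positive and shrinks toward zero as muscle disposal worsens),
    disposition below ``di_cutoff`` flags impaired beta-cell function.
    """

    hiri_cutoff: float
    misi_cutoff: float
    di_cutoff: float
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("hiri_cutoff", "misi_cutoff", "di_cutoff"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hiri": self.hiri_cutoff,
            "misi": self.misi_cutoff,
            "disposition": self.di_cutoff,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CutoffConfig":
        payload = json.loads(Path(path).read_text())
        return cls(
            hiri_cutoff=float(payload["hiri"]),
            misi_cutoff=float(payload["misi"]),
            di_cutoff=float(payload["disposition"]),
            provenance=str(payload.get("provenance", "")),
        )


@dataclass(frozen=True)
class SubtypeCall:
    """Three impairment flags plus the derived subtype label."""

    hepatic_ir: bool
    muscle_ir: bool
    impaired_bcf: bool
    label: str

    def __post_init__(self) -> None:
        expected = label_from_flags(self.hepatic_ir, self.muscle_ir, self.impaired_bcf)
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with flags "
                f"(expected {expected!r})"
            )


def label_from_flags(hepatic_ir: bool, muscle_ir: bool, impaired_bcf: bool) -> str:
    """Pure flag -> label map; the only place the naming rule lives."""
    if hepatic_ir and muscle_ir:
        ir = "CIR"
    elif hepatic_ir:
        ir = "HIR"
    elif muscle_ir:
        ir = "MIR"
    else:
        ir = ""
    if impaired_bcf:
        return f"IB-{ir}" if ir else "IB"
    return ir or "healthy"


def flags_from_label(label: str) -> tuple[bool, bool, bool]:
    """Inverse of :func:`label_from_flags`."""
    if label not in SUBTYPE_LABELS:
        raise ValueError(f"unknown subtype label {label!r}")
    impaired_bcf = label == "IB" or label.startswith("IB-")
    ir_part = label.removeprefix("IB-") if label != "IB" else ""
    hepatic = ir_part in ("HIR", "CIR")
    muscle = ir_part in ("MIR", "CIR")
    return hepatic, muscle, impaired_bcf


def classify_subtype(panel: IndexPanel, cutoffs: CutoffConfig) -> SubtypeCall:
    """Assign one of the eight subtypes by strict cutoff comparison.

    Equality with a cutoff is *not* impairment (ties resolve healthy).
    """
    hepatic = panel.hiri > cutoffs.hiri_cutoff
    muscle = panel.misi > cutoffs.misi_cutoff
    impaired = panel.disposition < cutoffs.di_cutoff
    return SubtypeCall(
        hepatic_ir=hepatic,
        muscle_ir=muscle,
        impaired_bcf=impaired,
        label=label_from_flags(hepatic, muscle, impaired),
    )


def youden_threshold(
    values: Sequence[float],
    is_t2d: Sequence[bool],
    *,
    higher_is_t2d: bool,
) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between adjacent distinct
    sorted values; when several candidates tie on J the midpoint of the
    tied candidates is returned.  T2D is called when the value is
    strictly above (``higher_is_t2d``) or strictly below the threshold.

    Returns ``(threshold, J)``.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(is_t2d, dtype=bool)
    if not (y.any() and (~y).any()):
        raise ValueError("both classes must be present")
    uniq = np.unique(v)
    if uniq.size == 1:
        warnings.warn("index is constant: cutoff set at pooled median", stacklevel=2)
        return float(uniq[0]), 0.0
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if higher_is_t2d:
        calls = v[None, :] > candidates[:, None]
    else:
        calls = v[None, :] < candidates[:, None]
    sens = (calls & y).sum(axis=1) / n_pos
    spec = (~calls & ~y).sum(axis=1) / n_neg
    j = sens + spec - 1.0
    best = j.max()
    tied = candidates[np.isclose(j, best)]
    threshold = float((tied.min() + tied.max()) / 2.0)
    # the scan maximum is positively biased on null data (~1/sqrt(n)),
    # so "barely separates" means J below ~0.2, not merely near 0
    if best <= 0.2:
        warnings.warn(
            f"index barely separates classes (J = {best:.3f}); "
            "cutoff set at pooled median",
            stacklevel=2,
        )
        return float(np.median(v)), float(best)
    return threshold, float(best)


def calibrate_cutoffs(
    reference: Iterable[tuple[IndexPanel, str]],
    *,
    min_per_class: int = 20,
    provenance: str = "Youden-J calibration on labeled reference panels",
) -> CutoffConfig:
    """Derive per-index cutoffs from a labeled healthy/T2D reference set.

    Each index gets the threshold maximizing Youden's J for separating
    T2D from healthy panels in its fixed impairment direction.
    """
    panels, statuses = [], []
    for panel, status in reference:
        if status not in ("healthy", "T2D"):
            raise ValueError(f"reference status must be healthy or T2D, got {status!r}")
        panels.append(panel)
        statuses.append(status)
    y = np.array([s == "T2D" for s in statuses])
    if not (y.any() and (~y).any()):
        raise ValueError("reference must contain both healthy and T2D panels")
    if y.sum() < min_per_class or (~y).sum() < min_per_class:
        raise ValueError(f"need at least {min_per_class} panels per class")

    hiri_cut, _ = youden_threshold([p.hiri for p in panels], y, higher_is_t2d=True)
    misi_cut, _ = youden_threshold([p.misi for p in panels], y, higher_is_t2d=True)
    di_cut, _ = youden_threshold([p.disposition for p in panels], y, higher_is_t2d=False)
    return CutoffConfig(
        hiri_cutoff=hiri_cut,
        misi_cutoff=misi_cut,
        di_cutoff=di_cut,
        provenance=provenance,
    )


def subtype_flow(calls: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-visit subtype counts and visit-to-visit transition tables.

    ``calls`` needs columns ``participant_id``, ``visit``, ``label``;
    participants absent at a visit are counted as missing there.

    Returns ``{"counts": per-visit counts (rows: labels + "missing"),
    "baseline_to_month3": ..., "month3_to_month6": ...}`` where the
    transition tables count participants moving between labels
    ("missing" rows/columns included).
    """
    required = {"participant_id", "visit", "label"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls must have columns {sorted(required)}")
    visits = [v.value for v in Visit]
    participants = sorted(calls["participant_id"].unique())
    # one label per participant-visit cell, NaN -> "missing"
    wide = (
        calls.pivot_table(
            index="participant_id", columns="visit", values="label", aggfunc="first"
        )
        .reindex(index=participants, columns=visits)
        .fillna("missing")
    )
    categories = list(SUBTYPE_LABELS) + ["missing"]
    counts = pd.DataFrame(
        {v: wide[v].value_counts().reindex(categories, fill_value=0) for v in visits}
    )
    counts.index.name = "label"

    out = {"counts": counts}
    for a, b in zip(visits, visits[1:]):
        table = pd.crosstab(wide[a], wide[b], dropna=False).reindex(
            index=categories, columns=categories, fill_value=0
        )
        table.index.name = f"{a}_label"
        table.columns.name = f"{b}_label"
        out[f"{a}_to_{b}"] = table
    return out
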