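"""CSV readers and writers for the pipeline's tabular interchange formats.

All tables are plain RFC-4180 CSV (UTF-8, '.' decimal); cutoffs and run
configuration are JSON.  Schemas:

* OGTT long format: ``participant_id, visit, time_min, glucose_mmol_l,
  insulin_mu_l`` — one row per sample.
* Index panels: one row per participant-visit with the five indices.
* Subtype calls: ``participant_id, visit, hepatic_ir, muscle_ir,
  impaired_bcf, label``.
* Labs: ``participant_id, visit, hba1c_mmol_mol, fpg_mmol_l``.
* Medications: ``participant_id, visit, drug_class, daily_dose,
  dose_unit``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .indices import CANONICAL_TIMES, IndexPanel, OGTTCurve, Visit, UNITS_NOTE

__all__ = [
    "RunConfig",
    "ReadReport",
    "read_ogtt_csv",
    "write_ogtt_csv",
    "write_panels_csv",
    "read_panels_csv",
    "read_labs_csv",
    "read_medications_csv",
    "write_calls_csv",
]

_OGTT_COLUMNS = [
    "participant_id",
    "visit",
    "time_min",
    "glucose_mmol_l",
    "insulin_mu_l",
]


@dataclass
class RunConfig:
    """Paths and options steering a pipeline run."""

    ogtt_csv: str | None = None
    labs_csv: str | None = None
    medications_csv: str | None = None
    cutoffs_json: str | None = None
    misi_convention: str = "span_slope"
    log10_variables: tuple[str, ...] = ()
    medication_reference_visit: str = "baseline"
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload["log10_variables"] = tuple(payload.get("log10_variables", ()))
        return cls(**payload)


@dataclass
class ReadReport:
    """Row-level findings from reading an OGTT CSV."""

    n_curves: int = 0
    partial: list[tuple[str, str]] = field(default_factory=list)
    rejected_rows: list[str] = field(default_factory=list)


def read_ogtt_csv(path: str | Path) -> tuple[list[OGTTCurve], ReadReport]:
    """Read a long-format OGTT CSV into curves grouped by participant-visit.

    Rows with non-canonical sampling times are rejected with a per-row
    report; visits missing some canonical times are returned as partial
    curves (flagged in the report — usable for HOMA-IR/HIRI only).
    Duplicated (participant, visit, time) rows and malformed numerics
    raise.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(_OGTT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"OGTT CSV missing columns {sorted(missing)}")
    for col in ("time_min", "glucose_mmol_l", "insulin_mu_l"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = int(bad[0]) + 2  # header + 1-based
            raise ValueError(f"malformed numeric in column {col!r} at line {row}") from exc
    dup = df.duplicated(subset=["participant_id", "visit", "time_min"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate sample for participant "
            f"{first['participant_id']!r} visit {first['visit']!r} "
            f"t={first['time_min']}"
        )

    report = ReadReport()
    canonical = set(CANONICAL_TIMES)
    keep = df["time_min"].isin(canonical)
    for idx in df.index[~keep]:
        report.rejected_rows.append(
            f"line {idx + 2}: non-canonical time {df.loc[idx, 'time_min']}"
        )
    df = df[keep]

    curves = []
    for (pid, visit), group in df.groupby(["participant_id", "visit"], sort=True):
        group = group.sort_values("time_min")
        curve = OGTTCurve(
            participant_id=str(pid),
            visit=Visit(visit),
            times=tuple(group["time_min"]),
            glucose=tuple(group["glucose_mmol_l"]),
            insulin=tuple(group["insulin_mu_l"]),
        )
        if not curve.is_full_panel:
            report.partial.append((str(pid), str(visit)))
        curves.append(curve)
    report.n_curves = len(curves)
    return curves, report


def write_ogtt_csv(curves: list[OGTTCurve], path: str | Path) -> None:
    rows = [
        {
            "participant_id": c.participant_id,
            "visit": c.visit.value,
            "time_min": t,
            "glucose_mmol_l": g,
            "insulin_mu_l": i,
        }
        for c in curves
        for t, g, i in zip(c.times, c.glucose, c.insulin)
    ]
    pd.DataFrame(rows, columns=_OGTT_COLUMNS).to_csv(path, index=False)


def write_panels_csv(
    panels: list[tuple[str, str, IndexPanel]], path: str | Path
) -> None:
    """Write (participant_id, visit, panel) rows with a units header comment."""
    rows = [
        {
            "participant_id": pid,
            "visit": visit,
            "matsuda": p.matsuda,
            "disposition": p.disposition,
            "hiri": p.hiri,
            "misi": p.misi,
            "homa_ir": p.homa_ir,
        }
        for pid, visit, p in panels
    ]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# units: {UNITS_NOTE}\n")
        pd.DataFrame(
            rows,
            columns=["participant_id", "visit", "matsuda", "disposition", "hiri", "misi", "homa_ir"],
        ).to_csv(fh, index=False)


def read_panels_csv(path: str | Path) -> list[tuple[str, str, IndexPanel]]:
    df = pd.read_csv(path, comment="#")
    out = []
    for row in df.itertuples():
        out.append(
            (
                str(row.participant_id),
                str(row.visit),
                IndexPanel(
                    matsuda=row.matsuda,
                    disposition=row.disposition,
                    hiri=row.hiri,
                    misi=row.misi,
                    homa_ir=row.homa_ir,
                ),
            )
        )
    return out


def read_labs_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"participant_id", "visit", "hba1c_mmol_mol", "fpg_mmol_l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"labs CSV missing columns {sorted(missing)}")
    return df


def read_medications_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"participant_id", "visit", "drug_class", "daily_dose", "dose_unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"medications CSV missing columns {sorted(missing)}")
    return df


def write_calls_csv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, index=False)
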