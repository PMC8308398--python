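"""Seeded synthetic OGTT cohorts for end-to-end pipeline testing.

No patient-level data from the underlying study are available, so this
module generates curves, labs and medication records with the
*statistical structure* the analysis assumes: eight subtype archetypes
whose index panels land on the correct side of calibrated cutoffs, and
study visits (baseline, month 3, month 6) with intervention effect
multipliers that emulate improvement at three months and a partial
relapse at six.

The curve generator is a deliberately simple discrete glucose balance
on a 5-minute grid, not a validated physiological model:

    G(t+dt) = G(t) + [absorption(t) - disposal_rate * I(t) * (G(t) - floor)] * dt

with gut absorption active over 0-60 min and a glucose floor somewhat
below the fasting level (hepatic output keeps fasting glucose up).
Insulin is a first-phase secretion bump scaled by ``beta_cell_gain``
(triangular, peaking at 30 min, amplitude tracking the fasting
glycemia — impaired beta cells blunt exactly this early response) plus
a late-phase term ``late_secretion_gain`` x glucose excursion that
ramps in after 30 min.  Multiplicative lognormal noise with
coefficient of variation ``noise_cv`` is applied per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .indices import CANONICAL_TIMES, OGTTCurve, Visit
from .status import DrugClass, MedicationItem, MedicationState

__all__ = [
    "ArchetypeSpec",
    "CohortSpec",
    "ARCHETYPES",
    "STUDY_MIX",
    "INTERVENTION_EFFECTS",
    "NULL_EFFECTS",
    "generate_curve",
    "generate_cohort",
    "reference_panels",
]

_GRID_DT = 5.0  # minutes
_GRID = np.arange(0.0, 121.0, _GRID_DT)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters for one subtype archetype.

    Units: fasting glucose mmol/L; fasting insulin mU/L;
    ``beta_cell_gain`` and ``late_secretion_gain`` mU/L of insulin per
    mmol/L of glucose excursion (first phase / late phase);
    ``disposal_rate`` per minute per mU/L; ``absorption_rate`` mmol/L
    per minute, a fixed gut-appearance rate over 0-60 min and zero
    after; ``noise_cv`` fractional CV of the multiplicative
    measurement noise.
    """

    label: str
    fasting_glucose_mean: float
    fasting_glucose_sd: float
    fasting_insulin_mean: float
    fasting_insulin_sd: float
    beta_cell_gain: float
    disposal_rate: float
    absorption_rate: float = 0.16
    late_secretion_gain: float = 6.0
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "fasting_glucose_mean",
            "fasting_glucose_sd",
            "fasting_insulin_mean",
            "fasting_insulin_sd",
            "beta_cell_gain",
            "disposal_rate",
            "absorption_rate",
            "late_secretion_gain",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def _first_phase(t: np.ndarray, fg: float) -> np.ndarray:
    """Triangular first-phase secretion shape, amplitude ~ fasting glycemia."""
    amplitude = 3.0 * fg / 5.5
    shape = np.where(
        t <= 30.0, t / 30.0, np.clip((90.0 - t) / 60.0, 0.0, None)
    )
    return amplitude * shape


def _simulate_traces(
    fg: float,
    fi: float,
    arch: ArchetypeSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free glucose/insulin traces on the 5-min grid."""
    floor = max(fg - 1.5, 0.1)
    bump = _first_phase(_GRID, fg)
    late_weight = np.clip((_GRID - 30.0) / 15.0, 0.0, 1.0)
    n = _GRID.size
    g = np.empty(n)
    ins = np.empty(n)
    g[0] = fg
    for i in range(n):
        excursion = max(g[i] - fg, 0.0)
        ins[i] = (
            fi
            + arch.beta_cell_gain * bump[i]
            + arch.late_secretion_gain * late_weight[i] * excursion
        )
        if i == n - 1:
            break
        absorption = arch.absorption_rate if _GRID[i] < 60.0 else 0.0
        dg = absorption - arch.disposal_rate * ins[i] * (g[i] - floor)
        g[i + 1] = g[i] + dg * _GRID_DT
        if g[i + 1] <= 0:
            raise ValueError("archetype parameters drove glucose non-positive")
    return g, ins


def generate_curve(
    arch: ArchetypeSpec,
    rng: np.random.Generator,
    *,
    participant_id: str = "synthetic",
    visit: Visit | str = Visit.baseline,
) -> OGTTCurve:
    """Draw one five-point OGTT curve from an archetype.

    Fasting values are drawn from the archetype's (truncated) normal
    distributions, the deterministic balance equation is stepped on a
    5-minute grid, the canonical sampling times are read off by linear
    interpolation, and multiplicative lognormal noise (``noise_cv``) is
    applied independently per sample.
    """
    fg = _truncated_normal(rng, arch.fasting_glucose_mean, arch.fasting_glucose_sd)
    fi = _truncated_normal(rng, arch.fasting_insulin_mean, arch.fasting_insulin_sd)
    g_grid, i_grid = _simulate_traces(fg, fi, arch)
    times = np.asarray(CANONICAL_TIMES)
    glucose = np.interp(times, _GRID, g_grid)
    insulin = np.interp(times, _GRID, i_grid)
    if arch.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(arch.noise_cv**2)))
        glucose = glucose * rng.lognormal(-0.5 * sigma**2, sigma, size=times.size)
        insulin = insulin * rng.lognormal(-0.5 * sigma**2, sigma, size=times.size)
    return OGTTCurve(
        participant_id=participant_id,
        visit=Visit(visit),
        times=tuple(times),
        glucose=tuple(glucose),
        insulin=tuple(insulin),
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo_frac: float = 0.3
) -> float:
    """Normal draw truncated below at ``lo_frac * mean`` (keeps values positive)."""
    lo = lo_frac * mean
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > lo:
            return float(x)
    return float(mean)


# Archetype table.  The three pathophysiology axes steer distinct
# parameters: hepatic IR -> elevated fasting glucose-insulin product
# (HIRI); muscle IR -> low disposal_rate, so glucose keeps climbing
# while insulin is plentiful (MISI near zero); impaired beta-cell
# function -> blunted first-phase beta_cell_gain (low disposition
# index).  The four impaired-BCF archetypes sit at overt-diabetic
# magnitudes (fasting glucose ~12 mmol/L, 2-h glucose ~18-21 mmol/L,
# fasting insulin ~24 mU/L for the hepatic ones); the BCF-normal IR
# archetypes are compensated hyperinsulinemic pre/early-diabetic
# states, since a beta cell that still compensates cannot coexist with
# overt fasting hyperglycemia.
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "healthy": ArchetypeSpec(
        label="healthy",
        fasting_glucose_mean=5.2,
        fasting_glucose_sd=0.3,
        fasting_insulin_mean=6.0,
        fasting_insulin_sd=1.0,
        beta_cell_gain=1.5,
        late_secretion_gain=6.0,
        disposal_rate=0.001,
        absorption_rate=0.16,
    ),
    "HIR": ArchetypeSpec(
        label="HIR",
        fasting_glucose_mean=7.0,
        fasting_glucose_sd=0.35,
        fasting_insulin_mean=24.0,
        fasting_insulin_sd=2.5,
        beta_cell_gain=2.0,
        late_secretion_gain=0.5,
        disposal_rate=0.0006,
        absorption_rate=0.24,
    ),
    "MIR": ArchetypeSpec(
        label="MIR",
        fasting_glucose_mean=6.0,
        fasting_glucose_sd=0.35,
        fasting_insulin_mean=11.0,
        fasting_insulin_sd=1.5,
        beta_cell_gain=12.0,
        late_secretion_gain=16.0,
        disposal_rate=0.00015,
        absorption_rate=0.14,
    ),
    "CIR": ArchetypeSpec(
        label="CIR",
        fasting_glucose_mean=6.8,
        fasting_glucose_sd=0.4,
        fasting_insulin_mean=28.0,
        fasting_insulin_sd=3.0,
        beta_cell_gain=16.0,
        late_secretion_gain=14.0,
        disposal_rate=0.00015,
        absorption_rate=0.14,
    ),
    "IB": ArchetypeSpec(
        label="IB",
        fasting_glucose_mean=12.0,
        fasting_glucose_sd=1.0,
        fasting_insulin_mean=6.0,
        fasting_insulin_sd=1.0,
        beta_cell_gain=0.3,
        late_secretion_gain=1.0,
        disposal_rate=0.001,
        absorption_rate=0.22,
    ),
    "IB-HIR": ArchetypeSpec(
        label="IB-HIR",
        fasting_glucose_mean=12.0,
        fasting_glucose_sd=1.0,
        fasting_insulin_mean=24.0,
        fasting_insulin_sd=2.5,
        beta_cell_gain=0.3,
        late_secretion_gain=0.5,
        disposal_rate=0.0003,
        absorption_rate=0.24,
    ),
    "IB-MIR": ArchetypeSpec(
        label="IB-MIR",
        fasting_glucose_mean=12.0,
        fasting_glucose_sd=1.0,
        fasting_insulin_mean=7.0,
        fasting_insulin_sd=1.0,
        beta_cell_gain=0.3,
        late_secretion_gain=34.0,
        disposal_rate=0.00015,
        absorption_rate=0.095,
    ),
    "IB-CIR": ArchetypeSpec(
        label="IB-CIR",
        fasting_glucose_mean=12.0,
        fasting_glucose_sd=1.0,
        fasting_insulin_mean=24.0,
        fasting_insulin_sd=2.5,
        beta_cell_gain=0.3,
        late_secretion_gain=26.0,
        disposal_rate=0.00015,
        absorption_rate=0.12,
    ),
}


#: Per-visit effect multipliers (fasting glucose, fasting insulin,
#: beta-cell gain, disposal rate).  The default intervention profile
#: emulates the study pattern: clear improvement at month 3, partial
#: relapse of glycemia at month 6 with continued insulin decline.
INTERVENTION_EFFECTS: dict[str, dict[str, float]] = {
    "baseline": {"fg": 1.0, "fi": 1.0, "gain": 1.0, "disposal": 1.0},
    "month3": {"fg": 0.73, "fi": 0.73, "gain": 1.2, "disposal": 1.4},
    "month6": {"fg": 0.87, "fi": 0.58, "gain": 1.1, "disposal": 1.6},
}

#: Archetype mix matching the study population: predominantly impaired
#: beta-cell function with hepatic IR, a little isolated IB and IB-CIR.
STUDY_MIX: dict[str, float] = {"IB-HIR": 0.8, "IB": 0.1, "IB-CIR": 0.1}

#: No-intervention profile (all multipliers 1) for null simulations.
NULL_EFFECTS: dict[str, dict[str, float]] = {
    v: {"fg": 1.0, "fi": 1.0, "gain": 1.0, "disposal": 1.0}
    for v in ("baseline", "month3", "month6")
}

# HbA1c (mmol/mol) synthesized as affine in a daily-mean glucose proxy
# (midpoint of fasting and OGTT-mean glucose), coefficients chosen so
# the impaired baseline archetypes land near HbA1c ~68 mmol/mol and the
# healthy archetype near ~36.
HBA1C_INTERCEPT = 14.6
HBA1C_SLOPE = 3.65
HBA1C_NOISE_SD = 2.0


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic three-visit cohort."""

    n: int
    archetype_mix: dict[str, float]
    visits: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in INTERVENTION_EFFECTS.items()}
    )
    seed: int = 0
    noise_cv: float | None = None
    #: SD of the per-participant response scalar (1 = average responder;
    #: strong responders overshoot every visit effect, weak ones undershoot)
    response_sd: float = 0.4
    #: per-participant month-3 -> month-6 relapse scalar: 0 keeps the
    #: month-3 state, 1 follows the average relapse, right-skewed so a
    #: sizeable minority maintain their improvement
    relapse_mean: float = 0.8
    relapse_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype proportions must sum to 1, got {total}")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")


def _visit_rng(seed: int, participant: int, visit_idx: int) -> np.random.Generator:
    # counter-style stream: independent of generation order
    return np.random.default_rng([seed, participant, visit_idx])


def _effective_multipliers(
    visits: dict[str, dict[str, float]], response: float, relapse: float
) -> dict[str, dict[str, float]]:
    """Per-participant effective visit multipliers.

    The responder scalar r rescales every month-3 multiplier m to
    1 - r * (1 - m) (r = 0: no change from baseline; r > 1: overshoots
    the average effect).  The month-6 value interpolates between the
    participant's own month-3 state (relapse = 0) and the average
    month-3 -> month-6 relapse (relapse = 1), again scaled by r.
    """
    keys = ("fg", "fi", "gain", "disposal")
    out: dict[str, dict[str, float]] = {"baseline": {k: 1.0 for k in keys}}
    m3, m6 = visits["month3"], visits["month6"]
    out["month3"] = {k: max(1.0 - response * (1.0 - m3[k]), 0.05) for k in keys}
    out["month6"] = {
        k: max(out["month3"][k] + response * relapse * (m6[k] - m3[k]), 0.05)
        for k in keys
    }
    return out


def _apply_effects(arch: ArchetypeSpec, eff: dict[str, float]) -> ArchetypeSpec:
    """Scale archetype parameters by one visit's effective multipliers."""
    return replace(
        arch,
        fasting_glucose_mean=arch.fasting_glucose_mean * eff["fg"],
        fasting_insulin_mean=arch.fasting_insulin_mean * eff["fi"],
        fasting_glucose_sd=arch.fasting_glucose_sd * eff["fg"],
        fasting_insulin_sd=arch.fasting_insulin_sd * eff["fi"],
        beta_cell_gain=arch.beta_cell_gain * eff["gain"],
        disposal_rate=arch.disposal_rate * eff["disposal"],
    )


def _baseline_medication(label: str, participant: int) -> tuple[MedicationItem, ...]:
    """Deterministic baseline regimen: impaired archetypes are treated."""
    if label == "healthy":
        return ()
    items = [MedicationItem(DrugClass.metformin, 2000.0, "mg")]
    if label in ("IB-CIR", "CIR"):
        items.append(MedicationItem(DrugClass.SU_derivative, 80.0, "mg"))
    if label in ("IB-CIR",) and participant % 3 == 0:
        items.append(MedicationItem(DrugClass.insulin, 24.0, "IU"))
    return tuple(items)


def _deescalate(
    baseline_items: tuple[MedicationItem, ...], hba1c: float, fpg: float
) -> tuple[MedicationItem, ...]:
    """Medication de-escalation rule driven by the simulated labs."""
    if hba1c < 48 and fpg <= 6.9:
        return ()
    if hba1c <= 53 and fpg < 8.0:
        kept = []
        for item in baseline_items:
            if item.drug_class == DrugClass.metformin:
                kept.append(replace(item, daily_dose=item.daily_dose / 2.0))
        return tuple(kept)
    return baseline_items


def generate_cohort(spec: CohortSpec) -> dict[str, object]:
    """Generate a full three-visit cohort.

    Returns a dict with keys ``curves`` (list of
    ``(archetype_label, OGTTCurve)``), ``labs`` (DataFrame:
    participant_id, visit, hba1c_mmol_mol, fpg_mmol_l),
    ``medications`` (DataFrame: participant_id, visit, drug_class,
    daily_dose, dose_unit) and ``truth`` (DataFrame: participant_id,
    archetype).  Fully reproducible from ``spec.seed``.
    """
    labels = sorted(spec.archetype_mix)
    probs = np.array([spec.archetype_mix[k] for k in labels])
    assign_rng = np.random.default_rng([spec.seed, 2**20])
    assigned = assign_rng.choice(labels, size=spec.n, p=probs)

    visit_names = [v.value for v in Visit]
    curves: list[tuple[str, OGTTCurve]] = []
    labs_rows = []
    med_rows = []
    truth_rows = []
    for p in range(spec.n):
        pid = f"P{p:04d}"
        label = str(assigned[p])
        base_arch = ARCHETYPES[label]
        if spec.noise_cv is not None:
            base_arch = replace(base_arch, noise_cv=spec.noise_cv)
        truth_rows.append({"participant_id": pid, "archetype": label})
        base_meds = _baseline_medication(label, p)
        prng = np.random.default_rng([spec.seed, 2**21, p])
        response = min(_truncated_normal(prng, 1.0, spec.response_sd, lo_frac=0.0), 2.0)
        relapse = min(
            max(prng.normal(spec.relapse_mean, spec.relapse_sd), 0.0), 2.0
        )
        effective = _effective_multipliers(spec.visits, response, relapse)
        for vi, visit in enumerate(visit_names):
            arch = _apply_effects(base_arch, effective[visit])
            rng = _visit_rng(spec.seed, p, vi)
            curve = generate_curve(arch, rng, participant_id=pid, visit=visit)
            curves.append((label, curve))
            proxy = 0.5 * (curve.fasting_glucose + curve.mean_glucose)
            hba1c = (
                HBA1C_INTERCEPT
                + HBA1C_SLOPE * proxy
                + rng.normal(0.0, HBA1C_NOISE_SD)
            )
            hba1c = max(hba1c, 10.0)
            labs_rows.append(
                {
                    "participant_id": pid,
                    "visit": visit,
                    "hba1c_mmol_mol": hba1c,
                    "fpg_mmol_l": curve.fasting_glucose,
                }
            )
            items = (
                base_meds
                if visit == "baseline"
                else _deescalate(base_meds, hba1c, curve.fasting_glucose)
            )
            if items:
                for item in items:
                    med_rows.append(
                        {
                            "participant_id": pid,
                            "visit": visit,
                            "drug_class": item.drug_class.value,
                            "daily_dose": item.daily_dose,
                            "dose_unit": item.dose_unit,
                        }
                    )
            else:
                # explicit marker row: medication-free, not unrecorded
                med_rows.append(
                    {
                        "participant_id": pid,
                        "visit": visit,
                        "drug_class": "none",
                        "daily_dose": 0.0,
                        "dose_unit": "",
                    }
                )
    med_columns = ["participant_id", "visit", "drug_class", "daily_dose", "dose_unit"]
    return {
        "curves": curves,
        "labs": pd.DataFrame(labs_rows),
        "medications": pd.DataFrame(med_rows, columns=med_columns),
        "truth": pd.DataFrame(truth_rows),
    }


def reference_panels(
    n_per_class: int = 200,
    seed: int = 1,
    noise_cv: float = 0.05,
):
    """Labeled (panel, status) reference set for cutoff calibration.

    Healthy panels come from the healthy archetype, T2D panels from the
    fully impaired IB-CIR archetype, so each index sees a clean
    two-class contrast.
    """
    from .indices import compute_panel

    out = []
    for ci, (label, status) in enumerate((("healthy", "healthy"), ("IB-CIR", "T2D"))):
        arch = replace(ARCHETYPES[label], noise_cv=noise_cv)
        for i in range(n_per_class):
            rng = np.random.default_rng([seed, 2**16 + ci, i])
            curve = generate_curve(arch, rng, participant_id=f"ref{ci}_{i}")
            out.append((compute_panel(curve), status))
    return out
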