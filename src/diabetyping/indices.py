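"""OGTT-derived insulin-resistance and beta-cell indices.

All indices are computed from a five-point oral glucose tolerance test
(OGTT; samples at t = 0, 30, 60, 90, 120 min) with plasma glucose in
mmol/L and plasma insulin in mU/L.  Unit conventions are fixed and
explicit:

* HOMA-IR uses glucose in mmol/L: ``fG * fI / 22.5``.
* Matsuda, disposition index, HIRI and MISI use glucose converted to
  mg/dL with the exact factor 18.0 and insulin in mU/L.

Consequently ``hiri == homa_ir * 22.5 * 18.0`` holds to machine
precision for every curve — the two indices read the same fasting
sample through two unit conventions.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Visit",
    "MISIConvention",
    "OGTTCurve",
    "IndexPanel",
    "CANONICAL_TIMES",
    "MGDL_PER_MMOLL",
    "glucose_to_mgdl",
    "trapezoid_auc",
    "homa_ir",
    "hiri",
    "matsuda",
    "disposition_index",
    "misi",
    "compute_panel",
]

#: Sampling grid (minutes) required for the full index panel.
CANONICAL_TIMES: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)

#: Exact mmol/L -> mg/dL conversion factor for glucose used throughout.
MGDL_PER_MMOLL: float = 18.0

#: hiri / homa_ir ratio implied by the two unit conventions (22.5 * 18).
HIRI_PER_HOMA: float = 22.5 * MGDL_PER_MMOLL

UNITS_NOTE = (
    "glucose mmol/L (HOMA-IR) or mg/dL via x18.0 (Matsuda, DI, HIRI, MISI); "
    "insulin mU/L; AUC over [0,30] min by trapezoid"
)


class Visit(str, enum.Enum):
    """Study visit at which an OGTT was performed."""

    baseline = "baseline"
    month3 = "month3"
    month6 = "month6"


class MISIConvention(str, enum.Enum):
    """Variant used to turn the OGTT glucose slope into MISI.

    ``span_slope`` (default): 100 * (Gmin - Gmax) / duration / mI with
    glucose in mg/dL, the duration between the curve extrema taken as a
    positive number of minutes.  The value is never positive; curves
    that keep rising (poor muscle disposal) score strongly negative.

    ``peak_decay``: classic decay-rate form, 100 * (Gpeak - Gnadir) /
    (t_nadir - t_peak) / mI using the post-peak nadir, positive for a
    curve that falls off its peak, 0 for a monotonically rising curve.
    """

    span_slope = "span_slope"
    peak_decay = "peak_decay"


def glucose_to_mgdl(g: float) -> float:
    """Convert a plasma glucose concentration from mmol/L to mg/dL."""
    if not g > 0:
        raise ValueError(f"glucose must be positive, got {g!r}")
    return g * MGDL_PER_MMOLL


@dataclass(frozen=True)
class OGTTCurve:
    """One participant-visit's glucose and insulin OGTT trajectory.

    Parameters
    ----------
    participant_id:
        Opaque participant identifier.
    visit:
        One of ``baseline``, ``month3``, ``month6``.
    times:
        Sampling times in minutes, strictly increasing, starting at 0.
    glucose:
        Plasma glucose in mmol/L, one value per sampling time, all > 0.
    insulin:
        Plasma insulin in mU/L, one value per sampling time, all > 0.
    """

    participant_id: str
    visit: Visit
    times: tuple[float, ...]
    glucose: tuple[float, ...]
    insulin: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "visit", Visit(self.visit))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "glucose", tuple(float(g) for g in self.glucose))
        object.__setattr__(self, "insulin", tuple(float(i) for i in self.insulin))
        if len(self.times) == 0:
            raise ValueError("curve needs at least one sample")
        if self.times[0] != 0:
            raise ValueError("first sampling time must be 0 (fasting sample)")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("sampling times must be strictly increasing")
        if len(self.glucose) != len(self.times) or len(self.insulin) != len(self.times):
            raise ValueError("glucose and insulin must match times in length")
        if any(g <= 0 for g in self.glucose) or any(i <= 0 for i in self.insulin):
            raise ValueError("all glucose and insulin values must be positive")

    @property
    def is_full_panel(self) -> bool:
        """Whether the curve has exactly the canonical five sampling times."""
        return self.times == CANONICAL_TIMES

    @property
    def fasting_glucose(self) -> float:
        return self.glucose[0]

    @property
    def fasting_insulin(self) -> float:
        return self.insulin[0]

    @property
    def mean_glucose(self) -> float:
        """Arithmetic mean of all glucose samples (mmol/L)."""
        return float(np.mean(self.glucose))

    @property
    def mean_insulin(self) -> float:
        """Arithmetic mean of all insulin samples (mU/L)."""
        return float(np.mean(self.insulin))

    def _require_full(self, what: str) -> None:
        if not self.is_full_panel:
            raise ValueError(
                f"{what} requires the five canonical sampling times "
                f"{CANONICAL_TIMES}, got {self.times}"
            )


@dataclass(frozen=True)
class IndexPanel:
    """The five OGTT indices under the package's fixed unit conventions."""

    matsuda: float
    disposition: float
    hiri: float
    misi: float
    homa_ir: float
    misi_flat: bool = False
    units_note: str = field(default=UNITS_NOTE, repr=False)

    def __post_init__(self) -> None:
        if not (self.matsuda > 0 and self.hiri > 0 and self.homa_ir > 0):
            raise ValueError("matsuda, hiri and homa_ir must be positive")
        if self.disposition < 0:
            raise ValueError("disposition index must be non-negative")


def trapezoid_auc(
    times,
    values,
    window: tuple[float, float],
) -> float:
    """Trapezoidal area under ``values`` over a sampling-time window.

    The window endpoints must be sampling times — no extrapolation or
    interpolation is performed.  Units are concentration x minutes.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    lo, hi = float(window[0]), float(window[1])
    if lo > hi:
        raise ValueError(f"window must satisfy t_lo <= t_hi, got {window}")
    for endpoint in (lo, hi):
        if not np.any(t == endpoint):
            raise ValueError(f"window endpoint {endpoint} is not a sampling time")
    mask = (t >= lo) & (t <= hi)
    return float(np.trapezoid(v[mask], t[mask]))


def homa_ir(fG: float, fI: float) -> float:
    """Homeostasis-model insulin resistance: ``fG * fI / 22.5``.

    ``fG`` is fasting glucose in mmol/L, ``fI`` fasting insulin in mU/L.
    """
    if not (fG > 0 and fI > 0):
        raise ValueError("fasting glucose and insulin must be positive")
    return fG * fI / 22.5


def hiri(fG: float, fI: float) -> float:
    """Hepatic insulin resistance index: fasting glucose-insulin product.

    Glucose enters in mg/dL (mmol/L input converted with factor 18.0),
    insulin in mU/L, so ``hiri = homa_ir * 405`` exactly.
    """
    if not (fG > 0 and fI > 0):
        raise ValueError("fasting glucose and insulin must be positive")
    return glucose_to_mgdl(fG) * fI


def matsuda(curve: OGTTCurve) -> float:
    """Matsuda whole-body insulin sensitivity index.

    ``10000 / sqrt(fG' * fI * mG' * mI)`` with glucose in mg/dL and the
    means taken over all five OGTT samples.
    """
    curve._require_full("Matsuda index")
    fg = glucose_to_mgdl(curve.fasting_glucose)
    mg = glucose_to_mgdl(curve.mean_glucose)
    return 10000.0 / math.sqrt(fg * curve.fasting_insulin * mg * curve.mean_insulin)


def disposition_index(curve: OGTTCurve) -> float:
    """Disposition index: early insulin/glucose AUC ratio x Matsuda.

    Both AUCs are trapezoids over [0, 30] min; glucose AUC in mg/dL.
    Low values indicate impaired beta-cell function.
    """
    curve._require_full("disposition index")
    auc_ins = trapezoid_auc(curve.times, curve.insulin, (0.0, 30.0))
    glu_mgdl = [glucose_to_mgdl(g) for g in curve.glucose]
    auc_glu = trapezoid_auc(curve.times, glu_mgdl, (0.0, 30.0))
    return (auc_ins / auc_glu) * matsuda(curve)


def misi(
    curve: OGTTCurve,
    convention: MISIConvention | str = MISIConvention.span_slope,
) -> tuple[float, bool]:
    """Muscle insulin sensitivity index (glucose slope / mean insulin).

    Returns ``(value, flat)`` where ``flat`` marks a degenerate curve
    (glucose maximum equals minimum) scored as 0.  See
    :class:`MISIConvention` for the two slope conventions.
    """
    curve._require_full("MISI")
    convention = MISIConvention(convention)
    g = np.array([glucose_to_mgdl(x) for x in curve.glucose])
    t = np.asarray(curve.times)
    mi = curve.mean_insulin

    if convention is MISIConvention.span_slope:
        i_max = int(np.argmax(g))
        i_min = int(np.argmin(g))
        if g[i_max] == g[i_min]:
            warnings.warn("flat glucose curve: MISI set to 0", stacklevel=2)
            return 0.0, True
        duration = abs(t[i_min] - t[i_max])
        return float(100.0 * (g[i_min] - g[i_max]) / duration / mi), False

    # peak_decay: slope of the fall from the glucose peak to the
    # post-peak nadir; positive when the curve decays, 0 when it never
    # falls off its peak.
    i_peak = int(np.argmax(g))
    if g[i_peak] == g.min():
        warnings.warn("flat glucose curve: MISI set to 0", stacklevel=2)
        return 0.0, True
    if i_peak == len(g) - 1:
        warnings.warn("glucose never decays from its peak: MISI set to 0", stacklevel=2)
        return 0.0, True
    tail = g[i_peak:]
    i_nadir = i_peak + int(np.argmin(tail))
    return float(100.0 * (g[i_peak] - g[i_nadir]) / (t[i_nadir] - t[i_peak]) / mi), False


def compute_panel(
    curve: OGTTCurve,
    convention: MISIConvention | str = MISIConvention.span_slope,
) -> IndexPanel:
    """Compute all five indices for a full five-point OGTT curve."""
    curve._require_full("index panel")
    misi_value, flat = misi(curve, convention)
    return IndexPanel(
        matsuda=matsuda(curve),
        disposition=disposition_index(curve),
        hiri=hiri(curve.fasting_glucose, curve.fasting_insulin),
        misi=misi_value,
        homa_ir=homa_ir(curve.fasting_glucose, curve.fasting_insulin),
        misi_flat=flat,
    )
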