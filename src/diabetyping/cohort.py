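"""Longitudinal cohort summaries: per-visit statistics, outlier masks,
and paired within-participant change.

The study-level inference this package reports is deliberately simple:
per-visit means and sample SDs, a |z| > 3 standardized-residual outlier
rule, and two-sided paired t contrasts between visits (optionally on
log10-transformed values).  Mixed-effects modelling is out of scope;
the outputs here are labeled paired contrasts, not model-based
estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .indices import Visit

__all__ = [
    "summarize_visits",
    "flag_outliers",
    "paired_change",
]

_VISITS = [v.value for v in Visit]


def _check_long_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "visit", "variable", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table.duplicated(subset=["participant_id", "visit", "variable"]).any():
        raise ValueError("one value per (participant, visit, variable) expected")
    bad = set(table["visit"]) - set(_VISITS)
    if bad:
        raise ValueError(f"unknown visits {sorted(bad)}")
    return table


def summarize_visits(table: pd.DataFrame) -> pd.DataFrame:
    """Per-visit mean, sample SD (ddof=1) and n for each variable.

    ``table`` is long-format with columns ``participant_id``, ``visit``,
    ``variable``, ``value``.  Missing values are excluded pairwise and
    reported in ``n_missing`` (participants present in the table but
    without a value for that variable-visit cell).
    """
    table = _check_long_table(table)
    n_participants = table["participant_id"].nunique()
    present = table.dropna(subset=["value"])
    grouped = present.groupby(["variable", "visit"])["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["n_missing"] = n_participants - out["n"]
    return out


def flag_outliers(residuals) -> np.ndarray:
    """Keep-mask over standardized residuals: ``True`` keeps |z| <= 3.

    The boundary |z| = 3 is kept (strict inequality excludes).
    """
    z = np.asarray(residuals, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("residuals must be finite")
    return np.abs(z) <= 3.0


def paired_change(
    table: pd.DataFrame,
    variable: str,
    visit_pair: tuple[str, str] = ("baseline", "month3"),
    *,
    log10: bool = False,
) -> dict[str, float]:
    """Within-participant change of one variable between two visits.

    Returns mean and sample SD of the per-participant differences
    (second visit minus first) and the two-sided paired-t p-value.
    With ``log10=True`` the differences are taken on log10 values, i.e.
    the contrast is on fold change.  Requires >= 3 complete pairs; the
    degenerate all-identical case reports p = 1 (no evidence of change).
    """
    table = _check_long_table(table)
    a, b = visit_pair
    for v in (a, b):
        if v not in _VISITS:
            raise ValueError(f"unknown visit {v!r}")
    sub = table[(table["variable"] == variable) & (table["visit"].isin([a, b]))]
    wide = sub.pivot(index="participant_id", columns="visit", values="value").dropna()
    if len(wide) < 3 or a not in wide.columns or b not in wide.columns:
        raise ValueError("need at least 3 complete pairs")
    x, y = wide[a].to_numpy(float), wide[b].to_numpy(float)
    if log10:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log10 transform requires positive values")
        x, y = np.log10(x), np.log10(y)
    diff = y - x
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
    else:
        p = float(stats.ttest_rel(y, x).pvalue)
    return {"mean_change": mean, "sd_change": sd, "p_value": p, "n_pairs": len(wide)}
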