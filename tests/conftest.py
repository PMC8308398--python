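"""Shared fixtures: hand-built curves and cohort-count tables.

The count fixtures encode only published aggregate counts (how many
participants carried each subtype or status at each visit); they contain
no patient-level data and are constructed programmatically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from diabetyping import OGTTCurve

TIMES = (0.0, 30.0, 60.0, 90.0, 120.0)


def make_curve(glucose, insulin, pid="p1", visit="baseline") -> OGTTCurve:
    return OGTTCurve(
        participant_id=pid,
        visit=visit,
        times=TIMES,
        glucose=tuple(glucose),
        insulin=tuple(insulin),
    )


@pytest.fixture
def flat_curve():
    """Glucose 100 mg/dL (100/18 mmol/L) and insulin 10 mU/L throughout."""
    return make_curve([100.0 / 18.0] * 5, [10.0] * 5)


@pytest.fixture
def rising_curve():
    """Monotone rise 12 -> 22 mmol/L (span 180 mg/dL), insulin 40 throughout."""
    return make_curve([12.0, 14.5, 17.0, 19.5, 22.0], [40.0] * 5)


def random_curves(n: int, seed: int = 0) -> list[OGTTCurve]:
    """Positive random five-point curves spanning realistic magnitudes."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        glucose = rng.uniform(3.0, 25.0, size=5)
        insulin = rng.uniform(2.0, 200.0, size=5)
        out.append(make_curve(glucose, insulin, pid=f"r{i}"))
    return out


@pytest.fixture
def subtype_flow_fixture() -> pd.DataFrame:
    """Cohort of 15 with the study's published subtype counts.

    Baseline: 12 IB-HIR + 1 IB, 2 not classifiable (missing).
    Month 3: 1 IB, 7 IB-HIR, 7 IB-CIR.  Month 6: 10 IB-HIR, 5 IB-CIR.
    """
    rows = []
    baseline = ["IB-HIR"] * 12 + ["IB"] + [None] * 2
    month3 = ["IB"] + ["IB-HIR"] * 7 + ["IB-CIR"] * 7
    month6 = ["IB-HIR"] * 10 + ["IB-CIR"] * 5
    for i in range(15):
        pid = f"P{i:02d}"
        if baseline[i] is not None:
            rows.append({"participant_id": pid, "visit": "baseline", "label": baseline[i]})
        rows.append({"participant_id": pid, "visit": "month3", "label": month3[i]})
        rows.append({"participant_id": pid, "visit": "month6", "label": month6[i]})
    return pd.DataFrame(rows)


@pytest.fixture
def status_counts_fixture() -> pd.DataFrame:
    """Status calls for 15 participants matching the published counts.

    All T2D at baseline; month 3: 4 reversal + 2 remission; month 6:
    3 reversal + 2 remission.
    """
    rows = []
    month3 = ["reversal"] * 4 + ["remission"] * 2 + ["T2D"] * 9
    month6 = ["reversal"] * 3 + ["remission"] * 2 + ["T2D"] * 10
    for i in range(15):
        pid = f"P{i:02d}"
        rows.append({"participant_id": pid, "visit": "baseline", "status": "T2D"})
        rows.append({"participant_id": pid, "visit": "month3", "status": month3[i]})
        rows.append({"participant_id": pid, "visit": "month6", "status": month6[i]})
    return pd.DataFrame(rows)
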