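"""Unit and property tests for the OGTT index computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diabetyping import (
    IndexPanel,
    MISIConvention,
    OGTTCurve,
    compute_panel,
    disposition_index,
    glucose_to_mgdl,
    hiri,
    homa_ir,
    matsuda,
    misi,
    trapezoid_auc,
)

from conftest import TIMES, make_curve, random_curves
from oracles import oracle_panel


class TestUnitConversion:
    @pytest.mark.parametrize(
        "mmol, mgdl", [(11.98, 215.64), (5.0, 90.0), (1.0 / 18.0, 1.0)]
    )
    def test_known_conversions(self, mmol, mgdl):
        assert glucose_to_mgdl(mmol) == pytest.approx(mgdl)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            glucose_to_mgdl(bad)


class TestTrapezoidAUC:
    def test_constant_curve(self):
        assert trapezoid_auc(TIMES, [7.0] * 5, (0, 30)) == pytest.approx(210.0)

    def test_hand_trapezoid(self):
        assert trapezoid_auc((0, 30), (10, 20), (0, 30)) == pytest.approx(450.0)

    def test_degenerate_window(self):
        assert trapezoid_auc(TIMES, [1, 2, 3, 4, 5], (60, 60)) == 0.0

    def test_off_grid_endpoint_rejected(self):
        with pytest.raises(ValueError, match="not a sampling time"):
            trapezoid_auc(TIMES, [1, 2, 3, 4, 5], (0, 45))

    def test_linearity_and_additivity(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(1, 50, size=5)
        w = rng.uniform(1, 50, size=5)
        a = trapezoid_auc(TIMES, v, (0, 120))
        b = trapezoid_auc(TIMES, w, (0, 120))
        assert trapezoid_auc(TIMES, 2.5 * v + w, (0, 120)) == pytest.approx(2.5 * a + b)
        assert trapezoid_auc(TIMES, v, (0, 60)) + trapezoid_auc(
            TIMES, v, (60, 120)
        ) == pytest.approx(a)


class TestFastingIndices:
    def test_homa_ir_values(self):
        assert homa_ir(11.98, 23.9) == pytest.approx(12.725, abs=5e-3)
        assert homa_ir(4.5, 5.0) == pytest.approx(1.0)
        assert homa_ir(22.5, 1.0) == pytest.approx(1.0)

    def test_hiri_unit_case(self):
        assert hiri(1.0 / 18.0, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("homa, printed", [(11.8, 4779), (15.35, 6217)])
    def test_hiri_from_homa(self, homa, printed):
        # same fasting sample read through the two unit conventions
        fi = 23.9
        fg = homa * 22.5 / fi
        assert hiri(fg, fi) == pytest.approx(printed, rel=5e-3)


class TestMatsudaAndDisposition:
    def test_flat_curve_matsuda(self, flat_curve):
        assert matsuda(flat_curve) == pytest.approx(10.0)

    def test_flat_curve_disposition(self, flat_curve):
        assert disposition_index(flat_curve) == pytest.approx(1.0)

    def test_hand_value(self):
        # fG'=215.6, fI=23.9, and a curve shaped to give mG'=280, mI=40
        g_mgdl = [215.6, 260.0, 320.0, 310.0, 294.4]
        ins = [23.9, 40.0, 52.0, 46.0, 38.1]
        assert sum(g_mgdl) / 5 == pytest.approx(280.0)
        assert sum(ins) / 5 == pytest.approx(40.0)
        curve = make_curve([g / 18.0 for g in g_mgdl], ins)
        expected = 10000.0 / math.sqrt(215.6 * 23.9 * 280.0 * 40.0)
        assert matsuda(curve) == pytest.approx(expected)
        assert expected == pytest.approx(1.32, abs=0.01)

    def test_matsuda_scaling_homogeneity(self, rising_curve):
        k = 1.7
        scaled = make_curve(
            [g * k for g in rising_curve.glucose],
            [i * k for i in rising_curve.insulin],
        )
        assert matsuda(scaled) == pytest.approx(matsuda(rising_curve) / k**2)

    def test_disposition_invariant_under_insulin_scaling(self, flat_curve):
        # insulin enters Matsuda as both fI and mI, so scaling the whole
        # insulin trace by c multiplies the AUC ratio by c and Matsuda by
        # 1/c: the disposition index is invariant
        doubled = make_curve(flat_curve.glucose, [2 * i for i in flat_curve.insulin])
        assert matsuda(doubled) == pytest.approx(matsuda(flat_curve) / 2)
        assert disposition_index(doubled) == pytest.approx(
            disposition_index(flat_curve)
        )

    def test_disposition_equals_matsuda_when_traces_match(self):
        # insulin numerically equal to the mg/dL glucose trace -> ratio 1
        glucose = [6.0, 8.0, 10.0, 9.0, 7.0]
        insulin = [g * 18.0 for g in glucose]
        curve = make_curve(glucose, insulin)
        assert disposition_index(curve) == pytest.approx(matsuda(curve))

    def test_partial_curve_rejected(self):
        curve = OGTTCurve("p", "baseline", (0, 30, 60, 120), (5, 6, 7, 5), (5, 9, 8, 6))
        with pytest.raises(ValueError, match="canonical"):
            matsuda(curve)


class TestMISI:
    def test_monotone_rise_hand_value(self, rising_curve):
        # span 180 mg/dL over 120 min, mean insulin 40
        value, flat = misi(rising_curve)
        assert not flat
        assert value == pytest.approx(100 * (-180.0 / 120.0) / 40.0)

    def test_flat_curve_flagged_zero(self, flat_curve):
        with pytest.warns(UserWarning):
            value, flat = misi(flat_curve)
        assert value == 0.0 and flat

    def test_peak_decay_positive_on_decaying_curve(self):
        curve = make_curve([6.0, 12.0, 10.0, 8.0, 7.0], [10.0] * 5)
        value, flat = misi(curve, MISIConvention.peak_decay)
        # fall 12 -> 7 mmol/L (90 mg/dL) over 90 min, mI = 10
        assert not flat
        assert value == pytest.approx(100 * (90.0 / 90.0) / 10.0)

    def test_peak_decay_zero_when_never_decaying(self, rising_curve):
        with pytest.warns(UserWarning):
            value, flat = misi(rising_curve, "peak_decay")
        assert value == 0.0 and flat

    def test_span_slope_never_positive(self):
        for curve in random_curves(50, seed=5):
            value, _ = misi(curve)
            assert value <= 0.0


class TestComputePanel:
    def test_hiri_homa_identity_random_curves(self):
        for curve in random_curves(100, seed=1):
            panel = compute_panel(curve)
            assert panel.hiri == pytest.approx(panel.homa_ir * 405.0, rel=1e-12)

    def test_oracle_equivalence(self):
        for curve in random_curves(200, seed=2):
            panel = compute_panel(curve)
            expected = oracle_panel(curve)
            for name in ("matsuda", "disposition", "hiri", "misi", "homa_ir"):
                assert getattr(panel, name) == pytest.approx(
                    expected[name], rel=1e-9
                ), name

    def test_missing_sample_rejected(self):
        curve = OGTTCurve("p", "baseline", (0, 30, 60, 120), (5, 6, 7, 5), (5, 9, 8, 6))
        with pytest.raises(ValueError):
            compute_panel(curve)


class TestCurveValidation:
    @pytest.mark.parametrize(
        "times, glucose, insulin",
        [
            ((30, 60, 90, 120, 150), [5] * 5, [5] * 5),  # no fasting sample
            ((0, 30, 30, 90, 120), [5] * 5, [5] * 5),  # non-increasing
            (TIMES, [5, 5, -1, 5, 5], [5] * 5),  # negative glucose
            (TIMES, [5] * 5, [5] * 4),  # length mismatch
        ],
    )
    def test_invalid_curves_rejected(self, times, glucose, insulin):
        with pytest.raises(ValueError):
            OGTTCurve("p", "baseline", tuple(times), tuple(glucose), tuple(insulin))

    def test_panel_invariants_enforced(self):
        with pytest.raises(ValueError):
            IndexPanel(matsuda=-1.0, disposition=0.1, hiri=1.0, misi=0.0, homa_ir=1.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    glucose=st.lists(st.floats(0.5, 30.0), min_size=5, max_size=5),
    insulin=st.lists(st.floats(0.5, 300.0), min_size=5, max_size=5),
    k=st.floats(0.1, 10.0),
)
def test_scaling_properties(glucose, insulin, k):
    """HIRI/HOMA scale as k^2, Matsuda as k^-2 under joint rescaling."""
    curve = make_curve(glucose, insulin)
    scaled = make_curve([g * k for g in glucose], [i * k for i in insulin])
    p, q = compute_panel(curve), compute_panel(scaled)
    assert q.hiri == pytest.approx(p.hiri * k**2, rel=1e-9)
    assert q.homa_ir == pytest.approx(p.homa_ir * k**2, rel=1e-9)
    assert q.matsuda == pytest.approx(p.matsuda / k**2, rel=1e-9)
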