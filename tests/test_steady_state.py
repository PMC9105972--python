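import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tdikin.assays import ProgressCurve
from tdikin.steady_state import (
    analyze_inhibition,
    approach_to_steady_state,
    classify,
    cornish_bowden_kiu,
    dixon_kic,
    equilibrium_fractions,
    fraction_dissociated,
    initial_velocity,
    lineweaver_burk,
    residence_time,
    v_meas_preincubated,
    v_ss_competitive,
)

VMAX, KM, KI = 1e-7, 10e-6, 1e-6


class TestRateLaws:
    def test_half_saturation_no_inhibitor(self):
        assert v_ss_competitive(VMAX, KM, KM, 0.0, KI) == pytest.approx(VMAX / 2)

    def test_vss_at_km_and_ki(self):
        # S = Km, I = Ki: v = Vmax/3
        assert v_ss_competitive(VMAX, KM, KM, KI, KI) == pytest.approx(3.3333e-8, rel=1e-4)

    def test_competitive_limit_recovers_vmax(self):
        assert v_ss_competitive(VMAX, KM, 1.0, 50 * KI, KI) == pytest.approx(VMAX, rel=1e-3)

    def test_vmeas_at_km_and_ki(self):
        # pure noncompetitive form: Vmax * 1/2 * 1/2
        assert v_meas_preincubated(VMAX, KM, KM, KI, KI) == pytest.approx(2.5e-8, rel=1e-12)

    def test_vmeas_to_vss_ratio(self):
        r = v_meas_preincubated(VMAX, KM, KM, KI, KI) / v_ss_competitive(VMAX, KM, KM, KI, KI)
        assert r == pytest.approx(0.75, rel=1e-12)

    def test_no_inhibitor_reduces_to_michaelis_menten(self):
        s = np.array([1e-6, 5e-6, 2e-5])
        assert np.allclose(
            v_meas_preincubated(VMAX, KM, s, 0.0, KI), VMAX * s / (s + KM), rtol=1e-14
        )


class TestEquilibriumFractions:
    def test_equal_thirds_at_km_and_ki(self):
        assert equilibrium_fractions(KM, KM, KI, KI) == pytest.approx((1 / 3,) * 3)

    def test_half_bound_without_substrate(self):
        assert equilibrium_fractions(0.0, KM, KI, KI) == pytest.approx((0.5, 0.0, 0.5))

    def test_free_enzyme_only(self):
        assert equilibrium_fractions(0.0, KM, 0.0, KI) == (1.0, 0.0, 0.0)

    @given(
        s=st.floats(0, 1e-3), i=st.floats(0, 1e-3),
        km=st.floats(1e-7, 1e-3), ki=st.floats(1e-9, 1e-3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_fractions_partition_unity(self, s, i, km, ki):
        f = equilibrium_fractions(s, km, i, ki)
        assert sum(f) == pytest.approx(1.0, rel=1e-12)
        assert all(x >= 0 for x in f)


class TestResidence:
    def test_printed_case_study_value(self):
        # k_off = 1.57e-2 1/s -> tau = 63.7 s
        assert residence_time(1.57e-2) == pytest.approx(63.69, rel=1e-3)

    def test_dissociation_fractions(self):
        assert fraction_dissociated(0.0, 1.0) == 0.0
        tau = residence_time(1e-2)
        assert fraction_dissociated(3 * tau, 1e-2) == pytest.approx(0.9502, rel=1e-4)
        # note: 3.5 residence times gives ~97%, not 95%
        assert fraction_dissociated(3.5 * tau, 1e-2) == pytest.approx(0.9698, rel=1e-4)

    def test_invalid_koff(self):
        with pytest.raises(ValueError):
            residence_time(0.0)


class TestInitialVelocity:
    def _linear(self, v=2e-9, t_end=30.0, p0=0.0):
        t = np.linspace(0, t_end, 61)
        return ProgressCurve(t, p0 + v * t, s0=1e-5, i0=0.0, p0=p0)

    @pytest.mark.parametrize("mode", ["chord", "window_slope", "instantaneous"])
    def test_linear_curve_returns_true_slope(self, mode):
        c = self._linear()
        assert initial_velocity(c, 10.0, 10.0, mode=mode) == pytest.approx(2e-9, rel=1e-9)

    def test_chord_equals_first_reading_over_elapsed_time(self):
        a, b = 1e-5, 1e-2
        t = np.linspace(0, 30, 301)
        c = ProgressCurve(t, a * (1 - np.exp(-b * t)), s0=1e-5, i0=0.0)
        expected = a * (1 - math.exp(-b * 10.0)) / 10.0
        assert initial_velocity(c, 10.0, 10.0, mode="chord") == pytest.approx(expected, rel=1e-9)

    def test_window_slope_is_bracketed_by_endpoint_rates(self):
        # concave-down exponential: OLS slope lies between the derivatives
        # at the window edges
        a, b = 1e-5, 1e-2
        t = np.linspace(0, 30, 301)
        c = ProgressCurve(t, a * (1 - np.exp(-b * t)), s0=1e-5, i0=0.0)
        s = initial_velocity(c, 10.0, 10.0, mode="window_slope")
        assert a * b * math.exp(-b * 20) < s < a * b * math.exp(-b * 10)

    def test_window_slope_matches_exact_ols_oracle(self):
        # brute-force normal equations on the same samples
        a, b = 1e-5, 1e-2
        t = np.linspace(0, 30, 61)
        y = a * (1 - np.exp(-b * t))
        c = ProgressCurve(t, y, s0=1e-5, i0=0.0)
        m = (t >= 10) & (t <= 20)
        tm, ym = t[m], y[m]
        oracle = ((tm - tm.mean()) @ (ym - ym.mean())) / ((tm - tm.mean()) @ (tm - tm.mean()))
        assert initial_velocity(c, 10.0, 10.0, mode="window_slope") == pytest.approx(oracle, rel=1e-12)

    def test_baseline_product_subtracted_in_chord(self):
        c = self._linear(p0=5e-6)
        assert initial_velocity(c, 10.0, 10.0, mode="chord") == pytest.approx(2e-9, rel=1e-9)

    def test_too_few_window_samples(self):
        t = np.array([0.0, 5.0, 30.0])
        c = ProgressCurve(t, t * 1e-9, s0=1e-5, i0=0.0)
        with pytest.raises(ValueError, match="samples"):
            initial_velocity(c, 10.0, 10.0, mode="window_slope")


def _closed_form_dataset(law, i_levels=(0, 0.5e-6, 1e-6, 2e-6, 5e-6, 10e-6, 20e-6, 50e-6)):
    s_levels = np.array([1, 2, 5, 10, 20, 50, 100, 150, 200]) * 1e-6
    rows = []
    for i0 in i_levels:
        for s0 in s_levels:
            rows.append(
                {"s0_M": s0, "i0_M": i0, "replicate": 0, "v_M_per_s": float(law(VMAX, KM, s0, i0, KI))}
            )
    return pd.DataFrame(rows)


class TestDoubleReciprocal:
    def test_exact_mm_slope_and_intercept(self):
        ds = _closed_form_dataset(v_ss_competitive, i_levels=(0.0,))
        lb = lineweaver_burk(ds)
        assert lb.loc[0, "slope"] == pytest.approx(KM / VMAX, rel=1e-12)
        assert lb.loc[0, "intercept"] == pytest.approx(1 / VMAX, rel=1e-12)

    def test_competitive_lines_share_the_1v_intercept(self):
        lb = lineweaver_burk(_closed_form_dataset(v_ss_competitive))
        assert np.allclose(lb["intercept"], 1 / VMAX, rtol=1e-3)

    def test_preincubated_intercepts_scale_noncompetitively(self):
        lb = lineweaver_burk(_closed_form_dataset(v_meas_preincubated))
        expected = (1 + lb["i0_M"] / KI) / VMAX
        assert np.allclose(lb["intercept"], expected, rtol=1e-9)

    def test_replots_recover_generating_constants(self):
        # competitive truth: Kic = Ki, no uncompetitive component
        lb = lineweaver_burk(_closed_form_dataset(v_ss_competitive))
        assert dixon_kic(lb) == pytest.approx(KI, rel=1e-3)
        assert math.isinf(cornish_bowden_kiu(lb))
        # preincubated appearance: pure noncompetitive at the true Ki
        lb = lineweaver_burk(_closed_form_dataset(v_meas_preincubated))
        assert dixon_kic(lb) == pytest.approx(KI, rel=1e-3)
        assert cornish_bowden_kiu(lb) == pytest.approx(KI, rel=1e-3)

    def test_replot_requires_three_levels(self):
        lb = lineweaver_burk(_closed_form_dataset(v_ss_competitive, i_levels=(0.0, 1e-6)))
        with pytest.raises(ValueError, match="3 inhibitor levels"):
            dixon_kic(lb)

    def test_weighting_name_checked(self):
        with pytest.raises(ValueError):
            lineweaver_burk(_closed_form_dataset(v_ss_competitive), weighting="huber")


class TestClassify:
    @pytest.mark.parametrize(
        "kic,kiu,expected",
        [
            (1e-6, math.inf, "competitive"),
            (1e-6, 1.05e-6, "noncompetitive"),
            (1e-6, 8e-6, "mixed"),
            (8e-6, 1e-7, "uncompetitive"),
            (math.inf, math.inf, "none"),
        ],
    )
    def test_labels(self, kic, kiu, expected):
        assert classify(kic, kiu) == expected


class TestApproachToSteadyState:
    def test_recovery_time_scales_with_residence_time(self):
        t_slow, _ = approach_to_steady_state(k_off=1e-2, t_max=600.0, dt=2.0)
        t_faster, _ = approach_to_steady_state(k_off=3e-2, t_max=600.0, dt=2.0)
        assert t_faster < t_slow
        # first-order expectation: ~3.5 residence times, accelerated a
        # little by rebinding
        assert 200.0 < t_slow < 400.0

    def test_table_contains_both_trajectories(self):
        _, tab = approach_to_steady_state(t_max=400.0, dt=5.0)
        assert {"time_s", "ES_slow_M", "ES_reference_M"} <= set(tab.columns)
        # slow system starts at roughly half occupancy relative to reference
        r = tab["ES_slow_M"][1] / tab["ES_reference_M"][1]
        assert 0.4 < r < 0.6
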