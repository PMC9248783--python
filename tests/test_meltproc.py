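"""Melting-curve processing: smoothing, derivative, Tm, differences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meltid import synthdata
from meltid.meltproc import (
    DifferenceCurve,
    MeltCurve,
    SmoothingConfig,
    average_replicates,
    call_tm,
    difference_curves,
    negative_derivative,
    normalize_fluorescence,
    process_dataset,
    regrid,
    smooth,
)

GRID3 = np.array([65.0, 65.1, 65.2])


def curve(values, grid=None, sid="c", **kw):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = 65.0 + 0.1 * np.arange(values.size)
    return MeltCurve(np.asarray(grid, dtype=float), values, sid, **kw)


class TestSmooth:
    def test_constant_series_unchanged(self):
        t = 65.0 + 0.1 * np.arange(11)
        out = smooth(np.full(11, 7.5), t)
        np.testing.assert_allclose(out, 7.5)

    def test_quadratic_in_fit_space_reproduced(self):
        t = 65.0 + 0.1 * np.arange(21)
        f = 3.0 + 0.5 * t - 0.02 * t**2
        np.testing.assert_allclose(smooth(f, t), f, atol=1e-9)

    def test_disabled_returns_input(self):
        t = 65.0 + 0.1 * np.arange(9)
        f = np.random.default_rng(0).normal(size=9)
        out = smooth(f, t, SmoothingConfig(enabled=False))
        assert out is f or np.array_equal(out, f)

    def test_nonuniform_grid_refused(self):
        t = np.array([65.0, 65.1, 65.3, 65.4, 65.5, 65.6, 65.7])
        with pytest.raises(ValueError, match="regrid"):
            smooth(np.ones(7), t)

    def test_window_longer_than_series_refused(self):
        t = 65.0 + 0.1 * np.arange(5)
        with pytest.raises(ValueError, match="window"):
            smooth(np.ones(5), t, SmoothingConfig(window=7))

    @pytest.mark.parametrize("window,order", [(4, 2), (3, 2)])
    def test_invalid_config(self, window, order):
        with pytest.raises(ValueError):
            SmoothingConfig(window=window, poly_order=order)


class TestNegativeDerivative:
    def test_hand_finite_differences(self):
        mc = negative_derivative([100.0, 90.0, 70.0], GRID3)
        np.testing.assert_allclose(mc.dneg[1], 150.0)  # -(70-100)/0.2
        np.testing.assert_allclose(mc.dneg[0], 100.0)  # one-sided
        np.testing.assert_allclose(mc.dneg[2], 200.0)

    def test_constant_input_zero_output(self):
        mc = negative_derivative([5.0, 5.0, 5.0, 5.0], 65.0 + 0.1 * np.arange(4))
        np.testing.assert_allclose(mc.dneg, 0.0)

    def test_linear_input_constant_output(self):
        t = 65.0 + 0.1 * np.arange(10)
        mc = negative_derivative(1000.0 - 3.0 * t, t)
        np.testing.assert_allclose(mc.dneg, 3.0, atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            negative_derivative([1.0, 2.0], np.array([65.0, 65.1]))

    def test_quadrature_consistency(self):
        """Trapezoidal integral of -dF/dT equals F(a) - F(b) + O(step^2)."""
        t = np.linspace(65, 95, 301)
        f = 1.0 + 1.0 / (1.0 + np.exp((t - 78.0) / 0.6))
        mc = negative_derivative(f, t)
        integral = np.trapezoid(mc.dneg, t)
        assert integral == pytest.approx(f[0] - f[-1], abs=1e-4)


class TestCallTm:
    def test_noiseless_two_state_curve(self):
        params = synthdata.MeltModelParams(noise_sd=0.0, tm=78.3)
        ds, _ = synthdata.simulate_melt_plate({"w": 78.3}, params, replicates=1)
        mc = process_dataset(ds)[0]
        assert mc.tm == pytest.approx(78.3, abs=0.05)

    def test_monotone_dneg_flags_no_peak(self):
        mc = call_tm(curve(np.arange(10.0)))
        assert mc.no_peak and mc.tm is None

    def test_symmetric_triangle_peak_on_grid_point(self):
        mc = call_tm(curve([0.0, 1.0, 2.0, 1.0, 0.0]))
        assert mc.tm == pytest.approx(65.2)

    def test_tie_broken_toward_lower_temperature(self):
        mc = call_tm(curve([0.0, 2.0, 1.0, 2.0, 0.0]))
        assert mc.tm <= 65.15


class TestAverageReplicates:
    def test_identical_curves_mean_identical(self):
        cs = [curve([0.0, 1.0, 0.0], sid=f"w{i}", replicate_group="g") for i in range(5)]
        out = average_replicates(cs)
        assert len(out) == 1
        np.testing.assert_allclose(out[0].dneg, [0, 1, 0])

    def test_hand_mean(self):
        a = curve([0.0, 2.0], grid=[65.0, 65.1], sid="a", replicate_group="g")
        b = curve([2.0, 0.0], grid=[65.0, 65.1], sid="b", replicate_group="g")
        np.testing.assert_allclose(average_replicates([a, b])[0].dneg, [1.0, 1.0])

    def test_group_sizes_5_5_1(self):
        cs = [curve([0, 1, 0], sid=f"a{i}", replicate_group="g1") for i in range(5)]
        cs += [curve([0, 2, 0], sid=f"b{i}", replicate_group="g2") for i in range(5)]
        cs += [curve([0, 3, 0], sid="solo", replicate_group="g3")]
        assert len(average_replicates(cs)) == 3

    def test_mismatched_grids_error_names_group(self):
        a = curve([0.0, 1.0], grid=[65.0, 65.1], sid="a", replicate_group="bad")
        b = curve([0.0, 1.0], grid=[65.0, 65.2], sid="b", replicate_group="bad")
        with pytest.raises(ValueError, match="bad"):
            average_replicates([a, b])


class TestDifferenceCurves:
    def test_hand_worked_example(self):
        cs = [curve([2.0, 4.0], grid=[65, 65.1], sid="a"),
              curve([0.0, 0.0], grid=[65, 65.1], sid="b"),
              curve([1.0, 2.0], grid=[65, 65.1], sid="c")]
        deltas = difference_curves(cs)
        np.testing.assert_allclose(deltas[0].delta, [-1.0, -2.0])
        np.testing.assert_allclose(deltas[1].delta, [1.0, 2.0])
        np.testing.assert_allclose(deltas[2].delta, [0.0, 0.0])
        total = sum(d.delta for d in deltas)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_single_curve_set_zero_delta(self):
        d = difference_curves([curve([3.0, 1.0], grid=[65, 65.1])])
        np.testing.assert_allclose(d[0].delta, 0.0)

    def test_all_identical_all_zero(self):
        cs = [curve([1.0, 5.0], grid=[65, 65.1], sid=f"w{i}") for i in range(4)]
        for d in difference_curves(cs):
            np.testing.assert_allclose(d.delta, 0.0)

    def test_outside_curves_use_reference_mean(self):
        cs = [curve([2.0, 2.0], grid=[65, 65.1], sid="ref1"),
              curve([4.0, 4.0], grid=[65, 65.1], sid="ref2"),
              curve([0.0, 0.0], grid=[65, 65.1], sid="unknown")]
        deltas = difference_curves(cs, reference_set=["ref1", "ref2"])
        np.testing.assert_allclose(deltas[2].delta, [3.0, 3.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.lists(st.floats(-100, 100), min_size=4, max_size=4),
                    min_size=2, max_size=6))
    def test_sum_zero_property(self, rows):
        cs = [curve(row, sid=f"w{i}") for i, row in enumerate(rows)]
        deltas = difference_curves(cs)
        np.testing.assert_allclose(sum(d.delta for d in deltas), 0.0, atol=1e-9)


class TestRegrid:
    def test_identity_on_same_grid(self):
        t = np.array([65.0, 65.1, 65.2])
        np.testing.assert_allclose(regrid([1.0, 2.0, 3.0], t, t), [1, 2, 3])

    def test_linear_data_exact_anywhere(self):
        t = np.linspace(65, 95, 31)
        v = 2.0 * t - 1.0
        target = np.linspace(66.05, 94.35, 17)
        np.testing.assert_allclose(regrid(v, t, target), 2.0 * target - 1.0)

    def test_extrapolation_refused(self):
        with pytest.raises(ValueError, match="extrapolation"):
            regrid([1.0, 2.0], np.array([65.0, 66.0]), np.array([64.0, 65.0]))


class TestPipelineEquivariance:
    def test_offset_invariance_and_scaling(self):
        """+const on raw F leaves curves unchanged; scaling scales them."""
        params = synthdata.MeltModelParams(noise_sd=0.003, seed=4)
        ds, _ = synthdata.simulate_melt_plate({"a": 74.0, "b": 75.0}, params, replicates=2)
        base = process_dataset(ds)
        base_d = difference_curves(base)
        for s in ds.samples:
            s.rfu = 3.0 * s.rfu + 100.0
        scaled = process_dataset(ds)
        scaled_d = difference_curves(scaled)
        for b, s in zip(base, scaled):
            np.testing.assert_allclose(s.dneg, 3.0 * b.dneg, rtol=1e-9, atol=1e-12)
        for b, s in zip(base_d, scaled_d):
            np.testing.assert_allclose(s.delta, 3.0 * b.delta, rtol=1e-9, atol=1e-12)


class TestTmRecovery:
    @pytest.mark.parametrize("width", [0.3, 0.6, 1.2])
    @pytest.mark.parametrize("tm", [70.25, 78.3, 88.0])
    def test_noiseless_recovery_within_0p05(self, width, tm):
        params = synthdata.MeltModelParams(noise_sd=0.0, s=width)
        ds, _ = synthdata.simulate_melt_plate({"w": tm}, params, replicates=1)
        mc = process_dataset(ds)[0]
        assert mc.tm == pytest.approx(tm, abs=0.05)


class TestNormalizeFluorescence:
    def test_maps_baselines_to_unit_interval(self):
        t = np.linspace(65, 95, 301)
        f = 2.0 - 0.001 * t + 1.0 / (1.0 + np.exp((t - 78.0) / 0.6))
        norm = normalize_fluorescence(f, t)
        assert norm[(t >= 65) & (t <= 70)].mean() == pytest.approx(1.0, abs=0.01)
        assert norm[(t >= 90) & (t <= 95)].mean() == pytest.approx(0.0, abs=0.01)
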