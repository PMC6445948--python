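"""Speed computation, Kalman reconstruction and the scalar filters."""

import numpy as np
import pytest

from phasevel import (
    BENCHMARK_FILTERS,
    Calibration,
    FilterSpec,
    KalmanModel,
    Track,
    VelocitySeries,
    apply_filter,
    compute_speed,
    kalman_reconstruct,
    r_squared,
)
from phasevel.filters import (
    SPENCER_WEIGHTS,
    FilterSpecError,
    InsufficientDataError,
    kalman_filter_positions,
)

from conftest import constant_velocity_track


class TestComputeSpeed:
    def test_three_four_five(self):
        t = Track("a", [0, 1, 2], [0.0, 3.0, 6.0], [0.0, 4.0, 8.0])
        np.testing.assert_allclose(compute_speed(t).values, [5.0, 5.0])

    def test_calibration_scales_to_um_per_s(self):
        t = Track("a", [0, 1], [0.0, 5.0], [0.0, 0.0])
        s = compute_speed(t, Calibration(pixel_size=0.1, frame_interval=0.1))
        np.testing.assert_allclose(s.values, [5.0])
        assert s.units == "um/s"

    def test_stationary(self):
        t = Track("a", [0, 1, 2], [1.0] * 3, [2.0] * 3)
        np.testing.assert_allclose(compute_speed(t).values, 0.0)

    def test_gap_divides_by_elapsed_frames(self):
        t = Track("a", [0, 3], [0.0, 9.0], [0.0, 0.0])
        np.testing.assert_allclose(compute_speed(t).values, [3.0])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            compute_speed(Track("a", [0], [0.0], [0.0]))


class TestKalman:
    def test_noiseless_constant_velocity_converges_to_true_speed(self):
        track = constant_velocity_track(3.0, 4.0, n=100)
        s = kalman_reconstruct(track)
        assert len(s) == 99
        # after burn-in the estimate must sit on the true 5 px/frame
        np.testing.assert_allclose(s.values[20:], 5.0, atol=1e-3)

    def test_reconstruction_beats_raw_on_noisy_track(self, rng):
        n = 200
        f = np.arange(n)
        x, y = 3.0 * f, 4.0 * f
        noisy = Track("n", f, x + rng.normal(0, 1, n), y + rng.normal(0, 1, n))
        truth = VelocitySeries(np.full(n - 1, 5.0), variant="true")
        raw = compute_speed(noisy)
        filt = kalman_reconstruct(noisy)
        r2 = r_squared(raw, filt, truth).r2
        assert r2 > 0.5  # strictly better than the raw signal (R^2 = 0)

    def test_three_point_track_rejected(self):
        with pytest.raises(InsufficientDataError):
            kalman_reconstruct(constant_velocity_track(n=3))

    def test_gap_handled_by_prediction(self):
        t = constant_velocity_track(3.0, 4.0, n=50)
        gappy = Track("g", np.delete(t.frames, 25), np.delete(t.x, 25),
                      np.delete(t.y, 25))
        s = kalman_reconstruct(gappy)
        assert len(s) == len(gappy) - 1
        np.testing.assert_allclose(s.values[20:], 5.0, atol=1e-3)

    def test_speed_is_nonnegative(self, rng):
        n = 50
        walk = np.cumsum(rng.normal(0, 2, (n, 2)), axis=0)
        t = Track("w", np.arange(n), walk[:, 0], walk[:, 1])
        assert np.all(kalman_reconstruct(t).values >= 0)

    def test_zero_velocity_init_has_startup_transient(self):
        track = constant_velocity_track(3.0, 4.0, n=100)
        s0 = kalman_reconstruct(track, KalmanModel(init_velocity="zero"))
        s1 = kalman_reconstruct(track, KalmanModel())
        assert s0.values[0] < 4.0  # starts well below the true 5
        np.testing.assert_allclose(s1.values, 5.0, atol=1e-9)

    def test_model_matrices(self):
        m = KalmanModel()
        states = kalman_filter_positions(constant_velocity_track(n=10), m)
        assert states.shape == (10, 4)
        q = m.process_noise()
        np.testing.assert_allclose(q, q.T)
        assert np.min(np.linalg.eigvalsh(q)) >= -1e-12


class TestScalarFilters:
    LINEAR = ["mean", "gaussian", "kz", "sg", "spencer"]

    @pytest.mark.parametrize("kind", LINEAR)
    def test_unit_dc_gain_on_constant(self, kind):
        s = VelocitySeries(np.full(60, 7.25))
        out = apply_filter(s, BENCHMARK_FILTERS[kind])
        np.testing.assert_allclose(out.values, 7.25, atol=1e-12)

    def test_spencer_weights_sum_to_one(self):
        assert abs(SPENCER_WEIGHTS.sum() - 1.0) < 1e-12

    def test_median_removes_single_impulse_exactly(self):
        v = np.full(30, 4.0)
        v[13] = 50.0
        out = apply_filter(VelocitySeries(v), FilterSpec("median", {"window": 5}))
        np.testing.assert_allclose(out.values, 4.0)

    def test_sg_reproduces_quadratic_interior(self):
        t = np.arange(60, dtype=float)
        v = 0.05 * t**2 - 0.3 * t + 2.0
        out = apply_filter(VelocitySeries(v),
                           FilterSpec("sg", {"window": 9, "order": 2}))
        np.testing.assert_allclose(out.values[4:-4], v[4:-4], atol=1e-9)

    def test_kz_is_iterated_moving_average(self, rng):
        v = rng.uniform(0, 10, 80)
        out = apply_filter(VelocitySeries(v),
                           FilterSpec("kz", {"window": 5, "iterations": 3}))
        ref = v
        for _ in range(3):
            ref = apply_filter(VelocitySeries(ref),
                               FilterSpec("mean", {"window": 5})).values
        np.testing.assert_allclose(out.values, ref, atol=1e-12)

    def test_same_length_output(self, rng):
        v = rng.uniform(0, 10, 40)
        for kind in self.LINEAR + ["median"]:
            assert len(apply_filter(VelocitySeries(v),
                                    BENCHMARK_FILTERS[kind])) == 40

    def test_too_short_series(self):
        with pytest.raises(InsufficientDataError):
            apply_filter(VelocitySeries(np.ones(5)),
                         FilterSpec("mean", {"window": 9}))

    def test_unknown_kind(self):
        with pytest.raises(FilterSpecError):
            FilterSpec("lowess", {})

    def test_even_window_rejected(self):
        with pytest.raises(FilterSpecError):
            FilterSpec("mean", {"window": 8})

    def test_kalman_spec_rejected_by_scalar_path(self):
        with pytest.raises(FilterSpecError):
            apply_filter(VelocitySeries(np.ones(30)),
                         BENCHMARK_FILTERS["kalman"])
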