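"""Control loop: reference generation, metrics, scheme runner, PID."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from cerebdea import (
    LinearPlant,
    PIDController,
    ReferenceModel,
    SchemeConfig,
    element_count_sweep,
    generate_reference,
    run_scheme,
    steady_state_rms,
    windowed_rms,
)
from cerebdea.loop import TABLE_SCHEMES, pid_step


class TestGenerateReference:
    def test_deterministic(self):
        a = generate_reference(30, 50, seed=9)
        b = generate_reference(30, 50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_realized_range(self):
        r = generate_reference(900, 50, amp_range=(0.1, 1.8), seed=1)
        assert r.min() == pytest.approx(0.1, abs=1e-12)
        assert r.max() == pytest.approx(1.8, abs=1e-12)

    def test_spectral_rolloff(self):
        # energy above 2 Hz well below the 0-1 Hz band
        r = generate_reference(900, 50, cutoff_hz=1.0, seed=2)
        f, pxx = sps.welch(r - r.mean(), fs=50, nperseg=4096)
        band = pxx[(f > 0.05) & (f <= 1.0)].mean()
        high = pxx[f > 2.0].mean()
        assert 10 * np.log10(band / high) > 20

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(10, 50, amp_range=(1.0, 1.0), seed=0)


class TestReferenceModel:
    def test_unit_dc_gain(self):
        m = ReferenceModel()
        assert m.dc_gain == pytest.approx(1.0)
        for _ in range(2000):
            y = m.step(0.7)
        assert y == pytest.approx(0.7, abs=1e-9)

    def test_impulse_expansion(self):
        m = ReferenceModel()
        ys = [m.step(1.0)] + [m.step(0.0) for _ in range(4)]
        np.testing.assert_allclose(ys, [0.18 * 0.82**k for k in range(5)],
                                   atol=1e-12)


class TestMetrics:
    def test_windowed_rms_constants(self):
        fs = 50.0
        assert np.all(windowed_rms(np.zeros(1000), 2.0, fs) == 0)
        np.testing.assert_allclose(windowed_rms(np.full(1000, -0.3), 2.0, fs),
                                   0.3)

    def test_windowed_rms_sinusoid(self):
        # whole number of periods per window: RMS = A / sqrt(2)
        fs, A = 50.0, 0.8
        t = np.arange(5000) / fs
        e = A * np.sin(2 * np.pi * 1.0 * t)
        np.testing.assert_allclose(windowed_rms(e, 2.0, fs), A / np.sqrt(2),
                                   atol=1e-6)

    def test_steady_state_equals_tail_rms_for_constant(self):
        e = np.concatenate([np.ones(30000), np.full(16000, 0.5)])
        assert steady_state_rms(e, 50.0, 320.0, 20.0) == pytest.approx(0.5)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            windowed_rms(np.zeros(10), 2.0, 50.0)


class TestSchemePresets:
    def test_published_rows(self):
        six = SchemeConfig.preset(6)
        assert six.nu == 5 and six.zeta == 0.01 and six.m == 8
        assert six.gains_init == (2.1, 0.9, 0, 0, 0, 0, 0, 0, 0)
        five = SchemeConfig.preset(5)
        assert five.gains_init[:3] == (0.92, 2.38, 1.07)
        assert five.rho[-1] == 1.785
        one = SchemeConfig.preset(1)
        assert one.nu == 0 and one.m == 1 and one.beta == 8.0
        assert set(TABLE_SCHEMES) == {"1", "2", "4", "5", "6", "pid"}

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            SchemeConfig.preset(3)


class TestRunScheme:
    def test_bit_exact_reproducibility(self, short_cfg):
        a = run_scheme(short_cfg)
        b = run_scheme(short_cfg)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_series_shapes_and_error_identity(self, short_cfg):
        res = run_scheme(short_cfg)
        n = int(short_cfg.duration * short_cfg.fs)
        assert all(len(getattr(res, k)) == n
                   for k in ("r", "y", "x", "x_true", "u", "z", "v", "e"))
        np.testing.assert_allclose(res.e, res.x - res.y, atol=1e-12)

    def test_frozen_controller_is_deterministic_feedforward(self, short_cfg):
        cfg = dataclasses.replace(short_cfg, beta=0.0, zeta=0.0)
        res = run_scheme(cfg)
        # no adaptation: weights remain zero, z stays at the bias
        assert np.all(res.weights == 0)
        np.testing.assert_allclose(res.z, 0.0, atol=1e-12)

    def test_exactly_invertible_linear_plant(self):
        # B_L composed with P = 0.18/(0.66 - 0.48 q^-1) equals M, so a
        # unit recruitment map is a perfect controller: the error falls to
        # the sensor-noise floor and the cerebellum stays near silent
        cfg = SchemeConfig.preset("1", seed=3, duration=300.0,
                                  gains_init=(1.0, 0.0))
        plant = LinearPlant(noise_sd=0.02, rng_seed=3)
        res = run_scheme(cfg, plant=plant)
        assert res.steady_state_rms(final_span_s=200.0, measured=True) < 0.03
        assert res.steady_state_rms(final_span_s=200.0) < 0.01
        mean_abs_z = np.abs(res.z[-5000:]).mean()
        mean_abs_u = np.abs(res.u[-5000:]).mean()
        assert mean_abs_z < 0.05 * mean_abs_u

    def test_error_decreases_during_learning(self):
        # learning must descend the error surface from the untrained state
        cfg = SchemeConfig.preset("2", seed=4, duration=240.0)
        res = run_scheme(cfg)
        w = res.windowed_rms()
        assert np.mean(w[-3:]) < np.mean(w[:3])

    def test_divergence_guard(self, short_cfg):
        from cerebdea import SimulationDiverged

        # sign-flipped plant turns learning into positive feedback; on an
        # unclipped linear plant the error grows without bound until the
        # guard aborts the run
        plant = LinearPlant(b0=-0.18, rng_seed=0)
        with pytest.raises(SimulationDiverged):
            run_scheme(short_cfg, plant=plant)


class TestPID:
    def test_zero_error_zero_output(self):
        pid = PIDController(kp=1.0, ki=1.0, kd=0.0)
        assert pid_step(pid, 0.0, 0.02) == 0.0

    def test_pure_proportional(self):
        pid = PIDController(kp=2.0, ki=0.0, kd=0.0)
        pid.step(0.5, 0.02)
        assert pid.step(0.5, 0.02) == pytest.approx(-1.0)

    def test_integrator_clamp(self):
        pid = PIDController(kp=0.0, ki=1.0, kd=0.0, windup_limit=0.1)
        for _ in range(1000):
            u = pid.step(1.0, 0.02)
        assert u == pytest.approx(-0.1)

    def test_pid_run_tracks(self):
        cfg = SchemeConfig.preset("pid", seed=5, duration=240.0)
        res = run_scheme(cfg)
        assert res.steady_state_rms(final_span_s=200.0) < 0.08


class TestElementSweep:
    def test_nu_zero_matches_scheme_one(self):
        base = SchemeConfig.preset("2", seed=6, duration=360.0,
                                   pretrain_duration=30.0)
        sweep = element_count_sweep(base, nu_values=[0])
        direct = run_scheme(SchemeConfig.preset("1", seed=6, duration=360.0,
                                                pretrain_duration=30.0))
        assert sweep["steady_state_rms_mm"].iloc[0] == pytest.approx(
            direct.steady_state_rms(), abs=1e-12)

    def test_published_thresholds_recovered_at_nu5(self):
        sigma = np.linspace(2.18, 3.38, 5)
        np.testing.assert_allclose(sigma, [2.18, 2.48, 2.78, 3.08, 3.38],
                                   atol=1e-12)
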