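"""Frequency-domain double integration and wavelet trend removal."""

import numpy as np
import pytest

from gaitevents.exceptions import LengthError, ParameterError
from gaitevents.integration import (
    acceleration_to_displacement,
    detrend_wavelet,
    double_integrate_fft,
)
from gaitevents.preprocess import remove_gravity
from gaitevents.signal_io import AccelerometerRecording

FS = 1000.0


class TestDoubleIntegration:
    def test_sinusoid_closed_form(self):
        # a(t) = -w^2 sin(wt) over integer periods integrates to sin(wt)
        w = 2 * np.pi * 2.0
        t = np.arange(0, 2.0, 1 / FS)
        az = -(w**2) * np.sin(w * t)
        out = double_integrate_fft(az, FS, highpass_hz=0.1)
        ref = np.sin(w * t)
        assert np.linalg.norm(out - ref) <= 1e-6 * np.linalg.norm(ref)

    def test_zero_in_zero_out(self):
        assert np.allclose(double_integrate_fft(np.zeros(64), FS), 0.0)

    def test_linearity_in_amplitude(self):
        w = 2 * np.pi * 3.0
        t = np.arange(0, 1.0, 1 / FS)
        az = -(w**2) * np.sin(w * t)
        one = double_integrate_fft(az, FS)
        five = double_integrate_fft(5.0 * az, FS)
        np.testing.assert_allclose(five, 5.0 * one, rtol=1e-9, atol=1e-12)

    def test_sparse_fourier_oracle(self, rng):
        """Band-limited content above the high-pass corner integrates to the
        analytic double antiderivative."""
        n = 4000
        t = np.arange(n) / FS
        for _ in range(5):
            freqs = rng.integers(2, 40, size=4)  # integer Hz -> integer periods
            amps = rng.normal(size=4)
            phases = rng.uniform(0, 2 * np.pi, size=4)
            az = np.zeros(n)
            ref = np.zeros(n)
            for f, a, p in zip(freqs, amps, phases):
                w = 2 * np.pi * f
                az += -a * w**2 * np.sin(w * t + p)
                ref += a * np.sin(w * t + p)
            out = double_integrate_fft(az, FS, highpass_hz=0.5)
            assert np.linalg.norm(out - ref) <= 1e-6 * np.linalg.norm(ref)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            double_integrate_fft(np.ones(64), FS, highpass_hz=FS)
        with pytest.raises(LengthError):
            double_integrate_fft(np.ones(4), FS)


class TestDetrend:
    def test_constant_maps_to_zero(self):
        out = detrend_wavelet(np.full(4096, 5.0), FS)
        assert np.abs(out).max() <= 1e-8 * 5.0

    def test_zero_in_zero_out(self):
        assert np.allclose(detrend_wavelet(np.zeros(4096), FS), 0.0)

    def test_ramp_removed_sinusoid_preserved(self):
        t = np.arange(0, 30.0, 1 / FS)
        sine = np.sin(2 * np.pi * 1.0 * t)
        ramp = 0.5 * t
        out = detrend_wavelet(ramp + sine, FS, levels=8, basis="sym8")
        target = sine - sine.mean()
        assert np.linalg.norm(out - target) <= 0.10 * np.linalg.norm(target)
        ramp_only = detrend_wavelet(ramp, FS)
        assert np.linalg.norm(ramp_only) ** 2 <= 0.10 * np.linalg.norm(ramp) ** 2

    def test_slow_drift_removed(self):
        t = np.arange(0, 30.0, 1 / FS)
        drift = 0.05 * np.sin(2 * np.pi * 0.05 * t)
        out = detrend_wavelet(drift, FS)
        assert np.linalg.norm(out) <= 0.1 * np.linalg.norm(drift - drift.mean())

    def test_projection_weak_idempotence(self, rng):
        x = rng.normal(size=13000) + 0.2 * (np.arange(13000) / FS) ** 2
        once = detrend_wavelet(x, FS)
        twice = detrend_wavelet(once, FS)
        assert np.linalg.norm(twice - once) <= 1e-8 * np.linalg.norm(once)

    def test_too_short_raises(self):
        with pytest.raises(LengthError):
            detrend_wavelet(np.ones(100), FS, levels=8)

    def test_db6_basis_selectable(self):
        out = detrend_wavelet(np.full(4096, 2.0), FS, basis="db6")
        assert np.abs(out).max() <= 1e-8 * 2.0

    def test_soft_threshold_mode_runs(self, rng):
        x = rng.normal(size=4096)
        out = detrend_wavelet(x, FS, mode="approx_and_details")
        assert len(out) == len(x)
        assert abs(out.mean()) < 1e-9


class TestAccelerationToDisplacement:
    def test_zero_recording_zero_trace(self, cfg):
        rec = AccelerometerRecording(
            site="heel", fs=FS, ax=np.zeros(4096), ay=np.zeros(4096),
            az=np.full(4096, 9.81),
        )
        trace = acceleration_to_displacement(rec, cfg.integration)
        assert np.abs(trace.detrended).max() < 1e-12

    def test_amplitude_linearity(self, cfg):
        w = 2 * np.pi * 3.0
        t = np.arange(4096) / FS
        az = -(w**2) * 0.01 * np.sin(w * t)
        recs = [
            AccelerometerRecording(
                site="heel", fs=FS, ax=np.zeros_like(t), ay=np.zeros_like(t),
                az=scale * az,
            )
            for scale in (1.0, 2.0)
        ]
        traces = [acceleration_to_displacement(r, cfg.integration) for r in recs]
        np.testing.assert_allclose(
            traces[1].detrended, 2.0 * traces[0].detrended, rtol=1e-6, atol=1e-12
        )

    def test_synthetic_correlation(self, noiseless_trial, cfg):
        """Integrated displacement tracks the ground-truth trajectory: r >= 0.9
        against the raw truth and r >= 0.99 once both are detrended (the
        walking-bout envelope lies below the high-pass corner and cannot be
        recovered by any double integration)."""
        trial = noiseless_trial
        az = remove_gravity(trial.heel_rec.az)
        est = detrend_wavelet(double_integrate_fft(az, FS, 0.1), FS)
        truth = trial.heel_disp
        r_raw = np.corrcoef(est, truth - truth.mean())[0, 1]
        r_dt = np.corrcoef(est, detrend_wavelet(truth, FS))[0, 1]
        assert r_raw >= 0.9
        assert r_dt >= 0.99
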