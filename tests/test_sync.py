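"""Trigger detection, alignment, resampling and FIR filtering checks."""

import numpy as np
import pytest

from earqc.recording import Recording
from earqc.simulate import SimConfig, generate_alpha_test
from earqc.sync import (
    SyncError,
    align_pair,
    bandpass_fir,
    detect_triggers,
    resample,
)


def pulse_trace(times_s, fs, n_s, width_s=0.04, amp=100.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(n_s * fs)
    t = np.arange(n) / fs
    x = rng.normal(0, noise, n) if noise else np.zeros(n)
    for t0 in times_s:
        x[(t >= t0) & (t < t0 + width_s)] += amp
    return x


def trigger_recording(times_s, fs, n_s, **kw):
    n = int(n_s * fs)
    return Recording(
        labels=["x"], data=np.zeros((1, n)), fs=fs,
        trigger=pulse_trace(times_s, fs, n_s, **kw),
    )


class TestDetectTriggers:
    def test_isolated_pulses_detected_at_onset(self):
        ev = detect_triggers(pulse_trace([1.0, 31.0], 250.0, 40.0), 250.0)
        assert ev == pytest.approx([1.0, 31.0], abs=1 / 250.0)

    def test_flat_trace_yields_no_events(self):
        assert detect_triggers(np.zeros(1000), 250.0).size == 0

    def test_negative_pulses_found_via_absolute_value(self):
        ev = detect_triggers(-pulse_trace([2.0], 250.0, 10.0), 250.0)
        assert ev == pytest.approx([2.0], abs=1 / 250.0)

    def test_pulses_in_noise_recovered_exactly(self):
        times = [1.0, 61.0, 121.0, 181.0]
        x = pulse_trace(times, 250.0, 200.0, noise=10.0, seed=4)  # SNR 10
        ev = detect_triggers(x, 250.0)
        assert ev.size == len(times)
        assert ev == pytest.approx(times, abs=2 / 250.0)


class TestAlignPair:
    def test_identical_recordings_align_at_zero(self):
        rec = trigger_recording([1.0, 31.0, 61.0], 250.0, 90.0)
        result, _, _ = align_pair(rec, rec.copy())
        assert result.offset_s == 0.0
        assert np.all(result.residual_s == 0.0)

    def test_injected_offset_recovered_within_one_sample(self):
        """2.345-s inter-device start offset, recovered from the triggers of
        a full synthetic session to within one sample of the slower device."""
        cfg = SimConfig(
            seed=6, n_trials=4, scalp_channels=["T7", "T8"],
            clock_offset_s=2.345, clock_drift_ppm=0.0,
            artifact_rate=0.0, contact_loss_prob=0.0,
        )
        s = generate_alpha_test(cfg)
        result, _, _ = align_pair(s.scalp, s.inear)
        assert result.offset_s == pytest.approx(2.345, abs=1 / 250.0)

    def test_drift_residual_stays_within_lag_tolerance(self):
        """20 ppm of clock drift over one hour spreads trigger differences by
        ~0.072 s; after constant-offset removal every residual is < 0.1 s."""
        times = np.arange(0.5, 3600.0, 60.0)
        rec_a = trigger_recording(times, 250.0, 3600.0)
        rec_b = trigger_recording(times * (1 + 20e-6), 250.0, 3600.5)
        result, _, _ = align_pair(rec_a, rec_b)
        assert result.drift_span_s == pytest.approx(20e-6 * 3600, abs=0.01)
        assert result.max_abs_residual_s < 0.1

    def test_missing_triggers_raise_sync_error(self):
        good = trigger_recording([1.0], 250.0, 10.0)
        bad = Recording(
            labels=["x"], data=np.zeros((1, 2500)), fs=250.0,
            trigger=np.zeros(2500),
        )
        with pytest.raises(SyncError):
            align_pair(good, bad)

    def test_alignment_is_idempotent(self):
        rec_a = trigger_recording([1.0, 31.0, 61.0], 250.0, 90.0)
        rec_b = trigger_recording([0.6, 30.6, 60.6], 250.0, 90.0)
        result, a1, b1 = align_pair(rec_a, rec_b)
        result2, _, _ = align_pair(a1, b1)
        # re-aligning the already-aligned pair finds the same offset again
        # (offsets are carried in start_offset_s, the traces are untouched)
        assert result2.offset_s == pytest.approx(result.offset_s, abs=1 / 250.0)


class TestResample:
    def test_eight_fold_decimation_length(self):
        rec = Recording(labels=["x"], data=np.zeros((1, 160000)), fs=2000.0)
        out = resample(rec, 250.0)
        assert out.fs == 250.0
        assert out.n_samples == 20000

    def test_in_band_amplitude_preserved(self):
        fs = 2000.0
        t = np.arange(int(80 * fs)) / fs
        rec = Recording(labels=["x"], data=10 * np.sin(2 * np.pi * 10 * t)[None, :],
                        fs=fs)
        out = resample(rec, 250.0)
        mid = out.data[0][2500:-2500]
        assert np.max(np.abs(mid)) == pytest.approx(10.0, rel=0.01)

    def test_above_nyquist_tone_attenuated(self):
        fs = 2000.0
        t = np.arange(int(80 * fs)) / fs
        x = 10 * np.sin(2 * np.pi * 140 * t)
        rec = Recording(labels=["x"], data=x[None, :], fs=fs)
        out = resample(rec, 250.0)
        # 140 Hz is above the 125 Hz output Nyquist: >= 20 dB down
        assert np.sqrt(np.mean(out.data[0] ** 2)) < 0.1 * (10 / np.sqrt(2))

    def test_upsampling_refused(self):
        rec = Recording(labels=["x"], data=np.zeros((1, 1000)), fs=250.0)
        with pytest.raises(ValueError):
            resample(rec, 500.0)


class TestBandpass:
    fs = 250.0

    def _tone(self, f, amp=10.0, n_s=60.0):
        t = np.arange(int(n_s * self.fs)) / self.fs
        return Recording(
            labels=["x"], data=(amp * np.sin(2 * np.pi * f * t))[None, :], fs=self.fs
        )

    def test_dc_removed(self):
        rec = Recording(labels=["x"], data=np.full((1, 15000), 50.0), fs=self.fs)
        out = bandpass_fir(rec)
        assert abs(out.data[0][2500:-2500].mean()) < 0.5

    def test_passband_gain_within_1db(self):
        out = bandpass_fir(self._tone(10.0))
        mid = out.data[0][2500:-2500]
        gain = np.max(np.abs(mid)) / 10.0
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)

    def test_stopband_tone_attenuated_20db(self):
        out = bandpass_fir(self._tone(50.0))
        mid = out.data[0][2500:-2500]
        assert np.sqrt(np.mean(mid**2)) < 0.1 * (10 / np.sqrt(2))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_fir(self._tone(10.0), 0.3, 200.0)

    def test_filter_is_linear(self, rng):
        x = rng.standard_normal(5000)
        y = rng.standard_normal(5000)
        rec = lambda d: Recording(labels=["x"], data=d[None, :], fs=self.fs)
        lhs = bandpass_fir(rec(2.0 * x + 3.0 * y)).data[0]
        rhs = 2.0 * bandpass_fir(rec(x)).data[0] + 3.0 * bandpass_fir(rec(y)).data[0]
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_resample_filter_commute_for_in_band_signal(self):
        fs = 2000.0
        t = np.arange(int(40 * fs)) / fs
        x = 10 * np.sin(2 * np.pi * 10 * t) + 5 * np.sin(2 * np.pi * 4 * t)
        rec = Recording(labels=["x"], data=x[None, :], fs=fs)
        a = bandpass_fir(resample(rec, 250.0)).data[0]
        b = resample(bandpass_fir(rec), 250.0).data[0]
        core = slice(2500, -2500)
        assert np.sqrt(np.mean((a[core] - b[core]) ** 2)) < 0.05
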