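"""Generator checks: protocol structure, spectral content, artifacts, clocks.

Spectral assertions use an independent periodogram oracle
(scipy.signal.periodogram) on the generated traces, never the package's own
spectral code.
"""

import numpy as np
import pytest
from scipy.signal import periodogram
from scipy.stats import linregress

from earqc.quality import epoch_and_flag
from earqc.recording import Recording
from earqc.simulate import (
    ConfigError,
    SimConfig,
    generate_alpha_test,
    generate_nap,
    inject_artifacts,
)


def band_power_oracle(x, fs, lo, hi):
    f, p = periodogram(x, fs=fs)
    return p[(f >= lo) & (f < hi)].sum()


class TestAlphaProtocol:
    def test_trace_length_is_duration_times_rate(self, alpha_session):
        cfg, s = alpha_session
        assert s.inear.n_samples == int(10 * 30 * 250)
        assert s.scalp.n_samples == int(10 * 30 * 2000)

    def test_schedule_tiles_session_alternating_from_eyes_closed(
        self, alpha_session
    ):
        _, s = alpha_session
        assert s.schedule[0]["condition"] == "EC"
        conditions = [it["condition"] for it in s.schedule]
        assert conditions == ["EC", "EO"] * 5
        total = sum(it["end_s"] - it["start_s"] for it in s.schedule)
        assert total == pytest.approx(300.0)
        for prev, nxt in zip(s.schedule, s.schedule[1:]):
            assert prev["end_s"] == nxt["start_s"]

    def test_eyes_closed_alpha_power_exceeds_eyes_open(self, alpha_session):
        """Alpha reactivity: EC segments carry more 8-12 Hz power than EO."""
        _, s = alpha_session
        x = s.scalp.channel("T7") - s.scalp.channel("T8")
        fs = s.scalp.fs
        ec = np.concatenate(
            [
                x[int(it["start_s"] * fs) : int(it["end_s"] * fs)]
                for it in s.schedule
                if it["condition"] == "EC"
            ]
        )
        eo = np.concatenate(
            [
                x[int(it["start_s"] * fs) : int(it["end_s"] * fs)]
                for it in s.schedule
                if it["condition"] == "EO"
            ]
        )
        ratio = band_power_oracle(ec, fs, 8, 12) / band_power_oracle(eo, fs, 8, 12)
        assert ratio > 3.0  # spec requires > 1; the default conditions give much more

    def test_same_seed_is_bit_identical(self):
        cfg = SimConfig(seed=9, n_trials=2, scalp_channels=["T7", "T8"])
        s1, s2 = generate_alpha_test(cfg), generate_alpha_test(cfg)
        assert np.array_equal(s1.inear.data, s2.inear.data)
        assert np.array_equal(s1.scalp.data, s2.scalp.data)
        assert np.array_equal(s1.inear.trigger, s2.inear.trigger)

    def test_odd_trial_count_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_trials=5)

    def test_inconsistent_session_length_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_trials=10, trial_len_s=30.0, session_len_s=200.0)

    def test_trigger_pulses_on_both_devices(self, alpha_session):
        _, s = alpha_session
        for rec in (s.inear, s.scalp):
            assert rec.trigger is not None
            assert np.max(np.abs(rec.trigger)) > 50.0


class TestNapProtocol:
    def test_hypnogram_epoch_count(self):
        cfg = SimConfig(protocol="nap", nap_len_s=900, seed=1,
                        scalp_channels=["T7", "T8"])
        s = generate_nap(cfg)
        assert s.hypnogram.n_epochs == 30
        assert s.inear.n_samples == int(900 * 250)

    def test_all_stages_present_in_long_nap(self, nap_session):
        _, s = nap_session
        assert s.hypnogram.observed_stages() == ["Wake", "N1", "N2", "N3", "REM"]

    def test_n3_delta_dominates(self, nap_session):
        """Slow-wave stage: delta band carries the largest relative power."""
        _, s = nap_session
        x = s.scalp.channel("T7") - s.scalp.channel("T8")
        fs = s.scalp.fs
        n3 = np.concatenate(
            [
                x[int(i * 30 * fs) : int((i + 1) * 30 * fs)]
                for i, st in enumerate(s.hypnogram.stages)
                if st == "N3"
            ]
        )
        bands = {
            "delta": (0.3, 4), "theta": (4, 8), "alpha": (8, 12),
            "beta1": (12, 18), "beta2": (18, 35),
        }
        powers = {b: band_power_oracle(n3, fs, *e) for b, e in bands.items()}
        assert max(powers, key=powers.get) == "delta"

    def test_stage_template_band_has_largest_power(self):
        """Spectral fidelity: each stage's dominant template band dominates
        the generated segment (independent periodogram oracle)."""
        cfg = SimConfig(protocol="nap", nap_len_s=1200, seed=5,
                        scalp_channels=["T7", "T8"],
                        artifact_rate=0.0, contact_loss_prob=0.0)
        s = generate_nap(cfg)
        x = s.inear.data[0]
        fs = s.inear.fs
        dominant = {"Wake": (8, 12), "N1": (4, 7), "N3": (0.3, 4)}
        rest = {"Wake": [(4, 8), (12, 18)], "N1": [(8, 12), (12, 18)],
                "N3": [(8, 12), (12, 18)]}
        for stage, band in dominant.items():
            seg = np.concatenate(
                [
                    x[int(i * 30 * fs) : int((i + 1) * 30 * fs)]
                    for i, st in enumerate(s.hypnogram.stages)
                    if st == stage
                ]
            )
            if seg.size == 0:
                continue
            p_dom = band_power_oracle(seg, fs, *band)
            for other in rest[stage]:
                assert p_dom > band_power_oracle(seg, fs, *other)

    def test_wake_alpha_envelope_ratio_recovers_amp_ratio(self):
        """With little independent noise the scalp alpha envelope is
        amp_ratio times the in-ear envelope (envelope regression oracle)."""
        from earqc.sync import bandpass_array, resample

        cfg = SimConfig(
            protocol="nap", nap_len_s=600, seed=3,
            scalp_channels=["T7", "T8"],
            stage_rho={st: 0.97 for st in ("Wake", "N1", "N2", "N3", "REM")},
            artifact_rate=0.0, contact_loss_prob=0.0,
            clock_offset_s=0.0, clock_drift_ppm=0.0,
        )
        s = generate_nap(cfg)
        sc = resample(s.scalp, 250.0)
        t7t8 = sc.channel("T7") - sc.channel("T8")
        n = min(t7t8.size, s.inear.n_samples)
        wake = np.zeros(n, bool)
        for i, st in enumerate(s.hypnogram.stages):
            if st == "Wake":
                wake[int(i * 30 * 250) : int((i + 1) * 30 * 250)] = True
        from scipy.signal import hilbert

        env_sc = np.abs(hilbert(bandpass_array(t7t8[:n], 250.0, 8, 12,
                                               trans_low=1.0, trans_high=1.0)))
        env_in = np.abs(hilbert(bandpass_array(s.inear.data[0][:n], 250.0, 8, 12,
                                               trans_low=1.0, trans_high=1.0)))
        slope = linregress(env_in[wake], env_sc[wake]).slope
        assert slope == pytest.approx(cfg.amp_ratio, rel=0.15)

    def test_unknown_stage_template_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(protocol="nap", stage_template={"Lucid": ()})


class TestArtifacts:
    @staticmethod
    def _background(n_s=3600, fs=250.0, sd=15.0, seed=0):
        rng = np.random.default_rng(seed)
        return Recording(
            labels=["InEar"],
            data=rng.normal(0.0, sd, int(n_s * fs))[np.newaxis, :],
            fs=fs,
        )

    def test_zero_rates_are_a_no_op(self):
        rec = self._background(n_s=60)
        cfg = SimConfig(artifact_rate=0.0, contact_loss_prob=0.0)
        out, events = inject_artifacts(rec, cfg)
        assert events == []
        assert np.array_equal(out.data, rec.data)

    def test_every_excursion_peaks_above_threshold(self):
        rec = self._background(n_s=600, sd=15.0)
        cfg = SimConfig(artifact_rate=2.0, contact_loss_prob=0.0, seed=1)
        out, events = inject_artifacts(rec, cfg)
        assert events
        for ev in events:
            sl = slice(int(ev["start_s"] * rec.fs), int(ev["end_s"] * rec.fs))
            assert np.max(np.abs(out.data[0, sl])) > 100.0

    def test_flagged_fraction_matches_contamination(self):
        """Downstream flag rate equals the configured per-epoch contamination
        within binomial error (360 epochs x 3 seeds, counting oracle)."""
        rate, p_cl = 1.2, 0.05
        p_art = rate * 10.0 / 60.0
        p_expected = p_art + p_cl - p_art * p_cl
        flagged = total = 0
        for seed in range(3):
            rec = self._background(seed=seed)
            cfg = SimConfig(
                artifact_rate=rate, contact_loss_prob=p_cl, seed=seed + 100
            )
            out, _ = inject_artifacts(rec, cfg)
            grid = epoch_and_flag(out, "InEar")
            flagged += int(grid.artifact_flag.sum())
            total += grid.n_epochs
        assert total == 3 * 360
        se = np.sqrt(p_expected * (1 - p_expected) / total)
        assert abs(flagged / total - p_expected) < 2.6 * se + 0.01
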