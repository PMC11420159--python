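"""Synthetic paired in-ear / scalp EEG sessions.

This module generates the two study protocols — an alternating eyes-closed /
eyes-open "alpha test" and a ~1 h nap with a hypnogram — as simultaneous
recordings from two independently clocked devices, so that every downstream
stage (synchronization, artifact rejection, RMS, alpha SNR, relative band
power, lag-tolerant correlation, permutation inference) can be exercised and
parameter-recovery tested without any real data.

Signal model
------------
Each oscillatory band is synthesized as band-limited Gaussian noise plus an
optional sinusoidal carrier with random phase, so band power is analytically
controllable.  The two devices observe a *shared source* ``C`` through
independent noise: with ``g = sqrt(1/rho - 1)`` and ``D`` an independent
realization with the same spectrum as ``C``,

    in-ear          = C + g * D_in
    scalp (L - R)   = amp_ratio * (w * C + g * E),   var(E) = var(C)

so the inter-device Pearson correlation of the best derivation (source
weight ``w = 1``, i.e. T7-T8) equals ``rho`` at every frequency, and the
slope of sqrt(scalp alpha power) on sqrt(in-ear alpha power) equals
``amp_ratio`` in expectation.  Electrodes farther from the temporal sources
carry smaller ``w`` and therefore weaker correlations, giving the map a
temporal maximum.

Clock behaviour: the in-ear device starts ``clock_offset_s`` after the scalp
device and its clock runs fast/slow by ``clock_drift_ppm``; both devices see
the same rectangular trigger pulses on a dedicated channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np

from .recording import Recording, Hypnogram, SLEEP_STAGES
from .montage import is_midline, is_left

__all__ = [
    "SimConfig",
    "BandComponent",
    "AlphaSession",
    "NapSession",
    "generate_alpha_test",
    "generate_nap",
    "inject_artifacts",
    "DEFAULT_STAGE_TEMPLATE",
    "DEFAULT_STAGE_RHO",
]


class ConfigError(ValueError):
    """Inconsistent or out-of-range simulation configuration."""


@dataclass(frozen=True)
class BandComponent:
    """One spectral component of a stage/condition template.

    ``rms`` is the target root-mean-square amplitude in microvolts of the
    component in the *common source*; ``carrier_frac`` is the fraction of the
    component's power carried by a sinusoid at ``carrier_hz`` (random phase),
    the rest being band-limited Gaussian noise on [f_lo, f_hi).
    """

    f_lo: float
    f_hi: float
    rms: float
    shape: Literal["flat", "pink"] = "flat"
    carrier_hz: float | None = None
    carrier_frac: float = 0.5
    # per-realization frequency jitter: distinct realizations must be
    # incoherent, which identical-frequency sinusoids are not
    carrier_jitter_hz: float = 0.75


# Stage-dependent spectral content of the common source (microvolt RMS).
# Wake: ~10 Hz alpha peak; N1: theta; N2: theta + 12-16 Hz spindles;
# N3: 0.5-2 Hz slow waves + theta; REM: low-amplitude mixed theta.
DEFAULT_STAGE_TEMPLATE: dict[str, tuple[BandComponent, ...]] = {
    "Wake": (BandComponent(8.0, 12.0, 6.0, carrier_hz=10.0),),
    "N1": (BandComponent(4.0, 7.0, 7.0),),
    "N2": (
        BandComponent(4.0, 7.0, 6.0),
        BandComponent(12.0, 16.0, 5.0, carrier_hz=13.5, carrier_frac=0.3),
    ),
    "N3": (
        BandComponent(0.5, 2.0, 15.0),
        BandComponent(4.0, 7.0, 7.0),
    ),
    "REM": (BandComponent(4.0, 7.0, 5.0),),
}

# Target inter-device broadband correlation per stage (shared-source rho).
DEFAULT_STAGE_RHO: dict[str, float] = {
    "Wake": 0.45,
    "N1": 0.50,
    "N2": 0.55,
    "N3": 0.60,
    "REM": 0.50,
}

# Source coupling of each scalp electrode to the temporal-lobe generators
# (left sign +, right sign -); T7/T8 couple fully, coupling decays with
# distance from the temporal region.  Midline electrodes see no lateralized
# source and carry their own noise only.
DEFAULT_SOURCE_WEIGHTS: dict[str, float] = {
    "T7": 1.0, "T8": 1.0,
    "FT11": 0.8, "FT12": 0.8,
    "F7": 0.65, "F8": 0.65,
    "P7": 0.6, "P8": 0.6,
    "C3": 0.45, "C4": 0.45,
    "P3": 0.4, "P4": 0.4,
    "P1": 0.4, "P2": 0.4,
    "O1": 0.35, "O2": 0.35,
    "Fp1": 0.3, "Fp2": 0.3,
    "Fz": 0.0, "Cz": 0.0, "Pz": 0.0,
}

DEFAULT_ALPHA_SCALP_CHANNELS = [
    "Fp1", "Fp2", "F7", "F8", "FT11", "FT12", "C3", "C4",
    "T7", "T8", "P3", "P4", "P7", "P8", "O1", "O2", "Fz", "Cz", "Pz",
]
DEFAULT_NAP_SCALP_CHANNELS = ["T7", "T8"]

IN_EAR_LABEL = "InEar"

TRIGGER_PULSE_S = 0.040  # rectangular trigger pulse width
TRIGGER_AMP = 100.0      # pulse height, 10x the trigger-channel noise floor


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated dual-device session.

    Defaults mirror the recording protocols: 10 alternating 30-s
    eyes-closed / eyes-open trials (always starting eyes-closed) for the
    alpha test; a ~1 h nap staged in 30-s epochs; in-ear device at 250 Hz
    (one bipolar cross-ear channel), scalp at 2000 Hz with 10-10 labels;
    a ~2x scalp/in-ear amplitude ratio; intermittent high-voltage artifacts
    at 5-10x the brain-signal amplitude plus occasional contact loss; and a
    small inter-device clock offset and drift bridged by shared triggers.
    """

    protocol: Literal["alpha_test", "nap"] = "alpha_test"
    n_trials: int = 10
    trial_len_s: float = 30.0
    session_len_s: float | None = None  # consistency check only
    nap_len_s: float = 3600.0
    fs_inear: float = 250.0
    fs_scalp: float = 2000.0
    scalp_channels: list[str] | None = None
    amp_ratio: float = 2.0
    alpha_freq: float = 10.0
    alpha_rms: float = 8.0          # EC alpha component of the common source, uV
    band_noise_sd: float = 6.0      # 1/f background RMS per channel, uV
    rho: float = 0.5                # target alpha-band inter-device correlation
    stage_rho: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_RHO)
    )
    artifact_rate: float = 0.5      # events per minute (in-ear channel)
    artifact_amp_factor: float = 10.0
    artifact_len_s: float = 5.0
    contact_loss_prob: float = 0.01  # per 10-s epoch
    clock_offset_s: float = 0.25
    clock_drift_ppm: float = 20.0
    trigger_times_s: list[float] | None = None
    stage_template: dict[str, tuple[BandComponent, ...]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_TEMPLATE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_inear <= 0 or self.fs_scalp <= 0:
            raise ConfigError("sampling rates must be positive")
        for name in (
            "trial_len_s", "nap_len_s", "amp_ratio", "alpha_rms",
            "band_noise_sd", "artifact_rate", "artifact_amp_factor",
            "artifact_len_s",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.amp_ratio <= 0:
            raise ConfigError("amp_ratio must be positive")
        if not 0 < self.rho <= 1:
            raise ConfigError("rho must be in (0, 1]")
        if not 0 <= self.contact_loss_prob <= 1:
            raise ConfigError("contact_loss_prob must be a probability")
        if self.protocol == "alpha_test":
            if self.n_trials % 2 != 0 or self.n_trials < 2:
                raise ConfigError(
                    "alpha_test needs an even trial count (alternating EC/EO "
                    "starting with eyes closed)"
                )
            if self.session_len_s is not None and not np.isclose(
                self.session_len_s, self.n_trials * self.trial_len_s
            ):
                raise ConfigError(
                    f"session_len_s={self.session_len_s} inconsistent with "
                    f"{self.n_trials} trials x {self.trial_len_s} s"
                )
        unknown = set(self.stage_template) - set(SLEEP_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage labels in template: {sorted(unknown)}")

    @property
    def alpha_session_len_s(self) -> float:
        return self.n_trials * self.trial_len_s

    def channels(self) -> list[str]:
        if self.scalp_channels is not None:
            return list(self.scalp_channels)
        if self.protocol == "alpha_test":
            return list(DEFAULT_ALPHA_SCALP_CHANNELS)
        return list(DEFAULT_NAP_SCALP_CHANNELS)


class AlphaSession(NamedTuple):
    inear: Recording
    scalp: Recording
    schedule: list[dict]          # {start_s, end_s, condition}
    ground_truth: dict


class NapSession(NamedTuple):
    inear: Recording
    scalp: Recording
    hypnogram: Hypnogram
    ground_truth: dict


# ---------------------------------------------------------------------------
# spectral-shaping primitives


def _band_noise(
    n: int, fs: float, comp: BandComponent, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian noise (optionally 1/f-shaped, optionally with a
    sinusoidal carrier), normalized to the component's exact RMS."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= comp.f_lo) & (freqs < comp.f_hi)
    noise_frac = 1.0 - (comp.carrier_frac if comp.carrier_hz is not None else 0.0)
    out = np.zeros(n)
    if mask.any() and noise_frac > 0 and comp.rms > 0:
        spec = np.zeros(freqs.size, dtype=complex)
        k = int(mask.sum())
        amp = np.ones(k)
        if comp.shape == "pink":
            amp = 1.0 / np.sqrt(np.maximum(freqs[mask], max(comp.f_lo, 1e-3)))
        spec[mask] = amp * (rng.standard_normal(k) + 1j * rng.standard_normal(k))
        x = np.fft.irfft(spec, n=n)
        sd = x.std()
        if sd > 0:
            out += x * (comp.rms * np.sqrt(noise_frac) / sd)
    if comp.carrier_hz is not None and comp.carrier_frac > 0 and comp.rms > 0:
        phase = rng.uniform(0, 2 * np.pi)
        f_c = comp.carrier_hz + rng.uniform(
            -comp.carrier_jitter_hz, comp.carrier_jitter_hz
        )
        a = comp.rms * np.sqrt(2.0 * comp.carrier_frac)
        t = np.arange(n) / fs
        out += a * np.sin(2 * np.pi * f_c * t + phase)
    return out


def _composite(
    n: int,
    fs: float,
    components: tuple[BandComponent, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of independent band components — one realization of a source."""
    out = np.zeros(n)
    for comp in components:
        out += _band_noise(n, fs, comp, rng)
    return out


def _cosine_gate(
    n: int, fs: float, intervals: list[tuple[float, float]], ramp_s: float = 0.5
) -> np.ndarray:
    """0/1 gate over the given intervals with cosine on/off ramps."""
    t = np.arange(n) / fs
    gate = np.zeros(n)
    for a, b in intervals:
        lin = np.clip(np.minimum((t - a) / ramp_s, (b - t) / ramp_s), 0.0, 1.0)
        gate = np.maximum(gate, 0.5 - 0.5 * np.cos(np.pi * lin))
    return gate


def _device_sample(
    master: np.ndarray,
    fs_master: float,
    fs_device: float,
    n_out: int,
    offset_s: float,
    drift_ppm: float,
) -> np.ndarray:
    """Sample a master-timeline signal with a device clock.

    Sample ``k`` of the device is taken at master time
    ``offset_s + k * (1 + drift_ppm*1e-6) / fs_device`` (a fast device clock
    stretches real time).  Linear interpolation is accurate here because all
    master content is band-limited far below the master Nyquist.
    """
    t_master = np.arange(master.size) / fs_master
    t_dev = offset_s + np.arange(n_out) * (1.0 + drift_ppm * 1e-6) / fs_device
    return np.interp(t_dev, t_master, master, left=0.0, right=0.0)


def _trigger_trace(
    n: int, fs: float, times_s: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rectangular pulse train on a dedicated channel over a small noise floor."""
    trace = rng.normal(0.0, TRIGGER_AMP / 10.0, size=n)
    t = np.arange(n) / fs
    for t0 in times_s:
        trace[(t >= t0) & (t < t0 + TRIGGER_PULSE_S)] += TRIGGER_AMP
    return trace


def _noise_gain(rho: float) -> float:
    """g such that corr(C + g D, C + g D') = rho for equal-variance C, D."""
    return float(np.sqrt(1.0 / rho - 1.0))


# ---------------------------------------------------------------------------
# protocol generators


def _electrode_signals(
    channels: list[str],
    common: np.ndarray,
    fs: float,
    g: float,
    amp_ratio: float,
    indep_realizer,
    rng: np.random.Generator,
) -> np.ndarray:
    """Build scalp-electrode traces from the common source.

    Each lateral electrode sees ``±(amp_ratio/2) * w * common`` plus
    independent same-spectrum noise at a fixed level, scaled so that the
    contralateral derivation of a fully coupled pair (w = 1) has
    inter-device correlation rho against the in-ear channel; less coupled
    pairs (w < 1) correlate more weakly, giving the topographic gradient.
    """
    out = np.empty((len(channels), common.size))
    for i, lb in enumerate(channels):
        w = DEFAULT_SOURCE_WEIGHTS.get(lb, 0.3)
        sign = 0.0 if is_midline(lb) else (1.0 if is_left(lb) else -1.0)
        indep = indep_realizer(rng)
        out[i] = (amp_ratio / 2.0) * (sign * w * common + np.sqrt(2.0) * g * indep)
    return out


def generate_alpha_test(config: SimConfig) -> AlphaSession:
    """Simulate one alternating eyes-closed/eyes-open session on both devices.

    Returns the in-ear and scalp recordings (each with its trigger channel,
    on its own clock), the EC/EO schedule on the scalp-device timeline, and a
    ground-truth dictionary (schedule, trigger times, artifact intervals,
    clock offset/drift, target rho).
    """
    if config.protocol != "alpha_test":
        raise ConfigError("generate_alpha_test requires protocol='alpha_test'")
    rng = np.random.default_rng(config.seed)
    fs_hi = config.fs_scalp
    session = config.alpha_session_len_s
    drift = config.clock_drift_ppm * 1e-6
    ext = session + config.clock_offset_s + session * abs(drift) + 1.0
    n_hi = int(round(ext * fs_hi))

    # EC/EO schedule: alternating trials, always starting eyes-closed
    schedule = []
    for k in range(config.n_trials):
        schedule.append(
            {
                "start_s": k * config.trial_len_s,
                "end_s": (k + 1) * config.trial_len_s,
                "condition": "EC" if k % 2 == 0 else "EO",
            }
        )
    ec_intervals = [
        (s["start_s"], s["end_s"]) for s in schedule if s["condition"] == "EC"
    ]
    gate = _cosine_gate(n_hi, fs_hi, ec_intervals)

    alpha_comp = BandComponent(
        8.0, 12.0, config.alpha_rms, carrier_hz=config.alpha_freq
    )
    bg_comp = BandComponent(0.3, 35.0, config.band_noise_sd, shape="pink")
    g = _noise_gain(config.rho)

    def realize(r: np.random.Generator) -> np.ndarray:
        return gate * _band_noise(n_hi, fs_hi, alpha_comp, r) + _band_noise(
            n_hi, fs_hi, bg_comp, r
        )

    common = realize(rng)
    inear_master = common + g * realize(rng)
    channels = config.channels()
    scalp_data = _electrode_signals(
        channels, common, fs_hi, g, config.amp_ratio, realize, rng
    )

    # triggers: one pulse shortly after each trial onset, on the master clock
    if config.trigger_times_s is not None:
        trig_times = np.asarray(config.trigger_times_s, dtype=float)
    else:
        trig_times = np.array([s["start_s"] + 0.5 for s in schedule])
    trig_master = _trigger_trace(n_hi, fs_hi, trig_times, rng)

    n_scalp = int(round(session * fs_hi))
    scalp = Recording(
        labels=channels,
        data=scalp_data[:, :n_scalp],
        fs=fs_hi,
        trigger=trig_master[:n_scalp].copy(),
        meta={"device": "scalp", "protocol": "alpha_test"},
    )

    n_in = int(round(session * config.fs_inear))
    inear_trace = _device_sample(
        inear_master, fs_hi, config.fs_inear, n_in,
        config.clock_offset_s, config.clock_drift_ppm,
    )
    inear_trig = _device_sample(
        trig_master, fs_hi, config.fs_inear, n_in,
        config.clock_offset_s, config.clock_drift_ppm,
    )
    inear = Recording(
        labels=[IN_EAR_LABEL],
        data=inear_trace[np.newaxis, :],
        fs=config.fs_inear,
        trigger=inear_trig,
        meta={"device": "inear", "protocol": "alpha_test"},
    )

    inear, artifact_intervals = inject_artifacts(
        inear, config, rng=np.random.default_rng(rng.integers(2**31))
    )

    ground_truth = {
        "schedule": schedule,
        "trigger_times_s": trig_times.tolist(),
        "clock_offset_s": config.clock_offset_s,
        "clock_drift_ppm": config.clock_drift_ppm,
        "rho": config.rho,
        "amp_ratio": config.amp_ratio,
        "artifact_intervals": artifact_intervals,
    }
    inear.meta["ground_truth"] = ground_truth
    return AlphaSession(inear, scalp, schedule, ground_truth)


def _make_hypnogram(n_epochs: int, rng: np.random.Generator) -> list[str]:
    """Plausible nap staging: Wake -> N1 -> N2 -> N3 -> N2 -> REM cycles.

    Per-phase durations are drawn around physiological nap proportions; every
    canonical stage appears whenever the nap is long enough (>= 10 epochs).
    """
    cycle = ["Wake", "N1", "N2", "N3", "N2", "REM"]
    mean_epochs = {"Wake": 5, "N1": 4, "N2": 8, "N3": 6, "REM": 4}
    stages: list[str] = []
    i = 0
    while len(stages) < n_epochs:
        st = cycle[i % len(cycle)]
        k = max(1, int(rng.poisson(mean_epochs[st])))
        stages.extend([st] * k)
        i += 1
    return stages[:n_epochs]


def generate_nap(config: SimConfig) -> NapSession:
    """Simulate a staged nap on both devices plus its 30-s hypnogram.

    Each contiguous stage run is synthesized from the stage's band-amplitude
    template with the stage's target inter-device correlation; runs are
    blended with short cosine ramps.
    """
    if config.protocol != "nap":
        raise ConfigError("generate_nap requires protocol='nap'")
    for st, rho in config.stage_rho.items():
        if not 0 < rho <= 1:
            raise ConfigError(f"stage_rho[{st!r}] must be in (0, 1]")
    rng = np.random.default_rng(config.seed)
    fs_hi = config.fs_scalp
    epoch_len = 30.0
    n_epochs = int(config.nap_len_s // epoch_len)
    if n_epochs < 1:
        raise ConfigError("nap_len_s shorter than one 30-s epoch")
    session = n_epochs * epoch_len
    stages = _make_hypnogram(n_epochs, rng)
    missing = set(stages) - set(config.stage_template)
    if missing:
        raise ConfigError(f"stage_template lacks stages: {sorted(missing)}")

    drift = config.clock_drift_ppm * 1e-6
    ext = session + config.clock_offset_s + session * abs(drift) + 1.0
    n_hi = int(round(ext * fs_hi))
    bg_comp = BandComponent(0.3, 35.0, config.band_noise_sd, shape="pink")
    channels = config.channels()

    common = np.zeros(n_hi)
    inear_master = np.zeros(n_hi)
    scalp_master = np.zeros((len(channels), n_hi))

    # contiguous stage runs
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, n_epochs + 1):
        if i == n_epochs or stages[i] != stages[start]:
            runs.append((stages[start], start, i))
            start = i
    for st, e0, e1 in runs:
        a, b = e0 * epoch_len, e1 * epoch_len
        if e1 == n_epochs:
            b = ext  # let the last stage cover the drift/offset margin
        # synthesize only over this run's slice (plus ramp margins)
        i0 = max(0, int(round((a - 0.5) * fs_hi)))
        i1 = min(n_hi, int(round((b + 0.5) * fs_hi)))
        m = i1 - i0
        seg_gate = _cosine_gate(
            m, fs_hi, [(a - i0 / fs_hi, b - i0 / fs_hi)], ramp_s=0.25
        )
        comps = tuple(config.stage_template[st])
        g = _noise_gain(config.stage_rho.get(st, config.rho))

        def realize(r: np.random.Generator) -> np.ndarray:
            return seg_gate * (
                _composite(m, fs_hi, comps, r)
                + _band_noise(m, fs_hi, bg_comp, r)
            )

        c = realize(rng)
        common[i0:i1] += c
        inear_master[i0:i1] += c + g * realize(rng)
        for i, lb in enumerate(channels):
            w = DEFAULT_SOURCE_WEIGHTS.get(lb, 0.3)
            sign = 0.0 if is_midline(lb) else (1.0 if is_left(lb) else -1.0)
            scalp_master[i, i0:i1] += (config.amp_ratio / 2.0) * (
                sign * w * c + np.sqrt(2.0) * g * realize(rng)
            )

    if config.trigger_times_s is not None:
        trig_times = np.asarray(config.trigger_times_s, dtype=float)
    else:
        trig_times = np.arange(0.5, session, 60.0)
    trig_master = _trigger_trace(n_hi, fs_hi, trig_times, rng)

    n_scalp = int(round(session * fs_hi))
    scalp = Recording(
        labels=channels,
        data=scalp_master[:, :n_scalp],
        fs=fs_hi,
        trigger=trig_master[:n_scalp].copy(),
        meta={"device": "scalp", "protocol": "nap"},
    )
    n_in = int(round(session * config.fs_inear))
    inear_trace = _device_sample(
        inear_master, fs_hi, config.fs_inear, n_in,
        config.clock_offset_s, config.clock_drift_ppm,
    )
    inear_trig = _device_sample(
        trig_master, fs_hi, config.fs_inear, n_in,
        config.clock_offset_s, config.clock_drift_ppm,
    )
    inear = Recording(
        labels=[IN_EAR_LABEL],
        data=inear_trace[np.newaxis, :],
        fs=config.fs_inear,
        trigger=inear_trig,
        meta={"device": "inear", "protocol": "nap"},
    )
    inear, artifact_intervals = inject_artifacts(
        inear, config, rng=np.random.default_rng(rng.integers(2**31))
    )

    hyp = Hypnogram(stages=stages, epoch_len_s=epoch_len)
    ground_truth = {
        "stages": stages,
        "trigger_times_s": trig_times.tolist(),
        "clock_offset_s": config.clock_offset_s,
        "clock_drift_ppm": config.clock_drift_ppm,
        "stage_rho": dict(config.stage_rho),
        "amp_ratio": config.amp_ratio,
        "artifact_intervals": artifact_intervals,
    }
    inear.meta["ground_truth"] = ground_truth
    return NapSession(inear, scalp, hyp, ground_truth)


# ---------------------------------------------------------------------------
# artifact injection


def inject_artifacts(
    rec: Recording,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    epoch_len_s: float = 10.0,
) -> tuple[Recording, list[dict]]:
    """Add intermittent high-voltage artifacts and contact-loss epochs.

    Each 10-s epoch independently receives a transient artifact with
    probability ``artifact_rate * epoch_len_s / 60`` — a Tukey-windowed
    low-frequency burst whose peak is ``artifact_amp_factor`` times the
    channel's clean RMS — and becomes a contact-loss epoch (a large slow
    swing spanning the whole epoch) with probability ``contact_loss_prob``.
    Events never straddle epoch boundaries.  Returns a modified copy and the
    ground-truth event list; with zero rates the copy equals the input.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = rec.copy()
    events: list[dict] = []
    p_evt = min(1.0, config.artifact_rate * epoch_len_s / 60.0)
    n_ep = int(rec.duration_s // epoch_len_s)
    n_per_ep = int(round(epoch_len_s * rec.fs))
    dur = min(config.artifact_len_s, epoch_len_s)
    n_evt = int(round(dur * rec.fs))
    win = _tukey(n_evt, 0.25)
    for ci, label in enumerate(rec.labels):
        clean_rms = float(np.sqrt(np.mean(rec.data[ci] ** 2)))
        peak = config.artifact_amp_factor * clean_rms
        for e in range(n_ep):
            e0 = e * n_per_ep
            if p_evt > 0 and rng.random() < p_evt:
                start = e0 + rng.integers(0, n_per_ep - n_evt + 1)
                phase = rng.uniform(0, 2 * np.pi)
                t = np.arange(n_evt) / rec.fs
                burst = peak * win * np.sin(2 * np.pi * 1.2 * t + phase)
                out.data[ci, start : start + n_evt] += burst
                events.append(
                    {
                        "channel": label,
                        "kind": "transient",
                        "start_s": start / rec.fs,
                        "end_s": (start + n_evt) / rec.fs,
                        "peak_uV": peak,
                    }
                )
            if config.contact_loss_prob > 0 and rng.random() < config.contact_loss_prob:
                t = np.arange(n_per_ep) / rec.fs
                phase = rng.uniform(0, 2 * np.pi)
                swing = (
                    2.0
                    * peak
                    * _tukey(n_per_ep, 0.1)
                    * np.sin(2 * np.pi * 0.3 * t + phase)
                )
                out.data[ci, e0 : e0 + n_per_ep] += swing
                events.append(
                    {
                        "channel": label,
                        "kind": "contact_loss",
                        "start_s": e0 / rec.fs,
                        "end_s": (e0 + n_per_ep) / rec.fs,
                        "peak_uV": 2.0 * peak,
                    }
                )
    return out, events


def _tukey(n: int, alpha: float) -> np.ndarray:
    from scipy.signal.windows import tukey

    return tukey(n, alpha)


# ---------------------------------------------------------------------------
# ground-truth sidecar


def write_sidecar(path: str | Path, ground_truth: dict, config: SimConfig) -> None:
    """Write the simulation ground truth + config next to the exported EDFs."""
    payload = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if not isinstance(v, dict)
        },
        "ground_truth": ground_truth,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
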