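"""Time-frequency decomposition, alpha-band SNR, and relative band power.

The alpha SNR statistic is the mean time-frequency power over 8–12 Hz
divided by the mean power over 5–35 Hz excluding 7–13 Hz (the surround
noise), computed from a Gabor/Morlet wavelet spectrogram averaged over clean
eyes-closed intervals.  A ratio above 1.5 — equivalently 20·log10(1.5) ≈
3.52 dB in the amplitude convention — marks a "clear" alpha peak.

Relative spectral power (RSP) divides the summed PSD in each canonical band
by the summed PSD over the wide 0.3–35 Hz range, per clean 10-s window,
averaged across windows.  The five bands partition 0.3–35 Hz with half-open
edges (the last band closes at 35 Hz), so the five RSP values sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import periodogram

__all__ = [
    "BANDS",
    "SpectralEstimate",
    "BandPowerTable",
    "gabor_spectrogram",
    "snr_alpha",
    "snr_to_db",
    "relative_band_power",
]

# canonical bands partitioning 0.3-35 Hz; half-open [lo, hi), last closed
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.3, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta1": (12.0, 18.0),
    "beta2": (18.0, 35.0),
}
WIDE_BAND = (0.3, 35.0)

ALPHA_BAND = (8.0, 12.0)
SNR_SIGNAL_BAND = (8.0, 12.0)
SNR_NOISE_RANGE = (5.0, 35.0)
SNR_NOISE_NOTCH = (7.0, 13.0)
CLEAR_PEAK_SNR = 1.5


class NoCleanDataError(RuntimeError):
    """Every window was rejected by the artifact rule."""


@dataclass
class SpectralEstimate:
    """Power as a function of frequency (and optionally time).

    ``power`` has shape (n_freqs,) for an averaged spectrum or
    (n_freqs, n_times) for a spectrogram; ``valid`` marks time points free
    of wavelet edge effects (None for averaged spectra).
    """

    freqs: np.ndarray
    power: np.ndarray
    window_len_s: float
    method: Literal["gabor_wavelet", "fft_window"]
    times: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    def time_average(self) -> "SpectralEstimate":
        """Average a spectrogram over its valid time region."""
        if self.power.ndim == 1:
            return self
        valid = (
            self.valid
            if self.valid is not None
            else np.ones(self.power.shape[1], dtype=bool)
        )
        if valid.sum() == 0:
            raise ValueError("no valid time points to average")
        return SpectralEstimate(
            freqs=self.freqs,
            power=self.power[:, valid].mean(axis=1),
            window_len_s=self.window_len_s,
            method=self.method,
        )


@dataclass
class BandPowerTable:
    """Relative spectral power per canonical band for one condition/stage."""

    rsp: dict[str, float]
    label: str = ""
    n_windows: int = 0

    def __post_init__(self) -> None:
        for band, v in self.rsp.items():
            if not 0.0 <= v <= 1.0 + 1e-9:
                raise ValueError(f"rsp[{band!r}]={v} outside [0, 1]")


def gabor_spectrogram(
    signal: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    cycles: float = 7.0,
) -> SpectralEstimate:
    """Time-resolved power via Gabor (Morlet-family) wavelets.

    Uses a constant-Q family with ``cycles`` cycles per wavelet.  Time
    points within one wavelet half-length of either edge at the lowest
    frequency are marked invalid and excluded from averaged spectra.
    """
    from mne.time_frequency import tfr_array_morlet

    signal = np.asarray(signal, dtype=float)
    if freqs is None:
        freqs = np.arange(1.0, 35.0 + 0.25, 0.25)
    freqs = np.asarray(freqs, dtype=float)
    if cycles < 3:
        raise ValueError("cycles must be at least 3")
    if freqs.min() <= 0 or freqs.max() >= fs / 2:
        raise ValueError("frequencies must lie within (0, Nyquist)")
    power = tfr_array_morlet(
        signal[np.newaxis, np.newaxis, :],
        sfreq=fs,
        freqs=freqs,
        n_cycles=cycles,
        output="power",
        verbose=False,
    )[0, 0]
    times = np.arange(signal.size) / fs
    half_len_s = cycles / (2.0 * freqs.min())
    valid = (times >= half_len_s) & (times <= times[-1] - half_len_s)
    if not valid.any():  # signal shorter than one wavelet: keep everything
        valid = np.ones_like(times, dtype=bool)
    return SpectralEstimate(
        freqs=freqs,
        power=power,
        window_len_s=signal.size / fs,
        method="gabor_wavelet",
        times=times,
        valid=valid,
    )


def snr_alpha(est: SpectralEstimate) -> tuple[float, bool]:
    """Alpha-band SNR: mean power 8–12 Hz over mean power 5–35 Hz minus 7–13 Hz.

    Returns ``(ratio, clear_peak)`` where ``clear_peak = ratio > 1.5``.
    Spectrograms are first averaged over their valid time region.  Means are
    taken over frequency bins (uniform grids assumed).
    """
    spec = est.time_average()
    f, p = spec.freqs, spec.power
    if f.min() > SNR_NOISE_RANGE[0] or f.max() < SNR_NOISE_RANGE[1]:
        raise ValueError("spectral estimate must cover 5-35 Hz")
    sig = (f >= SNR_SIGNAL_BAND[0]) & (f <= SNR_SIGNAL_BAND[1])
    noise = (
        (f >= SNR_NOISE_RANGE[0])
        & (f <= SNR_NOISE_RANGE[1])
        & ~((f >= SNR_NOISE_NOTCH[0]) & (f <= SNR_NOISE_NOTCH[1]))
    )
    denom = p[noise].mean()
    if denom <= 0:
        raise ZeroDivisionError("undefined SNR: zero power in the noise band")
    ratio = float(p[sig].mean() / denom)
    return ratio, ratio > CLEAR_PEAK_SNR


def snr_to_db(ratio: float) -> float:
    """Amplitude-convention decibels: 20·log10(ratio).

    This is the convention under which a power-ratio criterion of 1.5
    corresponds to 3.52 dB.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return float(20.0 * np.log10(ratio))


def _band_mask(f: np.ndarray, lo: float, hi: float, closed: bool) -> np.ndarray:
    m = (f >= lo) & ((f <= hi) if closed else (f < hi))
    return m


def relative_band_power_windows(
    signal: np.ndarray,
    fs: float,
    mask: np.ndarray | None = None,
    window_len_s: float = 10.0,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-window relative band power.

    Returns ``(band_names, rsp, window_indices)`` where ``rsp`` has one row
    per clean window (columns in band order, each row summing to 1) and
    ``window_indices`` gives the original window positions of those rows.
    """
    signal = np.asarray(signal, dtype=float)
    n_per = int(round(window_len_s * fs))
    n_win = signal.size // n_per
    if n_win < 1:
        raise ValueError("signal shorter than one window")
    if mask is None:
        mask = np.ones(n_win, dtype=bool)
    mask = np.asarray(mask, dtype=bool)[:n_win]
    if mask.sum() == 0:
        raise NoCleanDataError("no clean windows for relative band power")
    idx = np.flatnonzero(mask)
    windows = signal[: n_win * n_per].reshape(n_win, n_per)[idx]
    f, psd = periodogram(windows, fs=fs, window="hann", axis=1)
    wide = _band_mask(f, *WIDE_BAND, closed=True)
    total = psd[:, wide].sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total power in a window; RSP undefined")
    band_names = list(BANDS)
    rsp_win = np.empty((windows.shape[0], len(band_names)))
    for j, name in enumerate(band_names):
        lo, hi = BANDS[name]
        closed = name == band_names[-1]
        m = _band_mask(f, lo, hi, closed=closed) & wide
        rsp_win[:, j] = psd[:, m].sum(axis=1) / total
    return band_names, rsp_win, idx


def relative_band_power(
    signal: np.ndarray,
    fs: float,
    mask: np.ndarray | None = None,
    window_len_s: float = 10.0,
    label: str = "",
) -> BandPowerTable:
    """Relative power in the five canonical bands from clean 10-s windows.

    Per non-overlapping Hann-tapered window, RSP(band) = Σ PSD over the band
    divided by Σ PSD over 0.3–35 Hz; values are averaged across clean
    windows (``mask``: True = clean, one entry per window).
    """
    band_names, rsp_win, idx = relative_band_power_windows(
        signal, fs, mask=mask, window_len_s=window_len_s
    )
    mean_rsp = rsp_win.mean(axis=0)
    return BandPowerTable(
        rsp={name: float(v) for name, v in zip(band_names, mean_rsp)},
        label=label,
        n_windows=int(idx.size),
    )
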