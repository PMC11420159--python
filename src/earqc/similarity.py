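"""In-ear vs scalp similarity: lag-tolerant correlation, topography, stages.

Because the two devices keep imperfect clocks, correlations are evaluated as
normalized cross-correlations over all integer-sample lags within ±0.1 s,
taking the lag that maximizes |r|.  The alpha-band correlation map pairs the
in-ear channel with every contralateral bipolar scalp derivation over clean
eyes-closed data; the nap analysis correlates 10-s windows of broadband
(0.3–35 Hz) signal against T7-T8, grouped by the sleep stage of the
containing 30-s epoch.  Observed |r| maps onto conventional agreement
categories, and the scalp/in-ear amplitude relation is summarized by the
least-squares slope of sqrt(alpha power) across 10-s epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .montage import Derivation, contralateral_pairs
from .recording import Recording, Hypnogram
from .spectral import ALPHA_BAND

__all__ = [
    "Derivation",
    "CorrelationResult",
    "MAX_LAG_S",
    "AGREEMENT_CATEGORIES",
    "contralateral_montage",
    "xcorr_max",
    "alpha_correlation_map",
    "stage_correlations",
    "classify_agreement",
    "amplitude_ratio",
]

MAX_LAG_S = 0.1

# |r| category edges; the lower bound of "fair" is 0.2 (the conventional
# scale; see docs/methods.md on the off-by-10x lower edge sometimes quoted)
AGREEMENT_CATEGORIES: list[tuple[float, float, str]] = [
    (0.0, 0.2, "poor"),
    (0.2, 0.4, "fair"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "substantial"),
    (0.8, 1.01, "almost perfect"),
]


@dataclass
class CorrelationResult:
    """Correlation of the in-ear channel with one derivation or stage."""

    label: str
    r: float
    best_lag_s: float
    n_windows: int = 0
    r_dispersion: float = float("nan")  # across-window SD of r
    r_fisher_mean: float = float("nan")
    p: float = float("nan")
    q_significant: bool | None = None
    per_window_r: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-9:
            raise ValueError("|r| cannot exceed 1")


def contralateral_montage(
    channel_labels: list[str],
) -> tuple[list[Derivation], list[str]]:
    """Build contralateral bipolar derivations from available 10-10 labels.

    Returns ``(derivations, skipped)``; midline and unpaired electrodes are
    reported in ``skipped``.  Raises when nothing is pairable.
    """
    pairs, skipped = contralateral_pairs(channel_labels)
    if not pairs:
        raise ValueError("no pairable contralateral electrodes in montage")
    return [Derivation(left, right) for left, right in pairs], skipped


def derivation_signal(rec: Recording, deriv: Derivation) -> np.ndarray:
    """Left-minus-right difference trace for a derivation."""
    return rec.channel(deriv.left_label) - rec.channel(deriv.right_label)


def xcorr_max(
    a: np.ndarray,
    b: np.ndarray,
    fs: float,
    max_lag_s: float = MAX_LAG_S,
) -> tuple[float, float]:
    """Pearson correlation maximized over integer-sample lags in ±max_lag_s.

    For lag L > 0, ``b`` is considered delayed: a[t] is compared with
    b[t + L].  Returns ``(r, best_lag_s)`` where the best lag maximizes |r|
    and ``r`` is the signed correlation there.  Ties prefer the smaller |lag|.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("series must have equal length >= 2")
    if max_lag_s < 0:
        raise ValueError("max_lag_s must be nonnegative")
    max_lag = int(np.floor(max_lag_s * fs))
    lags = np.arange(-max_lag, max_lag + 1)
    best = (0.0, 0)
    best_abs = -np.inf
    # order lags by |lag| so ties resolve to the smallest shift
    for lag in sorted(lags, key=abs):
        if lag >= 0:
            x, y = a[: a.size - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: b.size + lag]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            raise ValueError("zero-variance input; correlation undefined")
        r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        if abs(r) > best_abs + 1e-15:
            best_abs = abs(r)
            best = (r, lag)
    return best[0], best[1] / fs


def clean_concat(
    x: np.ndarray, fs: float, mask: np.ndarray, window_len_s: float = 10.0
) -> np.ndarray:
    """Concatenate the windows marked clean in ``mask`` (True = clean)."""
    x = np.asarray(x, dtype=float)
    n_per = int(round(window_len_s * fs))
    n_win = x.size // n_per
    m = np.asarray(mask, dtype=bool)[:n_win]
    windows = x[: n_win * n_per].reshape(n_win, n_per)
    return windows[m].ravel()


_clean_concat = clean_concat


def alpha_correlation_map(
    inear: np.ndarray,
    scalp: Recording,
    fs: float,
    mask: np.ndarray | None = None,
    window_len_s: float = 10.0,
    max_lag_s: float = MAX_LAG_S,
) -> tuple[list[CorrelationResult], list[str]]:
    """Lag-tolerant alpha correlation of the in-ear channel with every
    contralateral scalp derivation.

    Inputs must already be aligned, at a common sampling rate, and
    alpha-band filtered, with ``mask`` marking clean eyes-closed windows
    (True = clean) on the shared 10-s grid.  Permutation p-values and FDR
    decisions are attached downstream by the inference module.
    """
    derivs, skipped = contralateral_montage(scalp.labels)
    if mask is not None and not np.asarray(mask, bool).any():
        raise ValueError("no clean eyes-closed windows")
    results = []
    n_per = int(round(window_len_s * fs))
    for d in derivs:
        sig = derivation_signal(scalp, d)
        if mask is None:
            a, b = inear, sig
            n_win = inear.size // n_per
        else:
            a = _clean_concat(inear, fs, mask, window_len_s)
            b = _clean_concat(sig, fs, mask, window_len_s)
            n_win = int(np.asarray(mask, bool)[: sig.size // n_per].sum())
        r, lag = xcorr_max(a, b, fs, max_lag_s)
        results.append(
            CorrelationResult(label=d.name, r=r, best_lag_s=lag, n_windows=n_win)
        )
    return results, skipped


def stage_correlations(
    inear: np.ndarray,
    scalp_t7t8: np.ndarray,
    hyp: Hypnogram,
    fs: float,
    mask: np.ndarray | None = None,
    window_len_s: float = 10.0,
    max_lag_s: float = MAX_LAG_S,
) -> tuple[list[CorrelationResult], list[str]]:
    """Per-sleep-stage correlation between in-ear and scalp T7-T8.

    Both series must be broadband (0.3–35 Hz) filtered and aligned.  Each
    clean 10-s window is correlated with the lag-tolerant maximum; windows
    inherit the stage of their containing 30-s hypnogram epoch.  Returns
    per-stage results (plain mean r, Fisher-z mean, dispersion, window
    count) in canonical stage order, plus stages omitted for lack of clean
    windows.
    """
    inear = np.asarray(inear, dtype=float)
    scalp_t7t8 = np.asarray(scalp_t7t8, dtype=float)
    n_per = int(round(window_len_s * fs))
    n_win = min(inear.size, scalp_t7t8.size) // n_per
    if n_win < 1:
        raise ValueError("signals shorter than one window")
    if mask is None:
        mask = np.ones(n_win, dtype=bool)
    mask = np.asarray(mask, dtype=bool)[:n_win]
    win_per_epoch = max(1, int(round(hyp.epoch_len_s / window_len_s)))

    per_stage_r: dict[str, list[float]] = {}
    per_stage_lag: dict[str, list[float]] = {}
    for w in range(n_win):
        if not mask[w]:
            continue
        epoch_idx = w // win_per_epoch
        if epoch_idx >= hyp.n_epochs:
            break
        stage = hyp.stages[epoch_idx]
        sl = slice(w * n_per, (w + 1) * n_per)
        try:
            r, lag = xcorr_max(inear[sl], scalp_t7t8[sl], fs, max_lag_s)
        except ValueError:
            continue  # constant window
        per_stage_r.setdefault(stage, []).append(r)
        per_stage_lag.setdefault(stage, []).append(lag)

    results: list[CorrelationResult] = []
    omitted: list[str] = []
    for stage in hyp.observed_stages():
        rs = np.array(per_stage_r.get(stage, []))
        if rs.size == 0:
            omitted.append(stage)
            continue
        z = np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12))
        results.append(
            CorrelationResult(
                label=stage,
                r=float(rs.mean()),
                best_lag_s=float(np.mean(per_stage_lag[stage])),
                n_windows=int(rs.size),
                r_dispersion=float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
                r_fisher_mean=float(np.tanh(z.mean())),
                per_window_r=rs,
            )
        )
    return results, omitted


def classify_agreement(r: float) -> str:
    """Map |r| onto the conventional five agreement categories."""
    if not np.isfinite(r):
        raise ValueError("r must be finite")
    a = abs(r)
    for lo, hi, name in AGREEMENT_CATEGORIES:
        if lo <= a < hi:
            return name
    return "almost perfect"  # |r| == 1 lands here


def amplitude_ratio(
    power_scalp: np.ndarray, power_inear: np.ndarray
) -> tuple[float, float]:
    """Slope of sqrt(scalp alpha power) on sqrt(in-ear alpha power).

    Ordinary least squares across paired clean 10-s epochs, intercept
    included; returns ``(slope, intercept)``.  With the scalp channel an
    exact multiple of the in-ear channel the slope equals that multiple.
    """
    ps = np.asarray(power_scalp, dtype=float)
    pi = np.asarray(power_inear, dtype=float)
    if ps.size != pi.size or ps.size < 3:
        raise ValueError("need at least 3 paired epochs")
    if np.any(ps < 0) or np.any(pi < 0):
        raise ValueError("powers must be nonnegative")
    x, y = np.sqrt(pi), np.sqrt(ps)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance powers; slope undefined")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def alpha_power_per_epoch(
    signal: np.ndarray,
    fs: float,
    window_len_s: float = 10.0,
    band: tuple[float, float] = ALPHA_BAND,
) -> np.ndarray:
    """Alpha-band power per non-overlapping 10-s epoch (periodogram sum)."""
    from scipy.signal import periodogram

    n_per = int(round(window_len_s * fs))
    n_win = signal.size // n_per
    windows = np.asarray(signal, float)[: n_win * n_per].reshape(n_win, n_per)
    f, psd = periodogram(windows, fs=fs, window="hann", axis=1)
    m = (f >= band[0]) & (f <= band[1])
    return psd[:, m].sum(axis=1)
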