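"""Epoching, amplitude-threshold artifact flagging, RMS and bad-data stats.

The artifact rule: a 10-s non-overlapping epoch is rejected when its signal
spends at least 10% of the time outside the −100..+100 μV range.  Rejected
epochs are excluded from RMS, SNR, relative-power and correlation
computations alike; for paired statistics the two channels' flags are
OR-combined so both devices are compared over identical clean time ranges.
A whole recording is considered low quality when more than 10% of its epochs
are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import Recording

__all__ = [
    "EpochGrid",
    "RmsSummary",
    "epoch_and_flag",
    "rms_per_epoch",
    "bad_data_fraction",
    "combine_masks",
]

AMP_THRESH_UV = 100.0
FRAC_THRESH = 0.10
EPOCH_LEN_S = 10.0
BAD_DATA_PCT_LIMIT = 10.0


@dataclass
class EpochGrid:
    """Non-overlapping fixed-length windowing of one channel with flags.

    ``data`` has shape (n_epochs, samples_per_epoch); ``artifact_flag[e]``
    is True when epoch ``e`` violates the amplitude rule.  The trailing
    partial epoch, if any, is discarded.
    """

    data: np.ndarray
    fs: float
    epoch_len_s: float
    artifact_flag: np.ndarray
    source_channel: str
    start_times_s: np.ndarray

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_clean(self) -> int:
        return int((~self.artifact_flag).sum())


@dataclass
class RmsSummary:
    per_epoch_uV: np.ndarray  # NaN where excluded
    mean_uV: float
    sd_uV: float
    min_uV: float
    max_uV: float
    n_epochs_used: int
    status: str  # "ok" | "no clean data"


def epoch_and_flag(
    rec: Recording,
    channel: str,
    epoch_len_s: float = EPOCH_LEN_S,
    amp_thresh_uV: float = AMP_THRESH_UV,
    frac_thresh: float = FRAC_THRESH,
) -> EpochGrid:
    """Tile a channel into epochs and apply the amplitude-threshold rule.

    An epoch is flagged iff the fraction of its samples with
    ``|x| > amp_thresh_uV`` is **at least** ``frac_thresh``.
    """
    if amp_thresh_uV <= 0:
        raise ValueError("amp_thresh_uV must be positive")
    if not 0 < frac_thresh < 1:
        raise ValueError("frac_thresh must be in (0, 1)")
    n_per = int(round(epoch_len_s * rec.fs))
    if n_per < 1:
        raise ValueError("epoch shorter than one sample")
    x = rec.channel(channel)
    n_ep = x.size // n_per
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    windows = x[: n_ep * n_per].reshape(n_ep, n_per)
    frac_exceed = np.mean(np.abs(windows) > amp_thresh_uV, axis=1)
    flags = frac_exceed >= frac_thresh
    return EpochGrid(
        data=windows,
        fs=rec.fs,
        epoch_len_s=epoch_len_s,
        artifact_flag=flags,
        source_channel=channel,
        start_times_s=np.arange(n_ep) * epoch_len_s + rec.start_offset_s,
    )


def rms_per_epoch(grid: EpochGrid, include_flagged: bool = False) -> RmsSummary:
    """Per-epoch RMS (μV) with summary statistics over retained epochs.

    Flagged epochs are excluded by default; their per-epoch entries are NaN.
    With every epoch flagged the summary carries the "no clean data" status.
    """
    if grid.n_epochs == 0:
        raise ValueError("empty epoch grid")
    rms = np.sqrt(np.mean(grid.data**2, axis=1))
    keep = (
        np.ones(grid.n_epochs, dtype=bool)
        if include_flagged
        else ~grid.artifact_flag
    )
    per_epoch = np.where(keep, rms, np.nan)
    if keep.sum() == 0:
        return RmsSummary(
            per_epoch_uV=per_epoch,
            mean_uV=float("nan"),
            sd_uV=float("nan"),
            min_uV=float("nan"),
            max_uV=float("nan"),
            n_epochs_used=0,
            status="no clean data",
        )
    used = rms[keep]
    return RmsSummary(
        per_epoch_uV=per_epoch,
        mean_uV=float(used.mean()),
        sd_uV=float(used.std(ddof=1)) if used.size > 1 else 0.0,
        min_uV=float(used.min()),
        max_uV=float(used.max()),
        n_epochs_used=int(keep.sum()),
        status="ok",
    )


def bad_data_fraction(grid: EpochGrid) -> tuple[float, bool]:
    """Percentage of flagged epochs and whether it exceeds the 10% limit.

    The quality verdict uses strict ``>`` (a recording with exactly 10% bad
    epochs is still acceptable).
    """
    if grid.n_epochs == 0:
        raise ValueError("empty epoch grid")
    pct = 100.0 * float(grid.artifact_flag.sum()) / grid.n_epochs
    return pct, pct > BAD_DATA_PCT_LIMIT


def combine_masks(*grids: EpochGrid) -> np.ndarray:
    """Shared clean-epoch mask (True = clean) across channels of one pair.

    Epoch counts may differ by trailing truncation; the shortest grid wins.
    """
    n = min(g.n_epochs for g in grids)
    clean = np.ones(n, dtype=bool)
    for g in grids:
        clean &= ~g.artifact_flag[:n]
    return clean
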