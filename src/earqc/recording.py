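"""Core in-memory containers for dual-device EEG sessions.

A :class:`Recording` is a labeled multichannel time series in microvolts with
a sampling rate and an optional dedicated trigger channel.  A
:class:`Hypnogram` is a sequence of 30-s sleep-stage labels aligned to the
start of a recording.  Both are deliberately plain containers: all signal
processing lives in the operation modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SLEEP_STAGES = ("Wake", "N1", "N2", "N3", "REM")


@dataclass
class Recording:
    """Multichannel EEG segment on a single device clock.

    Parameters
    ----------
    labels
        Channel names (10-10 labels for scalp, e.g. ``"T7"``; the in-ear
        device exposes a single bipolar channel, conventionally ``"InEar"``).
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    trigger
        Optional trigger trace of length ``n_samples`` (arbitrary units).
    start_offset_s
        Start time of sample 0 on the common post-alignment timeline.
    meta
        Free-form provenance (device name, simulation ground truth, ...).
    """

    labels: list[str]
    data: np.ndarray
    fs: float
    trigger: np.ndarray | None = None
    start_offset_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, :]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sample values must be finite")
        if self.trigger is not None:
            self.trigger = np.asarray(self.trigger, dtype=float)
            if self.trigger.shape[0] != self.data.shape[1]:
                raise ValueError("trigger length must match data length")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times on the common timeline (seconds)."""
        return self.start_offset_s + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D trace for a channel by label."""
        try:
            idx = self.labels.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in {self.labels}") from err
        return self.data[idx]

    def has_channel(self, label: str) -> bool:
        return label in self.labels

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (order preserved)."""
        idx = [self.labels.index(lb) for lb in labels]
        return replace(
            self,
            labels=list(labels),
            data=self.data[idx].copy(),
            trigger=None if self.trigger is None else self.trigger.copy(),
        )

    def copy(self) -> "Recording":
        return replace(
            self,
            labels=list(self.labels),
            data=self.data.copy(),
            trigger=None if self.trigger is None else self.trigger.copy(),
            meta=dict(self.meta),
        )


@dataclass
class Hypnogram:
    """Sleep-stage labels in fixed-length (default 30-s) epochs."""

    stages: list[str]
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"unknown sleep stage labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def stage_at(self, t_s: float) -> str:
        """Stage containing time ``t_s`` (half-open epochs [t, t+30))."""
        idx = int(t_s // self.epoch_len_s)
        if not 0 <= idx < self.n_epochs:
            raise IndexError(f"time {t_s} s outside hypnogram")
        return self.stages[idx]

    def observed_stages(self) -> list[str]:
        """Stages present, in canonical Wake→REM order."""
        present = set(self.stages)
        return [s for s in SLEEP_STAGES if s in present]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"epoch_index": np.arange(self.n_epochs), "stage": self.stages}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, epoch_len_s: float = 30.0) -> "Hypnogram":
        df = pd.read_csv(path)
        df = df.sort_values("epoch_index")
        return cls(stages=list(df["stage"].astype(str)), epoch_len_s=epoch_len_s)
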