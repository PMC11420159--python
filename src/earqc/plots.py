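"""Figure helpers: average spectrograms, correlation maps, stage bars.

Thin matplotlib wrappers used by the analysis drivers; all take an explicit
Axes or create one, and return the Figure so callers decide where to save.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .spectral import SpectralEstimate


def plot_spectrogram(
    est: SpectralEstimate, title: str = "", vmax: float | None = None
):
    """Time-frequency power (dB re max) of one channel."""
    if est.power.ndim != 2:
        raise ValueError("need a time-resolved estimate")
    fig, ax = plt.subplots(figsize=(8, 3.2))
    p = 10 * np.log10(np.maximum(est.power, est.power.max() * 1e-6))
    mesh = ax.pcolormesh(
        est.times, est.freqs, p, shading="auto", cmap="magma", vmax=vmax
    )
    fig.colorbar(mesh, ax=ax, label="power (dB)")
    ax.set(xlabel="time (s)", ylabel="frequency (Hz)", title=title)
    fig.tight_layout()
    return fig


def plot_correlation_map(corr_df: pd.DataFrame, title: str = ""):
    """Bar chart of r per contralateral derivation, significance marked."""
    fig, ax = plt.subplots(figsize=(7, 3))
    colors = [
        "tab:red" if sig else "tab:gray"
        for sig in corr_df.get("q_significant", [False] * len(corr_df))
    ]
    ax.bar(corr_df["derivation"], corr_df["r"], color=colors)
    ax.axhline(0, color="k", lw=0.5)
    ax.set(ylabel="r (alpha band, eyes closed)", title=title, ylim=(-1, 1))
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig


def plot_stage_correlations(stage_df: pd.DataFrame, title: str = ""):
    """Mean window correlation per sleep stage with dispersion bars."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(stage_df["stage"], stage_df["mean_r"], yerr=stage_df["r_sd"],
           color="tab:blue", capsize=3)
    ax.set(ylabel="mean r (0.3–35 Hz, 10-s windows)", title=title, ylim=(0, 1))
    fig.tight_layout()
    return fig
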