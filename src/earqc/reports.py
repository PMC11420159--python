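"""End-to-end orchestration of the two study protocols.

``run_alpha_report`` executes the resting eyes-closed/eyes-open pipeline:
trigger alignment → resampling to 250 Hz → 0.3–35 Hz FIR → 10-s epoching
with the ±100 μV / 10% artifact rule → RMS and bad-data statistics → Gabor
spectrogram and alpha SNR over clean eyes-closed data → contralateral
correlation map with block-permutation p-values and BH-FDR → sqrt-power
amplitude-ratio slope.

``run_nap_report`` executes the nap pipeline: the same alignment and
filtering, per-stage relative band power for both devices with per-band
permutation mean-difference tests under FDR, and per-stage lag-tolerant
correlations against scalp T7-T8.

Every number in a report is traceable to a library operation with its
parameters recorded in the report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, quality, similarity, spectral, sync
from .io import read_edf, write_json
from .recording import Hypnogram, Recording
from .simulate import (
    IN_EAR_LABEL,
    SimConfig,
    generate_alpha_test,
    generate_nap,
)

__all__ = ["StudyReport", "run_alpha_report", "run_nap_report"]

ANALYSIS_FS = 250.0


@dataclass
class StudyReport:
    """Tabular results of one protocol run plus full parameter metadata."""

    protocol: str
    tables: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def to_dir(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        write_json(out / "report_meta.json", self.metadata)
        return out


def _load_pair(
    inear, scalp
) -> tuple[Recording, Recording]:
    rec_in = read_edf(inear) if isinstance(inear, (str, Path)) else inear
    rec_sc = read_edf(scalp) if isinstance(scalp, (str, Path)) else scalp
    return rec_in, rec_sc


def _sync_resample_filter(
    rec_in: Recording, rec_sc: Recording
) -> tuple[Recording, Recording, sync.AlignmentResult]:
    """Scalp is device A (reference clock); in-ear is re-timed onto it."""
    alignment, sc_aligned, in_aligned = sync.align_pair(rec_sc, rec_in)
    in_aligned = sync.shift_to_common_grid(in_aligned)
    sc250 = sync.resample(sc_aligned, ANALYSIS_FS)
    if not np.isclose(in_aligned.fs, ANALYSIS_FS):
        in_aligned = sync.resample(in_aligned, ANALYSIS_FS)
    sc_f = sync.bandpass_fir(sc250, 0.3, 35.0)
    in_f = sync.bandpass_fir(in_aligned, 0.3, 35.0)
    return in_f, sc_f, alignment


def _derivation_recording(scalp: Recording, name: str = "T7-T8") -> np.ndarray:
    left, right = name.split("-")
    return scalp.channel(left) - scalp.channel(right)


def _ec_window_mask(
    schedule: list[dict], n_windows: int, window_len_s: float = 10.0
) -> np.ndarray:
    """True for 10-s windows fully inside an eyes-closed interval."""
    mask = np.zeros(n_windows, dtype=bool)
    for item in schedule:
        if item["condition"] != "EC":
            continue
        w0 = int(np.ceil(item["start_s"] / window_len_s))
        w1 = int(np.floor(item["end_s"] / window_len_s))
        mask[w0:min(w1, n_windows)] = True
    return mask


def run_alpha_report(
    inear=None,
    scalp=None,
    sim_config: SimConfig | None = None,
    schedule: list[dict] | None = None,
    n_perm: int = inference.DEFAULT_N_PERM,
    q: float = 0.05,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Run the full alpha-test quality pipeline; see the module docstring.

    Either pass ``sim_config`` to generate a synthetic session, or ``inear``
    and ``scalp`` as EDF paths / :class:`Recording` objects together with an
    EC/EO ``schedule`` (on the scalp-device timeline).  Without a schedule,
    alternating 30-s trials starting eyes-closed at t=0 are assumed.
    """
    if sim_config is not None:
        session = generate_alpha_test(sim_config)
        rec_in, rec_sc, schedule = session.inear, session.scalp, session.schedule
    else:
        if inear is None or scalp is None:
            raise ValueError("need sim_config or both recordings")
        rec_in, rec_sc = _load_pair(inear, scalp)
    in_f, sc_f, alignment = _sync_resample_filter(rec_in, rec_sc)
    if schedule is None:
        n_trials = int(in_f.duration_s // 30.0)
        schedule = [
            {
                "start_s": 30.0 * k,
                "end_s": 30.0 * (k + 1),
                "condition": "EC" if k % 2 == 0 else "EO",
            }
            for k in range(n_trials)
        ]

    # --- artifact-aware epoching (shared mask over the channel pair)
    inear_label = in_f.labels[0]
    grid_in = quality.epoch_and_flag(in_f, inear_label)
    t7t8 = _derivation_recording(sc_f)
    sc_pair = Recording(labels=["T7-T8"], data=t7t8[np.newaxis, :], fs=sc_f.fs)
    grid_sc = quality.epoch_and_flag(sc_pair, "T7-T8")
    clean = quality.combine_masks(grid_in, grid_sc)

    rms_rows = []
    for device, grid in (("inear", grid_in), ("scalp_T7-T8", grid_sc)):
        summary = quality.rms_per_epoch(grid)
        pct_bad, exceeds = quality.bad_data_fraction(grid)
        rms_rows.append(
            {
                "device": device,
                "rms_mean_uV": summary.mean_uV,
                "rms_sd_uV": summary.sd_uV,
                "rms_min_uV": summary.min_uV,
                "rms_max_uV": summary.max_uV,
                "n_epochs_used": summary.n_epochs_used,
                "bad_data_pct": pct_bad,
                "exceeds_10pct": exceeds,
            }
        )
    rms_in = quality.rms_per_epoch(grid_in).per_epoch_uV
    rms_sc = quality.rms_per_epoch(grid_sc).per_epoch_uV
    both = np.isfinite(rms_in[: clean.size]) & np.isfinite(rms_sc[: clean.size])
    p_rms = inference.rank_sum_right(rms_in[: clean.size][both],
                                     rms_sc[: clean.size][both])

    # --- alpha SNR on clean eyes-closed data
    n_win = clean.size
    ec_mask = _ec_window_mask(schedule, n_win) & clean
    snr_rows = []
    for device, trace in (("inear", in_f.data[0]), ("scalp_T7-T8", t7t8)):
        seg = similarity._clean_concat(trace, in_f.fs, ec_mask, 10.0)
        est = spectral.gabor_spectrogram(seg, in_f.fs,
                                         freqs=np.arange(2.0, 36.0, 0.25))
        ratio, clear = spectral.snr_alpha(est)
        snr_rows.append(
            {
                "device": device,
                "snr_alpha": ratio,
                "snr_alpha_db": spectral.snr_to_db(ratio),
                "clear_peak": clear,
            }
        )

    # --- alpha-band correlation map + permutation inference + FDR
    in_alpha = sync.bandpass_array(in_f.data[0], in_f.fs, 8.0, 12.0,
                                   trans_low=1.0, trans_high=1.0)
    sc_alpha = sc_f.copy()
    sc_alpha.data = sync.bandpass_array(sc_f.data, sc_f.fs, 8.0, 12.0,
                                        trans_low=1.0, trans_high=1.0)
    corr_results, skipped = similarity.alpha_correlation_map(
        in_alpha, sc_alpha, in_f.fs, mask=ec_mask
    )
    pvals = []
    for res in corr_results:
        deriv_trace = sc_alpha.channel(res.label.split("-")[0]) - sc_alpha.channel(
            res.label.split("-")[1]
        )
        perm = inference.permutation_corr_test(
            similarity._clean_concat(in_alpha, in_f.fs, ec_mask, 10.0),
            similarity._clean_concat(deriv_trace, in_f.fs, ec_mask, 10.0),
            fs=in_f.fs,
            n_perm=n_perm,
            seed=seed,
        )
        res.p = perm.p_two_sided
        pvals.append(perm.p_two_sided)
    reject, p_adj = inference.bh_fdr(pvals, q=q)
    for res, rej in zip(corr_results, reject):
        res.q_significant = bool(rej)
    corr_df = pd.DataFrame(
        {
            "derivation": [r.label for r in corr_results],
            "r": [r.r for r in corr_results],
            "best_lag_s": [r.best_lag_s for r in corr_results],
            "agreement": [similarity.classify_agreement(r.r) for r in corr_results],
            "p": [r.p for r in corr_results],
            "p_adj": p_adj,
            "q_significant": [r.q_significant for r in corr_results],
            "n_windows": [r.n_windows for r in corr_results],
        }
    )

    # --- amplitude-ratio slope over clean shared epochs
    p_in = similarity.alpha_power_per_epoch(in_f.data[0], in_f.fs)
    p_sc = similarity.alpha_power_per_epoch(t7t8, sc_f.fs)
    n = min(p_in.size, p_sc.size, clean.size)
    slope, intercept = similarity.amplitude_ratio(
        p_sc[:n][clean[:n]], p_in[:n][clean[:n]]
    )

    report = StudyReport(
        protocol="alpha_test",
        tables={
            "rms_summary": pd.DataFrame(rms_rows),
            "snr_alpha": pd.DataFrame(snr_rows),
            "correlation_map": corr_df,
        },
        metadata={
            "alignment_offset_s": alignment.offset_s,
            "alignment_max_residual_s": alignment.max_abs_residual_s,
            "n_matched_triggers": len(alignment.matched_triggers),
            "skipped_electrodes": skipped,
            "rms_rank_sum_right_p": p_rms,
            "amplitude_ratio_slope": slope,
            "amplitude_ratio_intercept": intercept,
            "n_clean_shared_epochs": int(clean.sum()),
            "n_clean_ec_windows": int(ec_mask.sum()),
            "params": {
                "analysis_fs": ANALYSIS_FS,
                "band": [0.3, 35.0],
                "alpha_band": [8.0, 12.0],
                "epoch_len_s": 10.0,
                "amp_thresh_uV": quality.AMP_THRESH_UV,
                "frac_thresh": quality.FRAC_THRESH,
                "n_perm": n_perm,
                "alpha_level": inference.ALPHA_LEVEL,
                "fdr_q": q,
                "seed": seed,
            },
        },
    )
    if out_dir is not None:
        report.to_dir(out_dir)
    return report


def run_nap_report(
    inear=None,
    scalp=None,
    hypnogram: Hypnogram | str | Path | None = None,
    sim_config: SimConfig | None = None,
    n_perm: int = inference.DEFAULT_N_PERM,
    q: float = 0.05,
    seed: int = 0,
    min_windows: int = 3,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Run the nap pipeline: per-stage RSP (both devices, with per-band
    permutation mean-difference tests under FDR) and per-stage correlations
    against scalp T7-T8."""
    if sim_config is not None:
        session = generate_nap(sim_config)
        rec_in, rec_sc, hyp = session.inear, session.scalp, session.hypnogram
    else:
        if inear is None or scalp is None or hypnogram is None:
            raise ValueError("need sim_config or recordings + hypnogram")
        rec_in, rec_sc = _load_pair(inear, scalp)
        hyp = (
            hypnogram
            if isinstance(hypnogram, Hypnogram)
            else Hypnogram.from_csv(hypnogram)
        )
    n_rec_epochs = int(rec_sc.duration_s // hyp.epoch_len_s)
    if abs(n_rec_epochs - hyp.n_epochs) > 1:
        raise ValueError(
            f"hypnogram has {hyp.n_epochs} epochs but the recording spans "
            f"{n_rec_epochs}; misaligned inputs"
        )
    in_f, sc_f, alignment = _sync_resample_filter(rec_in, rec_sc)

    grid_in = quality.epoch_and_flag(in_f, in_f.labels[0])
    t7t8 = _derivation_recording(sc_f)
    sc_pair = Recording(labels=["T7-T8"], data=t7t8[np.newaxis, :], fs=sc_f.fs)
    grid_sc = quality.epoch_and_flag(sc_pair, "T7-T8")
    clean = quality.combine_masks(grid_in, grid_sc)

    rms_rows = []
    for device, grid in (("inear", grid_in), ("scalp_T7-T8", grid_sc)):
        summary = quality.rms_per_epoch(grid)
        pct_bad, exceeds = quality.bad_data_fraction(grid)
        rms_rows.append(
            {
                "device": device,
                "rms_mean_uV": summary.mean_uV,
                "rms_sd_uV": summary.sd_uV,
                "n_epochs_used": summary.n_epochs_used,
                "bad_data_pct": pct_bad,
                "exceeds_10pct": exceeds,
            }
        )

    # --- per-stage relative band power, both devices
    win_per_epoch = int(round(hyp.epoch_len_s / 10.0))
    stage_of_window = np.array(
        [hyp.stages[min(w // win_per_epoch, hyp.n_epochs - 1)]
         for w in range(clean.size)]
    )
    rsp_rows, band_test_rows = [], []
    observed, untested = hyp.observed_stages(), []
    for stage in observed:
        stage_mask = clean & (stage_of_window == stage)
        if stage_mask.sum() < min_windows:
            untested.append(stage)
            continue
        per_dev = {}
        for device, trace in (("inear", in_f.data[0]), ("scalp", t7t8)):
            bands, rsp_win, _ = spectral.relative_band_power_windows(
                trace, in_f.fs, mask=stage_mask
            )
            per_dev[device] = rsp_win
            mean_rsp = rsp_win.mean(axis=0)
            rsp_rows.append(
                {"stage": stage, "device": device,
                 **{b: float(v) for b, v in zip(bands, mean_rsp)},
                 "n_windows": rsp_win.shape[0]}
            )
        for j, band in enumerate(bands):
            res = inference.permutation_mean_diff_test(
                per_dev["scalp"][:, j], per_dev["inear"][:, j],
                n_perm=n_perm, seed=seed + j,
            )
            band_test_rows.append(
                {"stage": stage, "band": band,
                 "mean_diff_scalp_minus_inear": res.observed_stat,
                 "p": res.p_two_sided}
            )
    band_df = pd.DataFrame(band_test_rows)
    if not band_df.empty:
        reject, p_adj = inference.bh_fdr(band_df["p"].to_numpy(), q=q)
        band_df["p_adj"] = p_adj
        band_df["q_significant"] = reject

    # --- per-stage correlations (broadband, T7-T8)
    stage_results, omitted = similarity.stage_correlations(
        in_f.data[0], t7t8, hyp, in_f.fs, mask=clean
    )
    stage_pvals = []
    for res in stage_results:
        stage_mask = clean & (stage_of_window == res.label)
        if stage_mask.sum() < 2:
            stage_pvals.append(np.nan)
            continue
        perm = inference.permutation_corr_test(
            similarity._clean_concat(in_f.data[0], in_f.fs, stage_mask, 10.0),
            similarity._clean_concat(t7t8, in_f.fs, stage_mask, 10.0),
            fs=in_f.fs, n_perm=n_perm, seed=seed,
        )
        res.p = perm.p_two_sided
        stage_pvals.append(perm.p_two_sided)
    finite = np.isfinite(stage_pvals)
    if finite.any():
        reject_st, p_adj_st = inference.bh_fdr(
            np.asarray(stage_pvals)[finite], q=q
        )
        it = iter(zip(reject_st, p_adj_st))
        adj_full = []
        for ok in finite:
            if ok:
                rej, pa = next(it)
                adj_full.append((bool(rej), float(pa)))
            else:
                adj_full.append((None, np.nan))
    else:
        adj_full = [(None, np.nan)] * len(stage_results)
    for res, (rej, _) in zip(stage_results, adj_full):
        res.q_significant = rej
    stage_df = pd.DataFrame(
        {
            "stage": [r.label for r in stage_results],
            "mean_r": [r.r for r in stage_results],
            "fisher_mean_r": [r.r_fisher_mean for r in stage_results],
            "r_sd": [r.r_dispersion for r in stage_results],
            "agreement": [similarity.classify_agreement(r.r)
                          for r in stage_results],
            "p": stage_pvals,
            "p_adj": [pa for _, pa in adj_full],
            "q_significant": [r.q_significant for r in stage_results],
            "n_windows": [r.n_windows for r in stage_results],
        }
    )

    report = StudyReport(
        protocol="nap",
        tables={
            "rms_summary": pd.DataFrame(rms_rows),
            "rsp_by_stage": pd.DataFrame(rsp_rows),
            "rsp_band_tests": band_df,
            "stage_correlations": stage_df,
        },
        metadata={
            "alignment_offset_s": alignment.offset_s,
            "alignment_max_residual_s": alignment.max_abs_residual_s,
            "stages_observed": observed,
            "stages_not_observed": [
                s for s in ("Wake", "N1", "N2", "N3", "REM") if s not in observed
            ],
            "stages_untested": untested,
            "stages_omitted_no_clean_windows": omitted,
            "params": {
                "analysis_fs": ANALYSIS_FS,
                "band": [0.3, 35.0],
                "epoch_len_s": 10.0,
                "hypnogram_epoch_len_s": hyp.epoch_len_s,
                "amp_thresh_uV": quality.AMP_THRESH_UV,
                "frac_thresh": quality.FRAC_THRESH,
                "n_perm": n_perm,
                "alpha_level": inference.ALPHA_LEVEL,
                "fdr_q": q,
                "min_windows": min_windows,
                "seed": seed,
            },
        },
    )
    if out_dir is not None:
        report.to_dir(out_dir)
    return report
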