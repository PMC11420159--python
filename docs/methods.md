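# Methods

`earqc` quantifies how faithfully a single-channel dry-electrode in-ear EEG
device reproduces what a research-grade wet-electrode scalp system records at
the same time. Because paired human recordings of this kind are rarely
shareable, the package couples the full analysis pipeline to a synthetic
generator of paired sessions with known ground truth, so that every stage is
testable as a parameter-recovery problem.

## The signal model behind the generator

Both devices are assumed to observe a common cortical source through
independent sensor noise. Each oscillatory band is synthesized as
band-limited Gaussian noise (spectral shaping in the frequency domain,
normalized to an exact RMS in μV) plus an optional sinusoidal carrier with a
random phase *and a small random frequency jitter per realization* — two
realizations of "the same" rhythm must be incoherent, which identical-
frequency sinusoids are not. With `C` the common source, `D` an independent
realization with the same spectrum, and

```
g = sqrt(1/ρ − 1)
in-ear            = C + g·D_in
scalp (T7 − T8)   = amp_ratio · (C + g·E),   var(E) = var(C)
```

the Pearson correlation between the devices equals `ρ` at every frequency,
and the least-squares slope of `sqrt(scalp alpha power)` on
`sqrt(in-ear alpha power)` across 10-s epochs equals `amp_ratio` in
expectation (the scalp derivation's noise scales with the derivation, which
keeps both axes' noise floors proportional). Other electrodes couple to the
source with weights `w < 1` but carry full-strength independent noise, so
their derivations correlate as `w / sqrt((1+g²)(w²+g²))` — a topographic
gradient with its maximum at T7-T8, the derivation closest to the ear-canal
sources.

Key generator parameters (all in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_trials`, `trial_len_s` | 10, 30 s | alternating EC/EO trials, always starting eyes-closed |
| `fs_inear`, `fs_scalp` | 250, 2000 Hz | device sampling rates |
| `amp_ratio` | 2.0 | scalp/in-ear amplitude ratio of the shared source |
| `alpha_rms`, `alpha_freq` | 8 μV, 10 Hz | eyes-closed alpha component of the common source |
| `band_noise_sd` | 6 μV | 1/f background per channel over 0.3–35 Hz |
| `rho` | 0.5 | target alpha-band inter-device correlation (T7-T8) |
| `stage_rho` | Wake 0.45 … N3 0.60 | per-stage broadband correlation targets |
| `artifact_rate` | 0.5 /min | transient high-voltage events on the in-ear channel |
| `artifact_amp_factor` | 10 | event peak as a multiple of the clean-signal RMS |
| `contact_loss_prob` | 0.01 /epoch | whole-epoch slow high-amplitude swings |
| `clock_offset_s`, `clock_drift_ppm` | 0.25 s, 20 ppm | in-ear clock behaviour vs the scalp clock |

Nap sessions draw a plausible staging sequence (Wake → N1 → N2 → N3 → N2 →
REM cycles with Poisson-distributed phase durations) and synthesize each
stage run from a band-amplitude template: alpha in Wake, 4–7 Hz theta in
N1/N3, 12–16 Hz spindles in N2, 0.5–2 Hz slow waves in N3 (15 μV — large
enough to dominate delta power, small enough that the scalp derivation stays
inside the ±100 μV artifact bound). Artifacts are placed per 10-s epoch
(Bernoulli with probability `rate/6`, events never straddling epoch
boundaries) so the expected flagged-epoch fraction is exactly
`p_art + p_cl − p_art·p_cl` and can be checked against a binomial bound.

Clocks: the in-ear device starts `clock_offset_s` after the scalp device and
its sample clock runs off by `clock_drift_ppm`; its trace is produced by
sampling the master-timeline signal at the warped times (linear
interpolation, valid because all content is band-limited far below the
2 kHz master rate). Both devices carry the same rectangular 40-ms trigger
pulses on a dedicated channel.

## The analysis pipeline

1. **Synchronization.** Trigger onsets are detected by thresholding the
   absolute trigger trace at 0.5×max with a 200-ms refractory window. The
   inter-device offset is the median of paired trigger-time differences;
   the coarse pairing uses the most supported cluster of pairwise
   differences (ties broken toward the smallest offset), which survives a
   missed leading pulse. A device with no detectable pulses makes the
   session unsyncable and the pipeline aborts with that diagnosis. Residual
   per-pair misalignment after constant-offset removal is reported: 20 ppm
   of drift over an hour spreads differences by 0.072 s, which motivates
   the ±0.1 s lag tolerance used for correlations.
2. **Harmonization.** The scalp stream is polyphase-resampled to 250 Hz;
   both streams get a zero-phase windowed-sinc FIR band-pass, 0.3–35 Hz
   (transition 0.3 Hz at the low edge, 5 Hz at the high edge).
3. **Artifact rule.** Non-overlapping 10-s epochs; an epoch is rejected
   when at least 10% of its samples exceed ±100 μV. "At least" is read
   inclusively (≥); the whole-recording quality verdict ("bad data
   exceeding 10%") is strict (>). For paired statistics the two channels'
   flags are OR-combined so both devices are compared over identical time.
   Rejected epochs are excluded from RMS, SNR, band power and correlations
   alike; artifacts are never corrected.
4. **RMS and bad data.** Per-epoch RMS in μV with mean/SD/range over clean
   epochs; the in-ear vs scalp per-epoch RMS distributions are compared
   with a right-tail Wilcoxon rank-sum test.
5. **Alpha SNR.** A constant-Q Morlet/Gabor spectrogram (7 cycles; the
   lowest-frequency wavelet half-length is marked edge-invalid) is averaged
   over clean eyes-closed data; `SNR(alpha)` = mean power 8–12 Hz divided by
   mean power over 5–35 Hz excluding 7–13 Hz, with bin-weighted means on a
   uniform grid. A ratio above 1.5 marks a clear peak; in decibels the
   package uses the amplitude convention `20·log10(r)`, under which 1.5 ↔
   3.52 dB. The synthetic background is a clean 1/f process without the
   broadband muscle and electrode noise of real recordings, so synthetic
   SNR values run far higher than the 1–3 range typical of real dry-contact
   data; SNR-related checks therefore target the analytic anchor and
   monotonicity in alpha amplitude, not absolute levels.
6. **Relative spectral power.** Per clean 10-s window, a Hann periodogram;
   RSP(band) = ΣPSD(band)/ΣPSD(0.3–35 Hz) averaged over windows. The five
   bands (delta 0.3–4, theta 4–8, alpha 8–12, beta1 12–18, beta2 18–35 Hz)
   use half-open edges with the last band closed, so they partition the
   wide band exactly and RSP sums to 1 by construction.
7. **Correlations.** Pearson correlation maximized over every integer-
   sample lag within ±0.1 s (ties to the smallest |lag|), taking the signed
   r at the maximizing |r|. The alpha map correlates the in-ear channel
   with every contralateral bipolar derivation (left electrode minus its
   right homolog; midline and unpaired electrodes skipped with notice) over
   concatenated clean eyes-closed windows, alpha-filtered. Nap correlations
   use broadband 10-s windows against T7-T8, grouped by the stage of the
   containing 30-s hypnogram epoch; both the plain mean r and the Fisher-z
   mean are reported. |r| maps onto the conventional categories poor <0.2,
   fair 0.2–0.4, moderate 0.4–0.6, substantial 0.6–0.8, almost perfect
   >0.8 (the lower edge of "poor" is sometimes quoted as 0.02 — an
   evident misprint of 0.2, which this package uses). The amplitude
   relation is the OLS slope (intercept included, as a guard against noise
   floors) of sqrt alpha power across paired clean epochs.
8. **Inference.** Correlations are tested with a Pitman-style block
   permutation: one signal fixed, the other's consecutive 10-s blocks
   reordered uniformly (1600 permutations by default, trailing partial
   block dropped, only mutually clean blocks enter), two-sided p from the
   add-one convention (1+k)/(1+N), significance at p < 0.01. Because
   permuting equal-length blocks leaves each series' mean and variance
   unchanged, each permuted r is an O(n_blocks) lookup in the block
   cross-dot matrix — algebraically identical to recomputing Pearson r,
   which a test verifies against naive recomputation. When the whole
   permutation group (or label-assignment space) is small enough to fit in
   the permutation budget, it is enumerated instead and the p-value is
   exact. Group mean differences (e.g. scalp vs in-ear RSP per band) use
   label permutation with the same conventions. Families of tests are
   corrected with Benjamini–Hochberg step-up FDR (q = 0.05 default, applied
   within-session across the derivation map, and across stage×band cells
   in the nap report).

## What passing tests do and do not show

The generator produces stationary Gaussian band-limited processes with
exactly known cross-device structure. Real in-ear EEG adds nonstationary
muscle and movement artifacts with broadband spectra, electrode-impedance
drift, non-Gaussian amplitude distributions, and imperfectly linear
coupling between sites. Recovery of `ρ`, `amp_ratio` and clock parameters
here demonstrates that the *estimators and their implementation* are
unbiased and correctly calibrated at realistic SNR — not that any physical
device meets these numbers. Conversely the type-I calibration of the
permutation tests (white-noise nulls) and the exact-enumeration equivalences
are implementation guarantees that carry over to real data unchanged.

## Numerical and design choices

- Trigger threshold 0.5×max|trace|, 200 ms refractory; offset = median of
  paired differences (robust to one missed pulse).
- Epoch/window timestamps are half-open `[t, t+w)` on the common
  post-alignment timeline, 0-based sample indexing; trailing partial
  epochs are dropped everywhere.
- Upsampling is refused: the fast stream is always brought down to the
  slow one (250 Hz), never the reverse.
- "Sliding windows of 10 s" for RSP are resolved to non-overlapping
  windows, consistent with the 10-s artifact epochs.
- The correlation-recovery study uses standard-length sessions (14 trials,
  420 s) and the concatenated clean-EC estimator: per-10-s-window signed r
  is meaningless for narrowband signals under a ±0.1 s lag search (the
  ±envelope peaks tie in magnitude, so the sign flips at random), while a
  single very long session lets clock drift decorrelate a global-lag
  estimate. Pooling five seeds yields >100 clean windows.
- Problem sizes in the recovery/calibration suite (500 replicates for
  type-I rates, 5×21 eyes-closed windows, 3×150 epochs for the slope,
  20-min naps) were chosen to make Monte-Carlo error small relative to the
  effects under test while keeping the full suite in the minutes range.
- Degenerate inputs fail loudly: zero-variance windows raise, all-flagged
  grids return an explicit "no clean data" status, a flat trigger trace is
  the "missing triggers" diagnosis, and hypnogram/recording length
  mismatches beyond one epoch are errors.

## Known limitations

- No biophysical head model: electrode weights are a plausible gradient,
  not a forward solution; ear-canal geometry is not modeled.
- Artifacts are injected per-epoch for analytic tractability; real
  artifacts cluster in time and straddle epoch boundaries.
- Drift is linear; no mid-recording re-estimation is attempted beyond the
  ±0.1 s lag search (nothing in the pipeline needs it below ~50 ppm·h).
- Sleep staging itself is out of scope; hypnograms are inputs.
- EDF export writes a deliberately small 16-bit subset of the format
  (integer rates, 1-s records) — sufficient for round-tripping sessions,
  not a general-purpose EDF library.
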