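# Methods

## Model and assumptions

`respyre` treats the PPG waveform as a quasi-periodic pulse train whose
timing and amplitude are both modulated by respiration. The estimator uses
the timing route: respiratory sinus arrhythmia (RSA) imprints a spectral
line at the breathing frequency on the sequence of inter-beat (RR)
intervals. The estimate is the frequency of the maximum of a Welch power
spectral density of the RR series, restricted to the physiological band
0.1–0.4 Hz (6–24 breaths/min), times 60.

Assumptions this rests on:

- RSA coupling is present (fractional RR modulation on the order of a few
  percent). Subjects with strongly suppressed RSA (e.g. under certain
  medications) weaken the spectral line.
- The breathing rate is quasi-stationary within one analysis window; the
  windowed design (default 90 s) is the resolution/stationarity trade-off.
- Systolic peaks are detectable after band-pass filtering — heart rates in
  roughly 40–180 bpm and a cardiac fundamental inside the 0.5–3.5 Hz
  cardiac branch.

## Processing chain (per window)

1. **Missing samples** — NaNs are filled: isolated gaps by the mean of the
   two neighbours, runs by linear interpolation between the bounding valid
   samples, edges by nearest-value extension. Naive alternatives
   (`nan_policy="zero"` / `"drop"`) are kept for ablation studies.
2. **ESQI gate** — `E = −Σ x²·ln x²` on the raw-scale window; any sample
   with |x| ≤ 1e−12 makes the 0·ln 0 term undefined and (when gating is
   enabled) the window is skipped. The tolerance exists because
   floating-point underflow of x² produces the same pathology as an exact
   zero. No normalisation is applied before the sum; the statistic is
   intentionally scale-sensitive.
3. **Hampel filter** — sliding window of the sample plus 3 neighbours per
   side; robust σ = 1.4826·MAD; samples deviating from the window median
   by > 3σ are replaced by it. The signal is end-padded with 3 samples
   equal to the overall mean so trailing samples see a full right
   neighbourhood; at the start the window is truncated instead. Detection
   uses the original (not progressively replaced) samples.
4. **Clip repair** — maximal runs of ≥ 3 samples at the window's global
   maximum (1e−9 relative tolerance) are treated as sensor saturation and
   replaced by a cubic spline through 3 anchor samples on each side; a run
   touching a window end is left as-is (one-sided spline extrapolation is
   unstable). Hampel runs first: a surviving spike would otherwise be the
   global maximum and hide genuine saturation plateaus.
5. **Two filter branches** — zero-phase (forward–backward) Butterworth
   band-passes of order 2 per pass: 0.1–0.4 Hz yields the respiratory
   waveform whose amplitude range feeds the post-processing scaling;
   0.5–3.5 Hz yields the cardiac pulse train used for peak detection.
   Zero-phase filtering is essential because RR intervals inherit any
   timing shift. Band-limiting does smooth the fast systolic rise, which
   delays every apex by the same few tens of milliseconds; RR intervals
   are invariant to this uniform delay.
6. **Peak enhancement** — affine rescale onto [l_lt, l_lt + rb] (defaults
   0 and 1024); order-preserving, so it changes no peak location but gives
   every window the same dynamic range for thresholding.
7. **Peak detection** — a moving average (0.75 s span) is elevated by p %
   of the signal's amplitude range; maximal runs above the threshold are
   regions of interest, each contributing one peak at its argmax (ties →
   earliest sample). p is swept over {5, 10, …, 40}; candidates whose mean
   rate falls outside 40–180 bpm are discarded and the remaining candidate
   with the smallest RR standard deviation wins. A window where no
   candidate yields ≥ 2 peaks becomes a skipped estimate.
8. **False-peak rejection** — while any RR interval is shorter than 30 %
   of the current mean RR, the later peak of the first offending pair is
   dropped and intervals (and the mean) are recomputed.
9. **Spectral estimate** — RR values are placed at the beat times that
   close them, cubic-spline resampled onto a uniform 4 Hz grid
   (125 Hz would be meaningless for a beat-indexed sequence; 4 Hz
   comfortably covers the 0.4 Hz band edge), and mean-removed. Welch PSD:
   Hann taper, segments of half the series length, 50 % overlap, FFT
   zero-padded to the full series length with a floor of 256 bins, density
   scaling, mean averaging. The estimate is 60× the frequency of the
   in-band PSD maximum; ties break to the lowest frequency (the
   physiologically slower rate). By construction the raw estimate lies in
   [6, 24] breaths/min.
10. **Post-processing** — multiplicative RIAV correction
    `scale = 1 + gain·(range/ref_range − 1)/window_s` (identity at the
    default gain 0; `calibrate_scaling` fits gain and ref_range by a
    deterministic grid search against reference rates), then a clamp to
    [6, 45] breaths/min. The functional form of the correction is this
    package's own parametric choice: only its inputs (respiratory-band
    amplitude range and window length) are dictated by the design, so a
    calibratable form defaulting to the identity keeps the stage concrete
    without inventing constants. 45 sits above the paediatric upper-normal
    rate of 40 as a safety margin.

Windows are consecutive and non-overlapping from t = 0; a trailing
remainder is discarded. Skipped windows carry a reason
(`esqi-undefined`, detection failure, flat signal, all-missing) and are
excluded from MAE/RMSE. Evaluation pairs each window with the mean of the
reference samples falling inside its span. Best-window selection evaluates
a candidate list and returns the size with minimal MAE, ties to the
smaller (cheaper) window; a single user-entered calibration rate can stand
in for a reference series.

## Synthetic data generator

The generator emulates exactly the couplings the estimator exploits. Beat
times are produced iteratively with interval
`(60/hr)·(1 + fm_depth·sin(2π·f_resp·t))`; each beat renders a skewed
positive pulse (two-sided Gaussian, 0.10 s rise, ~0.35 s width) scaled by
`1 + am_depth·sin(2π·f_resp·t)`. Defaults: fs 125 Hz, heart rate 70 bpm,
fm_depth 0.05, am_depth 0.2, white noise σ 0.05, baseline wander 0.3 at
0.05 Hz, and a DC offset of 2.0 pulse units — real PPG rides on a large
sensor baseline, and the offset matters when judging naive
missing-sample policies (inserting zeros creates large steps only if the
signal does not already sit near zero). Artefacts are layered on
reproducibly from the seed: single-sample spikes of 5–10× the signal
range, NaN dropout runs (default 1 s), and saturation clipping at an
absolute level or at a quantile of the rendered clean signal.

What the generator does **not** emulate: dicrotic-notch pulse morphology,
motion artefacts beyond isolated spikes and slow wander, non-stationary
breathing, and RSA suppression. Passing the synthetic suites therefore
demonstrates correct mechanics and artefact handling, not clinical
accuracy on ICU recordings.

## Numerical choices and degenerate inputs

- Filter padding for the forward–backward pass is capped at 3 cycles of
  the low cut-off to avoid `padlen` errors on short windows.
- A constant window cannot be peak-enhanced (zero range) and becomes a
  skipped estimate, never an exception from `estimate_record`.
- Sampling-rate inference from a time column uses the median step with a
  1 % uniformity check, tolerating up to 5 % glitched timestamps.
- Estimate CSVs are written with 6 decimals; a write/read round trip
  preserves values to 1e−6.
- All randomness (generator, calibration grids) is seed-driven; repeated
  runs are byte-identical.

## Known limitations

- **Dropout runs that span whole beats are not recoverable.** Interpolating
  a 1 s gap restores the waveform scale but cannot re-create missed
  pulses, so the RR series acquires a ~2× outlier interval whose broadband
  leakage can overwhelm the few-percent RSA line. The measured effect is
  documented by the ablation quantities in the acceptance output: on
  dropout-laden records the zero-fill policy can score a lower MAE than
  interpolation, because the step-edge filter ringing incidentally
  produces pseudo-peaks that keep the RR sequence quasi-continuous.
  Principled handling would require an RR-domain gap policy, which is
  outside this pipeline's design.
- The false-peak rule only removes short intervals; missed beats (long
  intervals) pass through.
- The RIAV scaling stage is identity until calibrated; no universal
  constants are claimed.
- Supported inputs are plain CSVs (generic or BIDMC-style paired files);
  there is no waveform-database or EDF reader and no streaming mode.

## Study sizes used in tests and acceptance

The synthetic acceptance suites use 24 records of 180 s each (the 7×3 grid
of 8–22 breaths/min × 55–90 bpm heart rate, plus three extra seeds),
analysed at a 90 s window — two windows per record. The best-window sweep
uses a single 480 s record over the 10–120 s candidate list. These sizes
give stable suite-level MAEs (tens of windows per condition) while keeping
the whole acceptance run in the seconds range.
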