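# Methods

This note documents the scientific model behind `hrvkit`, the default
parameter choices, and the numerical decisions that shape the results.

## Study design

The statistics layer targets a within-subject crossover: every subject
is measured once with an intervention off and once with it on, and each
variable is tested on the paired off − on contrast. The packaged
fixtures (`hrvkit.load_patient_table()`, `hrvkit.load_hrv_table()`)
hold a 22-subject cohort with pain scores and five HRV summary
variables per condition; all cohort-level outputs of the package can be
regenerated from them at runtime.

## Preprocessing

RR tachograms are cleaned in beat domain and then, for the spectral
domains only, converted to a uniformly sampled signal:

1. **Ectopic detection** — beat *i* is flagged when it deviates from the
   median of its 11-beat neighborhood (excluding itself) by more than
   20 % of that median. Edge windows slide inward so every beat is
   compared against 10 neighbors.
2. **Ectopic correction** — flagged beats are replaced by a cubic
   spline through the unflagged (cumulative beat time, RR) points. A
   recording with more than 20 % flagged beats is marked low-quality.
3. **Outlier screening** — corrected intervals beyond mean ± 3 SD are
   flagged and corrected the same way.
4. **Resampling** — cubic-spline interpolation on a uniform 2 Hz grid
   (Nyquist 1 Hz, comfortably above the 0.4 Hz analysis ceiling), with
   `floor(duration × rate)` samples starting at the first beat time.
5. **Detrending** — a wavelet-packet high-pass at 0.0391 Hz: the db4
   packet tree is taken to the depth where terminal-node bandwidth
   falls below the cutoff (level 5 at 2 Hz) and all frequency-ordered
   terminal nodes lying entirely below the cutoff are zeroed. A
   least-squares line is removed first — the slowest trend component,
   which also suppresses wrap-around leakage of the periodized
   transform — and the reconstruction is truncated to the original
   length and de-meaned.

Time-domain and nonlinear metrics use the corrected beat series;
frequency and time–frequency metrics use the detrended tachogram.

**Idempotence caveat.** The detrender is a projection only on dyadic
lengths. A 300 s segment at 2 Hz gives 600 samples, which is not a
multiple of 2⁵, so symmetric padding, truncation and the line removal
each introduce a small boundary residual: applying the detrender twice
changes the signal by ~0.3 % in norm, not zero. The test suite asserts
double-application changes < 1 %.

## Frequency domain

Spectra are autoregressive: Burg's reflection-coefficient recursion
(order 16, via `statsmodels`) fits the AR model and the one-sided
density is evaluated from the transfer function with Parseval scaling,
so the integral over [0, Nyquist] approximates the signal variance.
Band powers are trapezoidal integrals over ULF [0, 0.0033), VLF
[0.0033, 0.04), LF [0.04, 0.15) and HF [0.15, 0.4] Hz (half-open
except the closed HF top edge, so no grid point is double-counted).
Normalized powers nLF and nHF are defined against LF + HF.

**Grid density.** Order-16 AR spectra of weakly noisy modulated
tachograms have peaks narrower than a 1024-point grid on [0, 1] Hz can
represent, which made band integrals grid-dependent (normalized-LF
errors up to 0.18). The default grid is therefore 4096 points
(≈ 0.00024 Hz), where recovery of simulator ground truth is stable to
≈ 0.04. The cost is negligible (≈ 0.15 s for a 19-window spectrogram).

## Time–frequency domain

The detrended tachogram is split into 30 s windows overlapping by 15 s
(19 windows for a 300 s segment); each window is mean-removed and given
its own Burg spectrum. The summary rLF/HF is the arithmetic mean over
windows of the per-window LF/HF ratio (a median variant is
configurable). Unlike the whole-segment LF/HF, rLF/HF weights each
window equally and therefore differs from the ratio of mean powers
whenever the balance varies over time. Values above 1 are read as
sympathetic dominance, below 1 as parasympathetic preeminence.

## Nonlinear domain

- **Poincaré SD1/SD2** — dispersions of the lag-1 return map along its
  minor/major axes. SD1 is the *uncentered* RMS of
  (RR(i+1) − RR(i))/√2, which makes SD1 = RMSSD/√2 an exact identity;
  SD2 is the n−1 sample SD of the major-axis coordinate.
- **Sample entropy** — m = 2, tolerance r = 0.2 × SD, Chebyshev
  matching with templates drawn from the first N − m points at both
  lengths and self-matches excluded; undefined (None) for constant
  series or when no matches exist. The vectorized implementation is
  tested for exact equality against a literal O(n²) reference.
- **DFA** — the mean-centered series is integrated, linearly detrended
  in non-overlapping boxes on a log-spaced integer grid from 4 to 64
  beats, and the scaling exponents are log–log regression slopes: α1
  over box sizes ≤ 13 beats, α2 above, α over the full grid.

## Statistics

- **Wilcoxon signed-rank**: zeros dropped, average ranks for ties,
  statistic V = sum of positive ranks. The p-value is exact when there
  are no ties or zeros and n ≤ 25, otherwise a tie-corrected normal
  approximation with continuity correction — matching mainstream
  statistical software.
- **Paired t** on the raw differences; **routing** by Shapiro–Wilk on
  the differences (α = 0.05) with per-variable overrides to reproduce a
  fixed published assignment (`TABLE_TEST_OVERRIDES`).
- **Descriptives**: quantiles by linear interpolation of order
  statistics at h = (n − 1)p; t-tested variables present mean ± SD,
  signed-rank variables median (IQR).
- **Simes step-up** for optional familywise correction; reports default
  to uncorrected p-values with the Simes column opt-in.
- Unpaired helpers: Mann-Whitney U (exact for small tie-free samples)
  and mean-centered Levene.

## Synthetic ground truth

Recordings are generated with an IPFM model: the instantaneous rate
(1000/mean_ibi)(1 + a_lf sin 2πf_lf t + a_hf sin(2πf_hf t + φ)) is
integrated on a 1 ms grid and a beat is emitted at each integer
crossing; per-beat Gaussian noise, a linear drift and premature-beat
artifacts (a 40 %-early beat plus exactly compensating pause) can be
added. To first order in the depths the normalized LF power is
a_lf²/(a_lf² + a_hf²), giving analytical ground truth. Condition
templates `OFF_STATE` (mean IBI 910 ms, depths 0.050/0.040 → nLF 0.61)
and `ON_STATE` (975 ms, 0.048/0.046 → nLF 0.52) mirror the direction
and size of the crossover effect; `simulate_cohort` adds log-normal
between-subject (8 %) and within-subject (2 %) parameter variability.

**Scope.** The simulator validates band recovery, artifact handling and
test calibration. It does not model respiration dynamics, circadian
nonstationarity or pharmacology, and the first-order fraction formula
is only used at depths ≤ 0.2.

**Calibration at parameter level.** Null type-I calibration (1000
replicate cohorts) runs on the simulator's realized parameters
(`generate_recordings=False`) rather than on 44 000 full signal
pipelines; the paired tests see per-subject values drawn from identical
off/on templates, which is the property being calibrated.

**Recovery regime.** End-to-end recovery tests of nLF against the
first-order formula use per-beat noise of 5 ms — the low-measurement-
noise regime where the formula applies — over a grid of depth pairs;
cohort-emulating defaults keep the noisier 25 ms.

## Problem sizes

Defaults target the 5-minute short-term HRV standard: 300 s segments,
~300–400 beats, 600-sample tachograms. The full test suite runs in
~15 s and the acceptance script in ~6 s on one CPU.
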