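# Methods

This note documents the models, numerical choices, and limitations behind
`ecgid`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from external data.

## Synthetic ECG model

**Morphology.** A subject is a sum of five Gaussian bumps — P, Q, R, S, T —
each with an amplitude (mV), a center offset relative to the R peak
(seconds), and a width (Gaussian sd, seconds), plus first-order R-R
statistics (`rr_mean`, `rr_sd`) and a per-beat multiplicative jitter on
amplitudes and widths. Parameter ranges (see `CohortConfig`) were chosen
once for physiological plausibility of resting adult ECG: R amplitude
0.9–1.6 mV, T 0.25–0.5 mV, P 0.08–0.2 mV, Q/S negative and small, R-R mean
0.7–1.1 s at rest. The constraint R > T > P in amplitude is enforced by
construction because the pipeline's premise is that the two tallest
positive peaks of a cycle are R and then T. P- and T-wave latencies and the
T width are drawn as *fractions* of `rr_mean` (repolarization timing tracks
cycle length), Q and S in absolute seconds.

**Rendering.** A beat drawn at interval `rr` is the morphology time-warped
by `rr / rr_mean`: all centers and widths scale proportionally. A recording
is the superposition of all beats' Gaussians on one time grid (tails spill
smoothly into neighbors; no splice discontinuities), plus additive white
noise, a powerline sinusoid (60 Hz), and a sub-band baseline-wander
sinusoid (0.15 Hz, below the band-pass low cutoff so preprocessing can
remove it). R-R intervals are Normal(`rr_mean`, `rr_sd`) truncated to
0.4–2.0 s by rejection.

Each wave's scaled center is quantized to the integer sample grid at render
time and those integers are the reported ground truth. This makes the
ground truth exact: a fiducial-recovery test measures the detector, not the
renderer's rounding.

**Noise presets.** `wrist` (0.05 mV white, 0.05 mV powerline, 0.30 mV
baseline), `finger` (0.02 / 0.03 / 0.20 — finger contacts gave visibly
cleaner traces in the emulated acquisition), `clean` (none). These are
plausibility choices, not calibrated to any measured cohort.

**What the generator does not emulate.** Ectopic beats, arrhythmia,
motion/contact artifacts, electrode repositioning between sessions,
day-to-day autonomic variation, and the long-tailed inter-subject
similarity structure of real populations. Synthetic subjects are drawn
independently from a broad parameter box and are therefore *easier* to
tell apart than 55 humans: the default-noise cohorts saturate at 100%
identification. Passing the end-to-end tests shows the pipeline is correct
and self-consistent, not that real-cohort accuracy would match.

## Preprocessing

Band-pass 0.3–35 Hz, then subtraction of a global order-6 polynomial
least-squares fit (abscissa mapped to [−1, 1] for conditioning; the fit is
global, not windowed). The band-pass is realized as a **zero-phase DFT band
projection**: the least-squares line is subtracted (the DFT's periodic
extension would otherwise convert a drifting record's endpoint mismatch
into in-band ringing), bins outside [0.3, 35] Hz are zeroed, and the signal
is inverse-transformed. Two properties motivated choosing a projection over
the more conventional forward-backward Butterworth (which remains available
via `FilterConfig(realization="butterworth")`):

- *Zero phase* — shared by both realizations; fiducial timing, which the
  matching stage depends on, is not displaced (verified: per-beat argmax
  moves ≤ 1 sample on clean signals).
- *Idempotence* — the preprocessing operator's contract is that cleaning an
  already-clean signal is a no-op. A projection satisfies this exactly as a
  filter, and to 0.2–0.7% RMS for the full band-pass + detrend composition
  (the residual is the non-commutation of the two stages). An IIR filter
  cannot: its transition band (0.3–0.6 Hz) re-attenuates real signal content
  — R-R-variability sidebands and finite-window leakage — on every pass;
  measured once-vs-twice residuals with the order-4 Butterworth were 1.2–9.6%
  across clean synthetic records.

## Fiducial detection

The emphasis operator is the squared first difference smoothed by a
centered order-5 moving average (edge windows truncated). Regions where the
emphasis exceeds 0.35 of the record's global maximum are QRS candidates;
the global threshold is stable because records are short (10 s). Regions
closer than the 0.25 s refractory period are merged — a QRS fires the
emphasis on *both* of its slopes with a dip at the R peak itself. The R
index is the argmax of the original (not emphasis) signal over the merged
region, then hill-climbed to the adjacent local maximum: when only one
slope clears the threshold, the region starts a few samples past the peak,
and the climb recovers it. Localization on noise-free synthetic data is
exact to ≤ 2 samples for R across resting heart rates (R-R 0.5–1.2 s).

T search: within each R-R window, excluding 0.10 s guard bands after/before
the delimiting R peaks (QRS flanks must not masquerade as T), the T index
is the argmax of the signal; ties break to the earliest index. A cycle with
no interior local maximum (window max at an edge, or an over-short window)
is flagged invalid rather than imputed; invalid cycles carry a sentinel
index and are excluded from every downstream window. Differentiation is the
one-sample first difference; all indices are 0-based.

## Standard frames

Each fiducial-delimited segment is resampled onto 50 points by linear
interpolation at query positions spanning the half-open interval
[start, end): a segment owns its starting fiducial, and concatenated
segments never duplicate the shared boundary sample. R-R and T-T anchored
frames carry two segments per cycle (100 samples), R-T and T-R one
(50 samples). Frames are extracted for every stride-1 window of consecutive
*valid* cycles; windows never span an invalid cycle. No amplitude
normalization is applied — cosine is scale-free by construction, the
distances deliberately are not, and normalizing would erase the distinction.

**Heart-rate invariance.** Under the generator's proportional time-warp,
frames are invariant to the drawn R-R up to interpolation error. The test
harness (`warp_reference_morphology`) re-references a morphology to
`rr_mean` = 1 s and snaps wave-center fractions to a 10 ms lattice so that
renders at R-R 0.6 s and 1.0 s share an exact common warp grid. Measured
frame differences are then < 0.3% of the R amplitude (bound asserted at 2%).
Without the snap, the comparison is dominated by ±0.5-sample rounding of
wave centers onto each render's grid — up to ~5% of R amplitude near the
steep S flank — which is an artifact of comparing two discrete renders,
not a property of the resampling stage under test.

## Matching

The cross-correlation score uses the biased (1/N) mean-removed cross
covariance at lags |k| ≤ T, normalized by `√(f_AA(0)·f_BB(0))` — the square
root is forced by requiring identical signals to score 1. The default lag
bound T = 10 samples: frames are already fiducial-aligned, so only small
residual lags are meaningful; T = 0 reduces the score to the zero-lag
coefficient, which equals the cosine similarity of the mean-subtracted
vectors (asserted numerically). Lags are searched ascending from −T; ties
keep the first maximum. Cosine similarity is implemented on its full
mathematical range [−1, 1]. Identification is the argmax of the oriented
score (distances negated); ties break to the lexicographically lowest
subject id. Zero-norm vectors (cosine) and constant signals (cross
correlation) are rejected as undefined rather than patched.

## Cross-validation protocol

Each repetition assigns every subject's 4 records to 4 folds by an
independent uniform permutation, so each fold holds exactly one record per
subject. Per fold, a subject's template is the mean of its 3 training
record patterns; a record's pattern is the mean of all its stride-1 frame
windows, giving one identification trial per test record. Four repetitions
with fresh partitions are pooled (trial-level pooling, not fold-averaging)
into `I = Σ xᵢ / N`; percentages are rounded half-up to 2 decimals at
report time only, acting on the shortest decimal repr of the float so the
rounding matches the printed value. Records yielding no complete frame
window are dropped from both enrollment and testing with a warning, and
reduce the trial count. The label-permutation control re-labels templates
by a random permutation of subjects; its rate is assessed at the
permutation level (mean over 20 permutations against
s.e. = 1/(n_subjects·√20)), because trials within one permutation are
strongly dependent — the per-permutation rate on separable data is the
fixed-point fraction of the permutation, whose count has sd ≈ 1.

## Problem sizes and determinism

Test cohorts are 10–20 subjects × 4 records × 10 s at 500 Hz; the
cycle-count trend is averaged over 10 partition seeds on one fixed
20-subject cohort, with preprocessing and fiducials computed once per
record and reused across cells. Every stochastic component — morphology
sampling, R-R draws, jitter, noise, fold partitions, label permutations —
derives from explicit integer seeds (numpy `default_rng`), and whole-corpus
generation is a pure function of (config, seed).

## Known limitations

- Closed-set identification only: no verification thresholds, no reject
  option, no ROC/EER analysis.
- The detector assumes R is the tallest and T the second-tallest positive
  peak per cycle; inverted QRS, tall P waves, or severe T flattening would
  break the premise (real cohorts include such subjects).
- Global emphasis threshold assumes short records; long ambulatory traces
  would need an adaptive threshold.
- The proportional time-warp is a simplification: in real hearts the QRS
  duration shortens far less with heart rate than the diastolic interval,
  so real frames are less rate-invariant than synthetic ones.
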