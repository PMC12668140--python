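# Methods

This package reimplements, as tested library code driven entirely by a
synthetic-data generator, the analysis stack used in rodent sleep/anesthesia
neurophysiology: vigilance-state classification from EEG/EMG/accelerometer,
state-conditioned calcium-transient quantification, Markov sleep-dynamics
metrics, subthreshold resonance (ZAP) electrophysiology, and the exact
statistics that summarize them. This note records the models, the defaults
and their units, the numerical choices, and what the synthetic benchmarks do
and do not demonstrate.

## Synthetic recordings (`synthio`)

**Hypnogram model.** Vigilance states (Wake, NREM, REM) follow a bout-level
first-order Markov chain: the next state is drawn from a 3×3 row-stochastic
transition matrix and the bout length (in 2.5 s windows) is geometric with a
per-state mean. Geometric dwell is the discrete memoryless distribution and
is the unique dwell model consistent with a first-order Markov chain at the
window level. Defaults: mean dwell 60 windows (150 s) per state; transition
matrix with zero diagonal (bout-level), W→N 0.95 / W→R 0.05, N→W 0.60 /
N→R 0.40, R→W 0.80 / R→N 0.20 — wake transitions overwhelmingly into NREM,
REM entered only from NREM-adjacent dynamics and usually exiting to wake,
the canonical rodent pattern.

**Signals.** Each of two EEG electrodes receives its own realization of
1/f-shaped Gaussian background (default 10 µV RMS, exponent 1) plus
state-gated band-limited Gaussian noise: delta (0.5–4 Hz) variance
25 µV² in wake and REM vs 250 µV² in NREM (10×), theta (5–9 Hz) variance
16 µV² in wake and NREM vs 80 µV² in REM (5×). A shared common-mode
drift term is added to both electrodes; it is what mean re-referencing
removes. EMG is white noise with per-sample RMS 25 µV in wake vs 5 µV in
sleep (5×), emitted as a differential pair; the 3-axis accelerometer is
white noise at 0.05 g RMS (wake) vs 0.005 g (sleep). All channels are
synthesized at 1 kHz. The 10×/5×/5× contrasts are the stated study
conditions for the staging benchmark; the absolute levels are calibration
choices in a physiologically plausible range (rodent cortical EEG tens of
µV), flagged as such in the config.

Band noise is made by hard spectral masking of white Gaussian noise and the
1/f background by spectral-factor filtering (|amplitude| ∝ f^(−α/2)), both
normalized to target RMS — analytically checkable constructions rather than
fitted AR models.

**Calcium traces.** Transients arrive as an inhomogeneous Poisson process
with per-state rates (default 0.2 / 2.0 / 1.0 events·min⁻¹ in W/N/R,
an NREM-biased profile). Each event adds an amplitude drawn uniformly from
[1.5, 3.0] ΔF/F decaying exponentially (τ = 1 s), sampled at 4 Hz, plus
polynomial drift and white noise (default SD 0.1 ΔF/F). Amplitudes start at
1.5 so ground truth is recoverable above the 1.0/0.8 detection thresholds;
the point of the generator is a known answer, not a hard detection problem.

**Membranes.** The resonant cell is the standard two-variable linearization
of an h-current membrane: C·dv/dt = −g_L·v − w + i(t), τ_w·dw/dt = g_1·v − w,
with closed-form impedance Z(ω) = 1/(g_L + iωC + g_1/(1 + iωτ_w)). Units:
g in nS, C in pF, τ in ms, i in pA, v in mV; |Z| is reported in MΩ.
Integration is exact matrix-exponential (zero-order-hold) stepping, so the
simulated response is limited only by the stimulus sample rate; dt must
resolve both time constants (dt < τ_m/10 and < τ_w/10). Reference
parameters g_L = 5 nS, C = 150 pF (τ_m = 30 ms), g_1 = 10.36 nS,
τ_w = 150 ms put the analytic impedance peak at 4.0 Hz — inside the
high-delta band that marks extratelencephalic-like (ET-like) physiology.
No Hodgkin–Huxley dynamics are modeled; the linear surrogate is exactly
what ZAP analysis assumes.

## Signal conditioning (`sigproc`)

EEG: polyphase anti-aliased decimation 1 kHz → 125 Hz, 4th-order Butterworth
high-pass at 0.5 Hz applied forward–backward (zero phase), per-sample mean
re-reference. EMG: channel difference, zero-phase 4th-order high-pass at
300 Hz. Spectrograms are multitaper: 5 s windows, 2.5 s step, 35 Slepian
tapers. Thirty-five tapers in a 5 s window imply time–bandwidth NW = 18
(K = 2NW − 1), i.e. ±3.6 Hz spectral smoothing — a very heavy setting that
is the protocol default but left configurable. Power is scaled so the
sum over frequency bins equals the windowed signal variance (Parseval),
which makes white-noise flatness and band fractions easy to verify.

Windows are anchored with the first center at window/2 and the start index
of window k is round(k·step·fs), so the nominal 2.5 s grid is preserved
even where step·fs is not an integer (312.5 samples at 125 Hz); partial
trailing windows are dropped. All modalities share this grid, which is what
makes the per-window 8-dim feature vector well defined. Slow-wave activity
(SWA) is the fraction of power in 0.5–4 Hz relative to a total band
defaulting to 0.5–62.5 Hz (high-pass cutoff to the Nyquist of the decimated
record): the quantity is a unitless fraction in [0, 1]. The spectrogram is
computed on the decimated record; computing it on the raw 1 kHz record is a
config switch away but changes only the Nyquist.

Thermal traces take the median of the hottest 1% of pixels per frame and a
5-min moving median (robust to single-frame flat-field artifacts), with
optional baseline normalization to a reference interval.

## Staging (`staging`)

Pooled training-subject spectrogram rows are factorized with rank-6 NMF
(scikit-learn, `nndsvda` init, seeded). Variance captured is defined as
1 − ‖X − WH‖²/‖X − X̄‖² (residual relative to the mean-centered total);
near-constant inputs count as fully captured. Held-out windows are projected
by per-row nonnegative least squares against the frozen basis. The 8-vector
(6 loadings + EMG RMS + accelerometer RMS) is z-scored with training-set
statistics only, class-balanced by seeded downsampling to the rarest class,
and classified by a feedforward network with one hidden layer of 32 ReLU
units trained with L-BFGS. L-BFGS was chosen over SGD/Adam because at 8
input dimensions and ~10⁴ samples it is faster, insensitive to feature
scaling, and deterministic given the seeded initialization; early stopping
heuristics on stochastic solvers proved fragile on small folds.

The persistence filter suppresses any maximal run shorter than 15 windows
(37.5 s at the 2.5 s step) by merging it into the preceding surviving
state; leading short runs merge into the first survivor, and if no run
reaches threshold the longest run wins. The merge direction is a design
choice — the scientific requirement is only that no state survive for less
than the minimum duration — and the filter is idempotent and
label-conservative by construction.

Leave-one-subject-out cross-validation refits the NMF basis,
standardization, balancing, and network on the training subjects of each
fold; nothing derived from the held-out subject enters training. Reported
accuracy is over persistence-filtered held-out windows, aggregated over all
folds.

## Dynamics and physiology metrics (`metrics`, `calcium`, `ephys`)

Bout tables are run-length encodings of hypnograms; transition matrices
count ordered bout pairs (diagonal structurally zero) and row-normalize;
rows without outgoing transitions are flagged undefined rather than zeroed,
and baseline-normalized ratios propagate those flags. Jackknife CIs use
leave-one-subject-out pseudovalues with a t critical value; for the sample
mean this is exactly the classical t-interval (tested as an identity).
Righting-reflex probability uses sliding windows of 10 trials (step 1) with
Clopper–Pearson exact bounds. Temperature deltas are means over a 50 min
window centered 90 min post-injection minus the matching window 24 h later.

ΔF/F is (raw − cubic trend)/mean(raw): dividing by the raw-trace mean keeps
"100% ΔF/F" at its conventional meaning of a transient that doubles
fluorescence. Transients are `find_peaks` maxima with height ≥ 1.0,
prominence ≥ 0.8, separation ≥ 1 s (the higher of two close candidates
survives). The two-photon variant normalizes to an F0 taken from the
longest ≥ 2 s stretch below the trace median — an operationalization of
"inactive period" — and thresholds at mean + 3 SD. The preference index is
S_i = F_i/Σ_j F_j over recorded states (scale-invariant, sums to 1); the
preferred state is the state with most transients, ties broken toward
greater exposure then the fixed order W < N < R; cells with no transients
anywhere are excluded.

ZAP impedance is |FFT(V)|/|FFT(I)| on 0.2–40 Hz, unsmoothed by default
(optional 3-point median smoothing behind a flag); fR = argmax |Z|,
strength = |Z|max/|Z|(0.5 Hz) with linear interpolation at 0.5 Hz, 3 dB
cutoff = first frequency above fR where |Z| ≤ √0.5·|Z|max (band edge if no
crossing). ET-like classification is the strict rule fR > 2 Hz. Input
resistances come from least-squares I–V slopes over hyperpolarizing steps
only (−150…−10 pA), avoiding near-threshold nonlinearity; the steady state
is the final 200 ms of the 1 s step; rebound amplitude is the post-offset
overshoot beyond baseline opposite the step polarity (zero for a passive
membrane), regressed on steady-state potential. Spike threshold is the
first crossing of dV/dt = 20 V/s before the peak; half-width is measured at
half the threshold-to-peak amplitude; SFA is the 2nd/last ISI of the first
train with ≥ 10 spikes.

## Statistics (`stats`)

Pearson chi-square is computed without continuity correction — the printed
2×2 statistic (16.15) only reproduces uncorrected. Fisher's exact two-sided
p uses the point-probability convention (sum of hypergeometric probabilities
≤ that of the observed table, with a 1e−7 relative tolerance for
floating-point ties); the test suite checks it against exact rational
enumeration for every table with total ≤ 30. Binomial quantities are exact
(scipy distributions); Clopper–Pearson endpoints are the defining beta
quantiles. GMM positivity fits two univariate Gaussians by EM initialized
at the 25th/75th intensity percentiles (tol 1e−8, ≤ 500 iterations, seeded);
positives need posterior > 0.9 for the higher-mean component; near-constant
inputs are flagged degenerate and called all-negative. Soma filters apply
inclusive bounds (area 30–1500 px, circularity 0.3–1.7, equivalent diameter
5–40 px) in 2-D and the strict volume < 2000 µm³ rule in 3-D.
Colocalization flags an ROI when its overlap with any partner ROI reaches
25% of its own area (the threshold is a package default).

## Benchmark scales and what they show

The staging benchmark runs 6 synthetic subjects × 2 h (2879 windows each) —
a desk-scale cohort chosen so the full LOSO study completes in a few
minutes on one core — and requires ≥ 93% held-out accuracy under the
10×/5×/5× contrast conditions; typical runs land near 97%. Parameter
recovery is asserted on means across ≥ 10 seeds: transition matrices at
~500 bouts within 0.05 sup-norm, Poisson rates at 60 min exposure within
10% — per-seed bounds at those sample sizes would be dominated by binomial/
Poisson sampling noise (SD ≈ 0.03 per row, ≈ 9% per rate) rather than by
estimator quality.

Passing these benchmarks shows the pipeline is a faithful, well-calibrated
implementation of the analysis on data matching its assumptions. It does
not show field performance on real recordings: the generator has stationary
within-state spectra, no artifacts or electrode drift beyond the modeled
common mode, no state-transition ambiguity, Poisson (non-bursty) calcium
events with indicator-friendly amplitudes, and perfectly linear membranes.
Real-data accuracy claims require real labeled data.

## Known limitations

* The classifier architecture, training details, and the variance-captured
  formula are explicit package choices; other implementations of the same
  workflow may differ in these details.
* The persistence-filter merge direction (into the preceding state) is a
  convention; alternatives (majority vote, bidirectional) differ on toy
  sequences.
* `transition_matrix` reports the W→R cell like any other; on generators
  with zero W→R mass it is structurally zero only in expectation.
* EDF support covers the common 16-bit continuous-recording case (read via
  MNE, minimal writer for fixtures); EDF+ annotations are out of scope.
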