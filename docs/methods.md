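# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `blinkclean`.

## Problem setting

Eye blinks superimpose high-amplitude (up to hundreds of μV), roughly
Gaussian-shaped transients on scalp EEG. The deflection is strongest at the
fronto-polar electrodes (Fp1 sits closest to the eye) and attenuates toward
occipital sites. The package removes these transients from a 16-channel,
512 Hz recording in three ways — a convolutional network, reference-channel
regression, and ICA component rejection — and quantifies the result with five
statistics computed against a known clean signal.

Because no public recording pairs a contaminated EEG with its true clean
counterpart, evaluation (and network training) rests on a synthetic
generator whose outputs follow the amplitude statistics of real
512 Hz N-back-task recordings: per-window standard deviation 5–15 μV,
peak-to-peak 45–100 μV, blink amplitude 0–650 μV, inter-blink interval
0.5–4 s.

## Surrogate EEG generation

Clean EEG is produced one 1-s (512-sample) window at a time:

1. **Reference window.** A 1/f-noise ("pink") window stands in for a real
   EEG fragment: rFFT-space complex-Gaussian coefficients with power ∝ 1/f,
   zero DC, inverted to the time domain and linearly rescaled so that the
   window statistics land inside the std and peak-to-peak ranges. The scale
   factor is drawn uniformly from the interval of factors satisfying both
   ranges at once. A real EEG window can be substituted wherever a
   `ReferenceSpectrum` is accepted.
2. **Spectrum jitter.** The window's DFT coefficients receive i.i.d. uniform
   perturbations in [−2, +2] μV on the real and imaginary part of every
   positive-frequency bin (DC and Nyquist: real part only), mirrored onto
   the negative frequencies so the spectrum stays Hermitian. The inverse
   transform is then real up to numerical noise (< 1e−9 μV residue, checked
   and enforced). Applied to raw DFT coefficients, a ±2 μV jitter perturbs
   each time sample by ~0.07 μV RMS, so a generated window is a close
   sibling of its reference; window-to-window diversity comes from drawing
   a fresh pink reference per window.
3. **Range enforcement.** If the jittered window leaves the std/peak-to-peak
   ranges, the jitter is redrawn (up to 100 attempts) before falling back to
   a linear rescale; the path taken is reported in the bookkeeping dict.
4. **Stitching.** Consecutive windows are concatenated under the constraint
   that the amplitude jump at a junction stays within 7 μV. During recording
   generation the jitter of an incoming window is redrawn while a redraw can
   plausibly close the gap; otherwise the incoming window receives a
   linearly tapered offset — the full correction at its first sample,
   decaying to zero at its last — so the junction bound holds exactly while
   window endpoints and the per-window DC stay essentially untouched. A
   constant vertical offset would satisfy the same bound but chains from
   window to window and gives the clean signal a nonstationary DC
   random-walk that the windowed construction is not meant to have; the
   standalone `stitch_windows` operation (which cannot redraw) still uses
   the plain vertical offset.

Blinks are Gaussian pulses `a·exp(−t²/2σ²)` with peak amplitude `a` uniform
in [0, 650] μV, σ = width/2 with width uniform in [0.2, 0.4] s, and support
truncated at ±3σ (≈1-s visible envelope). Onsets accumulate uniform gaps in
[0.5, 4] s. One blink train is drawn per recording — the subject blinks once,
all electrodes see it — and propagated to channel c as `g_c · blink(t)`.

The default gain topography decays monotonically from front to back:

| electrodes            | gain |
|-----------------------|------|
| Fp1 (reference)       | 1.00 |
| F9                    | 0.85 |
| F3, F4, F7, F8, Fz    | 0.65 |
| C3, C4, Cz            | 0.40 |
| P3, P4, Pz            | 0.25 |
| O1, O2, Oz            | 0.10 |

The exact per-electrode propagation coefficients of any given subject are
unknowable in advance, so each recording jitters the non-reference gains by
±20% (clipped to [0, 0.98] so the reference row always carries the largest
artifact). Contamination is strictly additive: `contaminated = clean +
g ⊗ blink`, and the realized gains and blink events are stored in the
recording metadata, so the exact artifact is always reconstructible.

**What the generator does not emulate:** inter-channel correlation of the
background EEG (channels are independent surrogates), eye movements and
rolls, muscle/cardiac artifacts, line noise, electrode drift and pops, and
non-stationarity of blink shape. Tests passing on this generator therefore
demonstrate correct mechanics and the relative behavior of the three
methods under additive, rank-one blink contamination — not clinical-grade
performance on real recordings.

## The convolutional denoiser

Input is a (512, 2) window: channel 0 the contaminated Fp1 reference,
channel 1 the contaminated target channel; output is the 512-sample clean
target window. Architecture: Conv1D (20 filters, kernel 40, stride 2, same
padding) + ReLU → Conv1D (10 filters, kernel 20, stride 1, same padding) +
ReLU → flatten (2560) → dense (512). No batch normalization. One shared
network serves all electrodes; training examples pool every non-reference
channel. Parameters: ~1.37 M.

Training: Adam (lr 1e−3, β₁ 0.9, β₂ 0.999, ε 1e−7), MSE loss, batch 128,
80/20 train/validation split, 10 epochs by default. The implementation is
pure NumPy: convolutions gather patches with one strided copy per kernel
tap and reduce to a single BLAS matrix product; the backward pass mirrors
this. Float32 arithmetic is used for the network (weights serialize and
round-trip bit-exactly); all stochastic steps come from one seeded
generator, so a fixed seed reproduces the loss history exactly.

Convergence at desk scale: Adam with a fixed learning rate is step-count
limited, so the final loss depends on `windows × epochs / batch`. On a
zero-artifact (identity) task, 3,000 windows × 10 epochs still leave a
residual MSE of tens of μV² out of a ~115 μV² signal variance; reaching
≪1 μV² requires a step budget of the order of the full 70,000-window
schedule. The package's standard desk-scale run — used by the test
battery — is 10,000 windows with the default 10 epochs; the headline
scaled-down comparison additionally uses an abbreviated 5-epoch run.

Whole-recording cleaning splits each non-reference channel into consecutive
1-s windows, pairs each with the synchronous reference window, replaces it
with the network output and reassembles; Fp1 passes through unchanged
(mirroring the regression convention that the reference is a sensor, not a
target). A trailing partial window is zero-padded and the output truncated.
Input windows are fed in raw μV; optional per-window standardization
(`TrainConfig(standardize=True)`) normalizes both input channels and the
target by the target-window statistics, and is off by default.

## Regression baseline

With reference r (Fp1) and target x, both mean-centered,

    cov = rᵀr,    B = rᵀx / cov,    x_clean = x − B·r,

per channel independently, i.e. ordinary least squares onto the reference.
Cleaned channels are returned mean-centered: restoring the raw channel mean
would re-inject the artifact's DC, because blinks are one-sided pulses
whose time average over a recording is several μV times the channel gain.
By construction
the centered cleaned channel is numerically orthogonal to the centered
reference — this is why the cleaned-vs-reference correlation is < 0.001 to
machine precision. The method's irreducible error is −B·(clean reference
EEG): whatever genuine EEG the reference electrode carries is injected,
scaled by B, into every cleaned channel. This makes regression excellent
occipitally (B ≈ 0.1) and poor frontally (B ≈ 0.7).

A constant reference makes cov = 0 and raises a degenerate-input error.

## ICA baseline

The recording is high-pass filtered (zero-phase forward-backward
Butterworth, order 6, cutoff 1 Hz; the effective magnitude response is the
squared analog response), then decomposed with FastICA: mean removal,
whitening onto 15 principal directions (of 16 channels), fixed-point
iteration with the log-cosh contrast, tolerance 1e−4, at most 1,000
iterations, seeded initialization. Non-convergence is carried as a flag on
the model, not an exception. The components most correlated (in absolute
Pearson r) with the reference signal are selected for removal — 2 by
default — as the automatic stand-in for visual component inspection; an
explicit component list can override the selection. Reconstruction zeroes
the selected columns of the mixing matrix, remixes the remaining sources
and restores channel means.

Two reconstruction error floors are inherent: the 16→15 dimensionality
reduction (identical to the rank-15 PCA truncation error, since ICA rotates
inside the PCA subspace), and the removed non-blink component (the blink
subspace is rank one here, so the second removed component is genuine EEG).
Cross-method reports compare every method against the same unfiltered clean
recording, so the ICA rows also absorb the sub-1 Hz content the filter
removed; evaluating ICA against an identically filtered clean signal is
possible by filtering both inputs with `highpass_filter` first.

## Evaluation suite

Per channel and method: C_kk = r(cleaned, clean); C_Fp1 = r(cleaned,
reference); MAPE = mean(|y−ŷ|/|y|) reported as a raw ratio (no ×100);
RMSE in μV; skewness as the bias-uncorrected g₁ = m₃/m₂^{3/2}. Statistics
are computed per 1-s window and averaged across windows; windows on which a
statistic is undefined (constant signal, fully guarded MAPE) are skipped.
MAPE excludes samples with |y| < 1e−3 μV — the printed formula divides by
|y| and near-zero samples would otherwise dominate the mean. Cross-channel
means are plain arithmetic means of the per-channel values; descriptive
tables report standard deviation and peak-to-peak per channel for raw and
cleaned signals.

## Numerical and design choices

* FFT conventions: plain NumPy DFT for the jitter pipeline (Hermitian
  symmetry enforced by mirroring); one-sided amplitude spectra scale
  interior bins by 2/n.
* "Same" padding follows the ceil convention (output length ⌈L/stride⌉,
  left pad = total//2), so conv1 maps 512 → 256.
* Degenerate inputs raise `ValueError` with a description (constant
  reference, constant correlation input, all-guarded MAPE, empty dataset);
  size mismatches raise `ValueError` naming both shapes; a missing channel
  raises `KeyError`.
* Ties in ICA component ranking resolve by stable sort order.
* EDF I/O is 16-bit with the physical range per channel taken from the
  data; quantization error is bounded by range/2¹⁶. Text I/O writes a
  header row of channel names with a leading time column. Every writer
  leaves a JSON sidecar echoing configuration, seed and realized gains.
* Seeds: every stochastic routine takes an explicit NumPy `Generator` (or
  an integer); the package-wide default seed is 20220211.

## Desk-scale problem sizes

The test battery and the acceptance script use: 10,000 training windows
(default 10-epoch schedule for the cross-method battery; a 5-epoch
abbreviation for the headline comparison); 60-s, 16-channel held-out
recordings; 10,000 draws for generator bound audits; ten seeded recordings
for cross-method ordering checks. These sizes are the package's standard
small-scale experiment; the full-scale schedule (70,000 windows, 10
epochs) is the configured default of `generate_dataset` and `TrainConfig`.

## Known limitations

* The propagation-gain topography is a documented stand-in; real subjects
  differ, and absolute error statistics shift with the gains.
* The denoiser is sampling-rate- and montage-specific: a 512-sample window
  at 512 Hz with Fp1 as reference. Other montages require retraining.
* Offline only: cleaning consumes whole windows; no streaming path.
* The ICA component count (15) and removal count (2) are configuration
  values, not adaptively chosen.
* MAPE depends strongly on the small-|y| tail of the clean signal; compare
  MAPE values only between methods evaluated on identical clean references.
* At desk-scale training budgets the network's residual error exceeds
  regression's central-channel injection under the default (monotone,
  central gain 0.40) topography, so the network's central-channel advantage
  holds against ICA but not against regression at that scale; with larger
  reference leakage (real recordings show parietal artifact amplitudes
  rivalling Fp1) and the full training schedule the balance shifts toward
  the network.
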