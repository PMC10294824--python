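# Methods

## Signal model and preprocessing

A recorded heart sound is modelled as `y(n) = (s(n) + a(n)) * h(n)`: cardiac
source `s`, additive background noise `a` (breath, ambient, sensor
friction), stethoscope impulse response `h`, `*` linear convolution.  All
processing happens at 2 kHz.  Preprocessing band-limits to 25–950 Hz with an
order-4 Butterworth filter applied forward–backward (zero phase; the order
is a package choice — standard biosignal practice, stable at these band
edges), smooths with a Savitzky–Golay filter (window 11 samples, polyorder
3; mild smoothing that preserves the S1/S2 transients at 2 kHz), and cuts
non-overlapping 2.5 s segments.  The phrase sometimes used for this band
limit ("resampling from 25 to 950 Hz") is read as band-pass filtering, its
only physically coherent meaning; true sample-rate conversion is a separate
polyphase resampler applied first when input rates differ.

Segmentation does not attempt cardiac-cycle detection, which no part of the
processing chain defines.  Two alignment modes are exposed: `none` (fixed
stride from sample 0, the default) and `energy_peak` (first segment starts
at the first short-time-energy peak, a documented stand-in for "start of the
cardiac cycle").

## Features

Segments are framed with a periodic Hanning window (240 samples, hop 60),
zero-padded to a 512-point FFT, and turned into a one-sided periodogram
|FFT|² (no 1/N normalisation: any global scale is a constant log offset and
is removed by the per-map standardisation below).  A bank of 128 triangular
filters with centres equally spaced on the Mel scale
(`mel = 2595·log10(1 + f/700)`) between 25 and 950 Hz — the Butterworth
passband — produces the MelSpectrum; its elementwise natural log (floored at
`eps = 1e-10` × map maximum, keeping silent bands finite without distorting
the dynamic range) is the Log-MelSpectrum.

A 2.5 s segment yields 80 frames but the classifier takes 128×128 inputs,
a mismatch the processing description leaves open; the default policy
linearly interpolates the time axis to 128 columns (preserving global
temporal structure), with right-padding kept as an alternative.  Last, each
map is standardised to zero mean and unit variance.  Standardisation is a
package decision: raw Mel (power) and log-Mel (log-power) magnitudes differ
by orders of magnitude, and a fair comparison of the two *representations*
requires matched input scales.  Note that per-map standardisation removes a
global offset but not the per-band structure of a channel, so it does not
neutralise the log-domain advantage being tested.

### The additive-shift property

For an LTI channel `h`, `log mel(s*h) − log mel(s)` should be constant over
frames in each band (≈ `log|H_m|²`), while `mel(s*h) − mel(s)` is not for a
non-stationary source.  The property is verified with a murmur-bearing
clean source (broadband excitation keeps every Mel band away from the
leakage floor; with a tonal-only source, bands between harmonics are
dominated by window-sidelobe leakage, which does not follow the per-band
multiplicative model) and a first-order channel `h[n] = 0.25·0.7ⁿ`
(16 taps) whose gain is bounded away from 1 so no band's shift crosses
zero.  Frames are kept per band when the clean band energy is ≥ 5% of that
band's maximum; the first/last two frames (convolution transients) are
dropped.  Measured: median relative SD of the log-Mel shift ≈ 0.007 (well
under the 0.10 bound asserted), vs ≈ 0.8 for the Mel difference.

## Synthetic acquisition simulator

Nothing in the pipeline prescribes functional forms for `s`, `a`, `h`; the
simulator's forms are package choices, made smooth and band-limited so the
log-domain argument applies to good approximation, and every choice is
seeded and configurable.

- **Source**: cycles at a jittered heart rate (default jitter 3%); S1/S2 as
  Gaussian-enveloped tones (defaults: S1 40–70 Hz, S2 60–100 Hz, width
  ~45 ms, S2 amplitude 0.8 of S1, ±5% amplitude jitter); abnormal records
  add a systolic murmur — band-limited (150–400 Hz) noise, Tukey-windowed
  between S1 and S2, amplitude 0.25–0.45 of the S1 peak.  These place the
  murmur where the S1/S2 spectra are weak, so a band-power threshold
  separates the clean classes with accuracy > 0.95 (verified): the
  classification task is learnable by construction.
- **Noise**: white, pink (default; ambient/body noise is low-frequency
  heavy) or band-limited, scaled to an exact target SNR against the clean
  source (default 15 dB — audible but not overwhelming).
- **Channels**: one per domain; linear-phase FIR (65 taps) fit to a smooth
  log-linear spectral tilt across 25–950 Hz plus a mild random resonance.
  The first channel is near-flat; the rest alternate ±6, ±10, … dB tilts
  with random overall gain (±3 dB), giving pairwise magnitude differences
  > 1 dB — devices that audibly differ, as mixed-equipment corpora do.
- **Dataset**: per-domain record counts default to the six-domain reference
  corpus proportions (66% in domain "e", ~3.9:1 normal:abnormal overall),
  scaled by a single factor.  Every record derives its own random stream
  from the dataset seed, so generation is byte-reproducible.

## Classifier

The modified VGG16: seven 3×3 same-padded convolutions in three blocks,
each block followed by 2×2 max pooling (spatial trace 128→64→32→16), then
four fully-connected layers ending in a 2-way softmax.  The census and
trace are validated structurally; channel widths are configurable.  Default
widths are (32,32)/(64,64)/(128,128,128) with FC (256,128,64,2) — VGG-style
doubling scaled to a single-channel 128×128 input.  Desk-scale experiments
use (4,4)/(8,8)/(16,16,16) with FC (64,32,16,2): the same census at a size
one CPU trains in seconds per epoch, sufficient for the band-pattern
discrimination the simulator poses.

Weights are Kaiming-initialised (variance 2/fan-in, suited to ReLU);
training is Adam on cross-entropy.  Reference hyper-parameters (learning
rate 1e-4, batch 160) are the config defaults; desk-scale runs use lr 1e-3,
batch 32, 6 epochs, matched to the reduced network and dataset.  An
optional steps-per-epoch cap is exposed (some training recipes count epochs
in fixed step blocks); the default is a full pass.

The 20% validation split is stratified by label and made at the *record*
level before oversampling, so no recording's segments straddle the split
and no duplicated minority sample leaks across it.  Oversampling duplicates
minority-class entries (with replacement, seeded) on the training portion
only.  The best-validation-epoch parameters are kept for testing.

The network is a self-contained numpy implementation (convolutions
JIT-compiled with numba); with fixed seeds, initialisation, splits,
shuffling and updates are bit-reproducible on a fixed machine.

## Evaluation protocol

Abnormal is the positive class: `Se = TP/(TP+FN)`, `Sp = TN/(TN+FP)`,
`MAcc = (Se+Sp)/2`.  The LODO protocol holds out each minor domain in turn
(five folds over a,b,c,d,f) while the dominant domain "e" stays in every
training set — it is too large to hold out.  Validation accuracies are
summarised as mean ± *population* SD (dividing by n, which is what
reproduces the reference summary of five fold accuracies exactly).
Reported display rounding is half-up to 4 decimals (fractions) or 2
decimals (percent).  Metrics are computed at segment level by default;
recording-level majority vote (ties to abnormal, the safer clinical call)
is reported alongside.

The desk-scale experiment: ~200 records (scale 1/16, 3 s each → one 2.5 s
segment per record), six domains, both flavors, three seeds — 30 trainings,
about ten minutes on one CPU.  At these settings mean cross-domain MAcc is
1.00 for Log-Mel vs 0.93 for Mel; the Mel deficit concentrates in the
strongly tilted domains, as the theory predicts.

## What the simulator does and does not show

The simulator reproduces the *structure* that motivates the protocol —
unequal domains, class imbalance, per-domain coloration, additive noise —
not the physiology of real PCGs (no respiration modulation, no ECG-coupled
timing, no pathology taxonomy beyond binary murmur presence, and synthetic
channels emulate only the existence of device differences, not any specific
hardware).  Passing the desk-scale experiment shows the pipeline is
correct and that the log-domain advantage materialises under controlled
domain shift; it does not certify clinical performance on real recordings.

## Numerical choices and degenerate inputs

- Band edges must satisfy 0 < low < high < Nyquist; violation raises.
- Recordings shorter than one segment yield an empty segment list (logged,
  not an error); frames shorter than one window raise.
- Log flooring `eps` is relative to the map maximum (absolute floor 1e-300).
- Max-pool backward routes gradient to the first maximal element of each
  2×2 cell (deterministic tie-break).
- A constant feature map standardises to all zeros (zero variance guard).
- Filterbank rows may warn when more filters are requested than FFT bins
  can resolve; columns-sum-to-one normalisation is available for
  energy-conservation checks (default filters peak at 1, unnormalised).
- Convolution output in the simulator is truncated to the input length
  (causal start), keeping segment arithmetic exact.
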