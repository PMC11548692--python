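# Methods

This note documents the models and procedures implemented in `cardiocouple`,
the parameters that matter, and the choices made where the design was open.
No number below is asserted that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and preprocessing

Inputs are paired single-channel ECG and PCG traces sampled at `fs` (default
1000 Hz), one pair per subject, with a binary label (1 = CAD by angiography,
0 = non-CAD). Denoising follows standard practice for these signals:

- ECG: 4th-order Butterworth band-pass 0.5–60 Hz (removes baseline wander and
  EMG noise while keeping PQRST morphology);
- PCG: 4th-order Butterworth high-pass at 20 Hz (removes respiratory and
  motion rumble; S1/S2 and murmurs live above it);
- both: IIR notch at the mains frequency (default 50 Hz, Q = 30).

All filters are applied forward-backward (`sosfiltfilt`/`filtfilt`), so the
effective attenuation is squared and the phase response is exactly zero —
a symmetric pulse keeps its peak sample. Filter order and phase handling are
not dictated by the modelling problem; order 4 zero-phase is the package's
choice and is what the frequency-response tests pin down (unity ±1 dB in the
passband, ≥20 dB in the stop bands).

Records are denoised **before** segmentation (so filter transients fall at
record edges, not window edges), cropped into 10-s windows (configurable
overlap; 0 by default, 50 % available for augmenting a minority class), and
each window is z-scored with the population (1/N) standard deviation, which
makes the unit-variance invariant exact.

## ECG–PCG coupling signal

Cardiac electrical activity precedes and drives mechanical activity, so the
PCG segment `y` is modelled as the ECG segment `x` driving an LTI
electromechanical system with impulse response `h`: `y = x * h`. With `x`
padded by N−1 zeros the linear convolution becomes circular at length
L = 2N−1 and the system matrix is circulant, `X[i,j] = x_pad[(i−j) mod L]`.
Circulant matrices are diagonalized by the DFT, so the Tikhonov-regularized
least-squares solution

    min ‖X h − y‖² + ε²‖h‖²,   ε = reg_lambda · max_f |X(f)|

has the closed form `H(f) = Y(f)·conj(X(f)) / (|X(f)|² + ε²)`, computed in
O(L log L). A dense solver (explicit circulant matrix, normal equations)
is retained for L ≤ 4096 and used as the oracle in tests; the two agree to
machine precision on well-conditioned instances.

Choices that the problem statement leaves open:

- **Regularization.** A z-scored ECG has an exact DC spectral zero (its
  samples sum to zero), so unregularized division is ill-posed on real
  inputs. Default `reg_lambda = 1e-3` (relative to the spectral maximum);
  `reg_lambda = 0` is allowed and raises a clear error when the spectrum has
  a near-zero (below 1e-12 of the maximum).
- **Solution length.** The model is solved in the length-L space and the
  first N samples are reported as the coupling signal (the physically
  meaningful response window); the full-length solution remains available
  (`deconvolve_full`).
- **Target preparation.** The length-N PCG segment is right-padded with
  zeros to length 2N−1. This is exact whenever the effective coupling
  response is short relative to the window (the planted-kernel test
  constructs exactly this situation and recovers the kernel with
  Pearson r > 0.99).
- The coupling signal is re-z-scored before imaging so the three modalities
  are on a common scale.

## Modified recurrence plots

Each channel is delay-embedded (`X(i) = [x_i, x_{i+τ}, …, x_{i+(m−1)τ}]`) and
the matrix of pairwise Euclidean distances is rendered as an image. The
classic recurrence plot thresholds these distances
(`R_ij = Θ(ε − ‖X_i − X_j‖)`, with Θ(0) = 1); the modified plot skips the
threshold and maps raw distances through a luminance-monotone color scale
(darkest = coincident, brightest = the segment's largest distance). Defaults
m = τ = 1: at that setting the MRP is exactly the |x_i − x_j| matrix, and the
class-relevant information is the amplitude micro-structure of the signal.

Practical choices:

- **Decimation.** A 10-s, 1000-Hz segment would give a 10⁴×10⁴ distance
  matrix; channels are first shortened to `target_len` samples (default
  1000; 500 in the desk profile). The default method is **uniform stride
  subsampling**, not anti-aliased resampling: the distance matrix sees only
  sample amplitudes, and an anti-aliasing low-pass at the decimated Nyquist
  (25 Hz at target_len 500) would erase exactly the broadband content —
  S1/S2 bursts and 150–400 Hz murmurs — that distinguishes the classes. In a
  direct measurement, anti-aliased decimation left the PCG modality at
  chance while subsampling preserved its class signal. Anti-aliased
  `resample` remains available for smooth narrow-band channels.
- **Normalization.** Distances are min–max normalized per image (an
  all-equal matrix maps to 0); this makes images comparable across subjects
  with different amplitude scales and is invariant to affine rescaling of
  the input.
- **Color map.** Grayscale replicated to 3 channels — only luminance
  monotonicity is meaningful; any perceptually monotone map would do.
- **Resize.** The distance image is resized to 224×224 bilinearly and
  clipped to [0, 1].

## Parallel CNN deep coding

Each modality has an independent branch: 13 conv layers (3×3, stride 1,
spatial-size-preserving zero padding, ReLU) in five sections of
(2×64, 2×128, 3×256, 3×512, 3×512) kernels, each section closed by a 2×2
max-pool, so 224 → 112 → 56 → 28 → 14 → 7. The final 7×7×512 map is
flattened (25 088 values) and passed through one ReLU dense projection to the
2000-d deep code that the autoencoder consumes; the projection layer is the
package's bridge between the flattened map and the fixed code width. Branch
codes concatenate in the fixed order (ecg, pcg, coupling).

The implementation is NumPy end to end (im2col convolution, explicit
backward pass), which makes the forward operators directly checkable against
six-loop oracles — the tests do exactly that on small instances.

Three weight modes exist:

- `random` — seeded He-uniform initialization, no training. Fixed random
  convolutional features are a standard strong baseline for texture images,
  are trivially leakage-free, and are the desk profile's default: they make
  the full benchmark reproducible in minutes on one CPU.
- `trained` — per-branch supervised training with a temporary head (global
  average pool → linear → 2 classes, cross-entropy, seeded mini-batch SGD),
  head discarded after fitting. When used inside the pipeline the branches
  are retrained per cross-validation fold on that fold's training subjects
  only, and all images are re-encoded with that fold's weights.
- `pretrained` — weights loaded from a local checkpoint (.npz + JSON spec).

Conv weights use He-uniform initialization (bound √(6/fan_in)): plain
fan-in scaling attenuates activations to ~0 through a 13-layer ReLU stack.

## Autoencoder compression

One symmetric fully connected autoencoder per modality:
2000-1000-400-1000-2000 (ReLU hidden layers, linear output — the codes are
unbounded, so a bounded output activation would be mis-specified). Training
minimizes the squared reconstruction error ‖x − x′‖² by seeded mini-batch
stochastic gradient descent with classical momentum 0.9, learning rate
0.001, batch 32, 1000 epochs at full scale. "SGD" is implemented with
momentum because that is the conventional setting in the VGG-lineage
literature this network follows, and because cold-start momentum-free SGD at
lr 0.001 provably stalls an order of magnitude above the PCA reconstruction
floor within any reasonable epoch budget — the loss-trajectory test pins the
implemented behavior (20-epoch moving average non-increasing).

Deep codes are standardized (per dimension, statistics fitted on the
training fold) before autoencoding; the same statistics transform evaluation
rows. Autoencoders are always fitted on training-fold rows only — the
per-fold compressor inside the cross-validation loop enforces this
structurally, and the leakage audit verifies it bit-for-bit.

## Feature selection and classification

Per cross-validation fold, on training rows only: standardize → SVM-RFE rank
(linear SVC, importance = squared weight, step 1 by default) → choose the
feature count k by inner 3-fold accuracy over a schedule (dense for k ≤ 20,
strided above; smallest k wins ties) → grid-search an SVM over 18 linear
configurations (C = 2⁻⁴…2¹³) and 18×14 RBF configurations (γ = 2⁻⁷…2⁶),
270 total, by inner 3-fold accuracy with ties broken toward smaller C and
the linear kernel → refit on the full training fold → evaluate on the
held-out fold.

Folds are stratified at the **subject** level: all segments of a subject
share a fold, so segment-level evaluation never sees a training identity.
Metrics are ACC = (tp+tn)/total, SEN = tp/(tp+fn), SPE = tn/(tn+fp),
F1 = 2tp/(2tp+fp+fn), each ×100; a zero-denominator metric is reported as
undefined (None), never as 0. Evaluation is per segment; the fold report
records the selected k, feature set, hyperparameters, and scaler state so
the leakage audit can compare trained state across runs.

## Feature statistics

Per-feature group comparison uses a normality gate: each group is tested
against a normal with its sample mean/sd by the Kolmogorov–Smirnov
statistic; if both groups pass, a two-sample t-test, otherwise Mann–Whitney
U (two-sided). Raw p < 0.05 marks significance — no multiple-testing
correction by default, matching the single-feature screening convention; a
Benjamini–Hochberg option exists. The KS gate with estimated parameters is
anticonservative; it is kept deliberately, and the type-I error of the
*combined* procedure is what the test suite checks (empirically within the
binomial band [0.02, 0.09] at α = 0.05 over 500 null features). Correlation
heat maps use Pearson coefficients; zero-variance features are NaN-masked.
The pipeline's `featurestats` stage is descriptive (its autoencoders are
fitted on all segments) and is not part of the classification path.

## Synthetic data generator

The generator emulates the features of real paired recordings that the
method exploits, with analytic control so tests have exact oracles:

- **ECG**: Gaussian-bump P, Q, R, S, T waves per beat at jittered RR
  intervals (per-subject heart rate ~ N(72, 8) bpm, clipped to 40–150;
  beat-to-beat RR jitter 3 %). The CAD class adds a flat ST-segment
  elevation of `st_shift` × (clean-signal sd) between S and T (60–240 ms
  after R) — the boxcar form makes the ST-mean test exact.
- **PCG**: a damped 50 Hz S1 oscillation at each R peak, a 90 Hz S2 burst at
  R + 0.35·RR, and — CAD class only — Hann-windowed 150–400 Hz band-passed
  noise of amplitude `murmur_gain` filling diastole (S2 end to next S1).
- Both channels add white noise (sd 0.05) and a 50 Hz mains sinusoid
  (amplitude 0.1) so the notch filter has real work end to end.

Defaults: 20 subjects per class, 300-s records (the clinical protocol's
5 minutes), fs 1000 Hz, `st_shift` 2.0, `murmur_gain` 1.5. Everything is
deterministic under one seed; two runs write byte-identical files.

What the generator does **not** emulate: real PQRST variability and
pathology other than ST shift, respiratory modulation, sensor artifacts,
inter-beat morphology drift, and the partial overlap of class distributions
seen clinically. Passing the synthetic benchmark therefore demonstrates that
the pipeline's plumbing, leakage discipline and information routing are
correct — not that clinical-grade accuracy transfers to real recordings.

## Scale profiles and problem sizes

The `full` profile keeps the clinical-scale dimensions (full-width CNN,
2000-d codes, 400-d latents, 1200-d fusion, autoencoder 1000 epochs). The
`desk` profile — used by the tests and the acceptance script — scales the
method proportionally for a single CPU: CNN width ÷ 8, 250-d codes,
autoencoder 250-125-50-125-250 (50-d latents, 150-d fusion, 200 epochs),
MRP target_len 500, 30-s records (3 segments/subject), encoder mode
`random`. The scaling is recorded in the artifacts' metadata. Per-fold
`trained` encoding at full 224-px scale is implemented and unit-tested at
small image sizes; the desk benchmark uses `random` mode as its default
encoder setting.

## Numerical details and degenerate inputs

- z-score of a constant signal, all-zero deconvolution input, single-class
  training sets, asymmetric autoencoder widths, odd pooling dimensions, and
  empty modality subsets all raise explicit errors.
- Min–max of an all-equal distance matrix maps to 0 (darkest image).
- Grid-search ties: smaller C, then linear kernel (enforced by evaluation
  order plus strict improvement).
- Autoencoder divergence (non-finite loss) raises rather than returning
  garbage weights.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; two identical runs produce identical reports.

## Pipeline caching

Each stage writes a JSON manifest with its parameter hash, upstream manifest
hashes and SHA-256 digests of its outputs. A stage re-runs iff its
parameters, upstream chain or output digests changed — rerunning an
unchanged pipeline performs no recomputation, and corrupting one
intermediate recomputes exactly the downstream stages. Manifests form the
provenance chain from the final report back to the raw signals.

## Known limitations

- The benchmark's absolute accuracy depends on the synthetic generator's
  separability settings; it validates mechanism, not clinical performance.
- `random`-mode deep features are weaker than trained features would be at
  full scale; the desk profile trades that for tractable, fully seeded runs.
- The coupling model assumes a per-segment LTI system; real electromechanical
  coupling is nonstationary within segments.
- KS-gated test routing is anticonservative by construction (see above).
- The stride-subsampling decimation aliases high-frequency content into the
  retained samples; this is intentional for amplitude-structure imaging but
  means the decimated series is not a spectral representation of the signal.
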