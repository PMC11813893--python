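# Methods

This note records the modelling choices behind the package, the defaults and
why they were picked, and what the synthetic evaluation can and cannot show.

## Signal model and the synthetic generator

The generator emulates the statistical structure a murmur detector relies on,
not cardiac hemodynamics. A record of `duration_s` seconds (default 10 s, a
typical auscultation clip) at `sample_rate` 4 kHz (a common electronic-
stethoscope rate) contains one cardiac cycle per beat at `heart_rate_bpm`
(default 70). Each cycle holds two Gaussian-enveloped sinusoid bursts: S1
(50 Hz fundamental, unit peak) at the cycle start and S2 (45 Hz, peak 0.8) at
`s2_offset_frac` = 0.35 of the cycle. The envelope std is 25 ms, giving
bursts of roughly 100–150 ms — the right order for heart sounds. Optional
per-cycle timing jitter (`cycle_jitter_frac`, std as a fraction of the
period) prevents pathological periodicity.

The anomaly class adds band-limited Gaussian noise (4th-order Butterworth
band-pass, zero-phase) to every systolic S1→S2 interval, scaled so its RMS is
`murmur_rel_amplitude` times the S1 peak. The default band (25, 60) Hz is
deliberate: the denoising stage keeps only the deepest approximation band of
a 5-level decomposition (0–62.5 Hz at 4 kHz), so a murmur placed above that
band would be erased by the pipeline's own preprocessing and the evaluation
would measure nothing. Records are peak-normalized to [−1, 1] (the decoder
ends in Tanh). One consequence, verified in the test suite: when a strong
murmur sets the record's peak, normalization shrinks the heart sounds, so
absolute band-energy comparisons between records are only meaningful at the
pre-normalization scale (`synthesize_unnormalized`).

Ambient noise is i.i.d. Gaussian with std `sigma` in normalized units, added
to the *raw* records before any denoising or windowing, and never
re-normalized — re-scaling would silently change the noise level the
robustness sweep controls.

What the generator does **not** emulate: respiration and friction artefacts,
baseline wander, heart-rate variability beyond cycle jitter, diastolic or
continuous murmurs, sensor transfer functions, and inter-patient variation.
A passing synthetic study shows the pipeline's machinery is sound and its
components rank as expected under controlled conditions; it does not certify
clinical performance.

## Wavelet-reconstruction denoising

Multilevel decimated DWT with the orthogonal `sym4` wavelet, 5 levels,
symmetric boundary extension; every detail vector is zeroed unconditionally
(no thresholding) and the signal is resynthesised and cropped to the stored
original length (the decimated transform is not length-preserving). The
operation is linear — a projection onto the approximation subspace — hence
homogeneous and energy non-increasing; the test oracles use periodization
extension, under which orthogonality is exact, to check energy conservation
and approximate idempotence (tolerance 1e−6, boundary effects only).

## Convolutional autoencoder

Architecture (lengths for the default 20 000-sample window):

| stage | op | channels | output |
|---|---|---|---|
| conv1 | k=16, s=8, p=4 | 1 → i | 2500 |
| conv2 | k=16, s=8, p=4 | i → j | 312 |
| deconv1 | transposed, output-padding derived | j → i | 2500 |
| deconv2 | transposed, + Tanh | i → 1 | 20000 |

Batch norm and Leaky ReLU (slope 0.2) follow each encoder conv; batch norm
and ReLU follow deconv1. Transposed-conv output padding is computed from the
encoder lengths so decoding restores the input length exactly for odd and
even lengths. The latent fed to the one-class SVM is the final feature maps
mean-pooled to `pooled_steps` = 4 time steps and flattened (length 4·j): a raw
flatten would hand the kernel machine 10⁴–10⁵ dimensions, while 4 pooled
steps keep the coarse temporal energy profile (enough to distinguish a
noise-filled systole) at kernel-friendly dimensionality. The decoder always
consumes the un-pooled maps.

Training: Adam (lr 1e−3), batch 32, mean-per-element L1 loss (so the loss is
in amplitude units and a constant offset c costs exactly |c|), seeded
initialization (uniform fan-in) and shuffling; batch-norm running statistics
are frozen in eval mode for all scoring so training statistics never leak
into inference. The implementation is plain numpy with explicit
backpropagation, verified against central finite differences to 1e−5; the
arithmetic runs in float32 (double precision buys nothing here and halves
throughput). Everything is bit-reproducible from the config seed.

The default channel pair is (8, 16) — mid-grid, and sufficient for the
synthetic study; the six-pair grid (2,4)…(64,128) is available for searches.

## One-class SVM

The control factor C ∈ (0, 1] multiplies the slack term as 1/(C·N), which is
exactly the ν-formulation's 1/(ν·N); C is therefore identified with ν and
passed as such to the libsvm solver (scikit-learn, precomputed Gram). The
dual weights returned by libsvm sum to ν·N and are rescaled to Σwᵢ = 1 so
the exposed model matches the textbook dual (0 ≤ αᵢ ≤ 1/(νN), Σα = 1)
directly — the test suite checks both the dual objective (1e−6) and
predictions against a brute-force SLSQP solution of that program.

Kernels follow the four-family parameterization: linear h·h′; polynomial
(a₁h·h′ + b₁)^d with a₁ = b₁ = 1, d = 3; RBF exp(−‖h−h′‖²/2σ²) with σ
defaulting to the median pairwise training distance (the standard heuristic;
latent scales vary across folds); sigmoid tanh(a₂h·h′ + b₂) with
a₂ = 1/dim, b₂ = 0. A decision value of exactly zero predicts normal. A
single-point training set is solved in closed form (α = 1, ρ = k(h,h)),
since the solver's finite tolerance can misclassify the boundary case.

TF24 feature vectors are z-scored per feature with training-fold statistics
before the kernel machine (kernel methods are scale-sensitive and the 24
descriptors span orders of magnitude); raw windows are polyphase-resampled to
a fixed 512-sample vector.

## Windowing and cross-validation

Windows are 10 frames of 0.5 s (5 s of audio) advanced by 5 frames; a window
is abnormal iff it overlaps any murmur interval by a positive duration (the
simplest rule that is monotone in murmur exposure). Folds are assigned at the
*record* level: overlapping windows of one record are near-duplicates, and
splitting them across train and test would leak. Training folds contain
normal samples only — the semi-supervised contract — and the guard is
enforced with errors in both `train_cae` and `ocsvm.fit`. Each repeat
reshuffles records with a seed derived from the master seed.

AUC pools all fold × repeat values per configuration; summaries report mean,
sample standard deviation (N−1) and variance = sd², with half-up rounding
applied only at report time (4 decimals for statistics, as-printed precision
for percent comparisons).

## Study sizes and numerical conventions

The packaged end-to-end study uses 100 normal / 20 abnormal records (strong
imbalance, murmur relative amplitude 0.8), 5 folds × 2 repeats, 20 training
epochs, and noise sigmas {0, 0.25, 0.5}, comparing the raw-window group
against the full pipeline; the full 6-group, 4-sigma, 10-repeat protocol and
the complete hyperparameter grids (6 C values × 4 kernels, × 6 channel pairs
for the autoencoder groups — 24 and 144 cells) are available through the same
API for larger runs. Degenerate inputs (constant windows, all-zero spectra,
single spectral lines) raise explicit errors rather than emitting NaN.

## Known limitations

* The synthetic murmur is stationary band noise; real murmurs have shaped
  envelopes (crescendo–decrescendo) and harmonic content.
* Detail-zeroing denoising discards everything above fs/2^(L+1); genuine
  high-frequency murmur energy would be lost at these settings. The band
  placement of the generator sidesteps, not solves, this.
* The raw-window control group feeds phase-sensitive waveforms to a kernel
  machine and can rank below chance; this is informative about the baseline,
  not a defect of the metric.
* Latent pooling to 4 steps is coarse for murmurs much shorter than a
  quarter-window.
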