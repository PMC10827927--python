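# Methods

## The model

ERTNet is a hybrid convolution + transformer classifier for multichannel
EEG epochs. An epoch is a `[C × S]` array (C electrodes, S samples). The
network has three parts:

**Feature extraction (EEGNet lineage).** A bank of `F1` temporal
convolution kernels of length `T` (same padding, stride 1, no bias, *no
activation*) acts as a learnable FIR filter bank along time; because no
nonlinearity precedes or follows it before batch norm, each kernel's
discrete-time Fourier transform is an exact description of what it passes
— this is what makes the kernels interpretable. A depthwise spatial
convolution then learns `D` weight vectors over all `C` electrodes per
temporal kernel, collapsing the channel axis and producing
`F2 = F1 × D` maps (the constraint is enforced by the config type and
cannot be violated through any public constructor). Batch norm + ELU,
average-pool of length 4, dropout; a separable convolution (depthwise
temporal length 16, then 1×1 pointwise mixing to `F2`), batch norm + ELU,
average-pool of length 8, dropout.

**Transformer encoder.** The pooled maps are transposed to a token
sequence `[d × F2]`, `d = S / pool1 / pool2` (integer division; trailing
remainders are truncated at each pool). A fixed sinusoidal positional
encoding `PE[p, 2i] = sin(p / 10000^{2i/F2})`, `PE[p, 2i+1] = cos(·)` is
added — it is the only order-aware component, which the tests verify by
showing token-permutation invariance once it is disabled. Each of
`n_blocks` encoder blocks computes full-width multi-head self-attention:
every head has its own `F2 × F2` query/key/value projections (heads are
*not* split into F2/n slices), scores are scaled by `1/√F2`, and the `n`
concatenated head outputs (`[d × nF2]`) are projected back to `F2` by
`W^O ∈ R^{nF2×F2}`. Residual connection and layer normalization follow the
attention and again the single-layer ELU feed-forward (`F2 → F2`; no
expansion, to keep the parameter count small).

**Head.** Global average pooling over tokens (in place of flatten) and a
dense softmax over the K classes.

The minimum frequency a length-`T` kernel can represent at sampling rate
`Sr` is `Fmin = Sr/T` (one full cycle must fit in the kernel); the
`fmin_sweep_experiment` turns this rule into a measurable prediction.

An `EEGNetBaseline` (identical extraction stack + flatten + dense head)
ships as the transfer-learning source: `transfer_init` copies the
temporal/spatial/separable/batch-norm parameters (including running
statistics) bit-exactly into an ERTNet whose extraction stack has the same
`(C, F1, T, D)`.

### Default architecture parameters

| symbol | meaning | default |
|---|---|---|
| F1 | temporal kernels | 8 |
| T | temporal kernel length (samples) | 64 |
| D | spatial kernels per temporal kernel | 4 |
| F2 | pointwise kernels, always F1·D | 32 |
| pool1 / pool2 | average-pool lengths | 4 / 8 |
| n | attention heads (full width) | 8 |
| n_blocks | encoder blocks | 1 |
| dropout | extraction-stack dropout | 0.5 (subject-dependent); 0.25 for subject-independent protocols |
| α | ELU decay factor | 1.0 |

Initialization is Glorot-uniform (seeded); convolution biases are omitted
wherever a batch norm immediately follows; batch-norm scale/shift start at
1/0 and running statistics use momentum 0.1. No max-norm constraints are
applied anywhere.

## The numerics engine

No deep-learning framework is used: the layer engine (`ertnet.nn`) is a
compact numpy implementation with per-layer hand-derived reverse-mode
gradients, verified against central finite differences (worst absolute
deviation ~1e-10 at float64) and, for the whole forward pass, against a
dependency-free straight-loop reimplementation. Temporal convolutions are
computed by FFT (transform length ≥ S+T−1, so circular equals linear
correlation; exact up to rounding). Models default to float64; training
runs use float32 for speed — same-machine, single-threaded runs are
bit-reproducible per seed either way. The optimizer is Adam (β₁ 0.9,
β₂ 0.999), with optional decoupled weight decay and an optional
network-slimming L1 proximal step on the first-stage batch-norm scales
(both off by default).

## Preprocessing

Zero-phase FIR filtering uses windowed-sinc (Hamming) designs applied once
(the symmetric kernel has linear phase; centred application gives zero net
phase) with reflect padding — this keeps edge transients small on short
recordings, where forward-backward filtering leaves large reflections.
The design targets a 0.5 Hz transition band (1 Hz for the notch); the tap
count is capped at a third of the signal length, widening the transition
accordingly on short inputs. Resampling is Fourier-domain with the new
sample count `round(n · target/source)`. Epochs are half-open windows
`[t, t+4 s)` starting at 0; trailing remainders are discarded.
Normalization is a per-channel, per-epoch z-score; constant traces map to
zeros. Two preset recipes are provided: `deap` (band-pass 4–45 Hz →
resample 128 Hz → 4-s epochs, no re-normalization) and `seedv` (notch
50 Hz → band-pass 1–50 Hz → 4-s epochs → resample 200 Hz → z-score).
Dimensional labels threshold valence/arousal ratings at 5.0; a rating
equal to the threshold counts as "high". Artifact correction (EOG/ICA) is
out of scope; inputs are assumed artifact-reduced.

## The synthetic generator

The generator emulates the statistical structure the interpretability
claims rest on: band- and channel-localized oscillatory class codes in
1/f background. Per epoch and channel it draws pink noise (spectral
synthesis, PSD ∝ 1/f^exponent, default exponent 1, unit variance), adds
white noise (sd 0.3), optional 50 Hz line interference, optional
broadband >45 Hz bursts, and — on the target channels of the epoch's
class — a sinusoid whose frequency is drawn per epoch inside the class
band (so kernels must learn a band-pass, not a single tone) with random
phase. Bundled montages: a 32-channel Biosemi-style layout and a
62-channel 10-10 layout, with 2-D coordinates obtained by
azimuthal-equidistant projection of the standard 10-05 electrode
positions (the two inferior-occipital cap electrodes are mapped to the
PO9/PO10 sites). Everything is a deterministic function of the config
seed, and the manifest records the true band/channels per class so
recovery can be scored without consulting the model.

What the generator does **not** emulate: volume conduction and source
mixing (each channel's background is independent), non-stationarity,
eye/muscle artifacts beyond generic broadband bursts, and inter-subject
variability (all subjects share one generative process). Passing the
recovery tests therefore shows the machinery is correct, not that real
recordings are this separable; real-data accuracies are far below the
synthetic ceiling.

## Training and evaluation protocols

`fit` is mini-batch Adam on categorical cross-entropy with an optional
stratified validation slice (10%) for early stopping (best-validation
weights restored). Defaults: lr 1e-3, batch 64, up to 100 epochs,
patience 10. The synthetic experiments use lr 3e-3, batch 32 and no early
stopping: at a few hundred training epochs the loss sits on a long
plateau before breaking through, and the smaller batches / larger steps
cross it reliably within ~15 epochs.

Protocols: stratified segment-level k-fold (subject leakage is possible
in this subject-dependent design — by construction; use LOSOCV for
subject-independent claims, where dropout defaults to 0.25),
stratified 8:2 holdout, and leave-one-subject-out grouped by the
per-epoch subject id. Accuracy comes from the confusion matrix; AUC is
macro one-vs-rest by trapezoidal ROC integration; a single-class test set
reports AUC as missing.

Paired fold accuracies are compared with a Wilcoxon signed-rank test
(zero differences dropped; exact p for n ≤ 25 by a rank-sum distribution
convolution that remains valid under midrank ties; normal approximation
with continuity and tie correction beyond). Paired AUCs on one test set
use the fast DeLong estimator (midrank structural components); K > 2
classes run one-vs-rest per class with Bonferroni correction.
Hyperparameter search is seeded random search over the integer ranges
F1 ∈ [4,20], T ∈ [5,100], D ∈ [1,5], heads ∈ [4,20], honoring F2 = F1·D,
with mean CV accuracy as the objective.

## Interpretability

**Kernel spectra.** Magnitude of the kernel DTFT on a ≥1024-point grid up
to Nyquist; dominant frequency is the argmax above 0.5 Hz (a kernel whose
response only decays from DC reports the lowest grid frequency). Band
labels use delta <4 Hz, theta 4–8, alpha 8–13, beta 13–30, gamma 30–50;
a kernel whose spectral flatness (geometric/arithmetic mean of power)
exceeds 0.5 is labeled broadband.

**Topographies.** The D depthwise spatial weight vectors attached to a
temporal kernel, reported with montage coordinates; values round-trip
exactly from the stored parameters.

**Ablation.** "Removing" a kernel zeroes its temporal weights *and* the
corresponding first-stage batch-norm scale and shift, so the branch
contributes exactly zero downstream; evaluation is retraining-free and
the original weights are restored afterwards (bit-identically — asserted
in tests). The study table has one row per singleton, optional named
groups, and the unablated "None" reference; its AUC columns are the
per-class one-vs-rest values plus their row-wise average.

**Minimal sufficient filter bank.** Trained banks are redundant: when a
task is solvable by one filter, several kernels typically co-converge on
it, and then no single-kernel ablation moves AUC even though the band is
critical as a group — single-kernel tables systematically understate
importance. Before attributing, `prune_redundant_kernels` greedily
silences kernels whose removal costs no macro AUC (tolerance 0.01) on the
attribution data, then the decision layer alone is briefly refit
(silencing branches shifts constant offsets into the logits; ranking, and
hence AUC, is unaffected, but the argmax decision needs recalibration).
On the reduced model, ablation pinpoints the kernels that actually carry
the information. This mirrors the classic observation that group ablation
reveals what redundant singleton ablations hide.

**Gaussian fit.** Bounded least squares of `a·exp(−(t−t0)²/2σ²)` with t0
initialized at the kernel's centre of mass and σ at T/6; reports σ (in
samples), the fitted peak a, and the Pearson r between kernel and fit
(r = NaN on non-convergence). Kernels with r ≥ 0.9 are summarized as
Gaussian-like smoothers, distinct from band-selective filters.

## The recovery experiments (problem sizes)

`band_recovery_experiment`: 32 channels / 128 Hz / 4-s epochs, 8 subjects
× 50 epochs per class per subject (800 epochs), 20 Hz (18–22 Hz band)
signature of amplitude 2 on T7/T8 over unit-variance background; model
F1=4, T=32, D=2, one block; 15 training epochs, 8:2 holdout; then pruning
and head recalibration. Success = test accuracy >85%, the most
ablation-critical kernel dominant in 13–30 Hz, strictly more damaging
than any other singleton, and its top spatial channels intersecting
{T7, T8}.

`fmin_sweep_experiment`: equal-amplitude (1.0) theta 5–7 Hz vs beta
18–22 Hz codes on the same channels — class information is purely
spectral, so raw signal power is uninformative. 400 epochs, 2-fold CV per
kernel length, 20 training epochs. A length-4 kernel (Fmin = 32 Hz)
cannot resolve either band and must underperform the length-32 kernel
(Fmin = 4 Hz ≤ the 5 Hz band edge). Fold-averaging matters here: single
training runs at these sizes are optimization-noisy.

These sizes keep every experiment to about a minute per seed on one CPU
and are the package's chosen study conditions for its own validation.

## Known limitations

- The engine is single-process numpy: fine at these problem sizes,
  not intended for full-scale dataset training.
- Segment-level k-fold in the subject-dependent protocol allows subject
  leakage; this mirrors the common practice it models and is documented
  rather than silently fixed.
- EDF support covers the standard continuous layout (one sampling rate
  per channel set); EDF+ annotations are ignored.
- The Gaussian/band-selective dichotomy in `kernel_report` uses fixed
  thresholds (r ≥ 0.9, flatness > 0.5); borderline kernels exist.
- Optuna-style TPE search is not implemented; the search is random
  (seeded) over the same ranges.
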