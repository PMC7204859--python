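# Methods

## Problem and model

`eegsr` treats EEG acquisition cost as a resolution problem on two axes:
the sampling rate (samples per second) and the sensitivity (microvolts per
digitizer bit). A low-rate, low-sensitivity recording `z` of a trial is
modeled as the output of an acquisition operator applied to the underlying
high-resolution signal `x`: an anti-aliased factor-2 decimation followed
by uniform amplitude quantization with step equal to the device
sensitivity. The package learns an approximate inverse `G(z) ≈ x` from
paired examples.

`G` is a residual convolutional network over the (channel × time) plane:
one input feature map, a head convolution, `n_blocks` residual blocks of
two 3×3 stride-1 convolutions with batch normalization and ReLU, a
fractional-stride (transposed) convolution that doubles the time axis, and
a linear 3×3 output convolution. A fixed Catmull-Rom cubic-interpolation
skip connects the upsampled input to the output, so the network learns a
residual correction on top of cubic upsampling. The output convolution is
zero-initialized: the untrained generator reproduces cubic interpolation
exactly, training can only refine it, and early training cannot inject
noise larger than the signal. The network is fully convolutional, so a
trained generator applies to any channel count and any trial length at
least the training patch length; whole trials are reconstructed in a
single pass (no patch tiling, no seam artifacts).

The critic `D` mirrors the published layout: eight 3×3 convolutions with
LeakyReLU, feature maps doubling every two layers, stride alternating 1
and 2 along time only, then dense layers (1024 → 1 at full width). For the
classic GAN variant it ends in a sigmoid and keeps batch normalization; for
the Wasserstein variant it has no sigmoid and batch normalization defaults
to off, because batch statistics couple the samples inside a batch and make
the per-sample input-gradient norms that the gradient penalty constrains
ill-defined (a `use_batchnorm` switch restores the printed layout).

## Objective

The generator minimizes `L_TSF + λ₁·L_adv + λ₂·L_TV` with

- **Temporal MSE** — mean squared point-wise error between generated and
  real patches.
- **Spatial MSE** — mean squared error between CSP log-variance feature
  vectors of generated vs real patches. The CSP filters are fitted once
  per training round on the broadband (8-30 Hz) filtered real high-rate
  training trials and frozen; no gradient flows through the fitting. The
  features use central variance, so the affine scope normalization cancels
  exactly.
- **Frequency MSE** — mean squared error between per-channel Hann
  periodogram densities (zero-padded to nfft=256 so that 24-sample patches
  land on a stable frequency grid). The differentiable periodogram is
  numerically identical to the evaluation-side `compute_psd`.

Every MSE divides by the total element count of the compared tensors; the
printed normalizations of the source formulation are ambiguous between
per-axis and per-element, and the per-element reading is scale-stable
across patch sizes (a `normalize=False` switch gives the raw summed
Frobenius form). The literal formulation also applies the generator to the
feature extractors, `G(CSP(z))`; that reading is dimensionally inconsistent
with the generator's input contract, so the implementation compares
features of the generator output, `CSP(G(z))` vs `CSP(x)`, which is what
the loss-calculator description conveys.

Total variation is the mean absolute forward difference along time
(channel-axis differences are optional and off by default: temporal
coherence is the stated aim and channel order is arbitrary). The
adversarial term is the non-saturating generator loss for the GAN variant
and `-E[D(G(z))]` for the Wasserstein variant; the critic adds the
two-sided gradient penalty `λ_gp·E[(‖∇_x̃D(x̃)‖₂−1)²]` on uniform
straight-line interpolates, with λ_gp = 10.

Weight presets: λ₁=10⁻³, λ₂=2×10⁻⁸ by default and
(λ_T, λ_S, λ_F)=(0.46, 0.23, 0.30); the per-dataset-pair averages reported
for the nine same/cross-sensitivity settings ship as named presets
("AO->AO" … "GAL->MI"), plus a "fig3" preset (0.5/0.25/0.25,
λ₁=λ₂=0.1) quoted alongside the training-procedure figure. The two
sources disagree; both are retained, with the first as default.

## Training protocol

Patch pairs `(N×τ, N×2τ)` with τ=12 are drawn uniformly with replacement
over (trial, start); a low-rate start `s` maps to high-rate start `2s`.
Amplitudes are normalized from the declared scope `[lo, hi]` onto `[-1, 1]`
at the network boundary only; the trial-set container stays in microvolts
throughout. Minibatches of 32 alternate one critic step and one generator
step (`n_critic` is configurable; the strict alternation of the published
procedure is the default). Optimizers are Adam(α=10⁻⁵, β₁=0.5, β₂=0.9) for
the GAN variant and RMSprop(α=10⁻⁵, β=0.9) for the Wasserstein variant.
Ten validation snapshots per epoch record the temporal, spatial, frequency
and combined TSF losses on a held-out set of patch pairs (disjoint draw
from the same trial set) plus the Wasserstein surrogate
`-E[D(x)] + E[D(G(z))]`, unnormalized, in the network's normalized
amplitude units. A non-finite loss aborts training with a diagnostic
record rather than continuing silently — adversarial instability is an
expected failure mode worth surfacing. Given a seed, the whole loop is
bit-reproducible.

The "leave-one-rest" split used for multi-subject protocols holds one
recording unit out and samples `k` of the remaining units uniformly
without replacement for training.

## Synthetic ERD/ERS data

The generator emulates the statistical structure that filter-bank CSP
classification relies on, not the biophysics of real EEG. Each trial is a
sum of a mu (10 Hz) and a beta (20 Hz) sinusoid per source channel with
per-trial random phases and ~10% lognormal amplitude jitter, multiplied by
`1 − erd_depth[class, channel]` inside a smooth task window (raised-cosine
edges, 0.1 s), mixed through a seeded random orthonormal channel matrix,
plus 1/f-power background noise made by spectral shaping of white noise.
Class effects are multiplicative amplitude modulation — true
event-related-desynchronization semantics — not additive signal.
Defaults: 2 classes, 8 channels, 250 Hz, 2 s trials, task window
0.5-1.5 s, rhythm amplitudes 10/5 μV, noise 5 μV, scope ±100 μV,
sensitivity 0.1 μV/bit. What the simulator does **not** model — volume
conduction from dipole sources, artifacts (EMG, blinks), non-stationary
rhythm frequency, inter-subject variability — means that passing tests
demonstrate the pipeline's correctness and its behavior under controlled
ERD contrast, not expected accuracy on real recordings.

## Evaluation

FBCSP+SVM: each of the ten 8-30 Hz sub-bands (width 4 Hz, overlap 2 Hz) is
band-pass filtered (4th-order Butterworth, forward-backward), CSP is
fitted per band on training trials only (one-vs-rest per class when there
are more than two classes), and the concatenated normalized log-variance
features feed a linear SVM with C=0.01. (The recorded `g=2` kernel
hyperparameter is inert under a linear kernel; it is stored, not silently
dropped.) The "8×8" protocol is stratified 8-fold cross-validation
repeated 8 times with reshuffling; band filtering is per-trial and
label-free, so it is computed once and shared across folds, while CSP and
SVM fitting never see test trials. Two-sided paired t-tests compare
accuracy vectors, flagged at p<0.05 and p<0.01.

Qualitative diagnostics: per-sample mean temporal error, mean PSD
difference over 1-45 Hz, and scalp maps of 12±1 Hz band power interpolated
from a bundled standard 10-20 position table with a thin-plate radial
basis, masked to the head disk near sensor support (radial-basis
extrapolation far outside the electrode hull is unreliable). Maps are raw
band power; no baseline normalization is applied, since none is specified
for the reference figures.

## CSP algorithm

Per-trial spatial covariances are trace-normalized and averaged per side
of the contrast; the composite covariance `C₁+C₂` is whitened by its
eigendecomposition and the whitened `C₁` is eigendecomposed; the `m` most
and `m` least discriminative directions form the 2m filters. Eigenvalues
are variance ratios in [0,1]; for every filter the ratios with respect to
the two classes sum to one. A rank-deficient composite covariance raises
an error that names the shrinkage parameter (`reg`) as the remedy.

## Numerical choices

- Anti-alias filter for decimation: 8th-order Butterworth low-pass at
  0.8× the target Nyquist, applied forward-backward (zero phase), as
  second-order sections.
- Band-pass filters: 4th-order Butterworth, forward-backward.
- Decimation refuses any factor that would put the Nyquist frequency at or
  below 30 Hz (the top of the analysis band).
- Quantization: `round(value/step)·step`, error ≤ step/2 per sample.
- Gradient-penalty norms add 1e-12 under the square root; GAN scores are
  clamped to [1e-7, 1−1e-7] before logs.
- All computation is float64; training is deterministic given the seed
  (pure numpy, no threading nondeterminism).

## Desk-scale validation conditions

The package validates itself end to end at a size one CPU handles in
minutes: 2 classes × 150 trials, 8 channels, 250 Hz high-rate / 125 Hz
low-rate, ERD depth 0.8 on disjoint lateralized channel groups; generator
reduced to 4 residual blocks × 16 maps; critic with the same
doubling pattern at base width 8 and a 64-unit dense head; τ=12, batch 32,
5 epochs of the Wasserstein variant over 3,584 patch pairs with 128
held-out validation pairs; optimizer and learning rate at their standard
values. Under these conditions the held-out TSF loss drops roughly
threefold and the reconstruction's 8×8 FBCSP+SVM accuracy stays within a
point of the cubic-spline baseline. The Wasserstein surrogate behaves
differently at this scale than in long full-scale training: with the
zero-initialized generator already close to the data and only five epochs
at the standard learning rate, the critic is still in (or just past) its
warm-up, so |W| is small (~10⁻³ in normalized units) and whether it has
started its eventual decline by the last epoch depends on the seed — some
seeds show the full rise-peak-decline arc, others are still rising at
epoch five. Epoch-end snapshot values are used for the comparison,
matching how convergence is tracked per epoch.

## Known limitations

- Only upsampling factor 2 is implemented (the transposed convolution is
  specialized to it).
- The critic's dense head fixes its input geometry; only the generator is
  channel/length agnostic.
- Training at the published scale (16 blocks × 64 maps, 30 epochs,
  thousands of trials) is supported by the same code but is not practical
  on one CPU; the desk-scale preset above is the tested configuration.
- The spatial loss term requires labeled high-rate training data with at
  least two classes; without labels the spatial term is dropped.
- Mutual-information band selection, shrinkage-CSP variants and
  alternative adversarial objectives (hinge, LSGAN, spectral
  normalization) are out of scope.
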