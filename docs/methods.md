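# Methods

This note records the model as implemented, the conventions this package
pins where the published description of LMCSleepNet is ambiguous, what the
synthetic data generator does and does not emulate, and the problem sizes the
test suite uses. Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Scalogram preprocessing

Each 30 s epoch of each channel (3000 samples at 100 Hz) is correlated with a
bank of complex Morlet wavelets, `ψ_a[k] = a^(-1/2) e^(-(k/a)²/2) e^(iω₀k/a)`
for integer scales a = 1…32, sampled on a symmetric grid wide enough for the
Gaussian envelope to fall below 1e-8. Pinned conventions:

* **ω₀ = 6.0.** The published description never states the Morlet center
  frequency; 6 is the standard admissibility-safe choice. Exposed in
  `ScalogramConfig`.
* **Scale normalisation a^(-1/2)** (L2). With it, the discrete wavelet norm
  is scale-invariant (≈ π^¼; asserted by test). The alternative 1/a (L1)
  convention would only rescale scalogram columns and is removed anyway by
  the per-map z-score.
* **Scale→frequency mapping** f(a) = ω₀·fs/(2πa): 95.5 Hz at a = 1 down to
  3.0 Hz at a = 32. Note this grid does **not** reach the 0.5–2 Hz delta
  band at fs = 100 under any standard Morlet mapping; delta activity still
  leaves most of its energy at the largest scales, which is sufficient for
  classification, but the common claim that scales (1, 32) "cover delta" is
  not literally achievable with ω₀ = 6. We implement the formula, not the
  claim.
* **Magnitude scalograms** (|coefficient|), not power or real part.
* **Boundaries:** zero-padded same-length convolution; the bias affects less
  than 1 s at each edge at the largest scale.
* **Median downsampling:** non-overlapping windows of m = 3000/200 = 15; an
  even window takes the mean of the two central order statistics. The median
  of an odd window is its central order statistic, so it is exactly invariant
  to arbitrary corruption of samples that stay on their side of the median
  (amplified outliers) and moves at most one order statistic for any
  single-sample corruption. Mean and max modes exist only for the
  downsampling comparison harness.
* **Normalisation:** per-epoch, per-channel z-score, (x − μ)/(σ + 1e-8). The
  original description is silent on input normalisation; the z-score gives
  amplitude invariance across subjects and stable optimisation, and makes
  EDF physical-unit questions moot.

Epochs beyond the annotated span and trailing partial epochs are discarded
(`n_seg = ⌊L/30fs⌋`); MOVEMENT/UNKNOWN epochs are removed; R&K stages 3 and 4
merge into N3. Labels are encoded W=0, N1=1, N2=2, N3=3, REM=4 everywhere.
Optional trimming of long pre/post-sleep wake runs is deliberately **not**
performed (the published protocol does not mention it).

## Network

Input `[3, 200, 32]`. The Table-style output sizes of the original
description correspond to a nominal 224×224 image; this implementation keeps
the stride schedule and lets shapes fall where they do
(200×32 → 100×16 → 50×8 → 50×8 → 25×4 → 13×2 → 7×1), with a global adaptive
average pool instead of a fixed 7×7 pool — equation-level fidelity over
table-artifact fidelity.

* **MSDC stem:** three parallel 3×3 convolutions, stride 2, dilation d ∈
  {1,2,3} with padding d (3→64 each, batch-norm each); channel concat (192)
  → 1×1 fusion conv to 64 → BN → ReLU. An `add` fusion mode (no fusion conv)
  exists for the fusion-comparison harness. The non-MSDC variant uses the
  standard 7×7 stride-2 stem.
* **Body:** four stages × two residual basic blocks, widths 64/128/256/512;
  first block of stages 2–4 has stride 2 and a 1×1+BN projection shortcut.
  With DSC enabled every 3×3 convolution becomes depthwise 3×3 (+BN) then
  pointwise 1×1 (+BN); the stride lives on the depthwise stage; shortcut
  1×1 convs stay dense (they are already pointwise). All convolutions are
  bias-free.
* **CBAM**, applied once after stage 4 (not per block): channel attention
  with a shared bias-free bottleneck MLP (512→32→512, reduction 16) over
  global avg- and max-pooled descriptors, then spatial attention via a 7×7
  convolution (2→1, with bias) over channel-wise mean/max maps. The
  published formula writes CBAM as an element-wise product of two
  independently weighted maps, but also describes spatial attention as
  operating on "the output of the channel attention module"; the canonical
  sequential form (channel then spatial) is implemented.
* **Head:** global average pool → dropout p = 0.5 (the description says only
  that dropout was added) → FC 512→5 (with bias) → softmax.

This pinning yields **1,492,840** parameters for the full model and
**1,484,392** for the no-MSDC ablation — 1.49 M / 1.48 M at two decimals,
matching the published counts, which is the strongest available evidence that
the pinning reconstructs the original layer graph. With all three flags off
and a 1000-way head the builder reproduces the standard ImageNet ResNet18
exactly (11,689,512). The published baseline figure 11.69 M matches only
that 1000-class configuration (a 5-class head would give ≈11.18 M), so the
baseline is counted in its ImageNet configuration.

The whole engine (convolution via strided-slice patch extraction + BLAS
contraction, batch-norm, pooling, attention, explicit reverse-mode
gradients, Adam) is NumPy; every forward operator is verified against
nested-loop oracles and every backward pass against central finite
differences.

## Training protocol

Adam β₁ = 0.9, β₂ = 0.999, lr = 5·10⁻⁶, batch 64; weighted cross-entropy,
`w_c = N/(K·n_c)` (mean-normalised inverse frequency, e.g. w_N1 ≈ 3.08 on
the SleepEDF-20 distribution); L2 weight decay 10⁻³ applied through the
optimizer to convolution/linear weights only — batch-norm affine parameters
and biases are excluded, the standard practice, and compatible with the
published "applied to the loss function". Early stopping: strict
improvement of validation accuracy, ties do not reset patience (20), best
checkpoint restored. The published lr 5·10⁻⁶ is unusually small for Adam
from scratch; it is implemented as printed and exposed in config (the quick
CPU checks raise it to 10⁻³). A maximum epoch budget is never published;
the default is 200.

Cross-validation is **subject-wise** (the original says only "divided into
10 parts"); subject-disjoint folds prevent leakage and are the field
standard. A record-wise mode exists behind a flag. Pooled (summed) fold
matrices are the canonical reporting surface; fold-averaged mean ± sd are
reported alongside.

## Synthetic data

The generator emulates: three synchronized 100 Hz channels; stage-typical
oscillations (W: 10 Hz alpha + frequent EOG deflections; N1: low-amplitude
5.5 Hz theta; N2: theta + 13 Hz spindle bursts of 0.5–1 s at ~15% duty;
N3: high-amplitude 1.2 Hz delta; REM: 6 Hz theta + large slow EOG-only
deflections); SleepEDF-20 stage proportions (21.1/6.5/41.3/13.2/17.9%),
enforced by per-subject quotas so realized proportions match to within
rounding; and hypnogram run structure via geometric runs (persistence 0.85,
mean run ≈ 6.7 epochs), which makes subject-wise splits meaningfully harder
than i.i.d. shuffling. Amplitudes are arbitrary units — normalisation
removes scale.

It does **not** emulate: 1/f background, K-complexes, artifacts, arousals,
inter-subject spectral variability, or scorer noise. The classes are
linearly separable in band-power space by construction (a nearest-centroid
band-power classifier clears 80%; asserted by test). Consequently a passing
end-to-end check shows that the pipeline — generator, scalograms, network,
loss, optimisation, CV plumbing — learns and generalises across synthetic
subjects; it says nothing about accuracy on real Sleep-EDF recordings,
which would require the dataset download and roughly GPU-days of training.

## Problem sizes and numerical choices in the test suite

* End-to-end learning check: 10 subjects × 40 epochs, reduced widths
  16/32/64/128, subject-wise 5-fold CV, lr 10⁻³, 5 epochs per fold, median
  pooled accuracy over 3 training seeds, threshold 60% against 20% chance.
  These sizes were chosen to keep the full CPU-only suite around six
  minutes; the margin above threshold is large.
* Forward/backward equivalence checks run on tensors ≤ [4, 8, 8] at 1e-5
  (forward vs nested loops) and ~2e-2 absolute (gradients vs central
  differences at float32).
* CWT peak-scale recovery is asserted on an extended grid (scales 1…64) so
  the 2 Hz target (ideal scale ≈ 47.7) is interior to the grid; the default
  analysis grid remains 1…32.
* Degenerate cases: PR/RE/F1 are defined as 0 (and flagged) on empty
  rows/columns; κ is NaN when expected agreement is 1; constant maps z-score
  to 0 via the ε in the denominator; logs are clamped at 1e-12.
* Determinism: preprocessing is exactly deterministic; training is
  deterministic given the config seed on a single device (seeding covers
  initialisation, shuffling and dropout).

## Known limitations

* No sequence-level modelling (epochs are classified independently, as in
  the original), no pretrained weights, no focal loss (evaluated and
  rejected by the original), no LR schedules or distributed training.
* The EDF writer exists only to round-trip synthetic fixtures; reading
  supports the Sleep-EDF montage only, with no resampling or artifact
  rejection.
* CPU-only NumPy training is roughly two orders of magnitude slower than a
  GPU framework; full-width training on real-data scale is out of scope.
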