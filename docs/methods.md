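# Methods

## Model

The network is a U-shaped encoder–decoder for 2D segmentation.

**Encoder.** A strided stem convolution (kernel 2s−1, stride s, s = 4 by
default) brings the image to 1/4 resolution; three stages of three
channel-prior convolutional attention (CPCA) blocks each, separated by
3×3 stride-2 convolutions, yield features at 1/4, 1/8, 1/16 resolution
with widths [C, 2C, 4C]. A CPCA block gates channels with a pooled
bottleneck MLP (sigmoid), refines space with multi-scale depthwise strip
convolutions (1×k then k×1, k ∈ {5, 7, 11, 21}), mixes pointwise, and
adds the result residually. The geometric width progression is not a
free choice: the decoder's patch-expanding layers halve channels while
doubling resolution, so the skip width at each scale must be half the
next deeper width.

**Decoder.** The deepest features pass through a bottleneck of stacked
CASA blocks, then two decoder stages of [patch expand → skip fusion →
n × CASA block] and a 1×1 projection head with 4× bilinear upsampling to
full resolution.

**CASA block.** Tokens are the rows of the row-major-flattened feature
map (channels last). The default cascade is channel-attention first:
LN→XCA(+skip), LN→MixFFN(+skip), LN→TKSA(+skip), LN→MixFFN(+skip).
XCA ℓ2-normalizes the columns (channels) of Q and K, forms the d×d
cross-covariance KᵀQ per head, divides by a learnable per-head
temperature, and softmax-normalizes over the key-channel axis so each
output channel's mixture weights sum to one (the cross-covariance
convention). TKSA forms the per-head channel similarity S = QKᵀ scaled
by its own learnable per-head temperature, keeps per row the entries
≥ the k-th largest (ties kept, others −∞), softmaxes, and applies the
result to V; branches at k = round(f·C_head) for f ∈ {1/2, 2/3, 3/4,
4/5} are summed with learnable scalar weights initialized to 1.
Rounding is half-up (f·C_head + 0.5 floored) and k is clamped to ≥ 1.
Mix-FFN is FC₂(GELU(LN(DWConv₃ₓ₃(FC₁x) + FC₁x))) with expansion 4.
Alternative orders (sparse-first, parallel averaging of the two
operators with a single FFN, and single-operator variants) are
selectable to span the attention-composition design space.

**SSCF block.** Skip and upsampled decoder features (each C channels)
are concatenated; the 2C-channel map is refined by two residual
branches scaled by learnable per-channel gains γ₁, γ₂ (init 0.01,
bounded ≤ 0.1 at configuration time): first a spatial/channel
synergistic attention (SMSA: per-group 1D depthwise convolutions with
kernels {3, 5, 7, 9} on H- and W-pooled channel profiles, channel-
layer-normalized, sigmoid-gated, outer-product applied; then a channel
shuffle over 4 groups; then PCSA: channel self-attention over 7×7-pooled
tokens whose spatially averaged, sigmoid-squashed output gates the
channels), second a Lite-FFN (1×1 → depthwise 3×3 → GELU → 1×1,
expansion 2). Compression back to C channels is depthwise 3×3 followed
by pointwise 1×1; a pure pointwise mode and the additive-aggregation /
plain-SCSA variants cover the fusion ablation axes. Layer normalization
is applied over channels at each spatial position; the internals of the
SCSA and CPCA operators follow their published designs and are isolated
behind single classes so a replacement cannot ripple.

## Objective and metrics

Loss = λ·CE + (1−λ)·Dice on softmax probabilities; λ = 0.4 in the
SGD profile (multi-class CT/MRI), 0.5 in the Adam profile (binary
dermoscopy). Cross-entropy uses a clamped log (1e−12). Soft Dice is
computed per class including background and averaged; the denominator
carries an ε = 1e−6 guard only (no smoothing added to the numerator),
which leaves nonempty-class values unchanged to five decimals and makes
an absent class with zero predicted mass score 0 rather than 0/0.

Evaluation Dice binarizes per class; both-empty masks score 1, one-empty
0 (the common multi-organ evaluation convention). Boundaries are mask
pixels with a background 4-neighbor (the image border counts as
background); HD is the symmetric maximum of directed nearest-boundary
distances (KD-tree), HD95 the symmetric 95th percentile, so HD95 ≤ HD
by construction. Distances are in pixel units unless a spacing vector
is supplied. Slices can be stacked per case for volume-wise evaluation.
Empty boundaries make HD undefined; it is reported as NaN with a
warning and skipped in aggregation. Binary tasks additionally report
accuracy, precision, sensitivity, specificity, and IoU from the
confusion counts, with zero-denominator ratios reported as NaN.

## Budget calibration

The reference budget for the full-size model is 42.02 M parameters and
18.47 GFLOPs for one 224×224 forward pass. Per-stage widths, stem, and
bottleneck composition are otherwise open design choices, so they were
fixed by a one-time scan (`scripts/calibrate_budget.py`) over the base
width and the bottleneck FFN expansion: the shipped defaults —
widths [160, 320, 640], three CPCA blocks per stage, bottleneck of two
CASA blocks with Mix-FFN expansion 6 (expansion 4 elsewhere), decoder
depths [2, 2] — measure 42.29 M parameters (+0.6%) and 18.87 GFLOPs
(+2.2%). FLOPs are counted by instrumenting the autodiff conv/matmul
primitives during a real forward pass: one multiply–accumulate = one
FLOP; elementwise ops, normalizations, and interpolation are excluded
(the convention of the profilers whose numbers segmentation papers
typically quote). The default input is single-channel; a 3-channel
configuration changes only the stem cost (< 0.01 GFLOPs).

## Training

SGD profile: momentum 0.9, lr 3.4e−3, weight decay 1e−4, 400 epochs,
batch 16. Adam profile: lr 1e−4, 100 epochs, batch 4. The learning rate
follows polynomial decay (power 0.9) over the scheduled steps — the
standard schedule of 2D medical-segmentation recipes; only the initial
rate is part of the reference recipe. Augmentation (optional) applies
joint flips, quarter-turns, and small-angle (±20°) rotations with
nearest-neighbor mask interpolation. Runs are fully seeded: parameter
initialization, batch order, and augmentation draw from generators
derived from the configured seed, and repeated runs reproduce losses
bitwise. Checkpoints are single-file archives with the model config
embedded as YAML.

## Synthetic phantoms

The generator emulates the difficulty axes of the three clinical
regimes rather than their appearance: smoothly deformed ellipses
(Fourier-perturbed radii) stand in for irregular anatomy; class gray
levels are evenly spaced across a configurable `contrast` around 0.5;
`boundary_softness` blurs edges; Gaussian `noise_sd` models acquisition
noise; a low-amplitude smooth texture breaks within-class uniformity.
The cardiac regime builds the concentric LV/myocardium pair with an
adjacent RV crescent; the multi-organ regime places eight
non-overlapping structures of graded sizes, skipping an organ after
bounded placement retries rather than failing (placement failure of the
whole image raises). Defaults (contrast 0.6, noise 0.04, softness 1.5 px)
were fixed once as a plausibly difficult mid-range setting. Masks are
exact by construction. What passing tests on phantoms demonstrate is
that the architecture, objective, metrics, and training loop are
correct and can learn; they say nothing about segmentation accuracy on
real CT/MR/dermoscopy data, which differs in texture statistics,
artifacts, anatomy, and resolution.

Test-time problem sizes were chosen for CPU practicality: unit blocks
run at 4–8 channels, end-to-end learning checks use 32×32 phantoms with
stage widths [8, 16, 32] (the full-size architecture is exercised for
shape contracts and budget accounting only).

## Numerical choices and limitations

* float64 throughout; softmax subtracts the row max and treats fully
  −∞ rows as uniform (cannot occur with k ≥ 1 but guarded).
* Top-k ties at the threshold are all kept (≥ comparison), so a row of
  equal values is never masked.
* Adaptive average pooling falls back to the largest divisor of the
  spatial size not exceeding the target, keeping pooling exact on the
  small grids of reduced-size models.
* The depthwise-convolution path supports groups = 1 and groups = C
  only — all the architecture needs.
* Single-process CPU execution only; no mixed precision, no 3D
  convolutions, no pretrained weights. Attention is O(N·d²) per head in
  the channel dimension (the point of transposed attention), but the
  numpy core is still one to two orders slower than a compiled
  framework, so full-size 224×224 training is out of desk scope;
  inference and profiling at 224×224 take seconds.
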