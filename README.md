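# dcfnet

A hybrid CNN–Transformer encoder–decoder for 2D medical image
segmentation, built as a tested, self-contained Python library and CLI.
It targets the recurring difficulties of clinical images — weak
boundaries, low contrast, irregular anatomy — with two ideas:

* **A dual channel-attention decoder block (CASA).** Feature maps are
  treated as token matrices `X ∈ ℝ^{N×d}` (N = H·W spatial tokens, d
  channels) and refined by a pre-norm residual cascade

  ```
  X₁ = X  + XCA(LN(X))        X₂ = X₁ + MixFFN(LN(X₁))
  X₃ = X₂ + TKSA(LN(X₂))      X₄ = X₃ + MixFFN(LN(X₃))
  ```

  **XCA** (cross-covariance attention) attends over channels rather than
  positions: `XCA(Q,K,V) = V·Softmax(KᵀQ/τ)` with ℓ2-normalized Q, K
  columns — every entry of the d×d similarity lies in (−1, 1) — and a
  learnable per-head temperature τ. **TKSA** (top-k sparse attention)
  computes the transposed similarity `S = QKᵀ ⊙ τ`, keeps only the k
  largest entries per row (ties kept; the rest set to −∞ before the
  softmax), and fuses four sparsity levels k = C/2, 2C/3, 3C/4, 4C/5 of
  the per-head width with learnable weights α₁..α₄.

* **An attention-refined skip connection (SSCF).** Encoder skip x₁ and
  upsampled decoder feature x₂ are concatenated to 2C channels, refined
  by a dual-residual block — `x_s = x_cat + γ₁·SCSA(LN(x_cat))`, then
  `x_f = x_s + γ₂·LiteFFN(LN(x_s))` with small learnable channel gains
  γ — and compressed back to C channels (depthwise 3×3 + pointwise 1×1).

Around these sit a three-stage channel-prior convolutional encoder
(features at 1/4, 1/8, 1/16 resolution), patch-expanding upsamplers
(halve channels, double resolution), a linear projection head with 4×
bilinear upsampling, the hybrid objective
`Loss = λ·L_CE + (1−λ)·L_Dice`, and an evaluation suite (per-class
DSC, HD, HD95, accuracy/precision/sensitivity/specificity/IoU).

Everything — including backpropagation — runs on a small numpy
reverse-mode autodiff core inside the package (`dcfnet.autodiff`,
`dcfnet.nn`), so the library has no deep-learning framework dependency
and trains on a plain CPU. A seeded phantom generator produces
CT-like multi-organ, cardiac-MR-like, and lesion-like synthetic
datasets so every pipeline is exercisable without downloads.

## Worked example

```bash
# 24 synthetic 32x32 skin-lesion-like phantoms, split 70/10/20
dcfnet make-phantoms --regime lesion --n-images 24 --img-size 32 --seed 0 --out data
# width-reduced model, 120 optimizer steps on one CPU (~15 s)
dcfnet train --data data --out run --width 8 --max-steps 120 --epochs 60 \
             --batch-size 8 --lr 2e-3 --seed 0
dcfnet evaluate run/best.npz --data data --split test --out report
```

The training log ends around

```
{"epoch": 40, "step": 120, "loss": 0.0616, "train_dsc": 0.9205, "val_dsc": 0.8809}
```

and evaluation prints

```
{"mean_dsc": 0.8079, "hd": 5.107, "hd95": 4.465}
```

— i.e. after 120 steps the tiny model already overlaps ~92% of training
and ~81% of held-out lesion pixels (Dice), with predicted boundaries
within ~5 pixels (Hausdorff) of the truth on 32×32 test phantoms.
`report.csv` / `report.json` contain the per-case rows including the
binary confusion metrics.

The model budget of the full-size default architecture:

```bash
$ dcfnet info
{"params": 42290421, "params_m": 42.29, "gflops": 18.87, "img_size": 224, "in_channels": 1}
```

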