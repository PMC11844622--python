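# mrimoco

Physics-informed simulation, detection and correction of rigid-motion
artifacts in brain MRI.

Long MRI acquisitions make patient motion almost inevitable: when the
head moves between phase-encoding (PE) shots, some k-space lines are
recorded from a rotated/translated brain, and the reconstructed image
shows ghosting and ringing.  This package is for researchers who need a
controlled end-to-end testbed for that problem — simulating corruption,
localising it in k-space, and learning to undo it — on a single CPU with
no external data.

## What it implements

**Motion simulation.**  Given a clean slice, each motion event
`Θᵢ = (θᵢ, tx,ᵢ, ty,ᵢ)` owns one slab of PE lines, and the corrupted
spectrum splices the transformed lines into the clean one:

    k_motion = (1 − M) ⊙ k_GT + Σᵢ Mᵢ ⊙ 𝓣Θᵢ(k_GT),
    𝓣Θ = 𝓕 ∘ R_θ ∘ T_(tx,ty) ∘ 𝓕⁻¹

with three severity presets (5 / 10 / 15 slabs of 3–7 lines, |θ| ≤ 7°,
|t| ≤ 5 mm) and a protected band at the k-space centre.  Unmasked lines
stay bit-identical — the physical basis for data consistency.

**Detection.**  A U-net over the corrupted spectrum predicts corrupted
lines; a spatial-averaging module collapses the prediction to one value
per PE line `M(y) = (1/Nx) Σₓ M′(x, y)`, and training minimises
`L_seg = L_Dice + L_BCE` against the ground-truth line mask.

**Correction.**  A residual U-net with Swin Transformer blocks restores
the magnitude image under the composite loss

    L = λr·L1 + λl·L_perc + λd·L_dc,   λr=10, λl=0.5, λd=100,

where `L_dc = ‖𝓕(x̂)⊙Mp − 𝓕(x_GT)⊙Mp‖²` enforces k-space data
consistency on the lines the detector flagged.

**Evaluation.**  PSNR / SSIM / NMSE, 95 % bootstrap CIs (percentile and
BCa), one-way ANOVA with Tukey HSD, and signed difference maps.

Networks run on a small, gradient-checked reverse-mode autodiff engine
over NumPy (`mrimoco.nn`) — no deep-learning framework required.
Synthetic brain-like phantoms (bright skull rim, piecewise-smooth
tissue interior) make every stage testable without downloading data.
See `docs/methods.md` for modelling assumptions and numerical choices.

## Worked example

Corrupt one phantom at the three severities
(`python examples/simulate_motion.py`):

```
  severity  slabs  PSNR [dB]    SSIM  NMSE [%]
     minor      5      28.78   0.771      0.88
  moderate     10      19.89   0.584      6.85
     heavy     15      17.73   0.475     11.27
```

More corrupted slabs → lower PSNR/SSIM and higher NMSE, the
characteristic monotone degradation of inter-shot motion.

Train both networks at desk scale — 8 phantoms at 64×64, 200 joint
steps, ~2–3 CPU minutes (`python examples/train_and_correct.py`):

```
segmentation loss: 1.737 -> 0.017  (102x drop)
held-out detection Dice: 0.929 (1.0 = every corrupted PE line found, none falsely flagged)
correction PSNR gain: +8.0 dB over the corrupted input
```

The detector localises corrupted PE lines on phantoms it never saw, and
the corrector recovers several dB of PSNR over its corrupted input.
`examples/evaluate_and_compare.py` shows the metric/statistics layer on
two synthetic methods.

A thin CLI wraps the same library calls:

```bash
mrimoco make-fixtures --n 10 --size 64 --seed 1 --out pairs.npz
mrimoco train --data pairs.npz --preset desk --out ckpt/
mrimoco correct --data pairs.npz --checkpoints ckpt/ --out fixed.npz
mrimoco evaluate --pred fixed.npz --ref pairs.npz --out report.json
```

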