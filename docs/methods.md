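# Methods

## Problem and model

Inter-shot rigid head motion during a Cartesian 2-D spin-echo acquisition
displaces individual phase-encoding (PE) lines of k-space: the scanner
records some lines from a rotated/translated version of the object.
Because each line is acquired quickly relative to the motion, corruption
is modelled as line-wise and piecewise-constant — every motion event
`Θᵢ = (θᵢ, tx,ᵢ, ty,ᵢ)` owns one contiguous slab of PE lines.  The
corrupted spectrum is

    k_motion = (1 − M) ⊙ k_GT + Σᵢ Mᵢ ⊙ 𝓣Θᵢ(k_GT),

where `M = Σᵢ Mᵢ` is the binary per-line corruption mask and
`𝓣Θ = 𝓕 ∘ R_θ ∘ T_(tx,ty) ∘ 𝓕⁻¹` applies the rigid transform in the
image domain.  The package's two learned components are:

* a **detection network** `𝓓θ` — a U-net over a two-channel k-space
  representation (standardised log-magnitude, phase/π) predicting which
  PE lines are corrupted.  A *spatial averaging module* collapses the 2-D
  prediction to one value per PE line (the mean along the frequency
  encoding direction), and the outermost PE lines are excluded;
  training minimises Dice + binary cross-entropy against the
  ground-truth line mask;
* a **correction network** `𝓒ν` — a residual U-net whose attention
  stages are Swin Transformer blocks (windowed multi-head
  self-attention, alternating plain/shifted windows, pre-norm MLPs),
  trained under `λr·L1 + λl·L_perc + λd·L_dc` with `λr=10, λl=0.5,
  λd=100`.  `L_dc` compares the orthonormal centred FFTs of output and
  target on the masked lines only, which is what makes the model
  physics-informed: the network is pushed to fix exactly the measured-
  to-be-wrong part of the spectrum and leave consistent lines alone.

Both networks are trained simultaneously as alternating Adam steps on a
shared batch; the corrector's DC mask is the detector's binarised
prediction, detached, so no gradient couples the two losses and the
correction loss never reads the ground-truth mask.

## Numerical conventions

* FFTs are orthonormal and DC-centred (`ifftshift → fft2 → fftshift`),
  so Parseval's identity holds with unit constant and round trips are
  exact to ~1e-15.
* The PE direction is axis 0 (rows) everywhere — a single global
  constant, never a per-call option.
* Rigid transforms translate first, then rotate about the geometric
  image centre `((H−1)/2, (W−1)/2)`, with bilinear interpolation and
  zero fill.  The opposite order differs only at second order for the
  small motions simulated; the composed affine is applied in one
  interpolation pass.
* Translations are in millimetres, converted through the slice's pixel
  spacing (fixtures use 1 mm/px so ±5 mm ≡ ±5 px).
* Corrupted spectra lose conjugate symmetry, so reconstruction after
  corruption takes the magnitude image — matching how MR magnitude
  images are displayed.
* Dice uses ε = 1e-6; BCE clips probabilities to [1e-7, 1−1e-7].  All
  loss reductions (BCE, L1, perceptual, DC) are **means** over elements
  rather than sums, so the λ weights transfer across image sizes; this
  is a deliberate normalisation of the summed notation.
* The networks run on a small reverse-mode autodiff engine over NumPy
  float64 arrays (`mrimoco.nn`).  The centred FFT is a differentiable
  primitive whose backward pass is its adjoint; the engine is gradient-
  checked against finite differences in the test suite.

## Motion sampling

Severity presets corrupt 5 (minor), 10 (moderate) or 15 (heavy) slabs of
3–7 PE lines, with θ ~ U(−7°, 7°) and tx, ty ~ U(−5, 5) mm, each slab
with an independent Θᵢ.  Slabs are sampled pairwise disjoint — the
splicing sum is ill-defined on overlaps, and disjointness gives every
corrupted line a unique owning event, which the tests exploit.
Placement draws widths first, assigns slabs to the free segments on
either side of the protected centre band, and positions them by a
uniform stars-and-bars composition of the leftover lines; on grids too
small to ever fit the request it fails with the required height.  On
small grids the width draw is conditioned on feasibility (at 256 lines
and above the presets are never truncated).

The central 8 % of PE lines are never corrupted (configurable).  The
low-frequency centre carries almost all image contrast; protecting it
mirrors how catastrophic, contrast-destroying corruptions are rare, and
those lines are correspondingly excluded from the ground-truth mask —
they are never wrong, so the detector should not be trained to flag
them.

## Perceptual loss

No pretrained backbone weights ship with the package, so the default
feature extractor `ϕ` is a three-stage convolutional network (widths
8/16/32, strides 1/2/2, leaky-ReLU) with **fixed random weights** drawn
from a seeded generator, and channel-unit-normalised activations as in
LPIPS.  Random convolutional features are a serviceable perceptual
metric for ranking distortions — the tests verify that at matched L2
distortion, high-frequency noise scores as perceptually worse than
Gaussian blur in ≥ 8 of 10 seeds.  The normalisation matters: without
it, high-amplitude edge responses drown out spatially distributed
distortions.  Pretrained weights can be injected through the ``state``
argument when available.

## Synthetic phantoms

Phantoms emulate the two features of an axial T1-weighted brain slice
that drive this task: a bright elliptical rim (subcutaneous fat — the
dominant ghosting source) at intensity 0.95 enclosing a piecewise-smooth
interior of 4–8 overlapping tissue ellipses around intensity ~0.35, on a
zero background, at 64–128 px.  Geometry is randomised per seed so the
detection task does not collapse to a template.  What they do *not*
model: anatomical detail, T1/T2 contrast physics, coil sensitivities,
noise, 3-D structure, or the intensity statistics of in-vivo data.
Passing tests therefore demonstrate that the algebra, the optimisation
and the architecture work — not clinical performance, which requires
training at full scale on real brain data.

## Scale presets

* ``full`` — batch 32, lr 2e-4, 25 epochs, Adam(0.9, 0.999): the
  configuration for full-size training on a real dataset.
* ``desk`` — 8 phantoms at 64×64, batch 4, 200 joint steps, lr 2e-3,
  seed 7; detector U-net depth 2/width 8; corrector depth 2/width 8,
  window 4, two Swin blocks per stage.  This is the overfit harness the
  test suite runs on one CPU in ~2 minutes.  The learning rate is
  raised an order of magnitude relative to the full-scale preset
  because a 200-step schedule cannot amortise 2e-4; the desk severity
  default is "moderate", the middle preset.  At this scale the
  expected behaviour (and what the acceptance tests assert) is:
  segmentation loss drops ≥ 10×, held-out line-mask Dice ≥ 0.8, and
  corrected-image PSNR exceeds corrupted-image PSNR by ≥ 3 dB.

The loss-ablation harness retrains the corrector under "L1 only",
"L1 + DC" and the full composite loss on identical data and seeds
(150 steps × 3 seeds at desk scale, heavy severity) and compares
per-image test metrics; the directional expectation is that the full
loss does not do worse in NMSE than L1 alone.

## Evaluation choices

* PSNR at data range 1.0, capped at 100 dB so perfect reconstructions
  aggregate finitely.
* SSIM with the Gaussian 11×11, σ = 1.5 window, K1 = 0.01, K2 = 0.03,
  sample-covariance correction — verified against scikit-image to 1e-4.
* NMSE = ‖x̂ − x‖² / ‖x‖² × 100 (percent).  NMSE conventions vary; this
  package uses the squared-norm ratio, stated here explicitly.
* Group summaries: 95 % bootstrap CIs of the mean — percentile
  (vectorised resampling, implemented here) or BCa (delegated to
  ``scipy.stats.bootstrap``); BCa is the reporting default.  Between-
  method comparisons: one-way ANOVA, then Tukey HSD at α = 0.05
  (``scipy.stats.f_oneway`` / ``statsmodels``).  Metrics are aggregated
  per slice.

## Known limitations

* 2-D, single-coil, in-plane rigid motion only; no through-plane or
  non-rigid motion, no B0/spin-history effects, no continuous intra-line
  motion (events are assumed slower than the PE sampling rate).
* The Swin blocks apply the cyclic shift without the cross-boundary
  attention mask of the full-scale architecture; at desk window sizes
  windows cover a large fraction of the map and the approximation is
  immaterial, but a full-scale port should add the mask.
* The default perceptual metric uses random features; rankings are
  statistically reliable but individual values are not comparable to
  published LPIPS numbers.
* Desk-scale training deliberately overfits a handful of phantoms; its
  metrics characterise the optimisation machinery, not generalisation.
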