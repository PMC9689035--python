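# Methods

## Neuron model

Units follow a normalised Hodgkin–Huxley-style membrane equation. Per
simulation step (`dt = 1`, capacitance `C = 1`):

```
I_ion = g_Na·m³·h·(U − E_Na) + g_K·n⁴·(U − E_K) + g_L·(U − E_L)
Uᵗ    = Uᵗ⁻¹ + (dt/C)·(I_syn − I_ion) − spikeᵗ⁻¹·V_th
spikeᵗ = 1[Uᵗ > V_th]
```

* **Soft reset.** Subtracting `V_th` (rather than resetting to a constant)
  conserves super-threshold charge: with sub-threshold constant drive `c`
  the k-th spike falls exactly at step `⌊k·V_th/c⌋ + 1`; with `c > V_th`
  the unit fires every step while the membrane keeps climbing. Both regimes
  are property-tested. The stored state is the *pre-reset* potential; the
  previous step's spike flag carries the reset into the next update.
* **Strict threshold.** `U = V_th` exactly does not fire. Long-horizon
  trajectories at currents that make `k·V_th/c` integral are numerically
  ill-conditioned (a float rounding decides the step); tests keep ≥0.01
  clearance from such crossings.
* **Gating variables.** The literature the model descends from does not fix
  `dm/dt, dn/dt, dh/dt`. We implement first-order relaxation toward
  sigmoidal steady states (`m, n` activation, `h` inactivation, midpoint
  0.25, slope 0.1) at a configurable rate, with **rate 0 as the default**:
  gates frozen at `m = h = 1, n = 0.5`. The network layers use this static
  form, so the effective ion-channel term is a configurable leak.
* **Defaults.** `V_th = 0.5`, `a₁ = 1`, `g_Na = g_K = 0`, `g_L = 0.1`,
  `E_L = 0`. All quantities are dimensionless and sized for convolution-scale
  inputs; the full conductance form stays available through `NeuronParams`.
* **LIF baseline.** `Uᵗ = λ·Uᵗ⁻¹·(1 − spikeᵗ⁻¹) + I_syn` with hard reset to
  zero and decay `λ = 0.5`, used for the neuron-model comparison.

## Surrogate gradients

The forward pass emits hard binary spikes everywhere. The backward pass
replaces the spike derivative by the rectangle `(1/a₁)·1[|U − V_th| < a₁/2]`
(unit integral for every `a₁`), including through the reset pathway. For
verification the spiking layers expose a `relaxed` diagnostic mode in which
the step function becomes its integral, the ramp
`clip((U − V_th)/a₁ + ½, 0, 1)`; the rectangle is that ramp's exact
derivative, so central finite differences on the relaxed forward check every
hand-written backward in the chain (asserted to 1e-4 relative error in
float64).

## Architecture

Channel plan 24→48→96→192→384 in the contracting path (SC modules double
width by concatenating their input), pyramid pooling with bins 1/2/3/6 and
96-channel branches (768 channels before the 1×1 compression), and a mirrored
decoder. The expansive-path widths are not dictated by the channel
arithmetic; the defaults **(232, 116, 58, 29)** are calibrated once so that
the default network stores 16.745 MB of float32 parameters (4,186,265
parameters × 4 bytes), matching the published ≈16.6 MB budget to within 1%.
Upsampling is bilinear throughout; there are no transposed convolutions and
no batch normalisation.

Two value-lattice facts follow from the printed architecture and are asserted
rather than idealised away: 2×2 *average* pooling maps binary spikes onto
quarter-integer values, and the SC identity branch forwards those pooled
activations unchanged, so stage-s skip tensors live on the `4⁻ˢ` lattice
while every RGC-processed output remains exactly binary. Inside the pyramid
pooling module activations are real-valued (pooled averages); its compressed
output re-enters the spiking regime through an RGC layer. The final
prediction convolution accumulates real-valued class evidence per step —
cross-entropy needs continuous predictions — and rate decoding takes the
argmax of the time-summed evidence with ties broken toward class 0.

## Training

Adam (β₁ = 0.9, β₂ = 0.999) on the softmax cross-entropy of time-summed
evidence, mean over pixels and batch. The published configuration is
lr = 1e-4 for 1000 epochs at 256×256; `TrainConfig` keeps that default.
Desk-scale experiments (reduced widths, 64×64, tens of epochs) use
**lr = 1e-3 and batch size 4**: 1e-4 is sized for thousand-epoch schedules
(a 3e-3 probe collapses the segmenter onto the constant majority-class
predictor, so the rate cannot simply be scaled with the epoch budget), and
with only ~10³ updates available the smaller batch buys twice the Adam
steps per epoch at equal wall cost. Colour jitter is re-drawn per image per
batch during training (one of brightness/contrast/saturation/sharpness with
the offline factor ranges), in addition to the offline ×20 expansion; this
belongs to the clinical-photograph pipeline, so the synthetic desk-scale
experiments train on the generator's images as-is (`online_jitter=False`). All
randomness — initialisation, shuffling, jitter, synthetic data — flows from
a single seed; two runs with equal seeds produce bit-identical histories.

Numerical choices: the tape computes in float32 (float64 for gradient
checks); non-finite losses abort with a diagnostic rather than training
through NaNs; Adam's ε = 1e-8.

## Data pipeline

Masks use class 0 = burn, class 1 = non-burn. Offline augmentation expands
each image exactly 20-fold: 5 geometric variants (original + 4 random
flip/translate ±100 px/rotate ±90° copies; masks nearest-neighbour, borders
fill with background class 1) × 4 photometric variants (one per jitter type,
factor 1 = identity, brightness/contrast in [0.5, 1.5], saturation/sharpness
in [0, 2]), then in-place salt-and-pepper noise (density 0.01) and, with
probability 0.5, one zeroed 16×16 patch — the noise geometry is not specified
in the source configuration, so both are exposed as policy fields.
Photometric ops are computed in float RGB (PIL-compatible semantics:
luminance-anchored contrast/saturation, box-blur-anchored sharpness) so that
factor 1 is an exact identity. Balanced cropping scores candidate windows by
`min(class-0 share, class-1 share)` and picks disjoint windows greedily,
falling back to a regular grid for single-class images.

## Synthetic data

The generator emulates the gross statistics of clinical burn photographs:
per-image skin tone drawn from a broad RGB range with low-frequency texture,
1–3 lesions as ellipses whose boundary radius is perturbed by a 4-mode
random Fourier series, recoloured toward red-brown with a difficulty knob
(0.35) pulling lesion colour toward the skin tone, and Gaussian pixel noise
(σ = 0.02). Default lesion radii (0.12–0.30 of image size) put the class-0
share near 0.2–0.3, so a constant predictor cannot reach the desk-scale
pixel-accuracy bar. What it does **not** model: specular highlights, depth
heterogeneity within a wound, occlusion, clothing/background clutter, or
annotation noise — passing tests demonstrate that the architecture and
training machinery work, not clinical performance.

The digit generator (seven-segment glyphs, sub-pixel shifts, amplitude
jitter, Gaussian noise on 16×16 canvases) is a self-contained stand-in for
the standard digit/event datasets used in the neuron-model comparison, which
cannot be downloaded at build time.

## Problem sizes for the bundled experiments

The acceptance-style tests run the full-width network only for shape and
size checks; learning experiments use the reduced plan (8, 16, 32, 64, 128)
at 64×64 with 8 time steps — 200 training / 40 test synthetic images, at
most 30 epochs with early stopping at PA 0.85 — and the neuron-model
comparison trains the benchmark "MNIST" topology (width 16) on 1000
synthetic digits for 10 epochs across three seeds (the RGC variant trails
the LIF baseline early in training and overtakes it around epoch 8–10, so
shorter schedules misrepresent the converged comparison). These sizes are the
package's desk-scale defaults; scaling up is a matter of configuration.

## Known limitations

* The published gating kinetics and conductance values are not reproduced
  (unavailable); the static-gate default is a documented stand-in.
* PPM internals and pooled transitions are analog by construction; a purely
  binary pipeline would need max-pooling and spiking pyramid branches.
* The single-file checkpoint stores float64 copies of float32-trained
  weights; cross-platform bit-reproducibility is guaranteed only per
  BLAS build.
* No learning-rate schedules, mixed precision, or distributed training.
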