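# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments can show. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Speckle model

Speckle is modelled as multiplicative uniform noise,
`Y = X (1 + sqrt(12 σ) u)` with `u ~ U(−0.5, 0.5)`, so the factor
`N = sqrt(12 σ) u` has zero mean and variance exactly σ. Consequences used
throughout the tests: on a constant image `X ≡ a` the corruption variance is
`a² σ`, and an all-zero image is a fixed point of the model. The noisy image
is *not* clipped to [0, 1] by default — clipping would truncate the
distribution and break the closed-form variance checks — but an explicit
`clip=True` exists for writing to integer containers. Every noise field is a
pure function of `(image shape, NoiseSpec)`, with one private RNG stream per
call and no global state.

**Intensity vs. noise level.** The intensity parameter σ is the variance of
the multiplicative factor, not the standard deviation of the image-domain
noise; those are related by `std = sqrt(mean(X²) σ)`. The denoiser's
`sigma` parameter *is* an image-domain noise level, so every harness that
knows the speckle intensity of its input converts it with
`speckle_equivalent_sigma(noisy, σ)` (using the noisy image itself as the
second-moment estimate, which is slightly conservative and needs no ground
truth). Skipping this conversion under-states the noise at small σ —
during development this surfaced as a non-monotone quality-vs-intensity
curve — and is the most likely user error when driving `denoise()` by hand.

## The iterative WNNM denoiser

One outer iteration performs, in order:

1. **Residual feedback** `x_in = x + δ (y − x)` with δ = 0.1, re-injecting
   a fraction of the original noisy image (first iteration: `x_in = y`).
2. **Block matching** (refreshed every `match_every` iterations): for each
   reference anchor, all patch anchors within a window of half-side R
   around it are scored by mean squared difference; the K − 1 closest join
   the reference, ties broken by raster order so results are
   platform-independent. Anchors near the border are clamped ("edge
   snapping"), and the last row/column anchor is always emitted so every
   pixel is covered at any stride.
3. **Per-stack noise update**
   `σ_stack = sqrt(λ max(σ² − mean((y_stack − x_stack)²), 0))` with
   λ = 0.56: variance already removed in earlier iterations is subtracted
   from the assumed level.
4. **Weighted shrinkage** of each stack's singular values with
   `wᵢ = intensity · C √K σ_stack² / (σ̂ᵢ + ε)`, C = 2√2, ε = 1e−16. The
   stack mean is not subtracted before the decomposition; rank deficiency
   and clean stacks are handled by the `max(·, 0)` clamps (a stack with
   σ_stack = 0 passes through unchanged, exactly).
5. **Collaborative aggregation**: every output pixel is the uniform average
   of all denoised patch values covering it. (An aggregate of *unmodified*
   stacks reproduces the image up to one ulp — averaging m identical
   doubles is not bit-exact for general m — which is why `denoise()` with
   `sigma = 0` short-circuits to return its input verbatim.)

Default iteration count is 8. The constants C, ε, λ, δ and the iteration
count follow the established weighted-nuclear-norm denoising practice; none
is hard-coded — all live in `WNNMConfig`.

**Presets.** The differences between `baseline` and `tuned` are exactly the
ones that define the tuned variant: stride 2 → 1 (a patch per pixel),
matching every 2nd iteration → every iteration, and a larger search window
and stack. The concrete sizes (tuned: patch 7, window half-side 14, stack
32; baseline: patch 7, window 10, stack 24) are this package's desk-scale
choice: they keep a full 5-phantom × 4-intensity × 3-seed evaluation grid
at 96×96 within minutes on one CPU while preserving every directional
relationship between the presets. Larger windows/stacks buy small quality
gains at steep cost (runtime grows ~linearly in window area and ~quadratic
in stack size via the eigendecomposition).

**Denoising intensity.** `intensity_scale` multiplies all shrinkage
weights; the shipped levels are low = 0.8, medium = 1.0, high = 1.3. Only
the ordering is meaningful: raising it removes more noise and residual
energy ‖y − x̂‖² grows monotonically, at the price of mild blurring.

**Implementation.** The reference implementations of matching, shrinkage
and aggregation live in `patch_match.py`/`wnnm.py` as plain NumPy; the
iterative loop runs numerically equivalent numba kernels (`_kernels.py`)
that (a) score each window displacement for all references at once via
separable box sums of the squared-difference image, keeping the K best per
reference with a bounded max-heap, and (b) shrink through the
eigendecomposition of the K×K Gram matrix, whose nonzero eigenvalues are
the squared singular values of the stack. Equivalence is asserted by the
test suite; the only caveat is that *mathematically tied* distances can be
ordered differently by the two paths when different float summation orders
round them apart (relevant only for adversarially quantised images; ties
between bit-identical patches agree exactly).

## Metrics

PSNR is `10 log10(range²/MSE)` with `range = 1` on the internal scale (the
identity `PSNR([0,1], range 1) = PSNR(×255, range 255)` is tested). SSIM
uses the original defaults: 11×11 Gaussian-weighted window (sd 1.5),
k₁ = 0.01, k₂ = 0.03, population (weighted) statistics, mean over valid
window positions; a uniform window is selectable. Metrics are computed on
unclipped float images by default. `evaluate_grid` corrupts → denoises →
scores over a σ×seed grid and reports per-σ means as a DataFrame/CSV.

## Phantoms

Three deterministic families stand in for anatomical districts: `layers`
(4–7 smooth horizontal bands with gently undulating sharp interfaces and a
weak sinusoidal shading — muscle-like), `ellipses` (3–6 bright/dark
inclusions on a weakly textured background — organ-like), and `checker`
(an exact two-valued grid for analytic edge tests; with contrast 1 its
histogram is exactly {0, 1}). Every phantom is a pure function of its
`PhantomSpec`. The default evaluation suite is two `layers`, two
`ellipses` and one `checker` phantom at 96×96 with contrast 0.8.

**What passing these experiments does and does not show.** The phantoms
are nearly piecewise-constant and thus closer to low-rank than real tissue:
absolute PSNR/SSIM figures here say nothing about clinical images, and the
trends (quality degrading with σ, tuned ≥ baseline at high noise) are the
meaningful outputs. Real ultrasound additionally has log-compressed
Rayleigh envelope statistics, scan-conversion geometry and depth-dependent
gain, none of which the uniform multiplicative surrogate reproduces.

## Surrogate network

A U-Net-style encoder–decoder: `depth` stride-2 4×4 convolutions
(leaky-ReLU 0.2, filters `min(base·2ⁱ, max)`) mirrored by stride-2 4×4
transposed convolutions (ReLU) with skip concatenations; the final stage is
linear and predictions are clamped to [0, 1]. There are no normalisation
layers — inputs are already on [0, 1] and their absence keeps single-image
prediction trivially deterministic. Forward pass and gradients are
hand-written on NumPy arrays (the 16 kernel-offset slices of a strided
convolution, each a `tensordot`), verified against numerical
differentiation and the conv/transposed-conv adjoint identity in the tests.

Training: Adam (lr 2e−3, β = 0.9/0.999), batch size 4, masked MAE — the
mask marks the original image region inside the zero-padded square canvas,
so padded pixels contribute neither loss nor gradient (growing the canvas
of a fixed model leaves the loss unchanged; tested). A validation split
(10% of the pairs by default) is scored each epoch; training stops when it
has not improved for `patience` consecutive epochs (defaults: `epochs_max`
200, `patience` 5) and the best-validation snapshot is returned. The
validation scorer is injectable, which is how the early-stopping contract
is unit-tested. Training is a pure function of `(TrainingSet, arch,
hyperparameters, seed)`.

Profiles: `tiny` (depth 2, filters 8→32, 64 px canvas) is the desk-scale
workhorse; `small` (depth 3) an intermediate; `full` carries the
full-scale constants (10 paired stages, 4×4 kernels, stride 2, filters
32→512). Ten stride-2 halvings are geometrically impossible on a 600 px
canvas, so the `full` profile pads to 1024; it is constructible and
save/load-able but not meant to be trained in this repository's tests.

Training pairs are (noisy phantom, tuned-WNNM output) — the denoiser's
output plays the role of ground truth, exactly as in the intended clinical
workflow where no clean reference exists. The district-specialisation
experiment (train on one phantom family, test on another) reproduces the
qualitative finding that a family-specific surrogate tracks its denoiser
better than a cross-family one.

## Problem sizes used by the shipped experiments

Denoising grids run on the five-phantom suite at 96×96 over
σ ∈ {0.05, 0.1, 0.2, 0.3} (three noise seeds in the tests, one in the
acceptance script); the tuned-vs-baseline comparison uses σ = 0.3 and two
seeds. The surrogate experiment uses 40 pairs of 64×64 `layers` phantoms
at σ = 0.1 (32 train / 8 held-out), tiny profile, `epochs_max` 80,
`patience` 8. These sizes are the package's own defaults for a
single-CPU desk-scale study.

## Known limitations

- The multiplicative-uniform model is a surrogate for physical speckle
  formation; no envelope statistics, no log compression.
- The denoiser assumes one scalar noise level per image (after the
  intensity conversion); strongly depth-dependent noise would need a
  spatially varying σ.
- Aggregation uses uniform patch weights; the optional inverse-residual
  weighting is exposed but not the default.
- The surrogate is a pure regressor: no adversarial term, so its outputs
  are smoother than a GAN-trained generator's would be.
- Absolute metric values on phantoms do not transfer to clinical images
  (see above); only trends are asserted.
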