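# uswnnm — tuned-WNNM despeckling for ultrasound-like images

Ultrasound acquisition corrupts images with *speckle*: signal-dependent,
multiplicative granular noise that degrades both visual reading and every
downstream step (segmentation, feature extraction, quantitative analysis).
`uswnnm` implements a patch-based low-rank despeckling pipeline for
single-channel 2D images, together with the synthetic speckle model used to
evaluate it, PSNR/SSIM scoring, and a small learned surrogate network that
replicates the slow iterative filter in a single forward pass — the route to
real-time denoising on clinical hardware.

## The method

**Noise model.** A clean image X on the [0, 1] scale is corrupted as

    Y(x) = X(x) + N(x) X(x),   N(x) = sqrt(12 σ) u(x),   u ~ U(−0.5, 0.5)

so the multiplicative factor N has zero mean and variance σ (the *noise
intensity*). Note that σ is **not** an additive noise standard deviation;
the image-domain equivalent is `sqrt(mean(X²) σ)` and
`speckle_equivalent_sigma()` performs that conversion before the denoiser is
invoked.

**Weighted nuclear norm minimisation (WNNM).** For every reference patch
P_x (7×7 by default) the K most similar patches inside a bounded search
window are found by block matching (mean squared difference, raster-order
tie-break) and vectorised into a p²×K stack matrix. Each stack is denoised
by the closed-form minimiser of

    ½ ‖Y − X‖²_F + Σᵢ wᵢ σᵢ(X)      (weights wᵢ non-descending)

which is U·diag(max(σᵢ − wᵢ, 0))·Vᵀ on the stack's SVD. The weights

    wᵢ = intensity · C √K σ_stack² / (σ̂ᵢ + ε),   σ̂ᵢ = sqrt(max(σᵢ² − K σ_stack², 0))

put large penalties on the small, noise-dominated singular values and barely
touch the large, structure-carrying ones. Denoised patches are aggregated
back by collaborative (weighted-average) filtering, and the whole procedure
is iterated with residual feedback `x ← x + δ(y − x)` and per-stack noise
re-estimation. The scalar `intensity` exposes the clinical low/medium/high
denoising-strength control.

**Presets.** `preset("baseline")` places a reference patch every second
pixel and refreshes the matching every second iteration;
`preset("tuned")` assigns a patch to *every* pixel, re-matches *every*
iteration, and uses a larger search window and stack — the configuration
specialised for speckle-laden ultrasound-like data.

**Surrogate.** Because the iterative filter is far from real time, a U-Net
style encoder–decoder (4×4 kernels, stride 2, skip connections) is trained
by masked mean-absolute-error regression on (raw, tuned-WNNM-denoised)
pairs, with zero-padding + masking to handle arbitrary resolutions and
early stopping on a validation split. Prediction is a single deterministic
forward pass. The network and its gradients are implemented directly on
NumPy arrays; the `tiny` profile trains on a desktop CPU in under a minute.

No clinical data are required: `make_phantom()` generates deterministic
ultrasound-like phantoms (layered tissue bands, elliptic inclusions, an
analytic checkerboard) and the noise model corrupts them at any intensity.

## Worked example

```python
import numpy as np
from uswnnm import (PhantomSpec, NoiseSpec, make_phantom, add_speckle,
                    preset, psnr, ssim, speckle_equivalent_sigma)
from uswnnm.wnnm import denoise, with_sigma

clean = make_phantom(PhantomSpec("layers", (96, 96), seed=11))
noisy = add_speckle(clean, NoiseSpec("speckle", sigma=0.1, seed=1))

cfg = preset("tuned", "medium", 0.1)
cfg = with_sigma(cfg, speckle_equivalent_sigma(noisy, 0.1))
out = denoise(noisy, cfg)

print(f"PSNR noisy    {psnr(clean, noisy):5.2f} dB   SSIM {ssim(clean, noisy):.3f}")
print(f"PSNR denoised {psnr(clean, out):5.2f} dB   SSIM {ssim(clean, out):.3f}")
```

prints

```
PSNR noisy    14.54 dB   SSIM 0.180
PSNR denoised 27.16 dB   SSIM 0.898
```

i.e. the tuned filter recovers ≈12.6 dB on this phantom at intensity
σ = 0.1 and lifts the structural similarity from 0.18 to 0.90 (the
variance-matched noise level fed to the denoiser here is
`speckle_equivalent_sigma(noisy, 0.1) ≈ 0.197`). The same pipeline is
available from the shell:

```bash
uswnnm phantom --kind layers --size 96x96 --seed 11 -o clean.tiff
uswnnm corrupt --sigma 0.10 --seed 1 -i clean.tiff -o noisy.tiff
uswnnm denoise -i noisy.tiff -o out.tiff --preset tuned --intensity medium --sigma 0.197
uswnnm evaluate --sigmas 0.05,0.1,0.2,0.3 --seeds 1,2,3 -o report.csv
```

and the surrogate workflow is `uswnnm make-dataset` → `uswnnm train` →
`uswnnm predict`.

## Determinism

The denoiser contains no randomness at all; phantoms, noise fields and
surrogate training are pure functions of their seeds. Outputs are
bit-identical across runs on one machine; across platforms they are
reproducible up to floating-point differences in BLAS/LAPACK kernels.
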