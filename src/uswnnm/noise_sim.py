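"""Synthetic noise models for corrupting ground-truth images.

Speckle is modelled as signal-dependent multiplicative noise

    Y(x) = X(x) + N(x) X(x),    N(x) = sqrt(12 sigma) u(x),  u ~ U(-0.5, 0.5)

so that Var(N) = 12 sigma / 12 = sigma: on a constant image X = a the
corruption has variance a^2 sigma.  An additive zero-mean Gaussian model with
standard deviation sigma is provided as the usual alternative.

By default the noisy image is NOT clipped to [0, 1], which keeps the sampling
distribution exact (variance checks close in closed form); pass ``clip=True``
when the output is destined for an integer container.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from uswnnm.imaging_io import as_image

NoiseFamily = Literal["speckle", "gaussian"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise family, intensity and RNG seed.

    The noise field is a pure function of the image shape and this spec: the
    same spec applied to same-shaped images yields the identical field.
    """

    family: NoiseFamily
    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("speckle", "gaussian"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.sigma < 0:
            raise ValueError(f"noise intensity sigma must be >= 0, got {self.sigma}")


def add_speckle(img: np.ndarray, spec: NoiseSpec, clip: bool = False) -> np.ndarray:
    """Corrupt ``img`` with multiplicative uniform speckle of intensity sigma."""
    if spec.family != "speckle":
        raise ValueError(f"add_speckle requires family='speckle', got {spec.family!r}")
    img = as_image(img)
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(-0.5, 0.5, size=img.shape)
    out = img * (1.0 + np.sqrt(12.0 * spec.sigma) * u)
    return np.clip(out, 0.0, 1.0) if clip else out


def add_gaussian(img: np.ndarray, spec: NoiseSpec, clip: bool = False) -> np.ndarray:
    """Corrupt ``img`` with additive zero-mean Gaussian noise of sd sigma."""
    if spec.family != "gaussian":
        raise ValueError(f"add_gaussian requires family='gaussian', got {spec.family!r}")
    img = as_image(img)
    rng = np.random.default_rng(spec.seed)
    out = img + rng.normal(0.0, spec.sigma, size=img.shape)
    return np.clip(out, 0.0, 1.0) if clip else out


def speckle_equivalent_sigma(img: np.ndarray, intensity: float) -> float:
    """Image-domain noise standard deviation equivalent to a speckle intensity.

    The multiplicative model has per-pixel variance ``X(x)^2 * intensity``:
    the intensity parameter is not itself a standard deviation.  A denoiser
    that assumes a single additive noise level should be given the
    variance-matched value ``sqrt(mean(img^2) * intensity)``; passing the
    (noisy) image itself gives a slightly conservative estimate without
    needing the ground truth.
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    return float(np.sqrt(np.mean(np.square(np.asarray(img, dtype=np.float64))) * intensity))


def corrupt(img: np.ndarray, spec: NoiseSpec, clip: bool = False) -> np.ndarray:
    """Dispatch to the noise model named by ``spec.family``."""
    if spec.family == "speckle":
        return add_speckle(img, spec, clip=clip)
    return add_gaussian(img, spec, clip=clip)
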