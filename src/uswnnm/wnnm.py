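"""Weighted nuclear norm minimisation (WNNM) denoising of patch stacks.

Each stack of similar patches is treated as a low-rank matrix corrupted by
noise: its singular values are soft-thresholded with value-dependent weights
(large weights on the small, noise-dominated singular values), the shrunken
stacks are aggregated collaboratively, and the whole procedure is iterated
with a residual feedback step that re-injects a fraction of the original
noisy image before each pass.

Two presets are shipped.  The *baseline* preset places a reference patch
every second pixel and refreshes the block matching every second iteration;
the *tuned* preset assigns a patch to every pixel, re-matches every
iteration, and uses a larger search window and stack — the configuration
that specialises the method to speckle-laden ultrasound-like images.  A
scalar *denoising intensity* multiplies the shrinkage weights, trading noise
removal against blurring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from uswnnm import _kernels
from uswnnm.imaging_io import as_image
from uswnnm.patch_match import MatchConfig, reference_anchors


@dataclass(frozen=True)
class IntensityLevel:
    """A named denoising-intensity setting; ``scale`` multiplies the
    singular-value shrinkage weights."""

    name: Literal["low", "medium", "high"]
    scale: float


#: The three denoising intensities offered to the operator, ordered
#: low < medium < high in threshold strength.
INTENSITY_LEVELS: dict[str, IntensityLevel] = {
    "low": IntensityLevel("low", 0.8),
    "medium": IntensityLevel("medium", 1.0),
    "high": IntensityLevel("high", 1.3),
}


@dataclass(frozen=True)
class WNNMConfig:
    """All tunable parameters of the iterative denoiser.

    match:
        Block-matching geometry (patch size, stride, window, stack size).
    iterations:
        Number of outer iterations.
    match_every:
        Iterations between block-matching refreshes (1 = every iteration).
    sigma:
        Assumed noise intensity on the [0, 1] image scale.
    intensity_scale:
        Multiplier on the singular-value threshold weights (the denoising
        intensity); larger removes more noise at the cost of mild blurring.
    weight_const:
        Constant C of the weight formula ``w_i = C sqrt(K) s^2 / (sv_i + eps)``.
    weight_eps:
        Small positive stabiliser in the weight denominator.
    feedback:
        Residual feedback fraction delta in [0, 1]: each iteration starts
        from ``x + delta (y - x)``.
    noise_rescale:
        Factor lambda of the per-stack noise update
        ``sigma_stack = sqrt(lambda * max(sigma^2 - mean residual^2, 0))``.
    """

    match: MatchConfig = field(default_factory=MatchConfig)
    iterations: int = 8
    match_every: int = 1
    sigma: float = 0.1
    intensity_scale: float = 1.0
    weight_const: float = 2.0 * math.sqrt(2.0)
    weight_eps: float = 1e-16
    feedback: float = 0.1
    noise_rescale: float = 0.56

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.match_every < 1:
            raise ValueError("match_every must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be > 0")
        if not (0.0 <= self.feedback <= 1.0):
            raise ValueError("feedback must be in [0, 1]")
        if self.weight_eps <= 0:
            raise ValueError("weight_eps must be > 0")
        if self.noise_rescale < 0:
            raise ValueError("noise_rescale must be >= 0")


def preset(
    name: Literal["baseline", "tuned"],
    level: IntensityLevel | str = "medium",
    sigma: float = 0.1,
) -> WNNMConfig:
    """Build the baseline or tuned configuration at a denoising intensity.

    The tuned preset assigns a reference patch to every pixel (stride 1),
    refreshes the block matching every iteration, and enlarges the search
    window and the stack relative to the baseline (stride 2, matching every
    second iteration).
    """
    if isinstance(level, str):
        try:
            level = INTENSITY_LEVELS[level]
        except KeyError:
            raise ValueError(f"unknown intensity level {level!r}") from None
    if name == "tuned":
        match = MatchConfig(patch_size=7, stride=1, window_radius=14, stack_size=32)
        match_every = 1
    elif name == "baseline":
        match = MatchConfig(patch_size=7, stride=2, window_radius=10, stack_size=24)
        match_every = 2
    else:
        raise ValueError(f"unknown preset {name!r}")
    return WNNMConfig(
        match=match,
        match_every=match_every,
        sigma=sigma,
        intensity_scale=level.scale,
    )


def wnnm_shrink(stack_matrix: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted singular-value soft-thresholding of a stack matrix.

    For non-descending ``weights`` paired with the descending singular
    values, returns ``U diag(max(s_i - w_i, 0)) V^T`` — the closed-form
    minimiser of ``1/2 ||Y - X||_F^2 + sum_i w_i s_i(X)``.
    """
    stack_matrix = np.asarray(stack_matrix, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    n_sv = min(stack_matrix.shape)
    if weights.shape != (n_sv,):
        raise ValueError(
            f"expected {n_sv} weights for a {stack_matrix.shape} matrix, "
            f"got {weights.shape}"
        )
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(np.diff(weights) < 0):
        raise ValueError("weights must be non-descending")
    if not weights.any():
        return stack_matrix.copy()
    u, s, vt = np.linalg.svd(stack_matrix, full_matrices=False)
    s_shrunk = np.maximum(s - weights, 0.0)
    return (u * s_shrunk) @ vt


def default_weights(
    singular_values: np.ndarray, sigma_stack: float, K: int, cfg: WNNMConfig
) -> np.ndarray:
    """Noise-adaptive shrinkage weights for one stack.

    ``w_i = intensity_scale * C * sqrt(K) * sigma_stack^2 / (sv_i + eps)``
    with ``sv_i = sqrt(max(s_i^2 - K sigma_stack^2, 0))`` the estimate of the
    i-th *signal* singular value.  Small singular values (noise-dominated)
    receive large weights; the result is non-descending for descending input.
    """
    s = np.asarray(singular_values, dtype=np.float64)
    if sigma_stack < 0:
        raise ValueError("sigma_stack must be >= 0")
    sv = np.sqrt(np.maximum(s**2 - K * sigma_stack**2, 0.0))
    return (
        cfg.intensity_scale
        * cfg.weight_const
        * np.sqrt(K)
        * sigma_stack**2
        / (sv + cfg.weight_eps)
    )


def update_stack_sigma(
    noisy_stack: np.ndarray, denoised_stack: np.ndarray, cfg: WNNMConfig
) -> float:
    """Re-estimate the residual noise level of a stack between iterations.

    The variance already removed from the stack (the mean squared residual
    against the original noisy values) is subtracted from the assumed noise
    variance and rescaled by ``noise_rescale``.
    """
    if noisy_stack.shape != denoised_stack.shape:
        raise ValueError("noisy and denoised stacks must have the same shape")
    msr = float(np.mean((np.asarray(noisy_stack) - np.asarray(denoised_stack)) ** 2))
    return float(np.sqrt(cfg.noise_rescale * max(cfg.sigma**2 - msr, 0.0)))


def denoise(y: np.ndarray, cfg: WNNMConfig) -> np.ndarray:
    """Run the full iterative WNNM denoiser on a noisy image.

    Each outer iteration applies residual feedback ``x <- x + delta (y - x)``,
    (re)computes the block matching on the fed-back image every
    ``match_every`` iterations, re-estimates each stack's noise level,
    shrinks the stack's singular values with :func:`default_weights`, and
    aggregates the denoised patches.  Entirely deterministic.

    With ``cfg.sigma == 0`` every weight is zero and the pipeline is the
    identity; the input is returned unchanged.
    """
    y = as_image(y)
    p = cfg.match.patch_size
    if y.shape[0] < p or y.shape[1] < p:
        raise ValueError(f"image {y.shape} smaller than patch size {p}")
    if cfg.sigma == 0.0:
        return y.copy()
    anchors = reference_anchors(y, cfg.match)
    refs_r = np.array([a[0] for a in anchors], dtype=np.int64)
    refs_c = np.array([a[1] for a in anchors], dtype=np.int64)
    x = y.copy()
    members = None
    for it in range(cfg.iterations):
        x_in = x + cfg.feedback * (y - x)
        if members is None or it % cfg.match_every == 0:
            members = _kernels.match_all(
                np.ascontiguousarray(x_in),
                refs_r,
                refs_c,
                p,
                cfg.match.window_radius,
                cfg.match.stack_size,
            )
        members_r, members_c, counts = members
        x = _kernels.shrink_and_aggregate(
            np.ascontiguousarray(x_in),
            np.ascontiguousarray(y),
            members_r,
            members_c,
            counts,
            p,
            cfg.sigma,
            cfg.weight_const,
            cfg.weight_eps,
            cfg.intensity_scale,
            cfg.noise_rescale,
        )
    return x


def with_sigma(cfg: WNNMConfig, sigma: float) -> WNNMConfig:
    """Copy ``cfg`` with a different assumed noise level."""
    return replace(cfg, sigma=sigma)


def speckle_denoiser(cfg: WNNMConfig, intensity: float):
    """Denoising callable for images carrying speckle of a known intensity.

    The multiplicative speckle intensity is not an additive noise standard
    deviation; each input is denoised with the variance-matched equivalent
    ``sqrt(mean(img^2) * intensity)`` substituted for ``cfg.sigma`` (see
    :func:`uswnnm.noise_sim.speckle_equivalent_sigma`).
    """
    from uswnnm.noise_sim import speckle_equivalent_sigma

    def run(img: np.ndarray) -> np.ndarray:
        return denoise(img, with_sigma(cfg, speckle_equivalent_sigma(img, intensity)))

    return run
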