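"""Patch extraction, search-window-restricted block matching, and
collaborative aggregation.

A *patch* is the ``p x p`` pixel neighbourhood anchored at its top-left
pixel; a *stack* (3D block) collects the ``K`` patches most similar to a
reference patch inside a bounded search window, vectorised as the columns of
an ``p^2 x K`` matrix.  Similarity is the mean squared intensity difference.
All coordinates are 0-based ``(row, col)``; patches are half-open
``[r, r+p) x [c, c+p)``.

These are the reference (pure NumPy) implementations; the iterative denoiser
in :mod:`uswnnm.wnnm` runs the numerically identical compiled kernels from
:mod:`uswnnm._kernels`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from uswnnm.imaging_io import as_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchConfig:
    """Block-matching geometry.

    patch_size:
        Side ``p`` of the square patch, odd, at least 3.
    stride:
        Pixels between consecutive reference anchors (1 = a patch per pixel).
    window_radius:
        Half-side of the square search window centred on the reference
        anchor; candidate anchors may deviate by at most this many pixels on
        each axis (the window is clipped at the image border).
    stack_size:
        Number of patches ``K`` kept per stack, reference included.
    """

    patch_size: int = 7
    stride: int = 1
    window_radius: int = 14
    stack_size: int = 32

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError(f"patch_size must be odd and >= 3, got {self.patch_size}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.window_radius < self.patch_size:
            raise ValueError(
                f"window_radius ({self.window_radius}) must be >= patch_size "
                f"({self.patch_size})"
            )
        if self.stack_size < 1:
            raise ValueError(f"stack_size must be >= 1, got {self.stack_size}")


@dataclass(frozen=True)
class Patch:
    anchor: tuple[int, int]
    size: int
    values: np.ndarray


@dataclass
class PatchStack:
    """A reference patch and its K most similar neighbours.

    ``matrix`` has shape ``(p^2, K)``: column ``k`` is the vectorised (row
    major) patch at ``members[k]``.  ``distances`` are non-decreasing and
    ``members[0]`` is the reference itself at distance 0.
    """

    ref_anchor: tuple[int, int]
    members: list[tuple[int, int]]
    matrix: np.ndarray
    distances: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def size(self) -> int:
        return len(self.members)


def reference_anchors(img: np.ndarray, cfg: MatchConfig) -> list[tuple[int, int]]:
    """Raster-order reference anchors at the configured stride.

    The last valid row/column anchor is always included ("edge snapping"), so
    every pixel of the image is covered by at least one reference patch.
    """
    img = as_image(img)
    h, w = img.shape
    p = cfg.patch_size
    if h < p or w < p:
        raise ValueError(f"image {img.shape} smaller than patch size {p}")
    rows = _snapped_positions(h - p, cfg.stride)
    cols = _snapped_positions(w - p, cfg.stride)
    return [(r, c) for r in rows for c in cols]


def _snapped_positions(last: int, stride: int) -> list[int]:
    pos = list(range(0, last + 1, stride))
    if pos[-1] != last:
        pos.append(last)
    return pos


def candidate_anchors(
    img_shape: tuple[int, int], ref: tuple[int, int], cfg: MatchConfig
) -> list[tuple[int, int]]:
    """All valid patch anchors inside the search window, raster order."""
    h, w = img_shape
    p, rad = cfg.patch_size, cfg.window_radius
    r0, r1 = max(0, ref[0] - rad), min(h - p, ref[0] + rad)
    c0, c1 = max(0, ref[1] - rad), min(w - p, ref[1] + rad)
    return [(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)]


def block_match(img: np.ndarray, ref: tuple[int, int], cfg: MatchConfig) -> PatchStack:
    """Build the stack of the K patches most similar to the reference.

    The reference is always first with distance 0; the remaining slots are
    the smallest mean-squared-difference candidates from the search window,
    ties broken by raster order of the candidate anchors.  If the window
    holds fewer than K candidates the stack is truncated (and logged).
    """
    img = as_image(img)
    h, w = img.shape
    p = cfg.patch_size
    if not (0 <= ref[0] <= h - p and 0 <= ref[1] <= w - p):
        raise ValueError(f"reference anchor {ref} does not fit a {p}x{p} patch")
    ref_patch = img[ref[0] : ref[0] + p, ref[1] : ref[1] + p]
    cands = candidate_anchors(img.shape, ref, cfg)
    others = [a for a in cands if a != ref]
    dists = np.array(
        [np.mean((img[r : r + p, c : c + p] - ref_patch) ** 2) for (r, c) in others]
    )
    order = np.argsort(dists, kind="stable")[: cfg.stack_size - 1]
    members = [ref] + [others[i] for i in order]
    distances = np.concatenate(([0.0], dists[order]))
    if len(members) < cfg.stack_size:
        logger.debug(
            "stack at %s truncated to %d of %d requested patches",
            ref,
            len(members),
            cfg.stack_size,
        )
    matrix = np.column_stack(
        [img[r : r + p, c : c + p].ravel() for (r, c) in members]
    )
    return PatchStack(ref_anchor=ref, members=members, matrix=matrix, distances=distances)


def aggregate(
    stacks: list[PatchStack],
    img_shape: tuple[int, int],
    stack_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Collaboratively aggregate (denoised) stacks back into an image.

    Every output pixel is the weighted average of all patch values covering
    it; each stack contributes with a single nonnegative scalar weight
    (uniform 1 by default).  Aggregating an image's own unmodified stacks
    reproduces the image (up to float rounding of the average).
    """
    if stack_weights is None:
        stack_weights = np.ones(len(stacks))
    num = np.zeros(img_shape)
    den = np.zeros(img_shape)
    for stack, w in zip(stacks, stack_weights):
        if w < 0:
            raise ValueError("stack weights must be nonnegative")
        p = int(round(np.sqrt(stack.matrix.shape[0])))
        for k, (r, c) in enumerate(stack.members):
            num[r : r + p, c : c + p] += w * stack.matrix[:, k].reshape(p, p)
            den[r : r + p, c : c + p] += w
    hole = den == 0
    if hole.any():
        r, c = np.argwhere(hole)[0]
        raise ValueError(f"coverage hole: pixel ({r}, {c}) is covered by no patch")
    return num / den
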