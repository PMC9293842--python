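"""Grayscale image I/O, normalisation, zero-padding with masks, and
synthetic ultrasound-like phantoms.

The internal image representation shared by every stage of the pipeline is a
2D ``float64`` array with values on the nominal [0, 1] scale (noisy images
may exceed it; see :mod:`uswnnm.noise_sim`).  Integer containers are
normalised on read by their nominal range (255 for 8-bit, 65535 for 16-bit)
and re-quantised on write.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)

PhantomKind = Literal["layers", "ellipses", "checker"]

_MIN_PHANTOM_SIDE = 16


def as_image(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce ``arr`` to the internal 2D float64 representation."""
    img = np.asarray(arr, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"image must be at least 1x1, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


@dataclass(frozen=True)
class PaddedImage:
    """A square zero-padded image together with the mask of the original region.

    ``pixels`` is an ``side x side`` array; ``mask`` is a boolean array of the
    same shape that is True exactly on the region occupied by the original
    image; ``origin`` is the (row, col) of that region's top-left corner.
    """

    pixels: np.ndarray
    mask: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask shapes differ")


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic recipe for a synthetic test image.

    Parameters
    ----------
    kind:
        ``"layers"`` — smooth horizontal tissue-like bands with sharp,
        gently undulating interfaces (muscle-like districts);
        ``"ellipses"`` — bright/dark elliptic inclusions on a weakly
        textured background (organ-like districts);
        ``"checker"`` — an analytic two-valued edge grid for oracle tests.
    size:
        (rows, cols), each at least 16.
    seed:
        Seed of the private RNG stream; the same spec always produces a
        bit-identical phantom.
    contrast:
        Intensity separation between structures, in (0, 1].
    """

    kind: PhantomKind
    size: tuple[int, int] = (128, 128)
    seed: int = 0
    contrast: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in ("layers", "ellipses", "checker"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if min(self.size) < _MIN_PHANTOM_SIDE:
            raise ValueError(f"phantom size must be at least 16x16, got {self.size}")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must be in (0, 1]")


def read_image(path: str | Path, bit_depth_hint: str | None = None) -> np.ndarray:
    """Read a single-channel PNG/TIFF and normalise it to [0, 1].

    Integer data are divided by the container's nominal range (255 or 65535);
    floating-point data are taken verbatim.  Multi-frame TIFFs are reduced to
    their first frame with a warning.  A multi-channel image whose channels
    are not identical is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[0] > 4 and data.shape[2] > 4:
        # multi-frame container: (frames, rows, cols)
        logger.warning("multi-frame image %s: reading only the first frame", path)
        data = data[0]
    if data.ndim == 3:
        if np.all(data == data[..., :1]):
            data = data[..., 0]
        else:
            raise ValueError(
                f"{path} has {data.shape[2]} non-identical channels; "
                "only grayscale images are supported"
            )
    if data.ndim != 2:
        raise ValueError(f"{path}: unsupported image dimensionality {data.ndim}")
    if data.dtype == np.uint8 or bit_depth_hint == "8":
        return data.astype(np.float64) / 255.0
    if data.dtype == np.uint16 or bit_depth_hint == "16":
        return data.astype(np.float64) / 65535.0
    if np.issubdtype(data.dtype, np.floating):
        return as_image(data)
    raise ValueError(f"{path}: unsupported pixel type {data.dtype}")


def write_image(
    img: np.ndarray,
    path: str | Path,
    depth: Literal["8", "16", "float32"] = "float32",
) -> None:
    """Write an image, quantising by the container's nominal range.

    ``depth="8"`` and ``"16"`` clip to [0, 1] and round to the integer grid;
    ``"float32"`` writes the values losslessly (TIFF only).
    """
    img = np.asarray(img, dtype=np.float64)
    path = Path(path)
    is_tiff = path.suffix.lower() in (".tif", ".tiff")
    if depth == "8":
        data = np.rint(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    elif depth == "16":
        data = np.rint(np.clip(img, 0.0, 1.0) * 65535.0).astype(np.uint16)
    elif depth == "float32":
        if not is_tiff:
            raise ValueError("float32 output requires a TIFF container")
        data = img.astype(np.float32)
    else:
        raise ValueError(f"unknown depth {depth!r}")
    if is_tiff:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def pad_to_square(img: np.ndarray, side: int) -> PaddedImage:
    """Zero-pad ``img`` into a ``side x side`` canvas, keeping a mask.

    The original image is placed at the top-left corner; everything outside
    is exactly zero.  :func:`unpad` inverts the operation bit-exactly.
    """
    img = as_image(img)
    h, w = img.shape
    if side < max(h, w):
        raise ValueError(f"pad side {side} smaller than image dimensions {img.shape}")
    pixels = np.zeros((side, side), dtype=np.float64)
    pixels[:h, :w] = img
    mask = np.zeros((side, side), dtype=bool)
    mask[:h, :w] = True
    return PaddedImage(pixels=pixels, mask=mask, origin=(0, 0))


def unpad(p: PaddedImage) -> np.ndarray:
    """Extract the original image region selected by the mask."""
    rows = np.flatnonzero(p.mask.any(axis=1))
    cols = np.flatnonzero(p.mask.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        raise ValueError("empty mask")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    if not p.mask[r0:r1, c0:c1].all() or p.mask.sum() != (r1 - r0) * (c1 - c0):
        raise ValueError("mask is not a contiguous rectangle")
    return p.pixels[r0:r1, c0:c1].copy()


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate a synthetic ultrasound-like test image from ``spec``.

    Pure function of the spec: the same spec always yields a bit-identical
    image.  Every kind contains at least one sharp intensity discontinuity so
    edge preservation is observable.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.size
    if spec.kind == "layers":
        img = _layers(rng, rows, cols, spec.contrast)
    elif spec.kind == "ellipses":
        img = _ellipses(rng, rows, cols, spec.contrast)
    else:
        img = _checker(rows, cols, spec.contrast)
    return np.clip(img, 0.0, 1.0)


def _layers(rng: np.random.Generator, rows: int, cols: int, contrast: float) -> np.ndarray:
    """Horizontal tissue-like bands with undulating sharp interfaces."""
    n_bands = int(rng.integers(4, 8))
    # band intensities centred on 0.5, spread by contrast, shuffled so
    # neighbouring bands differ
    levels = 0.5 + contrast * (np.linspace(-0.5, 0.5, n_bands))
    rng.shuffle(levels)
    boundaries = np.sort(rng.uniform(0.1, 0.9, n_bands - 1)) * rows
    phase = rng.uniform(0, 2 * np.pi, n_bands - 1)
    amp = rng.uniform(1.0, 3.0, n_bands - 1)
    period = rng.uniform(0.5, 1.5, n_bands - 1) * cols
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    img = np.full((rows, cols), levels[0])
    for k in range(n_bands - 1):
        edge = boundaries[k] + amp[k] * np.sin(2 * np.pi * c / period[k] + phase[k])
        img = np.where(r >= edge, levels[k + 1], img)
    # mild smooth within-band shading, well below the band contrast
    shade = 0.05 * contrast * np.sin(2 * np.pi * c / cols + rng.uniform(0, 2 * np.pi))
    return img + shade


def _ellipses(rng: np.random.Generator, rows: int, cols: int, contrast: float) -> np.ndarray:
    """Bright/dark elliptic inclusions on a weakly textured background."""
    base = 0.5
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (rows, cols)), sigma=3.0)
    texture *= 0.03 / max(texture.std(), 1e-12)
    img = base + texture
    n_ell = int(rng.integers(3, 7))
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    for k in range(n_ell):
        cy = rng.uniform(0.15, 0.85) * rows
        cx = rng.uniform(0.15, 0.85) * cols
        ay = rng.uniform(0.08, 0.25) * rows
        ax = rng.uniform(0.08, 0.25) * cols
        theta = rng.uniform(0, np.pi)
        dy, dx = r - cy, c - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        inside = (u / ay) ** 2 + (v / ax) ** 2 <= 1.0
        sign = 1.0 if k % 2 == 0 else -1.0
        img = np.where(inside, base + sign * contrast / 2, img)
    return img


def _checker(rows: int, cols: int, contrast: float) -> np.ndarray:
    """Exact two-valued checkerboard; with contrast 1 the values are {0, 1}."""
    cell = max(rows, cols) // 8
    cell = max(cell, 4)
    r = np.arange(rows)[:, None] // cell
    c = np.arange(cols)[None, :] // cell
    lo, hi = (1.0 - contrast) / 2.0, (1.0 + contrast) / 2.0
    return np.where((r + c) % 2 == 0, lo, hi).astype(np.float64)


def default_phantom_suite(
    size: tuple[int, int] = (128, 128), contrast: float = 0.8
) -> list[PhantomSpec]:
    """The five-phantom evaluation suite used by the benchmark harness."""
    return [
        PhantomSpec("layers", size, seed=11, contrast=contrast),
        PhantomSpec("layers", size, seed=12, contrast=contrast),
        PhantomSpec("ellipses", size, seed=21, contrast=contrast),
        PhantomSpec("ellipses", size, seed=22, contrast=contrast),
        PhantomSpec("checker", size, seed=31, contrast=contrast),
    ]
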