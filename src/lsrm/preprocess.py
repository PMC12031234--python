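"""Pre/post-processing chain applied around the unsupervised denoiser.

All operations take and return :class:`~lsrm.image_io.ImageSlice`, preserve
shape, and keep intensities inside the ``[0, 1]`` contract.  Edge handling is
reflect padding throughout for shift-invariance near borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage import exposure, morphology

from .image_io import ImageSlice

__all__ = [
    "subtract_background",
    "median_filter",
    "circular_roi_mask",
    "adaptive_hist_eq",
    "morph_refine",
    "bandpass_filter",
    "make_noise_pairs",
    "PreprocessConfig",
    "PostprocessConfig",
    "apply_preprocess",
    "apply_postprocess",
]


def _check_same_shape(a: ImageSlice, b: ImageSlice) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def subtract_background(image: ImageSlice, reference: ImageSlice) -> ImageSlice:
    """``clip(image - reference, 0, 1)`` against a reference background frame."""
    _check_same_shape(image, reference)
    out = np.clip(image.pixels - reference.pixels, 0.0, 1.0)
    return image.replace(pixels=out)


def median_filter(image: ImageSlice, kernel: int = 3) -> ImageSlice:
    """Square median filter with reflect edge handling; kernel must be odd."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be a positive odd integer, got {kernel}")
    out = ndi.median_filter(image.pixels, size=kernel, mode="reflect")
    return image.replace(pixels=out)


def circular_roi_mask(
    shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> np.ndarray:
    """Boolean disk mask; pixels with distance <= radius from the center.

    Defaults: center = geometric image center, radius = 0.45 * min(shape)
    (covers a 300-400 µm spheroid inside the 635 µm field of view).  The
    disk is cropped wherever it leaves the frame.
    """
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if radius is None:
        radius = 0.45 * min(h, w)
    if radius <= 0:
        raise ValueError("radius must be positive")
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def adaptive_hist_eq(
    image: ImageSlice,
    mask: np.ndarray | None = None,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> ImageSlice:
    """Contrast-limited adaptive histogram equalization inside a mask.

    Pixels outside the mask are returned unchanged.  Output stays in [0, 1].
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    h, w = image.shape
    kernel = (max(1, h // tile_grid[0]), max(1, w // tile_grid[1]))
    data = image.pixels.astype(np.float64)
    if data.max() == data.min():
        return image.replace(pixels=data.copy())
    eq = exposure.equalize_adapthist(
        np.clip(data, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit
    )
    if mask is not None:
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        eq = np.where(mask, eq, data)
    return image.replace(pixels=np.clip(eq, 0.0, 1.0))


def morph_refine(
    image: ImageSlice, op: str, structuring_radius: int = 1
) -> ImageSlice:
    """Grayscale morphology over a disk structuring element.

    ``dilate`` is the neighborhood max, ``erode`` the neighborhood min;
    ``open``/``close`` are the erode-dilate / dilate-erode compositions
    (opening removes bright speckle smaller than the disk without biasing
    smooth regions).
    """
    ops = {
        "dilate": (morphology.dilation,),
        "erode": (morphology.erosion,),
        "open": (morphology.erosion, morphology.dilation),
        "close": (morphology.dilation, morphology.erosion),
    }
    if op not in ops:
        raise ValueError(f"op must be one of {sorted(ops)}")
    if structuring_radius < 1:
        raise ValueError("structuring_radius must be >= 1")
    selem = morphology.disk(structuring_radius)
    out = image.pixels
    for fn in ops[op]:
        out = fn(out, footprint=selem)
    return image.replace(pixels=out)


def bandpass_filter(
    image: ImageSlice, low_cut: float, high_cut: float
) -> ImageSlice:
    """Radial annular mask in the 2D Fourier domain.

    Cutoffs are radial frequencies in cycles/image.  Frequencies with
    ``low_cut <= r <= high_cut`` are kept, so ``low_cut = 0`` retains the DC
    component while any positive ``low_cut`` rejects it.  The filtered real
    part is re-clipped to [0, 1].
    """
    if low_cut < 0 or high_cut <= low_cut:
        raise ValueError(f"need 0 <= low_cut < high_cut, got ({low_cut}, {high_cut})")
    h, w = image.shape
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    r = np.hypot(fy[:, None], fx[None, :])
    mask = (r >= low_cut) & (r <= high_cut)
    spectrum = np.fft.fft2(image.pixels)
    out = np.fft.ifft2(spectrum * mask).real
    return image.replace(pixels=np.clip(out, 0.0, 1.0))


def make_noise_pairs(
    image: ImageSlice, sigma: float, seed: int = 0
) -> tuple[ImageSlice, ImageSlice]:
    """Corrupted pair from a single shared Gaussian draw.

    Returns ``(clip(image + n, 0, 1), clip(image - n, 0, 1))`` with the same
    noise field ``n ~ Gaussian(0, sigma)`` added and subtracted, so before
    clipping the pair averages back to the input exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.normal(0.0, sigma, image.shape) if sigma > 0 else np.zeros(image.shape)
    plus = image.replace(pixels=np.clip(image.pixels + n, 0.0, 1.0))
    minus = image.replace(pixels=np.clip(image.pixels - n, 0.0, 1.0))
    return plus, minus


# ---------------------------------------------------------------------------
# configurable chains (each step individually switchable)


@dataclass
class PreprocessConfig:
    """Steps applied before denoising, in order: background subtraction,
    median filter, circular ROI, adaptive equalization, morphology."""

    background_subtraction: bool = True
    median_kernel: int | None = 3
    roi: bool = True
    roi_radius: float | None = None
    clahe: bool = False
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    morphology_op: str | None = "open"
    morphology_radius: int = 1


@dataclass
class PostprocessConfig:
    """Steps applied after denoising: band-pass filtering and morphology."""

    bandpass: bool = True
    bandpass_low: float = 0.0
    bandpass_high: float | None = None  # None -> 0.45 * min(shape)
    morphology_op: str | None = "open"
    morphology_radius: int = 1


def apply_preprocess(
    image: ImageSlice,
    config: PreprocessConfig,
    reference: ImageSlice | None = None,
) -> ImageSlice:
    out = image
    if config.background_subtraction and reference is not None:
        out = subtract_background(out, reference)
    if config.median_kernel:
        out = median_filter(out, config.median_kernel)
    mask = None
    if config.roi:
        mask = circular_roi_mask(out.shape, radius=config.roi_radius)
        out = out.replace(pixels=np.where(mask, out.pixels, 0.0))
    if config.clahe:
        out = adaptive_hist_eq(
            out, mask, config.clahe_clip_limit, config.clahe_tile_grid
        )
    if config.morphology_op:
        out = morph_refine(out, config.morphology_op, config.morphology_radius)
    return out


def apply_postprocess(image: ImageSlice, config: PostprocessConfig) -> ImageSlice:
    out = image
    if config.bandpass:
        high = config.bandpass_high
        if high is None:
            high = 0.45 * min(out.shape)
        out = bandpass_filter(out, config.bandpass_low, high)
    if config.morphology_op:
        out = morph_refine(out, config.morphology_op, config.morphology_radius)
    return out
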