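"""Image quality metrics: PSNR, SSIM, RMSE and Fourier Ring Correlation.

The four metrics are implemented directly from their defining expressions so
they can be checked against independent brute-force oracles.  ``qc_curves``
evaluates them slice-by-slice over a Z-stack and records which image served
as the reference (the instrument workflow compares noisy input vs denoised
output; synthetic benchmarks additionally use the clean ground truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .image_io import ImageSlice, ImageStack

__all__ = [
    "psnr",
    "ssim",
    "rmse",
    "frc",
    "frc_mean",
    "FRCCurve",
    "MetricReport",
    "qc_curves",
]


def _pixels(img) -> np.ndarray:
    if isinstance(img, ImageSlice):
        return img.pixels.astype(np.float64)
    return np.asarray(img, dtype=np.float64)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    x, y = _pixels(a), _pixels(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def psnr(a, b, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(MAX^2 / MSE)`` in dB.

    Identical images have zero MSE and return ``inf`` (never a large float).
    """
    x, y = _pair(a, b)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_value**2 / mse)


def rmse(a, b) -> float:
    """Root mean squared pixel difference."""
    x, y = _pair(a, b)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def ssim(
    a,
    b,
    c1: float | None = None,
    c2: float | None = None,
    window: int = 7,
    max_value: float = 1.0,
    mode: str = "windowed",
) -> float:
    """Structural similarity index.

    ``mode='windowed'`` (default) averages the SSIM expression over sliding
    ``window``-sized uniform windows; ``mode='global'`` evaluates it once
    from whole-image means, variances and covariance (the literal printed
    form).  Default stabilizers are ``C1=(0.01*MAX)^2`` and
    ``C2=(0.03*MAX)^2``.
    """
    x, y = _pair(a, b)
    if c1 is None:
        c1 = (0.01 * max_value) ** 2
    if c2 is None:
        c2 = (0.03 * max_value) ** 2
    if mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - mx) * (y - my)).mean()
        return float(
            (2 * mx * my + c1) * (2 * cov + c2)
            / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    if mode != "windowed":
        raise ValueError("mode must be 'windowed' or 'global'")
    if window < 1 or window > min(x.shape):
        raise ValueError(f"window {window} larger than image {x.shape}")

    def mean(v):
        return uniform_filter(v, size=window, mode="reflect")

    mx, my = mean(x), mean(y)
    vx = mean(x * x) - mx**2
    vy = mean(y * y) - my**2
    cov = mean(x * y) - mx * my
    ssim_map = (
        (2 * mx * my + c1) * (2 * cov + c2)
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )
    return float(ssim_map.mean())


@dataclass
class FRCCurve:
    """Fourier ring correlation per frequency shell.

    ``radii`` are shell radii in cycles/image; ``correlations`` lie in
    [-1, 1].  ``mean_below_half_nyquist`` is the scalar summary used in
    reports (average over shells below half the Nyquist frequency).
    """

    radii: np.ndarray
    correlations: np.ndarray
    mean_below_half_nyquist: float


def frc(a, b, shell_width: int = 1) -> FRCCurve:
    """Fourier ring correlation between two images.

    Per shell ``R_f = Re(sum FFT1 * conj(FFT2)) / sqrt(sum|FFT1|^2 *
    sum|FFT2|^2)``.  The DC bin is excluded; empty shells are skipped with a
    warning.  Non-square inputs are zero-padded to square.
    """
    x, y = _pair(a, b)
    if shell_width < 1:
        raise ValueError("shell_width must be >= 1")
    h, w = x.shape
    n = max(h, w)
    if h != w:
        pad = ((0, n - h), (0, n - w))
        x = np.pad(x, pad)
        y = np.pad(y, pad)
    f1 = np.fft.fft2(x)
    f2 = np.fft.fft2(y)
    fy = np.fft.fftfreq(n) * n
    r = np.hypot(fy[:, None], fy[None, :])
    shells = (r / shell_width).astype(int)
    dc = (r == 0)
    shells = np.where(dc, -1, shells)  # DC excluded from shell 0

    nshell = shells.max() + 1
    flat = shells.ravel()
    valid = flat >= 0
    cross = np.bincount(
        flat[valid], weights=(f1 * np.conj(f2)).real.ravel()[valid], minlength=nshell
    )
    p1 = np.bincount(flat[valid], weights=(np.abs(f1) ** 2).ravel()[valid], minlength=nshell)
    p2 = np.bincount(flat[valid], weights=(np.abs(f2) ** 2).ravel()[valid], minlength=nshell)
    counts = np.bincount(flat[valid], minlength=nshell)

    radii, corr = [], []
    for k in range(nshell):
        if counts[k] == 0:
            if k > 0:  # shell 0 holding only the excluded DC bin is expected
                warnings.warn(f"empty frequency shell {k} skipped", stacklevel=2)
            continue
        denom = np.sqrt(p1[k] * p2[k])
        radii.append((k + 0.5) * shell_width)
        corr.append(cross[k] / denom if denom > 0 else 0.0)
    radii = np.asarray(radii)
    corr = np.asarray(corr)
    half_nyquist = n / 4.0
    below = radii < half_nyquist
    mean = float(corr[below].mean()) if below.any() else float("nan")
    return FRCCurve(radii, corr, mean)


def frc_mean(a, b, shell_width: int = 1) -> float:
    """Scalar FRC summary: mean correlation over shells below half-Nyquist."""
    return frc(a, b, shell_width).mean_below_half_nyquist


@dataclass
class MetricReport:
    """Per-slice and aggregate quality metrics for a processed stack."""

    per_slice: pd.DataFrame
    aggregate: dict[str, float]
    reference_convention: str

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.per_slice.to_csv(path, index=False)
        return path


def qc_curves(
    original: ImageStack,
    processed: ImageStack,
    reference_convention: str = "noisy_input",
) -> MetricReport:
    """Slice-wise PSNR/SSIM/RMSE/FRC between two aligned stacks."""
    if reference_convention not in ("noisy_input", "clean_truth"):
        raise ValueError("reference_convention must be 'noisy_input' or 'clean_truth'")
    if original.n_slices != processed.n_slices:
        raise ValueError(
            f"slice count mismatch: {original.n_slices} vs {processed.n_slices}"
        )
    rows = []
    for i, (ref, out) in enumerate(zip(original, processed)):
        rows.append(
            {
                "slice_index": i,
                "psnr_db": psnr(ref, out),
                "ssim": ssim(ref, out),
                "rmse": rmse(ref, out),
                "frc_mean": frc_mean(ref, out),
            }
        )
    table = pd.DataFrame(rows)
    aggregate = {
        col: float(table[col].mean())
        for col in ("psnr_db", "ssim", "rmse", "frc_mean")
    }
    return MetricReport(table, aggregate, reference_convention)
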