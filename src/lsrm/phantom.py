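"""Synthetic spheroid stacks and Raman spectra for pipeline testing.

The phantom emulates the three artifact classes the imaging pipeline has to
cope with: a structured object (a spheroid with rim/core contrast), a smooth
additive autofluorescence-like background, and per-pixel Gaussian read noise.
Intensities are unit-normalized to ``[0, 1]`` throughout so phantoms plug
directly into the sigmoid-bounded denoiser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import FIELD_OF_VIEW_UM, ImageStack, write_stack
from .spectra import Spectrum

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "generate_spheroid_phantom",
    "generate_synthetic_spectrum",
    "standard_phantom_spec",
    "write_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic spheroid Z-stack.

    The square field of view is fixed at 635 µm, so ``pixel_pitch_um`` is
    derived from ``grid_size``.  Identical seeds produce bit-identical
    phantoms.
    """

    grid_size: int = 128
    n_slices: int = 41
    z_step_um: float = 10.0
    spheroid_diameter_um: float = 350.0
    core_intensity: float = 0.5
    rim_intensity: float = 0.8
    noise_sigma: float = 0.05
    fluor_amplitude: float = 0.2
    fluor_scale_px: float = 16.0
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if not 0 <= self.noise_sigma < 1:
            raise ValueError("noise_sigma must lie in [0, 1)")
        if self.spheroid_diameter_um <= 0:
            raise ValueError("spheroid_diameter_um must be positive")
        if self.spheroid_diameter_um > FIELD_OF_VIEW_UM:
            raise ValueError(
                f"spheroid diameter {self.spheroid_diameter_um} µm exceeds the "
                f"{FIELD_OF_VIEW_UM} µm field of view"
            )
        if self.fluor_amplitude < 0:
            raise ValueError("fluor_amplitude must be non-negative")
        if self.fluor_scale_px <= 0:
            raise ValueError("fluor_scale_px must be positive")
        for name in ("core_intensity", "rim_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")

    @property
    def pixel_pitch_um(self) -> float:
        return FIELD_OF_VIEW_UM / self.grid_size


@dataclass
class PhantomVolume:
    """Ground truth, corrupted observation and the background field alone."""

    clean: ImageStack
    noisy: ImageStack
    background: ImageStack
    spec: PhantomSpec

    def __post_init__(self) -> None:
        shapes = {self.clean.data.shape, self.noisy.data.shape, self.background.data.shape}
        if len(shapes) != 1:
            raise ValueError(f"stacks disagree on shape: {shapes}")


def standard_phantom_spec(seed: int = 42) -> PhantomSpec:
    """The reference phantom used by the quality-gate checks.

    128×128 slices, spheroid spanning ~60 % of the frame, rim 0.8 / core 0.5,
    Gaussian noise sigma 0.05 and a smooth background of amplitude 0.2.
    """
    return PhantomSpec(
        grid_size=128,
        n_slices=41,
        spheroid_diameter_um=0.6 * FIELD_OF_VIEW_UM,
        core_intensity=0.5,
        rim_intensity=0.8,
        noise_sigma=0.05,
        fluor_amplitude=0.2,
        seed=seed,
    )


def _slice_profile(spec: PhantomSpec, chord_radius_px: float) -> np.ndarray:
    """One clean Z-plane: disk of the sphere's chord with rim/core contrast.

    Intensity depends on radius only (quadratic ramp from core to rim with a
    one-pixel anti-aliased edge), so a centered plane is exactly invariant
    under 90° rotation.
    """
    n = spec.grid_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    if chord_radius_px <= 0:
        return np.zeros((n, n))
    frac = np.clip(r / chord_radius_px, 0.0, 1.0)
    profile = spec.core_intensity + (spec.rim_intensity - spec.core_intensity) * frac**2
    coverage = np.clip(chord_radius_px - r + 0.5, 0.0, 1.0)  # soft 1-px edge
    return profile * coverage


def generate_spheroid_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Generate a clean/noisy/background triple for the given spec.

    The clean stack samples a solid sphere at each Z plane (per-slice disk
    radius follows the sphere's chord at that height), the background is a
    large-kernel-blurred seeded random field scaled to ``fluor_amplitude``,
    and the noise is i.i.d. Gaussian of std ``noise_sigma`` (or Poisson shot
    noise of matched variance when ``noise_model='poisson'``).  The noisy
    stack is exactly ``clip(clean + background + noise, 0, 1)``.
    """
    rng = np.random.default_rng(spec.seed)
    n, nz = spec.grid_size, spec.n_slices
    radius_um = spec.spheroid_diameter_um / 2.0
    z_center = (nz - 1) / 2.0

    clean = np.zeros((nz, n, n))
    for k in range(nz):
        dz_um = (k - z_center) * spec.z_step_um
        chord_sq = radius_um**2 - dz_um**2
        chord_px = np.sqrt(chord_sq) / spec.pixel_pitch_um if chord_sq > 0 else 0.0
        clean[k] = _slice_profile(spec, chord_px)

    if spec.fluor_amplitude > 0:
        rough = rng.standard_normal((nz, n, n))
        smooth = np.stack(
            [gaussian_filter(p, spec.fluor_scale_px, mode="reflect") for p in rough]
        )
        lo, hi = smooth.min(), smooth.max()
        background = spec.fluor_amplitude * (smooth - lo) / (hi - lo)
    else:
        background = np.zeros_like(clean)

    if spec.noise_sigma > 0:
        if spec.noise_model == "poisson":
            # shot noise with variance sigma^2 at unit intensity
            rate = np.clip(clean + background, 0, None) / spec.noise_sigma**2
            noise = rng.poisson(rate) * spec.noise_sigma**2 - np.clip(
                clean + background, 0, None
            )
        else:
            noise = rng.normal(0.0, spec.noise_sigma, (nz, n, n))
    else:
        noise = np.zeros_like(clean)

    noisy = np.clip(clean + background + noise, 0.0, 1.0)

    def _stack(data: np.ndarray) -> ImageStack:
        return ImageStack.from_array(data, spec.z_step_um, spec.pixel_pitch_um)

    return PhantomVolume(_stack(clean), _stack(noisy), _stack(background), spec)


def write_phantom(volume: PhantomVolume, directory: str | Path) -> dict[str, Path]:
    """Persist a phantom as three multi-page TIFFs plus a JSON spec sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("clean", "noisy", "background"):
        paths[name] = write_stack(getattr(volume, name), directory / f"{name}.tiff")
    spec_path = directory / "phantom_spec.json"
    spec_path.write_text(json.dumps(asdict(volume.spec), indent=2))
    paths["spec"] = spec_path
    return paths


def generate_synthetic_spectrum(
    bands: Sequence[tuple[float, float, float]],
    baseline_poly: Sequence[float] = (),
    noise_sigma: float = 0.0,
    seed: int = 0,
    wavenumbers: np.ndarray | None = None,
    excitation_nm: float | None = None,
) -> Spectrum:
    """Gaussian bands on a polynomial baseline with optional noise.

    ``bands`` are ``(center cm^-1, width cm^-1, amplitude)`` triples; the
    width is the Gaussian standard deviation.  ``baseline_poly`` holds
    highest-power-first coefficients evaluated on the normalized coordinate
    ``(w - w_min) / (w_max - w_min)`` so coefficient magnitudes read as
    intensities.  Ground-truth band parameters are recorded in
    ``Spectrum.meta['bands']`` for recovery tests.
    """
    if wavenumbers is None:
        wavenumbers = np.arange(2500.0, 3501.0, 1.0)
    wavenumbers = np.asarray(wavenumbers, dtype=np.float64)
    intensity = np.zeros_like(wavenumbers)
    for center, width, amplitude in bands:
        if width <= 0:
            raise ValueError(f"band width must be positive, got {width}")
        if amplitude < 0:
            raise ValueError(f"band amplitude must be non-negative, got {amplitude}")
        if not wavenumbers[0] <= center <= wavenumbers[-1]:
            raise ValueError(
                f"band center {center} cm^-1 outside axis "
                f"[{wavenumbers[0]}, {wavenumbers[-1]}]"
            )
        intensity += amplitude * np.exp(-((wavenumbers - center) ** 2) / (2 * width**2))
    if len(baseline_poly):
        span = wavenumbers[-1] - wavenumbers[0]
        u = (wavenumbers - wavenumbers[0]) / (span if span > 0 else 1.0)
        intensity += np.polyval(np.asarray(baseline_poly, dtype=np.float64), u)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, wavenumbers.shape)
    return Spectrum(
        wavenumbers,
        intensity,
        excitation_nm=excitation_nm,
        meta={"bands": [tuple(map(float, b)) for b in bands]},
    )
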