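"""Image and spectral-cube containers with TIFF/JSON persistence.

Stacks are stored as multi-page grayscale TIFF (page order = ascending Z,
0-based slice indexing).  Hyperspectral cubes are stored as TIFF pages over
the wavenumber axis plus a JSON sidecar carrying the axis and excitation
metadata.  Integer containers round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageSlice",
    "ImageStack",
    "SpectralCube",
    "FormatError",
    "read_stack",
    "write_stack",
    "read_cube",
    "write_cube",
]

#: default camera pixel pitch in micrometres (sCMOS sensor)
CAMERA_PIXEL_PITCH_UM = 6.5
#: effective square field of view in micrometres
FIELD_OF_VIEW_UM = 635.0
#: default axial step between Z planes in micrometres
DEFAULT_Z_STEP_UM = 10.0

_BIT_DEPTHS = ("8", "16", "float")
_DTYPE_FOR_DEPTH = {"8": np.uint8, "16": np.uint16, "float": np.float32}
_MAX_FOR_DEPTH = {"8": 255, "16": 65535}


class FormatError(ValueError):
    """Raised when an on-disk container violates the expected layout."""


@dataclass
class ImageSlice:
    """A single 2D single-channel image.

    Parameters
    ----------
    pixels:
        2D intensity array.  Float arrays flagged ``normalized`` must lie in
        ``[0, 1]``.
    pixel_pitch_um:
        Physical sampling pitch in micrometres per pixel.
    bit_depth:
        One of ``"8"``, ``"16"`` or ``"float"``.
    normalized:
        True when intensities are unit-normalized to ``[0, 1]``.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = CAMERA_PIXEL_PITCH_UM
    bit_depth: str = "float"
    normalized: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"ImageSlice requires a 2D array, got ndim={self.pixels.ndim}"
            )
        if self.bit_depth not in _BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_BIT_DEPTHS}")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.normalized and self.bit_depth == "float":
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"normalized slice must lie in [0, 1]; got [{lo}, {hi}]"
                )

    @classmethod
    def from_array(
        cls, pixels: np.ndarray, pixel_pitch_um: float = CAMERA_PIXEL_PITCH_UM
    ) -> "ImageSlice":
        """Wrap a float array in ``[0, 1]`` as a normalized slice."""
        return cls(np.asarray(pixels, dtype=np.float64), pixel_pitch_um, "float", True)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def normalize(self) -> "ImageSlice":
        """Return a unit-normalized float copy (integer depths divide by dtype max)."""
        if self.bit_depth == "float":
            if self.normalized:
                return self.replace(pixels=self.pixels.astype(np.float64))
            data = self.pixels.astype(np.float64)
            span = data.max() - data.min()
            data = (data - data.min()) / span if span > 0 else np.zeros_like(data)
        else:
            data = self.pixels.astype(np.float64) / _MAX_FOR_DEPTH[self.bit_depth]
        return ImageSlice(data, self.pixel_pitch_um, "float", True)

    def replace(self, **changes) -> "ImageSlice":
        return dataclasses.replace(self, **changes)


@dataclass
class ImageStack:
    """Ordered Z-series of equally shaped slices."""

    slices: list[ImageSlice]
    z_step_um: float = DEFAULT_Z_STEP_UM

    def __post_init__(self) -> None:
        if not self.slices:
            raise FormatError("ImageStack requires at least one slice")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        shape = self.slices[0].shape
        norm = self.slices[0].normalized
        for i, s in enumerate(self.slices):
            if s.shape != shape:
                raise FormatError(f"slice {i} shape {s.shape} != {shape}")
            if s.normalized != norm:
                raise FormatError("slices disagree on normalization state")

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        z_step_um: float = DEFAULT_Z_STEP_UM,
        pixel_pitch_um: float = CAMERA_PIXEL_PITCH_UM,
    ) -> "ImageStack":
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 3:
            raise FormatError("expected a (z, y, x) array")
        return cls(
            [ImageSlice.from_array(p, pixel_pitch_um) for p in data], z_step_um
        )

    @property
    def data(self) -> np.ndarray:
        """The stack as a ``(z, y, x)`` array (copy)."""
        return np.stack([s.pixels for s in self.slices])

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def pixel_pitch_um(self) -> float:
        return self.slices[0].pixel_pitch_um

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[ImageSlice]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> ImageSlice:
        return self.slices[i]

    def normalize(self) -> "ImageStack":
        return ImageStack([s.normalize() for s in self.slices], self.z_step_um)


@dataclass
class SpectralCube:
    """Hyperspectral cube ``(y, x, wavenumber)`` with an ascending axis in cm^-1."""

    data: np.ndarray
    wavenumbers: np.ndarray
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError("cube data must be 3D (y, x, wavenumber)")
        if self.wavenumbers.ndim != 1:
            raise FormatError("wavenumber axis must be 1D")
        if self.data.shape[2] != self.wavenumbers.size:
            raise FormatError(
                f"axis length {self.wavenumbers.size} does not match "
                f"spectral dimension {self.data.shape[2]}"
            )
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise FormatError("wavenumber axis must be strictly increasing")
        if self.data.min() < 0:
            raise FormatError("cube intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# TIFF stacks


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page grayscale TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    first = stack.slices[0]
    dtype = _DTYPE_FOR_DEPTH[first.bit_depth]
    pages = np.stack([s.pixels.astype(dtype) for s in stack.slices])
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "z_step_um": stack.z_step_um,
        "pixel_pitch_um": first.pixel_pitch_um,
        "bit_depth": first.bit_depth,
        "normalized": first.normalized,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path, normalize: bool = False) -> ImageStack:
    """Read a multi-page single-channel TIFF as an :class:`ImageStack`.

    ``normalize=True`` divides integer data by the dtype maximum (65535 for
    16-bit) so intensities land in ``[0, 1]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        shapes = set()
        for page in tif.pages:
            if page.samplesperpixel != 1:
                raise FormatError(
                    f"{path} is not single-channel "
                    f"(samples per pixel = {page.samplesperpixel})"
                )
            shapes.add(page.shape)
        if len(shapes) != 1:
            raise FormatError(f"inconsistent page shapes in {path}: {shapes}")
        pages = tif.asarray()
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(
            f"expected single-channel pages; got array of shape {pages.shape}"
        )
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    pitch = float(meta.get("pixel_pitch_um", CAMERA_PIXEL_PITCH_UM))
    z_step = float(meta.get("z_step_um", DEFAULT_Z_STEP_UM))
    if np.issubdtype(pages.dtype, np.integer):
        depth = "8" if pages.dtype.itemsize == 1 else "16"
        norm = False
    else:
        depth = "float"
        norm = bool(meta.get("normalized", True))
    slices = [ImageSlice(p, pitch, depth, norm) for p in pages]
    stack = ImageStack(slices, z_step)
    return stack.normalize() if normalize else stack


# ---------------------------------------------------------------------------
# spectral cubes


def write_cube(cube: SpectralCube, path: str | Path) -> Path:
    """Write a cube as TIFF pages over wavenumber plus a JSON axis sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(cube.data, 2, 0).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "wavenumbers_cm1": cube.wavenumbers.tolist(),
        "excitation_nm": cube.excitation_nm,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_cube(path: str | Path) -> SpectralCube:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing axis sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.moveaxis(pages.astype(np.float64), 0, 2)
    return SpectralCube(
        data,
        np.asarray(meta["wavenumbers_cm1"], dtype=np.float64),
        meta.get("excitation_nm"),
    )
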