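"""Raman spectral processing: baseline correction, peak ratios, band lookup.

Baseline estimation uses an iterative Savitzky–Golay lower-envelope scheme:
the running baseline estimate is repeatedly smoothed and clamped to the
pointwise minimum with the input spectrum, which converges onto the slowly
varying fluorescence envelope while narrow vibrational peaks are shaved off.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "Band",
    "BandAssignment",
    "DEFAULT_BAND_TABLE",
    "MODALITY_PRESETS",
    "baseline_correct",
    "peak_ratio",
    "assign_bands",
    "raman_shift",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


@dataclass
class Spectrum:
    """A 1D spectrum on a strictly increasing wavenumber axis (cm^-1)."""

    wavenumbers: np.ndarray
    intensity: np.ndarray
    excitation_nm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.wavenumbers.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity axes must have equal length")
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass(frozen=True)
class Band:
    low_cm1: float
    high_cm1: float
    label: str

    def __post_init__(self) -> None:
        if not self.low_cm1 < self.high_cm1:
            raise ValueError(f"band bounds out of order: {self}")


#: vibrational-mode assignment windows for the C-H stretching region
DEFAULT_BAND_TABLE: tuple[Band, ...] = (
    Band(3000.0, 3400.0, "CH stretch"),
    Band(2880.0, 2895.0, "CH2 asymmetric stretching"),
    Band(2929.0, 2937.0, "CH3 stretching"),
)

#: acquisition presets per excitation laser and modality (powers in mW,
#: exposures in ms, AOTF and detected wavelengths in nm)
MODALITY_PRESETS: dict[tuple[int, str], dict] = {
    (532, "rayleigh"): dict(
        power_mw=1, exposure_ms=100, aotf_nm=522.0, filter="none", detected_nm=532.0
    ),
    (532, "raman"): dict(
        power_mw=350,
        exposure_ms=400,
        aotf_nm=631.6,
        filter="longpass 532 nm",
        detected_nm=631.6,
    ),
    (660, "rayleigh"): dict(
        power_mw=1, exposure_ms=100, aotf_nm=650.0, filter="none", detected_nm=660.0
    ),
    (660, "raman"): dict(
        power_mw=130,
        exposure_ms=5000,
        aotf_nm=815.0,
        filter="longpass 660 nm",
        detected_nm=815.0,
    ),
}


@dataclass
class BandAssignment:
    band: Band
    peak_cm1: float | None
    intensity: float
    present: bool


def baseline_correct(
    s: Spectrum,
    window: int = 101,
    polyorder: int = 2,
    iterations: int = 20,
) -> tuple[Spectrum, Spectrum]:
    """Estimate and remove a slowly varying baseline.

    Returns ``(corrected, baseline)`` with ``corrected = s - baseline``.  The
    converged baseline is pointwise <= the input (lower-envelope property)
    and the procedure is idempotent to within a small tolerance.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window >= len(s):
        raise ValueError("window must be smaller than the spectrum length")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    signal = s.intensity.astype(np.float64)
    baseline = signal.copy()
    for _ in range(iterations):
        smoothed = savgol_filter(baseline, window, polyorder)
        # clamp against the signal so the estimate is a lower envelope and
        # the scheme has a fixed point (idempotent on corrected spectra)
        baseline = np.minimum(signal, smoothed)
    corrected = signal - baseline
    return (
        Spectrum(s.wavenumbers, corrected, s.excitation_nm, dict(s.meta)),
        Spectrum(s.wavenumbers, baseline, s.excitation_nm),
    )


def _band_slice(s: Spectrum, low: float, high: float) -> np.ndarray:
    idx = np.nonzero((s.wavenumbers >= low) & (s.wavenumbers <= high))[0]
    if idx.size == 0:
        raise ValueError(f"band [{low}, {high}] cm^-1 contains no samples")
    return idx


def peak_ratio(
    s: Spectrum,
    band_a: tuple[float, float],
    band_b: tuple[float, float],
    mode: str = "max",
) -> float:
    """Ratio of band_a intensity to band_b intensity on a corrected spectrum.

    ``mode='max'`` uses the band maximum (peak intensity); ``mode='integral'``
    uses the trapezoidal integral over the band.
    """
    if mode not in ("max", "integral"):
        raise ValueError("mode must be 'max' or 'integral'")
    values = []
    for low, high in (band_a, band_b):
        idx = _band_slice(s, low, high)
        if mode == "max":
            values.append(float(s.intensity[idx].max()))
        else:
            values.append(float(np.trapezoid(s.intensity[idx], s.wavenumbers[idx])))
    if values[1] == 0:
        raise ZeroDivisionError("band_b has zero intensity")
    return values[0] / values[1]


def assign_bands(
    s: Spectrum,
    table: Sequence[Band] = DEFAULT_BAND_TABLE,
    noise_floor: float = 0.0,
) -> list[BandAssignment]:
    """Locate the peak inside each assignment window of a corrected spectrum.

    Bands whose maximum does not exceed ``noise_floor`` are flagged absent.
    """
    out = []
    for band in table:
        mask = (s.wavenumbers >= band.low_cm1) & (s.wavenumbers <= band.high_cm1)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            out.append(BandAssignment(band, None, 0.0, False))
            continue
        j = idx[np.argmax(s.intensity[idx])]
        peak = float(s.intensity[j])
        present = peak > noise_floor
        out.append(
            BandAssignment(band, float(s.wavenumbers[j]) if present else None, peak, present)
        )
    return out


def raman_shift(excitation_nm: float, detected_nm: float) -> float:
    """Stokes shift in cm^-1: ``1e7 * (1/excitation - 1/detected)``.

    Anti-Stokes (detected < excitation) yields a negative shift and a warning.
    """
    if excitation_nm <= 0 or detected_nm <= 0:
        raise ValueError("wavelengths must be positive")
    shift = 1e7 * (1.0 / excitation_nm - 1.0 / detected_nm)
    if shift < 0:
        warnings.warn(
            f"anti-Stokes shift ({shift:.1f} cm^-1): detected wavelength is "
            "shorter than the excitation wavelength",
            stacklevel=2,
        )
    return shift


def write_spectrum_csv(s: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavenumber_cm1", "intensity"])
        for w, i in zip(s.wavenumbers, s.intensity):
            writer.writerow([repr(float(w)), repr(float(i))])
    return path


def read_spectrum_csv(path: str | Path, excitation_nm: float | None = None) -> Spectrum:
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path} is not a 2-column spectrum CSV")
    return Spectrum(data[:, 0], data[:, 1], excitation_nm)
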