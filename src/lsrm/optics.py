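"""Analytic calculators for the instrument-design relations.

Pure functions used for documentation, configuration validation and sanity
checks; there is no hardware control here.  Conventions follow the source
design sheet exactly — notably the telescope magnification is ``f1 / f2``
as printed, with the conventional reciprocal available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticsParams",
    "LASER_PRESETS",
    "cross_section_ratio",
    "telescope_magnification",
    "sheet_intensity",
    "beam_width",
    "aotf_center_wavelength",
    "rayleigh_resolution",
    "parameter_report",
]


@dataclass(frozen=True)
class OpticsParams:
    """Bag of physical instrument parameters (positive quantities)."""

    lambda_nm: float = 532.0
    f1_mm: float = 25.0
    f2_mm: float = 50.0
    w0_um: float = 8.0
    zR_um: float = 100.0
    I0: float = 1.0
    NA: float = 1.2
    acoustic_velocity: float = 650.0   # m/s, AOTF crystal
    refractive_index: float = 2.2
    acoustic_frequency: float = 1.0e6  # Hz
    immersion_index: float = 1.33

    def __post_init__(self) -> None:
        for name in (
            "lambda_nm", "f1_mm", "f2_mm", "w0_um", "zR_um", "I0", "NA",
            "acoustic_velocity", "refractive_index", "acoustic_frequency",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.NA > self.immersion_index:
            warnings.warn(
                f"NA {self.NA} exceeds immersion refractive index "
                f"{self.immersion_index}",
                stacklevel=2,
            )


#: the two excitation lasers (wavelength nm, adjustable power range mW)
LASER_PRESETS = {
    532: {"wavelength_nm": 532.0, "power_mw": (0.5, 2000.0)},
    660: {"wavelength_nm": 660.0, "power_mw": (0.5, 130.0)},
}


def cross_section_ratio(lambda1_nm: float, lambda2_nm: float) -> float:
    """Scattering-efficiency ratio from the lambda^-4 law:
    ``(lambda2/lambda1)^4``, the factor by which scattering at ``lambda1``
    exceeds scattering at ``lambda2`` with all other terms equal."""
    if lambda1_nm <= 0 or lambda2_nm <= 0:
        raise ValueError("wavelengths must be positive")
    return (lambda2_nm / lambda1_nm) ** 4


def telescope_magnification(
    f1_mm: float, f2_mm: float, convention: str = "as_printed"
) -> float:
    """Keplerian telescope magnification.

    ``as_printed`` returns ``f1 / f2``; ``conventional`` returns the
    textbook ``f2 / f1``.
    """
    if f1_mm <= 0 or f2_mm <= 0:
        raise ValueError("focal lengths must be positive")
    if convention == "as_printed":
        return f1_mm / f2_mm
    if convention == "conventional":
        return f2_mm / f1_mm
    raise ValueError("convention must be 'as_printed' or 'conventional'")


def sheet_intensity(x_um: float, z_um: float, params: OpticsParams) -> float:
    """Gaussian sheet profile ``I0 exp(-2 x^2 / w0^2) sinc^2(z / zR)``
    with the unnormalized sinc ``sin(u)/u``."""
    u = z_um / params.zR_um
    sinc = np.sinc(u / np.pi)  # np.sinc is sin(pi t)/(pi t)
    return float(params.I0 * np.exp(-2.0 * x_um**2 / params.w0_um**2) * sinc**2)


def beam_width(z_um: float, params: OpticsParams) -> float:
    """Gaussian beam width ``w0 sqrt(1 + (z/zR)^2)`` in micrometres."""
    return float(params.w0_um * np.sqrt(1.0 + (z_um / params.zR_um) ** 2))


def aotf_center_wavelength(
    acoustic_velocity: float, refractive_index: float, acoustic_frequency: float
) -> float:
    """Acousto-optic passband center ``lambda_c = v * n / f`` in the units
    implied by the inputs (consistent units are the caller's contract)."""
    if acoustic_frequency <= 0:
        raise ValueError("acoustic frequency must be positive")
    if acoustic_velocity <= 0 or refractive_index <= 0:
        raise ValueError("velocity and refractive index must be positive")
    return acoustic_velocity * refractive_index / acoustic_frequency


def rayleigh_resolution(lambda_nm: float, NA: float) -> float:
    """Rayleigh-criterion resolution ``0.61 lambda / NA`` in nm."""
    if NA <= 0:
        raise ValueError("NA must be positive")
    if lambda_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 0.61 * lambda_nm / NA


def parameter_report(params: OpticsParams) -> str:
    """Human-readable summary of the derived optical quantities."""
    lines = [
        "optical parameter report",
        f"  excitation wavelength : {params.lambda_nm:.1f} nm",
        f"  telescope M (f1/f2)   : {telescope_magnification(params.f1_mm, params.f2_mm):.3f}",
        f"  beam waist w0         : {params.w0_um:.2f} um",
        f"  beam width at zR      : {beam_width(params.zR_um, params):.2f} um",
        f"  rayleigh resolution   : {rayleigh_resolution(params.lambda_nm, params.NA):.1f} nm (NA {params.NA})",
        f"  scattering ratio vs 660 nm : {cross_section_ratio(params.lambda_nm, 660.0):.2f}",
    ]
    return "\n".join(lines)
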