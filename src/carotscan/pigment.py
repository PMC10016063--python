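"""Beer-Lambert conversion of acetone-extract absorbance spectra to
beta-carotene mass per wet biomass.

Spectra are baseline-zeroed at 600 nm (where carotenoids do not absorb),
the absorbance at 454 nm is converted to a molar concentration with the
extinction coefficient of beta-carotene in acetone, and the extract's
pigment content is reported as mg per g of wet cell pellet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .seqio import Spectrum

#: extinction coefficient of beta-carotene in acetone, M^-1 cm^-1
EPSILON_BETA_CAROTENE_ACETONE = 134_000.0
#: molar mass of beta-carotene, g/mol
MOLAR_MASS_BETA_CAROTENE = 536.88


@dataclass
class PigmentParams:
    epsilon: float = EPSILON_BETA_CAROTENE_ACETONE
    molar_mass: float = MOLAR_MASS_BETA_CAROTENE
    zero_wavelength: float = 600.0
    read_wavelength: float = 454.0
    path_length_cm: float = 1.0
    #: tolerance for nearest-wavelength lookup on the sampled grid
    wavelength_tolerance: float = 0.25

    def __post_init__(self) -> None:
        for name in ("epsilon", "molar_mass", "zero_wavelength",
                     "read_wavelength", "path_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def zero_spectrum(spectrum: Spectrum, params: PigmentParams | None = None) -> Spectrum:
    """Subtract the absorbance at the zeroing wavelength from every point."""
    params = params or PigmentParams()
    baseline = spectrum.value_at(
        params.zero_wavelength, tolerance=params.wavelength_tolerance
    )
    return Spectrum(
        wavelengths=spectrum.wavelengths.copy(),
        absorbance=spectrum.absorbance - baseline,
    )


def beta_carotene_mass(
    spectrum: Spectrum,
    extract_volume_l: float,
    biomass_g: float,
    params: PigmentParams | None = None,
    apply_zeroing: bool = True,
) -> float:
    """Beta-carotene content, mg per g wet biomass, from an extract spectrum.

    c = A(read) / (epsilon * path); mass_mg = c * V * M * 1000; the result
    is mass_mg / biomass_g.  A negative zeroed absorbance (measurement near
    blank) is clamped to zero with a warning.
    """
    params = params or PigmentParams()
    if extract_volume_l <= 0:
        raise ValueError("extract volume must be positive")
    if biomass_g <= 0:
        raise ValueError("biomass must be positive")
    if apply_zeroing:
        spectrum = zero_spectrum(spectrum, params)
    a_read = spectrum.value_at(
        params.read_wavelength, tolerance=params.wavelength_tolerance
    )
    if a_read < 0:
        warnings.warn(
            f"zeroed absorbance at {params.read_wavelength} nm is negative "
            f"({a_read:.4g}); clamping to 0", stacklevel=2,
        )
        a_read = 0.0
    concentration_m = a_read / (params.epsilon * params.path_length_cm)
    mass_mg = concentration_m * extract_volume_l * params.molar_mass * 1000.0
    return mass_mg / biomass_g
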