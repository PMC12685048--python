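"""Photon-flux and irradiance unit conversions.

The photokinetic equations work with photon flux densities in
einstein cm^-2 s^-1 (one einstein = one mole of photons), while imaging
protocols quote irradiances in W cm^-2 or kW cm^-2 and bulk photochemistry
protocols quote umol m^-2 s^-1.  Everything funnels through the two functions
here so unit bugs stay in one file.
"""

from __future__ import annotations

from .errors import InvalidArgumentError

AVOGADRO = 6.02214076e23  # mol^-1
PLANCK = 6.62607015e-34  # J s
LIGHTSPEED = 2.99792458e8  # m s^-1

#: 1 umol m^-2 s^-1 expressed in einstein cm^-2 s^-1 (1 m^2 = 1e4 cm^2).
UMOL_PER_M2_S = 1e-6 / 1e4


def photon_energy(wavelength_nm: float) -> float:
    """Energy of a single photon in joules at the given vacuum wavelength."""
    if wavelength_nm <= 0:
        raise InvalidArgumentError(f"wavelength must be positive, got {wavelength_nm}")
    return PLANCK * LIGHTSPEED / (wavelength_nm * 1e-9)


def photon_flux_from_irradiance(irradiance_w_cm2: float, wavelength_nm: float) -> float:
    """Convert an irradiance (W cm^-2) into a photon flux density.

    Returns einstein cm^-2 s^-1, i.e. irradiance * lambda / (N_A h c).
    """
    if irradiance_w_cm2 < 0:
        raise InvalidArgumentError("irradiance must be >= 0")
    return irradiance_w_cm2 / (photon_energy(wavelength_nm) * AVOGADRO)


def irradiance_from_photon_flux(flux_einstein_cm2_s: float, wavelength_nm: float) -> float:
    """Inverse of :func:`photon_flux_from_irradiance` (returns W cm^-2)."""
    if flux_einstein_cm2_s < 0:
        raise InvalidArgumentError("photon flux must be >= 0")
    return flux_einstein_cm2_s * photon_energy(wavelength_nm) * AVOGADRO


def flux_from_umol_m2_s(flux_umol_m2_s: float) -> float:
    """Convert umol m^-2 s^-1 (common actinometry unit) to einstein cm^-2 s^-1."""
    return flux_umol_m2_s * UMOL_PER_M2_S
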