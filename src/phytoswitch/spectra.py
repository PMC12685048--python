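"""Absorption-spectrum operations: extinction anchoring, Pfr unmixing,
normalization, and band-maximum bookkeeping.

Bacteriophytochrome extinction spectra are anchored at the biliverdin Soret
band: the free-chromophore extinction at 391 nm (39,900 M^-1 cm^-1) is taken
as a per-bound-chromophore reference, so the derived extinction values hold
for the holo-protein.  The ensemble off-state reached under red light is a
photostationary Pr/Pfr mixture; the pure Pfr spectrum is obtained by
subtracting the residual Pr contribution, whose fraction follows from the
switching contrast (f_Pr = 1/contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnchorError, InvalidArgumentError

__all__ = [
    "Spectrum",
    "anchor_extinction_spectrum",
    "unmix_pfr_spectrum",
    "normalize_spectrum",
    "find_band_maximum",
]


@dataclass
class Spectrum:
    """Wavelength-indexed values: absorbance or extinction (see ``kind``)."""

    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray
    kind: str = "absorbance"  # absorbance | extinction

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise InvalidArgumentError("wavelengths and values must align")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidArgumentError("wavelengths must be strictly increasing")

    def value_at(self, wavelength: float) -> float:
        lam = self.wavelengths
        if not lam[0] <= wavelength <= lam[-1]:
            raise InvalidArgumentError(
                f"{wavelength} nm outside spectrum grid [{lam[0]}, {lam[-1]}]"
            )
        return float(np.interp(wavelength, lam, self.values))

    def resampled_to(self, grid: np.ndarray) -> "Spectrum":
        grid = np.asarray(grid, dtype=float)
        if grid[0] < self.wavelengths[0] or grid[-1] > self.wavelengths[-1]:
            raise InvalidArgumentError("target grid extends beyond the spectrum")
        return Spectrum(grid, np.interp(grid, self.wavelengths, self.values), self.kind)


def _common_grid(a: Spectrum, b: Spectrum):
    """Resample both spectra onto the coarser of their overlapping grids."""
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if hi <= lo:
        raise InvalidArgumentError("spectra do not overlap")
    if np.array_equal(a.wavelengths, b.wavelengths):
        return a, b
    grid_a = a.wavelengths[(a.wavelengths >= lo) & (a.wavelengths <= hi)]
    grid_b = b.wavelengths[(b.wavelengths >= lo) & (b.wavelengths <= hi)]
    grid = grid_a if grid_a.size <= grid_b.size else grid_b
    return a.resampled_to(grid), b.resampled_to(grid)


def anchor_extinction_spectrum(
    abs_spectrum: Spectrum,
    soret_wavelength: float = 391.0,
    soret_eps: float = 39900.0,
) -> Spectrum:
    """Scale an absorbance spectrum to extinction via the Soret anchor.

    eps(lambda) = soret_eps * A(lambda) / A(soret_wavelength); the result is
    a per-holo-protein (per bound chromophore) extinction spectrum.
    """
    anchor = abs_spectrum.value_at(soret_wavelength)
    if anchor <= 0:
        raise AnchorError(f"absorbance at {soret_wavelength} nm is not positive")
    return Spectrum(
        abs_spectrum.wavelengths.copy(),
        soret_eps * abs_spectrum.values / anchor,
        kind="extinction",
    )


def unmix_pfr_spectrum(eq_spectrum: Spectrum, off_spectrum: Spectrum, contrast: float):
    """Pure-Pfr spectrum from equilibrium (pure Pr) and off-state spectra.

    The off-state contains a residual Pr fraction f_Pr = 1/contrast;
    A_Pfr = (A_off - f_Pr * A_Pr) / (1 - f_Pr).  Negative unmixed values
    (noise) are clipped to zero and flagged.  Returns
    ``(pfr_spectrum, fractions, clipped_mask)`` with
    ``fractions = {"pr": f_Pr, "pfr": 1 - f_Pr}``.
    """
    if contrast <= 1:
        raise InvalidArgumentError(f"contrast must be > 1, got {contrast}")
    pr, off = _common_grid(eq_spectrum, off_spectrum)
    f_pr = 1.0 / contrast
    raw = (off.values - f_pr * pr.values) / (1.0 - f_pr)
    clipped = raw < 0
    values = np.where(clipped, 0.0, raw)
    return (
        Spectrum(pr.wavelengths.copy(), values, kind=off.kind),
        {"pr": f_pr, "pfr": 1.0 - f_pr},
        clipped,
    )


def normalize_spectrum(
    spectrum: Spectrum,
    reference_wavelength: float = 280.0,
    baseline_window: tuple | None = None,
) -> Spectrum:
    """Divide by the value at a reference wavelength (default the 280 nm
    protein peak), optionally after subtracting a flat baseline estimated
    from a silent window (e.g. 800-850 nm)."""
    values = spectrum.values.copy()
    if baseline_window is not None:
        lo, hi = baseline_window
        sel = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
        if not sel.any():
            raise InvalidArgumentError("baseline window contains no samples")
        values = values - float(values[sel].mean())
    work = Spectrum(spectrum.wavelengths.copy(), values, spectrum.kind)
    ref = work.value_at(reference_wavelength)
    if ref <= 0:
        raise InvalidArgumentError(
            f"reference absorbance at {reference_wavelength} nm is not positive"
        )
    return Spectrum(work.wavelengths, np.clip(values / ref, 0.0, None), spectrum.kind)


def find_band_maximum(
    spectrum: Spectrum, window: tuple = (600.0, 800.0)
) -> float:
    """Wavelength of the maximum within a band window (e.g. the Q band)."""
    sel = (spectrum.wavelengths >= window[0]) & (spectrum.wavelengths <= window[1])
    if not sel.any():
        raise InvalidArgumentError("window contains no samples")
    lam = spectrum.wavelengths[sel]
    val = spectrum.values[sel]
    return float(lam[np.argmax(val)])
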