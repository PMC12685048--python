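"""Two-state Pr/Pfr photoswitching kinetics under piecewise-constant light.

Bacteriophytochrome-derived reversibly switchable fluorescent proteins cycle
between a red-absorbing fluorescent form (Pr, the "on" state) and a
far-red-absorbing dark form (Pfr, the "off" state).  Under irradiation the
populations obey the rate equation

    d[Pr]/dt = -phi_off * R_Pr + phi_on * R_Pfr + sum_i k_i [Pfr]_i

where ``R_X`` is the volumetric photon-absorption rate of species X and the
``k_i`` are parallel first-order thermal Pfr->Pr recovery channels.  Each
species absorbs its share of the attenuated photon flux through the
photokinetic factor ``(1 - 10**-A)``:

    R_X = I0 * (eps_X [X] / S) * (1 - 10**-A) * 1000 / l,   S = sum eps_Y [Y]

with ``I0`` the incident photon flux density (einstein cm^-2 s^-1), ``l`` the
optical path (cm), ``A = l * S`` the total absorbance, and the factor
``1000 / l`` converting the absorbed areal flux (einstein cm^-2 s^-1) into a
volumetric rate (einstein L^-1 s^-1 = M s^-1).  In the optically thin limit
this reduces to the per-molecule rate ``phi * sigma * F`` with
``sigma = ln(10) * eps * 1000 / N_A`` cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import (
    DegenerateInputError,
    IntegrationError,
    InvalidArgumentError,
    InvalidStateError,
)

LN10 = math.log(10.0)

__all__ = [
    "ExtinctionSpectrum",
    "SwitchingParameters",
    "IlluminationSegment",
    "StateVector",
    "Trajectory",
    "absorbed_photon_rates",
    "simulate_protocol",
    "photostationary_state",
    "switching_contrast",
    "fluorescence_readout",
]


class ExtinctionSpectrum:
    """Molar extinction as a function of wavelength on a stored grid.

    Linear interpolation between nodes; queries outside the grid raise
    (extinction is never extrapolated).
    """

    def __init__(self, wavelengths_nm: Sequence[float], values: Sequence[float]):
        lam = np.asarray(wavelengths_nm, dtype=float)
        val = np.asarray(values, dtype=float)
        if lam.ndim != 1 or lam.size < 2 or lam.shape != val.shape:
            raise InvalidArgumentError("extinction grid needs >= 2 matched nodes")
        if np.any(np.diff(lam) <= 0):
            raise InvalidArgumentError("wavelength grid must be strictly increasing")
        if np.any(val < 0):
            raise InvalidArgumentError("extinction values must be >= 0")
        self.wavelengths = lam
        self.values = val

    @classmethod
    def constant(cls, value: float, lam_min: float = 200.0, lam_max: float = 900.0):
        """Wavelength-independent extinction over ``[lam_min, lam_max]``."""
        return cls([lam_min, lam_max], [value, value])

    def covers(self, wavelength_nm: float) -> bool:
        return self.wavelengths[0] <= wavelength_nm <= self.wavelengths[-1]

    def __call__(self, wavelength_nm: float) -> float:
        if not self.covers(wavelength_nm):
            raise InvalidArgumentError(
                f"wavelength {wavelength_nm} nm outside extinction grid "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}]"
            )
        return float(np.interp(wavelength_nm, self.wavelengths, self.values))


@dataclass(frozen=True)
class SwitchingParameters:
    """Photophysical constants of one switchable protein.

    phi_off / phi_on are the Pr->Pfr and Pfr->Pr switching quantum yields per
    absorbed photon; ``k_thermal`` lists parallel thermal Pfr->Pr recovery
    channels as (rate s^-1, amplitude fraction) pairs with fractions summing
    to 1; ``qy_fluo_pfr`` models the residual fluorescence of the ensemble
    off-state.
    """

    phi_off: float
    phi_on: float
    eps_pr: ExtinctionSpectrum
    eps_pfr: ExtinctionSpectrum
    k_thermal: tuple = ()
    qy_fluo_pr: float = 0.09
    qy_fluo_pfr: float = 0.0

    def __post_init__(self):
        for name in ("phi_off", "phi_on", "qy_fluo_pr", "qy_fluo_pfr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name}={v} outside [0, 1]")
        k = tuple((float(r), float(a)) for r, a in self.k_thermal)
        if k:
            if any(r < 0 or a < 0 for r, a in k):
                raise InvalidArgumentError("thermal rates/amplitudes must be >= 0")
            total = sum(a for _, a in k)
            if abs(total - 1.0) > 1e-9:
                raise InvalidArgumentError(
                    f"thermal amplitude fractions must sum to 1, got {total}"
                )
        object.__setattr__(self, "k_thermal", k)

    @property
    def k_thermal_total(self) -> float:
        """Amplitude-weighted total thermal recovery rate (s^-1)."""
        return sum(r * a for r, a in self.k_thermal)

    @property
    def thermal_rates(self) -> np.ndarray:
        return np.array([r for r, _ in self.k_thermal], dtype=float)

    @property
    def thermal_fractions(self) -> np.ndarray:
        return np.array([a for _, a in self.k_thermal], dtype=float)


@dataclass(frozen=True)
class IlluminationSegment:
    """One piecewise-constant exposure: wavelength, flux, duration, path."""

    wavelength: float  # nm
    photon_flux: float  # einstein cm^-2 s^-1; 0 for dark segments
    duration: float  # s
    path_length: float = 1.0  # cm

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidArgumentError("segment duration must be > 0")
        if self.photon_flux < 0:
            raise InvalidArgumentError("photon flux must be >= 0")
        if self.path_length <= 0:
            raise InvalidArgumentError("path length must be > 0")

    @classmethod
    def dark(cls, duration: float):
        return cls(wavelength=660.0, photon_flux=0.0, duration=duration)


@dataclass(frozen=True)
class StateVector:
    """Pr/Pfr concentrations in mol/L."""

    c_pr: float
    c_pfr: float

    def __post_init__(self):
        if self.c_pr < 0 or self.c_pfr < 0:
            raise InvalidStateError("concentrations must be >= 0")

    @property
    def total(self) -> float:
        return self.c_pr + self.c_pfr


@dataclass
class Trajectory:
    """Sampled Pr/Pfr concentrations along a protocol."""

    times: np.ndarray  # s, strictly increasing
    c_pr: np.ndarray  # M
    c_pfr: np.ndarray  # M, summed over thermal sub-pools
    segment_index: np.ndarray = field(default=None)

    def state_at(self, i: int) -> StateVector:
        return StateVector(float(self.c_pr[i]), float(self.c_pfr[i]))

    @property
    def total(self) -> np.ndarray:
        return self.c_pr + self.c_pfr


def _check_segment(params: SwitchingParameters, seg: IlluminationSegment) -> None:
    if seg.photon_flux > 0 and not (
        params.eps_pr.covers(seg.wavelength) and params.eps_pfr.covers(seg.wavelength)
    ):
        raise InvalidArgumentError(
            f"segment wavelength {seg.wavelength} nm not covered by extinction grids"
        )


def absorbed_photon_rates(
    state: StateVector, params: SwitchingParameters, seg: IlluminationSegment
) -> tuple[float, float]:
    """Volumetric photon-absorption rates (R_Pr, R_Pfr) in einstein L^-1 s^-1.

    Total absorbance ``A = l (eps_Pr [Pr] + eps_Pfr [Pfr])``; the incident
    flux is attenuated by the photokinetic factor ``1 - 10**-A`` and split
    between the species in proportion to their absorbance contribution.
    """
    if state.c_pr < 0 or state.c_pfr < 0:
        raise InvalidStateError("negative concentration")
    if seg.photon_flux == 0:
        return 0.0, 0.0
    _check_segment(params, seg)
    eps_pr = params.eps_pr(seg.wavelength)
    eps_pfr = params.eps_pfr(seg.wavelength)
    s = eps_pr * state.c_pr + eps_pfr * state.c_pfr
    if s == 0:
        return 0.0, 0.0
    absorbance = seg.path_length * s
    total_areal = seg.photon_flux * (1.0 - 10.0 ** (-absorbance))
    per_unit = total_areal / s * 1000.0 / seg.path_length
    return per_unit * eps_pr * state.c_pr, per_unit * eps_pfr * state.c_pfr


def _rhs_factory(params: SwitchingParameters, seg: IlluminationSegment):
    """RHS over state [Pr, Pfr_1, ..., Pfr_n] (n thermal sub-pools, min 1)."""
    n_pools = max(len(params.k_thermal), 1)
    rates = params.thermal_rates if params.k_thermal else np.zeros(1)
    fractions = params.thermal_fractions if params.k_thermal else np.ones(1)
    if seg.photon_flux > 0:
        eps_pr = params.eps_pr(seg.wavelength)
        eps_pfr = params.eps_pfr(seg.wavelength)
    else:
        eps_pr = eps_pfr = 0.0
    flux, path = seg.photon_flux, seg.path_length

    def rhs(_t, y):
        pr = y[0]
        pools = y[1:]
        dy = np.empty(1 + n_pools)
        thermal = rates * pools
        if flux > 0:
            s = eps_pr * pr + eps_pfr * pools.sum()
            if s > 0:
                a = path * s
                per_unit = flux * (1.0 - 10.0 ** (-a)) / s * 1000.0 / path
            else:
                per_unit = 0.0
            r_pr = per_unit * eps_pr * pr
            r_pools = per_unit * eps_pfr * pools
        else:
            r_pr = 0.0
            r_pools = np.zeros(n_pools)
        off_flux = params.phi_off * r_pr
        dy[0] = -off_flux + params.phi_on * r_pools.sum() + thermal.sum()
        dy[1:] = fractions * off_flux - params.phi_on * r_pools - thermal
        return dy

    return rhs, n_pools, fractions


def simulate_protocol(
    initial: StateVector,
    params: SwitchingParameters,
    protocol: Sequence[IlluminationSegment],
    samples_per_segment: int = 200,
    rtol: float = 1e-10,
    atol: float = 1e-15,
) -> Trajectory:
    """Integrate the switching kinetics across a piecewise-constant protocol.

    Integration restarts at each segment with state hand-off; the initial
    Pfr population is distributed over the thermal sub-pools according to
    their amplitude fractions.  Uses LSODA (adaptive, stiffness-switching).
    """
    if not protocol:
        raise InvalidArgumentError("protocol must be non-empty")
    for seg in protocol:
        _check_segment(params, seg)

    n_pools = max(len(params.k_thermal), 1)
    fractions = params.thermal_fractions if params.k_thermal else np.ones(1)
    y = np.empty(1 + n_pools)
    y[0] = initial.c_pr
    y[1:] = fractions * initial.c_pfr

    times, prs, pfrs, seg_idx = [], [], [], []
    t_offset = 0.0
    for i, seg in enumerate(protocol):
        rhs, _, _ = _rhs_factory(params, seg)
        t_eval = np.linspace(0.0, seg.duration, samples_per_segment)
        sol = solve_ivp(
            rhs,
            (0.0, seg.duration),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed in segment {i}: {sol.message}", segment_index=i
            )
        start = 1 if times else 0  # drop duplicated hand-off sample
        times.append(sol.t[start:] + t_offset)
        prs.append(sol.y[0, start:])
        pfrs.append(sol.y[1:, start:].sum(axis=0))
        seg_idx.append(np.full(sol.t.size - start, i))
        y = sol.y[:, -1]
        t_offset += seg.duration

    return Trajectory(
        times=np.concatenate(times),
        c_pr=np.concatenate(prs),
        c_pfr=np.concatenate(pfrs),
        segment_index=np.concatenate(seg_idx),
    )


def switching_contrast(params: SwitchingParameters, wavelength: float) -> float:
    """Switching contrast [Pr]_0/[Pr]_inf = 1 + eps_Pr phi_off / (eps_Pfr phi_on).

    Valid when thermal recovery is negligible.  Returns ``math.inf`` (a
    documented sentinel) when the on-switching channel vanishes.
    """
    eps_pr = params.eps_pr(wavelength)
    eps_pfr = params.eps_pfr(wavelength)
    denom = eps_pfr * params.phi_on
    if denom == 0:
        return math.inf
    return 1.0 + eps_pr * params.phi_off / denom


def photostationary_state(
    params: SwitchingParameters, seg: IlluminationSegment, total_conc: float
) -> StateVector:
    """Steady state of the kinetics under one constant illumination segment.

    With no thermal recovery the residual Pr fraction is the closed-form
    ``1 / contrast``; with thermal channels the stationary sub-pool balance
    is solved self-consistently (the photokinetic factor depends on state).
    """
    if total_conc < 0:
        raise InvalidArgumentError("total concentration must be >= 0")
    _check_segment(params, seg)
    k_rates = params.thermal_rates if params.k_thermal else np.zeros(1)
    fractions = params.thermal_fractions if params.k_thermal else np.ones(1)
    any_thermal = params.k_thermal_total > 0

    if seg.photon_flux == 0:
        if not any_thermal:
            raise DegenerateInputError("no light and no thermal recovery")
        return StateVector(total_conc, 0.0)

    eps_pr = params.eps_pr(seg.wavelength)
    eps_pfr = params.eps_pfr(seg.wavelength)
    off_rate = eps_pr * params.phi_off
    on_rate = eps_pfr * params.phi_on
    if off_rate == 0 and on_rate == 0 and not any_thermal:
        raise DegenerateInputError("all switching and thermal rates are zero")

    if not any_thermal:
        if on_rate == 0:
            # absorbing off-state (no error per contract)
            if off_rate == 0:
                raise DegenerateInputError("no interconversion channel at all")
            return StateVector(0.0, total_conc)
        pr_frac = on_rate / (on_rate + off_rate)  # = 1/contrast
        return StateVector(total_conc * pr_frac, total_conc * (1.0 - pr_frac))

    # Thermal + light: stationary pools Pfr_i = a_i*phi_off*R_unit*eps_pr*Pr /
    # (phi_on*eps_pfr*R_unit + k_i) with R_unit the shared photokinetic factor
    # per unit eps*c; solve for Pr by bisection on the conservation residual.
    flux, path = seg.photon_flux, seg.path_length

    def pools_for(pr):
        # fixed-point on the pool vector (converges fast; R_unit varies slowly)
        pools = np.zeros_like(k_rates) + (total_conc - pr) * fractions
        for _ in range(200):
            s = eps_pr * pr + eps_pfr * pools.sum()
            if s <= 0:
                r_unit = 0.0
            else:
                a = path * s
                r_unit = flux * (1.0 - 10.0 ** (-a)) / s * 1000.0 / path
            new = (
                fractions * params.phi_off * r_unit * eps_pr * pr
                / (params.phi_on * eps_pfr * r_unit + k_rates)
            )
            if np.allclose(new, pools, rtol=1e-13, atol=1e-30):
                pools = new
                break
            pools = new
        return pools

    def residual(pr):
        return pr + pools_for(pr).sum() - total_conc

    if total_conc == 0:
        return StateVector(0.0, 0.0)
    lo, hi = 0.0, total_conc
    if residual(lo) >= 0:
        return StateVector(0.0, total_conc)
    pr = brentq(residual, lo, hi, xtol=1e-18 * max(total_conc, 1.0), rtol=1e-14)
    return StateVector(pr, total_conc - pr)


def fluorescence_readout(
    traj: Trajectory,
    params: SwitchingParameters,
    seg: IlluminationSegment,
    detection_efficiency: float = 1.0,
):
    """Emitted-photon rate vs. time during a readout segment.

    signal(t) = eta * (qy_fluo_pr * R_Pr(t) + qy_fluo_pfr * R_Pfr(t)); the
    Pfr term models residual off-state fluorescence.  Returns
    (times, signal) arrays over the trajectory samples.
    """
    signal = np.empty(traj.times.size)
    for i in range(traj.times.size):
        r_pr, r_pfr = absorbed_photon_rates(traj.state_at(i), params, seg)
        signal[i] = detection_efficiency * (
            params.qy_fluo_pr * r_pr + params.qy_fluo_pfr * r_pfr
        )
    return traj.times.copy(), signal
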