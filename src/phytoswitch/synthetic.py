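"""Seeded generators for every input class the analysis pipeline consumes.

Each generator draws from one explicitly seeded RNG stream (no global state)
and returns the data together with a ``truth`` record holding the exact
parameters used, so recovery can be scored without re-deriving ground truth.
Defaults emulate the study conditions of the characterization experiments:
microsecond off-switching sampled at 5 us over a 3 ms window with Poisson
counting noise, absorbance kinetics at 1-20 umol m^-2 s^-1, millisecond
log-time dark recovery, ~1,000-cycle fatigue series, and cytokeratin-like
filament phantoms for scan simulation.
"""

from __future__ import annotations

import math

import numpy as np

from . import photokinetics as pk
from .errors import InvalidArgumentError
from .qy import AbsorbanceSeries
from .resolft import Phantom
from .spectra import Spectrum
from .traces import Trace

__all__ = [
    "generate_switching_trace",
    "generate_absorbance_series",
    "generate_titration",
    "generate_fatigue_series",
    "generate_recovery_trace",
    "generate_bleach_series",
    "generate_filament_phantom",
    "generate_parallel_pair_phantom",
    "generate_absorption_spectrum",
]


def _rng(seed):
    return np.random.default_rng(seed)


def generate_switching_trace(
    half_time: float = 86e-6,
    residual_fraction: float = 0.0608,
    peak_counts: float = 5000.0,
    window: float = 3e-3,
    dt: float = 5e-6,
    n_cycles: int = 1,
    noise: str = "poisson",
    seed: int | None = None,
):
    """Off-switching fluorescence trace(s) with Poisson counting noise.

    The noiseless model is exponential-plus-plateau,
    ``y(t) = peak * (residual + (1 - residual) * 2**(-t/half_time))``;
    ``n_cycles > 1`` concatenates identical cycles (fresh on-state at each
    cycle start), emulating multicycle recordings.  Defaults are the
    bacterial-colony regime (86 us half-time, 6.08% residual, 5,000-count
    peak, 3 ms window at 5 us sampling).
    """
    if not (0 <= residual_fraction <= 1) or half_time <= 0:
        raise InvalidArgumentError("invalid truth record")
    t_cycle = np.arange(0.0, window, dt)
    model_cycle = peak_counts * (
        residual_fraction + (1.0 - residual_fraction) * 0.5 ** (t_cycle / half_time)
    )
    model = np.tile(model_cycle, n_cycles)
    times = np.arange(model.size) * dt
    if noise == "poisson":
        signal = _rng(seed).poisson(model).astype(float)
    elif noise == "none":
        signal = model.copy()
    else:
        raise InvalidArgumentError(f"unknown noise model '{noise}'")
    truth = {
        "half_time_s": half_time,
        "residual_fraction": residual_fraction,
        "peak_counts": peak_counts,
        "n_cycles": n_cycles,
        "cycle_samples": t_cycle.size,
        "seed": seed,
    }
    return Trace(times, signal, noise_model=noise, metadata={"truth": truth}), truth


def generate_absorbance_series(
    phi_off: float = 0.03,
    eps_pr_irr: float = 86100.0,
    eps_pr_probe: float = 86100.0,
    photon_flux: float = 1.0e-9,
    irradiation_path: float = 0.2,
    probe_path: float = 1.0,
    initial_conc: float = 5e-6,
    duration: float | None = None,
    n_samples: int = 200,
    conversion: float = 0.3,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Probe-absorbance decay under constant irradiation, via the forward model.

    The kinetics are integrated with the photokinetic ODE (pure off-switching:
    phi_on = 0, no thermal recovery, Pfr transparent at both wavelengths) and
    the probe absorbance is ``eps_pr_probe * l_probe * [Pr](t)``.  ``duration``
    defaults to the time needed for the requested fractional ``conversion`` of
    the initial Pr pool (optically-thin estimate).  Gaussian absorbance noise
    of absolute standard deviation ``noise_sd`` is added when requested.
    """
    if phi_off < 0 or photon_flux <= 0 or initial_conc <= 0:
        raise InvalidArgumentError("invalid truth record")
    params = pk.SwitchingParameters(
        phi_off=phi_off,
        phi_on=0.0,
        eps_pr=pk.ExtinctionSpectrum.constant(eps_pr_irr),
        eps_pfr=pk.ExtinctionSpectrum.constant(0.0),
    )
    if duration is None:
        if phi_off == 0:
            duration = 10.0
        else:
            k_thin = phi_off * math.log(10.0) * eps_pr_irr * 1000.0 * photon_flux
            duration = -math.log(1.0 - conversion) / k_thin
    seg = pk.IlluminationSegment(
        wavelength=638.0,
        photon_flux=photon_flux,
        duration=duration,
        path_length=irradiation_path,
    )
    traj = pk.simulate_protocol(
        pk.StateVector(initial_conc, 0.0), params, [seg],
        samples_per_segment=n_samples,
    )
    absorbance = eps_pr_probe * probe_path * traj.c_pr
    if noise_sd > 0:
        absorbance = absorbance + _rng(seed).normal(0.0, noise_sd, absorbance.size)
        absorbance = np.clip(absorbance, 0.0, None)
    series = AbsorbanceSeries(
        times=traj.times,
        absorbance=absorbance,
        probe_wavelength=680.0,
        probe_path=probe_path,
        irradiation_wavelength=638.0,
        irradiation_path=irradiation_path,
        photon_flux=photon_flux,
    )
    truth = {
        "phi_off": phi_off,
        "eps_pr_irr": eps_pr_irr,
        "eps_pr_probe": eps_pr_probe,
        "photon_flux": photon_flux,
        "initial_conc": initial_conc,
        "duration_s": duration,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return series, truth


def generate_titration(
    pka: float = 4.5,
    hill: float = 1.0,
    ph_min: float = 3.0,
    ph_max: float = 9.0,
    n_points: int = 12,
    base: float = 0.05,
    span: float = 1.0,
    noise_fraction: float = 0.0,
    seed: int | None = None,
):
    """pH titration of the chromophore band: Henderson-Hasselbalch sigmoid.

    Returns ``(ph, signal, truth)``; noise is gaussian with standard
    deviation ``noise_fraction * span``.
    """
    ph = np.linspace(ph_min, ph_max, n_points)
    model = base + span / (1.0 + 10.0 ** (hill * (pka - ph)))
    signal = model.copy()
    if noise_fraction > 0:
        signal = signal + _rng(seed).normal(0.0, noise_fraction * span, signal.size)
    truth = {"pka": pka, "hill": hill, "base": base, "span": span, "seed": seed}
    return ph, signal, truth


def generate_fatigue_series(
    cycles_to_half: float = 972.0,
    n_cycles: int = 1200,
    initial_max: float = 1.0,
    noise_fraction: float = 0.0,
    seed: int | None = None,
):
    """Per-cycle maxima with geometric fatigue: m_n = m_0 * q**n.

    The per-cycle survival ``q = 0.5**(1/cycles_to_half)``; multiplicative
    gaussian noise of the given fraction is applied.  Returns
    ``(maxima, truth)``.
    """
    if cycles_to_half <= 0:
        raise InvalidArgumentError("cycles_to_half must be > 0")
    q = 0.5 ** (1.0 / cycles_to_half)
    n = np.arange(n_cycles)
    maxima = initial_max * q**n
    if noise_fraction > 0:
        maxima = maxima * (1.0 + _rng(seed).normal(0.0, noise_fraction, maxima.size))
        maxima = np.clip(maxima, 1e-12, None)
    truth = {"q": q, "cycles_to_half": cycles_to_half, "seed": seed}
    return maxima, truth


def generate_recovery_trace(
    model: str = "logarithmic",
    half_time: float = 6.8e-3,
    components: tuple = ((68.0, 0.03), (770.0, 0.97)),
    plateau: float = 0.85,
    t_min: float = 1e-4,
    t_max: float = 0.1,
    n_points: int = 30,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Dark fluorescence-recovery trace on a log-spaced time grid.

    ``model="logarithmic"``: a + b*log10(t) clipped to [0, plateau], with
    (a, b) chosen so the curve crosses 0.5 (half of the equilibrium signal,
    which is 1 by normalization) at ``half_time`` and reaches ``plateau`` at
    ``t_max`` — emulating the millisecond fluorescence-recovery regime.
    ``model="multi_exponential"``: 1 - sum_i a_i exp(-t/tau_i) from
    ``components`` as (time-constant s, fraction) pairs — the bulk-absorption
    regime.  Returns ``(Trace, truth)`` with equilibrium normalized to 1.
    """
    times = np.geomspace(t_min, t_max, n_points)
    if model == "logarithmic":
        b = (plateau - 0.5) / math.log10(t_max / half_time)
        a = 0.5 - b * math.log10(half_time)
        signal = np.clip(a + b * np.log10(times), 0.0, plateau)
        truth = {"model": model, "a": a, "b": b, "half_time_s": half_time,
                 "plateau": plateau, "seed": seed}
    elif model == "multi_exponential":
        fractions = np.array([f for _, f in components])
        taus = np.array([tau for tau, _ in components])
        fractions = fractions / fractions.sum()
        signal = 1.0 - np.sum(
            fractions[:, None] * np.exp(-times[None, :] / taus[:, None]), axis=0
        )
        half = _half_time_multi_exp(fractions, taus)
        truth = {"model": model, "components": tuple(zip(taus, fractions)),
                 "half_time_s": half, "seed": seed}
    else:
        raise InvalidArgumentError(f"unknown recovery model '{model}'")
    if noise_sd > 0:
        signal = signal + _rng(seed).normal(0.0, noise_sd, signal.size)
        signal = np.clip(signal, 0.0, None)
    return Trace(times, signal, noise_model="gaussian" if noise_sd else "none",
                 metadata={"truth": truth}), truth


def _half_time_multi_exp(fractions, taus):
    from scipy.optimize import brentq

    f = lambda t: 1.0 - np.sum(fractions * np.exp(-t / taus)) - 0.5
    return brentq(f, taus.min() * 1e-6, taus.max() * 1e3)


def generate_bleach_series(
    frames_to_half: float = 2300.0,
    n_frames: int = 5000,
    every: int = 100,
    initial: float = 1.0,
    noise_fraction: float = 0.0,
    seed: int | None = None,
):
    """Frame-mean intensity under mono-exponential photobleaching.

    Sampled every ``every`` frames, as in long time-lapse recordings.
    Returns ``(Trace, truth)`` (Trace.times carries the frame numbers).
    """
    if frames_to_half <= 0:
        raise InvalidArgumentError("frames_to_half must be > 0")
    frames = np.arange(0, n_frames, every, dtype=float)
    lam = math.log(2.0) / frames_to_half
    signal = initial * np.exp(-lam * frames)
    if noise_fraction > 0:
        signal = signal * (1.0 + _rng(seed).normal(0.0, noise_fraction, signal.size))
        signal = np.clip(signal, 1e-12, None)
    truth = {"frames_to_half": frames_to_half, "rate_per_frame": lam, "seed": seed}
    return Trace(frames, signal, noise_model="gaussian" if noise_fraction else "none",
                 metadata={"truth": truth}), truth


def generate_filament_phantom(
    n_filaments: int = 3,
    field_size: tuple = (3000.0, 3000.0),
    labeling_density: float = 100.0,
    curvature: float = 0.3,
    seed: int | None = None,
) -> Phantom:
    """Smooth curved filaments with Poisson-distributed fluorophore labels.

    Each filament is a random smooth polyline spanning the field; label
    positions follow a Poisson process along the arc at ``labeling_density``
    fluorophores per um.  Emulates cytokeratin filaments in adherent cells.
    """
    if labeling_density <= 0:
        raise InvalidArgumentError("labeling density must be > 0")
    rng = _rng(seed)
    w, h = field_size
    labels = []
    for _ in range(n_filaments):
        # random chord across the field, perturbed by a smooth sine bow
        theta = rng.uniform(0, math.pi)
        cx, cy = rng.uniform(0.3 * w, 0.7 * w), rng.uniform(0.3 * h, 0.7 * h)
        length = 1.2 * math.hypot(w, h)
        s = np.linspace(-0.5, 0.5, 200)
        bow = curvature * min(w, h) * np.sin(math.pi * s + rng.uniform(0, 2 * math.pi))
        x = cx + length * s * math.cos(theta) - bow * math.sin(theta)
        y = cy + length * s * math.sin(theta) + bow * math.cos(theta)
        seg_len = np.hypot(np.diff(x), np.diff(y))
        arc = np.concatenate([[0.0], np.cumsum(seg_len)])
        n_labels = rng.poisson(labeling_density * arc[-1] / 1000.0)
        pos_arc = np.sort(rng.uniform(0.0, arc[-1], n_labels))
        lx = np.interp(pos_arc, arc, x)
        ly = np.interp(pos_arc, arc, y)
        inside = (lx >= 0) & (lx <= w) & (ly >= 0) & (ly <= h)
        labels.append(np.column_stack([lx[inside], ly[inside]]))
    positions = np.vstack([p for p in labels if p.size]) if labels else np.empty((0, 2))
    if positions.shape[0] == 0:
        raise InvalidArgumentError("no labels generated; increase density or field")
    return Phantom(positions=positions, weights=np.ones(positions.shape[0]),
                   field_size=field_size)


def generate_parallel_pair_phantom(
    separation: float = 129.0,
    length: float = 900.0,
    labeling_density: float = 200.0,
    field_size: tuple | None = None,
    margin: float = 450.0,
    seed: int | None = None,
) -> Phantom:
    """Canonical two parallel vertical lines ``separation`` nm apart.

    Labels are Poisson-placed along each line; the preset probes whether a
    scan scheme resolves line pairs at the given separation (e.g. 129 nm,
    the closest filament spacing resolved in live-cell recordings).
    """
    if labeling_density <= 0:
        raise InvalidArgumentError("labeling density must be > 0")
    rng = _rng(seed)
    if field_size is None:
        field_size = (2 * margin + separation, length)
    w, h = field_size
    x_left = (w - separation) / 2.0
    positions = []
    for x in (x_left, x_left + separation):
        n = rng.poisson(labeling_density * h / 1000.0)
        ys = rng.uniform(0.0, h, n)
        positions.append(np.column_stack([np.full(n, x), ys]))
    pos = np.vstack(positions)
    return Phantom(positions=pos, weights=np.ones(pos.shape[0]), field_size=field_size)


def generate_absorption_spectrum(
    holo_fraction: float = 1.0,
    q_band_nm: float = 689.0,
    q_band_eps: float = 86100.0,
    soret_nm: float = 391.0,
    soret_eps: float = 39900.0,
    aromatic_eps: float = 128000.0,
    off_state: bool = False,
    baseline: float = 0.0,
    grid: np.ndarray | None = None,
    concentration_path: float = 1e-5,
) -> Spectrum:
    """Synthetic bacteriophytochrome-like absorbance spectrum.

    Gaussian bands at the aromatic (278 nm), biliverdin Soret (391 nm) and
    Q-band maxima; the off-state variant shifts the Q band to 720 nm with
    reduced amplitude.  ``holo_fraction`` scales the chromophore bands
    relative to the protein band (apo-protein absorbs only at 278 nm);
    ``concentration_path`` = c*l (M cm) sets the absolute absorbance scale.
    This is a synthetic stand-in spectrum for generator round-trips, not a
    measured reference.
    """
    if grid is None:
        grid = np.arange(250.0, 850.0, 1.0)
    grid = np.asarray(grid, dtype=float)

    def band(center, eps, width):
        return eps * np.exp(-0.5 * ((grid - center) / width) ** 2)

    eps_curve = band(278.0, aromatic_eps, 12.0)
    chromo = band(soret_nm, soret_eps, 25.0)
    if off_state:
        chromo = chromo + band(720.0, 0.55 * q_band_eps, 22.0) + band(
            q_band_nm, 0.1 * q_band_eps, 18.0
        )
    else:
        chromo = chromo + band(q_band_nm, q_band_eps, 18.0)
    eps_curve = eps_curve + holo_fraction * chromo
    values = eps_curve * concentration_path + baseline
    return Spectrum(grid, values, kind="absorbance")
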