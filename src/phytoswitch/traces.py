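"""Fitting and summary statistics for characterization traces.

Covers the standard characterization battery for a reversibly switchable
fluorescent protein: off-switching decay (half-time and residual off-state
fluorescence), switching fatigue over repeated cycles, thermal dark
recovery, photobleaching across frames, pH titration, and small derived
scalars (molecular brightness, holo-protein fraction), plus the Lorentzian
line-profile FWHM used to quantify image resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.special import gammaincc
from scipy import stats

from .errors import (
    AmbiguousPeakError,
    FitFailureError,
    InvalidArgumentError,
    MarkupError,
    NoDecayError,
    NoRecoveryError,
)

__all__ = [
    "Trace",
    "OffSwitchFit",
    "RecoveryFit",
    "fit_off_switching",
    "analyze_switching_fatigue",
    "fatigue_from_maxima",
    "fit_thermal_recovery",
    "estimate_recovery_ratio",
    "fit_photobleaching",
    "fit_pka",
    "molecular_brightness",
    "holo_fraction",
    "holo_fraction_from_absorbance",
    "lorentzian_fwhm",
    "round_sig",
]

#: Sentinel for "no decay / no fatigue": cycles-to-half is undefined.
UNDEFINED = math.inf


@dataclass
class Trace:
    """A measured or synthetic signal vs. time."""

    times: np.ndarray
    signal: np.ndarray
    noise_model: str = "none"  # none | poisson | gaussian
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise InvalidArgumentError("times and signal must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if self.noise_model == "poisson" and np.any(self.signal < 0):
            raise InvalidArgumentError("poisson counts must be >= 0")


@dataclass
class OffSwitchFit:
    half_time: float  # s
    residual_fraction: float  # plateau / initial, in [0, 1]
    amplitude: float  # decaying amplitude in signal units
    model_label: str  # "exponential" or "gamma"
    fit_rmse: float
    params: dict = field(default_factory=dict)
    aicc: dict = field(default_factory=dict)


@dataclass
class RecoveryFit:
    components: tuple  # ((time_constant_s, amplitude_fraction), ...)
    model_label: str  # "multi_exponential" or "logarithmic"
    half_recovery_time: float  # s
    aicc: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (presentation helper)."""
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _aicc(rss: float, n: int, k: int, scale: float) -> float:
    # floor the RSS so that noiseless data cannot drive AICc to -inf and
    # reward spurious extra parameters
    rss = max(rss, n * (1e-10 * max(scale, 1e-300)) ** 2)
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# off-switching


def _exp_plateau(t, plateau, amp, k):
    return plateau + amp * np.exp(-k * t)


def _gamma_plateau(t, plateau, amp, shape, theta):
    # gamma-survival decay; reduces to the exponential at shape = 1
    return plateau + amp * gammaincc(shape, t / theta)


def fit_off_switching(trace: Trace) -> OffSwitchFit:
    """Fit an off-switching fluorescence decay.

    Both an exponential-plus-plateau and a gamma-survival-plus-plateau model
    are fitted and the winner chosen by AICc.  The half-time is reported
    model-free as the time where the fitted curve crosses midway between its
    initial value and its plateau; the residual fraction is plateau/initial.
    """
    t, y = trace.times, trace.signal
    if len(t) < 20:
        raise InvalidArgumentError("need >= 20 samples for an off-switching fit")
    head = float(np.mean(y[: max(3, len(y) // 20)]))
    tail = float(np.mean(y[-max(3, len(y) // 10):]))
    noise_scale = float(np.std(np.diff(y))) / math.sqrt(2.0) if len(y) > 2 else 0.0
    if head - tail <= 3.0 * noise_scale / math.sqrt(len(y) // 10 + 1) or head <= tail:
        raise NoDecayError("trace does not decay")

    t0 = t - t[0]
    span = t0[-1]
    # crude half-crossing for rate initialisation
    mid = tail + 0.5 * (head - tail)
    below = np.nonzero(y <= mid)[0]
    t_half0 = t0[below[0]] if below.size else span / 2
    k0 = math.log(2.0) / max(t_half0, span / len(t0))

    fits = {}
    try:
        popt, _ = curve_fit(
            _exp_plateau, t0, y, p0=[tail, head - tail, k0],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
        rss = float(np.sum((y - _exp_plateau(t0, *popt)) ** 2))
        fits["exponential"] = (popt, rss, 3, lambda tt, p=popt: _exp_plateau(tt, *p))
    except (RuntimeError, ValueError):
        pass
    try:
        popt, _ = curve_fit(
            _gamma_plateau, t0, y, p0=[tail, head - tail, 1.0, 1.0 / k0],
            bounds=([0.0, 0.0, 0.05, 0.0], [np.inf, np.inf, 50.0, np.inf]),
            maxfev=20000,
        )
        rss = float(np.sum((y - _gamma_plateau(t0, *popt)) ** 2))
        fits["gamma"] = (popt, rss, 4, lambda tt, p=popt: _gamma_plateau(tt, *p))
    except (RuntimeError, ValueError):
        pass
    if not fits:
        raise FitFailureError("neither decay model converged")

    aicc = {
        name: _aicc(rss, len(y), k, head) for name, (_, rss, k, _) in fits.items()
    }
    best = min(aicc, key=aicc.get)
    popt, rss, _, curve = fits[best]
    plateau = float(popt[0])
    initial = float(curve(np.array([0.0]))[0])
    amp = initial - plateau
    if amp <= 0:
        raise NoDecayError("fitted amplitude is non-positive")

    target = plateau + 0.5 * amp
    # model-free half-time: first crossing of the fitted curve
    f = lambda tt: float(curve(np.array([tt]))[0]) - target
    hi = span
    while f(hi) > 0 and hi < span * 1e6:
        hi *= 2.0
    half = brentq(f, 0.0, hi, xtol=span * 1e-12)

    names = (
        ("plateau", "amp", "k") if best == "exponential"
        else ("plateau", "amp", "shape", "theta")
    )
    return OffSwitchFit(
        half_time=float(half),
        residual_fraction=min(max(plateau / initial, 0.0), 1.0),
        amplitude=amp,
        model_label=best,
        fit_rmse=math.sqrt(rss / len(y)),
        params=dict(zip(names, (float(p) for p in popt))),
        aicc=aicc,
    )


# ---------------------------------------------------------------------------
# switching fatigue


def fatigue_from_maxima(maxima: np.ndarray):
    """Geometric-decay fit to per-cycle maxima.

    Fits m_n = m_0 q**n (log-linear least squares) and returns
    ``(maxima, q, cycles_to_half)`` with the interpolated
    cycles-to-half ``ln(0.5)/ln(q)``; ``q >= 1`` yields the UNDEFINED
    sentinel with a warning.
    """
    maxima = np.asarray(maxima, dtype=float)
    if len(maxima) < 3:
        raise InvalidArgumentError("need >= 3 cycle maxima")
    if np.any(maxima <= 0):
        raise InvalidArgumentError("cycle maxima must be > 0")
    n = np.arange(len(maxima))
    res = stats.linregress(n, np.log(maxima))
    q = math.exp(res.slope)
    if q >= 1.0:
        warnings.warn("cycle maxima do not decay (q >= 1); cycles_to_half undefined",
                      stacklevel=2)
        return maxima, q, UNDEFINED
    return maxima, q, math.log(0.5) / math.log(q)


def analyze_switching_fatigue(multicycle: Trace, cycle_boundaries: Sequence[int]):
    """Per-cycle maxima and interpolated cycles-to-half from a multicycle trace.

    ``cycle_boundaries`` are sample indices delimiting consecutive cycles
    (protocol markup, len >= 4 for >= 3 cycles).
    """
    bounds = list(cycle_boundaries)
    if len(bounds) < 4:
        raise MarkupError("need boundaries for >= 3 cycles")
    maxima = np.array(
        [float(np.max(multicycle.signal[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    )
    return fatigue_from_maxima(maxima)


# ---------------------------------------------------------------------------
# thermal recovery


def _multi_exp_curve(t, plateau, amps, taus):
    y = np.full_like(t, plateau, dtype=float)
    for a, tau in zip(amps, taus):
        y -= a * np.exp(-t / tau)
    return y


def _fit_n_exp(t, y, n_comp):
    plateau0 = float(np.max(y))
    depth0 = plateau0 - float(np.min(y))
    taus0 = np.exp(
        np.linspace(math.log(max(t[t > 0].min(), 1e-12)), math.log(t.max()), n_comp + 2)
    )[1:-1]

    def model(tt, *p):
        plateau = p[0]
        amps = p[1 : 1 + n_comp]
        taus = p[1 + n_comp :]
        return _multi_exp_curve(tt, plateau, amps, taus)

    p0 = [plateau0] + [depth0 / n_comp] * n_comp + list(taus0)
    lb = [0.0] + [0.0] * n_comp + [1e-12] * n_comp
    ub = [np.inf] * (1 + 2 * n_comp)
    popt, _ = curve_fit(model, t, y, p0=p0, bounds=(lb, ub), maxfev=40000)
    rss = float(np.sum((y - model(t, *popt)) ** 2))
    return popt, rss, 1 + 2 * n_comp, model


def _log_model(t, a, b):
    return a + b * np.log10(t)


def fit_thermal_recovery(recovery: Trace, equilibrium: float | None = None) -> RecoveryFit:
    """Fit a dark-recovery trace and report the half-recovery time.

    Candidate models: saturating multi-exponentials with 1-3 components
    (y = plateau - sum_i a_i exp(-t/tau_i)) and a logarithmic growth curve
    a + b*log10(t), clipped to [0, plateau]; the winner is chosen by AICc.
    ``equilibrium`` is the reference level defining 50% recovery; when
    omitted the fitted plateau is used.
    """
    t, y = recovery.times, recovery.signal
    if len(t) < 8:
        raise InvalidArgumentError("need >= 8 samples for a recovery fit")
    head = float(np.mean(y[: max(2, len(y) // 10)]))
    tail = float(np.mean(y[-max(2, len(y) // 10):]))
    if tail <= head or (tail - head) < 1e-3 * max(abs(tail), abs(head), 1e-300):
        raise NoRecoveryError("trace does not recover (already at plateau?)")
    if np.any(t <= 0):
        raise InvalidArgumentError("recovery times must be > 0 (log-time models)")

    fits, aicc = {}, {}
    for n_comp in (1, 2, 3):
        try:
            popt, rss, k, model = _fit_n_exp(t, y, n_comp)
            label = f"exp{n_comp}"
            fits[label] = (popt, rss, model, n_comp)
            aicc[label] = _aicc(rss, len(y), k, tail)
        except (RuntimeError, ValueError):
            continue
    try:
        b0 = (tail - head) / max(math.log10(t[-1] / t[0]), 1e-12)
        popt, _ = curve_fit(_log_model, t, y, p0=[head, b0], maxfev=20000)
        rss = float(np.sum((y - _log_model(t, *popt)) ** 2))
        fits["logarithmic"] = (popt, rss, _log_model, 0)
        aicc["logarithmic"] = _aicc(rss, len(y), 2, tail)
    except (RuntimeError, ValueError):
        pass
    if not fits:
        raise FitFailureError("no recovery model converged")

    best = min(aicc, key=aicc.get)
    popt, rss, model, n_comp = fits[best]

    if best == "logarithmic":
        a, b = (float(p) for p in popt)
        if b <= 0:
            raise NoRecoveryError("fitted logarithmic slope is non-positive")
        ref = equilibrium if equilibrium is not None else float(model(t[-1], *popt))
        half = 10.0 ** ((0.5 * ref - a) / b)
        return RecoveryFit(
            components=(),
            model_label="logarithmic",
            half_recovery_time=float(half),
            aicc=aicc,
            params={"a": a, "b": b, "reference": ref},
        )

    plateau = float(popt[0])
    amps = np.array(popt[1 : 1 + n_comp], dtype=float)
    taus = np.array(popt[1 + n_comp :], dtype=float)
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    fractions = amps / amps.sum() if amps.sum() > 0 else amps
    ref = equilibrium if equilibrium is not None else plateau
    target = 0.5 * ref

    def f(tt):
        return float(_multi_exp_curve(np.array([tt]), plateau, amps, taus)[0]) - target

    lo, hi = t[0] * 1e-3, t[-1]
    while f(hi) < 0 and hi < t[-1] * 1e6:
        hi *= 2.0
    if f(lo) > 0:
        half = lo
    else:
        half = brentq(f, lo, hi, rtol=1e-12)
    return RecoveryFit(
        components=tuple((float(tau), float(fr)) for tau, fr in zip(taus, fractions)),
        model_label="multi_exponential",
        half_recovery_time=float(half),
        aicc=aicc,
        params={"plateau": plateau, "n_components": n_comp},
    )


def estimate_recovery_ratio(trace: Trace, protocol_markup: dict):
    """Raw and normalized recovery after a dark or light-driven interval.

    ``protocol_markup`` must name ``off_end_index`` (last sample of the
    initial off-switching step) and ``readout_start_index`` (first sample of
    the final readout step); optional ``equilibrium`` and ``off_plateau``
    references enable the normalized fraction
    (readout_start - off_plateau) / (equilibrium - off_plateau).
    """
    for key in ("off_end_index", "readout_start_index"):
        if key not in protocol_markup:
            raise MarkupError(f"protocol markup missing '{key}'")
    i_off = int(protocol_markup["off_end_index"])
    i_read = int(protocol_markup["readout_start_index"])
    try:
        off_val = float(trace.signal[i_off])
        read_val = float(trace.signal[i_read])
    except IndexError as exc:
        raise MarkupError(f"markup index out of range: {exc}") from None
    if off_val == 0:
        raise MarkupError("off-switching end value is zero; ratio undefined")
    ratio = read_val / off_val
    fraction = None
    if "equilibrium" in protocol_markup:
        eq = float(protocol_markup["equilibrium"])
        off_plateau = float(protocol_markup.get("off_plateau", off_val))
        if eq != off_plateau:
            fraction = (read_val - off_plateau) / (eq - off_plateau)
    return ratio, fraction


# ---------------------------------------------------------------------------
# photobleaching


def fit_photobleaching(frame_means: Trace):
    """Mono-exponential bleaching fit over frame index.

    Returns ``(frames_to_half, params)``; non-decaying series yield the
    UNDEFINED sentinel (with a warning), mirroring the fatigue analyzer.
    """
    n, y = frame_means.times, frame_means.signal
    if len(n) < 10:
        raise InvalidArgumentError("need >= 10 frames")

    def model(nn, y0, lam):
        return y0 * np.exp(-lam * nn)

    head = float(np.mean(y[: max(2, len(y) // 10)]))
    tail = float(np.mean(y[-max(2, len(y) // 10):]))
    if tail >= head:
        warnings.warn("frame means do not decay; frames_to_half undefined",
                      stacklevel=2)
        return UNDEFINED, {}
    lam0 = max(math.log(head / max(tail, 1e-300)) / (n[-1] - n[0]), 1e-12)
    popt, _ = curve_fit(model, n, y, p0=[head, lam0], maxfev=20000)
    y0, lam = (float(p) for p in popt)
    if lam <= 0:
        warnings.warn("fitted bleaching rate non-positive; frames_to_half undefined",
                      stacklevel=2)
        return UNDEFINED, {"y0": y0, "rate_per_frame": lam}
    return math.log(2.0) / lam, {"y0": y0, "rate_per_frame": lam}


# ---------------------------------------------------------------------------
# pH titration


def fit_pka(ph: np.ndarray, signal: np.ndarray):
    """Henderson-Hasselbalch sigmoid fit: base + span/(1 + 10**(n(pKa - pH))).

    Returns ``(pka, hill, report)`` with standard errors in the report.
    """
    ph = np.asarray(ph, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(ph) < 6:
        raise InvalidArgumentError("need >= 6 pH points")
    span0 = float(np.max(signal) - np.min(signal))
    if span0 < 1e-6 * max(abs(float(np.max(signal))), 1e-300):
        raise FitFailureError("titration signal is constant; no transition to fit")
    # warn on non-monotone sections beyond the noise scale
    noise = float(np.std(np.diff(signal))) / math.sqrt(2.0)
    if np.any(np.diff(signal) < -4.0 * noise):
        warnings.warn("titration curve is non-monotone beyond noise", stacklevel=2)

    def model(x, base, span, pka, hill):
        return base + span / (1.0 + 10.0 ** (hill * (pka - x)))

    mid = float(ph[np.argmin(np.abs(signal - (np.min(signal) + span0 / 2)))])
    try:
        popt, pcov = curve_fit(
            model, ph, signal,
            p0=[float(np.min(signal)), span0, mid, 1.0],
            bounds=([-np.inf, 0.0, ph.min() - 2, 0.05], [np.inf, np.inf, ph.max() + 2, 10.0]),
            maxfev=40000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"pKa fit did not converge: {exc}") from None
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    base, span, pka, hill = (float(p) for p in popt)
    report = {
        "base": base, "span": span,
        "pka_se": float(perr[2]), "hill_se": float(perr[3]),
    }
    return pka, hill, report


# ---------------------------------------------------------------------------
# derived scalars


def molecular_brightness(ec: float, qy: float) -> float:
    """Molecular brightness = extinction coefficient x fluorescence QY / 1000."""
    if ec < 0 or qy < 0:
        raise InvalidArgumentError("ec and qy must be >= 0")
    return ec * qy / 1000.0


def holo_fraction(holo: float, apo: float) -> float:
    """Holo-protein fraction from a holo:apo ratio h:a -> h/(h+a)."""
    if holo < 0 or apo < 0 or holo + apo == 0:
        raise InvalidArgumentError("ratio terms must be >= 0 and not both zero")
    return holo / (holo + apo)


def holo_fraction_from_absorbance(r1: float, r2: float, tolerance: float = 0.02) -> float:
    """Holo fraction via absorbance ratios: r1 = Amax/A280, r2 = eps_max/eps280.

    r1/r2 compares the chromophore-band absorbance of the sample to that of a
    fully chromophore-bound protein; values slightly above 1 (noise) are
    clipped with a warning.
    """
    if r1 <= 0 or r2 <= 0:
        raise InvalidArgumentError("absorbance ratios must be > 0")
    frac = r1 / r2
    if frac > 1.0 + tolerance:
        warnings.warn(
            f"r1/r2 = {frac:.3f} exceeds 1 beyond tolerance; clipping to 1",
            stacklevel=2,
        )
    return min(frac, 1.0)


# ---------------------------------------------------------------------------
# Lorentzian line profiles


def _lorentzian(x, base, amp, x0, gamma):
    return base + amp / (1.0 + ((x - x0) / gamma) ** 2)


def lorentzian_fwhm(
    positions: np.ndarray,
    intensity: np.ndarray,
    averaging_width: int = 3,
    window: tuple | None = None,
):
    """FWHM of a single-peak line profile via a Lorentzian fit.

    ``intensity`` may be 1-D (a single profile) or 2-D (a patch of parallel
    adjacent profiles, one per row); for a patch, ``averaging_width``
    adjacent central rows are averaged first, following common line-profile
    practice.  Returns ``(fwhm, report)`` with FWHM = 2*gamma in the units
    of ``positions``.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if y.ndim == 2:
        mid = y.shape[0] // 2
        half = max(averaging_width // 2, 0)
        rows = y[max(mid - half, 0) : mid + half + 1]
        y = rows.mean(axis=0)
    if x.shape != y.shape:
        raise InvalidArgumentError("positions and intensity must align")
    if window is not None:
        keep = (x >= window[0]) & (x <= window[1])
        x, y = x[keep], y[keep]
    if len(x) < 5:
        raise InvalidArgumentError("profile too short")

    base0 = float(np.min(y))
    amp0 = float(np.max(y) - base0)
    noise = float(np.std(np.diff(y))) / math.sqrt(2.0)
    if amp0 <= 5.0 * noise or amp0 == 0:
        raise AmbiguousPeakError("no dominant peak in profile")
    if window is None:
        # require a single dominant local maximum above half height
        above = y > base0 + 0.5 * amp0
        runs = np.diff(above.astype(int))
        n_rises = int(np.sum(runs == 1)) + (1 if above[0] else 0)
        if n_rises > 1:
            raise AmbiguousPeakError(
                f"{n_rises} half-height peaks found; supply a window"
            )
    x0_0 = float(x[np.argmax(y)])
    gamma0 = max((x[-1] - x[0]) / 10.0, abs(x[1] - x[0]))
    try:
        popt, pcov = curve_fit(
            _lorentzian, x, y, p0=[base0, amp0, x0_0, gamma0],
            bounds=([-np.inf, 0.0, x[0], 0.0], [np.inf, np.inf, x[-1], np.inf]),
            maxfev=40000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"Lorentzian fit failed: {exc}") from None
    base, amp, x0, gamma = (float(p) for p in popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    report = {
        "baseline": base, "amplitude": amp, "center": x0,
        "gamma": gamma, "gamma_se": float(perr[3]),
        "rmse": float(np.sqrt(np.mean((y - _lorentzian(x, *popt)) ** 2))),
    }
    return 2.0 * gamma, report
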