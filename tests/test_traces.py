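"""Characterization fitters: off-switching, fatigue, recovery, bleach, pKa,
derived scalars, Lorentzian profiles."""

import math

import numpy as np
import pytest

from phytoswitch import synthetic as syn
from phytoswitch import traces as ta
from phytoswitch.errors import (
    AmbiguousPeakError,
    FitFailureError,
    InvalidArgumentError,
    MarkupError,
    NoDecayError,
    NoRecoveryError,
)


class TestOffSwitching:
    def test_noiseless_recovery_to_4_significant_figures(self):
        trace, _ = syn.generate_switching_trace(
            half_time=86e-6, residual_fraction=0.0608, noise="none"
        )
        fit = ta.fit_off_switching(trace)
        assert fit.half_time == pytest.approx(86e-6, rel=1e-4)
        assert fit.residual_fraction == pytest.approx(0.0608, rel=1e-4)

    def test_constant_trace_is_no_decay(self):
        trace = ta.Trace(np.arange(30) * 1e-5, np.full(30, 100.0))
        with pytest.raises(NoDecayError):
            ta.fit_off_switching(trace)

    def test_median_recovery_under_poisson_noise(self):
        halves = []
        for seed in range(1, 51):
            trace, _ = syn.generate_switching_trace(seed=seed)
            halves.append(ta.fit_off_switching(trace).half_time)
        assert np.median(halves) == pytest.approx(86e-6, rel=0.05)

    def test_affine_invariance(self):
        trace, _ = syn.generate_switching_trace(seed=5)
        fit1 = ta.fit_off_switching(trace)
        scaled = ta.Trace(trace.times, trace.signal * 3.7 + 0.0)
        fit2 = ta.fit_off_switching(scaled)
        assert fit2.half_time == pytest.approx(fit1.half_time, rel=1e-6)
        assert fit2.residual_fraction == pytest.approx(fit1.residual_fraction, rel=1e-6)

    def test_gamma_truth_still_yields_midpoint_half_time(self):
        # gamma-survival decay (shape 3) is not exponential; the model-free
        # half-time must match the curve's own midpoint crossing
        from scipy.special import gammaincc

        t = np.arange(0.0, 3e-3, 5e-6)
        theta = 40e-6
        y = 100.0 + 4900.0 * gammaincc(3.0, t / theta)
        fit = ta.fit_off_switching(ta.Trace(t, y))
        assert fit.model_label == "gamma"
        from scipy.optimize import brentq

        target_half = brentq(
            lambda tt: gammaincc(3.0, tt / theta) - 0.5, 1e-7, 1e-3
        )
        assert fit.half_time == pytest.approx(target_half, rel=1e-3)


class TestFatigue:
    def test_q_half_gives_one_cycle(self):
        _, q, cycles = ta.fatigue_from_maxima(np.array([1.0, 0.5, 0.25, 0.125]))
        assert q == pytest.approx(0.5)
        assert cycles == pytest.approx(1.0)

    def test_no_fatigue_sentinel(self):
        with pytest.warns(UserWarning):
            _, q, cycles = ta.fatigue_from_maxima(np.ones(10))
        assert cycles == ta.UNDEFINED

    def test_interpolated_cycles_to_half(self):
        maxima, _ = syn.generate_fatigue_series(cycles_to_half=972.0, n_cycles=1200)
        _, _, cycles = ta.fatigue_from_maxima(maxima)
        assert cycles == pytest.approx(972.0, rel=5e-3)

    @pytest.mark.parametrize("q", [0.99, 0.999, 0.9999])
    def test_agrees_with_closed_form(self, q):
        maxima = q ** np.arange(1000)
        _, q_fit, cycles = ta.fatigue_from_maxima(maxima)
        assert cycles == pytest.approx(math.log(0.5) / math.log(q), rel=5e-3)

    def test_from_multicycle_trace_with_markup(self):
        trace, truth = syn.generate_switching_trace(n_cycles=6, seed=2)
        n = truth["cycle_samples"]
        bounds = list(range(0, 7 * n, n))
        # identical cycles -> no fatigue -> undefined sentinel with warning
        with pytest.warns(UserWarning):
            maxima, q, cycles = ta.analyze_switching_fatigue(trace, bounds)
        assert len(maxima) == 6
        assert cycles == ta.UNDEFINED


class TestThermalRecovery:
    def test_two_component_truth_selects_two_components(self):
        trace, truth = syn.generate_recovery_trace(
            model="multi_exponential",
            components=((68.0, 0.03), (770.0, 0.97)),
            t_min=1.0, t_max=10000.0, n_points=60,
        )
        fit = ta.fit_thermal_recovery(trace)
        assert fit.model_label == "multi_exponential"
        assert fit.params["n_components"] == 2
        taus = sorted(tau for tau, _ in fit.components)
        assert taus[0] == pytest.approx(68.0, rel=0.1)
        assert taus[1] == pytest.approx(770.0, rel=0.1)

    def test_logarithmic_regime_half_recovery(self):
        halves = []
        for seed in range(1, 21):
            trace, _ = syn.generate_recovery_trace(
                model="logarithmic", half_time=6.8e-3, noise_sd=0.05, seed=seed
            )
            fit = ta.fit_thermal_recovery(trace, equilibrium=1.0)
            halves.append(fit.half_recovery_time)
        assert np.median(halves) == pytest.approx(6.8e-3, rel=0.15)

    def test_plateau_trace_is_no_recovery(self):
        trace = ta.Trace(np.geomspace(1e-4, 0.1, 20), np.full(20, 0.85))
        with pytest.raises(NoRecoveryError):
            ta.fit_thermal_recovery(trace)


class TestRecoveryRatio:
    def test_equal_values_ratio_one(self):
        trace = ta.Trace(np.arange(1, 5, dtype=float), np.array([0.5, 0.5, 0.5, 0.5]))
        ratio, frac = ta.estimate_recovery_ratio(
            trace, {"off_end_index": 1, "readout_start_index": 2,
                    "equilibrium": 1.0, "off_plateau": 0.5},
        )
        assert ratio == 1.0
        assert frac == 0.0

    def test_arithmetic(self):
        trace = ta.Trace(np.arange(1, 4, dtype=float), np.array([1.0, 0.06, 0.90]))
        ratio, frac = ta.estimate_recovery_ratio(
            trace, {"off_end_index": 1, "readout_start_index": 2,
                    "equilibrium": 1.0},
        )
        assert ratio == pytest.approx(15.0)
        assert frac == pytest.approx((0.90 - 0.06) / (1.0 - 0.06))

    def test_missing_markup(self):
        trace = ta.Trace(np.arange(1, 4, dtype=float), np.ones(3))
        with pytest.raises(MarkupError):
            ta.estimate_recovery_ratio(trace, {"off_end_index": 0})

    def test_simulated_recovery_modes_separate(self):
        """Dark recovery plateaus below light-driven recovery when the
        configured plateau scaling is applied."""
        dark, _ = syn.generate_recovery_trace(model="logarithmic", plateau=0.825)
        light, _ = syn.generate_recovery_trace(model="logarithmic", plateau=0.925)
        assert 0.80 <= dark.signal[-1] <= 0.85
        assert 0.90 <= light.signal[-1] <= 0.95


class TestPhotobleaching:
    def test_noiseless_frames_to_half(self):
        trace, _ = syn.generate_bleach_series(frames_to_half=2300.0)
        half, _ = ta.fit_photobleaching(trace)
        assert half == pytest.approx(2300.0, rel=1e-3)

    def test_constant_series_sentinel(self):
        trace = ta.Trace(np.arange(0, 1000, 100, dtype=float), np.ones(10))
        with pytest.warns(UserWarning):
            half, _ = ta.fit_photobleaching(trace)
        assert half == ta.UNDEFINED

    def test_median_under_noise(self):
        halves = []
        for seed in range(1, 21):
            trace, _ = syn.generate_bleach_series(noise_fraction=0.02, seed=seed)
            halves.append(ta.fit_photobleaching(trace)[0])
        assert np.median(halves) == pytest.approx(2300.0, rel=0.05)


class TestPka:
    def test_noiseless_exact(self):
        ph, signal, _ = syn.generate_titration(pka=4.5, hill=1.0)
        pka, hill, _ = ta.fit_pka(ph, signal)
        assert pka == pytest.approx(4.5, abs=1e-3)
        assert hill == pytest.approx(1.0, abs=1e-3)

    def test_constant_signal_fails(self):
        with pytest.raises(FitFailureError):
            ta.fit_pka(np.linspace(3, 9, 10), np.full(10, 0.5))

    def test_median_under_noise(self):
        pkas = []
        for seed in range(1, 21):
            ph, signal, _ = syn.generate_titration(noise_fraction=0.03, seed=seed)
            pkas.append(ta.fit_pka(ph, signal)[0])
        assert np.median(pkas) == pytest.approx(4.5, abs=0.1)


class TestScalars:
    @pytest.mark.parametrize(
        "ec,qy,expected",
        [(86100.0, 0.09, 7.75), (87400.0, 0.14, 12.2), (149200.0, 0.022, 3.28)],
    )
    def test_molecular_brightness_values(self, ec, qy, expected):
        assert ta.round_sig(ta.molecular_brightness(ec, qy), 3) == pytest.approx(expected)

    def test_zero_qy(self):
        assert ta.molecular_brightness(86100.0, 0.0) == 0.0

    def test_holo_fraction_from_ratio(self):
        assert ta.holo_fraction(1.0, 2.2) == pytest.approx(0.3125)
        assert ta.holo_fraction(1.0, 0.0) == 1.0

    def test_holo_fraction_absorbance_route_roundtrip(self):
        from phytoswitch.spectra import anchor_extinction_spectrum

        sample = syn.generate_absorption_spectrum(holo_fraction=0.4)
        pure = syn.generate_absorption_spectrum(holo_fraction=1.0)
        r1 = sample.value_at(689.0) / sample.value_at(278.0)
        eps = anchor_extinction_spectrum(pure, 391.0, 39900.0)
        r2 = eps.value_at(689.0) / eps.value_at(278.0)
        assert ta.holo_fraction_from_absorbance(r1, r2) == pytest.approx(0.40, rel=0.01)

    def test_holo_fraction_clips_with_warning(self):
        with pytest.warns(UserWarning):
            assert ta.holo_fraction_from_absorbance(1.2, 1.0) == 1.0


class TestLorentzianFwhm:
    def test_exact_lorentzian(self):
        x = np.linspace(-300, 300, 241)
        y = 0.1 + 5.0 / (1.0 + (x / 30.0) ** 2)
        fwhm, _ = ta.lorentzian_fwhm(x, y)
        assert fwhm == pytest.approx(60.0, rel=1e-6)

    def test_gaussian_model_mismatch_bias_bounded(self):
        # profile window ~2x the FWHM, as typical for filament line profiles;
        # wider windows let the heavy Lorentzian tails bias the width low
        x = np.linspace(-120, 120, 201)
        y = np.exp(-4 * math.log(2.0) * x**2 / 60.0**2)
        fwhm, _ = ta.lorentzian_fwhm(x, y)
        assert fwhm == pytest.approx(60.0, rel=0.10)

    def test_flat_profile_ambiguous(self):
        x = np.linspace(-300, 300, 101)
        with pytest.raises(AmbiguousPeakError):
            ta.lorentzian_fwhm(x, np.full_like(x, 2.0))

    def test_patch_averages_adjacent_profiles(self):
        x = np.linspace(-300, 300, 121)
        rows = np.vstack([
            0.0 + a / (1.0 + (x / 40.0) ** 2) for a in (0.8, 1.0, 0.8, 0.1, 0.1)
        ])
        fwhm, _ = ta.lorentzian_fwhm(x, rows[:3], averaging_width=3)
        assert fwhm == pytest.approx(80.0, rel=1e-6)

    def test_two_peaks_need_window(self):
        x = np.linspace(-300, 300, 241)
        y = 1.0 / (1 + ((x + 120) / 25) ** 2) + 1.0 / (1 + ((x - 120) / 25) ** 2)
        with pytest.raises(AmbiguousPeakError):
            ta.lorentzian_fwhm(x, y)
        fwhm, _ = ta.lorentzian_fwhm(x, y, window=(0.0, 300.0))
        assert fwhm == pytest.approx(50.0, rel=0.05)


def test_short_trace_rejected():
    with pytest.raises(InvalidArgumentError):
        ta.fit_off_switching(ta.Trace(np.arange(5.0), np.arange(5.0)[::-1] + 1))
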