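"""Forward photokinetic model: absorbed rates, ODE integration, stationarity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoswitch import photokinetics as pk
from phytoswitch import units
from phytoswitch.errors import DegenerateInputError, InvalidArgumentError

LN10 = math.log(10.0)


class TestAbsorbedRates:
    def test_single_absorber_takes_all(self, off_only_params):
        seg = pk.IlluminationSegment(660.0, 1e-9, 1.0, 0.2)
        r_pr, r_pfr = pk.absorbed_photon_rates(
            pk.StateVector(1e-6, 0.0), off_only_params, seg
        )
        assert r_pfr == 0.0
        assert r_pr > 0.0

    def test_symmetric_split(self):
        params = pk.SwitchingParameters(
            0.0, 0.0,
            pk.ExtinctionSpectrum.constant(50000.0),
            pk.ExtinctionSpectrum.constant(50000.0),
        )
        seg = pk.IlluminationSegment(660.0, 1e-9, 1.0, 0.2)
        r_pr, r_pfr = pk.absorbed_photon_rates(
            pk.StateVector(1e-6, 1e-6), params, seg
        )
        assert r_pr == pytest.approx(r_pfr, rel=1e-12)

    def test_optically_thin_expansion(self, off_only_params):
        # total absorbed areal flux ~ I0 * A * ln10 for A = 1e-3 (within 0.12%)
        conc = 1e-3 / (0.2 * 86100.0)
        seg = pk.IlluminationSegment(660.0, 1e-9, 1.0, 0.2)
        r_pr, _ = pk.absorbed_photon_rates(
            pk.StateVector(conc, 0.0), off_only_params, seg
        )
        areal = r_pr * 0.2 / 1000.0
        assert areal == pytest.approx(1e-9 * 1e-3 * LN10, rel=1.2e-3)

    def test_zero_flux_zero_rates(self, solution_params):
        seg = pk.IlluminationSegment.dark(1.0)
        assert pk.absorbed_photon_rates(
            pk.StateVector(1e-6, 1e-6), solution_params, seg
        ) == (0.0, 0.0)

    def test_wavelength_outside_grid_rejected(self):
        params = pk.SwitchingParameters(
            0.03, 0.0,
            pk.ExtinctionSpectrum([600.0, 700.0], [1.0, 1.0]),
            pk.ExtinctionSpectrum([600.0, 700.0], [1.0, 1.0]),
        )
        seg = pk.IlluminationSegment(500.0, 1e-9, 1.0)
        with pytest.raises(InvalidArgumentError):
            pk.absorbed_photon_rates(pk.StateVector(1e-6, 0.0), params, seg)


class TestSimulateProtocol:
    def test_dark_single_exponential(self):
        params = pk.SwitchingParameters(
            0.03, 0.0,
            pk.ExtinctionSpectrum.constant(86100.0),
            pk.ExtinctionSpectrum.constant(0.0),
            k_thermal=((1.0, 1.0),),
        )
        traj = pk.simulate_protocol(
            pk.StateVector(0.0, 1e-6), params, [pk.IlluminationSegment.dark(3.0)]
        )
        expected = 1e-6 * np.exp(-traj.times)
        assert np.max(np.abs(traj.c_pfr - expected) / 1e-6) < 1e-6

    def test_multiexponential_dark_recovery_closed_form(self):
        comps = ((1.0 / 68.0, 0.03), (1.0 / 770.0, 0.97))
        params = pk.SwitchingParameters(
            0.03, 0.0,
            pk.ExtinctionSpectrum.constant(86100.0),
            pk.ExtinctionSpectrum.constant(0.0),
            k_thermal=comps,
        )
        traj = pk.simulate_protocol(
            pk.StateVector(0.0, 1e-6), params, [pk.IlluminationSegment.dark(2000.0)],
            samples_per_segment=400,
        )
        recovered = sum(
            a * (1.0 - np.exp(-k * traj.times)) for k, a in comps
        ) * 1e-6
        assert np.max(np.abs(traj.c_pr - recovered) / 1e-6) < 1e-6

    def test_optically_thin_half_time(self, off_only_params, flux_1kw_660):
        # analytic k = phi_off * sigma * F -> half-time ~21.1 us at 1 kW/cm^2
        seg = pk.IlluminationSegment(660.0, flux_1kw_660, 1.2e-4, path_length=0.01)
        traj = pk.simulate_protocol(
            pk.StateVector(1e-9, 0.0), off_only_params, [seg],
            samples_per_segment=300,
        )
        k_fit = -np.polyfit(traj.times, np.log(traj.c_pr), 1)[0]
        k_expected = 0.03 * LN10 * 86100.0 * 1000.0 * flux_1kw_660
        assert k_fit == pytest.approx(k_expected, rel=0.01)
        assert math.log(2.0) / k_fit == pytest.approx(21.1e-6, rel=0.01)

    def test_terminal_state_matches_photostationary(self, solution_params):
        seg = pk.IlluminationSegment(660.0, 1e-9, 6000.0, 0.2)
        traj = pk.simulate_protocol(
            pk.StateVector(1e-6, 0.0), solution_params, [seg],
            samples_per_segment=100,
        )
        pss = pk.photostationary_state(solution_params, seg, 1e-6)
        assert traj.c_pr[-1] == pytest.approx(pss.c_pr, rel=1e-6)

    def test_concentration_conserved_across_segments(self, solution_params, flux_1kw_660):
        protocol = [
            pk.IlluminationSegment(660.0, flux_1kw_660, 1e-4, 0.01),
            pk.IlluminationSegment.dark(1e-3),
            pk.IlluminationSegment(660.0, flux_1kw_660 / 10, 1e-3, 0.01),
        ]
        traj = pk.simulate_protocol(
            pk.StateVector(0.7e-6, 0.3e-6), solution_params, protocol
        )
        assert np.max(np.abs(traj.total - 1e-6) / 1e-6) < 1e-8
        assert traj.c_pr[0] == pytest.approx(0.7e-6)

    def test_empty_protocol_rejected(self, solution_params):
        with pytest.raises(InvalidArgumentError):
            pk.simulate_protocol(pk.StateVector(1e-6, 0.0), solution_params, [])


class TestPhotostationaryState:
    def test_absorbing_off_state(self, off_only_params):
        seg = pk.IlluminationSegment(660.0, 1e-9, 1.0, 0.2)
        st_ = pk.photostationary_state(off_only_params, seg, 1e-6)
        assert st_.c_pr == 0.0
        assert st_.c_pfr == pytest.approx(1e-6)

    def test_symmetric_equilibrium(self):
        params = pk.SwitchingParameters(
            0.02, 0.02,
            pk.ExtinctionSpectrum.constant(50000.0),
            pk.ExtinctionSpectrum.constant(50000.0),
        )
        seg = pk.IlluminationSegment(660.0, 1e-9, 1.0, 0.2)
        st_ = pk.photostationary_state(params, seg, 1e-6)
        assert st_.c_pr == pytest.approx(5e-7, rel=1e-9)

    def test_residual_fraction_from_contrast(self):
        # phi_off/phi_on = 3 with equal extinctions -> contrast 4, residual 25%
        params = pk.SwitchingParameters(
            0.03, 0.01,
            pk.ExtinctionSpectrum.constant(50000.0),
            pk.ExtinctionSpectrum.constant(50000.0),
        )
        seg = pk.IlluminationSegment(660.0, 1e-9, 1.0, 0.2)
        st_ = pk.photostationary_state(params, seg, 1e-6)
        assert st_.c_pr / 1e-6 == pytest.approx(0.25, rel=1e-6)

    def test_all_rates_zero_degenerate(self):
        params = pk.SwitchingParameters(
            0.0, 0.0,
            pk.ExtinctionSpectrum.constant(50000.0),
            pk.ExtinctionSpectrum.constant(50000.0),
        )
        with pytest.raises(DegenerateInputError):
            pk.photostationary_state(
                params, pk.IlluminationSegment(660.0, 1e-9, 1.0, 0.2), 1e-6
            )

    def test_thermal_recovery_shifts_balance_toward_pr(self, solution_params):
        seg = pk.IlluminationSegment(660.0, 1e-9, 1.0, 0.2)
        no_thermal = pk.photostationary_state(solution_params, seg, 1e-6)
        with_thermal = pk.SwitchingParameters(
            solution_params.phi_off, solution_params.phi_on,
            solution_params.eps_pr, solution_params.eps_pfr,
            k_thermal=((1e-3, 1.0),),
        )
        shifted = pk.photostationary_state(with_thermal, seg, 1e-6)
        assert shifted.c_pr > no_thermal.c_pr
        # cross-check the thermal stationary state against the integrator
        traj = pk.simulate_protocol(
            pk.StateVector(1e-6, 0.0), with_thermal,
            [pk.IlluminationSegment(660.0, 1e-9, 20000.0, 0.2)],
            samples_per_segment=80,
        )
        assert traj.c_pr[-1] == pytest.approx(shifted.c_pr, rel=1e-5)


class TestSwitchingContrast:
    def test_no_off_switching_contrast_one(self):
        params = pk.SwitchingParameters(
            0.0, 0.01,
            pk.ExtinctionSpectrum.constant(50000.0),
            pk.ExtinctionSpectrum.constant(50000.0),
        )
        assert pk.switching_contrast(params, 660.0) == 1.0

    def test_symmetric_contrast_two(self):
        params = pk.SwitchingParameters(
            0.02, 0.02,
            pk.ExtinctionSpectrum.constant(50000.0),
            pk.ExtinctionSpectrum.constant(50000.0),
        )
        assert pk.switching_contrast(params, 660.0) == pytest.approx(2.0)

    def test_epsilon_ratio_contrast(self):
        # eps ratio 2, phi ratio 3 -> contrast 7
        params = pk.SwitchingParameters(
            0.03, 0.01,
            pk.ExtinctionSpectrum.constant(50000.0),
            pk.ExtinctionSpectrum.constant(25000.0),
        )
        assert pk.switching_contrast(params, 660.0) == pytest.approx(7.0)

    def test_infinite_contrast_sentinel(self, off_only_params):
        assert pk.switching_contrast(off_only_params, 660.0) == math.inf

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        phi_off=st.floats(1e-3, 0.2),
        phi_on=st.floats(1e-3, 0.2),
    )
    def test_residual_monotone_in_yields(self, phi_off, phi_on):
        """Residual Pr fraction falls with phi_off and rises with phi_on."""
        def residual(po, pn):
            params = pk.SwitchingParameters(
                po, pn,
                pk.ExtinctionSpectrum.constant(50000.0),
                pk.ExtinctionSpectrum.constant(25000.0),
            )
            return 1.0 / pk.switching_contrast(params, 660.0)

        base = residual(phi_off, phi_on)
        assert residual(phi_off * 1.5, phi_on) < base
        assert residual(phi_off, phi_on * 1.5) > base


class TestFluorescenceReadout:
    def test_dark_state_silent(self, off_only_params, flux_1kw_660):
        seg = pk.IlluminationSegment(660.0, flux_1kw_660, 1e-4, 0.01)
        traj = pk.Trajectory(
            times=np.array([0.0, 1e-5]),
            c_pr=np.zeros(2),
            c_pfr=np.full(2, 1e-6),
        )
        _, signal = pk.fluorescence_readout(traj, off_only_params, seg)
        assert np.all(signal == 0.0)

    def test_linear_in_flux_when_thin(self, solution_params, flux_1kw_660):
        traj = pk.Trajectory(
            times=np.array([0.0, 1e-5]),
            c_pr=np.full(2, 1e-9),
            c_pfr=np.zeros(2),
        )
        seg1 = pk.IlluminationSegment(660.0, flux_1kw_660, 1e-4, 0.01)
        seg2 = pk.IlluminationSegment(660.0, 2 * flux_1kw_660, 1e-4, 0.01)
        _, s1 = pk.fluorescence_readout(traj, solution_params, seg1)
        _, s2 = pk.fluorescence_readout(traj, solution_params, seg2)
        assert s2[0] == pytest.approx(2 * s1[0], rel=1e-3)

    def test_residual_off_state_signal_fraction(self, flux_1kw_660):
        # qy_fluo_pfr tuned so the fully-converted off state emits 6% of the
        # on-state signal at the readout wavelength
        eps_pr, eps_pfr = 86100.0, 25000.0
        qy_pr = 0.09
        qy_pfr = 0.06 * qy_pr * eps_pr / eps_pfr
        params = pk.SwitchingParameters(
            0.03, 0.01,
            pk.ExtinctionSpectrum.constant(eps_pr),
            pk.ExtinctionSpectrum.constant(eps_pfr),
            qy_fluo_pr=qy_pr, qy_fluo_pfr=qy_pfr,
        )
        seg = pk.IlluminationSegment(660.0, flux_1kw_660, 1e-4, 0.01)
        on = pk.Trajectory(np.array([0.0]), np.array([1e-9]), np.array([0.0]))
        off = pk.Trajectory(np.array([0.0]), np.array([0.0]), np.array([1e-9]))
        _, s_on = pk.fluorescence_readout(on, params, seg)
        _, s_off = pk.fluorescence_readout(off, params, seg)
        assert s_off[0] / s_on[0] == pytest.approx(0.06, rel=1e-6)
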