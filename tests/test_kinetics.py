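"""Two-step model: analytic observables and the mass-action ODE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covkin.kinetics import (
    TwoStepParams,
    analytic_kobs,
    occupancy_curve,
    simulate_two_step_ode,
)


class TestTwoStepParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TwoStepParams(K_I=-1e-6, k_inact=1e-3)
        with pytest.raises(ValueError):
            TwoStepParams(K_I=1e-6, k_inact=-1.0)
        with pytest.raises(ValueError):
            TwoStepParams(K_I=1e-6, k_inact=1e-3, k_1=1e6)  # missing k_minus1

    def test_microscopic_rates_must_match_equilibrium_constant(self):
        # K_I = k_minus1 / k_1 is the defining identity of the first step
        TwoStepParams(K_I=34.8e-6, k_inact=1e-3, k_1=1e6, k_minus1=34.8)
        with pytest.raises(ValueError, match="inconsistent"):
            TwoStepParams(K_I=34.8e-6, k_inact=1e-3, k_1=1e6, k_minus1=40.0)


class TestAnalyticKobs:
    def test_half_saturation_at_KI(self, params_1a):
        # c = K_I gives exactly half of k_inact
        assert analytic_kobs(params_1a, 34.8e-6) == pytest.approx(10.1e-3 / 2, rel=1e-12)

    def test_zero_concentration_gives_zero_rate(self, params_1a):
        assert analytic_kobs(params_1a, 0.0) == 0.0

    def test_matches_direct_arithmetic(self, params_1a):
        expected = 10.1e-3 * 160e-6 / (34.8e-6 + 160e-6)  # independent evaluation
        assert analytic_kobs(params_1a, 160e-6) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self, params_1a):
        with pytest.raises(ValueError):
            analytic_kobs(params_1a, -1e-6)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        c1=st.floats(0, 1e-2),
        c2=st.floats(0, 1e-2),
        ki=st.floats(1e-7, 1e-3),
        kin=st.floats(1e-6, 1.0),
    )
    def test_saturating_and_monotone(self, c1, c2, ki, kin):
        p = TwoStepParams(K_I=ki, k_inact=kin)
        lo, hi = sorted((c1, c2))
        assert analytic_kobs(p, lo) <= analytic_kobs(p, hi) <= kin


class TestOccupancyCurve:
    def test_starts_at_zero(self):
        assert occupancy_curve(1e-3, 0.9, 0.0) == 0.0

    def test_half_life_identity(self):
        tau = 1234.0
        assert occupancy_curve(np.log(2) / tau, 1.0, tau) == pytest.approx(0.5, rel=1e-12)

    def test_matches_direct_arithmetic(self):
        expected = 0.9 * (1.0 - np.exp(-1.0))  # independent evaluation
        assert occupancy_curve(1e-3, 0.9, 1000.0) == pytest.approx(expected, rel=1e-12)

    def test_plateau_domain_enforced(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                occupancy_curve(1e-3, bad, 10.0)

    def test_strictly_increasing_toward_plateau(self):
        t = np.linspace(0, 1e4, 50)
        y = occupancy_curve(5e-4, 0.8, t)
        assert np.all(np.diff(y) > 0)
        assert y[-1] < 0.8
        assert occupancy_curve(5e-4, 0.8, 1e9) == pytest.approx(0.8)


class TestTwoStepODE:
    def test_no_chemistry_limit_reaches_binding_equilibrium(self):
        # k_inact = 0: no adduct ever forms and E*I/EI settles at k_minus1/k_1
        k1, km1 = 1e5, 3.0
        traj = simulate_two_step_ode(k1, km1, 0.0, 2e-6, 160e-6,
                                     np.linspace(1e-3, 10.0, 50))
        assert np.all(traj.EI_cov == 0)
        ratio = traj.E[-1] * traj.I[-1] / traj.EI[-1]
        assert ratio == pytest.approx(km1 / k1, rel=1e-6)

    def test_enzyme_mass_conserved(self):
        traj = simulate_two_step_ode(1e6, 34.8, 10.1e-3, 2e-6, 160e-6,
                                     np.linspace(1.0, 600.0, 100))
        total = traj.E + traj.EI + traj.EI_cov
        assert np.all(np.abs(total - 2e-6) <= 1e-6 * 2e-6)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_two_step_ode(np.nan, 1.0, 1e-3, 1e-6, 1e-5, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            simulate_two_step_ode(1e6, np.inf, 1e-3, 1e-6, 1e-5, np.array([1.0, 2.0]))

    @pytest.mark.parametrize("k1", [1e4, 1e5, 1e6])
    def test_rapid_equilibrium_limit_matches_one_phase_curve(self, k1, params_1a):
        # 80-fold inhibitor excess: adduct fraction tracks the analytic
        # pseudo-first-order curve within 2% relative once the fast
        # pre-equilibration transient (timescale 1/lambda) has passed
        E0, I0 = 2e-6, 160e-6
        km1 = k1 * params_1a.K_I
        kobs = analytic_kobs(params_1a, I0)
        lam = k1 * I0 + km1 + params_1a.k_inact
        times = np.geomspace(100.0 / lam, 5.0 / kobs, 60)
        traj = simulate_two_step_ode(k1, km1, params_1a.k_inact, E0, I0, times)
        analytic = occupancy_curve(kobs, 1.0, times)
        rel = np.abs(traj.adduct_fraction - analytic) / analytic
        assert rel.max() < 0.02

    def test_trajectory_tidy_export(self):
        traj = simulate_two_step_ode(1e5, 3.48, 1e-3, 2e-6, 20e-6,
                                     np.linspace(0.1, 100.0, 10))
        df = traj.to_frame()
        assert list(df.columns) == ["time_s", "E_M", "EI_M", "EI_cov_M", "I_M"]
        assert len(df) == 10
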