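"""Regression stages: roundtrips, noise robustness, degenerate designs."""

import numpy as np
import pytest

from covkin.fitting import (
    GSH_CENSOR_HORIZON_H,
    InsufficientDataError,
    KobsEstimate,
    aggregate_replicates,
    correct_gsh_rate,
    fit_exponential_trace,
    fit_ic50,
    fit_kobs_vs_conc,
    fit_log_linear_rate,
    fit_one_phase,
    normalize_exchange_rates,
)
from covkin.kinetics import TwoStepParams, analytic_kobs, occupancy_curve

GSH_TIMES_H = np.array([0.0, 1, 2, 4, 8, 12, 24, 48, 72])


class TestOnePhase:
    def test_noiseless_roundtrip(self):
        t = np.linspace(0, 2e4, 8)
        y = occupancy_curve(2e-4, 0.95, t)
        est = fit_one_phase(t, y)
        assert est.k_obs == pytest.approx(2e-4, rel=1e-6)
        assert est.plateau == pytest.approx(0.95, rel=1e-6)

    def test_noisy_median_recovery(self):
        # sd 0.02 additive noise: median recovered rate within 5% of truth
        rng = np.random.default_rng(42)
        t = np.linspace(0, 2e4, 8)
        clean = occupancy_curve(2e-4, 0.95, t)
        recovered = []
        for _ in range(100):
            y = np.clip(clean + rng.normal(0, 0.02, t.shape), 0, 1)
            recovered.append(fit_one_phase(t, y).k_obs)
        assert np.median(recovered) == pytest.approx(2e-4, rel=0.05)

    def test_null_signal_flagged_degenerate(self):
        est = fit_one_phase(np.linspace(0, 100, 6), np.zeros(6))
        assert est.k_obs == 0.0
        assert est.degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_one_phase(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.1, 0.2]))


class TestKobsVsConc:
    CONCS = np.array([20e-6, 40e-6, 80e-6, 160e-6])

    def _estimates(self, kobs):
        return [KobsEstimate(conc=c, k_obs=k, k_obs_se=0.0, plateau=1.0,
                             plateau_se=0.0, n_points=5)
                for c, k in zip(self.CONCS, kobs)]

    def test_noiseless_roundtrip(self, params_1a):
        fit = fit_kobs_vs_conc(self._estimates(analytic_kobs(params_1a, self.CONCS)))
        assert fit.K_I == pytest.approx(34.8e-6, rel=1e-6)
        assert fit.k_inact == pytest.approx(10.1e-3, rel=1e-6)
        assert not fit.poorly_determined

    def test_noisy_median_bias(self, params_1a):
        # 3% relative noise on k_obs: median |bias| of K_I < 10%, k_inact < 5%
        rng = np.random.default_rng(7)
        clean = analytic_kobs(params_1a, self.CONCS)
        kis, kinacts = [], []
        for _ in range(200):
            noisy = np.clip(clean * (1 + rng.normal(0, 0.03, 4)), 0, None)
            fit = fit_kobs_vs_conc(self._estimates(noisy))
            kis.append(fit.K_I)
            kinacts.append(fit.k_inact)
        assert abs(np.median(kis) - params_1a.K_I) / params_1a.K_I < 0.10
        assert abs(np.median(kinacts) - params_1a.k_inact) / params_1a.k_inact < 0.05

    def test_linear_regime_flagged_poorly_determined(self):
        # k_obs proportional to c: second-order regime, K_I unidentifiable
        fit = fit_kobs_vs_conc(self._estimates(50.0 * self.CONCS))
        assert fit.poorly_determined

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_kobs_vs_conc(self._estimates(analytic_kobs(
                TwoStepParams(K_I=1e-5, k_inact=1e-3), self.CONCS))[:2])

    def test_invariant_to_concentration_ordering(self, params_1a):
        ests = self._estimates(analytic_kobs(params_1a, self.CONCS))
        shuffled = [ests[i] for i in (2, 0, 3, 1)]
        assert fit_kobs_vs_conc(shuffled).K_I == pytest.approx(
            fit_kobs_vs_conc(ests).K_I, rel=1e-9)

    def test_time_unit_rescaling_consistency(self, params_1a):
        # k_obs expressed in h^-1 instead of s^-1: K_I unchanged, k_inact scales
        kobs_s = analytic_kobs(params_1a, self.CONCS)
        fit_s = fit_kobs_vs_conc(self._estimates(kobs_s))
        fit_h = fit_kobs_vs_conc(self._estimates(kobs_s * 3600.0))
        assert fit_h.K_I == pytest.approx(fit_s.K_I, rel=1e-9)
        assert fit_h.k_inact / 3600.0 == pytest.approx(fit_s.k_inact, rel=1e-9)


class TestLogLinearRate:
    def test_exact_log_linear_decay(self):
        auc = 1e6 * np.exp(-0.05 * GSH_TIMES_H)
        assert fit_log_linear_rate(GSH_TIMES_H, auc) == pytest.approx(0.05, abs=1e-9)

    def test_constant_signal_gives_zero_rate(self):
        assert fit_log_linear_rate(GSH_TIMES_H, np.full(9, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(3)
        rates = [fit_log_linear_rate(
            GSH_TIMES_H, np.exp(-0.05 * GSH_TIMES_H + rng.normal(0, 0.05, 9)))
            for _ in range(50)]
        assert np.median(rates) == pytest.approx(0.05, rel=0.10)

    def test_nonpositive_auc_names_offender(self):
        auc = np.array([1.0, 0.5, -0.1, 0.2])
        with pytest.raises(ValueError, match=r"index\(es\) \[2\]"):
            fit_log_linear_rate(np.array([0.0, 1, 2, 4]), auc)


class TestGshCorrection:
    def test_half_life_19h_after_degradation_correction(self):
        k_deg = 0.013
        res = correct_gsh_rate(np.log(2) / 19.0 + k_deg, k_deg)
        assert res.t_half_gsh == pytest.approx(19.0, rel=1e-12)
        assert not res.censored

    def test_no_degradation_identity(self):
        res = correct_gsh_rate(0.08, 0.0)
        assert res.t_half_gsh == pytest.approx(np.log(2) / 0.08, rel=1e-12)

    def test_equal_rates_censored_beyond_horizon(self):
        res = correct_gsh_rate(0.02, 0.02)
        assert res.censored
        assert res.t_half_gsh == GSH_CENSOR_HORIZON_H
        assert res.display == ">72"

    def test_small_negative_slope_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = correct_gsh_rate(0.05, -5e-4)
        assert res.k_deg == 0.0

    def test_degradation_exceeding_apparent_rate_censored(self):
        res = correct_gsh_rate(0.01, 0.05)
        assert res.censored

    def test_large_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            correct_gsh_rate(-0.5, 0.0)


class TestExponentialTrace:
    TIMES = np.arange(0, 3601, 30.0)

    def test_noiseless_roundtrip(self):
        f = 0.2 + 0.8 * np.exp(-1e-3 * self.TIMES)
        assert fit_exponential_trace(self.TIMES, f) == pytest.approx(1e-3, rel=1e-6)

    def test_flat_trace_degenerate_zero_rate(self):
        from covkin.fitting import SingleExponentialTrace

        est = SingleExponentialTrace().fit(self.TIMES, np.full_like(self.TIMES, 0.7))
        assert est.rate_ == 0.0
        assert est.degenerate_

    def test_noisy_recovery(self):
        rng = np.random.default_rng(11)
        clean = 0.2 + 0.8 * np.exp(-1e-3 * self.TIMES)
        rates = [fit_exponential_trace(
            self.TIMES, clean + rng.normal(0, 0.008, clean.shape))
            for _ in range(50)]
        assert np.median(rates) == pytest.approx(1e-3, rel=0.05)


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        assert normalize_exchange_rates(1.5e-3, 1.5e-3, 2e-5) == pytest.approx(1.0)
        assert normalize_exchange_rates(2e-5, 1.5e-3, 2e-5) == pytest.approx(0.0)
        mid = (1.5e-3 + 2e-5) / 2
        assert normalize_exchange_rates(mid, 1.5e-3, 2e-5) == pytest.approx(0.5)

    def test_zero_dynamic_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_exchange_rates(1e-3, 1e-3, 1e-3)


class TestIC50:
    CONCS = np.array([100e-6, 20e-6, 4e-6, 0.8e-6, 0.16e-6, 0.032e-6])

    @staticmethod
    def logistic(c, ic50, hill=1.0, top=1.0, bottom=0.0):
        return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)

    def test_noiseless_roundtrip(self):
        dr = fit_ic50(self.CONCS, self.logistic(self.CONCS, 2.9e-6))
        assert dr.ic50 == pytest.approx(2.9e-6, rel=1e-6)
        assert dr.hill == pytest.approx(1.0, rel=1e-4)
        assert dr.censored is None

    def test_midpoint_definition(self):
        # a symmetric curve crossing half its range at c defines IC50 = c
        dr = fit_ic50(self.CONCS, self.logistic(self.CONCS, 4e-6, hill=1.7))
        assert dr.ic50 == pytest.approx(4e-6, rel=1e-6)
        assert self.logistic(dr.ic50, 4e-6, hill=1.7) == pytest.approx(0.5)

    def test_noisy_geometric_mean_bias(self):
        # 3 replicates x 6 concentrations, 5% noise: geometric-mean bias < 15%
        rng = np.random.default_rng(19)
        concs3 = np.tile(self.CONCS, 3)
        clean = self.logistic(concs3, 2.9e-6)
        log_ratio = []
        for _ in range(200):
            y = np.clip(clean + rng.normal(0, 0.05, clean.shape), 0, None)
            log_ratio.append(np.log(fit_ic50(concs3, y).ic50 / 2.9e-6))
        assert abs(np.exp(np.mean(log_ratio)) - 1.0) < 0.15

    def test_no_transition_censored(self):
        dr = fit_ic50(self.CONCS, self.logistic(self.CONCS, 5e-3))  # IC50 >> max conc
        assert dr.censored == ">max"

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_ic50(self.CONCS[:3], np.array([1.0, 0.6, 0.2]))


class TestAggregation:
    def test_single_value_has_no_sd(self):
        mean, sd = aggregate_replicates([290.2])
        assert mean == 290.2 and sd is None

    def test_identical_values_sd_zero(self):
        assert aggregate_replicates([9.8, 9.8]) == (9.8, 0.0)

    def test_sample_sd_denominator(self):
        mean, sd = aggregate_replicates([6.0, 12.0])
        assert mean == 9.0
        assert sd == pytest.approx(np.sqrt(((6 - 9) ** 2 + (12 - 9) ** 2) / 1), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])
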