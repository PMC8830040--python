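"""Structural model: covariate model, steady-state trough, residual error.

The closed-form steady-state trough is checked against an independent
oracle that integrates the gut/central ODE system over repeated dosing
intervals until the trough stabilises.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from digoxinpk.data import InvalidInputError
from digoxinpk.structural import (ConfigurationError, CovariateEffect,
                                  PopulationModel, apply_residual,
                                  final_digoxin_model, individual_cl,
                                  steady_state_trough, vd_from_weight)


def ode_trough_oracle(dose, tau, cl, vd, ka=1.0, max_intervals=3000,
                      rtol_stop=1e-8):
    """Steady-state trough by brute-force ODE integration.

    Amounts in gut (A) and central compartment (C): A' = -ka A,
    C' = ka A - ke C, a bolus ``dose`` into the gut every ``tau`` h,
    integrated interval by interval until successive troughs differ by
    less than ``rtol_stop`` relative.
    """
    ke = cl / vd

    def rhs(t, y):
        return [-ka * y[0], ka * y[0] - ke * y[1]]

    y = np.array([0.0, 0.0])
    prev = None
    for _ in range(max_intervals):
        y[0] += dose
        sol = solve_ivp(rhs, (0.0, tau), y, rtol=1e-12, atol=1e-14,
                        method="DOP853")
        y = sol.y[:, -1]
        trough = y[1] / vd
        if prev is not None and abs(trough - prev) <= rtol_stop * abs(trough):
            return trough
        prev = trough
    raise RuntimeError("trough did not stabilise")


class TestSteadyStateTrough:
    def test_matches_ode_oracle_on_random_grid(self):
        # a denser 100-point sweep runs in the acceptance suite
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(25):
            cl = rng.uniform(1.0, 20.0)
            vd = rng.uniform(100.0, 600.0)
            tau = float(rng.choice([12.0, 24.0]))
            dose = rng.uniform(50.0, 300.0)
            closed = steady_state_trough(dose, tau, cl, vd)
            oracle = ode_trough_oracle(dose, tau, cl, vd)
            worst = max(worst, abs(closed - oracle) / oracle)
        assert worst < 1e-6

    def test_reference_value(self):
        # 125 ug daily, CL/F 6.2 L/h, Vd 342 L (57 kg x 6 L/kg)
        assert steady_state_trough(125, 24, 6.2, 342) == pytest.approx(0.683, abs=0.001)

    def test_linearity_in_dose(self):
        c1 = steady_state_trough(125, 24, 6.2, 342)
        assert steady_state_trough(0, 24, 6.2, 342) == 0.0
        assert steady_state_trough(250, 24, 6.2, 342) == pytest.approx(2 * c1, rel=1e-12)

    def test_monotone_in_cl_and_dose(self):
        cls = np.linspace(1, 20, 25)
        troughs = steady_state_trough(125, 24, cls, 342)
        assert np.all(np.diff(troughs) < 0)
        doses = np.linspace(10, 500, 25)
        troughs_d = steady_state_trough(doses, 24, 6.2, 342)
        assert np.all(np.diff(troughs_d) > 0)

    def test_oral_bolus_limit_at_large_ka(self):
        cl, vd, tau, dose = 6.2, 342.0, 24.0, 125.0
        ke = cl / vd
        bolus = dose / vd * np.exp(-ke * tau) / (1 - np.exp(-ke * tau))
        assert steady_state_trough(dose, tau, cl, vd, ka=1e6) == pytest.approx(
            bolus, rel=1e-4)

    def test_flip_flop_degeneracy_is_finite_and_continuous(self):
        # ka == ke triggers the analytic-limit branch
        vd, tau, dose = 100.0, 24.0, 125.0
        ka = 0.05
        c_eq = steady_state_trough(dose, tau, ka * vd, vd, ka=ka)
        c_near = steady_state_trough(dose, tau, ka * vd * (1 + 1e-6), vd, ka=ka)
        assert np.isfinite(c_eq) and c_eq > 0
        assert c_eq == pytest.approx(c_near, rel=1e-4)
        assert c_eq == pytest.approx(ode_trough_oracle(dose, tau, ka * vd, vd, ka=ka),
                                     rel=1e-5)

    def test_within_interval_time_argument(self):
        # concentration declines monotonically over the post-absorption window
        ts = np.linspace(6, 24, 10)
        cs = steady_state_trough(125, 24, 6.2, 342, t=ts)
        assert np.all(np.diff(cs) < 0)
        assert cs[-1] == pytest.approx(steady_state_trough(125, 24, 6.2, 342))

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            steady_state_trough(125, 0, 6.2, 342)
        with pytest.raises(InvalidInputError):
            steady_state_trough(125, 24, -1, 342)


class TestCovariateModel:
    def test_final_model_typical_value(self, final_model):
        # CLcr 60, no amiodarone: every multiplier is 1
        assert individual_cl(final_model, {"clcr": 60, "amiodarone": 0}) == \
            pytest.approx(6.2)

    def test_amiodarone_reduction(self, final_model):
        cl = individual_cl(final_model, {"clcr": 60, "amiodarone": 1})
        assert cl == pytest.approx(6.2 * 0.76)

    def test_clcr_power_term(self, final_model):
        cl = individual_cl(final_model, {"clcr": 90, "amiodarone": 0})
        assert cl == pytest.approx(6.2 * (90 / 60) ** 0.41)

    def test_eta_is_exponential(self, final_model):
        cov = {"clcr": 45, "amiodarone": 1}
        assert individual_cl(final_model, cov, eta=np.log(2)) == pytest.approx(
            2 * individual_cl(final_model, cov), rel=1e-12)

    def test_missing_covariate_raises(self, final_model):
        with pytest.raises(ConfigurationError, match="amiodarone"):
            individual_cl(final_model, {"clcr": 60})

    def test_proportional_effect_must_keep_multiplier_positive(self):
        with pytest.raises(ConfigurationError):
            CovariateEffect("amiodarone", "proportional", -1.0)


class TestFixedParameters:
    def test_vd_from_weight(self):
        assert vd_from_weight(57) == pytest.approx(342.0)
        assert vd_from_weight(1) == pytest.approx(6.0)
        with pytest.raises(InvalidInputError):
            vd_from_weight(0)

    def test_apply_residual(self):
        assert apply_residual(1.0, 0.0, "additive") == 1.0
        assert apply_residual(1.0, 0.0, "multiplicative") == 1.0
        assert apply_residual(1.0, 0.1, "multiplicative") == pytest.approx(1.1)
        assert apply_residual(0.7, -0.7, "additive") == pytest.approx(0.0)
        with pytest.raises(ConfigurationError):
            apply_residual(1.0, 0.1, "banana")


class TestSerialization:
    def test_model_round_trip(self, final_model, tmp_path):
        p = tmp_path / "model.yaml"
        final_model.to_yaml(p)
        assert PopulationModel.from_file(p) == final_model
        p2 = tmp_path / "model.json"
        final_model.to_json(p2)
        assert PopulationModel.from_file(p2) == final_model
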