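"""NLME engine: marginal likelihood, fitting, EBEs, model comparison."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from digoxinpk import (AnalysisDataset, CohortConfig, base_digoxin_model,
                       compare_error_models, compute_ebe, compute_ebes,
                       fit_population, generate_dataset, lrt_significant,
                       marginal_ofv)
from digoxinpk.data import InvalidInputError
from digoxinpk.nlme import FlatData, LRT_CRITICAL
from digoxinpk.structural import steady_state_trough


class TestMarginalOFV:
    def test_omega_zero_matches_hand_written_sum(self, tiny_dataset, final_model):
        """With no random effect the OFV is the plain Gaussian -2LL of
        proportional residuals, computable by a direct sum."""
        model = replace(final_model, omega_cl=0.0)
        flat = FlatData(tiny_dataset)
        cl = flat.base_cl(model)[flat.pat_idx]
        vd = (flat.weight * model.vd_per_kg)[flat.pat_idx]
        f = steady_state_trough(flat.dose, flat.tau, cl, vd, t=flat.tald)
        sd = model.sigma * f
        ll = np.sum(-0.5 * np.log(2 * np.pi) - np.log(sd)
                    - 0.5 * ((flat.y - f) / sd) ** 2)
        assert marginal_ofv(model, tiny_dataset) == pytest.approx(-2 * ll, abs=1e-9)

    def test_laplace_close_to_agq_on_tiny_fixture(self, tiny_dataset, final_model):
        agq = marginal_ofv(final_model, tiny_dataset, method="agq", nodes=41)
        lap = marginal_ofv(final_model, tiny_dataset, method="laplace")
        assert abs(agq - lap) < 0.5

    def test_agq_converged_in_node_count(self, tiny_dataset, final_model):
        o41 = marginal_ofv(final_model, tiny_dataset, nodes=41)
        o81 = marginal_ofv(final_model, tiny_dataset, nodes=81)
        assert abs(o41 - o81) < 1e-6

    def test_invariant_to_patient_and_observation_order(self, small_dataset,
                                                        final_model):
        ref = marginal_ofv(final_model, small_dataset)
        rng = np.random.default_rng(3)
        patients = list(small_dataset.patients)
        obs = list(small_dataset.observations)
        rng.shuffle(patients)
        rng.shuffle(obs)
        shuffled = AnalysisDataset(patients, list(small_dataset.regimens), obs)
        assert marginal_ofv(final_model, shuffled) == pytest.approx(ref, abs=1e-8)

    def test_generating_model_beats_misspecified_base(self, final_model):
        """On data generated with covariate effects, the generating model
        should have the lower OFV (checked across seeds)."""
        wins = 0
        for seed in range(5):
            ds = generate_dataset(final_model, CohortConfig(n_patients=100),
                                  seed=100 + seed)
            base = replace(final_model, effects=())
            if marginal_ofv(final_model, ds) < marginal_ofv(base, ds):
                wins += 1
        assert wins == 5

    def test_empty_dataset_rejected(self, final_model):
        with pytest.raises(Exception):
            marginal_ofv(final_model, AnalysisDataset([], [], []))


class TestFit:
    def test_recovers_generating_values_small_scale(self, small_dataset,
                                                    final_model):
        fit = fit_population(final_model, small_dataset)
        assert fit.converged
        # 50 patients: loose sanity bands only
        assert fit.estimates["tv_cl"] == pytest.approx(6.2, rel=0.25)
        assert fit.estimates["omega_cl"] == pytest.approx(0.344, rel=0.5)
        assert fit.ofv < marginal_ofv(final_model, small_dataset)

    def test_robust_to_initial_values(self, small_dataset, final_model):
        f1 = fit_population(final_model, small_dataset,
                            init={"tv_cl": 3.1, "omega_cl": 0.45, "sigma": 0.45},
                            compute_se=False)
        f2 = fit_population(final_model, small_dataset,
                            init={"tv_cl": 9.3, "omega_cl": 0.15, "sigma": 0.15},
                            compute_se=False)
        assert f1.converged and f2.converged
        assert abs(f1.ofv - f2.ofv) < 0.1

    def test_rse_definition(self, study_fit):
        for name, se in study_fit.se.items():
            if se is not None:
                est = study_fit.estimates[name]
                assert study_fit.rse[name] == pytest.approx(100 * se / abs(est))

    def test_scale_equivariance_of_multiplicative_model(self, small_dataset,
                                                        final_model):
        """A concentration unit change (scaling doses and concentrations
        together, since PK is dose-linear) shifts the OFV by exactly the
        Jacobian constant 2*N*log(c) and leaves all estimates unchanged."""
        c = 2.5
        scaled = AnalysisDataset(
            list(small_dataset.patients),
            [replace(r, daily_dose=c * r.daily_dose)
             for r in small_dataset.regimens],
            [replace(o, concentration=c * o.concentration)
             for o in small_dataset.observations])
        f1 = fit_population(final_model, small_dataset, compute_se=False)
        f2 = fit_population(final_model, scaled, compute_se=False)
        n = f1.n_obs
        assert f2.n_obs == n
        assert f2.ofv - f1.ofv == pytest.approx(2 * n * np.log(c), abs=0.05)
        assert f2.estimates["beta_clcr"] == pytest.approx(
            f1.estimates["beta_clcr"], abs=0.01)
        assert f2.estimates["tv_cl"] == pytest.approx(
            f1.estimates["tv_cl"], rel=0.01)


class TestEBE:
    def test_zero_residual_patient_has_near_zero_ebe(self, final_model,
                                                     small_dataset):
        """Patient observed exactly at the population prediction."""
        from digoxinpk.data import DoseRegimen, TroughObservation, derive_covariates
        p = derive_covariates("Z", "male", 67, 161, 57, 0.94)
        model = final_model
        cl = 6.2 * (p.clcr / 60) ** 0.41
        f = steady_state_trough(125, 24, cl, 342, t=12.0)
        ds = AnalysisDataset([p], [DoseRegimen("Z", 125.0)],
                             [TroughObservation("Z", 240.0, 12.0, float(f))])
        # not exactly 0: the proportional error's -log f(eta) term biases
        # the conditional mode slightly, but far below the prior SD
        assert abs(compute_ebe(model, ds, "Z")) < 0.2 * model.omega_cl

    def test_shrinkage_toward_prior(self, final_model):
        """A single high observation yields 0 < eta_hat < the pure-likelihood
        value (which a grid search locates)."""
        from digoxinpk.data import DoseRegimen, TroughObservation, derive_covariates
        p = derive_covariates("Z", "male", 67, 161, 57, 0.94)
        cl0 = 6.2 * (p.clcr / 60) ** 0.41
        f0 = steady_state_trough(125, 24, cl0, 342, t=12.0)
        ds = AnalysisDataset([p], [DoseRegimen("Z", 125.0)],
                             [TroughObservation("Z", 240.0, 12.0, 2.0 * f0)])
        ebe = compute_ebe(final_model, ds, "Z")
        # pure-likelihood mode by grid search: eta giving f(eta) closest to y
        grid = np.linspace(-2, 2, 4001)
        f = steady_state_trough(125, 24, cl0 * np.exp(grid), 342, t=12.0)
        sd = final_model.sigma * f
        ll = -np.log(sd) - 0.5 * ((2.0 * f0 - f) / sd) ** 2
        ml_eta = grid[np.argmax(ll)]
        assert ml_eta < 0  # higher conc implies lower clearance
        assert ml_eta < ebe < 0

    def test_no_observations_fully_shrunk(self, final_model):
        from digoxinpk.data import DoseRegimen, derive_covariates
        p = derive_covariates("Z", "male", 67, 161, 57, 0.94)
        ds = AnalysisDataset([p], [DoseRegimen("Z", 125.0)], [])
        assert compute_ebe(final_model, ds, "Z") == 0.0

    def test_omega_zero_gives_zero(self, final_model, small_dataset):
        model = replace(final_model, omega_cl=0.0)
        pid = small_dataset.patients[0].id
        assert compute_ebe(model, small_dataset, pid) == 0.0

    def test_scalar_and_vectorised_ebes_agree(self, final_model, small_dataset):
        ebes = compute_ebes(final_model, small_dataset)
        for pid in list(ebes)[:5]:
            assert compute_ebe(final_model, small_dataset, pid) == pytest.approx(
                ebes[pid], abs=1e-5)


class TestLRT:
    def test_critical_value_is_chi2_at_0_05(self):
        assert round(float(stats.chi2.ppf(0.95, 1)), 2) == LRT_CRITICAL == 3.84

    @pytest.mark.parametrize("delta,expected", [
        (3.84, True), (0.0, False), (10.0, True), (3.83, False)])
    def test_significance(self, delta, expected):
        assert lrt_significant(delta) is expected

    def test_df_validation(self):
        with pytest.raises(InvalidInputError):
            lrt_significant(5.0, df=0)


class TestErrorModelComparison:
    @pytest.mark.parametrize("kind,sigma", [
        ("multiplicative", 0.37), ("additive", 0.25)])
    def test_generating_error_model_selected(self, kind, sigma, final_model):
        chosen_count = 0
        for seed in range(3):
            gen = replace(final_model, error_kind=kind, sigma=sigma)
            ds = generate_dataset(gen, CohortConfig(n_patients=100),
                                  seed=500 + seed)
            chosen, ofvs, _ = compare_error_models(ds, base_digoxin_model())
            assert set(ofvs) == {"additive", "multiplicative"}
            if chosen == kind:
                chosen_count += 1
        assert chosen_count == 3
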