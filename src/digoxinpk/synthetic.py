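"""Virtual AF/HF cohort generator.

Emulates the covariate structure of the study population (n = 391
Japanese adults with atrial fibrillation and heart failure on oral
digoxin) so that estimation, covariate selection, bootstrap and
diagnostics can be exercised without the confidential clinical dataset:

* age 67 +/- 14 y (truncated >= 19), weight 57 +/- 15 kg (>= 30),
  height 161 +/- 11 cm, 38% female;
* serum creatinine lognormal with median 0.94 mg/dL and log-SD 0.317
  (matching the reported creatinine median/IQR 0.94 [0.75-1.15]); the
  implied capped Cockcroft-Gault CLcr has median ~56.9 and
  IQR ~[41.6, 77.0] mL/min against the reported 56.5 [40.7-75.6] —
  creatinine is the sampled quantity and CLcr always derived, keeping
  age/weight/sex/CLcr mutually coherent;
* amiodarone/diltiazem/verapamil prevalences 16/8/6%;
* daily dose 250/125/62.5 ug with probabilities 0.13/0.77/0.10 (the
  4% "other doses" folded into the 125 ug majority);
* observations per patient = 1 + NegBin(r = 0.6, mean 7.86): median 5,
  IQR [2, 12], mean ~8.86, so 391 patients yield ~3465 troughs;
* sampling times 6-24 h after the last dose, skewed toward the end of
  the interval (Beta(4, 1) over the window): monitoring samples are
  intended pre-dose troughs, with occasional earlier draws, and the 6 h
  floor mirrors the eligibility rule for trough analysis.

Covariates are drawn independently (only the derivation formulas induce
correlation); real joint structure such as height-weight correlation is
not emulated.  Trough concentrations are generated under any specified
population model: per-patient eta ~ N(0, omega^2), closed-form
steady-state prediction at the drawn time after last dose, residual
error applied, and BLQ flagged by the assay-era limit of quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .data import (AnalysisDataset, BLQ_LIMITS, DoseRegimen, InvalidInputError,
                   PatientRecord, TroughObservation, derive_covariates)
from .structural import PopulationModel, apply_residual, steady_state_trough

__all__ = ["CohortConfig", "generate_covariates", "generate_trough_dataset",
           "generate_dataset"]


@dataclass(frozen=True)
class CohortConfig:
    """Distribution parameters of the virtual cohort (defaults = the study)."""

    n_patients: int = 391
    age_mean: float = 67.0
    age_sd: float = 14.0
    age_min: float = 19.0
    weight_mean: float = 57.0
    weight_sd: float = 15.0
    weight_min: float = 30.0
    height_mean: float = 161.0
    height_sd: float = 11.0
    height_min: float = 120.0
    female_fraction: float = 0.38
    scr_median: float = 0.94          # mg/dL, lognormal
    scr_log_sd: float = 0.317
    amiodarone_prevalence: float = 0.16
    diltiazem_prevalence: float = 0.08
    verapamil_prevalence: float = 0.06
    dose_levels_ug: tuple[float, ...] = (250.0, 125.0, 62.5)
    dose_fractions: tuple[float, ...] = (0.13, 0.77, 0.10)
    tau: float = 24.0
    obs_nb_r: float = 0.6             # 1 + NegBin(r, p): median 5, IQR [2,12]
    obs_nb_mean: float = 7.86
    tald_min: float = 6.0             # h, trough-sampling window
    tald_max: float = 24.0
    tald_beta_a: float = 4.0          # Beta(a, b) over the window; (1, 1) = uniform
    tald_beta_b: float = 1.0
    pre_era_fraction: float = 0.9     # share of samples on the pre-2016-12 assay
    interdose_days_mean: float = 30.0  # spacing of successive trough visits

    def __post_init__(self) -> None:
        fracs = np.asarray(self.dose_fractions, dtype=float)
        if self.n_patients < 0:
            raise InvalidInputError("n_patients must be >= 0")
        for f in (self.female_fraction, self.amiodarone_prevalence,
                  self.diltiazem_prevalence, self.verapamil_prevalence,
                  self.pre_era_fraction):
            if not 0.0 <= f <= 1.0:
                raise InvalidInputError(f"fraction {f} outside [0, 1]")
        if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
            raise InvalidInputError("dose_fractions must be >= 0 and sum to 1")
        if min(self.age_sd, self.weight_sd, self.height_sd, self.scr_log_sd) < 0:
            raise InvalidInputError("SDs must be non-negative")
        if not self.tald_min < self.tald_max:
            raise InvalidInputError("need tald_min < tald_max")

    def to_yaml(self, path=None) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        s = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("dose_levels_ug", "dose_fractions"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _truncated_normal(rng, mean, sd, lower, size):
    """Normal draws with sub-threshold values redrawn (not clipped)."""
    x = rng.normal(mean, sd, size)
    while True:
        bad = x < lower
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))


def generate_covariates(config: CohortConfig,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None
                        ) -> list[PatientRecord]:
    """Draw a seeded virtual cohort; all derived covariates (BMI, capped
    CLcr, eGFR) are computed through the same path as real data ingest."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = config.n_patients
    female = rng.random(n) < config.female_fraction
    age = _truncated_normal(rng, config.age_mean, config.age_sd, config.age_min, n)
    weight = _truncated_normal(rng, config.weight_mean, config.weight_sd,
                               config.weight_min, n)
    height = _truncated_normal(rng, config.height_mean, config.height_sd,
                               config.height_min, n)
    scr = np.exp(rng.normal(np.log(config.scr_median), config.scr_log_sd, n))
    amio = rng.random(n) < config.amiodarone_prevalence
    dilt = rng.random(n) < config.diltiazem_prevalence
    vera = rng.random(n) < config.verapamil_prevalence
    return [
        derive_covariates(
            id=f"P{i + 1:04d}",
            sex="female" if female[i] else "male",
            age=float(age[i]), height=float(height[i]), weight=float(weight[i]),
            scr=float(scr[i]), amiodarone=bool(amio[i]),
            diltiazem=bool(dilt[i]), verapamil=bool(vera[i]),
        )
        for i in range(n)
    ]


def generate_trough_dataset(patients: list[PatientRecord],
                            model: PopulationModel,
                            config: CohortConfig | None = None,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None
                            ) -> AnalysisDataset:
    """Simulate a trough dataset for ``patients`` under ``model``.

    Per patient: one maintenance regimen (dose drawn from the configured
    mix), eta ~ N(0, omega^2), and a right-skewed number of trough
    visits; per visit a time after last dose uniform on the trough
    window, the closed-form steady-state prediction, the residual error
    model, and a BLQ flag by the visit's assay-era quantification limit.
    BLQ rows keep their simulated value but are flagged for exclusion.
    """
    if not patients:
        raise InvalidInputError("patients must be non-empty")
    if config is None:
        config = CohortConfig(n_patients=len(patients))
    if rng is None:
        rng = np.random.default_rng(seed)

    regimens: list[DoseRegimen] = []
    observations: list[TroughObservation] = []
    p_nb = config.obs_nb_r / (config.obs_nb_r + config.obs_nb_mean)
    for p in patients:
        dose = float(rng.choice(config.dose_levels_ug, p=config.dose_fractions))
        regimens.append(DoseRegimen(patient_id=p.id, daily_dose=dose,
                                    tau=config.tau))
        eta = rng.normal(0.0, model.omega_cl) if model.omega_cl > 0 else 0.0
        cl = model.tv_cl * np.exp(eta)
        for e in model.effects:
            cl *= e.multiplier(p.covariates()[e.name])
        vd = p.weight * model.vd_per_kg

        n_obs = 1 + int(rng.negative_binomial(config.obs_nb_r, p_nb))
        # visits spaced ~monthly; first visit after >= 5 days (steady state)
        gaps_h = 24.0 * (5.0 + rng.exponential(config.interdose_days_mean,
                                               n_obs).cumsum())
        for t_visit in gaps_h:
            tald = float(config.tald_min
                         + (config.tald_max - config.tald_min)
                         * rng.beta(config.tald_beta_a, config.tald_beta_b))
            f = steady_state_trough(dose * config.tau / 24.0, config.tau,
                                    cl, vd, ka=model.ka, t=tald)
            eps = rng.normal(0.0, model.sigma) if model.sigma > 0 else 0.0
            c = float(apply_residual(f, eps, model.error_kind))
            era = ("pre-2016-12" if rng.random() < config.pre_era_fraction
                   else "post-2016-12")
            observations.append(TroughObservation(
                patient_id=p.id,
                time_after_first_dose=float(t_visit),
                time_after_last_dose=tald,
                concentration=c,
                blq=bool(c < BLQ_LIMITS[era]),
                assay_era=era,
            ))
    return AnalysisDataset(list(patients), regimens, observations,
                           provenance=f"synthetic cohort (n={len(patients)})")


def generate_dataset(model: PopulationModel,
                     config: CohortConfig | None = None,
                     seed: int | None = None) -> AnalysisDataset:
    """Convenience: covariates + troughs from a single seed."""
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(seed)
    patients = generate_covariates(config, rng=rng)
    return generate_trough_dataset(patients, model, config, rng=rng)
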