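"""One-compartment oral-absorption structural model and covariate model.

Digoxin kinetics are described by a one-compartment model with first-order
absorption (rate constant ``ka``, fixed at 1.0 /h because trough-only data
carry no absorption information) and first-order elimination
``ke = CL/Vd``.  All clearances and volumes are apparent oral quantities
(CL/F, Vd/F); bioavailability F is never a separate parameter.  The
apparent volume is fixed at 6.0 L/kg body weight — at steady state the
trough is insensitive to Vd, so it is not estimable from troughs either.

At steady state under repeated dosing every ``tau`` hours, superposition
of single-dose profiles gives the concentration ``t`` hours after a dose:

    C(t) = D*ka / (Vd*(ka-ke)) * [ exp(-ke*t)/(1-exp(-ke*tau))
                                   - exp(-ka*t)/(1-exp(-ka*tau)) ]

with dose D in micrograms and Vd in litres, so C is in ug/L = ng/mL.
The trough itself is C(tau).

The covariate model multiplies a typical clearance by power terms for
continuous covariates (normalised to a reference value) and by
``1 + coefficient`` for flags, then by the patient's exponential random
effect exp(eta), eta ~ N(0, omega^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import yaml

from .data import InvalidInputError, PatientRecord

__all__ = [
    "ConfigurationError",
    "StructuralParams",
    "CovariateEffect",
    "PopulationModel",
    "steady_state_trough",
    "individual_cl",
    "vd_from_weight",
    "apply_residual",
    "final_digoxin_model",
    "base_digoxin_model",
]

#: Published fixed constants of the digoxin model.
KA_FIXED = 1.0      # /h
VD_PER_KG = 6.0     # L/kg


class ConfigurationError(ValueError):
    """A model specification error (unknown covariate, error kind, ...)."""


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters: CL/F (L/h), Vd/F (L), ka (/h)."""

    cl: float
    vd: float
    ka: float = KA_FIXED

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.vd <= 0 or self.ka <= 0:
            raise InvalidInputError(
                f"cl, vd, ka must be positive (got {self.cl}, {self.vd}, {self.ka})"
            )

    @property
    def ke(self) -> float:
        return self.cl / self.vd


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate's multiplicative effect on typical clearance.

    ``power`` (continuous): multiplier ``(value/reference)**coefficient``.
    ``proportional`` (categorical): multiplier ``1 + coefficient*flag``
    (coefficient > -1 so the multiplier stays positive).
    """

    name: str
    kind: str                    # "power" | "proportional"
    coefficient: float
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("power", "proportional"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "power":
            if self.reference is None or self.reference <= 0:
                raise ConfigurationError(
                    f"power effect {self.name!r} needs a positive reference"
                )
        elif self.coefficient <= -1:
            raise ConfigurationError(
                f"proportional effect {self.name!r} must keep 1+coef > 0"
            )

    def multiplier(self, value: float) -> float:
        if self.kind == "power":
            return (value / self.reference) ** self.coefficient
        return 1.0 + self.coefficient * value


@dataclass(frozen=True)
class PopulationModel:
    """Population PK model: typical values, covariate effects, variabilities.

    ``omega_cl`` is the SD of the log-scale random effect eta on CL/F;
    ``sigma`` the residual-error magnitude (SD of epsilon: proportional for
    the multiplicative kind, ng/mL for the additive kind).
    """

    tv_cl: float                                  # L/h
    effects: tuple[CovariateEffect, ...] = ()
    omega_cl: float = 0.0
    sigma: float = 0.0
    error_kind: str = "multiplicative"            # | "additive"
    ka: float = KA_FIXED                          # /h, fixed
    vd_per_kg: float = VD_PER_KG                  # L/kg, fixed

    def __post_init__(self) -> None:
        if self.tv_cl <= 0:
            raise InvalidInputError(f"tv_cl must be positive, got {self.tv_cl}")
        if self.omega_cl < 0 or self.sigma < 0:
            raise InvalidInputError("omega_cl and sigma must be non-negative")
        if self.error_kind not in ("additive", "multiplicative"):
            raise ConfigurationError(f"unknown error kind {self.error_kind!r}")
        names = [e.name for e in self.effects]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate covariate effects in {names}")
        object.__setattr__(self, "effects", tuple(self.effects))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tv_cl": self.tv_cl,
            "effects": [
                {"name": e.name, "kind": e.kind, "coefficient": e.coefficient,
                 "reference": e.reference}
                for e in self.effects
            ],
            "omega_cl": self.omega_cl,
            "sigma": self.sigma,
            "error_kind": self.error_kind,
            "ka": self.ka,
            "vd_per_kg": self.vd_per_kg,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationModel":
        effects = tuple(
            CovariateEffect(e["name"], e["kind"], e["coefficient"],
                            e.get("reference"))
            for e in d.get("effects", ())
        )
        return cls(
            tv_cl=d["tv_cl"], effects=effects,
            omega_cl=d.get("omega_cl", 0.0), sigma=d.get("sigma", 0.0),
            error_kind=d.get("error_kind", "multiplicative"),
            ka=d.get("ka", KA_FIXED), vd_per_kg=d.get("vd_per_kg", VD_PER_KG),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_file(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))  # YAML is a JSON superset


def final_digoxin_model() -> PopulationModel:
    """The published final model for oral digoxin in AF/HF patients:

    CL/F = 6.2 * (CLcr/60)^0.41 * (1 - 0.24*[amiodarone]) * exp(eta),
    omega 34.4%, multiplicative residual 36.6%, ka 1.0 /h, Vd 6.0 L/kg.
    """
    return PopulationModel(
        tv_cl=6.2,
        effects=(
            CovariateEffect("clcr", "power", 0.41, reference=60.0),
            CovariateEffect("amiodarone", "proportional", -0.24),
        ),
        omega_cl=0.344,
        sigma=0.366,
        error_kind="multiplicative",
    )


def base_digoxin_model(tv_cl: float = 6.2, omega_cl: float = 0.344,
                       sigma: float = 0.366,
                       error_kind: str = "multiplicative") -> PopulationModel:
    """Covariate-free base model with the same fixed structure."""
    return PopulationModel(tv_cl=tv_cl, omega_cl=omega_cl, sigma=sigma,
                           error_kind=error_kind)


# ---------------------------------------------------------------------------
# operations


def individual_cl(model: PopulationModel,
                  patient: PatientRecord | Mapping[str, float],
                  eta: float = 0.0) -> float:
    """Individual CL/F (L/h): typical value x covariate multipliers x exp(eta)."""
    cov = patient.covariates() if isinstance(patient, PatientRecord) else patient
    cl = model.tv_cl
    for e in model.effects:
        if e.name not in cov:
            raise ConfigurationError(
                f"covariate {e.name!r} required by the model is missing"
            )
        cl *= e.multiplier(cov[e.name])
    return cl * float(np.exp(eta))


def vd_from_weight(weight, vd_per_kg: float = VD_PER_KG):
    """Apparent volume (L) from body weight at the fixed L/kg coefficient."""
    w = np.asarray(weight, dtype=float)
    if np.any(w <= 0):
        raise InvalidInputError("weight must be positive")
    out = w * vd_per_kg
    return float(out) if np.isscalar(weight) else out


def steady_state_trough(dose, tau, cl, vd, ka: float = KA_FIXED, t=None):
    """Steady-state concentration (ng/mL) ``t`` hours after a dose.

    ``t`` defaults to ``tau`` (the trough proper, evaluated just before the
    next dose).  Vectorised over any broadcastable mix of array arguments;
    dose in micrograms, volumes in litres.  Near the flip-flop singularity
    ka == ke the analytic limit is used instead of the generic formula.
    """
    dose = np.asarray(dose, dtype=float)
    tau_a = np.asarray(tau, dtype=float)
    cl_a = np.asarray(cl, dtype=float)
    vd_a = np.asarray(vd, dtype=float)
    if np.any(tau_a <= 0):
        raise InvalidInputError("tau must be positive")
    if np.any(dose < 0):
        raise InvalidInputError("dose must be non-negative")
    if np.any(cl_a <= 0) or np.any(vd_a <= 0) or ka <= 0:
        raise InvalidInputError("cl, vd and ka must be positive")
    t_a = tau_a if t is None else np.asarray(t, dtype=float)

    ke = cl_a / vd_a
    eket = np.exp(-ke * t_a)
    ekat = np.exp(-ka * t_a)
    dket = -np.expm1(-ke * tau_a)          # 1 - exp(-ke*tau), accurate for small ke
    dkat = -np.expm1(-ka * tau_a)

    diff = ka - ke
    degenerate = np.abs(diff) < 1e-8 * ka
    safe = np.where(degenerate, 1.0, diff)
    c = dose * ka / (vd_a * safe) * (eket / dket - ekat / dkat)
    if np.any(degenerate):
        # limit ka -> ke = k of the superposition formula
        k = ke
        c_lim = (dose * k / vd_a) * eket * (t_a * dket + tau_a * (1.0 - dket)) / dket**2
        c = np.where(degenerate, c_lim, c)
    return float(c) if c.ndim == 0 else c


def apply_residual(c_pred, eps, kind: str):
    """Apply the residual-error model: additive ``c+eps`` or multiplicative
    ``c*(1+eps)``."""
    if kind == "additive":
        return c_pred + eps
    if kind == "multiplicative":
        return c_pred * (1.0 + eps)
    raise ConfigurationError(f"unknown error kind {kind!r}")
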