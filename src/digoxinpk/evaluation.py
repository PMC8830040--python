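"""Goodness-of-fit diagnostics and patient-resampling bootstrap.

PRED is the population prediction (eta = 0), IPRED the individual
prediction at the empirical Bayes eta, and CWRES the conditional weighted
residual from the first-order conditional linearisation around the EBE:

    y_i ~ N( f_i(eta_hat) - G_i eta_hat,  G_i omega^2 G_i' + H_i )

with G_i = df_i/deta at eta_hat and H_i the residual covariance evaluated
at the individual prediction (sigma^2 f^2 for the multiplicative model).
CWRES decorrelates the residual vector by the Cholesky factor of that
covariance; for a correctly specified model it is approximately standard
normal.

The bootstrap resamples whole patients with replacement (all of a
patient's observations travel together) to the original patient count and
refits the fixed final-model structure per replicate, warm-started at the
original estimates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .data import AnalysisDataset, InvalidInputError
from .nlme import (FitResult, FlatData, _conditional_modes, fit_population,
                   natural_estimates)
from .structural import PopulationModel, steady_state_trough

__all__ = ["gof_table", "plot_gof", "bootstrap", "BootstrapSummary"]

logger = logging.getLogger(__name__)

GOF_COLUMNS = ["patient_id", "time_after_first_dose", "observed",
               "pred", "ipred", "cwres"]


def _predict(flat: FlatData, model: PopulationModel, eta: np.ndarray) -> np.ndarray:
    cl = (flat.base_cl(model) * np.exp(eta))[flat.pat_idx]
    vd = (flat.weight * model.vd_per_kg)[flat.pat_idx]
    return steady_state_trough(flat.dose, flat.tau, cl, vd,
                               ka=model.ka, t=flat.tald)


def gof_table(fit: FitResult, data: AnalysisDataset) -> pd.DataFrame:
    """Per-observation PRED, IPRED and CWRES for the four diagnostic
    scatter plots (DV vs PRED, DV vs IPRED, CWRES vs PRED, CWRES vs time)."""
    if not fit.converged:
        raise RuntimeError("goodness-of-fit requires a converged fit")
    model = fit.model
    view = data.estimation_view()
    flat = FlatData(view)

    if model.omega_cl == 0.0:
        eta_hat = np.zeros(flat.n_patients)
    else:
        eta_hat, _ = _conditional_modes(flat, model)
    pred = _predict(flat, model, np.zeros(flat.n_patients))
    ipred = _predict(flat, model, eta_hat)

    # numeric df/deta at the EBE, per observation
    h = 1e-5
    grad = (_predict(flat, model, eta_hat + h)
            - _predict(flat, model, eta_hat - h)) / (2.0 * h)

    w2 = model.omega_cl ** 2
    if model.error_kind == "multiplicative":
        res_var = (model.sigma * ipred) ** 2
    else:
        res_var = np.full_like(ipred, model.sigma ** 2)

    cwres = np.empty(flat.n_obs)
    times = np.array([o.time_after_first_dose for o in view.observations])
    for i in range(flat.n_patients):
        sel = flat.pat_idx == i
        g = grad[sel]
        mean = ipred[sel] - g * eta_hat[i]
        V = w2 * np.outer(g, g) + np.diag(res_var[sel])
        L = linalg.cholesky(V, lower=True)
        cwres[sel] = linalg.solve_triangular(L, flat.y[sel] - mean, lower=True)

    return pd.DataFrame({
        "patient_id": [flat.patient_ids[i] for i in flat.pat_idx],
        "time_after_first_dose": times,
        "observed": flat.y,
        "pred": pred,
        "ipred": ipred,
        "cwres": cwres,
    }, columns=GOF_COLUMNS)


def plot_gof(gof: pd.DataFrame, path) -> None:
    """Optional 2x2 diagnostic panel (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    lim = (0, float(max(gof["observed"].max(), gof["pred"].max(),
                        gof["ipred"].max())) * 1.05)
    for ax, x in zip(axes[0], ("pred", "ipred")):
        ax.plot(gof[x], gof["observed"], ".", ms=3, alpha=0.5)
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel(x.upper() + " (ng/mL)")
        ax.set_ylabel("DV (ng/mL)")
        ax.set_xlim(lim); ax.set_ylim(lim)
    for ax, x in zip(axes[1], ("pred", "time_after_first_dose")):
        ax.plot(gof[x], gof["cwres"], ".", ms=3, alpha=0.5)
        for y in (-2, 0, 2):
            ax.axhline(y, color="k", lw=1, ls="-" if y == 0 else ":")
        ax.set_xlabel("PRED (ng/mL)" if x == "pred" else "time after first dose (h)")
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class BootstrapSummary:
    """Patient-resampling bootstrap of the final model.

    ``params`` has one row per parameter with the replicate mean and the
    2.5th/97.5th percentile bounds over converged replicates.
    """

    n_requested: int
    n_converged: int
    params: pd.DataFrame            # index: parameter; mean, ci_lower, ci_upper
    seed: int | None
    replicate_estimates: pd.DataFrame | None = None

    @property
    def success_rate(self) -> float:
        return self.n_converged / self.n_requested

    def to_dict(self) -> dict:
        return {
            "n_requested": self.n_requested,
            "n_converged": self.n_converged,
            "success_rate": self.success_rate,
            "seed": self.seed,
            "params": {p: {k: float(v) for k, v in row.items()}
                       for p, row in self.params.iterrows()},
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def bootstrap(data: AnalysisDataset, model: PopulationModel,
              n: int = 1000, seed: int | None = None,
              init: dict[str, float] | None = None,
              method: str = "agq", nodes: int = 21,
              keep_replicates: bool = True) -> BootstrapSummary:
    """Bootstrap the final model by resampling patients with replacement.

    Each replicate draws the original number of patients (so the number
    of observations varies), refits the fixed model structure with the
    original estimates as starting values, and contributes to the summary
    only if the optimiser converges.  Success is defined as optimiser
    convergence (finite standard errors are not required).  Replicate
    failures are recorded, never fatal.
    """
    if n < 1:
        raise InvalidInputError(f"bootstrap needs n >= 1 replicates, got {n}")
    view = data.estimation_view()
    rng = np.random.default_rng(seed)
    pids = [p.id for p in view.patients]
    by_patient = {
        pid: (
            view.patient(pid),
            [r for r in view.regimens if r.patient_id == pid],
            [o for o in view.observations if o.patient_id == pid],
        )
        for pid in pids
    }

    rows = []
    n_converged = 0
    for b in range(n):
        draw = rng.integers(0, len(pids), size=len(pids))
        patients, regimens, observations = [], [], []
        for k, j in enumerate(draw):
            p, regs, obs = by_patient[pids[j]]
            alias = f"{p.id}#b{k}"     # duplicated draws become distinct ids
            patients.append(replace(p, id=alias))
            regimens.extend(r.__class__(alias, r.daily_dose, r.tau, r.start_time)
                            for r in regs)
            observations.extend(
                o.__class__(alias, o.time_after_first_dose,
                            o.time_after_last_dose, o.concentration,
                            o.blq, o.assay_era)
                for o in obs)
        replicate = AnalysisDataset(patients, regimens, observations,
                                    provenance=f"bootstrap replicate {b}")
        try:
            fit = fit_population(model, replicate, method=method, nodes=nodes,
                                 init=init, compute_se=False)
            ok = fit.converged
        except Exception as exc:
            logger.warning("replicate %d failed: %s", b, exc)
            ok = False
        if ok:
            n_converged += 1
            rows.append({"replicate": b, **fit.estimates})
        else:
            logger.warning("replicate %d did not converge", b)

    est = pd.DataFrame(rows).set_index("replicate") if rows else pd.DataFrame()
    if len(est):
        params = pd.DataFrame({
            "mean": est.mean(),
            "ci_lower": est.quantile(0.025),
            "ci_upper": est.quantile(0.975),
        })
    else:
        params = pd.DataFrame(columns=["mean", "ci_lower", "ci_upper"])
    return BootstrapSummary(
        n_requested=n, n_converged=n_converged, params=params, seed=seed,
        replicate_estimates=est if keep_replicates else None,
    )
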