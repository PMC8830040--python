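"""Stepwise forward selection of clearance covariates by OFV drop.

Candidates are tried one at a time on top of the current model; the
candidate with the largest OFV drop enters if the drop reaches the
likelihood-ratio threshold (3.84, one degree of freedom, p < 0.05), and
the search repeats until no candidate qualifies.  Renal-function
summaries (CLcr and eGFR) are declared collinear: once one of them
enters, the other is blocked, with ties broken by a clinical-priority
list that prefers CLcr (unadjusted for body surface area, it tracks
individual drug clearance more directly).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np

from .data import AnalysisDataset
from .nlme import FitResult, FlatData, LRT_CRITICAL, fit_population
from .structural import ConfigurationError, CovariateEffect, PopulationModel

__all__ = [
    "CONTINUOUS_COVARIATES",
    "CATEGORICAL_COVARIATES",
    "DEFAULT_CANDIDATES",
    "DEFAULT_COLLINEAR",
    "DEFAULT_PRIORITY",
    "SelectionStep",
    "SelectionTrace",
    "candidate_effects",
    "forward_select",
    "resolve_collinearity",
]

logger = logging.getLogger(__name__)

CONTINUOUS_COVARIATES = ("age", "bmi", "clcr", "egfr")
CATEGORICAL_COVARIATES = ("sex", "amiodarone", "diltiazem", "verapamil")

#: The screened candidate set: demographics, renal function, P-gp inhibitors.
DEFAULT_CANDIDATES = ("sex", "age", "bmi", "clcr", "egfr",
                      "amiodarone", "diltiazem", "verapamil")

#: Covariate pairs measuring the same physiology; only one may enter.
DEFAULT_COLLINEAR = (frozenset({"clcr", "egfr"}),)

#: Clinical priority for collinearity ties (first match wins).
DEFAULT_PRIORITY = ("clcr", "egfr")

#: Fixed normalisation for creatinine clearance in the power model (mL/min).
CLCR_REFERENCE = 60.0


def _round_2sf(x: float) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + 1)


def candidate_effects(name: str, data: AnalysisDataset | FlatData | None = None
                      ) -> CovariateEffect:
    """Null-initialised effect template for one candidate covariate.

    Continuous covariates get a power effect normalised to a typical
    value: 60 mL/min for CLcr (the convention of the final model), the
    dataset median rounded to two significant figures otherwise (which
    therefore requires ``data``).  Categorical covariates get a
    proportional effect on the flag, initialised at 0 (multiplier 1).
    """
    if name in CATEGORICAL_COVARIATES:
        return CovariateEffect(name, "proportional", 0.0)
    if name not in CONTINUOUS_COVARIATES:
        raise ConfigurationError(f"unknown candidate covariate {name!r}")
    if name == "clcr":
        return CovariateEffect(name, "power", 0.0, reference=CLCR_REFERENCE)
    if data is None:
        raise ConfigurationError(
            f"continuous candidate {name!r} needs the dataset for its reference"
        )
    flat = data if isinstance(data, FlatData) else FlatData(data)
    ref = _round_2sf(float(np.median(flat.covariates[name])))
    return CovariateEffect(name, "power", 0.0, reference=ref)


@dataclass
class SelectionStep:
    """One forward-selection round: every remaining candidate's OFV drop
    (``None`` where the fit failed), the chosen candidate (or ``None``)
    and any collinearity annotation."""

    delta_ofv: dict[str, float | None]
    chosen: str | None
    note: str = ""


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_model: PopulationModel
    final_fit: FitResult
    base_ofv: float
    threshold: float = LRT_CRITICAL

    @property
    def selected(self) -> list[str]:
        return [s.chosen for s in self.steps if s.chosen is not None]

    def to_json(self, path=None) -> str:
        d = {
            "threshold": self.threshold,
            "base_ofv": self.base_ofv,
            "selected": self.selected,
            "steps": [
                {"delta_ofv": s.delta_ofv, "chosen": s.chosen, "note": s.note}
                for s in self.steps
            ],
            "final_model": self.final_model.to_dict(),
            "final_ofv": self.final_fit.ofv,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def report(self) -> str:
        """Tabular text report: candidate, delta-OFV, decision per step."""
        lines = [f"forward selection (threshold dOFV >= {self.threshold}), "
                 f"base OFV {self.base_ofv:.3f}"]
        for i, s in enumerate(self.steps, 1):
            lines.append(f"step {i}:")
            for name, d in sorted(s.delta_ofv.items(),
                                  key=lambda kv: -(kv[1] if kv[1] is not None
                                                   else -np.inf)):
                tag = ("  <- added" if name == s.chosen else "")
                dtxt = "fit failed" if d is None else f"{d:8.3f}"
                lines.append(f"  {name:<12} dOFV {dtxt}{tag}")
            if s.chosen is None:
                lines.append("  no candidate reached the threshold; stop")
            if s.note:
                lines.append(f"  note: {s.note}")
        lines.append(f"selected: {self.selected or 'none'}; "
                     f"final OFV {self.final_fit.ofv:.3f}")
        return "\n".join(lines)


def resolve_collinearity(qualifying: dict[str, float],
                         collinear=DEFAULT_COLLINEAR,
                         priority=DEFAULT_PRIORITY) -> tuple[str, str]:
    """Pick the winner among qualifying candidates, honouring collinearity.

    Returns ``(chosen, note)``.  The candidate with the largest OFV drop
    wins; if a declared-collinear partner also qualifies, the partner is
    named in the note (the caller blocks it from later steps).  An exact
    tie within a collinear pair is broken by the priority list.
    """
    best = max(qualifying, key=lambda n: qualifying[n])
    note = ""
    for group in collinear:
        if best in group:
            partners = [n for n in group if n != best and n in qualifying]
            ties = [n for n in partners if qualifying[n] == qualifying[best]]
            if ties:
                ranked = sorted(ties + [best],
                                key=lambda n: (priority.index(n)
                                               if n in priority else len(priority)))
                best = ranked[0]
                partners = [n for n in group if n != best and n in qualifying]
                note = (f"tie within collinear group broken by priority "
                        f"({best} preferred)")
            if partners:
                note = (note + "; " if note else "") + \
                    f"collinear partner(s) {partners} blocked"
    return best, note


def forward_select(base: PopulationModel,
                   candidates=DEFAULT_CANDIDATES,
                   data: AnalysisDataset | FlatData = None,
                   threshold: float = LRT_CRITICAL,
                   collinear=DEFAULT_COLLINEAR,
                   priority=DEFAULT_PRIORITY,
                   method: str = "agq", nodes: int = 21) -> SelectionTrace:
    """Forward-select clearance covariates on ``data`` starting from ``base``.

    Each round refits the current model plus each remaining candidate,
    warm-started from the current estimates; a candidate fit failure is
    recorded in the trace and skipped, never fatal.
    """
    flat = data if isinstance(data, FlatData) else FlatData(data)
    base_fit = fit_population(base, flat, method=method, nodes=nodes,
                              compute_se=False)
    if not base_fit.converged:
        raise RuntimeError(f"base model fit failed: {base_fit.message}")

    current_fit = base_fit
    remaining = list(candidates)
    blocked: set[str] = set()
    steps: list[SelectionStep] = []

    while remaining:
        deltas: dict[str, float | None] = {}
        fits: dict[str, FitResult] = {}
        for name in remaining:
            try:
                eff = candidate_effects(name, flat)
                spec = replace(current_fit.model,
                               effects=current_fit.model.effects + (eff,))
                init = dict(current_fit.estimates)
                fit = fit_population(spec, flat, method=method, nodes=nodes,
                                     init=init, compute_se=False)
                if not fit.converged:
                    raise RuntimeError(fit.message)
                deltas[name] = current_fit.ofv - fit.ofv
                fits[name] = fit
            except Exception as exc:  # candidate failure is non-fatal
                logger.warning("candidate %s skipped: %s", name, exc)
                deltas[name] = None
        qualifying = {n: d for n, d in deltas.items()
                      if d is not None and d >= threshold}
        if not qualifying:
            steps.append(SelectionStep(delta_ofv=deltas, chosen=None))
            break
        chosen, note = resolve_collinearity(qualifying, collinear, priority)
        if note:
            logger.info("collinearity: %s", note)
        steps.append(SelectionStep(delta_ofv=deltas, chosen=chosen, note=note))
        current_fit = fits[chosen]
        remaining.remove(chosen)
        for group in collinear:
            if chosen in group:
                for partner in group:
                    if partner in remaining:
                        remaining.remove(partner)
                        blocked.add(partner)

    # refit the final model once more with standard errors
    final_fit = fit_population(current_fit.model, flat, method=method,
                               nodes=nodes, init=dict(current_fit.estimates))
    return SelectionTrace(steps=steps, final_model=final_fit.model,
                          final_fit=final_fit, base_ofv=base_fit.ofv,
                          threshold=threshold)
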