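"""Cohort data model: patients, dose regimens, trough observations, CSV I/O.

The estimation dataset is longitudinal trough-only therapeutic drug
monitoring data: one row per observed steady-state trough serum digoxin
concentration, with patient-level demographics, renal function and
P-glycoprotein-inhibitor co-medication flags repeated on every row.

Renal function is summarised two ways, both derived from serum creatinine
on ingest and never stored raw in :class:`PatientRecord`:

* creatinine clearance (Cockcroft-Gault), capped at 120 mL/min to avoid
  extrapolating renal drug clearance into the hyperfiltration range;
* eGFR by the Japanese MDRD-type equation (mL/min/1.73 m^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "InvalidInputError",
    "DatasetError",
    "PatientRecord",
    "DoseRegimen",
    "TroughObservation",
    "AnalysisDataset",
    "cockcroft_gault",
    "egfr_japanese",
    "cap_clcr",
    "derive_covariates",
    "read_dataset",
    "write_dataset",
    "CSV_COLUMNS",
    "CLCR_CAP",
    "MIN_TROUGH_HOURS",
    "BLQ_LIMITS",
]

logger = logging.getLogger(__name__)

#: Upper bound applied to Cockcroft-Gault creatinine clearance (mL/min).
CLCR_CAP = 120.0

#: Minimum hours after the last dose for a concentration to count as a trough.
MIN_TROUGH_HOURS = 6.0

#: Lower limit of quantification (ng/mL) by assay era.  The immunoassay used
#: before December 2016 was linear from 0.3 ng/mL; its replacement from
#: 0.2 ng/mL.
BLQ_LIMITS = {"pre-2016-12": 0.3, "post-2016-12": 0.2}

ASSAY_ERAS = tuple(BLQ_LIMITS)

#: Exact CSV column schema (one row per observation, UTF-8, "." decimals).
CSV_COLUMNS = [
    "ID", "SEX", "AGE", "HEIGHT", "WEIGHT", "SCR",
    "AMIO", "DILT", "VERA",
    "DOSE_UG", "TAU_H", "TIME_H", "TALD_H", "DV_NGML", "BLQ", "ASSAY_ERA",
]


class InvalidInputError(ValueError):
    """A physiologically or numerically invalid input value."""


class DatasetError(ValueError):
    """A malformed dataset file or an internally inconsistent dataset."""


# ---------------------------------------------------------------------------
# renal-function formulas


def cockcroft_gault(age: float, weight: float, scr: float, sex: str) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft-Gault equation.

    ``(140 - age) * weight / (72 * scr)``, times 0.85 for females.
    Uses actual body weight (kg); ``scr`` in mg/dL.  Valid for age < 140
    (the linear age term changes sign there).
    """
    if weight <= 0 or scr <= 0:
        raise InvalidInputError(
            f"weight and serum creatinine must be positive (got {weight}, {scr})"
        )
    if age >= 140:
        raise InvalidInputError(f"age {age} out of the formula's range (< 140)")
    if sex not in ("male", "female"):
        raise InvalidInputError(f"sex must be 'male' or 'female', got {sex!r}")
    clcr = (140.0 - age) * weight / (72.0 * scr)
    if sex == "female":
        clcr *= 0.85
    return clcr


def egfr_japanese(scr: float, age: float, sex: str) -> float:
    """eGFR (mL/min/1.73 m^2) by the Japanese MDRD-type equation.

    ``194 * scr^-1.094 * age^-0.287``, times 0.739 for females.
    """
    if scr <= 0 or age <= 0:
        raise InvalidInputError(
            f"serum creatinine and age must be positive (got {scr}, {age})"
        )
    if sex not in ("male", "female"):
        raise InvalidInputError(f"sex must be 'male' or 'female', got {sex!r}")
    egfr = 194.0 * scr ** -1.094 * age ** -0.287
    if sex == "female":
        egfr *= 0.739
    return egfr


def cap_clcr(clcr: float, cap: float = CLCR_CAP) -> float:
    """Cap creatinine clearance at ``cap`` (default 120 mL/min)."""
    if clcr <= 0:
        raise InvalidInputError(f"creatinine clearance must be positive, got {clcr}")
    return min(clcr, cap)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics, derived renal function and co-medication.

    ``clcr`` is the capped Cockcroft-Gault value (mL/min); ``egfr`` in
    mL/min/1.73 m^2; ``bmi`` in kg/m^2.  Build via :func:`derive_covariates`
    so the derived fields stay consistent with the raw ones.
    """

    id: str
    sex: str                      # "male" | "female"
    age: float                    # years
    height: float                 # cm
    weight: float                 # kg
    scr: float                    # mg/dL
    amiodarone: bool = False
    diltiazem: bool = False
    verapamil: bool = False
    clcr: float = 0.0             # mL/min, derived + capped
    egfr: float = 0.0             # mL/min/1.73 m^2, derived
    bmi: float = 0.0              # kg/m^2, derived

    def covariates(self) -> dict[str, float]:
        """Covariate lookup used by the clearance covariate model."""
        return {
            "clcr": self.clcr,
            "egfr": self.egfr,
            "age": self.age,
            "bmi": self.bmi,
            "weight": self.weight,
            "sex": 1.0 if self.sex == "female" else 0.0,
            "amiodarone": float(self.amiodarone),
            "diltiazem": float(self.diltiazem),
            "verapamil": float(self.verapamil),
        }


@dataclass(frozen=True)
class DoseRegimen:
    """A maintenance oral regimen: ``daily_dose`` micrograms every ``tau`` h
    starting at ``start_time`` hours from the study origin."""

    patient_id: str
    daily_dose: float             # micrograms
    tau: float = 24.0             # hours
    start_time: float = 0.0      # hours

    def __post_init__(self) -> None:
        if self.daily_dose <= 0:
            raise InvalidInputError(f"daily_dose must be positive, got {self.daily_dose}")
        if self.tau <= 0:
            raise InvalidInputError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class TroughObservation:
    """One measured trough concentration.

    ``time_after_first_dose`` locates the sample in the treatment course;
    ``time_after_last_dose`` (>= 6 h for estimation) locates it inside the
    dosing interval.  ``blq`` marks values below the assay-era limit of
    quantification; BLQ rows are kept in the dataset but excluded from the
    estimation view.
    """

    patient_id: str
    time_after_first_dose: float  # hours
    time_after_last_dose: float   # hours
    concentration: float          # ng/mL
    blq: bool = False
    assay_era: str = "pre-2016-12"

    def __post_init__(self) -> None:
        if self.time_after_first_dose < 0:
            raise InvalidInputError("time_after_first_dose must be >= 0")
        if self.assay_era not in ASSAY_ERAS:
            raise InvalidInputError(f"unknown assay era {self.assay_era!r}")
        if not self.blq and self.concentration <= 0:
            raise InvalidInputError(
                f"non-BLQ concentration must be positive, got {self.concentration}"
            )


@dataclass
class AnalysisDataset:
    """Patients + regimens + trough observations: the estimation input."""

    patients: list[PatientRecord]
    regimens: list[DoseRegimen]
    observations: list[TroughObservation]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = {p.id for p in self.patients}
        if len(ids) != len(self.patients):
            raise DatasetError("duplicate patient ids")
        for r in self.regimens:
            if r.patient_id not in ids:
                raise DatasetError(f"regimen references unknown patient {r.patient_id!r}")
        for o in self.observations:
            if o.patient_id not in ids:
                raise DatasetError(f"observation references unknown patient {o.patient_id!r}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def patient(self, pid: str) -> PatientRecord:
        for p in self.patients:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def regimen_at(self, pid: str, time_h: float) -> DoseRegimen:
        """The regimen active for ``pid`` at ``time_h`` (latest started)."""
        cands = [r for r in self.regimens
                 if r.patient_id == pid and r.start_time <= time_h]
        if not cands:
            raise DatasetError(f"no active regimen for patient {pid!r} at t={time_h}")
        return max(cands, key=lambda r: r.start_time)

    def estimation_view(self) -> "AnalysisDataset":
        """Dataset restricted to usable observations.

        Drops BLQ rows and rows sampled < 6 h after the last dose, then
        drops patients left without observations.  Logs the exclusion
        counts.
        """
        kept = [o for o in self.observations
                if not o.blq and o.time_after_last_dose >= MIN_TROUGH_HOURS]
        n_blq = sum(o.blq for o in self.observations)
        n_early = len(self.observations) - n_blq - len(kept)
        pids = {o.patient_id for o in kept}
        patients = [p for p in self.patients if p.id in pids]
        regimens = [r for r in self.regimens if r.patient_id in pids]
        logger.info(
            "estimation view: %d patients, %d observations "
            "(excluded %d BLQ, %d sampled <%g h post-dose)",
            len(patients), len(kept), n_blq, n_early, MIN_TROUGH_HOURS,
        )
        return AnalysisDataset(patients, regimens, kept,
                               provenance=self.provenance + " [estimation view]")

    def to_frame(self) -> pd.DataFrame:
        """Canonical one-row-per-observation table (the CSV schema)."""
        pat = {p.id: p for p in self.patients}
        rows = []
        for o in self.observations:
            p = pat[o.patient_id]
            r = self.regimen_at(o.patient_id, o.time_after_first_dose)
            rows.append({
                "ID": p.id, "SEX": p.sex, "AGE": p.age, "HEIGHT": p.height,
                "WEIGHT": p.weight, "SCR": p.scr,
                "AMIO": int(p.amiodarone), "DILT": int(p.diltiazem),
                "VERA": int(p.verapamil),
                "DOSE_UG": r.daily_dose, "TAU_H": r.tau,
                "TIME_H": o.time_after_first_dose,
                "TALD_H": o.time_after_last_dose,
                "DV_NGML": o.concentration, "BLQ": int(o.blq),
                "ASSAY_ERA": o.assay_era,
            })
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


# ---------------------------------------------------------------------------
# covariate derivation and I/O


def derive_covariates(
    id: str,
    sex: str,
    age: float,
    height: float,
    weight: float,
    scr: float,
    amiodarone: bool = False,
    diltiazem: bool = False,
    verapamil: bool = False,
) -> PatientRecord:
    """Build a :class:`PatientRecord` with bmi, clcr (capped) and eGFR derived."""
    try:
        if height <= 0:
            raise InvalidInputError(f"height must be positive, got {height}")
        bmi = weight / (height / 100.0) ** 2
        clcr = cap_clcr(cockcroft_gault(age, weight, scr, sex))
        egfr = egfr_japanese(scr, age, sex)
    except InvalidInputError as exc:
        raise InvalidInputError(f"patient {id!r}: {exc}") from exc
    return PatientRecord(
        id=str(id), sex=sex, age=age, height=height, weight=weight, scr=scr,
        amiodarone=bool(amiodarone), diltiazem=bool(diltiazem),
        verapamil=bool(verapamil), clcr=clcr, egfr=egfr, bmi=bmi,
    )


def _patient_from_rows(pid: str, g: pd.DataFrame) -> PatientRecord:
    first = g.iloc[0]
    return derive_covariates(
        id=str(pid), sex=str(first["SEX"]), age=float(first["AGE"]),
        height=float(first["HEIGHT"]), weight=float(first["WEIGHT"]),
        scr=float(first["SCR"]), amiodarone=bool(int(first["AMIO"])),
        diltiazem=bool(int(first["DILT"])), verapamil=bool(int(first["VERA"])),
    )


def read_dataset(path) -> AnalysisDataset:
    """Read an :class:`AnalysisDataset` from the canonical CSV schema.

    Patient-level fields are taken from each patient's first row; a change
    in (DOSE_UG, TAU_H) along a patient's time axis opens a new regimen.
    BLQ rows are retained (flagged); exclusion happens in
    :meth:`AnalysisDataset.estimation_view`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing column(s) {missing}")
    numeric = ["AGE", "HEIGHT", "WEIGHT", "SCR", "AMIO", "DILT", "VERA",
               "DOSE_UG", "TAU_H", "TIME_H", "TALD_H", "DV_NGML", "BLQ"]
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any() or df[c].isna().any():
            row = int((coerced.isna()).idxmax()) + 2  # header + 1-based
            raise DatasetError(f"{path}: non-numeric or missing {c} at file row {row}")
        df[c] = coerced

    patients, regimens, observations = [], [], []
    for pid, g in df.groupby("ID", sort=False):
        g = g.sort_values("TIME_H", kind="stable")
        patients.append(_patient_from_rows(str(pid), g))
        current: tuple[float, float] | None = None
        for _, row in g.iterrows():
            key = (float(row["DOSE_UG"]), float(row["TAU_H"]))
            if key != current:
                # first regimen opens at the study origin; a dose change is
                # anchored at the last-dose time of its first observation
                start = (0.0 if current is None
                         else float(row["TIME_H"]) - float(row["TALD_H"]))
                regimens.append(DoseRegimen(
                    patient_id=str(pid), daily_dose=key[0], tau=key[1],
                    start_time=start,
                ))
                current = key
            observations.append(TroughObservation(
                patient_id=str(pid),
                time_after_first_dose=float(row["TIME_H"]),
                time_after_last_dose=float(row["TALD_H"]),
                concentration=float(row["DV_NGML"]),
                blq=bool(int(row["BLQ"])),
                assay_era=str(row["ASSAY_ERA"]),
            ))
    ds = AnalysisDataset(patients, regimens, observations, provenance=str(path))
    n_blq = sum(o.blq for o in ds.observations)
    logger.info("read %s: %d patients, %d observations (%d BLQ flagged)",
                path, ds.n_patients, ds.n_observations, n_blq)
    return ds


def write_dataset(dataset: AnalysisDataset, path) -> None:
    """Write the dataset to CSV in the canonical schema (lossless round-trip
    up to regimen start times, which are re-derived on read)."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")
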