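"""Renal-function formulas, covariate derivation and dataset I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from digoxinpk.data import (AnalysisDataset, DatasetError, DoseRegimen,
                            InvalidInputError, PatientRecord,
                            TroughObservation, cap_clcr, cockcroft_gault,
                            derive_covariates, egfr_japanese, read_dataset,
                            write_dataset)


class TestRenalFormulas:
    def test_cockcroft_gault_reference_values(self):
        # typical study patient: 67 y, 57 kg, creatinine 0.94 mg/dL
        male = cockcroft_gault(67, 57, 0.94, "male")
        assert male == pytest.approx((140 - 67) * 57 / (72 * 0.94))
        assert male == pytest.approx(61.5, abs=0.05)
        assert cockcroft_gault(67, 57, 0.94, "female") == pytest.approx(0.85 * male)

    def test_cockcroft_gault_age_limit(self):
        assert cockcroft_gault(139, 57, 0.94, "male") > 0
        with pytest.raises(InvalidInputError):
            cockcroft_gault(140, 57, 0.94, "male")

    @pytest.mark.parametrize("kwargs", [
        dict(age=67, weight=0, scr=0.94, sex="male"),
        dict(age=67, weight=57, scr=-1, sex="male"),
        dict(age=67, weight=57, scr=0.94, sex="unknown"),
    ])
    def test_cockcroft_gault_invalid(self, kwargs):
        with pytest.raises(InvalidInputError):
            cockcroft_gault(**kwargs)

    @settings(max_examples=50, derandomize=True)
    @given(age=st.floats(19, 100), weight=st.floats(30, 150),
           scr=st.floats(0.3, 5.0))
    def test_cockcroft_gault_monotonicity(self, age, weight, scr):
        base = cockcroft_gault(age, weight, scr, "male")
        assert cockcroft_gault(age + 1, weight, scr, "male") < base
        assert cockcroft_gault(age, weight + 1, scr, "male") > base
        assert cockcroft_gault(age, weight, scr + 0.1, "male") < base

    def test_egfr_japanese_reference_values(self):
        male = egfr_japanese(1.0, 60, "male")
        assert male == pytest.approx(194 * 60 ** -0.287, rel=1e-12)  # scr term = 1
        assert male == pytest.approx(59.9, abs=0.05)
        assert egfr_japanese(1.0, 60, "female") == pytest.approx(0.739 * male)
        with pytest.raises(InvalidInputError):
            egfr_japanese(0.0, 60, "male")

    def test_cap_clcr(self):
        assert cap_clcr(130.0) == 120.0
        assert cap_clcr(120.0) == 120.0
        assert cap_clcr(56.5) == 56.5
        with pytest.raises(InvalidInputError):
            cap_clcr(0.0)

    @settings(max_examples=30, derandomize=True)
    @given(x=st.floats(0.1, 300), y=st.floats(0.1, 300))
    def test_cap_clcr_idempotent_and_order_preserving(self, x, y):
        assert cap_clcr(cap_clcr(x)) == cap_clcr(x)
        if x <= y:
            assert cap_clcr(x) <= cap_clcr(y)


class TestDeriveCovariates:
    def test_bmi_and_capping(self):
        p = derive_covariates("p1", "male", 67, 161, 57, 0.94)
        assert p.bmi == pytest.approx(57 / 1.61 ** 2)
        assert p.bmi == pytest.approx(22, abs=0.5)
        assert p.clcr == pytest.approx(61.48, abs=0.01)

    def test_high_clcr_is_capped(self):
        p = derive_covariates("p2", "male", 25, 90, 80, 0.5)
        assert cockcroft_gault(25, 80, 0.5, "male") > 120
        assert p.clcr == 120.0

    def test_degenerate_height_names_patient(self):
        with pytest.raises(InvalidInputError, match="p3"):
            derive_covariates("p3", "male", 67, 0, 57, 0.94)


def _fixture_dataset():
    patients = [
        derive_covariates("A", "male", 67, 161, 57, 0.94, amiodarone=True),
        derive_covariates("B", "female", 72, 150, 48, 1.2),
        derive_covariates("C", "male", 55, 170, 70, 0.8, diltiazem=True),
    ]
    regimens = [DoseRegimen("A", 125.0), DoseRegimen("B", 62.5),
                DoseRegimen("C", 250.0)]
    obs = []
    for i, (pid, era) in enumerate([("A", "pre-2016-12"), ("B", "post-2016-12"),
                                    ("C", "pre-2016-12")]):
        for j in range(3):
            obs.append(TroughObservation(
                pid, time_after_first_dose=240.0 + 24 * j + i,
                time_after_last_dose=6.0 + 2 * j,
                concentration=0.5 + 0.1 * j, assay_era=era))
    # two BLQ rows and one sampled too early
    obs.append(TroughObservation("A", 400.0, 8.0, 0.1, blq=True))
    obs.append(TroughObservation("B", 400.0, 8.0, 0.05, blq=True))
    obs.append(TroughObservation("C", 400.0, 3.0, 0.9))
    return AnalysisDataset(patients, regimens, obs)


class TestDatasetIO:
    def test_round_trip_identity(self, tmp_path):
        ds = _fixture_dataset()
        path = tmp_path / "ds.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        key = lambda o: (o.patient_id, o.time_after_first_dose)
        assert sorted(back.patients, key=lambda p: p.id) == \
            sorted(ds.patients, key=lambda p: p.id)
        assert sorted(back.observations, key=key) == sorted(ds.observations, key=key)
        assert sorted(back.regimens, key=lambda r: r.patient_id) == \
            sorted(ds.regimens, key=lambda r: r.patient_id)

    def test_estimation_view_excludes_blq_and_early_samples(self):
        ds = _fixture_dataset()
        view = ds.estimation_view()
        assert ds.n_observations == 12
        assert view.n_observations == 9   # 2 BLQ + 1 early sample dropped
        assert all(not o.blq and o.time_after_last_dose >= 6
                   for o in view.observations)

    def test_missing_column_raises(self, tmp_path):
        ds = _fixture_dataset()
        path = tmp_path / "ds.csv"
        write_dataset(ds, path)
        df = pd.read_csv(path).drop(columns=["SCR"])
        df.to_csv(path, index=False)
        with pytest.raises(DatasetError, match="SCR"):
            read_dataset(path)

    def test_non_numeric_field_names_row(self, tmp_path):
        ds = _fixture_dataset()
        path = tmp_path / "ds.csv"
        write_dataset(ds, path)
        df = pd.read_csv(path)
        df["DV_NGML"] = df["DV_NGML"].astype(object)
        df.loc[4, "DV_NGML"] = "oops"
        df.to_csv(path, index=False)
        with pytest.raises(DatasetError, match="DV_NGML"):
            read_dataset(path)

    def test_unknown_patient_reference_rejected(self):
        with pytest.raises(DatasetError, match="ghost"):
            AnalysisDataset(
                patients=[derive_covariates("A", "male", 67, 161, 57, 0.94)],
                regimens=[DoseRegimen("A", 125.0)],
                observations=[TroughObservation("ghost", 240.0, 8.0, 0.5)],
            )
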