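import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psynet.cohort import (classify_diagnosis, derive_covariates,
                           select_index_stays, build_cohort)
from psynet import ScenarioConfig


@pytest.mark.parametrize("code,expected", [
    ("F200", "psychotic"),
    ("F20", "psychotic"),
    ("F259", "psychotic"),
    ("f20.0", "psychotic"),          # case and dots normalised
    ("F300", "bipolar_personality"),
    ("F319", "bipolar_personality"),
    ("F603", "bipolar_personality"),
    ("F322", "severe_depressive"),
    ("F323", "severe_depressive"),
    ("F332", "severe_depressive"),
    ("F333", "severe_depressive"),
    ("F321", None),                  # moderate episode: not included
    ("F331", None),
    ("F600", None),
    ("F410", None),
    ("Z046", None),
    ("G309", None),
])
def test_classify_diagnosis(code, expected):
    assert classify_diagnosis(code) == expected


@pytest.mark.parametrize("bad", ["", "20F", "FX20", None, "F"])
def test_classify_diagnosis_malformed(bad):
    with pytest.raises(ValueError):
        classify_diagnosis(bad)


@given(st.text(alphabet="ABCDEFGHZ0123456789", min_size=3, max_size=4))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_classify_total_on_wellformed(code):
    import re
    if re.match(r"^[A-Z][0-9]{2,3}$", code):
        assert classify_diagnosis(code) in (
            "psychotic", "bipolar_personality", "severe_depressive", None)


def _mini_tables():
    providers = pd.DataFrame([
        dict(provider_id="H1", provider_type="hospital", in_region=1,
             zone="Z0", is_index=1, sectorized=1, military=0, private=0,
             specialized=0, beds=100.0, catchment_pop=1e5, area_typology=""),
        dict(provider_id="HM", provider_type="hospital", in_region=1,
             zone="Z0", is_index=1, sectorized=1, military=1, private=0,
             specialized=0, beds=100.0, catchment_pop=1e5, area_typology=""),
    ])
    patients = pd.DataFrame([
        dict(patient_id="P1", birth_year=1980, sex="M", low_income=0,
             somatic_ltd=0, residence_zone="Z0", referring_physician_id=""),
        dict(patient_id="P2", birth_year=1946, sex="F", low_income=0,
             somatic_ltd=1, residence_zone="Z0", referring_physician_id=""),
        dict(patient_id="P3", birth_year=1985, sex="F", low_income=1,
             somatic_ltd=0, residence_zone="Z0", referring_physician_id=""),
        dict(patient_id="P4", birth_year=1970, sex="M", low_income=0,
             somatic_ltd=0, residence_zone="Z0", referring_physician_id=""),
    ])
    d = pd.Timestamp
    stays = pd.DataFrame([
        # P1: two eligible stays -> earliest anchors
        dict(patient_id="P1", hospital_id="H1", admit_date=d("2012-03-01"),
             discharge_date=d("2012-04-01"), icd10_main="F200",
             care_type="full_time_psychiatric"),
        dict(patient_id="P1", hospital_id="H1", admit_date=d("2013-05-01"),
             discharge_date=d("2013-06-01"), icd10_main="F200",
             care_type="full_time_psychiatric"),
        # P2: aged 66 at admission -> excluded
        dict(patient_id="P2", hospital_id="H1", admit_date=d("2012-06-01"),
             discharge_date=d("2012-07-01"), icd10_main="F200",
             care_type="full_time_psychiatric"),
        # P3: Z-coded stay only -> excluded
        dict(patient_id="P3", hospital_id="H1", admit_date=d("2012-06-01"),
             discharge_date=d("2012-07-01"), icd10_main="Z046",
             care_type="full_time_psychiatric"),
        # P4: eligible code at a military hospital -> excluded
        dict(patient_id="P4", hospital_id="HM", admit_date=d("2012-06-01"),
             discharge_date=d("2012-07-01"), icd10_main="F200",
             care_type="full_time_psychiatric"),
    ])
    return providers, patients, stays


def test_index_stay_selection_rules():
    providers, patients, stays = _mini_tables()
    cfg = ScenarioConfig(n_index_hospitals=2, n_patients_per_hospital=1)
    idx = select_index_stays(stays, patients, providers, cfg)
    assert list(idx["patient_id"]) == ["P1"]
    assert idx.iloc[0]["admit_date"] == pd.Timestamp("2012-03-01")
    assert idx.iloc[0]["diagnosis_group"] == "psychotic"


def test_selection_order_independent():
    providers, patients, stays = _mini_tables()
    cfg = ScenarioConfig(n_index_hospitals=2, n_patients_per_hospital=1)
    a = select_index_stays(stays, patients, providers, cfg)
    b = select_index_stays(stays.iloc[::-1].reset_index(drop=True),
                           patients, providers, cfg)
    pd.testing.assert_frame_equal(a, b)


def test_empty_stays_warns_not_raises():
    providers, patients, stays = _mini_tables()
    cfg = ScenarioConfig(n_index_hospitals=2, n_patients_per_hospital=1)
    out = select_index_stays(stays.iloc[:0], patients, providers, cfg)
    assert out.empty


@pytest.mark.parametrize("gap_days,expected", [
    (400, True), (730, True), (731, False), (1, True),
])
def test_precedence_window_boundaries(gap_days, expected):
    providers, patients, stays = _mini_tables()
    cfg = ScenarioConfig(n_index_hospitals=2, n_patients_per_hospital=1)
    idx = select_index_stays(stays, patients, providers, cfg)
    prior = pd.DataFrame([dict(
        patient_id="P1", hospital_id="H1",
        admit_date=idx.iloc[0]["admit_date"] - pd.Timedelta(days=gap_days),
        discharge_date=idx.iloc[0]["admit_date"]
        - pd.Timedelta(days=gap_days),
        icd10_main="F200", care_type="ambulatory_psychiatric")])
    cov = derive_covariates(idx, pd.concat([stays, prior]), patients)
    assert bool(cov.iloc[0]["precedence"]) is expected


def test_no_prior_history_means_no_precedence():
    providers, patients, stays = _mini_tables()
    cfg = ScenarioConfig(n_index_hospitals=2, n_patients_per_hospital=1)
    idx = select_index_stays(stays, patients, providers, cfg)
    cov = derive_covariates(idx, stays.iloc[1:2], patients)
    assert cov.iloc[0]["precedence"] == 0


def test_missing_birth_year_raises():
    providers, patients, stays = _mini_tables()
    patients.loc[0, "birth_year"] = np.nan
    cfg = ScenarioConfig(n_index_hospitals=2, n_patients_per_hospital=1)
    idx = select_index_stays(stays, patients.fillna({"birth_year": 1980}),
                             providers, cfg)
    with pytest.raises(ValueError, match="birth year"):
        derive_covariates(idx, stays, patients)


def test_full_retention_on_clean_bundle(small_config, small_bundle,
                                        small_cohort):
    n_expected = (small_config.n_index_hospitals
                  * small_config.n_patients_per_hospital)
    assert len(small_cohort) == n_expected
    assert small_cohort["patient_id"].is_unique
    assert small_cohort["age_at_index"].between(18, 65).all()


def test_precedence_flag_matches_generator(small_config, small_bundle,
                                           small_cohort):
    """Generated prior contacts are recovered by the covariate rule."""
    amb = set(small_bundle.stays.loc[
        small_bundle.stays["care_type"] == "ambulatory_psychiatric",
        "patient_id"])
    derived = set(small_cohort.loc[small_cohort["precedence"] == 1,
                                   "patient_id"])
    assert derived == amb
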