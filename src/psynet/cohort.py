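"""Study-cohort selection and patient-level covariates.

Selects adult patients (18-65 at admission) with a qualifying full-time
psychiatric index hospitalization in the index window at a sectorized
public or private non-profit, non-military, in-region hospital, and
derives their covariates: demographics, low-income coverage, somatic
long-term-illness flag, diagnosis group and precedence of the disorder
(any hospital psychiatric contact in the 730 days before admission).
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .synthdata import CARE_FULL_TIME, PSYCHIATRIC_CARE_TYPES

log = logging.getLogger(__name__)

DIAGNOSIS_GROUPS = ("psychotic", "bipolar_personality", "severe_depressive")

_CODE_RE = re.compile(r"^[A-Z][0-9]{2,3}$")
_SEVERE_DEPRESSIVE = {"F322", "F323", "F332", "F333"}

PRECEDENCE_WINDOW_DAYS = 730
ADULT_AGE = 18
MAX_AGE = 65


def classify_diagnosis(icd10: str):
    """Map an ICD-10 main-diagnosis code to a severe-disorder group.

    Codes are compared after uppercasing and dot removal: any ``F2``
    prefix counts as psychotic; ``F30*``, ``F31*`` and ``F603`` as
    bipolar/personality; the four-character severe-depression codes
    ``F322/F323/F332/F333`` as severe depressive.  Returns ``None`` for
    any other code.
    """
    if not isinstance(icd10, str) or not icd10:
        raise ValueError(f"malformed ICD-10 code: {icd10!r}")
    code = icd10.upper().replace(".", "")
    if not _CODE_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {icd10!r}")
    if code.startswith("F2"):
        return "psychotic"
    if code.startswith("F30") or code.startswith("F31") or code == "F603":
        return "bipolar_personality"
    if code in _SEVERE_DEPRESSIVE:
        return "severe_depressive"
    return None


def _classify_series(codes: pd.Series) -> pd.Series:
    return codes.map(classify_diagnosis)


def select_index_stays(stays: pd.DataFrame, patients: pd.DataFrame,
                       providers: pd.DataFrame, config) -> pd.DataFrame:
    """One index stay per retained patient (earliest eligible stay).

    Eligibility: full-time psychiatric care, admission year within the
    index window, inclusion diagnosis, hospital sectorized / public or
    non-profit / non-military / in-region, age at admission in
    [18, 65].  Returns a DataFrame with one row per patient:
    ``patient_id, index_hospital_id, admit_date, discharge_date,
    icd10_main, diagnosis_group``.
    """
    if stays.empty:
        log.warning("empty stay table: no index stays selected")
        return pd.DataFrame(columns=[
            "patient_id", "index_hospital_id", "admit_date",
            "discharge_date", "icd10_main", "diagnosis_group"])

    year0, year1 = config.index_years
    hosp = providers.set_index("provider_id")
    eligible_hosp = set(hosp.index[
        (hosp["provider_type"] == "hospital")
        & (hosp["sectorized"] == 1) & (hosp["military"] == 0)
        & (hosp["private"] == 0) & (hosp["in_region"] == 1)])

    s = stays.loc[stays["care_type"] == CARE_FULL_TIME].copy()
    s = s[s["hospital_id"].isin(eligible_hosp)]
    s = s[s["admit_date"].dt.year.between(year0, year1)]
    s["diagnosis_group"] = _classify_series(s["icd10_main"])
    s = s.dropna(subset=["diagnosis_group"])

    birth = patients.set_index("patient_id")["birth_year"]
    s["age_at_index"] = s["admit_date"].dt.year - s["patient_id"].map(birth)
    s = s[s["age_at_index"].between(ADULT_AGE, MAX_AGE)]

    s = s.sort_values(["patient_id", "admit_date", "hospital_id"],
                      kind="stable")
    s = s.drop_duplicates("patient_id", keep="first")
    out = s.rename(columns={"hospital_id": "index_hospital_id"})[
        ["patient_id", "index_hospital_id", "admit_date", "discharge_date",
         "icd10_main", "diagnosis_group"]]
    return out.reset_index(drop=True)


def derive_covariates(index_stays: pd.DataFrame, stays: pd.DataFrame,
                      patients: pd.DataFrame) -> pd.DataFrame:
    """Patient covariates at the index admission.

    ``precedence`` is true iff any hospital psychiatric stay overlaps the
    730 days strictly before the index admission (admission date within
    [index - 730 d, index)).  Other flags come from the patient table;
    age is computed at the admission date.
    """
    pat = patients.set_index("patient_id")
    missing = index_stays.loc[~index_stays["patient_id"].isin(pat.index),
                              "patient_id"]
    if len(missing):
        raise ValueError(
            f"patients absent from patient table: {sorted(missing)[:5]}")
    if pat["birth_year"].reindex(index_stays["patient_id"]).isna().any():
        bad = pat.index[pat["birth_year"].isna()]
        raise ValueError(f"missing birth year for patients: {list(bad)[:5]}")

    cov = index_stays[["patient_id", "index_hospital_id", "admit_date",
                       "discharge_date", "diagnosis_group"]].copy()
    cov["age_at_index"] = (cov["admit_date"].dt.year
                           - cov["patient_id"].map(pat["birth_year"]))
    cov["sex"] = cov["patient_id"].map(pat["sex"])
    cov["low_income"] = cov["patient_id"].map(pat["low_income"]).astype(int)
    cov["somatic_ltd"] = cov["patient_id"].map(pat["somatic_ltd"]).astype(int)

    psy = stays.loc[stays["care_type"].isin(PSYCHIATRIC_CARE_TYPES),
                    ["patient_id", "admit_date"]].rename(
        columns={"admit_date": "prior_admit"})
    m = cov[["patient_id", "admit_date"]].merge(psy, on="patient_id",
                                                how="left")
    delta = (m["admit_date"] - m["prior_admit"]).dt.days
    m["prec"] = (delta >= 1) & (delta <= PRECEDENCE_WINDOW_DAYS)
    prec = m.groupby("patient_id")["prec"].any()
    cov["precedence"] = cov["patient_id"].map(prec).fillna(False).astype(int)
    return cov.reset_index(drop=True)


def build_cohort(bundle, config) -> pd.DataFrame:
    """Index stays + covariates, one row per retained patient."""
    idx = select_index_stays(bundle.stays, bundle.patients, bundle.providers,
                             config)
    if idx.empty:
        return idx
    return derive_covariates(idx, bundle.stays, bundle.patients)
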