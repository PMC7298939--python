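"""Utilization-based quality-of-care indicators.

Four binary indicators measured on the schizophrenia-spectrum
(psychotic) subcohort, each a pure function of events inside a window
anchored at the index discharge:

1. readmission — any full-time psychiatric admission within 15 days;
2. hospital-community transition — a contact with the patient's
   designated referring physician within 60 days;
3. somatic prevention — all three recommended prevention procedures
   within 730 days;
4. medication continuity — at least nine antipsychotic deliveries
   within 365 days.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthdata import CARE_FULL_TIME, PREVENTION_TAGS
from .typology import v_test

log = logging.getLogger(__name__)

INDICATORS = ("readmit_15d", "referring_contact_2m",
              "prevention_3proc_2y", "antipsychotic_9plus_12m")

READMIT_DAYS = 15
REFERRING_DAYS = 60
PREVENTION_DAYS = 730
DELIVERY_DAYS = 365
DELIVERIES_REQUIRED = 9


def _window_mask(event_dates, discharge, lo, hi):
    d = (event_dates - discharge).dt.days
    return (d >= lo) & (d <= hi)


def indicator_readmission(index_stay, stays: pd.DataFrame) -> bool:
    """Any full-time psychiatric admission in (discharge, discharge+15 d]."""
    s = stays[(stays["patient_id"] == index_stay["patient_id"])
              & (stays["care_type"] == CARE_FULL_TIME)]
    d = (s["admit_date"] - index_stay["discharge_date"]).dt.days
    return bool(((d >= 1) & (d <= READMIT_DAYS)).any())


def indicator_referring_physician(index_stay, contacts: pd.DataFrame,
                                  referring_map: dict) -> bool:
    """Contact with the designated referring physician within 60 days;
    false when no physician is designated."""
    doc = referring_map.get(index_stay["patient_id"])
    if doc is None or (isinstance(doc, float) and np.isnan(doc)) or doc == "":
        return False
    c = contacts[(contacts["patient_id"] == index_stay["patient_id"])
                 & (contacts["provider_id"] == doc)]
    d = (c["date"] - index_stay["discharge_date"]).dt.days
    return bool(((d >= 0) & (d <= REFERRING_DAYS)).any())


def indicator_prevention(index_stay, procedures: pd.DataFrame) -> bool:
    """All three distinct prevention procedures within 730 days."""
    p = procedures[procedures["patient_id"] == index_stay["patient_id"]]
    unknown = ~p["procedure_tag"].isin(PREVENTION_TAGS)
    if unknown.any():
        log.info("patient %s: %d events with unknown procedure tags ignored",
                 index_stay["patient_id"], int(unknown.sum()))
        p = p[~unknown]
    d = (p["date"] - index_stay["discharge_date"]).dt.days
    tags = set(p.loc[(d >= 0) & (d <= PREVENTION_DAYS), "procedure_tag"])
    return len(tags) >= len(PREVENTION_TAGS)


def indicator_antipsychotic(index_stay, deliveries: pd.DataFrame) -> bool:
    """At least nine antipsychotic deliveries within 365 days; multiple
    same-day deliveries count separately."""
    dd = deliveries[(deliveries["patient_id"] == index_stay["patient_id"])
                    & (deliveries["drug_class"] == "antipsychotic")]
    d = (dd["date"] - index_stay["discharge_date"]).dt.days
    return int(((d >= 0) & (d <= DELIVERY_DAYS)).sum()) >= DELIVERIES_REQUIRED


def compute_quality_rows(cohort: pd.DataFrame, bundle) -> pd.DataFrame:
    """Vectorized per-patient indicator table for the psychotic subcohort."""
    sub = cohort[cohort["diagnosis_group"] == "psychotic"]
    out = sub[["patient_id", "index_hospital_id", "discharge_date"]].copy()
    out = out.rename(columns={"index_hospital_id": "network_id"})
    anchor = out[["patient_id", "discharge_date"]]

    # 1. readmission
    s = bundle.stays[bundle.stays["care_type"] == CARE_FULL_TIME]
    s = s.merge(anchor, on="patient_id", suffixes=("", "_anchor"))
    d = (s["admit_date"] - s["discharge_date_anchor"]).dt.days
    hit = s.loc[(d >= 1) & (d <= READMIT_DAYS), "patient_id"].unique()
    out["readmit_15d"] = out["patient_id"].isin(hit).astype(int)

    # 2. referring physician
    ref = bundle.patients.set_index("patient_id")["referring_physician_id"]
    c = bundle.contacts.merge(anchor, on="patient_id")
    c = c[c["provider_id"] == c["patient_id"].map(ref)]
    d = (c["date"] - c["discharge_date"]).dt.days
    hit = c.loc[(d >= 0) & (d <= REFERRING_DAYS), "patient_id"].unique()
    out["referring_contact_2m"] = out["patient_id"].isin(hit).astype(int)

    # 3. prevention procedures
    p = bundle.procedures[bundle.procedures["procedure_tag"]
                          .isin(PREVENTION_TAGS)]
    p = p.merge(anchor, on="patient_id")
    d = (p["date"] - p["discharge_date"]).dt.days
    p = p[(d >= 0) & (d <= PREVENTION_DAYS)]
    n_tags = p.groupby("patient_id")["procedure_tag"].nunique()
    hit = n_tags[n_tags >= len(PREVENTION_TAGS)].index
    out["prevention_3proc_2y"] = out["patient_id"].isin(hit).astype(int)

    # 4. antipsychotic deliveries
    dd = bundle.deliveries[bundle.deliveries["drug_class"] == "antipsychotic"]
    dd = dd.merge(anchor, on="patient_id")
    d = (dd["date"] - dd["discharge_date"]).dt.days
    dd = dd[(d >= 0) & (d <= DELIVERY_DAYS)]
    n_del = dd.groupby("patient_id").size()
    hit = n_del[n_del >= DELIVERIES_REQUIRED].index
    out["antipsychotic_9plus_12m"] = out["patient_id"].isin(hit).astype(int)

    return out.drop(columns="discharge_date").reset_index(drop=True)


def aggregate_quality(quality_rows: pd.DataFrame,
                      labels: pd.Series | None = None,
                      alpha: float = 0.05) -> dict:
    """Per-network percentages and per-cluster mean (SD) with v-tests.

    ``labels`` maps network_id to cluster; when omitted only the
    network-level table is returned.
    """
    per_network = (quality_rows.groupby("network_id")[list(INDICATORS)]
                   .mean() * 100.0).reset_index()
    result = {"per_network": per_network}
    if labels is None:
        return result
    from scipy import stats as _st
    zcrit = _st.norm.ppf(1 - alpha / 2)
    lab = per_network["network_id"].map(labels)
    rows = []
    for c in sorted(labels.unique()):
        mask = (lab == c).to_numpy()
        for ind in INDICATORS:
            vals = per_network[ind].to_numpy(float)
            if not mask.any():
                rows.append(dict(cluster=int(c), indicator=ind,
                                 mean=float("nan"), sd=float("nan"),
                                 v_statistic=float("nan"),
                                 significant=False))
                continue
            v = v_test(vals, mask) if mask.sum() > 1 else float("nan")
            rows.append(dict(
                cluster=int(c), indicator=ind,
                mean=float(vals[mask].mean()),
                sd=float(vals[mask].std(ddof=1)) if mask.sum() > 1
                else float("nan"),
                v_statistic=v,
                significant=bool(abs(v) >= zcrit) if np.isfinite(v)
                else False))
    result["per_cluster"] = pd.DataFrame(rows)
    return result
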