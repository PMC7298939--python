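import numpy as np
import pandas as pd
import pytest

from psynet.quality import (aggregate_quality, indicator_antipsychotic,
                            indicator_prevention,
                            indicator_readmission,
                            indicator_referring_physician)

D = pd.Timestamp
DISCHARGE = D("2012-06-01")
INDEX = pd.Series(dict(patient_id="P1", discharge_date=DISCHARGE))


def _stays(days):
    if not days:
        return pd.DataFrame(columns=["patient_id", "hospital_id",
                                     "admit_date", "discharge_date",
                                     "icd10_main", "care_type"]).astype(
            {"admit_date": "datetime64[ns]"})
    return pd.DataFrame([dict(patient_id="P1", hospital_id="H9",
                              admit_date=DISCHARGE + pd.Timedelta(days=d),
                              discharge_date=DISCHARGE
                              + pd.Timedelta(days=d + 5),
                              icd10_main="F200",
                              care_type="full_time_psychiatric")
                         for d in days])


@pytest.mark.parametrize("days,expected", [
    ([14], True), ([15], True), ([16], False), ([1], True),
    ([], False), ([16, 200], False), ([15, 400], True),
])
def test_readmission_window(days, expected):
    assert indicator_readmission(INDEX, _stays(days)) is expected


def _contacts(entries):
    if not entries:
        return pd.DataFrame(columns=["patient_id", "provider_id",
                                     "date"]).astype({"date":
                                                      "datetime64[ns]"})
    return pd.DataFrame([dict(patient_id="P1", provider_id=p,
                              date=DISCHARGE + pd.Timedelta(days=d))
                         for p, d in entries])


@pytest.mark.parametrize("entries,designated,expected", [
    ([("G1", 59)], "G1", True),
    ([("G1", 60)], "G1", True),
    ([("G1", 61)], "G1", False),
    ([("G2", 10)], "G1", False),   # wrong physician
    ([("G1", 10)], None, False),   # no designation on file
    ([], "G1", False),
])
def test_referring_physician_window(entries, designated, expected):
    ref = {"P1": designated} if designated else {}
    assert indicator_referring_physician(INDEX, _contacts(entries),
                                         ref) is expected


def _procs(entries):
    if not entries:
        return pd.DataFrame(columns=["patient_id", "procedure_tag",
                                     "date"]).astype({"date":
                                                      "datetime64[ns]"})
    return pd.DataFrame([dict(patient_id="P1", procedure_tag=t,
                              date=DISCHARGE + pd.Timedelta(days=d))
                         for t, d in entries])


@pytest.mark.parametrize("entries,expected", [
    ([("P1", 100), ("P2", 400), ("P3", 700)], True),
    ([("P1", 100), ("P2", 400), ("P3", 730)], True),
    ([("P1", 100), ("P2", 400), ("P3", 731)], False),
    ([("P1", 100), ("P1", 400), ("P2", 500)], False),  # distinctness
    ([("P1", 100), ("P2", 400), ("BAD", 500)], False),  # unknown tag ignored
    ([], False),
])
def test_prevention_window_and_distinctness(entries, expected):
    assert indicator_prevention(INDEX, _procs(entries)) is expected


def _deliv(days):
    if not days:
        return pd.DataFrame(columns=["patient_id", "drug_class",
                                     "date"]).astype({"date":
                                                      "datetime64[ns]"})
    return pd.DataFrame([dict(patient_id="P1", drug_class="antipsychotic",
                              date=DISCHARGE + pd.Timedelta(days=d))
                         for d in days])


@pytest.mark.parametrize("days,expected", [
    (list(range(10, 100, 10)), True),          # 9 deliveries
    (list(range(10, 90, 10)), False),          # 8 deliveries
    (list(range(10, 80, 10)) + [370, 380], False),  # 2 beyond day 365
    ([20] * 9, True),                          # same-day count separately
    ([], False),
])
def test_antipsychotic_delivery_count(days, expected):
    assert indicator_antipsychotic(INDEX, _deliv(days)) is expected


def test_indicators_translation_invariant():
    """Shifting every event and the discharge by the same offset leaves
    all four indicators unchanged."""
    for offset in (0, 37, 365):
        shifted = pd.Series(dict(
            patient_id="P1",
            discharge_date=DISCHARGE + pd.Timedelta(days=offset)))
        stays = _stays([15])
        stays["admit_date"] += pd.Timedelta(days=offset)
        stays["discharge_date"] += pd.Timedelta(days=offset)
        assert indicator_readmission(shifted, stays) is True
        deliv = _deliv(list(range(10, 100, 10)))
        deliv["date"] += pd.Timedelta(days=offset)
        assert indicator_antipsychotic(shifted, deliv) is True


def test_quality_rows_restricted_to_psychotic(small_config, small_bundle,
                                              small_cohort):
    from psynet.quality import compute_quality_rows
    rows = compute_quality_rows(small_cohort, small_bundle)
    psychotic = set(small_cohort.loc[
        small_cohort["diagnosis_group"] == "psychotic", "patient_id"])
    assert set(rows["patient_id"]) == psychotic
    for ind in ["readmit_15d", "referring_contact_2m",
                "prevention_3proc_2y", "antipsychotic_9plus_12m"]:
        assert rows[ind].isin([0, 1]).all()


def test_vectorized_rows_match_scalar_indicators(small_config, small_bundle,
                                                 small_cohort):
    """The table-level computation agrees with the per-patient functions."""
    from psynet.quality import compute_quality_rows
    rows = compute_quality_rows(small_cohort, small_bundle).set_index(
        "patient_id")
    ref = small_bundle.patients.set_index("patient_id")[
        "referring_physician_id"].to_dict()
    sub = small_cohort[small_cohort["diagnosis_group"] == "psychotic"]
    for _, stay in sub.sample(12, random_state=0).iterrows():
        pid = stay["patient_id"]
        assert bool(rows.loc[pid, "readmit_15d"]) == indicator_readmission(
            stay, small_bundle.stays)
        assert bool(rows.loc[pid, "referring_contact_2m"]) == \
            indicator_referring_physician(stay, small_bundle.contacts, ref)
        assert bool(rows.loc[pid, "prevention_3proc_2y"]) == \
            indicator_prevention(stay, small_bundle.procedures)
        assert bool(rows.loc[pid, "antipsychotic_9plus_12m"]) == \
            indicator_antipsychotic(stay, small_bundle.deliveries)


def test_aggregate_quality_arithmetic():
    rows = pd.DataFrame(dict(
        patient_id=[f"P{i}" for i in range(10)],
        network_id=["N1"] * 5 + ["N2"] * 5,
        readmit_15d=[1, 1, 0, 0, 0] + [1, 1, 1, 0, 0],
        referring_contact_2m=[1] * 5 + [1] * 5,
        prevention_3proc_2y=[0] * 5 + [0] * 5,
        antipsychotic_9plus_12m=[1, 0, 1, 0, 1] + [0, 1, 0, 1, 0],
    ))
    labels = pd.Series({"N1": 0, "N2": 0})
    agg = aggregate_quality(rows, labels)
    per_net = agg["per_network"].set_index("network_id")
    assert per_net.loc["N1", "readmit_15d"] == pytest.approx(40.0)
    assert per_net.loc["N2", "readmit_15d"] == pytest.approx(60.0)
    cl = agg["per_cluster"].set_index("indicator")
    assert cl.loc["readmit_15d", "mean"] == pytest.approx(50.0)
    assert cl.loc["readmit_15d", "sd"] == pytest.approx(
        np.std([40.0, 60.0], ddof=1))
    # cluster mean equals overall mean -> v = 0 (single cluster)
    assert cl.loc["referring_contact_2m", "mean"] == pytest.approx(100.0)
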