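import numpy as np
import pandas as pd
import pytest

from psynet import ScenarioConfig
from psynet.netbuild import (build_network, compute_thresholds,
                             count_shared_patients, index_links,
                             zero_thresholds)
from .conftest import brute_force_pair_weights


def _micro_state():
    """Two cohort patients of hospital H1, hand-checkable contacts."""
    providers = pd.DataFrame([
        dict(provider_id=p, provider_type=t, in_region=r, zone="Z0",
             is_index=int(p == "H1"), sectorized=int(p == "H1"), military=0,
             private=0, specialized=0, beds=np.nan, catchment_pop=np.nan,
             area_typology="")
        for p, t, r in [("H1", "hospital", 1), ("G1", "gp", 1),
                        ("S1", "psychiatrist", 1), ("N1", "nurse", 1),
                        ("X1", "gp", 0)]])
    d = pd.Timestamp
    cohort = pd.DataFrame([
        dict(patient_id="P1", index_hospital_id="H1",
             admit_date=d("2012-01-01"), discharge_date=d("2012-02-01")),
        dict(patient_id="P2", index_hospital_id="H1",
             admit_date=d("2012-01-01"), discharge_date=d("2012-02-01")),
    ])
    base = d("2012-02-01")
    contacts = pd.DataFrame([
        # P1 sees GP twice (one distinct patient), psychiatrist, nurse
        dict(patient_id="P1", provider_id="G1", date=base + pd.Timedelta(days=30)),
        dict(patient_id="P1", provider_id="G1", date=base + pd.Timedelta(days=200)),
        dict(patient_id="P1", provider_id="S1", date=base + pd.Timedelta(days=10)),
        dict(patient_id="P1", provider_id="N1", date=base + pd.Timedelta(days=12)),
        # P2: psychiatrist + nurse; GP contact outside the window
        dict(patient_id="P2", provider_id="S1", date=base + pd.Timedelta(days=50)),
        dict(patient_id="P2", provider_id="N1", date=base + pd.Timedelta(days=51)),
        dict(patient_id="P2", provider_id="G1", date=base + pd.Timedelta(days=366)),
        # out-of-region provider: never counted
        dict(patient_id="P2", provider_id="X1", date=base + pd.Timedelta(days=5)),
    ])
    stays = pd.DataFrame(columns=["patient_id", "hospital_id", "admit_date",
                                  "discharge_date", "icd10_main",
                                  "care_type"])
    cfg = ScenarioConfig(n_index_hospitals=1, n_patients_per_hospital=2)
    return providers, cohort, contacts, stays, cfg


def test_distinct_patients_not_visits():
    providers, cohort, contacts, stays, cfg = _micro_state()
    pc = count_shared_patients(cohort, contacts, stays, providers, cfg)
    w = pc.set_index(["provider_a", "provider_b"])["weight"]
    assert w[("H1", "G1")] == 1          # two visits, one patient
    assert w[("H1", "S1")] == 2
    assert w[("H1", "N1")] == 2
    assert ("H1", "X1") not in w.index   # out of region
    # secondary pair (S1,N1) shared by both patients
    assert w[("N1", "S1")] == 2
    # G1 pairs only through P1
    assert w[("G1", "S1")] == 1


def test_day_366_contact_outside_window():
    providers, cohort, contacts, stays, cfg = _micro_state()
    pc = count_shared_patients(cohort, contacts, stays, providers, cfg)
    w = pc.set_index(["provider_a", "provider_b"])["weight"]
    assert w[("H1", "G1")] == 1          # P2's day-366 GP visit ignored


def test_quartile_rule_hand_checked():
    """Counts [1,2,2,3,4,6,8,20]: Q3 = 6.5 by linear interpolation, and
    strict inequality retains exactly {8, 20}."""
    counts = [1, 2, 2, 3, 4, 6, 8, 20]
    q3 = np.percentile(counts, 75)
    assert q3 == pytest.approx(6.5)
    assert [c for c in counts if c > q3] == [8, 20]


def test_compute_thresholds_per_type(small_config, small_bundle,
                                     small_cohort):
    pc = count_shared_patients(small_cohort, small_bundle.contacts,
                               small_bundle.stays, small_bundle.providers,
                               small_config)
    thr = compute_thresholds(pc, small_bundle.providers, small_config)
    il = index_links(pc)
    ptypes = small_bundle.providers.set_index("provider_id")["provider_type"]
    for t, q in thr.items():
        counts = il.loc[il["provider_b"].map(ptypes) == t,
                        "weight"].to_numpy(float)
        assert q == pytest.approx(np.percentile(counts, 75))


def test_degenerate_distribution_retains_nothing():
    providers = pd.DataFrame([
        dict(provider_id=p, provider_type=t, in_region=1, zone="Z0",
             is_index=int(t == "hospital"), sectorized=0, military=0,
             private=0, specialized=0, beds=np.nan, catchment_pop=np.nan,
             area_typology="")
        for p, t in [("H1", "hospital"), ("G1", "gp"), ("G2", "gp")]])
    pc = pd.DataFrame([
        dict(network_id="H1", provider_a="H1", provider_b="G1", weight=2),
        dict(network_id="H1", provider_a="H1", provider_b="G2", weight=2),
    ])
    thr = compute_thresholds(pc, providers)
    assert thr["gp"] == 2.0
    g = build_network("H1", pc, thr, providers)
    assert set(g.nodes) == {"H1"}        # strict inequality drops all


def test_projection_matches_brute_force(small_config, small_bundle,
                                        small_cohort):
    pc = count_shared_patients(small_cohort, small_bundle.contacts,
                               small_bundle.stays, small_bundle.providers,
                               small_config)
    oracle = brute_force_pair_weights(
        small_cohort.sample(frac=1, random_state=0),  # order-independence
        small_bundle.contacts, small_bundle.stays, small_bundle.providers,
        small_config)
    got = {}
    for _, r in pc.iterrows():
        a, b = sorted([r["provider_a"], r["provider_b"]])
        if r["provider_a"] == r["network_id"]:
            got[(r["network_id"], r["network_id"], r["provider_b"])] = \
                r["weight"]
        else:
            got[(r["network_id"], a, b)] = r["weight"]
    assert got == oracle


def test_secondary_links_not_thresholded():
    providers = pd.DataFrame([
        dict(provider_id=p, provider_type=t, in_region=1, zone="Z0",
             is_index=int(p == "H1"), sectorized=0, military=0, private=0,
             specialized=0, beds=np.nan, catchment_pop=np.nan,
             area_typology="")
        for p, t in [("H1", "hospital"), ("N1", "nurse"), ("N2", "nurse"),
                     ("N3", "nurse")]])
    pc = pd.DataFrame([
        dict(network_id="H1", provider_a="H1", provider_b="N1", weight=5),
        dict(network_id="H1", provider_a="H1", provider_b="N2", weight=5),
        dict(network_id="H1", provider_a="H1", provider_b="N3", weight=1),
        dict(network_id="H1", provider_a="N1", provider_b="N2", weight=1),
        dict(network_id="H1", provider_a="N1", provider_b="N3", weight=4),
    ])
    thr = {"nurse": 2.0}
    g = build_network("H1", pc, thr, providers)
    assert set(g.nodes) == {"H1", "N1", "N2"}
    assert g.edges["N1", "N2"]["weight"] == 1   # weight-1 secondary kept
    assert ("N1", "N3") not in g.edges          # dropped endpoint


def test_zero_thresholds_full_graph(small_config, small_bundle,
                                    small_cohort):
    pc = count_shared_patients(small_cohort, small_bundle.contacts,
                               small_bundle.stays, small_bundle.providers,
                               small_config)
    h = small_cohort["index_hospital_id"].iloc[0]
    g = build_network(h, pc, zero_thresholds(), small_bundle.providers)
    il = index_links(pc)
    expected_nodes = set(il.loc[il["network_id"] == h, "provider_b"]) | {h}
    assert set(g.nodes) == expected_nodes


def test_threshold_monotonicity(small_config, small_bundle, small_cohort):
    """Raising any threshold never adds a node or link."""
    pc = count_shared_patients(small_cohort, small_bundle.contacts,
                               small_bundle.stays, small_bundle.providers,
                               small_config)
    thr = compute_thresholds(pc, small_bundle.providers, small_config)
    h = small_cohort["index_hospital_id"].iloc[0]
    g_base = build_network(h, pc, thr, small_bundle.providers)
    g_zero = build_network(h, pc, zero_thresholds(), small_bundle.providers)
    assert set(g_base.nodes) <= set(g_zero.nodes)
    assert set(g_base.edges) <= set(g_zero.edges)
    higher = {t: q + 1 for t, q in thr.items()}
    g_high = build_network(h, pc, higher, small_bundle.providers)
    assert set(g_high.nodes) <= set(g_base.nodes)
    assert set(g_high.edges) <= set(g_base.edges)


def test_export_formats(tmp_path, small_config, small_bundle, small_cohort):
    import networkx as nx
    from psynet.netbuild import build_all_networks, export_network
    nets, _, _ = build_all_networks(small_cohort, small_bundle.contacts,
                                    small_bundle.stays,
                                    small_bundle.providers, small_config)
    h, g = next(iter(nets.items()))
    export_network(g, tmp_path, h)
    g2 = nx.read_graphml(tmp_path / f"{h}.graphml")
    assert set(g2.nodes) == set(g.nodes)
    edges = pd.read_csv(tmp_path / f"{h}.edgelist.tsv", sep="\t")
    assert len(edges) == g.number_of_edges()
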