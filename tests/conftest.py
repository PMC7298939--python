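import numpy as np
import pandas as pd
import pytest

from psynet import ScenarioConfig, generate_bundle
from psynet.cohort import build_cohort


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(n_index_hospitals=6, n_patients_per_hospital=40,
                          seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_bundle):
    return build_cohort(small_bundle, small_config)


@pytest.fixture(scope="session")
def default_run():
    """One full default-scale pipeline state, shared across tests."""
    from psynet.netbuild import build_all_networks
    from psynet.netmetrics import build_profiles
    cfg = ScenarioConfig(seed=11)
    bundle = generate_bundle(cfg)
    cohort = build_cohort(bundle, cfg)
    networks, pair_counts, thresholds = build_all_networks(
        cohort, bundle.contacts, bundle.stays, bundle.providers, cfg)
    profiles = build_profiles(networks, cohort, bundle, cfg)
    return dict(config=cfg, bundle=bundle, cohort=cohort, networks=networks,
                pair_counts=pair_counts, thresholds=thresholds,
                profiles=profiles)


def brute_force_pair_weights(cohort, contacts, stays, providers, config):
    """Set-intersection oracle for patient-sharing link weights."""
    from psynet.synthdata import PSYCHIATRIC_CARE_TYPES
    prov = providers.set_index("provider_id")
    window = config.follow_up_days
    result = {}
    for _, row in cohort.iterrows():
        pid, h, disch = (row["patient_id"], row["index_hospital_id"],
                         row["discharge_date"])
        seen = set()
        for _, c in contacts[contacts["patient_id"] == pid].iterrows():
            d = (c["date"] - disch).days
            p = c["provider_id"]
            if (0 <= d <= window
                    and prov.loc[p, "provider_type"] in
                    ("gp", "psychiatrist", "nurse")
                    and prov.loc[p, "in_region"] == 1 and p != h):
                seen.add(p)
        for _, s in stays[stays["patient_id"] == pid].iterrows():
            d = (s["admit_date"] - disch).days
            p = s["hospital_id"]
            if (0 <= d <= window and s["care_type"] in PSYCHIATRIC_CARE_TYPES
                    and prov.loc[p, "in_region"] == 1 and p != h):
                seen.add(p)
        result.setdefault(h, {})
        for p in seen:
            result[h].setdefault(p, set()).add(pid)
    weights = {}
    for h, by_prov in result.items():
        provs = sorted(by_prov)
        for p in provs:
            weights[(h, h, p)] = len(by_prov[p])
        for i, a in enumerate(provs):
            for b in provs[i + 1:]:
                w = len(by_prov[a] & by_prov[b])
                if w:
                    weights[(h, a, b)] = w
    return weights
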