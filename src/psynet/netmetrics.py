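"""Structural, compositional and contextual network characteristics.

Produces one :data:`NetworkProfile` row per patient-sharing network —
the input matrix of the typology.  Density and transitivity are
computed on the unweighted skeleton and expressed on a 0-100 scale;
link weights enter only through the weighted degree (strength).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .synthdata import CARE_AMBULATORY, PSYCHIATRIC_CARE_TYPES

log = logging.getLogger(__name__)

LOYALTY_BANDS = (">80%", "[60-80%]", "<60%")


def density(g: nx.Graph) -> float:
    """Percent of possible undirected links present (no self-loops)."""
    n = g.number_of_nodes()
    if n < 2:
        return float("nan")
    return 100.0 * g.number_of_edges() / (n * (n - 1) / 2)


def transitivity(g: nx.Graph) -> float:
    """Global clustering coefficient on a 0-100 scale.

    100 * 3*(triangles) / (connected triples); undefined (NaN) when the
    network has no connected triple.
    """
    if sum(1 for _, d in g.degree() if d >= 2) == 0:
        return float("nan")
    return 100.0 * nx.transitivity(g)


def median_weighted_degree(g: nx.Graph) -> float:
    """Median over all nodes (index hospital included) of the sum of
    incident link weights."""
    if g.number_of_nodes() == 0:
        return float("nan")
    strengths = [s for _, s in g.degree(weight="weight")]
    return float(np.median(strengths))


def composition(g: nx.Graph, catchment_population: float) -> dict:
    """Compositional fields of one network.

    Per-type counts and percentages are over the providers of the
    network excluding the index hospital; per-100k rates divide the
    community-professional counts by the adult catchment population;
    the private-hospital share uses all hospital nodes including the
    index hospital in its denominator.
    """
    if not catchment_population or catchment_population <= 0:
        raise ValueError("catchment_population must be positive")
    index_h = g.graph["index_hospital"]
    nodes = [(n, d) for n, d in g.nodes(data=True) if n != index_h]
    counts = {"gp": 0, "psychiatrist": 0, "nurse": 0, "hospital": 0}
    n_private_hosp = 0
    for _, d in nodes:
        counts[d["provider_type"]] += 1
        if d["provider_type"] == "hospital" and d.get("private"):
            n_private_hosp += 1
    total = sum(counts.values())
    out = {f"n_{t}s": c for t, c in counts.items()}
    for t, c in counts.items():
        out[f"pct_{t}s"] = 100.0 * c / total if total else float("nan")
    for t in ("gp", "psychiatrist", "nurse"):
        out[f"{t}s_per_100k"] = 1e5 * counts[t] / catchment_population
    community = counts["gp"] + counts["psychiatrist"] + counts["nurse"]
    if community:
        out["pct_specialists_among_community"] = (
            100.0 * counts["psychiatrist"] / community)
        out["pct_physicians_among_community"] = (
            100.0 * (counts["gp"] + counts["psychiatrist"]) / community)
    else:
        out["pct_specialists_among_community"] = float("nan")
        out["pct_physicians_among_community"] = float("nan")
    n_hosp_incl_index = counts["hospital"] + 1
    out["pct_private_among_hospitals"] = 100.0 * n_private_hosp / \
        n_hosp_incl_index
    out["n_providers_excl_index"] = total
    out["n_links"] = g.number_of_edges()
    return out


def loyalty_band(pct: float) -> str:
    """Band a loyalty percentage: >80%, [60-80%] (closed), <60%."""
    if pct > 80.0:
        return ">80%"
    if pct >= 60.0:
        return "[60-80%]"
    return "<60%"


def loyalty_index(index_stays: pd.DataFrame, patients: pd.DataFrame,
                  catchment_map: dict) -> pd.DataFrame:
    """Share of each hospital's index patients residing in its catchment.

    ``catchment_map`` maps hospital id to a set of residence zones.
    Returns one row per hospital: percentage and band.
    """
    res = patients.set_index("patient_id")["residence_zone"]
    rows = []
    for h, grp in index_stays.groupby("index_hospital_id"):
        if h not in catchment_map:
            raise KeyError(f"hospital {h!r} absent from catchment map")
        zones = catchment_map[h]
        in_catch = grp["patient_id"].map(res).isin(zones)
        pct = 100.0 * in_catch.mean()
        rows.append(dict(network_id=h, loyalty_index=pct,
                         loyalty_band=loyalty_band(pct)))
    return pd.DataFrame(rows)


def context_metrics(network_id: str, cohort: pd.DataFrame,
                    contacts: pd.DataFrame, stays: pd.DataFrame,
                    providers: pd.DataFrame, config) -> dict:
    """Ambulatory-in-index share and average contacts per patient.

    The specialized-ambulatory denominator is index-hospital ambulatory
    psychiatric contacts plus community psychiatrist visit events.
    ``avg_contacts`` counts every contact event in the follow-up window
    (community visits of any type, index-hospital ambulatory contacts,
    hospital admissions) averaged over all cohort patients of the
    network, including those with no contact at all.
    """
    window = config.follow_up_days
    coh = cohort[cohort["index_hospital_id"] == network_id]
    n_pat = len(coh)
    if n_pat == 0:
        return dict(pct_ambulatory_in_index=float("nan"),
                    avg_contacts_per_patient=float("nan"))
    anchor = coh[["patient_id", "discharge_date"]]
    c = contacts.merge(anchor, on="patient_id")
    if len(c):
        offs = (c["date"] - c["discharge_date"]).dt.days
        c = c[(offs >= 0) & (offs <= window)]
    ptypes = providers.set_index("provider_id")["provider_type"]

    in_index_amb = int((c["provider_id"] == network_id).sum())
    psy_visits = int((c["provider_id"].map(ptypes) == "psychiatrist").sum())
    denom = in_index_amb + psy_visits
    pct_amb = 100.0 * in_index_amb / denom if denom else float("nan")
    if denom == 0:
        log.warning("network %s: no specialized ambulatory contact",
                    network_id)

    s = stays.merge(anchor.rename(columns={"discharge_date": "anchor"}),
                    on="patient_id")
    if len(s):
        soffs = (s["admit_date"] - s["anchor"]).dt.days
        n_adm = int(((soffs >= 0) & (soffs <= window)).sum())
    else:
        n_adm = 0
    avg = (len(c) + n_adm) / n_pat
    return dict(pct_ambulatory_in_index=pct_amb,
                avg_contacts_per_patient=avg)


def build_profiles(networks: dict, cohort: pd.DataFrame, bundle,
                   config) -> pd.DataFrame:
    """One NetworkProfile row per network."""
    prov = bundle.providers.set_index("provider_id")
    catchment_map = {h: {prov.loc[h, "zone"]} for h in networks}
    loyal = loyalty_index(cohort, bundle.patients, catchment_map) \
        .set_index("network_id")
    rows = []
    for h in sorted(networks):
        g = networks[h]
        row = dict(network_id=h,
                   density=density(g),
                   transitivity=transitivity(g),
                   median_weighted_degree=median_weighted_degree(g),
                   index_specialized=int(prov.loc[h, "specialized"]),
                   index_beds=float(prov.loc[h, "beds"]),
                   area_typology=str(prov.loc[h, "area_typology"]))
        row.update(composition(g, float(prov.loc[h, "catchment_pop"])))
        row["loyalty_index"] = float(loyal.loc[h, "loyalty_index"])
        row["loyalty_band"] = str(loyal.loc[h, "loyalty_band"])
        row.update(context_metrics(h, cohort, bundle.contacts, bundle.stays,
                                   bundle.providers, config))
        rows.append(row)
    return pd.DataFrame(rows)
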