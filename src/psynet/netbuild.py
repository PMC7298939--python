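"""Patient-sharing network construction.

One weighted network per index hospital: nodes are the index hospital
and the providers retained by the third-quartile rule, links are
weighted by the number of distinct shared patients.  A provider is
retained when its count of patients shared with the index hospital is
strictly greater than the third quartile of the index-hospital-to-
provider counts of its type, pooled across all index hospitals.
Provider-provider (secondary) links are not thresholded; they are kept
(weight >= 1) whenever both endpoints are retained.

Shared-patient counting uses each patient's personal one-year window
after index discharge.  Eligible interactions are community visits to
in-region GPs, psychiatrists and nurses, plus psychiatric admissions to
in-region hospitals other than the index hospital; ambulatory contacts
within the index hospital itself feed the context metrics, not links.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .synthdata import PSYCHIATRIC_CARE_TYPES

log = logging.getLogger(__name__)

COMMUNITY_TYPES = ("gp", "psychiatrist", "nurse")


def count_shared_patients(cohort: pd.DataFrame, contacts: pd.DataFrame,
                          stays: pd.DataFrame, providers: pd.DataFrame,
                          config) -> pd.DataFrame:
    """Distinct-shared-patient counts for every provider pair per network.

    Returns a DataFrame ``[network_id, provider_a, provider_b, weight]``
    of unordered pairs.  Pairs involving the index hospital carry
    ``provider_a == network_id``; for those, ``weight`` is the number of
    distinct cohort patients of the network who contacted the provider
    (every cohort patient is by construction a patient of the index
    hospital).  Other rows are secondary provider-provider pairs.
    """
    cols = ["network_id", "provider_a", "provider_b", "weight"]
    if cohort.empty:
        return pd.DataFrame(columns=cols)
    window = config.follow_up_days
    anchor = cohort[["patient_id", "index_hospital_id", "discharge_date"]] \
        .rename(columns={"discharge_date": "anchor_discharge"})

    ptypes = providers.set_index("provider_id")["provider_type"]
    in_region = providers.set_index("provider_id")["in_region"]

    # community visits within the personal follow-up window
    c = contacts.merge(anchor, on="patient_id")
    if len(c):
        offs = (c["date"] - c["anchor_discharge"]).dt.days
        before = int((offs < 0).sum())
        if before:
            log.info("%d contacts dated before index discharge ignored",
                     before)
        c = c[(offs >= 0) & (offs <= window)]
        c = c[c["provider_id"].map(ptypes).isin(COMMUNITY_TYPES)]
        c = c[c["provider_id"].map(in_region) == 1]
        c = c[c["provider_id"] != c["index_hospital_id"]]

    # psychiatric admissions to other in-region hospitals
    s = stays[stays["care_type"].isin(PSYCHIATRIC_CARE_TYPES)]
    s = s.merge(anchor, on="patient_id")
    if len(s):
        soffs = (s["admit_date"] - s["anchor_discharge"]).dt.days
        s = s[(soffs >= 0) & (soffs <= window)]
        s = s[s["hospital_id"].map(in_region) == 1]
        s = s[s["hospital_id"] != s["index_hospital_id"]]
    s = s.rename(columns={"hospital_id": "provider_id"})

    pp = pd.concat([
        c[["index_hospital_id", "patient_id", "provider_id"]],
        s[["index_hospital_id", "patient_id", "provider_id"]],
    ], ignore_index=True).drop_duplicates()
    pp = pp.rename(columns={"index_hospital_id": "network_id"})

    # index-hospital links: distinct patients per provider
    index_links = (pp.groupby(["network_id", "provider_id"])["patient_id"]
                   .nunique().reset_index(name="weight"))
    index_links["provider_a"] = index_links["network_id"]
    index_links = index_links.rename(columns={"provider_id": "provider_b"})

    # secondary links: self-merge on (network, patient), unordered pairs
    pairs = pp.merge(pp, on=["network_id", "patient_id"])
    pairs = pairs[pairs["provider_id_x"] < pairs["provider_id_y"]]
    sec = (pairs.groupby(["network_id", "provider_id_x", "provider_id_y"])
           ["patient_id"].nunique().reset_index(name="weight")
           .rename(columns={"provider_id_x": "provider_a",
                            "provider_id_y": "provider_b"}))

    out = pd.concat([index_links[cols], sec[cols]], ignore_index=True)
    return (out.sort_values(cols[:3], kind="stable")
            .reset_index(drop=True))


def index_links(pair_counts: pd.DataFrame) -> pd.DataFrame:
    """Rows of the pair-count table linking an index hospital."""
    return pair_counts[pair_counts["provider_a"]
                       == pair_counts["network_id"]]


def compute_thresholds(pair_counts: pd.DataFrame,
                       providers: pd.DataFrame, config=None) -> dict:
    """Per-provider-type retention thresholds (third-quartile rule).

    For each provider type, the threshold is the third quartile (linear
    interpolation between order statistics) of the index-hospital-to-
    provider shared-patient counts of that type, pooled across all index
    hospitals; retention requires a count strictly greater than it.
    """
    q = 0.75 if config is None else config.quartile
    ptypes = providers.set_index("provider_id")["provider_type"]
    il = index_links(pair_counts).copy()
    il["ptype"] = il["provider_b"].map(ptypes)
    thresholds = {}
    for t, grp in il.groupby("ptype"):
        thresholds[str(t)] = float(np.percentile(
            grp["weight"].to_numpy(float), 100 * q))
    if not thresholds:
        log.warning("no index links: thresholds undefined for every type")
    return thresholds


def zero_thresholds() -> dict:
    """No-threshold sensitivity mode: every shared patient counts."""
    return {t: 0.0 for t in COMMUNITY_TYPES + ("hospital",)}


def build_network(network_id: str, pair_counts: pd.DataFrame,
                  thresholds: dict, providers: pd.DataFrame) -> nx.Graph:
    """Assemble one SharingNetwork as a weighted undirected graph.

    Nodes carry provider attributes; the graph attribute
    ``index_hospital`` names the center.  Retained providers are those
    whose index link exceeds their type threshold strictly; secondary
    links require both endpoints retained and are never thresholded.
    """
    prov = providers.set_index("provider_id")
    pc = pair_counts[pair_counts["network_id"] == network_id]
    il = pc[pc["provider_a"] == network_id]
    ptype = il["provider_b"].map(prov["provider_type"])
    thr = ptype.map(lambda t: thresholds.get(t, np.inf))
    retained = il[il["weight"] > thr]

    g = nx.Graph(index_hospital=network_id)

    def _add_node(pid):
        row = prov.loc[pid]
        g.add_node(pid, provider_type=str(row["provider_type"]),
                   zone=str(row["zone"]), private=int(row["private"]),
                   specialized=int(row["specialized"]),
                   is_index=int(pid == network_id))

    _add_node(network_id)
    for pid, w in zip(retained["provider_b"], retained["weight"]):
        _add_node(pid)
        g.add_edge(network_id, pid, weight=int(w))
    if g.number_of_nodes() == 1:
        log.warning("network %s: no provider passed any threshold",
                    network_id)

    kept = set(g.nodes)
    sec = pc[(pc["provider_a"] != network_id)
             & pc["provider_a"].isin(kept) & pc["provider_b"].isin(kept)]
    for a, b, w in zip(sec["provider_a"], sec["provider_b"], sec["weight"]):
        g.add_edge(a, b, weight=int(w))
    return g


def build_all_networks(cohort, contacts, stays, providers,
                       config) -> dict[str, nx.Graph]:
    """Pair counting + thresholds + assembly for every index hospital."""
    pair_counts = count_shared_patients(cohort, contacts, stays, providers,
                                        config)
    if config.threshold_mode == "zero":
        thresholds = zero_thresholds()
    else:
        thresholds = compute_thresholds(pair_counts, providers, config)
    nets = {}
    for h in sorted(cohort["index_hospital_id"].unique()):
        nets[h] = build_network(h, pair_counts, thresholds, providers)
    return nets, pair_counts, thresholds


def export_network(g: nx.Graph, out_dir, name: str) -> None:
    """GraphML plus three-column weighted edge list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, out_dir / f"{name}.graphml")
    with open(out_dir / f"{name}.edgelist.tsv", "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, d in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['weight']}\n")
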