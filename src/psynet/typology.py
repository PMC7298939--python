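"""Typology of patient-sharing networks.

Principal-component analysis of the quantitative network profile
(active variables after correlation pruning; qualitative variables
illustrative), hierarchical clustering on the retained components, a
robustness check across three clustering methods (Ward, average-link,
k-means) via pairwise adjusted Rand indices, and cluster
characterization through v-tests and parangons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

log = logging.getLogger(__name__)

#: Candidate active (quantitative) profile variables, in representative-
#: priority order: within a correlated group the earliest listed variable
#: survives pruning, so density represents the size/cohesion block
#: (transitivity, provider/link counts and bed counts are summarized by
#: density; per-type percentage shares by the community-composition vars).
ACTIVE_CANDIDATES = [
    "density",
    "avg_contacts_per_patient",
    "pct_physicians_among_community",
    "pct_ambulatory_in_index",
    "median_weighted_degree",
    "psychiatrists_per_100k",
    "gps_per_100k",
    "pct_hospitals",
    "pct_private_among_hospitals",
]

#: Measured quantitative variables reported per cluster but summarized by
#: an active representative in the PCA.
SUPPLEMENTARY_QUANTITATIVE = [
    "transitivity", "n_providers_excl_index", "n_links", "index_beds",
    "nurses_per_100k", "pct_gps", "pct_nurses", "pct_psychiatrists",
    "pct_specialists_among_community", "loyalty_index",
]

ILLUSTRATIVE_VARS = ["index_specialized", "area_typology", "loyalty_band"]


def prune_correlated(profiles: pd.DataFrame, r_threshold: float = 0.7,
                     candidates=None) -> tuple[list[str], dict[str, str]]:
    """Greedy correlation pruning of the active variable set.

    Variables are visited in priority order; one is kept only if its
    absolute Pearson correlation with every already-kept variable stays
    at or below ``r_threshold``.  Constant variables are dropped with a
    warning.  Returns (kept, dropped→representative map).
    """
    candidates = [c for c in (candidates or ACTIVE_CANDIDATES)
                  if c in profiles.columns]
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for var in candidates:
        col = profiles[var].astype(float)
        if col.isna().any() or np.isclose(col.std(ddof=0), 0.0):
            log.warning("variable %s constant or incomplete: dropped", var)
            dropped[var] = "<constant>"
            continue
        rep = None
        for k in kept:
            r = np.corrcoef(col, profiles[k].astype(float))[0, 1]
            if abs(r) > r_threshold:
                rep = k
                break
        if rep is None:
            kept.append(var)
        else:
            dropped[var] = rep
    return kept, dropped


@dataclass
class PCAResult:
    coordinates: pd.DataFrame        # networks x components (all ranks)
    eigenvalues: np.ndarray          # of the correlation matrix
    explained_share: np.ndarray
    loadings: pd.DataFrame           # variables x components
    n_retained: int                  # per the retention rule
    active_vars: list[str] = field(default_factory=list)
    illustrative_coords: pd.DataFrame | None = None


def run_pca(profiles: pd.DataFrame, active_vars: list[str],
            illustrative_vars=None, retention: str = "cumvar",
            cum_var: float = 0.95) -> PCAResult:
    """PCA of standardized active variables; illustrative variables are
    projected (correlation with component scores) but never drive axes.

    ``retention`` picks the components kept for clustering: ``cumvar``
    (default) keeps the smallest number of leading components covering
    ``cum_var`` of the variance, never fewer than two — close to
    clustering on the full standardized space, the usual practice for
    hierarchical clustering on principal components.  ``kaiser``
    (eigenvalue >= 1) is available but with two or three active
    variables it routinely keeps a single component — two standardized
    variables can never both exceed 1 — and collapses the profile
    geometry onto a line, hence it is not the default."""
    if len(profiles) < 3:
        raise ValueError("PCA needs at least 3 networks")
    X = profiles[active_vars].astype(float).to_numpy()
    n, p = X.shape
    if p > n:
        log.warning("more active variables (%d) than networks (%d): "
                    "rank-limited decomposition", p, n)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = (X - mu) / sd
    # eigendecomposition of the correlation matrix via SVD of Z
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / n
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    comp_names = [f"PC{j + 1}" for j in range(len(eig))]
    coords = pd.DataFrame(scores, index=profiles["network_id"],
                          columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=active_vars, columns=comp_names)
    if retention == "kaiser":
        n_retained = max(1, int((eig >= 1.0).sum()))
    else:
        share = np.cumsum(eig) / eig.sum()
        n_retained = int(np.searchsorted(share, cum_var) + 1)
        n_retained = min(len(eig), max(2, n_retained))

    ill = None
    illustrative_vars = [v for v in (illustrative_vars or [])
                         if v in profiles.columns]
    if illustrative_vars:
        rows = {}
        for v in illustrative_vars:
            col = profiles[v]
            if col.dtype.kind in "biufc":
                vals = col.astype(float).to_numpy()
                if np.std(vals) > 0:
                    rows[v] = [np.corrcoef(vals, scores[:, j])[0, 1]
                               for j in range(len(eig))]
            else:
                for cat in sorted(col.astype(str).unique()):
                    mask = (col.astype(str) == cat).to_numpy()
                    if mask.any():
                        rows[f"{v}={cat}"] = scores[mask].mean(axis=0)
        ill = pd.DataFrame(rows, index=comp_names).T
    total = eig.sum()
    return PCAResult(coordinates=coords, eigenvalues=eig,
                     explained_share=eig / total if total else eig,
                     loadings=loadings, n_retained=n_retained,
                     active_vars=list(active_vars), illustrative_coords=ill)


@dataclass
class ClusterSolution:
    k: int
    labels: pd.Series                    # network_id -> cluster (0..k-1)
    method_agreement: pd.DataFrame       # mean pairwise ARI per candidate k
    ari_matrix: pd.DataFrame             # pairwise ARI at selected k
    parangons: dict = field(default_factory=dict)
    coordinates: pd.DataFrame | None = None


def _partitions(X: np.ndarray, k: int, seed: int) -> dict[str, np.ndarray]:
    ward = AgglomerativeClustering(n_clusters=k, linkage="ward").fit(X)
    avg = AgglomerativeClustering(n_clusters=k, linkage="average").fit(X)
    km = KMeans(n_clusters=k, n_init=10,
                random_state=seed).fit(X)
    return {"ward": ward.labels_, "average": avg.labels_,
            "kmeans": km.labels_}


def cluster_networks(pca: PCAResult, k_range=(2, 6),
                     kmeans_seed: int = 1234) -> ClusterSolution:
    """Ward partition at the k most robust across the three methods.

    For each candidate k, Ward, average-link and k-means partitions of
    the retained component coordinates are compared by mean pairwise
    adjusted Rand index; the selected k maximizes that agreement.  Ties
    (within 1e-9) are broken by the silhouette score of the Ward
    partition, then by the smaller k.  Labels come from the Ward
    partition; the k-means seed is fixed and logged.
    """
    coords = pca.coordinates.iloc[:, :pca.n_retained]
    X = coords.to_numpy()
    n = len(X)
    if n < 4:
        raise ValueError("clustering needs at least 4 networks")
    lo, hi = k_range
    hi = min(hi, n - 1)
    log.info("k-means seed %d", kmeans_seed)
    rows = []
    per_k = {}
    for k in range(lo, hi + 1):
        parts = _partitions(X, k, kmeans_seed)
        names = sorted(parts)
        aris = [adjusted_rand_score(parts[a], parts[b])
                for i, a in enumerate(names) for b in names[i + 1:]]
        sil = silhouette_score(X, parts["ward"]) if k < n else float("nan")
        rows.append(dict(k=k, mean_ari=float(np.mean(aris)),
                         silhouette=float(sil)))
        per_k[k] = parts
    agreement = pd.DataFrame(rows).set_index("k")
    best = agreement["mean_ari"].max()
    tied = agreement[agreement["mean_ari"] >= best - 1e-9]
    k_sel = int(tied.sort_values(["silhouette", "k"],
                                 ascending=[False, True]).index[0])

    parts = per_k[k_sel]
    names = sorted(parts)
    ari = pd.DataFrame(
        [[adjusted_rand_score(parts[a], parts[b]) for b in names]
         for a in names], index=names, columns=names)
    labels = pd.Series(parts["ward"], index=coords.index, name="cluster")
    sol = ClusterSolution(k=k_sel, labels=labels, method_agreement=agreement,
                          ari_matrix=ari, coordinates=coords)
    sol.parangons = find_parangons(sol)
    return sol


def find_parangons(solution: ClusterSolution) -> dict:
    """Member closest (Euclidean, PCA coordinates) to each cluster centroid."""
    coords = solution.coordinates
    parangons = {}
    for c in sorted(solution.labels.unique()):
        members = coords[solution.labels == c]
        centroid = members.mean(axis=0)
        d = np.linalg.norm(members - centroid, axis=1)
        parangons[int(c)] = members.index[int(np.argmin(d))]
    return parangons


def v_test(values: np.ndarray, member_mask: np.ndarray) -> float:
    """Standardized deviation of a cluster mean from the overall mean,
    under sampling without replacement of n_k networks out of N."""
    values = np.asarray(values, dtype=float)
    N = len(values)
    n_k = int(member_mask.sum())
    if n_k == 0 or n_k == N or N < 2:
        return float("nan")
    var = values.var(ddof=0)
    if var == 0:
        return 0.0
    se = np.sqrt(var / n_k * (N - n_k) / (N - 1))
    return float((values[member_mask].mean() - values.mean()) / se)


def characterize_clusters(profiles: pd.DataFrame, solution: ClusterSolution,
                          variables=None, alpha: float = 0.05) -> pd.DataFrame:
    """v-test table: one row per (cluster, quantitative variable).

    Flags cells whose cluster mean differs from the overall mean at the
    two-sided ``alpha`` level; singleton clusters get missing v values.
    """
    variables = variables or [
        c for c in ACTIVE_CANDIDATES + SUPPLEMENTARY_QUANTITATIVE
        if c in profiles.columns]
    zcrit = stats.norm.ppf(1 - alpha / 2)
    labels = profiles["network_id"].map(solution.labels)
    rows = []
    for c in sorted(solution.labels.unique()):
        mask = (labels == c).to_numpy()
        for var in variables:
            vals = profiles[var].astype(float).to_numpy()
            v = v_test(vals, mask) if mask.sum() > 1 else float("nan")
            rows.append(dict(
                cluster=int(c), variable=var, n_members=int(mask.sum()),
                cluster_mean=float(vals[mask].mean()),
                cluster_sd=float(vals[mask].std(ddof=1))
                if mask.sum() > 1 else float("nan"),
                overall_mean=float(vals.mean()), v_statistic=v,
                significant=bool(abs(v) >= zcrit) if np.isfinite(v)
                else False))
    return pd.DataFrame(rows)


def run_typology(profiles: pd.DataFrame, config) -> dict:
    """Pruning + PCA + clustering + characterization in one call."""
    kept, dropped = prune_correlated(profiles, config.pca_r_threshold)
    pca = run_pca(profiles, kept, ILLUSTRATIVE_VARS)
    solution = cluster_networks(pca, config.k_range, config.kmeans_seed)
    characterization = characterize_clusters(profiles, solution)
    return dict(active_vars=kept, dropped=dropped, pca=pca,
                solution=solution, characterization=characterization)
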