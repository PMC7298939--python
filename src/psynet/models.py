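"""Cluster-correlated relative-rate models for the quality indicators.

Patient-level log-binomial marginal models (log link, binomial
distribution) fitted by generalized estimating equations with an
exchangeable working correlation and robust (sandwich) standard errors,
expressing covariate effects as relative rates with 95% confidence
intervals.  On log-binomial non-convergence the fit falls back to a
Poisson GEE with robust variance, which estimates the same log-rate
parameters, and flags the fallback.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .netbuild import build_all_networks, zero_thresholds
from .netmetrics import build_profiles
from .quality import INDICATORS, compute_quality_rows
from .typology import run_typology

log = logging.getLogger(__name__)

PATIENT_COVARIATES = ["age_at_index", "male", "low_income", "precedence",
                      "somatic_ltd"]
NETWORK_COVARIATES = ["density", "median_weighted_degree",
                      "index_specialized", "pct_physicians_among_community",
                      "pct_hospitals", "pct_private_among_hospitals",
                      "psychiatrists_per_100k", "gps_per_100k",
                      "pct_ambulatory_in_index", "avg_contacts_per_patient",
                      "loyalty_index"]


def screen_collinearity(design: pd.DataFrame, covariates: list[str],
                        r_threshold: float = 0.7,
                        protected: list[str] | None = None
                        ) -> tuple[list[str], dict[str, str]]:
    """Drop one member of each covariate pair with |r| above threshold.

    ``protected`` covariates (the patient adjustors) are always visited
    first and thus survive against later network variables.  Raises if
    every network covariate would be dropped.
    """
    protected = protected or []
    order = [c for c in protected if c in covariates] + \
        [c for c in covariates if c not in protected]
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for var in order:
        col = design[var].astype(float)
        if np.isclose(col.std(ddof=0), 0.0):
            dropped[var] = "<constant>"
            continue
        rep = None
        for k in kept:
            r = np.corrcoef(col, design[k].astype(float))[0, 1]
            if abs(r) > r_threshold:
                rep = k
                break
        if rep is None:
            kept.append(var)
        else:
            dropped[var] = rep
    network_kept = [c for c in kept if c not in protected]
    if any(c not in protected for c in covariates) and not network_kept:
        raise ValueError("all network covariates dropped: "
                         "collinearity threshold too strict")
    return kept, dropped


@dataclass
class ModelFit:
    """Relative rates with 95% CIs from one cluster-correlated fit."""

    outcome: str
    table: pd.DataFrame          # covariate, RR, ci_low, ci_high, significant
    convergence_status: str      # converged | poisson_fallback | failed
    n_obs: int = 0
    n_clusters: int = 0
    covariates: list[str] = field(default_factory=list)


def _gee_fit(y, X, groups, family, cov_struct):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, X, groups=groups, family=family,
                       cov_struct=cov_struct)
        return model.fit(maxiter=200)


def fit_log_binomial_gee(data: pd.DataFrame, outcome: str,
                         covariates: list[str], cluster_col: str = "cluster",
                         correlation: str = "exchangeable",
                         alpha: float = 0.05) -> ModelFit:
    """Fit one relative-rate model for a binary outcome.

    ``data`` holds the outcome column, the covariate columns and the
    cluster identifier.  Robust sandwich standard errors are always
    used; ``correlation`` selects the working structure (exchangeable
    or independence).
    """
    df = data.dropna(subset=[outcome] + covariates + [cluster_col])
    y = df[outcome].astype(float).to_numpy()
    X = sm.add_constant(df[covariates].astype(float), has_constant="add")
    groups = df[cluster_col].to_numpy()
    n_clusters = len(np.unique(groups))
    if n_clusters < 2:
        raise ValueError("GEE needs at least 2 clusters")
    structs = {"exchangeable": sm.cov_struct.Exchangeable,
               "independence": sm.cov_struct.Independence}
    cov_struct = structs[correlation]()

    status = "converged"
    res = None
    try:
        fam = sm.families.Binomial(link=sm.families.links.Log())
        res = _gee_fit(y, X, groups, fam, cov_struct)
        if not np.all(np.isfinite(res.params)) or \
                not np.all(np.isfinite(res.bse)):
            raise ValueError("non-finite log-binomial estimates")
        if np.max(np.abs(res.params)) > 30:
            # log link drove fitted rates out of (0, 1): divergent fit
            raise ValueError("divergent log-binomial estimates")
    except Exception as exc:                      # noqa: BLE001
        log.warning("log-binomial GEE failed for %s (%s); "
                    "falling back to Poisson", outcome, exc)
        status = "poisson_fallback"
        try:
            res = _gee_fit(y, X, groups, sm.families.Poisson(),
                           structs[correlation]())
        except Exception as exc2:                 # noqa: BLE001
            log.error("Poisson GEE also failed for %s (%s)", outcome, exc2)
            return ModelFit(outcome=outcome, table=pd.DataFrame(),
                            convergence_status="failed",
                            n_obs=len(df), n_clusters=n_clusters,
                            covariates=list(covariates))

    ci = res.conf_int(alpha=alpha)
    ci = np.asarray(ci)
    params = np.asarray(res.params)
    names = list(X.columns)
    rows = []
    for i, name in enumerate(names):
        if name == "const":
            continue
        rr = float(np.exp(params[i]))
        lo, hi = float(np.exp(ci[i, 0])), float(np.exp(ci[i, 1]))
        rows.append(dict(covariate=name, RR=rr, ci_low=lo, ci_high=hi,
                         significant=bool(not (lo <= 1.0 <= hi))))
    return ModelFit(outcome=outcome, table=pd.DataFrame(rows),
                    convergence_status=status, n_obs=len(df),
                    n_clusters=n_clusters, covariates=list(covariates))


def build_design(quality_rows: pd.DataFrame, cohort: pd.DataFrame,
                 profiles: pd.DataFrame,
                 cluster_labels: pd.Series) -> pd.DataFrame:
    """Patient-level design table: indicators + adjustors + network vars."""
    cov = cohort.copy()
    cov["male"] = (cov["sex"] == "M").astype(int)
    design = quality_rows.merge(
        cov[["patient_id", "age_at_index", "male", "low_income",
             "precedence", "somatic_ltd"]], on="patient_id")
    net_cols = [c for c in NETWORK_COVARIATES if c in profiles.columns]
    design = design.merge(profiles[["network_id"] + net_cols],
                          on="network_id")
    design["cluster"] = design["network_id"].map(cluster_labels)
    return design


def fit_all_models(design: pd.DataFrame, r_threshold: float = 0.7,
                   cluster_col: str = "cluster") -> dict[str, ModelFit]:
    """The four indicator models with collinearity screening."""
    candidates = PATIENT_COVARIATES + [c for c in NETWORK_COVARIATES
                                       if c in design.columns]
    kept, dropped = screen_collinearity(design, candidates, r_threshold,
                                        protected=PATIENT_COVARIATES)
    if dropped:
        log.info("collinearity screen dropped: %s", dropped)
    fits = {}
    for outcome in INDICATORS:
        fits[outcome] = fit_log_binomial_gee(design, outcome, kept,
                                             cluster_col=cluster_col)
    return fits


def sensitivity_no_threshold(bundle, cohort, config,
                             main_fits: dict[str, ModelFit]) -> dict:
    """Replicate the multivariable analysis without any threshold.

    Rebuilds every network with all retention thresholds at zero,
    recomputes profiles, the typology and the quality rows, refits the
    four models, and reports side-by-side RRs with the maximum absolute
    RR difference per covariate.
    """
    import copy
    cfg = copy.deepcopy(config)
    cfg.threshold_mode = "zero"
    networks, _, _ = build_all_networks(cohort, bundle.contacts,
                                        bundle.stays, bundle.providers, cfg)
    profiles = build_profiles(networks, cohort, bundle, cfg)
    typ = run_typology(profiles, cfg)
    quality_rows = compute_quality_rows(cohort, bundle)
    labels = typ["solution"].labels if cfg.model_cluster_level == "cluster" \
        else pd.Series({h: h for h in networks})
    design = build_design(quality_rows, cohort, profiles, labels)
    fits = fit_all_models(design, cfg.pca_r_threshold)

    comparison = []
    for outcome, fit in fits.items():
        main = main_fits.get(outcome)
        if main is None or main.table.empty or fit.table.empty:
            continue
        m = main.table.set_index("covariate")["RR"]
        s = fit.table.set_index("covariate")["RR"]
        common = m.index.intersection(s.index)
        for cov in common:
            comparison.append(dict(outcome=outcome, covariate=cov,
                                   RR_main=float(m[cov]),
                                   RR_no_threshold=float(s[cov]),
                                   abs_diff=float(abs(m[cov] - s[cov]))))
    comp = pd.DataFrame(comparison)
    max_diff = float(comp["abs_diff"].max()) if len(comp) else float("nan")
    return dict(fits=fits, profiles=profiles, typology=typ,
                comparison=comp, max_abs_rr_diff=max_diff)
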