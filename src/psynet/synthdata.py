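"""Synthetic claims generator with planted network archetypes and outcomes.

Emulates a national claims extract restricted to one region: a provider
roster (index hospitals, other hospitals, community GPs, psychiatrists
and nurses), a patient table, inpatient stays, community contacts,
antipsychotic deliveries, and somatic prevention procedures.  Each index
hospital is assigned one of three archetypes that shape the structure of
its patient-sharing network (see :mod:`psynet.config`), and each
patient's four quality-indicator outcomes follow a log-linear model with
configured coefficients and an archetype-level shared intercept inducing
exchangeable within-archetype correlation.

The generator is bit-reproducible for a fixed seed, and
:func:`planted_truth` exposes the ground truth (archetype labels,
relative rates) for parameter-recovery experiments; the analysis stages
never consume it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import (ARCHETYPES, COMMUNITY_TYPES, OUTCOMES, AREA_TYPOLOGIES,
                     ScenarioConfig)

EPOCH = pd.Timestamp("2012-01-01")
CARE_FULL_TIME = "full_time_psychiatric"
CARE_AMBULATORY = "ambulatory_psychiatric"
PSYCHIATRIC_CARE_TYPES = (CARE_FULL_TIME, CARE_AMBULATORY)
PREVENTION_TAGS = ("P1", "P2", "P3")

_ICD_CODES = {
    "psychotic": ["F200", "F201", "F205", "F209", "F220", "F250"],
    "bipolar_personality": ["F300", "F301", "F310", "F312", "F315", "F603"],
    "severe_depressive": ["F322", "F323", "F332", "F333"],
}

TABLE_NAMES = ("providers", "patients", "stays", "contacts",
               "deliveries", "procedures")


@dataclass
class ClaimsBundle:
    """The six delimited tables of one synthetic claims extract."""

    providers: pd.DataFrame
    patients: pd.DataFrame
    stays: pd.DataFrame
    contacts: pd.DataFrame
    deliveries: pd.DataFrame
    procedures: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}

    def write(self, out_dir) -> dict[str, Path]:
        """Write all tables as headered CSV files (ISO-8601 dates)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in self.tables().items():
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False, date_format="%Y-%m-%d")
            paths[name] = path
        return paths

    @classmethod
    def read(cls, in_dir) -> "ClaimsBundle":
        in_dir = Path(in_dir)
        kwargs = {}
        date_cols = {"stays": ["admit_date", "discharge_date"],
                     "contacts": ["date"], "deliveries": ["date"],
                     "procedures": ["date"]}
        for name in TABLE_NAMES:
            kwargs[name] = pd.read_csv(
                in_dir / f"{name}.csv", parse_dates=date_cols.get(name, []),
                keep_default_na=True)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# helpers

def _weighted_distinct_choice(rng, weights, n_per_row):
    """For each row i, pick ``n_per_row[i]`` distinct items proportional to
    ``weights`` (Gumbel top-k).  Returns (row_index, item_index) arrays."""
    n_rows = len(n_per_row)
    pool = len(weights)
    if n_rows == 0 or pool == 0:
        return np.empty(0, int), np.empty(0, int)
    logw = np.log(np.maximum(weights, 1e-300))
    keys = logw[None, :] + rng.gumbel(size=(n_rows, pool))
    order = np.argsort(-keys, axis=1, kind="stable")
    n = np.minimum(np.asarray(n_per_row, dtype=int), pool)
    mask = np.arange(pool)[None, :] < n[:, None]
    rows = np.repeat(np.arange(n_rows), n)
    cols = order[mask]
    return rows, cols


def _adherence_for_probability(p, n_slots=12, need=9):
    """Per-patient adherence a with P(Binomial(n_slots, a) >= need) = p."""
    a_grid = np.linspace(0.0, 1.0, 4001)
    p_grid = stats.binom.sf(need - 1, n_slots, a_grid)
    return np.interp(np.clip(p, 0.0, 1.0), p_grid, a_grid)


def _latent_sigma(rho: float, baseline: float) -> float:
    """SD of the shared log-rate intercept that induces (to first order)
    exchangeable binary-outcome correlation ``rho`` at rate ``baseline``."""
    if rho <= 0.0:
        return 0.0
    return float(np.sqrt(np.log1p(rho * (1.0 - baseline) / baseline)))


def _days(ts_offsets) -> pd.Series:
    return pd.to_timedelta(np.asarray(ts_offsets, dtype=int), unit="D")


# ---------------------------------------------------------------------------
# generation

def generate_bundle(config: ScenarioConfig) -> ClaimsBundle:
    """Generate one synthetic claims extract under ``config``.

    For each index hospital, patients receive an index-eligible
    psychiatric inpatient stay; follow-up contacts are drawn from the
    hospital's archetype propensities within ``config.follow_up_days``
    of discharge; and outcome-relevant events (readmissions, referring
    physician visits, prevention procedures, antipsychotic deliveries)
    are realised so that each indicator is Bernoulli with the planted
    log-linear probability.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    hospitals = sorted(config.archetype_assignment)

    # latent archetype-level intercepts, one per (archetype, outcome)
    latent = {}
    for arch in ARCHETYPES:
        for out in OUTCOMES:
            om = config.outcome_models[out]
            sig = _latent_sigma(config.cluster_correlation, om.baseline)
            latent[(arch, out)] = rng.normal(-0.5 * sig**2, sig) if sig else 0.0

    # deterministic per-archetype specialization counts
    arch_members: dict[str, list[str]] = {}
    for h in hospitals:
        arch_members.setdefault(config.archetype_assignment[h], []).append(h)
    specialized = {}
    for arch, members in arch_members.items():
        n_spec = max(1, round(config.archetypes[arch].p_specialized
                              * len(members))) if len(members) > 1 else \
            round(config.archetypes[arch].p_specialized * len(members))
        for i, h in enumerate(sorted(members)):
            specialized[h] = int(i < n_spec)

    prov_rows, pat_rows = [], []
    stay_parts, contact_parts, deliv_parts, proc_parts = [], [], [], []
    counters = {"gp": 0, "psychiatrist": 0, "nurse": 0, "hospital": 0,
                "patient": 0}
    prefix = {"gp": "GP", "psychiatrist": "PS", "nurse": "NU"}

    # out-of-region noise providers (GPs beyond the region boundary)
    oor_ids = [f"XR{i:03d}" for i in range(config.n_out_of_region_providers)]
    for pid in oor_ids:
        prov_rows.append(dict(provider_id=pid, provider_type="gp",
                              in_region=0, zone="ZX", is_index=0, sectorized=0,
                              military=0, private=0, specialized=0,
                              beds=np.nan, catchment_pop=np.nan,
                              area_typology=""))

    follow = config.follow_up_days
    year0, year1 = config.index_years
    index_span_days = (pd.Timestamp(f"{year1}-12-31")
                       - pd.Timestamp(f"{year0}-01-01")).days + 1
    diag_groups = sorted(config.diagnosis_mix)
    diag_probs = np.array([config.diagnosis_mix[g] for g in diag_groups])

    for hi, h in enumerate(hospitals):
        arch = config.archetype_assignment[h]
        par = config.archetypes[arch]
        zone = f"Z{hi:02d}"
        pop = int(par.catchment_pop * rng.uniform(0.95, 1.05))
        beds = max(20, int(rng.normal(par.beds_mean, 40)))
        area = rng.choice(AREA_TYPOLOGIES,
                          p=[par.area_typology_probs.get(a, 0.0)
                             for a in AREA_TYPOLOGIES])
        prov_rows.append(dict(provider_id=h, provider_type="hospital",
                              in_region=1, zone=zone, is_index=1, sectorized=1,
                              military=0, private=0,
                              specialized=specialized[h], beds=float(beds),
                              catchment_pop=float(pop), area_typology=str(area)))

        # local pools
        pool_ids: dict[str, list[str]] = {}
        for t in COMMUNITY_TYPES:
            ids = []
            for _ in range(par.pool_sizes[t]):
                ids.append(f"{prefix[t]}{counters[t]:05d}")
                counters[t] += 1
            pool_ids[t] = ids
            for pid in ids:
                prov_rows.append(dict(provider_id=pid, provider_type=t,
                                      in_region=1, zone=zone, is_index=0,
                                      sectorized=0, military=0, private=0,
                                      specialized=0, beds=np.nan,
                                      catchment_pop=np.nan, area_typology=""))
        n_oh = par.pool_sizes.get("hospital", 0)
        n_priv = round(par.p_private_other_hospital * n_oh)
        oh_ids = []
        for j in range(n_oh):
            pid = f"OH{counters['hospital']:04d}"
            counters["hospital"] += 1
            oh_ids.append(pid)
            prov_rows.append(dict(provider_id=pid, provider_type="hospital",
                                  in_region=1, zone=zone, is_index=0,
                                  sectorized=0, military=0,
                                  private=int(j < n_priv), specialized=0,
                                  beds=np.nan, catchment_pop=np.nan,
                                  area_typology=""))
        pool_ids["hospital"] = oh_ids

        # provider popularity within each pool; private hospitals are
        # boosted/damped by the archetype's private-sector affinity
        popularity = {
            t: rng.dirichlet(np.full(len(pool_ids[t]),
                                     par.concentration[t]))
            if pool_ids[t] else np.empty(0)
            for t in pool_ids}
        if n_oh and par.private_affinity != 1.0:
            w = popularity["hospital"]
            w[:n_priv] *= par.private_affinity
            popularity["hospital"] = w / w.sum()

        # ------------------------------------------------------------------
        # patients and their index stay
        n = config.n_patients_per_hospital
        pat_ids = np.array([f"PT{counters['patient'] + i:06d}"
                            for i in range(n)])
        counters["patient"] += n
        age = rng.integers(18, 66, n)
        male = rng.random(n) < config.p_male
        low_income = rng.random(n) < config.p_low_income
        somatic = rng.random(n) < config.p_somatic_ltd
        precedence = rng.random(n) < config.p_precedence
        diag = rng.choice(diag_groups, size=n, p=diag_probs)
        icd = np.array([rng.choice(_ICD_CODES[g]) for g in diag])
        in_catchment = rng.random(n) < par.loyalty_target
        other_zones = [f"Z{j:02d}" for j in range(len(hospitals)) if j != hi]
        res_zone = np.where(in_catchment, zone,
                            rng.choice(other_zones if other_zones else [zone],
                                       size=n))
        admit_off = rng.integers(0, index_span_days, n)
        los = 5 + rng.poisson(25, n)
        admit = EPOCH + _days(admit_off)
        discharge = admit + _days(los)
        birth_year = admit.year.values - age

        stay_parts.append(pd.DataFrame(dict(
            patient_id=pat_ids, hospital_id=h, admit_date=admit,
            discharge_date=discharge, icd10_main=icd,
            care_type=CARE_FULL_TIME)))

        # precedence: an ambulatory psychiatric hospital contact within the
        # 730 days before index admission (ineligible as an index stay)
        p_idx = np.flatnonzero(precedence)
        if p_idx.size:
            gap = rng.integers(30, 731, p_idx.size)
            p_admit = admit[p_idx] - _days(gap)
            stay_parts.append(pd.DataFrame(dict(
                patient_id=pat_ids[p_idx], hospital_id=h,
                admit_date=p_admit, discharge_date=p_admit,
                icd10_main=icd[p_idx], care_type=CARE_AMBULATORY)))

        # ------------------------------------------------------------------
        # follow-up community contacts
        contacted: dict[str, dict[int, np.ndarray]] = {}
        for t in COMMUNITY_TYPES:
            has = rng.random(n) < par.p_contact[t]
            n_dist = np.where(has, 1 + rng.poisson(par.extra_distinct[t], n), 0)
            rows, cols = _weighted_distinct_choice(rng, popularity[t], n_dist)
            contacted[t] = (rows, cols)

        # referring physician: designated wherever GPs are contactable
        has_designation = par.p_contact["gp"] > 0 and bool(pool_ids["gp"])
        if has_designation:
            gp_rows, gp_cols = contacted["gp"]
            referring_idx = np.full(n, -1)
            # first (most popular) contacted GP, else a random pool GP
            for r, c in zip(gp_rows, gp_cols):
                if referring_idx[r] < 0:
                    referring_idx[r] = c
            missing = referring_idx < 0
            referring_idx[missing] = rng.integers(0, len(pool_ids["gp"]),
                                                  missing.sum())
            referring = np.array(pool_ids["gp"])[referring_idx]
        else:
            referring = np.array([""] * n)

        # planted outcomes
        xcols = dict(male=male.astype(float),
                     low_income=low_income.astype(float),
                     precedence=precedence.astype(float),
                     somatic_ltd=somatic.astype(float),
                     index_specialized=np.full(n, float(specialized[h])))
        y, p_out = {}, {}
        for out in OUTCOMES:
            om = config.outcome_models[out]
            eta = np.full(n, np.log(om.baseline) + latent[(arch, out)])
            for cov, beta in om.coefficients.items():
                eta = eta + beta * xcols[cov]
            p = np.clip(np.exp(eta), 0.0, 0.995)
            p_out[out] = p
            y[out] = rng.random(n) < p

        # community visit events
        for t in COMMUNITY_TYPES:
            rows, cols = contacted[t]
            if rows.size == 0:
                continue
            visits = 1 + rng.poisson(par.visits_per_provider[t], rows.size)
            pr = np.repeat(rows, visits)
            pc = np.repeat(cols, visits)
            offs = rng.integers(0, follow + 1, pr.size)
            prov = np.array(pool_ids[t])[pc]
            if t == "gp" and has_designation:
                # visits to the designated referring GP stay outside the
                # 60-day transition window; the indicator event is added below
                is_ref = prov == referring[pr]
                n_ref = int(is_ref.sum())
                if n_ref:
                    offs[is_ref] = rng.integers(61, follow + 1, n_ref)
            contact_parts.append(pd.DataFrame(dict(
                patient_id=pat_ids[pr], provider_id=prov,
                date=discharge[pr] + _days(offs))))

        # referring-physician transition contact (indicator 2)
        if has_designation:
            ridx = np.flatnonzero(y["referring_contact_2m"])
            if ridx.size:
                offs = rng.integers(1, 61, ridx.size)
                contact_parts.append(pd.DataFrame(dict(
                    patient_id=pat_ids[ridx], provider_id=referring[ridx],
                    date=discharge[ridx] + _days(offs))))

        # ambulatory psychiatric contacts within the index hospital
        n_amb = rng.poisson(par.ambulatory_rate, n)
        pr = np.repeat(np.arange(n), n_amb)
        if pr.size:
            offs = rng.integers(0, follow + 1, pr.size)
            contact_parts.append(pd.DataFrame(dict(
                patient_id=pat_ids[pr], provider_id=h,
                date=discharge[pr] + _days(offs))))

        # out-of-region noise contacts (dropped by the region filter)
        if oor_ids and config.p_out_of_region_contact > 0:
            oidx = np.flatnonzero(rng.random(n)
                                  < config.p_out_of_region_contact)
            if oidx.size:
                contact_parts.append(pd.DataFrame(dict(
                    patient_id=pat_ids[oidx],
                    provider_id=rng.choice(oor_ids, oidx.size),
                    date=discharge[oidx]
                    + _days(rng.integers(0, follow + 1, oidx.size)))))

        # other-hospital psychiatric admissions (outside the 15-day window)
        if oh_ids:
            has = rng.random(n) < par.p_contact["hospital"]
            n_dist = np.where(has,
                              1 + rng.poisson(par.extra_distinct["hospital"],
                                              n), 0)
            rows, cols = _weighted_distinct_choice(rng, popularity["hospital"],
                                                   n_dist)
            if rows.size:
                offs = rng.integers(16, follow + 1, rows.size)
                a = discharge[rows] + _days(offs)
                stay_parts.append(pd.DataFrame(dict(
                    patient_id=pat_ids[rows],
                    hospital_id=np.array(oh_ids)[cols], admit_date=a,
                    discharge_date=a + _days(1 + rng.poisson(10, rows.size)),
                    icd10_main=icd[rows], care_type=CARE_FULL_TIME)))

        # indicator 1: 15-day psychiatric readmission
        ridx = np.flatnonzero(y["readmit_15d"])
        if ridx.size:
            offs = rng.integers(1, 16, ridx.size)
            to_index = rng.random(ridx.size) < 0.7
            if oh_ids:
                other = rng.choice(oh_ids, ridx.size,
                                   p=popularity["hospital"])
            else:
                other = np.full(ridx.size, h)
            hosp = np.where(to_index, h, other)
            a = discharge[ridx] + _days(offs)
            stay_parts.append(pd.DataFrame(dict(
                patient_id=pat_ids[ridx], hospital_id=hosp, admit_date=a,
                discharge_date=a + _days(1 + rng.poisson(15, ridx.size)),
                icd10_main=icd[ridx], care_type=CARE_FULL_TIME)))
        lidx = np.flatnonzero(~y["readmit_15d"]
                              & (rng.random(n) < 0.25))
        if lidx.size:
            a = discharge[lidx] + _days(rng.integers(16, 301, lidx.size))
            stay_parts.append(pd.DataFrame(dict(
                patient_id=pat_ids[lidx], hospital_id=h, admit_date=a,
                discharge_date=a + _days(1 + rng.poisson(15, lidx.size)),
                icd10_main=icd[lidx], care_type=CARE_FULL_TIME)))

        # indicator 3: prevention procedures within two years; positives get
        # all three distinct tags, negatives a random subset of at most two
        n_tags = np.where(y["prevention_3proc_2y"], 3,
                          rng.choice([0, 1, 2], size=n, p=[0.2, 0.4, 0.4]))
        tag_perm = np.argsort(rng.random((n, 3)), axis=1)
        tag_mask = np.arange(3)[None, :] < n_tags[:, None]
        rows = np.repeat(np.arange(n), n_tags)
        if rows.size:
            tags = np.array(PREVENTION_TAGS)[tag_perm[tag_mask]]
            proc_parts.append(pd.DataFrame(dict(
                patient_id=pat_ids[rows],
                date=discharge[rows] + _days(rng.integers(0, 731, rows.size)),
                procedure_tag=tags)))

        # indicator 4: monthly antipsychotic deliveries; adherence inverted
        # so that >=9 of 12 monthly slots occurs with the planted probability
        adher = _adherence_for_probability(p_out["antipsychotic_9plus_12m"])
        n_deliv = rng.binomial(12, adher)
        month_perm = np.argsort(rng.random((n, 12)), axis=1)
        month_mask = np.arange(12)[None, :] < n_deliv[:, None]
        rows = np.repeat(np.arange(n), n_deliv)
        if rows.size:
            months = month_perm[month_mask]
            offs = months * 30 + rng.integers(0, 28, rows.size)
            deliv_parts.append(pd.DataFrame(dict(
                patient_id=pat_ids[rows], date=discharge[rows] + _days(offs),
                drug_class="antipsychotic")))

        pat_rows.append(pd.DataFrame(dict(
            patient_id=pat_ids, birth_year=birth_year,
            sex=np.where(male, "M", "F"), low_income=low_income.astype(int),
            somatic_ltd=somatic.astype(int), residence_zone=res_zone,
            referring_physician_id=referring)))

    def _concat(parts, columns, sort_by):
        if not parts:
            return pd.DataFrame(columns=columns)
        df = pd.concat(parts, ignore_index=True)
        return df.sort_values(sort_by, kind="stable").reset_index(drop=True)

    bundle = ClaimsBundle(
        providers=pd.DataFrame(prov_rows).sort_values(
            "provider_id", kind="stable").reset_index(drop=True),
        patients=_concat(pat_rows,
                         ["patient_id", "birth_year", "sex", "low_income",
                          "somatic_ltd", "residence_zone",
                          "referring_physician_id"], ["patient_id"]),
        stays=_concat(stay_parts,
                      ["patient_id", "hospital_id", "admit_date",
                       "discharge_date", "icd10_main", "care_type"],
                      ["patient_id", "admit_date", "hospital_id"]),
        contacts=_concat(contact_parts,
                         ["patient_id", "provider_id", "date"],
                         ["patient_id", "date", "provider_id"]),
        deliveries=_concat(deliv_parts,
                           ["patient_id", "date", "drug_class"],
                           ["patient_id", "date"]),
        procedures=_concat(proc_parts,
                           ["patient_id", "date", "procedure_tag"],
                           ["patient_id", "date", "procedure_tag"]),
    )
    return bundle


def planted_truth(config: ScenarioConfig) -> dict:
    """Ground truth of the scenario: archetype labels and target RRs.

    Never consumed by the analysis stages; intended for recovery tests.
    """
    rr = {}
    for out, om in config.outcome_models.items():
        rr[out] = {cov: float(np.exp(beta))
                   for cov, beta in om.coefficients.items()}
    return {
        "archetype": dict(sorted(config.archetype_assignment.items())),
        "relative_rates": rr,
        "baselines": {out: om.baseline
                      for out, om in config.outcome_models.items()},
    }


# ---------------------------------------------------------------------------
# light-weight outcome simulator for model-recovery experiments

def simulate_outcome_data(n_patients: int, n_clusters: int, log_rr: float,
                          baseline: float, latent_sd: float,
                          seed: int) -> pd.DataFrame:
    """Cluster-correlated binary outcomes under a log-linear model.

    One binary exposure ``x`` with log relative rate ``log_rr``; a shared
    per-cluster Gaussian intercept of SD ``latent_sd`` on the log-rate
    scale (mean-centred so the marginal rate at x=0 equals ``baseline``).
    Used for relative-rate recovery and CI-coverage experiments where a
    cluster count >= 20 is wanted, independent of the network pipeline.
    """
    rng = np.random.default_rng(seed)
    cluster = rng.integers(0, n_clusters, n_patients)
    u = rng.normal(-0.5 * latent_sd**2, latent_sd, n_clusters)
    x = rng.integers(0, 2, n_patients)
    p = np.clip(np.exp(np.log(baseline) + log_rr * x + u[cluster]), 0, 0.995)
    y = (rng.random(n_patients) < p).astype(int)
    return pd.DataFrame(dict(y=y, x=x, cluster=cluster))
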