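"""End-to-end orchestration: tables → networks → typology → quality → models.

Stages run in a fixed order, each writing delimited outputs under the
run directory; a JSON manifest records the config snapshot, seeds,
stage timings, and a checksum inventory of every output file, so a
rerun with the same manifest reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import netbuild, netmetrics, quality, synthdata, typology
from .cohort import build_cohort
from .config import PROVIDER_TYPES, ScenarioConfig
from .models import build_design, fit_all_models, sensitivity_no_threshold

log = logging.getLogger(__name__)


def validate_tables(bundle) -> pd.DataFrame:
    """Schema / foreign-key / date-sanity report (one row per violation)."""
    v = []

    def add(table, row, issue):
        v.append(dict(table=table, row=int(row), issue=issue))

    prov_ids = set(bundle.providers["provider_id"])
    pat_ids = set(bundle.patients["patient_id"])
    hosp_ids = set(bundle.providers.loc[
        bundle.providers["provider_type"] == "hospital", "provider_id"])

    bad = ~bundle.providers["provider_type"].isin(PROVIDER_TYPES)
    for i in bundle.providers.index[bad]:
        add("providers", i, "unknown provider_type "
            f"{bundle.providers.at[i, 'provider_type']!r}")

    for i in bundle.stays.index[~bundle.stays["patient_id"].isin(pat_ids)]:
        add("stays", i, "unknown patient_id")
    for i in bundle.stays.index[~bundle.stays["hospital_id"].isin(hosp_ids)]:
        add("stays", i, "unknown hospital_id")
    bad = bundle.stays["discharge_date"] < bundle.stays["admit_date"]
    for i in bundle.stays.index[bad]:
        add("stays", i, "discharge before admission")

    for i in bundle.contacts.index[
            ~bundle.contacts["patient_id"].isin(pat_ids)]:
        add("contacts", i, "unknown patient_id")
    for i in bundle.contacts.index[
            ~bundle.contacts["provider_id"].isin(prov_ids)]:
        add("contacts", i, "unknown provider_id")

    for name in ("deliveries", "procedures"):
        df = getattr(bundle, name)
        for i in df.index[~df["patient_id"].isin(pat_ids)]:
            add(name, i, "unknown patient_id")

    return pd.DataFrame(v, columns=["table", "row", "issue"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: ScenarioConfig, out_dir, bundle=None,
            sensitivity: bool = False) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    When ``bundle`` is omitted the synthetic generator supplies it.
    Any stage failure raises with the failing stage named.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(config=config.to_dict(), seed=config.seed,
                    kmeans_seed=config.kmeans_seed, stages={}, outputs={},
                    warnings=[])
    results = {}
    stage_start = time.perf_counter()

    def finish(stage):
        nonlocal stage_start
        manifest["stages"][stage] = round(time.perf_counter() - stage_start, 4)
        stage_start = time.perf_counter()

    try:
        stage = "simulate"
        if bundle is None:
            bundle = synthdata.generate_bundle(config)
        paths = bundle.write(out_dir / "tables")
        finish(stage)

        stage = "validate"
        report = validate_tables(bundle)
        report.to_csv(out_dir / "validation_report.csv", index=False)
        if len(report):
            manifest["warnings"].append(
                f"{len(report)} table violations (see validation_report.csv)")
            raise ValueError(f"{len(report)} schema violations in input "
                             "tables; see validation_report.csv")
        finish(stage)

        stage = "cohort"
        cohort = build_cohort(bundle, config)
        cohort.to_csv(out_dir / "cohort.csv", index=False,
                      date_format="%Y-%m-%d")
        finish(stage)

        stage = "networks"
        networks, pair_counts, thresholds = netbuild.build_all_networks(
            cohort, bundle.contacts, bundle.stays, bundle.providers, config)
        pair_counts.to_csv(out_dir / "pair_counts.csv", index=False)
        with open(out_dir / "thresholds.json", "w") as fh:
            json.dump(thresholds, fh, indent=2, sort_keys=True)
        for h, g in networks.items():
            netbuild.export_network(g, out_dir / "networks", h)
        finish(stage)

        stage = "metrics"
        profiles = netmetrics.build_profiles(networks, cohort, bundle, config)
        profiles.to_csv(out_dir / "network_profiles.csv", index=False)
        finish(stage)

        stage = "typology"
        typ = typology.run_typology(profiles, config)
        sol = typ["solution"]
        sol.labels.rename_axis("network_id").reset_index().to_csv(
            out_dir / "cluster_labels.csv", index=False)
        sol.method_agreement.to_csv(out_dir / "method_agreement.csv")
        sol.ari_matrix.to_csv(out_dir / "ari_matrix.csv")
        typ["characterization"].to_csv(out_dir / "cluster_vtests.csv",
                                       index=False)
        pd.Series(sol.parangons, name="network_id").rename_axis(
            "cluster").reset_index().to_csv(out_dir / "parangons.csv",
                                            index=False)
        finish(stage)

        stage = "quality"
        qrows = quality.compute_quality_rows(cohort, bundle)
        qrows.to_csv(out_dir / "quality_rows.csv", index=False)
        agg = quality.aggregate_quality(qrows, sol.labels)
        agg["per_network"].to_csv(out_dir / "quality_per_network.csv",
                                  index=False)
        agg["per_cluster"].to_csv(out_dir / "quality_per_cluster.csv",
                                  index=False)
        finish(stage)

        stage = "models"
        labels = sol.labels if config.model_cluster_level == "cluster" \
            else pd.Series({h: h for h in networks})
        design = build_design(qrows, cohort, profiles, labels)
        fits = fit_all_models(design, config.pca_r_threshold)
        tables = []
        for outcome, fit in fits.items():
            t = fit.table.copy()
            t.insert(0, "outcome", outcome)
            t["convergence_status"] = fit.convergence_status
            tables.append(t)
        model_table = pd.concat(tables, ignore_index=True) if tables \
            else pd.DataFrame()
        model_table.to_csv(out_dir / "model_results.csv", index=False)
        finish(stage)

        if sensitivity:
            stage = "sensitivity"
            sens = sensitivity_no_threshold(bundle, cohort, config, fits)
            stables = []
            for outcome, fit in sens["fits"].items():
                t = fit.table.copy()
                t.insert(0, "outcome", outcome)
                stables.append(t)
            pd.concat(stables, ignore_index=True).to_csv(
                out_dir / "model_results_no_threshold.csv", index=False)
            sens["comparison"].to_csv(out_dir / "sensitivity_comparison.csv",
                                      index=False)
            results["sensitivity"] = sens
            finish(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") \
            from exc

    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out_dir))] = \
                _sha256(path)
    manifest["n_networks"] = len(networks)
    manifest["selected_k"] = int(sol.k)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    results.update(dict(bundle=bundle, cohort=cohort, networks=networks,
                        pair_counts=pair_counts, thresholds=thresholds,
                        profiles=profiles, typology=typ,
                        quality_rows=qrows, quality_agg=agg, design=design,
                        fits=fits, manifest=manifest))
    return results
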