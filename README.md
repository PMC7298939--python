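# psynet — patient-sharing networks for severe mental health disorders

`psynet` is a tested, reusable pipeline for analysing healthcare-provider
**patient-sharing networks** built from administrative claims, in the
setting of severe mental health disorders (schizophrenia-spectrum,
bipolar/personality, severe depressive disorders).  It covers the whole
chain from raw claims-like tables to:

1. **Cohort selection** — adults (18–65 at admission) with a qualifying
   full-time psychiatric *index hospitalization* at a sectorized
   public/non-profit hospital, with claims-derived covariates
   (deprivation, somatic long-term illness, precedence of the disorder).
2. **Network construction** — one weighted network per index hospital.
   Providers (community GPs, psychiatrists, nurses, other hospitals) are
   linked by the number of *distinct shared patients* within each
   patient's one-year post-discharge window.  A provider is retained
   when its shared-patient count with the index hospital is **strictly
   greater than the third quartile** of the counts of its provider type,
   pooled region-wide; provider–provider links are kept unthresholded
   between retained providers.
3. **Network characterization** — density and transitivity (0–100),
   median weighted degree (strength), composition (provider-type mix,
   per-100k rates over the catchment population), loyalty index,
   in-hospital ambulatory share, contact volume.
4. **Typology** — PCA on standardized quantitative profiles (after
   correlation pruning; qualitative variables illustrative), Ward
   clustering on the retained components, robustness across Ward /
   average-link / k-means via pairwise adjusted Rand indices, v-test
   characterization and parangon (cluster exemplar) identification.
5. **Quality of care** — four claims-computable indicators on the
   schizophrenia-spectrum subcohort: 15-day psychiatric readmission,
   referring-physician ("médecin traitant") contact within 60 days,
   three somatic prevention procedures within 730 days, and ≥9
   antipsychotic deliveries within 365 days.
6. **Association models** — patient-level **log-binomial GEE** models
   (log link, binomial family, exchangeable working correlation, robust
   sandwich variance) expressing effects as relative rates (RR) with
   95% CIs, plus a no-threshold sensitivity replication.

Real claims extracts of this kind (e.g. the French national health data
system) are access-restricted, so the package ships a first-class
**synthetic-data generator** that emulates the claims schema with three
planted network archetypes — hospital-centric (A1), scattered-urban
(A2), medically-oriented (A3) — and planted log-linear outcome effects,
making every stage testable end-to-end.

## Worked example

```python
from psynet import (ScenarioConfig, generate_bundle, build_cohort,
                    build_all_networks, build_profiles, run_typology)

cfg = ScenarioConfig(seed=1)          # 19 hospitals, 5/9/5 archetypes
bundle = generate_bundle(cfg)         # six claims-like tables
cohort = build_cohort(bundle, cfg)    # one index stay per patient
networks, pair_counts, thresholds = build_all_networks(
    cohort, bundle.contacts, bundle.stays, bundle.providers, cfg)
print(thresholds)
# {'gp': 6.0, 'hospital': 28.0, 'nurse': 5.0, 'psychiatrist': 13.0}

profiles = build_profiles(networks, cohort, bundle, cfg)
typ = run_typology(profiles, cfg)
print(typ["solution"].k, dict(typ["solution"].labels.value_counts()))
# 3 {1: 9, 2: 5, 0: 5}
```

The thresholds are the per-type third quartiles of the
index-hospital-to-provider shared-patient counts: a GP enters a network
only if it shares strictly more than 6 patients with the index
hospital, a psychiatrist more than 13, and so on.  The typology selects
three clusters whose sizes (9/5/5) match the planted archetype
assignment.

The same run is available from the shell:

```bash
psynet run-all --seed 1 --out-dir run1 --no-threshold
```

which writes the claims tables, cohort, pair counts, GraphML/edge-list
network exports, profiles, cluster labels and v-tests, quality tables,
model results (main and no-threshold sensitivity), and a JSON manifest
with checksums of every output.

## Layout

```
src/psynet/
  config.py      scenario configuration and archetype parameters
  synthdata.py   synthetic claims generator + planted ground truth
  cohort.py      index-stay selection, diagnosis groups, covariates
  netbuild.py    shared-patient counting, quartile thresholds, networks
  netmetrics.py  structural / compositional / contextual profiles
  typology.py    pruning, PCA, 3-method clustering, v-tests, parangons
  quality.py     the four indicators and their aggregation
  models.py      log-binomial GEE relative-rate models + sensitivity
  pipeline.py    end-to-end orchestration, validation, manifest
  cli.py         `psynet` command-line interface
docs/methods.md  model assumptions, defaults, and design rationale
```
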