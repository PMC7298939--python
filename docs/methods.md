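# Methods

This note documents the models and procedures implemented in `psynet`,
the defaults chosen where the method leaves genuine freedom, and what
the synthetic scenario does and does not emulate.

## Study design being emulated

The pipeline reproduces a regional claims-based study design: all
adults with a severe mental health disorder admitted to full-time
psychiatric inpatient care at a sectorized public or private non-profit
hospital during a two-year index window, followed for one year after
discharge.  Severe disorder is defined by the ICD-10 main diagnosis of
the stay: any `F2x` code (schizophrenia, schizotypal and delusional
disorders), `F30x`/`F31x`/`F603` (manic episode, bipolar disorder,
emotionally unstable personality disorder), or the four-character codes
`F322/F323/F332/F333` (severe depressive episodes).  Codes are compared
uppercased with dots removed; prefix matching for the first two groups,
exact matching for the third.

Operationalizations the source design leaves open, fixed here:

* "adult" = age ≥ 18 at admission; "over 65 excluded" = retain ≤ 65 at
  the admission date; age is computed from birth year and admission
  year, as in minimal claims data.
* Patients with several eligible stays are anchored on the earliest
  (longest follow-up).
* "Two previous years" for disorder precedence = 730 days before the
  index admission, day-exact; any hospital psychiatric contact
  (full-time or ambulatory care type) qualifies.
* All windows use day arithmetic from exact dates; calendar phrases are
  mapped as 2 months = 60 days, 12 months = 365 days, 2 years = 730
  days.

## Network construction

For each index hospital *h*, the bipartite patient-provider contact
relation over the follow-up windows of *h*'s cohort patients is
projected onto providers: the link weight between two providers is the
number of distinct patients of *h* seen by both.  Eligible
interactions are community visits to in-region GPs, psychiatrists and
nurses, and psychiatric admissions to in-region hospitals other than
*h*.  Ambulatory contacts within *h* itself never create links (no
self-loops); they feed the in-hospital ambulatory-share metric.

Retention thresholds: for each provider type, the threshold is the
third quartile (linear interpolation between order statistics, i.e.
the value at rank 0.75·(n−1)) of the index-hospital-to-provider counts
of that type pooled across all index hospitals; a provider is retained
iff its count is **strictly greater** than the threshold.  The
convention and the pooling level are configurable
(`ScenarioConfig.quartile`, `threshold_mode`), and a zero-threshold
mode retains every provider sharing at least one patient.
Provider-provider links are *not* thresholded: any weight ≥ 1 link
between two retained providers is kept.  Raising any threshold can
only shrink a network (tested property).

## Network profiles

Density and transitivity are computed on the unweighted skeleton and
reported on a 0–100 scale; link weights enter only the weighted degree
(strength), summarized by its median over all nodes including the
index hospital.  Per-type counts and percentages are over non-index
providers; per-100k rates divide community-professional counts by the
adult catchment population; the private-hospital share counts the
index hospital in its denominator.  The loyalty index is the share of
index patients residing in the hospital's catchment zone, banded as
`>80%`, `[60–80%]` (closed interval), `<60%`.  The specialized-
ambulatory share is in-index ambulatory psychiatric contacts over
in-index ambulatory plus community psychiatrist visit events; the
average contact count includes every in-window contact (all community
types, in-index ambulatory, hospital admissions) over all cohort
patients of the network, including patients with no contact.

## Typology

Candidate active variables are the nine quantitative profile measures
used as PCA actives in this literature (density, median weighted
degree, psychiatrist/GP per-100k rates, % hospitals, % physicians
among community professionals, % private hospitals, in-index
ambulatory share, contacts per patient); the remaining quantitative
measures are reported per cluster but summarized by a representative
in the PCA.  Greedy correlation pruning visits variables in a fixed
priority order (density first, so it represents the size/cohesion
block) and keeps a variable only if |r| ≤ 0.7 with everything already
kept; constant variables are dropped with a warning.

PCA standardizes the active variables (population SD) and
eigendecomposes the correlation matrix; qualitative variables (index
specialization, area typology, loyalty band) are projected as
illustrative coordinates and never influence the axes.  **Component
retention** defaults to the smallest leading set covering ≥ 95% of the
variance with a floor of two components — close to clustering on the
full standardized space, the usual practice for hierarchical
clustering on principal components.  The Kaiser rule (eigenvalue ≥ 1)
is available but not the default: with two or three active variables
it keeps a single component (two standardized variables can never both
have eigenvalue ≥ 1) and collapses the cluster geometry onto a line.

Cluster count selection formalizes "robust to the choice of clustering
method": for each candidate k, Ward, average-link (both Euclidean on
the retained components) and k-means (fixed, logged seed) partitions
are compared by mean pairwise adjusted Rand index; the selected k
maximizes that agreement.  Ties (within 1e-9) are broken by the
silhouette score of the Ward partition, then by the smaller k.  The
silhouette tie-break is essential: with well-separated clusters all
three methods agree perfectly at several k (at k=2 they merge the same
two closest clouds), so agreement alone cannot identify the true
count.  Final labels come from the Ward partition.

Cluster characterization uses the v-test,
v = (mean_k − mean) / sqrt((s²/n_k)·(N−n_k)/(N−1)) with population
variance s², flagged at the two-sided 5% level; the parangon of a
cluster is the member closest (Euclidean, retained components) to the
cluster centroid.

## Quality indicators

Measured on the psychotic (schizophrenia-spectrum) subcohort only, all
anchored at the index discharge:

1. **Readmission** — any full-time psychiatric admission in
   (discharge, discharge + 15 d]; day 15 inclusive.
2. **Referring physician** — any contact with the patient's designated
   referring physician within 60 days; patients with no designation
   score false (the indicator measures a realized transition).
3. **Prevention** — all three configured somatic-prevention procedure
   tags within 730 days; the tag list is configuration-defined, with
   three placeholder tags by default.
4. **Medication continuity** — ≥ 9 antipsychotic deliveries within
   365 days; multiple same-day deliveries count separately.

Each indicator is a pure function of events inside its window;
translating all dates by a constant leaves it unchanged (tested).
Aggregation reports per-network percentages and per-cluster mean (SD)
across member networks with v-test flags.

## Relative-rate models

Four patient-level models, one per indicator: binomial family with log
link (relative rates, not odds ratios), fitted by GEE with an
exchangeable working correlation over the network-cluster labels and
robust sandwich standard errors.  Covariates are the patient adjustors
(age per year, sex, low-income coverage, precedence, somatic long-term
illness) plus the network structural/compositional/contextual
variables, after a collinearity screen (|r| > 0.7 drops the
later-visited member of a pair; adjustors are visited first and thus
protected).  Continuous covariates enter untransformed per unit.

The log link does not respect the binomial domain, so log-binomial
fits can diverge (fitted rates pushed above 1); divergence — including
parameter magnitudes above 30 on the log scale — triggers a fallback
to a Poisson GEE with robust variance, which targets the same
log-rate parameters, flagged as `poisson_fallback`.  Significance is
5% two-sided throughout, and the significance flag is exactly "1
outside the 95% CI".  Multi-level random-effect models are
deliberately not implemented: with few clusters their variance
components are unreliable.  Because sandwich variances are
anti-conservative with very few clusters, the model-recovery
experiments use ≥ 20 clusters; the working-correlation structure and
the clustering level (typology cluster vs network) are configurable.

The no-threshold sensitivity analysis rebuilds every network with all
thresholds at zero, recomputes profiles, typology and quality rows,
refits the four models, and reports side-by-side RRs with the maximum
absolute difference; when the main analysis already ran at zero
thresholds it reproduces the main fits exactly (tested).

## Synthetic scenario

Defaults: 19 index hospitals assigned 5/9/5 to archetypes A1/A2/A3,
200 patients per hospital (a desk-scale stand-in for a regional
cohort), two index years plus a 365-day follow-up, diagnosis mix
66/22/12% (psychotic / bipolar-personality / severe depressive),
patient flags matching a deprived regional population (21% low-income
coverage, 15% somatic long-term illness, 56% precedence), ages uniform
18–65.

Each hospital owns a local community pool; provider popularity within
a pool is Dirichlet-distributed with archetype-specific concentration
(small values concentrate patient flows on few providers, which raises
density and transitivity).  Archetype signatures: A1 is
hospital-centric — high in-index ambulatory share (~35%), concentrated
flows (high density), a small all-retained psychiatrist core, high
loyalty (0.90), no patient-sharing with other hospitals; A2 is
scattered-urban — low ambulatory share (~17%), the highest contact
volume (~82/patient), large diverse rosters, lower loyalty (0.70),
large catchment population; A3 is medically-oriented — physician-heavy
community mix (few nurses), the lowest contact volume (~48/patient),
mid loyalty (0.82).  Contact volumes are calibrated to the 48–82
contacts-per-patient range reported for such cohorts.  All non-index
hospitals are modelled as private clinics, which matches the regional
pattern of public sectorized hospitals plus additional private
capacity and makes the private-share metric a smooth n/(n+1) quantity;
as a consequence the private-hospital share and the psychiatrist
per-100k rate are *not* archetype discriminators in the default
scenario, unlike in the real region.  Readmissions return to the index
hospital 70% of the time, otherwise to other hospitals by popularity.

Outcomes: each indicator is Bernoulli with
p = baseline·exp(Σβx + u), clipped at 0.995.  Default baselines
(0.32 / 0.36 / 0.50 / 0.55) approximate the observed subcohort rates;
default coefficients plant a protective specialized-hospital effect on
readmission (RR 0.58) and small demographic/clinical effects.  The
shared intercept u is drawn per (archetype, outcome) with variance
σ² = log(1 + ρ(1−p₀)/p₀) and mean −σ²/2 — the first-order inversion of
the exchangeable binary correlation ρ induced by a shared lognormal
rate multiplier, mean-corrected so the marginal baseline is preserved
(default ρ = 0.02).  Realization is exact: readmissions are placed
inside/outside the 15-day window according to the drawn outcome;
referring-physician visits are pushed past day 60 unless the outcome
is positive (every patient designates a GP wherever GPs practice);
prevention positives receive all three tags in-window, negatives at
most two; antipsychotic deliveries fill 12 monthly slots with a
per-patient adherence probability solved from
P(Binomial(12, a) ≥ 9) = p, so the ≥9-deliveries indicator is exactly
Bernoulli(p).

What the generator does **not** emulate: realistic billing
nomenclature, seasonal/touristic utilization, care outside the region
beyond a small noise pool, individual professionals within hospitals,
social care, and the real region's Table-level values (its cluster
means for private-hospital share and psychiatrist density in
particular).  Passing tests therefore demonstrate correctness of the
pipeline's logic and recoverability of planted structure — not that
real claims data would yield these particular clusters or effects.

## Problem sizes and numerical choices

The default test and acceptance workloads are sized for a single CPU:
archetype-recovery over 50 seeds at the default scenario (~2 minutes),
model recovery over 200 replicates of n = 5,000 with 25 clusters
(~2–4 minutes).  Quartiles use linear interpolation
(`numpy.percentile` default); PCA signs are fixed by making the
largest-magnitude loading of each component positive; k-means uses 10
restarts at a fixed seed; all randomness flows from a single
configurable seed, and a fixed seed reproduces every table
byte-identically.

## Known limitations

* With three network clusters (as in the emulated study) the GEE
  sandwich variance is anti-conservative; fitted CIs from the default
  bundle-level models should be read qualitatively.
* The log-binomial fallback changes the variance model (Poisson); the
  flag is always carried in the output.
* Loyalty banding and catchment logic assume one zone per hospital in
  the synthetic scenario; the metric accepts arbitrary zone sets for
  real extracts.
* The typology's selection rule assumes the candidate range [2, 6]
  contains the true structure; it is configurable.
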