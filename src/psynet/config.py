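"""Scenario configuration for the synthetic claims generator.

A :class:`ScenarioConfig` fully determines one synthetic claims extract:
the roster of index hospitals and their archetype, the local provider
pools, per-archetype contact propensities, and the log-linear outcome
model that drives the four quality indicators.  Three archetypes are
built in, mirroring the organisational types observed for French
psychiatric-sector hospitals:

* ``A1`` — hospital-centric: most specialized ambulatory care delivered
  by the index hospital itself, a small and concentrated community
  roster, high patient loyalty to the catchment area.
* ``A2`` — scattered-urban: large, diverse provider rosters in dense
  urban areas, high contact volume, low in-hospital ambulatory share.
* ``A3`` — medically-oriented: smaller networks dominated by physician
  providers (GPs and psychiatrists), low contact volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

PROVIDER_TYPES = ("hospital", "gp", "psychiatrist", "nurse")
COMMUNITY_TYPES = ("gp", "psychiatrist", "nurse")
ARCHETYPES = ("A1", "A2", "A3")
OUTCOMES = ("readmit_15d", "referring_contact_2m",
            "prevention_3proc_2y", "antipsychotic_9plus_12m")

#: Five-level national typology of local mental-care supply.
AREA_TYPOLOGIES = (
    "limited_resources",
    "hospital_concentrated",
    "strong_private_urban",
    "strong_resources",
    "rural_health_social",
)


class ConfigurationError(ValueError):
    """Raised when a ScenarioConfig field is out of its valid range."""


@dataclass
class ArchetypeParams:
    """Generative parameters for one network archetype.

    ``pool_sizes`` are per index hospital (each hospital owns a local
    community pool living in its catchment zone).  ``concentration`` is
    the Dirichlet concentration of provider popularity within a pool:
    small values concentrate patient choice on few providers, which
    raises density and transitivity of the retained network.
    """

    pool_sizes: dict[str, int]
    concentration: dict[str, float]
    p_contact: dict[str, float]          # P(patient has >=1 contact with type)
    extra_distinct: dict[str, float]     # Poisson mean of extra distinct providers
    visits_per_provider: dict[str, float]  # Poisson mean of extra visits per provider
    ambulatory_rate: float               # Poisson mean of in-index ambulatory contacts
    loyalty_target: float                # P(patient resides in catchment)
    catchment_pop: int                   # adult inhabitants served (20-65 y)
    p_specialized: float                 # P(index hospital specialized in psychiatry)
    beds_mean: float
    p_private_other_hospital: float
    area_typology_probs: dict[str, float]
    #: popularity multiplier for private hospitals in patient flows
    #: (urban archetypes favour private clinics, sector-centric ones avoid them)
    private_affinity: float = 1.0

    def validate(self, name: str) -> None:
        for t in PROVIDER_TYPES:
            if t != "hospital" and self.pool_sizes.get(t, 0) <= 0:
                raise ConfigurationError(
                    f"{name}.pool_sizes[{t!r}] must be a positive count")
            if not 0.0 <= self.p_contact.get(t, 0.0) <= 1.0:
                raise ConfigurationError(
                    f"{name}.p_contact[{t!r}] must lie in [0, 1]")
        if self.pool_sizes.get("hospital", 0) < 0:
            raise ConfigurationError(f"{name}.pool_sizes['hospital'] negative")
        for frac_name in ("loyalty_target", "p_specialized",
                          "p_private_other_hospital"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}.{frac_name} must lie in [0, 1]")
        if self.catchment_pop <= 0:
            raise ConfigurationError(f"{name}.catchment_pop must be positive")
        if abs(sum(self.area_typology_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{name}.area_typology_probs must sum to 1")


@dataclass
class OutcomeModel:
    """Log-linear model for one quality indicator.

    P(Y=1) = baseline * exp(sum_j beta_j x_j + u), with u a shared
    archetype-level intercept inducing exchangeable within-archetype
    correlation.  Coefficients are log relative rates per covariate;
    covariate names refer to patient/hospital design columns
    (``male``, ``low_income``, ``precedence``, ``somatic_ltd``,
    ``index_specialized``).
    """

    baseline: float
    coefficients: dict[str, float] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        if not 0.0 < self.baseline < 1.0:
            raise ConfigurationError(f"{name}.baseline must lie in (0, 1)")


def default_archetypes() -> dict[str, ArchetypeParams]:
    """Archetype parameters emulating the three observed network types."""
    return {
        "A1": ArchetypeParams(
            pool_sizes={"gp": 60, "psychiatrist": 6, "nurse": 35,
                        "hospital": 6},
            concentration={"gp": 0.12, "psychiatrist": 1.5,
                           "nurse": 0.15, "hospital": 2.0},
            p_contact={"gp": 0.90, "psychiatrist": 0.75,
                       "nurse": 0.50, "hospital": 0.05},
            extra_distinct={"gp": 1.0, "psychiatrist": 0.1,
                            "nurse": 0.5, "hospital": 0.0},
            visits_per_provider={"gp": 4.0, "psychiatrist": 19.0,
                                 "nurse": 42.0, "hospital": 0.0},
            ambulatory_rate=9.0,
            loyalty_target=0.90,
            catchment_pop=90_000,
            p_specialized=0.20,
            beds_mean=150.0,
            p_private_other_hospital=1.0,
            private_affinity=1.0,
            area_typology_probs={"limited_resources": 0.2,
                                 "hospital_concentrated": 0.0,
                                 "strong_private_urban": 0.0,
                                 "strong_resources": 0.4,
                                 "rural_health_social": 0.4},
        ),
        "A2": ArchetypeParams(
            pool_sizes={"gp": 200, "psychiatrist": 45,
                        "nurse": 110, "hospital": 12},
            concentration={"gp": 0.8, "psychiatrist": 1.0,
                           "nurse": 0.8, "hospital": 0.8},
            p_contact={"gp": 0.85, "psychiatrist": 0.70,
                       "nurse": 0.41, "hospital": 0.60},
            extra_distinct={"gp": 2.2, "psychiatrist": 1.0,
                            "nurse": 2.5, "hospital": 0.4},
            visits_per_provider={"gp": 4.0, "psychiatrist": 19.0,
                                 "nurse": 22.0, "hospital": 0.0},
            ambulatory_rate=6.0,
            loyalty_target=0.70,
            catchment_pop=240_000,
            p_specialized=0.45,
            beds_mean=160.0,
            p_private_other_hospital=1.0,
            private_affinity=1.0,
            area_typology_probs={"limited_resources": 0.0,
                                 "hospital_concentrated": 0.0,
                                 "strong_private_urban": 0.55,
                                 "strong_resources": 0.45,
                                 "rural_health_social": 0.0},
        ),
        "A3": ArchetypeParams(
            pool_sizes={"gp": 80, "psychiatrist": 10,
                        "nurse": 30, "hospital": 4},
            concentration={"gp": 0.8, "psychiatrist": 2.0,
                           "nurse": 0.5, "hospital": 2.0},
            p_contact={"gp": 0.92, "psychiatrist": 0.70,
                       "nurse": 0.30, "hospital": 0.60},
            extra_distinct={"gp": 1.2, "psychiatrist": 0.4,
                            "nurse": 0.3, "hospital": 0.5},
            visits_per_provider={"gp": 6.5, "psychiatrist": 15.0,
                                 "nurse": 23.0, "hospital": 0.0},
            ambulatory_rate=6.0,
            loyalty_target=0.82,
            catchment_pop=130_000,
            p_specialized=0.20,
            beds_mean=105.0,
            p_private_other_hospital=1.0,
            private_affinity=1.0,
            area_typology_probs={"limited_resources": 0.0,
                                 "hospital_concentrated": 0.0,
                                 "strong_private_urban": 0.8,
                                 "strong_resources": 0.2,
                                 "rural_health_social": 0.0},
        ),
    }


def default_outcomes() -> dict[str, OutcomeModel]:
    """Default planted outcome models.

    Baselines approximate the overall indicator rates observed for the
    schizophrenia-spectrum subcohort; the readmission model plants the
    protective effect of index-hospital specialization (RR 0.58).
    """
    return {
        "readmit_15d": OutcomeModel(
            baseline=0.32,
            coefficients={"index_specialized": math.log(0.58),
                          "precedence": math.log(1.23),
                          "male": math.log(1.12)}),
        "referring_contact_2m": OutcomeModel(
            baseline=0.36,
            coefficients={"male": math.log(0.79),
                          "somatic_ltd": math.log(1.39)}),
        "prevention_3proc_2y": OutcomeModel(
            baseline=0.50,
            coefficients={"male": math.log(0.82),
                          "somatic_ltd": math.log(1.26)}),
        "antipsychotic_9plus_12m": OutcomeModel(
            baseline=0.55,
            coefficients={"low_income": math.log(0.84),
                          "precedence": math.log(1.08)}),
    }


def default_assignment(n: int) -> dict[str, str]:
    """5/9/5-proportioned archetype assignment over ``n`` hospitals."""
    counts = {"A1": round(n * 5 / 19), "A3": round(n * 5 / 19)}
    counts["A2"] = n - counts["A1"] - counts["A3"]
    labels = (["A1"] * counts["A1"] + ["A2"] * counts["A2"]
              + ["A3"] * counts["A3"])
    return {f"IH{i:02d}": lab for i, lab in enumerate(labels)}


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic study scenario."""

    n_index_hospitals: int = 19
    archetype_assignment: dict[str, str] = field(default_factory=dict)
    n_patients_per_hospital: int = 200
    archetypes: dict[str, ArchetypeParams] = field(
        default_factory=default_archetypes)
    outcome_models: dict[str, OutcomeModel] = field(
        default_factory=default_outcomes)
    cluster_correlation: float = 0.02
    seed: int = 0

    # study window (two index years + one follow-up year)
    index_years: tuple[int, int] = (2012, 2013)
    follow_up_days: int = 365

    # patient mix
    p_male: float = 0.57
    p_low_income: float = 0.206
    p_somatic_ltd: float = 0.152
    p_precedence: float = 0.562
    diagnosis_mix: dict[str, float] = field(default_factory=lambda: {
        "psychotic": 0.664, "bipolar_personality": 0.221,
        "severe_depressive": 0.115})

    # out-of-region noise pool (exercises the region filter)
    n_out_of_region_providers: int = 8
    p_out_of_region_contact: float = 0.03

    # network thresholding mode: "quartile" (third-quartile rule) or "zero"
    threshold_mode: str = "quartile"
    quartile: float = 0.75

    # typology / model settings
    pca_r_threshold: float = 0.7
    k_range: tuple[int, int] = (2, 6)
    kmeans_seed: int = 1234
    model_cluster_level: str = "cluster"   # "cluster" (typology) or "network"

    def __post_init__(self) -> None:
        if not self.archetype_assignment:
            self.archetype_assignment = default_assignment(
                self.n_index_hospitals)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_index_hospitals <= 0:
            raise ConfigurationError("n_index_hospitals must be positive")
        if self.n_patients_per_hospital <= 0:
            raise ConfigurationError("n_patients_per_hospital must be positive")
        if len(self.archetype_assignment) != self.n_index_hospitals:
            raise ConfigurationError(
                "archetype_assignment must cover every index hospital "
                f"exactly once ({len(self.archetype_assignment)} labels for "
                f"{self.n_index_hospitals} hospitals)")
        for h, a in self.archetype_assignment.items():
            if a not in self.archetypes:
                raise ConfigurationError(
                    f"archetype_assignment[{h!r}] = {a!r} has no parameter set")
        for name, params in self.archetypes.items():
            params.validate(f"archetypes[{name!r}]")
        for name, om in self.outcome_models.items():
            om.validate(f"outcome_models[{name!r}]")
        if not 0.0 <= self.cluster_correlation < 1.0:
            raise ConfigurationError("cluster_correlation must lie in [0, 1)")
        for p in ("p_male", "p_low_income", "p_somatic_ltd", "p_precedence",
                  "p_out_of_region_contact"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ConfigurationError(f"{p} must lie in [0, 1]")
        if abs(sum(self.diagnosis_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("diagnosis_mix must sum to 1")
        if self.threshold_mode not in ("quartile", "zero"):
            raise ConfigurationError(
                "threshold_mode must be 'quartile' or 'zero'")
        if self.model_cluster_level not in ("cluster", "network"):
            raise ConfigurationError(
                "model_cluster_level must be 'cluster' or 'network'")

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["index_years"] = list(self.index_years)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "archetypes" in d:
            d["archetypes"] = {k: ArchetypeParams(**v) if isinstance(v, dict)
                               else v for k, v in d["archetypes"].items()}
        if "outcome_models" in d:
            d["outcome_models"] = {k: OutcomeModel(**v) if isinstance(v, dict)
                                   else v for k, v in d["outcome_models"].items()}
        for tup in ("index_years", "k_range"):
            if tup in d:
                d[tup] = tuple(d[tup])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
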