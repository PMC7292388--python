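"""Deployment configuration: pathway registry, survey category map, laboratory
conventions, priors, and simulation settings.

A deployment of the exposure-assessment tool is parameterized entirely by a
:class:`DeploymentConfig`.  The defaults encode the standard nine-pathway
registry (drinking water, bathing water, surface water, ocean water, flood
water, open drains, public/shared toilets, raw produce, street food) plus a
"soil" background sample type, a documented categorical-answer-to-monthly-count
map, membrane-filtration countable-range conventions, and weakly informative
priors.  Every convention that the field protocols leave open (answer-choice
midpoints, countable bounds, hand-to-mouth intake equivalents) lives here so
it can be overridden from a YAML/JSON file rather than edited in code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import yaml

SURVEY_TYPES = ("household", "school", "community")
POPULATIONS = ("adult", "child")

#: Routes by which pathway contact leads to ingestion.
DIRECT_INGESTION = "direct_ingestion"
HAND_TO_MOUTH = "hand_to_mouth"


class ConfigError(ValueError):
    """Raised when a deployment configuration is internally inconsistent."""


@dataclass(frozen=True)
class FrequencyCategoryMap:
    """Ordered mapping from survey answer categories to contacts per month.

    The survey instruments record behavior frequency as ordered categories
    ("never", "1-3 times per month", "daily", ...).  Estimation needs counts
    per month, so each category carries a representative monthly value
    (midpoint of its range, weekly midpoints scaled by ``weeks_per_month``).
    A zero-valued "never" category is mandatory: "never" is an explicit
    answer, distinct from a missing one.
    """

    categories: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        labels = [c[0] for c in self.categories]
        if len(set(labels)) != len(labels):
            raise ConfigError("category labels must be unique")
        if any(v < 0 for _, v in self.categories):
            raise ConfigError("category monthly values must be nonnegative")
        if not any(v == 0 for _, v in self.categories):
            raise ConfigError("a zero-valued 'never' category is required")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.categories)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(c[1] for c in self.categories)

    def monthly_count(self, label: str) -> float:
        for lab, val in self.categories:
            if lab == label:
                return val
        raise KeyError(f"unknown frequency category label: {label!r}")

    def encode(self, monthly_count: float) -> str:
        """Return the category whose monthly value is nearest ``monthly_count``.

        The inverse of the midpoint convention; ties go to the lower
        (coarser, more conservative) category.
        """
        best = min(
            self.categories,
            key=lambda c: (abs(c[1] - monthly_count), c[1]),
        )
        return best[0]


#: Default answer-choice map: weekly midpoints x 4.33 weeks/month, 30 days/month.
DEFAULT_CATEGORIES: tuple[tuple[str, float], ...] = (
    ("never", 0.0),
    ("<1/month", 0.5),
    ("1-3/month", 2.0),
    ("1-2/week", 6.5),
    ("3-5/week", 17.3),
    ("daily", 30.0),
)


@dataclass(frozen=True)
class PathwaySpec:
    """One environmental exposure pathway.

    ``intake_adult`` / ``intake_child`` are the effective amounts ingested per
    contact, expressed in the pathway's concentration denominator unit (e.g.
    2.5 units of a per-100 mL concentration = 250 mL swallowed).  For
    hand-to-mouth routes the constant is a volume-equivalent that folds hand
    adherence and transfer efficiency into a single number; shipped values are
    placeholders to be calibrated against local or literature data.
    """

    name: str
    denominator_unit: str  # per_100mL | per_serving | per_g | per_swab
    route: str  # direct_ingestion | hand_to_mouth
    intake_adult: float
    intake_child: float
    exposure_pathway: bool = True  # soil is measured but feeds no pathway

    def intake(self, population: str) -> float:
        if population == "adult":
            return self.intake_adult
        if population == "child":
            return self.intake_child
        raise ConfigError(f"unknown population: {population!r}")


def _default_pathways() -> tuple[PathwaySpec, ...]:
    return (
        PathwaySpec("drinking_water", "per_100mL", DIRECT_INGESTION, 2.5, 1.5),
        PathwaySpec("bathing_water", "per_100mL", DIRECT_INGESTION, 0.1, 0.2),
        PathwaySpec("surface_water", "per_100mL", HAND_TO_MOUTH, 0.02, 0.04),
        PathwaySpec("ocean_water", "per_100mL", HAND_TO_MOUTH, 0.02, 0.04),
        PathwaySpec("flood_water", "per_100mL", HAND_TO_MOUTH, 0.02, 0.04),
        PathwaySpec("drain_water", "per_100mL", HAND_TO_MOUTH, 0.01, 0.02),
        PathwaySpec("toilet_swab", "per_swab", HAND_TO_MOUTH, 0.01, 0.02),
        PathwaySpec("produce", "per_serving", DIRECT_INGESTION, 1.0, 0.5),
        PathwaySpec("street_food", "per_serving", DIRECT_INGESTION, 1.0, 0.5),
        PathwaySpec("soil", "per_g", HAND_TO_MOUTH, 0.02, 0.05,
                    exposure_pathway=False),
    )


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the weakly informative default priors.

    Negative-binomial frequency model: dispersion r ~ Gamma(shape, rate),
    success probability p ~ Beta(a, b).  Log-normal concentration model:
    mu ~ Normal(mu_loc, mu_scale^2) on the log10 scale, sigma ~
    Half-Normal(sigma_scale).  Defaults are broad enough not to dominate
    10-100 observations.
    """

    r_shape: float = 1.0
    r_rate: float = 0.5
    p_a: float = 1.0
    p_b: float = 1.0
    mu_loc: float = 0.0
    mu_scale: float = 10.0
    sigma_scale: float = 5.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0 and name != "mu_loc":
                raise ConfigError(f"prior hyperparameter {name} must be positive")


@dataclass(frozen=True)
class McmcSettings:
    """Sampler controls.  Proposal scales adapt during burn-in only, so seeded
    runs are bit-reproducible."""

    chains: int = 4
    iterations: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    prop_scale_logr: float = 0.5
    prop_scale_mu: float = 0.5
    prop_scale_logsigma: float = 0.5

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise ConfigError("require iterations > burn_in >= 0")
        if self.chains < 1 or self.thin < 1:
            raise ConfigError("chains and thin must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class SimulationSettings:
    """Monte Carlo risk-characterization controls: 1,000 iterations, each
    simulating a cohort of ``pop_size`` individuals."""

    n_iterations: int = 1000
    pop_size: int = 1000

    def __post_init__(self) -> None:
        if self.pop_size < 100:
            raise ConfigError("pop_size must be >= 100")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")


@dataclass(frozen=True)
class DeploymentConfig:
    pathways: tuple[PathwaySpec, ...] = field(default_factory=_default_pathways)
    category_map: FrequencyCategoryMap = field(
        default_factory=lambda: FrequencyCategoryMap(DEFAULT_CATEGORIES))
    pool_survey_types: bool = True
    restrict_survey_type: str | None = None
    days_per_month: float = 30.0
    weeks_per_month: float = 4.33
    countable_range: tuple[float, float] = (20.0, 200.0)
    conflict_factor: float = 10.0
    # Multiplier from "per unit amount assayed" to the denominator unit:
    # per_100mL assumes amounts in mL, per_g amounts in g, per_serving holds
    # the serving mass in g, per_swab assumes the full eluate fraction.
    denominator_scales: dict = field(default_factory=lambda: {
        "per_100mL": 100.0, "per_g": 1.0, "per_serving": 100.0, "per_swab": 1.0,
    })
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    min_frequency_obs: int = 5
    dominance_threshold_log10: float = 1.0
    # People Plot shade scale, log10 monthly dose bounds.
    dose_scale: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(set(names)) != len(names):
            raise ConfigError("pathway names must be unique")
        lo, hi = self.countable_range
        if not 0 <= lo < hi:
            raise ConfigError("countable_range must satisfy 0 <= low < high")
        if self.restrict_survey_type is not None and \
                self.restrict_survey_type not in SURVEY_TYPES:
            raise ConfigError(
                f"restrict_survey_type must be one of {SURVEY_TYPES}")

    @property
    def pathway_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pathways)

    @property
    def exposure_pathway_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pathways if p.exposure_pathway)

    def pathway(self, name: str) -> PathwaySpec:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(f"pathway {name!r} not in registry")

    def denominator_scale(self, unit: str) -> float:
        try:
            return float(self.denominator_scales[unit])
        except KeyError:
            raise ConfigError(f"no denominator scale for unit {unit!r}") from None


def default_config() -> DeploymentConfig:
    return DeploymentConfig()


# ----------------------------------------------------------------------------
# Serialization

def _config_to_dict(cfg: DeploymentConfig) -> dict:
    d = asdict(cfg)
    d["category_map"] = [list(c) for c in cfg.category_map.categories]
    d["pathways"] = [asdict(p) for p in cfg.pathways]
    return d


def save_config(cfg: DeploymentConfig, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def load_config(path: str | Path) -> DeploymentConfig:
    """Load a deployment configuration from YAML or JSON.

    Any omitted section falls back to the documented default, so a minimal
    file may override just the category map or just the priors.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        return default_config()
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> DeploymentConfig:
    kw: dict = {}
    if "pathways" in raw:
        kw["pathways"] = tuple(PathwaySpec(**p) for p in raw["pathways"])
    if "category_map" in raw:
        kw["category_map"] = FrequencyCategoryMap(
            tuple((str(lab), float(v)) for lab, v in raw["category_map"]))
    for key in ("pool_survey_types", "restrict_survey_type", "days_per_month",
                "weeks_per_month", "conflict_factor", "denominator_scales",
                "min_frequency_obs", "dominance_threshold_log10"):
        if key in raw:
            kw[key] = raw[key]
    for key in ("countable_range", "dose_scale"):
        if key in raw:
            kw[key] = tuple(raw[key])
    if "priors" in raw:
        kw["priors"] = PriorSpec(**raw["priors"])
    if "mcmc" in raw:
        kw["mcmc"] = McmcSettings(**raw["mcmc"])
    if "simulation" in raw:
        kw["simulation"] = SimulationSettings(**raw["simulation"])
    return DeploymentConfig(**kw)
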