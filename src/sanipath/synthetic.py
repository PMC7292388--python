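"""Synthetic deployments from known ground truth.

Emulates exactly the statistical structure the analysis assumes, so every
stage and the end-to-end pipeline can be tested against known parameters:

* monthly contact counts per respondent ~ NB(r, p), then *encoded* to the
  nearest survey answer category (the inverse of the category-midpoint
  decoding, which deliberately loses information the way a real categorical
  instrument does);
* per-sample true log10 concentration c ~ Normal(mu, sigma); each of 2-3
  ten-fold dilutions of the sample yields a Poisson colony count with mean
  10^c x amount x dilution / denominator_scale (the standard plating noise
  model), written as TNTC above the countable range.

Regeneration with the same seed is byte-identical, and the ground truth is
echoed to JSON alongside the CSVs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import DeploymentConfig, POPULATIONS

DEFAULT_N_HOUSEHOLDS = 100
DEFAULT_N_SAMPLES = 10


@dataclass(frozen=True)
class PathwayTruth:
    """Ground truth for one pathway: NB frequency parameters per population
    and the log-normal concentration parameters."""

    freq: dict  # population -> (r, p)
    mu: float  # log10 concentration, per denominator unit
    sigma: float

    def __post_init__(self) -> None:
        for pop, (r, p) in self.freq.items():
            if r <= 0 or not 0 < p < 1:
                raise ValueError(f"invalid NB({r}, {p}) for {pop}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def nb_mean(self, population: str) -> float:
        r, p = self.freq[population]
        return r * (1 - p) / p


@dataclass(frozen=True)
class GroundTruth:
    """Complete parameter set generating one synthetic deployment.

    The default survey battery matches the recommended deployment: 100
    household surveys plus four school and four community group surveys of
    ~17 participants each, all collecting identical behavior questions.
    """

    pathways: dict  # name -> PathwayTruth
    neighborhood: str = "synthville"
    n_households: int = DEFAULT_N_HOUSEHOLDS
    n_samples_per_pathway: int = DEFAULT_N_SAMPLES
    n_school_surveys: int = 4
    n_community_surveys: int = 4
    participants_per_group: int = 17

    def to_json(self) -> str:
        d = {
            "neighborhood": self.neighborhood,
            "n_households": self.n_households,
            "n_samples_per_pathway": self.n_samples_per_pathway,
            "n_school_surveys": self.n_school_surveys,
            "n_community_surveys": self.n_community_surveys,
            "participants_per_group": self.participants_per_group,
            "pathways": {
                name: {"freq": {pop: list(rp) for pop, rp in t.freq.items()},
                       "mu": t.mu, "sigma": t.sigma}
                for name, t in self.pathways.items()
            },
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            pathways={
                name: PathwayTruth(
                    freq={pop: tuple(rp) for pop, rp in t["freq"].items()},
                    mu=t["mu"], sigma=t["sigma"])
                for name, t in d["pathways"].items()
            },
            neighborhood=d["neighborhood"],
            n_households=d["n_households"],
            n_samples_per_pathway=d["n_samples_per_pathway"],
            n_school_surveys=d.get("n_school_surveys", 4),
            n_community_surveys=d.get("n_community_surveys", 4),
            participants_per_group=d.get("participants_per_group", 17),
        )


def nb_params(mean: float, dispersion: float) -> tuple[float, float]:
    """(r, p) for a negative binomial with the given mean and dispersion r."""
    return dispersion, dispersion / (dispersion + mean)


def default_ground_truth(config: DeploymentConfig | None = None) -> GroundTruth:
    """A plausible urban-neighborhood parameter set.

    Contact rates: drinking water and bathing near daily; raw produce and
    street food a few times weekly; drains/toilets intermittent with heavy
    overdispersion; surface/ocean/flood water rare for most respondents.
    Concentrations span the gradient typically seen across pathways — low
    log10 counts in treated drinking water up to heavily contaminated open
    drains — on each pathway's own denominator unit.
    """
    mk = nb_params
    p = {
        "drinking_water": PathwayTruth(
            {"adult": mk(25, 5.0), "child": mk(25, 5.0)}, mu=1.5, sigma=1.0),
        "bathing_water": PathwayTruth(
            {"adult": mk(20, 2.0), "child": mk(22, 2.0)}, mu=2.0, sigma=1.0),
        "surface_water": PathwayTruth(
            {"adult": mk(0.5, 0.3), "child": mk(1.0, 0.3)}, mu=4.0, sigma=1.0),
        "ocean_water": PathwayTruth(
            {"adult": mk(1.0, 0.3), "child": mk(2.0, 0.3)}, mu=3.0, sigma=1.0),
        "flood_water": PathwayTruth(
            {"adult": mk(0.5, 0.4), "child": mk(1.0, 0.4)}, mu=4.5, sigma=1.0),
        "drain_water": PathwayTruth(
            {"adult": mk(2.0, 0.5), "child": mk(3.0, 0.5)}, mu=6.5, sigma=1.0),
        "toilet_swab": PathwayTruth(
            {"adult": mk(10, 0.8), "child": mk(8, 0.8)}, mu=5.0, sigma=1.2),
        "produce": PathwayTruth(
            {"adult": mk(8, 1.5), "child": mk(6, 1.5)}, mu=4.0, sigma=1.2),
        "street_food": PathwayTruth(
            {"adult": mk(6, 1.0), "child": mk(5, 1.0)}, mu=3.0, sigma=1.0),
    }
    if config is not None:
        p = {k: v for k, v in p.items() if k in config.exposure_pathway_names}
    return GroundTruth(pathways=p)


@dataclass
class SyntheticDeployment:
    survey_csv: str
    samples_csv: str
    truth_json: str
    seed: int

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "surveys": outdir / "surveys.csv",
            "samples": outdir / "samples.csv",
            "truth": outdir / "truth.json",
        }
        paths["surveys"].write_text(self.survey_csv)
        paths["samples"].write_text(self.samples_csv)
        paths["truth"].write_text(self.truth_json)
        return paths


def generate_surveys(truth: GroundTruth, config: DeploymentConfig,
                     seed: int) -> str:
    """Survey CSV for the full recommended battery (household + school +
    community); NB monthly counts per respondent, encoded to the nearest
    answer category.

    Every instrument yields one adult and one child answer per pathway
    (adults report a child aged 5-12; schoolchildren report a household
    adult), so all rows share one schema.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    names = [n for n in config.exposure_pathway_names if n in truth.pathways]
    header = ["respondent_id", "survey_type", "neighborhood"]
    for n in names:
        for pop in POPULATIONS:
            header.append(f"{n}_{pop}")
    lines = [",".join(header)]

    respondents: list[tuple[str, str]] = []
    respondents += [(f"hh{i:04d}", "household")
                    for i in range(truth.n_households)]
    for g in range(truth.n_school_surveys):
        respondents += [(f"sc{g}{i:03d}", "school")
                        for i in range(truth.participants_per_group)]
    for g in range(truth.n_community_surveys):
        respondents += [(f"cm{g}{i:03d}", "community")
                        for i in range(truth.participants_per_group)]

    for rid, stype in respondents:
        row = [rid, stype, truth.neighborhood]
        for n in names:
            t = truth.pathways[n]
            for pop in POPULATIONS:
                r, p = t.freq[pop]
                count = int(rng.negative_binomial(r, p))
                row.append(config.category_map.encode(count))
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"


def _assay_series(mu: float, scale: float,
                  target_count: float = 150.0) -> list[tuple[float, float]]:
    """2-3 ten-fold (amount_assayed, dilution_factor) steps per sample.

    Mirrors bench practice: concentrated matrices (drains, swabs) are
    serially diluted, while dilute ones (treated drinking water) are assayed
    at larger volumes — up to 100 mL filtered — since dilution alone cannot
    raise a low count into the countable range.  The least-dilute step
    targets the upper countable bound at the expected concentration and the
    two further ten-fold steps are more dilute, because field contamination
    skews high and a saturated series (all plates TNTC) loses far more
    information than a series whose top plate saturates.
    """
    ideal = math.log10(target_count * scale / 10 ** mu)
    top = round(ideal)
    series = []
    for e in (top, top - 1, top - 2):
        e = min(e, 2)  # cannot assay more than 100 mL / 100 g-equivalents
        amt_exp = min(max(e, 0), 2)
        pair = (10.0 ** amt_exp, 10.0 ** (e - amt_exp))
        if pair not in series:
            series.append(pair)
    return series


def generate_samples(truth: GroundTruth, config: DeploymentConfig,
                     seed: int) -> str:
    """Environmental-sample CSV with Poisson dilution counts (TNTC above the
    countable range)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    _, hi = config.countable_range
    names = [n for n in config.pathway_names if n in truth.pathways]
    lines = [",".join(("sample_id", "sample_type", "neighborhood", "method",
                       "dilution_factor", "amount_assayed", "count"))]
    for name in names:
        t = truth.pathways[name]
        spec = config.pathway(name)
        scale = config.denominator_scale(spec.denominator_unit)
        series = _assay_series(t.mu, scale)
        for j in range(truth.n_samples_per_pathway):
            c = rng.normal(t.mu, t.sigma)
            sid = f"{name}-{j:03d}"
            for amount, d in series:
                lam = 10 ** c * amount * d / scale
                count = int(rng.poisson(lam)) if lam < 1e7 else int(lam)
                txt = "TNTC" if count > hi else str(count)
                lines.append(",".join((
                    sid, name, truth.neighborhood, "membrane_filtration",
                    f"{d:g}", f"{amount:g}", txt)))
    return "\n".join(lines) + "\n"


def effective_monthly_mean(truth: PathwayTruth, population: str,
                           config: DeploymentConfig,
                           tail: float = 1e-9) -> float:
    """The monthly-contact mean actually identified from categorized data.

    Encoding counts to answer categories and decoding them to (integerized)
    midpoints is lossy; the estimation pipeline targets the mean of the
    decoded counts, not the raw NB mean.  This computes that estimand
    analytically from the NB pmf so recovery tests can separate binning bias
    (a property of the instrument) from estimation error.
    """
    from scipy import stats

    r, p = truth.freq[population]
    kmax = int(stats.nbinom.ppf(1 - tail, r, p)) + 1
    k = np.arange(kmax + 1)
    pmf = stats.nbinom.pmf(k, r, p)
    decoded = np.array([
        math.floor(config.category_map.monthly_count(
            config.category_map.encode(int(c))) + 0.5)
        for c in k
    ], dtype=float)
    return float(np.sum(pmf * decoded) / np.sum(pmf))


def decoding_bias(truth: PathwayTruth, population: str,
                  config: DeploymentConfig) -> float:
    """Signed bias of the category-decoded mean relative to the NB mean."""
    return effective_monthly_mean(truth, population, config) \
        - truth.nb_mean(population)


def generate_deployment(truth: GroundTruth, config: DeploymentConfig,
                        seed: int) -> SyntheticDeployment:
    """Compose the survey and sample generators; echo the ground truth."""
    return SyntheticDeployment(
        survey_csv=generate_surveys(truth, config, seed),
        samples_csv=generate_samples(truth, config, seed),
        truth_json=truth.to_json() + "\n",
        seed=seed,
    )
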