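"""Monte Carlo risk characterization.

Each Monte Carlo iteration propagates parameter uncertainty by drawing one
(r, p) pair from the frequency posterior and one (mu, sigma) pair from the
concentration posterior, then simulates a cohort of individuals: monthly
contact counts f ~ NB(r, p); an individual is *exposed* when f >= 1; each
contact ingests 10^(c + log10 intake) E. coli units where c ~ N(mu, sigma)
is the log10 concentration encountered at that contact and ``intake`` is the
fixed amount ingested per contact (in the concentration's denominator unit).
Iteration statistics are the percent of the cohort exposed and the mean of
per-individual log10 monthly doses among the exposed; the exposure profile
reports their means and 2.5/97.5 percentiles across iterations (1,000 by
default).

Pathways are ranked by population-total exposure
log10(percent_exposed/100 x 10^mean_log10_dose); every pathway within the
dominance threshold (default 1 log10, inclusive) of the maximum is dominant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import ConcentrationPosterior, FrequencyPosterior
from .config import SimulationSettings


class ExposureError(ValueError):
    pass


@dataclass(frozen=True)
class ExposureProfile:
    """Percent exposed and mean log10 monthly dose for one
    pathway x population x neighborhood."""

    pathway: str
    population: str
    neighborhood: str
    percent_exposed: float
    percent_exposed_ci: tuple[float, float]
    mean_log10_dose: float  # nan when no iteration produced an exposed person
    mean_log10_dose_ci: tuple[float, float]
    arithmetic_mean_dose: float
    n_mc_iterations: int
    dose_defined: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.percent_exposed <= 100:
            raise ExposureError("percent_exposed must be in [0, 100]")

    @property
    def population_total_log10(self) -> float:
        """log10 of (fraction exposed x arithmetic-monthly-dose proxy) used
        for dominance ranking; -inf when nobody is exposed."""
        if self.percent_exposed <= 0 or not self.dose_defined:
            return float("-inf")
        return self.mean_log10_dose + math.log10(self.percent_exposed / 100.0)


@dataclass(frozen=True)
class DominantPathwayResult:
    ranked: tuple[tuple[str, float], ...]  # (pathway, population_total_log10)
    dominant: tuple[str, ...]
    threshold_log10: float


@dataclass(frozen=True)
class ProfileComparison:
    pathway: str
    population: str
    d_percent_exposed: float
    d_mean_log10_dose: float


@dataclass(frozen=True)
class PointMassFrequency:
    """Degenerate frequency distribution: every individual has exactly
    ``contacts`` contacts per month.

    The negative-binomial family cannot represent a zero-variance count, so
    validation against closed-form doses and what-if scenarios use this in
    place of a :class:`FrequencyPosterior`.
    """

    contacts: int
    pathway: str = ""
    population: str = ""
    neighborhood: str = ""

    def __post_init__(self) -> None:
        if self.contacts < 0:
            raise ExposureError("contacts must be nonnegative")

    @property
    def draws(self) -> np.ndarray:
        return np.array([[float(self.contacts), 1.0]])


def dose_per_contact(mu: float, sigma: float, intake_amount: float,
                     rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """log10 dose ingested at each of ``size`` contacts.

    Draws log10 concentration c ~ Normal(mu, sigma) and shifts by the fixed
    log10 intake amount: log10(10^c x intake) = c + log10(intake).
    """
    if sigma < 0:
        raise ExposureError("sigma must be nonnegative")
    if intake_amount <= 0:
        raise ExposureError("intake_amount must be positive")
    c = rng.normal(mu, sigma, size)
    return c + math.log10(intake_amount)


def simulate_exposure(freq_post: FrequencyPosterior,
                      conc_post: ConcentrationPosterior,
                      intake_amount: float,
                      settings: SimulationSettings,
                      seed: int) -> ExposureProfile:
    """Run the two-level Monte Carlo simulation for one pathway/population.

    Level 1 (parameter uncertainty): each iteration uses a single posterior
    draw of (r, p) and (mu, sigma).  Level 2 (individual variability): a
    cohort of ``settings.pop_size`` individuals' monthly contacts and
    per-contact doses.  Iterations where nobody is exposed contribute 0% and
    no dose statistic; if that happens in every iteration the profile is
    flagged ``dose_defined=False`` rather than failing.
    """
    fdraws = freq_post.draws
    cdraws = conc_post.draws
    if fdraws.size == 0 or cdraws.size == 0:
        raise ExposureError("posteriors must contain draws")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    nit, pop = settings.n_iterations, settings.pop_size
    log_intake = math.log10(intake_amount) if intake_amount > 0 else None
    if log_intake is None:
        raise ExposureError("intake_amount must be positive")

    pct = np.empty(nit)
    mean_log_dose = np.full(nit, np.nan)
    mean_lin_dose = np.full(nit, np.nan)

    point_mass = isinstance(freq_post, PointMassFrequency)
    fidx = rng.integers(0, fdraws.shape[0], nit)
    cidx = rng.integers(0, cdraws.shape[0], nit)
    for i in range(nit):
        r, p = fdraws[fidx[i]]
        mu, sigma = cdraws[cidx[i]]
        if point_mass:
            f = np.full(pop, int(r), dtype=np.int64)
        else:
            f = rng.negative_binomial(r, p, pop)
        exposed = f > 0
        n_exp = int(exposed.sum())
        pct[i] = 100.0 * n_exp / pop
        if n_exp == 0:
            continue
        contacts = f[exposed]
        total = int(contacts.sum())
        c = rng.normal(mu, sigma, total)
        lin = np.power(10.0, c + log_intake)
        ends = np.cumsum(contacts)
        starts = np.concatenate(([0], ends[:-1]))
        person_dose = np.add.reduceat(lin, starts)
        mean_log_dose[i] = np.log10(person_dose).mean()
        mean_lin_dose[i] = person_dose.mean()

    dose_ok = bool(np.isfinite(mean_log_dose).any())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dose_mean = float(np.nanmean(mean_log_dose)) if dose_ok else float("nan")
        dose_ci = (tuple(np.nanpercentile(mean_log_dose, [2.5, 97.5]))
                   if dose_ok else (float("nan"), float("nan")))
        lin_mean = float(np.nanmean(mean_lin_dose)) if dose_ok else float("nan")
    return ExposureProfile(
        pathway=freq_post.pathway or conc_post.pathway,
        population=freq_post.population,
        neighborhood=freq_post.neighborhood or conc_post.neighborhood,
        percent_exposed=float(pct.mean()),
        percent_exposed_ci=tuple(np.percentile(pct, [2.5, 97.5])),
        mean_log10_dose=dose_mean,
        mean_log10_dose_ci=(float(dose_ci[0]), float(dose_ci[1])),
        arithmetic_mean_dose=lin_mean,
        n_mc_iterations=nit,
        dose_defined=dose_ok,
    )


def identify_dominant(profiles: list[ExposureProfile],
                      threshold_log10: float = 1.0) -> DominantPathwayResult:
    """Rank pathways by population-total exposure and pick the dominant set.

    Expects one profile per pathway (i.e. a single population); the dominant
    set is every pathway whose total is within ``threshold_log10`` of the
    maximum, boundary inclusive.  If no pathway has an exposed population
    the dominant set is empty and a warning is issued.
    """
    if not profiles:
        raise ExposureError("identify_dominant requires at least one profile")
    names = [pr.pathway for pr in profiles]
    if len(set(names)) != len(names):
        raise ExposureError(
            "multiple profiles share a pathway; pass a single population")
    totals = sorted(((pr.pathway, pr.population_total_log10) for pr in profiles),
                    key=lambda t: -t[1])
    finite = [(n, t) for n, t in totals if math.isfinite(t)]
    if not finite:
        warnings.warn("no pathway has an exposed population; dominant set "
                      "is empty")
        return DominantPathwayResult(tuple(totals), (), threshold_log10)
    top = finite[0][1]
    dominant = tuple(n for n, t in finite if t >= top - threshold_log10 - 1e-12)
    return DominantPathwayResult(tuple(totals), dominant, threshold_log10)


def compare_profiles(a: ExposureProfile, b: ExposureProfile) -> ProfileComparison:
    """Signed differences (a - b) in percent exposed and mean log10 dose for
    the same pathway x population, e.g. across replicate deployments."""
    if a.pathway != b.pathway or a.population != b.population:
        raise ExposureError(
            f"cannot compare {a.pathway}/{a.population} with "
            f"{b.pathway}/{b.population}")
    return ProfileComparison(
        pathway=a.pathway, population=a.population,
        d_percent_exposed=a.percent_exposed - b.percent_exposed,
        d_mean_log10_dose=a.mean_log10_dose - b.mean_log10_dose,
    )


def profiles_frame(profiles: list[ExposureProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pathway": p.pathway,
        "population": p.population,
        "neighborhood": p.neighborhood,
        "percent_exposed": p.percent_exposed,
        "percent_exposed_lo": p.percent_exposed_ci[0],
        "percent_exposed_hi": p.percent_exposed_ci[1],
        "mean_log10_dose": p.mean_log10_dose,
        "mean_log10_dose_lo": p.mean_log10_dose_ci[0],
        "mean_log10_dose_hi": p.mean_log10_dose_ci[1],
        "arithmetic_mean_dose": p.arithmetic_mean_dose,
        "n_mc_iterations": p.n_mc_iterations,
        "dose_defined": p.dose_defined,
    } for p in profiles])
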