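"""End-to-end deployment analysis: ingest -> concentrations -> Bayesian fits
-> Monte Carlo exposure -> dominant pathways -> artifacts.

`run_deployment` is the library entry point the CLI wraps: it takes the two
input CSVs plus a configuration and returns a `DeploymentResult` holding all
intermediate and final objects; `write_artifacts` serializes them (CSVs,
SVG plots, Markdown report, JSON manifest) into an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import EstimationError, fit_concentration, fit_frequency
from .config import DeploymentConfig, POPULATIONS, default_config
from .exposure import (ExposureProfile, identify_dominant,
                       profiles_frame, simulate_exposure)
from .microbiology import estimate_concentrations, estimates_frame, \
    parse_samples_csv
from .plots import (PeoplePlotSpec, render_behavior_pie,
                    render_concentration_hist, render_people_plot)
from .report import ReportInputs, generate_report
from .survey import NoDataError, parse_survey_csv, tabulate_frequencies


@dataclass
class DeploymentResult:
    config: DeploymentConfig
    seed: int
    survey_result: object
    samples: list
    concentration_estimates: list
    frequency_posteriors: dict  # (pathway, population) -> FrequencyPosterior
    concentration_posteriors: dict  # pathway -> ConcentrationPosterior
    profiles: list[ExposureProfile]
    dominance: dict  # population -> DominantPathwayResult
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def profile(self, pathway: str, population: str) -> ExposureProfile:
        for p in self.profiles:
            if p.pathway == pathway and p.population == population:
                return p
        raise KeyError(f"no profile for {pathway}/{population}")


def _stable_subseed(seed: int, *tokens) -> int:
    """A reproducible child seed below 2^31 derived from a root seed and a
    tuple of labels (process-independent, unlike built-in str hashing)."""
    h = np.random.SeedSequence(
        seed, spawn_key=tuple(zlib.crc32(str(t).encode()) for t in tokens))
    return int(h.generate_state(1, np.uint32)[0] % (2 ** 31))


def run_deployment(surveys_path: str | Path,
                   samples_path: str | Path,
                   config: DeploymentConfig | None = None,
                   seed: int = 0) -> DeploymentResult:
    """Run the full analysis for one deployment.

    Pathways lacking sufficient behavioral or environmental data are skipped
    with a recorded reason rather than aborting the deployment.
    """
    config = config or default_config()
    sres = parse_survey_csv(surveys_path, config)
    samples = parse_samples_csv(samples_path, config)
    conc_est = estimate_concentrations(samples, config)

    mcmc = dataclasses.replace(config.mcmc, seed=_stable_subseed(seed, "mcmc"))
    freq_posts: dict = {}
    conc_posts: dict = {}
    skipped: list[tuple[str, str]] = []

    for name in config.exposure_pathway_names:
        ests = [e for e in conc_est if e.sample_type == name]
        if not ests:
            skipped.append((name, "no environmental samples"))
            continue
        try:
            conc_posts[name] = fit_concentration(
                ests, config.priors,
                dataclasses.replace(mcmc, seed=_stable_subseed(seed, "conc",
                                                               name)),
                pathway=name,
                neighborhood=ests[0].neighborhood)
        except EstimationError as err:
            skipped.append((name, f"concentration fit failed: {err}"))
            continue
        for pop in POPULATIONS:
            try:
                counts = tabulate_frequencies(sres.records, name, pop, config)
            except NoDataError:
                skipped.append((f"{name}/{pop}", "no behavioral data"))
                continue
            try:
                freq_posts[(name, pop)] = fit_frequency(
                    counts, config.priors,
                    dataclasses.replace(
                        mcmc, seed=_stable_subseed(seed, "freq", name, pop)),
                    pathway=name, population=pop,
                    neighborhood=sres.records[0].neighborhood if sres.records
                    else "",
                    min_obs=config.min_frequency_obs)
            except EstimationError as err:
                skipped.append((f"{name}/{pop}", f"frequency fit failed: {err}"))

    profiles: list[ExposureProfile] = []
    for (name, pop), fpost in freq_posts.items():
        cpost = conc_posts[name]
        intake = config.pathway(name).intake(pop)
        profiles.append(simulate_exposure(
            fpost, cpost, intake, config.simulation,
            seed=_stable_subseed(seed, "mc", name, pop)))

    dominance = {}
    for pop in POPULATIONS:
        pop_profiles = [p for p in profiles if p.population == pop]
        if pop_profiles:
            dominance[pop] = identify_dominant(
                pop_profiles, config.dominance_threshold_log10)

    return DeploymentResult(
        config=config, seed=seed, survey_result=sres, samples=samples,
        concentration_estimates=conc_est,
        frequency_posteriors=freq_posts,
        concentration_posteriors=conc_posts,
        profiles=profiles, dominance=dominance, skipped=skipped)


def write_artifacts(result: DeploymentResult, outdir: str | Path,
                    plots: bool = True) -> dict:
    """Write profiles/posterior CSVs, rejects report, SVG plots, Markdown
    report, and a JSON run manifest; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    prof = profiles_frame(result.profiles)
    paths["profiles"] = outdir / "exposure_profiles.csv"
    prof.to_csv(paths["profiles"], index=False, float_format="%.6g")

    paths["concentrations"] = outdir / "concentration_estimates.csv"
    estimates_frame(result.concentration_estimates).to_csv(
        paths["concentrations"], index=False, float_format="%.6g")

    paths["rejects"] = outdir / "survey_rejects.csv"
    result.survey_result.write_rejects(paths["rejects"])

    post_rows = []
    for (name, pop), post in result.frequency_posteriors.items():
        df = post.frame()
        df.insert(0, "pathway", name)
        df.insert(1, "population", pop)
        post_rows.append(df)
    if post_rows:
        paths["frequency_posteriors"] = outdir / "frequency_posteriors.csv"
        pd.concat(post_rows).to_csv(paths["frequency_posteriors"],
                                    index=False, float_format="%.6g")
    post_rows = []
    for name, post in result.concentration_posteriors.items():
        df = post.frame()
        df.insert(0, "pathway", name)
        post_rows.append(df)
    if post_rows:
        paths["concentration_posteriors"] = \
            outdir / "concentration_posteriors.csv"
        pd.concat(post_rows).to_csv(paths["concentration_posteriors"],
                                    index=False, float_format="%.6g")

    if plots:
        plot_dir = outdir / "plots"
        plot_dir.mkdir(exist_ok=True)
        cfg = result.config
        for p in result.profiles:
            spec = PeoplePlotSpec(
                percent_exposed=p.percent_exposed,
                mean_log10_dose=p.mean_log10_dose if p.dose_defined else None,
                pathway=p.pathway, population=p.population,
                neighborhood=p.neighborhood, dose_scale=cfg.dose_scale)
            (plot_dir / f"people_{p.pathway}_{p.population}.svg").write_text(
                render_people_plot(spec))
        for name, post in result.concentration_posteriors.items():
            ests = [e for e in result.concentration_estimates
                    if e.sample_type == name]
            (plot_dir / f"hist_{name}.svg").write_text(
                render_concentration_hist(ests, title=name))
        for (name, pop), fpost in result.frequency_posteriors.items():
            counts = tabulate_frequencies(
                result.survey_result.records, name, pop, cfg)
            (plot_dir / f"pie_{name}_{pop}.svg").write_text(
                render_behavior_pie(counts, cfg.category_map,
                                    title=f"{name} ({pop})"))
        paths["plots"] = plot_dir

    report = generate_report(ReportInputs(
        profiles=result.profiles,
        dominance=result.dominance,
        metadata={"seed": result.seed,
                  "n_survey_rows": result.survey_result.n_rows,
                  "n_samples": len(result.samples)},
    ))
    paths["report"] = outdir / "report.md"
    paths["report"].write_text(report)

    manifest = {
        "version": __version__,
        "seed": result.seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "skipped": result.skipped,
        "n_profiles": len(result.profiles),
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
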