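"""Automated assessment report: key findings, exposure profiles, dominant
pathways, and keyed intervention recommendations, rendered to Markdown.

Report content is a pure function of the analysis results and the
recommendation library; the run timestamp appears only in the metadata
header so that regenerating from the same results yields identical findings
sections.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .exposure import ExposureProfile


class ReportError(ValueError):
    pass


def load_recommendations(path: str | Path | None = None) -> dict:
    """Load the pathway-keyed recommendation text library (user-editable
    YAML; the shipped default is a structural template)."""
    if path is not None:
        return yaml.safe_load(Path(path).read_text())
    with resources.files("sanipath.data").joinpath(
            "recommendations.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class ReportInputs:
    profiles: list[ExposureProfile]
    dominance: dict  # population -> DominantPathwayResult
    metadata: dict


def _profile_table(profiles: list[ExposureProfile]) -> str:
    rows = ["| pathway | population | neighborhood | % exposed (95% CrI) | "
            "mean log10 dose/month (95% CrI) |",
            "|---|---|---|---|---|"]
    for p in sorted(profiles, key=lambda q: (q.neighborhood, q.population,
                                             q.pathway)):
        if p.dose_defined:
            dose = (f"{p.mean_log10_dose:.2f} "
                    f"({p.mean_log10_dose_ci[0]:.2f}-"
                    f"{p.mean_log10_dose_ci[1]:.2f})")
        else:
            dose = "undefined (no exposed individuals)"
        rows.append(
            f"| {p.pathway} | {p.population} | {p.neighborhood} | "
            f"{p.percent_exposed:.1f} ({p.percent_exposed_ci[0]:.1f}-"
            f"{p.percent_exposed_ci[1]:.1f}) | {dose} |")
    return "\n".join(rows)


def generate_report(inputs: ReportInputs,
                    recommendations: dict | None = None) -> str:
    """Render the assessment report as Markdown.

    Every dominant pathway must have an entry in the recommendation library;
    a missing key is an error naming the pathway rather than a silent gap.
    """
    if not inputs.profiles:
        raise ReportError("cannot generate a report without exposure profiles")
    recommendations = recommendations or load_recommendations()

    lines = ["# Fecal exposure assessment report", ""]
    for k, v in inputs.metadata.items():
        lines.append(f"- **{k}**: {v}")
    lines += [
        "",
        "## Methods summary",
        "",
        "Behavioral surveys provided contact frequencies per pathway "
        "(negative-binomial model); environmental samples provided log10 "
        "E. coli concentrations (log-normal model with censoring). "
        "Posterior distributions were estimated by MCMC and combined in "
        "Monte Carlo simulation with fixed per-contact intake amounts to "
        "estimate the percent of the population exposed and the mean log10 "
        "monthly dose per pathway, for adults and children aged 5-12.",
        "",
        "## Exposure profiles",
        "",
        _profile_table(inputs.profiles),
        "",
        "## Dominant pathways",
        "",
    ]
    dominant_all: list[str] = []
    for pop, res in sorted(inputs.dominance.items()):
        if not res.dominant:
            lines.append(f"- **{pop}**: no exposed population on any pathway")
            continue
        lines.append(f"- **{pop}**: {', '.join(res.dominant)} "
                     f"(within {res.threshold_log10:g} log10 of the maximum "
                     "population-total exposure)")
        dominant_all.extend(res.dominant)
    lines += ["", "## Recommendations", ""]
    seen = set()
    for pw in dominant_all:
        if pw in seen:
            continue
        seen.add(pw)
        if pw not in recommendations:
            raise ReportError(
                f"no recommendation text for dominant pathway {pw!r}")
        lines.append(f"### {pw}")
        lines.append("")
        lines.append(str(recommendations[pw]).strip())
        lines.append("")
    if not dominant_all:
        lines.append("No dominant pathway identified.")
    return "\n".join(lines) + "\n"
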