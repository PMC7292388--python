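"""Behavioral-survey ingestion: parse CSVs, validate rows, and convert
categorical contact-frequency answers to monthly counts.

Three survey instruments (household, school, community) collect identical
behavior-frequency questions; by default they are pooled for estimation.
Adults report their own behavior and that of one child aged 5-12, so each
pathway contributes an ``<pathway>_adult`` and an ``<pathway>_child`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import (DeploymentConfig, FrequencyCategoryMap, POPULATIONS,
                     SURVEY_TYPES)

MANDATORY_COLUMNS = ("respondent_id", "survey_type", "neighborhood")


class SurveyFormatError(ValueError):
    """Fatal structural problem with a survey file (e.g. missing column)."""


class NoDataError(ValueError):
    """A filter matched no behavioral observations."""


@dataclass(frozen=True)
class SurveyRecord:
    """One respondent's answers: pathway -> {population -> category label}."""

    respondent_id: str
    survey_type: str
    neighborhood: str
    answers: dict  # pathway -> {"adult": label | None, "child": label | None}
    collected_on: str | None = None


@dataclass(frozen=True)
class BehaviorObservation:
    """A single converted observation: contacts per month for one
    respondent x pathway x population."""

    pathway: str
    population: str
    monthly_count: float
    respondent_id: str
    neighborhood: str


@dataclass
class RejectedRow:
    row_number: int  # 1-based data-row index
    respondent_id: str
    reason: str


@dataclass
class SurveyParseResult:
    records: list[SurveyRecord] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.records) + len(self.rejects)

    def rejects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.row_number, r.respondent_id, r.reason) for r in self.rejects],
            columns=["row_number", "respondent_id", "reason"],
        )

    def write_rejects(self, path: str | Path) -> None:
        self.rejects_frame().to_csv(path, index=False)


def category_to_monthly(label: str, cat_map: FrequencyCategoryMap) -> float:
    """Monthly contact count for a categorical answer (pure lookup)."""
    return cat_map.monthly_count(label)


def survey_columns(config: DeploymentConfig) -> list[str]:
    """The full expected header for a survey CSV under ``config``."""
    cols = list(MANDATORY_COLUMNS)
    for name in config.exposure_pathway_names:
        for pop in POPULATIONS:
            cols.append(f"{name}_{pop}")
    return cols


def parse_survey_csv(path: str | Path,
                     config: DeploymentConfig) -> SurveyParseResult:
    """Parse and validate a behavioral survey CSV.

    Rows that fail validation (unknown survey type, answer label outside the
    configured category map) are collected into the rejects report with the
    offending value named; they are never silently dropped.  A missing
    mandatory column is fatal.  Empty answer cells are legal and mean "not
    asked / no answer" — the respondent is simply excluded from that
    pathway's tabulation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SurveyFormatError(
                f"survey file {path.name} is missing mandatory column {col!r}")

    answer_cols: list[tuple[str, str, str]] = []  # (column, pathway, population)
    for col in df.columns:
        for pop in POPULATIONS:
            suffix = f"_{pop}"
            if col.endswith(suffix):
                pw = col[: -len(suffix)]
                if pw in config.pathway_names:
                    answer_cols.append((col, pw, pop))
    if not answer_cols:
        raise SurveyFormatError(
            f"survey file {path.name} has no <pathway>_<population> columns "
            "matching the configured pathway registry")

    valid_labels = set(config.category_map.labels)
    result = SurveyParseResult()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        rid = rowd["respondent_id"].strip()
        stype = rowd["survey_type"].strip()
        reasons: list[str] = []
        if not rid:
            reasons.append("empty respondent_id")
        if stype not in SURVEY_TYPES:
            reasons.append(f"unknown survey_type {stype!r}")
        answers: dict = {}
        for col, pw, pop in answer_cols:
            raw = rowd[col].strip()
            if not raw:
                continue
            if raw not in valid_labels:
                reasons.append(f"unknown category label {raw!r} in {col}")
                continue
            answers.setdefault(pw, {})[pop] = raw
        if reasons:
            result.rejects.append(RejectedRow(i, rid, "; ".join(reasons)))
            continue
        result.records.append(SurveyRecord(
            respondent_id=rid,
            survey_type=stype,
            neighborhood=rowd["neighborhood"].strip(),
            answers=answers,
            collected_on=rowd.get("collected_on") or None,
        ))
    return result


def to_observations(records: list[SurveyRecord],
                    config: DeploymentConfig) -> list[BehaviorObservation]:
    """Convert parsed records to monthly-count observations."""
    obs = []
    for rec in records:
        for pw, pops in rec.answers.items():
            for pop, label in pops.items():
                obs.append(BehaviorObservation(
                    pathway=pw,
                    population=pop,
                    monthly_count=category_to_monthly(label, config.category_map),
                    respondent_id=rec.respondent_id,
                    neighborhood=rec.neighborhood,
                ))
    return obs


def tabulate_frequencies(records: list[SurveyRecord],
                         pathway: str,
                         population: str,
                         config: DeploymentConfig,
                         neighborhood: str | None = None,
                         survey_type: str | None = None) -> list[float]:
    """Monthly contact counts for every respondent answering ``pathway`` for
    ``population``, optionally restricted to one neighborhood/survey type.

    Survey types are pooled unless ``survey_type`` (or the config's
    ``restrict_survey_type``) narrows them, since all three instruments
    collect identical behavior questions.  Respondents with no answer for
    the pathway are excluded, not imputed as zero.
    """
    survey_type = survey_type or config.restrict_survey_type
    counts: list[float] = []
    for rec in records:
        if neighborhood is not None and rec.neighborhood != neighborhood:
            continue
        if survey_type is not None and rec.survey_type != survey_type:
            continue
        label = rec.answers.get(pathway, {}).get(population)
        if label is None:
            continue
        counts.append(category_to_monthly(label, config.category_map))
    if not counts:
        raise NoDataError(
            f"no behavioral data for pathway {pathway!r} "
            f"(population={population!r}, neighborhood={neighborhood!r})")
    return counts
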