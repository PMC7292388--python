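"""E. coli concentration estimation from multi-dilution plate/tray readings.

Each environmental sample is assayed at two to three serial dilutions
(membrane filtration colony counts or IDEXX tray MPN values).  A selection
step picks the dilutions whose counts fall in the countable range (default
20-200 colonies), concentrations are computed per reading as

    count / (amount_assayed x dilution_factor) x denominator_scale

and combined as the mean on the log10 scale (geometric mean), matching the
log-normal model used downstream.  Samples with no colonies at any dilution
are left-censored at the detection limit; too-numerous-to-count (TNTC) plates
at the most dilute level are right-censored at the countable range's upper
bound.  Discordant adjacent dilutions (implied concentrations differing by
the conflict factor, default 10x, or more) are flagged for review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import DeploymentConfig

MEMBRANE_FILTRATION = "membrane_filtration"
MPN_TRAY = "mpn_tray"
METHODS = (MEMBRANE_FILTRATION, MPN_TRAY)

OBSERVED = "observed"
LEFT_CENSORED = "left_censored"
RIGHT_CENSORED = "right_censored"


class SampleFormatError(ValueError):
    """Fatal structural problem with an environmental-sample file."""


class DilutionError(ValueError):
    """Invalid dilution arithmetic input (empty readings, zero amount...)."""


@dataclass(frozen=True)
class DilutionReading:
    """One plate/tray reading at one dilution.

    ``count`` is the colony count (or pre-computed MPN for tray methods);
    ``None`` encodes TNTC.  ``amount_assayed`` is in mL for liquids, g for
    solids, or fraction-of-eluate for swab/rinse samples.
    """

    dilution_factor: float
    amount_assayed: float
    count: float | None  # None == TNTC
    method: str = MEMBRANE_FILTRATION

    def __post_init__(self) -> None:
        if not 0 < self.dilution_factor <= 1:
            raise DilutionError(
                f"dilution_factor must be in (0, 1], got {self.dilution_factor}")
        if self.amount_assayed <= 0:
            raise DilutionError("amount_assayed must be positive")
        if self.count is not None and self.count < 0:
            raise DilutionError("count must be nonnegative or TNTC")
        if self.method not in METHODS:
            raise DilutionError(f"unknown method {self.method!r}")

    @property
    def is_tntc(self) -> bool:
        return self.count is None


@dataclass(frozen=True)
class EnvironmentalSample:
    sample_id: str
    sample_type: str
    neighborhood: str
    readings: tuple[DilutionReading, ...]
    denominator_unit: str

    def __post_init__(self) -> None:
        if not self.readings:
            raise DilutionError(f"sample {self.sample_id} has no readings")
        if len({r.method for r in self.readings}) > 1:
            raise DilutionError(
                f"sample {self.sample_id} mixes assay methods")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """log10 E. coli concentration for one sample, with censoring status.

    For censored samples ``log10_concentration`` holds log10 of the limit so
    the value is always finite; ``limit`` is the same bound on the linear
    scale in the sample's denominator units.
    """

    sample_id: str
    sample_type: str
    neighborhood: str
    log10_concentration: float
    censoring: str
    denominator_unit: str
    limit: float | None = None
    readings_used: tuple[int, ...] = ()
    conflicts: tuple[str, ...] = ()


def concentration_from_reading(reading: DilutionReading,
                               denominator_scale: float) -> float:
    """Linear-scale concentration implied by a single countable reading."""
    if reading.is_tntc:
        raise DilutionError("cannot compute a concentration from a TNTC reading")
    return reading.count / (reading.amount_assayed * reading.dilution_factor) \
        * denominator_scale


def select_dilutions(readings: list[DilutionReading] | tuple[DilutionReading, ...],
                     valid_range: tuple[float, float]) -> list[int]:
    """Indices of the readings to use for concentration calculation.

    All non-TNTC readings with counts inside ``valid_range`` (inclusive)
    qualify.  If none do, the single reading nearest the range is chosen:
    the highest non-TNTC count when everything is below range, or — when all
    readings saturated — the most dilute TNTC plate, whose flag propagates
    to right-censoring downstream.
    """
    if not readings:
        raise DilutionError("select_dilutions requires at least one reading")
    lo, hi = valid_range
    in_range = [i for i, r in enumerate(readings)
                if not r.is_tntc and lo <= r.count <= hi]
    if in_range:
        return in_range
    numeric = [i for i, r in enumerate(readings) if not r.is_tntc]
    if numeric:
        # distance from the countable range; ties -> higher count
        def dist(i: int) -> tuple[float, float]:
            c = readings[i].count
            return (lo - c if c < lo else c - hi, -c)
        return [min(numeric, key=dist)]
    # every plate TNTC: keep the most dilute one
    return [min(range(len(readings)),
                key=lambda i: readings[i].dilution_factor)]


def flag_conflicts(readings: list[DilutionReading] | tuple[DilutionReading, ...],
                   factor: float = 10.0) -> list[str]:
    """Describe adjacent dilution pairs with discordant implied concentrations.

    Readings are ordered from least to most dilute; a pair is flagged when
    the ratio of implied concentrations reaches ``factor`` (boundary
    inclusive).  Fewer than two numeric readings can never conflict.
    """
    numeric = [(r.dilution_factor, r) for r in readings if not r.is_tntc]
    if len(numeric) < 2:
        return []
    numeric.sort(key=lambda t: -t[0])
    flags = []
    for (d1, r1), (d2, r2) in zip(numeric, numeric[1:]):
        c1 = r1.count / (r1.amount_assayed * r1.dilution_factor)
        c2 = r2.count / (r2.amount_assayed * r2.dilution_factor)
        if c1 == 0 or c2 == 0:
            continue
        ratio = max(c1, c2) / min(c1, c2)
        if ratio >= factor * (1 - 1e-9):
            flags.append(
                f"dilutions {d1:g} and {d2:g} imply concentrations "
                f"differing {ratio:.3g}x (>= {factor:g}x)")
    return flags


def combine_dilutions(sample: EnvironmentalSample,
                      config: DeploymentConfig) -> ConcentrationEstimate:
    """One ConcentrationEstimate per sample, applying selection, log-scale
    averaging, and censoring conventions."""
    scale = config.denominator_scale(sample.denominator_unit)
    lo, hi = config.countable_range
    idx = select_dilutions(sample.readings, config.countable_range)
    chosen = [sample.readings[i] for i in idx]
    conflicts = tuple(flag_conflicts(sample.readings, config.conflict_factor))

    if all(r.is_tntc for r in chosen):
        # saturated even at the most dilute plate: right-censored at the
        # concentration a count of `hi` would imply there
        r = chosen[0]
        limit = hi / (r.amount_assayed * r.dilution_factor) * scale
        return ConcentrationEstimate(
            sample.sample_id, sample.sample_type, sample.neighborhood,
            math.log10(limit), RIGHT_CENSORED, sample.denominator_unit,
            limit=limit, readings_used=tuple(idx), conflicts=conflicts)

    positive = [r for r in chosen if not r.is_tntc and r.count > 0]
    if positive:
        logs = [math.log10(concentration_from_reading(r, scale))
                for r in positive]
        return ConcentrationEstimate(
            sample.sample_id, sample.sample_type, sample.neighborhood,
            sum(logs) / len(logs), OBSERVED, sample.denominator_unit,
            readings_used=tuple(idx), conflicts=conflicts)

    # no colonies anywhere: left-censored at the detection limit of the most
    # sensitive (largest amount x dilution) plate
    sens = max(r.amount_assayed * r.dilution_factor
               for r in sample.readings if not r.is_tntc)
    limit = 1.0 / sens * scale
    return ConcentrationEstimate(
        sample.sample_id, sample.sample_type, sample.neighborhood,
        math.log10(limit), LEFT_CENSORED, sample.denominator_unit,
        limit=limit, readings_used=tuple(idx), conflicts=conflicts)


# ----------------------------------------------------------------------------
# CSV ingestion: one row per sample-dilution.

SAMPLE_COLUMNS = ("sample_id", "sample_type", "neighborhood", "method",
                  "dilution_factor", "amount_assayed", "count")


def _denominator_for(sample_type: str, config: DeploymentConfig) -> str:
    try:
        return config.pathway(sample_type).denominator_unit
    except KeyError:
        raise SampleFormatError(
            f"sample_type {sample_type!r} not in pathway registry") from None


def parse_samples_csv(path: str | Path,
                      config: DeploymentConfig) -> list[EnvironmentalSample]:
    """Read an environmental-sample CSV (one row per sample-dilution) and
    group rows into EnvironmentalSample objects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            raise SampleFormatError(
                f"sample file {path.name} is missing mandatory column {col!r}")

    grouped: dict[str, dict] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        raw_count = row["count"].strip()
        count = None if raw_count.upper() == "TNTC" else float(raw_count)
        reading = DilutionReading(
            dilution_factor=float(row["dilution_factor"]),
            amount_assayed=float(row["amount_assayed"]),
            count=count,
            method=row["method"].strip(),
        )
        entry = grouped.setdefault(sid, {
            "sample_type": row["sample_type"].strip(),
            "neighborhood": row["neighborhood"].strip(),
            "readings": [],
        })
        entry["readings"].append(reading)

    samples = []
    for sid, entry in grouped.items():
        samples.append(EnvironmentalSample(
            sample_id=sid,
            sample_type=entry["sample_type"],
            neighborhood=entry["neighborhood"],
            readings=tuple(entry["readings"]),
            denominator_unit=_denominator_for(entry["sample_type"], config),
        ))
    return samples


def estimate_concentrations(samples: list[EnvironmentalSample],
                            config: DeploymentConfig
                            ) -> list[ConcentrationEstimate]:
    return [combine_dilutions(s, config) for s in samples]


def estimates_frame(estimates: list[ConcentrationEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": e.sample_id,
        "sample_type": e.sample_type,
        "neighborhood": e.neighborhood,
        "log10_concentration": e.log10_concentration,
        "censoring": e.censoring,
        "denominator_unit": e.denominator_unit,
        "limit": e.limit,
        "n_conflicts": len(e.conflicts),
    } for e in estimates])
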