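"""Consumption-survey design and questionnaire processing.

Covers the classical proportion-based sample-size formula
n = u²·P(1−P)/E², the chronic-consumer inclusion rule (consumption at
least once a week — 52 day/yr — sustained for at least three months —
0.25 yr), and the reduction of valid questionnaires to mean exposure
factors (DI, EF, ED, BW).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .data_model import DEFAULT_LIFESPAN_YEARS, ExposureFactors
from .errors import DomainError, EmptyDataError, SchemaError, ValidationError

__all__ = [
    "SurveyRecord",
    "required_sample_size",
    "filter_chronic",
    "summarize_factors",
    "response_rate",
    "read_survey",
    "write_survey",
    "CHRONIC_MIN_FREQ",
    "CHRONIC_MIN_DURATION",
]

CHRONIC_MIN_FREQ = 52.0  # day/yr ≙ once a week
CHRONIC_MIN_DURATION = 0.25  # yr ≙ three months

CONSUMPTION_MODES = ("direct", "tea", "medicine")

SURVEY_COLUMNS = [
    "respondent_id",
    "di_g_per_day",
    "freq_day_per_year",
    "duration_year",
    "bw_kg",
    "age_year",
    "mode",
]


@dataclass(frozen=True)
class SurveyRecord:
    respondent_id: str
    di: float  # g/day
    freq: float  # consumption day/yr
    duration: float  # yr
    bw: float  # kg
    age: float  # yr
    mode: str = "direct"
    valid: bool | None = None  # set by filter_chronic

    def __post_init__(self):
        for name in ("di", "freq", "duration", "bw", "age"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.respondent_id}: {name} must be ≥ 0")
        if self.mode not in CONSUMPTION_MODES:
            raise ValidationError(
                f"{self.respondent_id}: mode must be one of {CONSUMPTION_MODES}"
            )


def required_sample_size(
    u: float, p: float, e: float, ceil: bool = False
) -> int:
    """Minimum survey size n = u²·p(1−p)/e².

    Rounded half-up by default (384.16 → 384); ``ceil=True`` applies the
    conservative ceiling convention instead.  n is maximized at p = 0.5
    for fixed u and e.
    """
    if not 0 < p < 1:
        raise DomainError("p must lie strictly inside (0, 1)")
    if e <= 0 or u <= 0:
        raise DomainError("u and e must be > 0")
    n = u * u * p * (1 - p) / (e * e)
    return math.ceil(n) if ceil else math.floor(n + 0.5)


def filter_chronic(records: Iterable[SurveyRecord]) -> list[SurveyRecord]:
    """Mark each record's validity under the chronic-consumer rule.

    Returns all records with ``valid`` set; both boundaries are inclusive
    (exactly once a week for exactly three months qualifies).
    """
    out = []
    for r in records:
        ok = r.freq >= CHRONIC_MIN_FREQ and r.duration >= CHRONIC_MIN_DURATION
        out.append(replace(r, valid=ok))
    return out


def summarize_factors(
    records: Sequence[SurveyRecord], lt: float = DEFAULT_LIFESPAN_YEARS
) -> ExposureFactors:
    """Arithmetic-mean exposure factors over chronic-valid records.

    Records whose ``valid`` flag is unset are classified on the fly.
    """
    flagged = [
        r if r.valid is not None else filter_chronic([r])[0] for r in records
    ]
    valid = [r for r in flagged if r.valid]
    if not valid:
        raise EmptyDataError("no chronic-valid survey records")
    n = len(valid)
    return ExposureFactors(
        di=sum(r.di for r in valid) / n,
        ef=sum(r.freq for r in valid) / n,
        ed=sum(r.duration for r in valid) / n,
        bw=sum(r.bw for r in valid) / n,
        lt=lt,
    )


def response_rate(participants: int, contacted: int) -> float:
    """Survey response rate in percent."""
    if contacted <= 0 or participants < 0 or participants > contacted:
        raise DomainError("need 0 ≤ participants ≤ contacted, contacted > 0")
    return 100.0 * participants / contacted


def read_survey(path) -> list[SurveyRecord]:
    df = pd.read_csv(path, dtype={"respondent_id": str, "mode": str})
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"survey file missing columns {sorted(missing)}")
    return [
        SurveyRecord(
            respondent_id=str(row["respondent_id"]),
            di=float(row["di_g_per_day"]),
            freq=float(row["freq_day_per_year"]),
            duration=float(row["duration_year"]),
            bw=float(row["bw_kg"]),
            age=float(row["age_year"]),
            mode=str(row["mode"]),
        )
        for _, row in df.iterrows()
    ]


def write_survey(records: Sequence[SurveyRecord], path) -> None:
    pd.DataFrame(
        {
            "respondent_id": [r.respondent_id for r in records],
            "di_g_per_day": [r.di for r in records],
            "freq_day_per_year": [r.freq for r in records],
            "duration_year": [r.duration for r in records],
            "bw_kg": [r.bw for r in records],
            "age_year": [r.age for r in records],
            "mode": [r.mode for r in records],
        }
    ).to_csv(path, index=False, float_format="%.6g")
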