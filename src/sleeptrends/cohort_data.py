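"""Domain types and tabular I/O for per-response cohort records.

One row of cohort data is a single questionnaire response: who answered
(subject and twin-pair ids), when (survey wave), basic covariates (gender,
birth year) and the ordinal sleep-duration category they ticked.  On read the
rows are validated and enriched with the derived age group, birth cohort and
the censoring interval implied by the wave's response scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .interval_mapping import ResponseScheme

INTERVAL = "interval"
LEFT_CENSORED = "left_censored"
RIGHT_CENSORED = "right_censored"

GENDERS = ("female", "male")

#: Age-group labels, in display order.  Boundaries are inclusive; age is
#: computed as survey year minus birth year (no month-level data exists).
AGE_GROUPS = ("18-34", "35-54", "55+")

#: Birth-cohort labels, both endpoints inclusive.
BIRTH_COHORTS = ("<1900", "1900-1919", "1920-1939", "1940-1957")

CSV_COLUMNS = [
    "subject_id",
    "pair_id",
    "wave_year",
    "gender",
    "birth_year",
    "response_category",
]


class CohortDataError(ValueError):
    """Raised when a cohort record fails validation."""


@dataclass(frozen=True)
class CensorInterval:
    """A half-open censoring interval [left, right) on the duration axis (hours).

    ``left_censored`` means the duration is only known to be below ``right``
    (``left`` must be 0); ``right_censored`` means it is only known to be at
    least ``left`` (``right`` is +inf).  Likelihood contributions use
    S(left) - S(right), so the boundary-point convention is immaterial for
    continuous duration models.
    """

    left: float
    right: float
    kind: str = INTERVAL

    def __post_init__(self) -> None:
        if not (self.left >= 0.0):
            raise CohortDataError(f"interval left bound must be >= 0, got {self.left}")
        if not (self.right > self.left):
            raise CohortDataError(
                f"interval right bound must exceed left, got [{self.left}, {self.right})"
            )
        if self.kind not in (INTERVAL, LEFT_CENSORED, RIGHT_CENSORED):
            raise CohortDataError(f"unknown censor kind {self.kind!r}")
        if self.kind == LEFT_CENSORED and self.left != 0.0:
            raise CohortDataError("left-censored interval must start at 0")
        if self.kind == RIGHT_CENSORED and not math.isinf(self.right):
            raise CohortDataError("right-censored interval must end at +inf")

    def contains(self, t: float) -> bool:
        return self.left <= t < self.right


def age_group_of(age: int) -> str:
    """Age-group label for an integer age at survey (must be >= 18)."""
    if age < 18:
        raise CohortDataError(f"age {age} is below the adult range of the study")
    if age <= 34:
        return "18-34"
    if age <= 54:
        return "35-54"
    return "55+"


def birth_cohort_of(birth_year: int) -> str:
    """Birth-cohort label for a birth year (generations of the cohort)."""
    if birth_year < 1900:
        return "<1900"
    if birth_year <= 1919:
        return "1900-1919"
    if birth_year <= 1939:
        return "1920-1939"
    if birth_year <= 1957:
        return "1940-1957"
    raise CohortDataError(f"birth year {birth_year} is outside the cohort range (<=1957)")


@dataclass(frozen=True)
class Observation:
    """One questionnaire response, validated and enriched.

    ``age_at_survey``, ``age_group`` and ``birth_cohort`` are pure functions of
    (wave_year, birth_year); ``interval`` is the censoring interval the wave's
    response scheme assigns to ``response_category``.
    """

    subject_id: str
    pair_id: str
    wave_year: int
    gender: str
    birth_year: int
    response_category: str
    interval: CensorInterval
    age_at_survey: int = field(default=-1)
    age_group: str = field(default="")
    birth_cohort: str = field(default="")

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise CohortDataError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        age = self.wave_year - self.birth_year
        derived_group = age_group_of(age)
        derived_cohort = birth_cohort_of(self.birth_year)
        if self.age_at_survey == -1:
            object.__setattr__(self, "age_at_survey", age)
        elif self.age_at_survey != age:
            raise CohortDataError(
                f"age_at_survey {self.age_at_survey} inconsistent with "
                f"wave {self.wave_year} and birth year {self.birth_year}"
            )
        if not self.age_group:
            object.__setattr__(self, "age_group", derived_group)
        elif self.age_group != derived_group:
            raise CohortDataError(
                f"age_group {self.age_group!r} inconsistent with age {age}"
            )
        if not self.birth_cohort:
            object.__setattr__(self, "birth_cohort", derived_cohort)
        elif self.birth_cohort != derived_cohort:
            raise CohortDataError(
                f"birth_cohort {self.birth_cohort!r} inconsistent with "
                f"birth year {self.birth_year}"
            )


def _validate_pairs(observations: Sequence[Observation]) -> None:
    # both members of a pair share gender and birth year; at most 2 subjects
    pair_subjects: dict[str, dict[str, tuple[str, int]]] = {}
    for i, obs in enumerate(observations):
        members = pair_subjects.setdefault(obs.pair_id, {})
        members[obs.subject_id] = (obs.gender, obs.birth_year)
        if len(members) > 2:
            raise CohortDataError(
                f"row {i}: pair {obs.pair_id!r} has more than two subjects"
            )
        if len({g for g, _ in members.values()}) > 1:
            raise CohortDataError(f"row {i}: pair {obs.pair_id!r} has mixed gender")
        if len({b for _, b in members.values()}) > 1:
            raise CohortDataError(f"row {i}: pair {obs.pair_id!r} has mixed birth years")


def read_responses(path, scheme_registry=None) -> list[Observation]:
    """Read per-response records from CSV and return validated ``Observation``s.

    The CSV must have header columns ``subject_id, pair_id, wave_year, gender,
    birth_year, response_category``.  Rows are validated (known wave, known
    category under the wave's scheme, consistent pairs) and enriched with the
    derived age group, birth cohort and censoring interval.  Row order is
    preserved.  Unknown waves/categories and malformed pairs raise
    :class:`CohortDataError` naming the offending row.
    """
    from .interval_mapping import default_schemes, map_response

    if scheme_registry is None:
        scheme_registry = default_schemes()
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortDataError(f"missing CSV columns: {missing}")
    observations: list[Observation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            wave_year = int(row.wave_year)
        except ValueError:
            raise CohortDataError(f"row {i}: wave_year {row.wave_year!r} is not an integer")
        if wave_year not in scheme_registry:
            raise CohortDataError(f"row {i}: unknown wave_year {wave_year}")
        scheme = scheme_registry[wave_year]
        label = row.response_category
        try:
            interval = map_response(label, scheme)
        except KeyError:
            raise CohortDataError(
                f"row {i}: response_category {label!r} not in scheme "
                f"{scheme.scheme_id!r} of wave {wave_year}"
            )
        try:
            obs = Observation(
                subject_id=row.subject_id,
                pair_id=row.pair_id,
                wave_year=wave_year,
                gender=row.gender,
                birth_year=int(row.birth_year),
                response_category=label,
                interval=interval,
            )
        except (CohortDataError, ValueError) as exc:
            raise CohortDataError(f"row {i}: {exc}") from exc
        observations.append(obs)
    _validate_pairs(observations)
    return observations


def write_responses(observations: Iterable[Observation], path) -> None:
    """Write observations to CSV; round-trips losslessly through read_responses."""
    rows = [
        {
            "subject_id": o.subject_id,
            "pair_id": o.pair_id,
            "wave_year": o.wave_year,
            "gender": o.gender,
            "birth_year": o.birth_year,
            "response_category": o.response_category,
        }
        for o in observations
    ]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def to_frame(observations: Sequence[Observation]) -> pd.DataFrame:
    """Observations as a DataFrame with derived columns and interval bounds."""
    return pd.DataFrame(
        {
            "subject_id": [o.subject_id for o in observations],
            "pair_id": [o.pair_id for o in observations],
            "wave_year": [o.wave_year for o in observations],
            "gender": [o.gender for o in observations],
            "birth_year": [o.birth_year for o in observations],
            "age_at_survey": [o.age_at_survey for o in observations],
            "age_group": [o.age_group for o in observations],
            "birth_cohort": [o.birth_cohort for o in observations],
            "response_category": [o.response_category for o in observations],
            "interval_left": [o.interval.left for o in observations],
            "interval_right": [o.interval.right for o in observations],
            "censor_kind": [o.interval.kind for o in observations],
        }
    )
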