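"""Wave-specific response schemes: ordinal categories to censoring intervals.

The 1975 questionnaire offered seven whole-hour alternatives ("less than 4 h",
"5", ..., "9", "10 h or more"); the 1981, 1990 and 2011 questionnaires offered
nine half-hour alternatives ("6 h or less", "6.5", ..., "9.5", "10 h or
more").  Each interior category is read as "rounded to the nearest offered
value" and mapped to the half-open interval centred on its stated value, with
width equal to the wave's spacing (1.0 h in 1975, 0.5 h later).  The open-ended
lowest and highest categories become left- and right-censored intervals, so
every scheme tiles (0, +inf) with no gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .cohort_data import (
    INTERVAL,
    LEFT_CENSORED,
    RIGHT_CENSORED,
    CensorInterval,
)

WAVE_YEARS = (1975, 1981, 1990, 2011)

#: Per-wave survey metadata: response scheme, inclusive birth-year eligibility
#: and the survey's response rate.  The 1990 wave was restricted to pairs born
#: 1930-1957 and the 2011 wave to twins born 1945-1957; the first two waves
#: covered the whole cohort (born before 1958, adult at survey).
@dataclass(frozen=True)
class SurveyWave:
    year: int
    scheme_id: str
    eligible_birth_years: tuple[int, int]
    response_rate: float

    def __post_init__(self) -> None:
        if not (0.0 < self.response_rate <= 1.0):
            raise ValueError(f"response_rate must be in (0, 1], got {self.response_rate}")


DEFAULT_WAVES: dict[int, SurveyWave] = {
    1975: SurveyWave(1975, "coarse1975", (1880, 1957), 0.89),
    1981: SurveyWave(1981, "half_hour", (1880, 1957), 0.84),
    1990: SurveyWave(1990, "half_hour", (1930, 1957), 0.77),
    2011: SurveyWave(2011, "half_hour", (1945, 1957), 0.72),
}


@dataclass(frozen=True)
class ResponseScheme:
    """An ordered set of (label, interval) categories tiling (0, +inf)."""

    scheme_id: str
    categories: tuple[tuple[str, CensorInterval], ...]
    interior_width: float

    def __post_init__(self) -> None:
        intervals = [iv for _, iv in self.categories]
        if intervals[0].kind != LEFT_CENSORED:
            raise ValueError("first category must be left-censored")
        if intervals[-1].kind != RIGHT_CENSORED:
            raise ValueError("last category must be right-censored")
        for prev, nxt in zip(intervals, intervals[1:]):
            if not math.isclose(prev.right, nxt.left):
                raise ValueError(
                    f"scheme {self.scheme_id!r} does not tile: gap between "
                    f"{prev.right} and {nxt.left}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.categories)

    def __contains__(self, label: str) -> bool:
        return label in self.labels


def _scheme(scheme_id: str, first_label: str, first_right: float,
            interior_values: list[float], last_label: str,
            width: float) -> ResponseScheme:
    cats: list[tuple[str, CensorInterval]] = [
        (first_label, CensorInterval(0.0, first_right, LEFT_CENSORED))
    ]
    for v in interior_values:
        label = f"{v:g}"
        cats.append((label, CensorInterval(v - width / 2, v + width / 2, INTERVAL)))
    last_left = interior_values[-1] + width / 2
    cats.append((last_label, CensorInterval(last_left, math.inf, RIGHT_CENSORED)))
    return ResponseScheme(scheme_id, tuple(cats), width)


def coarse1975_scheme() -> ResponseScheme:
    """Seven whole-hour categories of the 1975 questionnaire.

    "less than 4 h" is mapped to (0, 4.5) so the 1-hour tiling is preserved;
    the options list skips a plain "4", and the open lowest category absorbs
    the gap (this also covers the reading "4 h or less").
    """
    return _scheme("coarse1975", "less than 4 h", 4.5,
                   [5.0, 6.0, 7.0, 8.0, 9.0], "10 h or more", 1.0)


def half_hour_scheme() -> ResponseScheme:
    """Nine half-hour categories used in 1981, 1990 and 2011."""
    return _scheme("half_hour", "6 h or less", 6.25,
                   [6.5, 7.0, 7.5, 8.0, 8.5, 9.0, 9.5], "10 h or more", 0.5)


class SchemeRegistry(dict):
    """Wave year -> ResponseScheme mapping; accepts int or str year keys."""

    def __missing__(self, key):
        if isinstance(key, str) and key.isdigit():
            return self[int(key)]
        raise KeyError(key)

    def __contains__(self, key) -> bool:
        if isinstance(key, str) and key.isdigit():
            key = int(key)
        return dict.__contains__(self, key)


def default_schemes() -> SchemeRegistry:
    """Registry of response schemes for the four survey waves."""
    coarse = coarse1975_scheme()
    half = half_hour_scheme()
    return SchemeRegistry(
        {year: coarse if wave.scheme_id == "coarse1975" else half
         for year, wave in DEFAULT_WAVES.items()}
    )


def map_response(label: str, scheme: ResponseScheme) -> CensorInterval:
    """The unique censoring interval for a category label of a scheme."""
    for lab, interval in scheme.categories:
        if lab == label:
            return interval
    raise KeyError(f"label {label!r} not in scheme {scheme.scheme_id!r}")


def scheme_to_dict(scheme: ResponseScheme) -> dict:
    """Serializable mapping of a scheme (label -> [left, right, kind])."""
    return {
        "scheme_id": scheme.scheme_id,
        "interior_width": scheme.interior_width,
        "categories": [
            [label, iv.left, None if math.isinf(iv.right) else iv.right, iv.kind]
            for label, iv in scheme.categories
        ],
    }


def scheme_from_dict(d: dict) -> ResponseScheme:
    cats = tuple(
        (label, CensorInterval(left, math.inf if right is None else right, kind))
        for label, left, right, kind in d["categories"]
    )
    return ResponseScheme(d["scheme_id"], cats, d["interior_width"])


def save_schemes(registry: SchemeRegistry, path) -> None:
    """Write a scheme registry to YAML so boundary choices can be swapped."""
    payload = {int(year): scheme_to_dict(s) for year, s in registry.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_schemes(path) -> SchemeRegistry:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return SchemeRegistry({int(y): scheme_from_dict(d) for y, d in payload.items()})
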