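"""Descriptive summaries of categorised sleep duration and trend statistics.

Means and standard deviations by survey wave and stratum (gender or age
group) are computed from midpoint-coded responses: every interior category
contributes its stated value, and the open-ended lowest/highest categories
contribute a configurable policy value (by default the stated boundary, e.g.
"10 h or more" -> 10.0 h).  Midpoint coding is used only here, for
descriptives; the regression likelihood always works with the full censoring
intervals.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_data import AGE_GROUPS, GENDERS, Observation
from .cohort_data import LEFT_CENSORED, RIGHT_CENSORED
from .interval_mapping import ResponseScheme, default_schemes

#: Supported open-category policies for midpoint coding.
OPEN_CATEGORY_POLICIES = ("boundary_value", "interval_bound")

GROUPINGS = ("gender", "age_group", "wave_gender", "wave_age_group")


def category_midpoint(label: str, scheme: ResponseScheme,
                      open_category_policy: str = "boundary_value") -> float:
    """Point value representing a response category for descriptive means.

    Interior categories return their stated value (the interval midpoint).
    For the open-ended categories, ``boundary_value`` returns the stated
    number in the label ("6 h or less" -> 6.0, "10 h or more" -> 10.0,
    "less than 4 h" -> 4.0); ``interval_bound`` returns the finite interval
    endpoint itself (6.25, 9.75, ...).
    """
    if open_category_policy not in OPEN_CATEGORY_POLICIES:
        raise ValueError(f"unknown open-category policy {open_category_policy!r}")
    for lab, iv in scheme.categories:
        if lab != label:
            continue
        half = scheme.interior_width / 2
        if iv.kind == LEFT_CENSORED:
            return iv.right - half if open_category_policy == "boundary_value" else iv.right
        if iv.kind == RIGHT_CENSORED:
            return iv.left + half if open_category_policy == "boundary_value" else iv.left
        return 0.5 * (iv.left + iv.right)
    raise KeyError(f"label {label!r} not in scheme {scheme.scheme_id!r}")


def _coded_durations(observations: Sequence[Observation], registry,
                     policy: str) -> np.ndarray:
    return np.array([
        category_midpoint(o.response_category, registry[o.wave_year], policy)
        for o in observations
    ])


def summarize(observations: Sequence[Observation], grouping: str,
              open_category_policy: str = "boundary_value",
              scheme_registry=None) -> pd.DataFrame:
    """Mean and SD of midpoint-coded sleep duration per stratum.

    ``grouping`` is one of ``gender``, ``age_group``, ``wave_gender``,
    ``wave_age_group``.  For wave-crossed groupings the full grid of strata is
    emitted; strata with no observations appear as "no data" rows (n = 0, NaN
    mean/SD).  Row order in the input never affects the result.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    if scheme_registry is None:
        scheme_registry = default_schemes()
    factor = "gender" if "gender" in grouping else "age_group"
    levels = GENDERS if factor == "gender" else AGE_GROUPS
    by_wave = grouping.startswith("wave")

    values = _coded_durations(observations, scheme_registry, open_category_policy)
    df = pd.DataFrame({
        "wave_year": [o.wave_year for o in observations],
        "stratum": [getattr(o, factor) for o in observations],
        "value": values,
    })
    waves = sorted(df["wave_year"].unique()) if by_wave else [None]
    rows = []
    for wave in waves:
        sub = df if wave is None else df[df["wave_year"] == wave]
        for level in levels:
            vals = sub.loc[sub["stratum"] == level, "value"]
            n = len(vals)
            rows.append({
                "wave_year": wave if wave is not None else "all",
                "stratum": level,
                "n": n,
                "mean_hours": float(vals.mean()) if n else math.nan,
                "sd_hours": float(vals.std(ddof=0)) if n else math.nan,
                "note": "" if n else "no data",
            })
    return pd.DataFrame(rows)


def trend_minutes_per_year(mean_first: float, mean_last: float,
                           year_first: int, year_last: int) -> float:
    """Average decrease in sleep duration in minutes per year of follow-up.

    Positive values mean sleep got shorter between the two years.
    """
    if year_last <= year_first:
        raise ValueError("year_last must exceed year_first")
    return (mean_first - mean_last) * 60.0 / (year_last - year_first)
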