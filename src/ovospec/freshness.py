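"""Haugh-unit freshness labels.

The Haugh unit (HU) is the standard egg-freshness index computed from thick
albumen (protein) height ``h`` (mm) and egg weight ``w`` (g):

    HU = 100 * log10(h + 7.57 - 1.7 * w**0.37)

During room-temperature storage HU declines approximately linearly with day;
a four-week storage horizon maps onto the USDA-style grades AA, A, B1, B2,
one grade per week.  Grades here are *defined* by the storage week (that is
how the cohorts are labelled), not by HU thresholds, whose published weekly
ranges leave gaps between grades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

GRADES: tuple[str, ...] = ("AA", "A", "B1", "B2")
WEEK_GRADE: dict[int, str] = {1: "AA", 2: "A", 3: "B1", 4: "B2"}

#: HU decline per storage day (units/day) of the linear degradation model.
DEFAULT_SLOPE = -1.75
#: Day-0 intercept (units) of the linear degradation model.
DEFAULT_INTERCEPT = 85.70


def haugh_unit(h: float, w: float) -> float:
    """Haugh unit from protein height ``h`` (mm) and egg weight ``w`` (g).

    Raises
    ------
    ValueError
        If ``h <= 0``, ``w < 0`` or the logarithm argument
        ``h + 7.57 - 1.7 * w**0.37`` is not positive.
    """
    if h <= 0:
        raise ValueError(f"protein height must be positive, got {h}")
    if w < 0:
        raise ValueError(f"weight must be nonnegative, got {w}")
    arg = h + 7.57 - 1.7 * w**0.37
    if arg <= 0:
        raise ValueError(f"Haugh log argument must be positive, got {arg}")
    return 100.0 * math.log10(arg)


def protein_height(hu: float, w: float) -> float:
    """Invert :func:`haugh_unit`: the height (mm) giving ``hu`` at weight ``w``."""
    if w < 0:
        raise ValueError(f"weight must be nonnegative, got {w}")
    h = 10.0 ** (hu / 100.0) - 7.57 + 1.7 * w**0.37
    if h <= 0:
        raise ValueError(f"no positive protein height realises HU={hu} at w={w}")
    return h


@dataclass(frozen=True)
class DegradationFit:
    """OLS fit of HU on storage day."""

    slope: float
    intercept: float
    residual_sd: float
    n: int


def fit_degradation(days, hu) -> DegradationFit:
    """Ordinary least squares of Haugh unit on storage day.

    Residual standard deviation uses n - 2 degrees of freedom (0.0 when
    n == 2, where the line interpolates).
    """
    days = np.asarray(days, dtype=float)
    hu = np.asarray(hu, dtype=float)
    if days.shape != hu.shape or days.ndim != 1:
        raise ValueError("days and hu must be 1-D arrays of equal length")
    n = days.size
    if n < 2 or np.unique(days).size < 2:
        raise ValueError("need at least two distinct days to fit a line")
    slope, intercept = np.polyfit(days, hu, 1)
    resid = hu - (intercept + slope * days)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return DegradationFit(float(slope), float(intercept), residual_sd, int(n))


def grade_of_day(day: int) -> str:
    """Freshness grade of storage day 1-28 (week 1→AA ... week 4→B2).

    Days beyond 28 fall into the spoiled range, which the grading table does
    not cover; they raise.
    """
    if int(day) != day:
        raise ValueError(f"day must be an integer, got {day}")
    day = int(day)
    if not 1 <= day <= 28:
        raise ValueError(f"day must be in 1..28, got {day}")
    return WEEK_GRADE[math.ceil(day / 7)]


def grade_code(grade: str) -> int:
    """Numeric code 1..4 for grades AA..B2 (used as regression target y)."""
    try:
        return GRADES.index(grade) + 1
    except ValueError:
        raise ValueError(f"unknown grade {grade!r}") from None
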