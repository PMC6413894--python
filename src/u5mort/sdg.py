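"""Mortality declines, annual rates of reduction, and SDG-3 classification.

The annual rate of reduction (ARR) is the constant yearly proportional
decline equivalent to a total decline D over t years:

    ARR = 100 * (1 - (1 - D)^(1/t))  percent per year,

with D = 1 - rate_end / rate_start.  The SDG-3 child-survival targets are
a neonatal mortality rate of at most 12 and an under-5 mortality rate of
at most 25 deaths per 1,000 live births; countries are classified by
whether their forecasts meet both thresholds by 2030, between 2030 and
2050, or later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

SDG_NMR_TARGET = 12.0   # per 1,000 live births
SDG_U5MR_TARGET = 25.0  # per 1,000 live births


class Category(str, Enum):
    ON_TRACK_2030 = "on-track by 2030"
    BETWEEN_2030_2050 = "between 2030 and 2050"
    AFTER_2050 = "after 2050"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TrendSummary:
    """A period's decline and ARR for one indicator."""

    rate_start: float   # per 1,000
    rate_end: float     # per 1,000
    years: float
    decline: float      # proportion, 1 - rate_end/rate_start
    arr: float          # percent per year


@dataclass(frozen=True)
class SDGAssessment:
    country: str
    nmr_2030: float | None
    u5mr_2030: float | None
    nmr_2050: float | None
    u5mr_2050: float | None
    category: Category


def compute_decline(rate_start: float, rate_end: float) -> float:
    """Proportional decline D = 1 - rate_end/rate_start (negative if rising)."""
    if rate_start <= 0:
        raise ValueError("rate_start must be positive")
    return 1.0 - rate_end / rate_start


def compute_arr(decline: float, years: float) -> float:
    """Annual rate of reduction in percent per year.

    ARR = 100 * (1 - (1 - D)^(1/t)); equivalently
    100 * (1 - (rate_end/rate_start)^(1/t)).
    """
    if decline >= 1.0:
        raise ValueError("decline must be < 1 (a rate cannot fall below zero)")
    if years <= 0:
        raise ValueError("period length must be positive")
    return 100.0 * (1.0 - (1.0 - decline) ** (1.0 / years))


def trend_summary(rate_start: float, rate_end: float, years: float) -> TrendSummary:
    d = compute_decline(rate_start, rate_end)
    return TrendSummary(rate_start=rate_start, rate_end=rate_end, years=years, decline=d, arr=compute_arr(d, years))


def assess_sdg(
    country: str,
    nmr_2030: float | None,
    u5mr_2030: float | None,
    nmr_2050: float | None,
    u5mr_2050: float | None,
) -> SDGAssessment:
    """Classify SDG-3 attainment timing from forecast rates (per 1,000).

    On track by 2030 iff NMR_2030 <= 12 and U5MR_2030 <= 25 (inclusive);
    between 2030 and 2050 iff not by 2030 but both thresholds met by
    2050; otherwise after 2050.  Pass upper forecast bounds instead of
    medians for a conservative assessment.  Missing forecasts give
    ``indeterminate``.
    """

    def _ok(nmr, u5mr):
        if nmr is None or u5mr is None or not (math.isfinite(nmr) and math.isfinite(u5mr)):
            return None
        return nmr <= SDG_NMR_TARGET and u5mr <= SDG_U5MR_TARGET

    ok30 = _ok(nmr_2030, u5mr_2030)
    ok50 = _ok(nmr_2050, u5mr_2050)
    if ok30 is None:
        category = Category.INDETERMINATE
    elif ok30:
        category = Category.ON_TRACK_2030
    elif ok50 is None:
        category = Category.INDETERMINATE
    elif ok50:
        category = Category.BETWEEN_2030_2050
    else:
        category = Category.AFTER_2050
    return SDGAssessment(
        country=country,
        nmr_2030=nmr_2030,
        u5mr_2030=u5mr_2030,
        nmr_2050=nmr_2050,
        u5mr_2050=u5mr_2050,
        category=category,
    )


def assessment_table(assessments: list[SDGAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "country": a.country,
                "nmr_2030": a.nmr_2030,
                "u5mr_2030": a.u5mr_2030,
                "nmr_2050": a.nmr_2050,
                "u5mr_2050": a.u5mr_2050,
                "category": a.category.value,
            }
            for a in assessments
        ]
    )
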