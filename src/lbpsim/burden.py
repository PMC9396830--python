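"""Years lived with disability (YLD) accounting.

Annual YLDs are the survey-weighted person-years spent in each pain
level multiplied by the GBD low-back-pain disability weight mapped to
that level.  Intervention impact is expressed as YLDs averted (base
case minus scenario), as a percentage of all LBP-related YLDs, and as
rates per 1,000 or 100,000 person-years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DisabilityWeightMap",
    "DEFAULT_WEIGHTS",
    "YldSeries",
    "compute_ylds",
    "person_years",
    "ylds_averted",
    "percent_of_total",
    "yld_rate",
]


@dataclass(frozen=True)
class DisabilityWeightMap:
    """Disability weight per pain level (level 0 is full health).

    Defaults map the five survey pain levels onto published GBD LBP
    severity weights: mild 0.020, moderate 0.054, severe 0.272, most
    severe (with leg pain) 0.372.
    """

    weights: tuple[float, ...] = (0.0, 0.020, 0.054, 0.272, 0.372)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.shape != (5,):
            raise ValueError("need 5 weights for pain levels 0-4")
        if w[0] != 0.0:
            raise ValueError("level-0 weight must be 0")
        if np.any(np.diff(w) < 0) or np.any((w < 0) | (w > 1)):
            raise ValueError("weights must be non-decreasing within [0, 1]")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    def weight(self, levels: np.ndarray) -> np.ndarray:
        return np.asarray(self.weights)[np.asarray(levels, int)]


DEFAULT_WEIGHTS = DisabilityWeightMap()


@dataclass
class YldSeries:
    """Per-year weighted YLDs for one scenario."""

    scenario_id: str
    years: np.ndarray
    ylds: np.ndarray
    person_years: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.ylds = np.asarray(self.ylds, float)
        if self.years.shape != self.ylds.shape:
            raise ValueError("years and ylds must align")
        if np.any(self.ylds < 0):
            raise ValueError("YLDs cannot be negative")

    def window(self, start: int, end: int) -> "YldSeries":
        m = (self.years >= start) & (self.years <= end)
        return YldSeries(
            self.scenario_id, self.years[m], self.ylds[m],
            None if self.person_years is None else np.asarray(self.person_years)[m],
        )

    def cumulative(self, start: int | None = None, end: int | None = None) -> float:
        s = self if start is None else self.window(start, end)
        return float(s.ylds.sum())

    def to_frame(self) -> pd.DataFrame:
        d = {"scenario": self.scenario_id, "year": self.years, "ylds": self.ylds}
        if self.person_years is not None:
            d["person_years"] = self.person_years
        return pd.DataFrame(d)


def compute_ylds(
    roster: pd.DataFrame, weights: DisabilityWeightMap = DEFAULT_WEIGHTS
) -> float:
    """Weighted YLDs of the roster's current year.

    Sum of survey_weight x disability-weight(pain level) over active
    back-problem cases; linear in survey weights.
    """
    cases = roster[roster["active"] & roster["has_back_problems"]]
    if len(cases) == 0:
        return 0.0
    levels = cases["pain_level"].to_numpy()
    if np.isnan(levels).any():
        raise ValueError("back-problem case with missing pain level")
    return float(
        np.dot(cases["survey_weight"].to_numpy(), weights.weight(levels))
    )


def person_years(roster: pd.DataFrame) -> float:
    """Weighted active person-years contributed this year."""
    return float(roster.loc[roster["active"], "survey_weight"].sum())


def ylds_averted(
    base: YldSeries, scenario: YldSeries, start: int = 2021, end: int = 2040
) -> tuple[pd.DataFrame, float]:
    """Per-year and cumulative YLDs averted by a scenario vs the base case."""
    b, s = base.window(start, end), scenario.window(start, end)
    if not np.array_equal(b.years, s.years):
        raise ValueError("scenario and base cover different years")
    per_year = pd.DataFrame(
        {"year": b.years, "ylds_averted": b.ylds - s.ylds}
    )
    return per_year, float(per_year["ylds_averted"].sum())


def percent_of_total(averted_cum: float, base_cum: float) -> float:
    """YLDs averted as % of all base-case LBP-related YLDs."""
    if base_cum <= 0:
        raise ValueError("base-case cumulative YLDs must be positive")
    return 100.0 * averted_cum / base_cum


def yld_rate(ylds: float, person_years: float, per: float = 1000.0) -> float:
    """YLD rate per ``per`` person-years."""
    if person_years <= 0:
        raise ValueError("person-years must be positive")
    return ylds / person_years * per
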