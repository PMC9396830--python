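"""Intervention families: weight reduction, ergonomics, exercise therapy.

Three population strategies against LBP burden, applied annually over a
2021-2040 horizon:

* **bmi_reduction** — everyone with BMI >= 25 at the start of the year
  loses a fixed number of BMI units (eligibility re-checked each year;
  hard floor 18.5 kg/m²).  The effect propagates through both the onset
  and the pain linear predictors, where BMI appears.
* **ergonomic** — occupational LBP risk is eliminated (offset reset to
  the clerical reference) for a persistent random fraction of workers,
  or for every worker in specified occupational groups.
* **exercise** — a constant fraction of the eligible patient group
  (back problems, age < 80, pain level < 4) participates each year.
  The effect is either a relative risk of 0.71 on the cumulative odds
  of pain (``rr`` mode) or a 10-point reduction on a 0-100 VAS scale,
  i.e. 0.4 levels on the continuous latent pain scale (``vas`` mode).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .synthpop import OCCUPATION_GROUPS

__all__ = [
    "BMI_FLOOR",
    "BMI_ELIGIBILITY",
    "EXERCISE_RR",
    "VAS_DECREMENT_LEVELS",
    "InterventionSpec",
    "apply_bmi_intervention",
    "apply_ergonomic_intervention",
    "apply_exercise_intervention",
    "exercise_eligible",
    "scenario_catalog",
    "catalog_frame",
]

BMI_FLOOR = 18.5
BMI_ELIGIBILITY = 25.0
EXERCISE_RR = 0.71
#: 10 VAS units on 0-100 mapped linearly to the 5-level (0-4) scale.
VAS_DECREMENT_LEVELS = 10.0 / 100.0 * 4.0

_TYPES = ("base", "bmi_reduction", "ergonomic", "exercise")
_WORK_GROUPS = tuple(g for g in OCCUPATION_GROUPS if g != "not_working")


@dataclass(frozen=True)
class InterventionSpec:
    """One scenario: intervention type, level, target rule and horizon.

    ``level`` is BMI units/year for ``bmi_reduction`` and a coverage
    fraction in [0, 1] for the other families.  ``target`` is
    ``all_overweight``, ``all_workers``, ``eligible_patients`` or a
    tuple of occupational group names.
    """

    id: str
    type: str
    level: float = 0.0
    target: object = None
    exercise_effect_mode: str = "rr"
    start_year: int = 2021
    end_year: int = 2040

    def __post_init__(self) -> None:
        if self.type not in _TYPES:
            raise ValueError(f"unknown intervention type {self.type!r}")
        if self.start_year > self.end_year:
            raise ValueError("start_year must not exceed end_year")
        if self.type == "bmi_reduction" and self.level < 0:
            raise ValueError("BMI reduction level must be non-negative")
        if self.type in ("ergonomic", "exercise") and not (
            isinstance(self.target, tuple) or 0.0 <= self.level <= 1.0
        ):
            raise ValueError("coverage must lie in [0, 1]")
        if self.exercise_effect_mode not in ("rr", "vas"):
            raise ValueError("exercise_effect_mode must be 'rr' or 'vas'")
        if isinstance(self.target, tuple):
            unknown = set(self.target) - set(_WORK_GROUPS)
            if unknown:
                raise ValueError(f"unknown occupation groups: {sorted(unknown)}")

    @property
    def is_base(self) -> bool:
        return self.type == "base"

    def active_in(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["target"], tuple):
            d["target"] = list(d["target"])
        return d


def apply_bmi_intervention(
    roster: pd.DataFrame, spec: InterventionSpec, year: int
) -> pd.DataFrame:
    """One year of gradual weight reduction for the overweight."""
    if spec.level < 0:
        raise ValueError("BMI reduction level must be non-negative")
    if not spec.active_in(year):
        return roster
    roster = roster.copy()
    mask = roster["active"] & (roster["bmi"] >= BMI_ELIGIBILITY)
    roster.loc[mask, "bmi"] = np.maximum(
        roster.loc[mask, "bmi"] - spec.level, BMI_FLOOR
    )
    return roster


def apply_ergonomic_intervention(
    roster: pd.DataFrame, spec: InterventionSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Eliminate occupational risk for a persistent subset of workers.

    Coverage targeting protects a random ``level`` fraction of workers;
    group targeting protects every worker in the named groups.
    Membership, once granted, is never revoked, and annual re-application
    tops coverage up so late entrants are protected at the same rate.
    """
    roster = roster.copy()
    worker = roster["active"] & roster["occupation"].isin(_WORK_GROUPS)
    if isinstance(spec.target, tuple):
        roster.loc[worker & roster["occupation"].isin(spec.target), "ergo_protected"] = True
        return roster
    if not 0.0 <= spec.level <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    protected = roster["ergo_protected"] & worker
    want = spec.level * int(worker.sum())
    shortfall = int(round(want - int(protected.sum())))
    if shortfall > 0:
        pool = roster.index[worker & ~roster["ergo_protected"]]
        pick = rng.choice(pool, size=min(shortfall, len(pool)), replace=False)
        roster.loc[pick, "ergo_protected"] = True
    return roster


def exercise_eligible(roster: pd.DataFrame) -> pd.Series:
    """Exercise target group: cases under 80 without most-severe pain."""
    return (
        roster["active"]
        & roster["has_back_problems"]
        & (roster["age"] < 80)
        & (roster["pain_level"] < 4)
    )


def apply_exercise_intervention(
    roster: pd.DataFrame, spec: InterventionSpec, year: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Top participation up to ``level`` x |eligible| for the year.

    Participants persist while they stay eligible; anyone who ages past
    80 or reaches pain level 4 drops out, and new participants are drawn
    to restore the target coverage.
    """
    if not 0.0 <= spec.level <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    roster = roster.copy()
    if not spec.active_in(year):
        roster["exercising"] = False
        return roster
    elig = exercise_eligible(roster)
    roster.loc[~elig, "exercising"] = False
    current = int((roster["exercising"] & elig).sum())
    want = int(round(spec.level * int(elig.sum())))
    if want > current:
        pool = roster.index[elig & ~roster["exercising"]]
        pick = rng.choice(pool, size=min(want - current, len(pool)), replace=False)
        roster.loc[pick, "exercising"] = True
    return roster


def scenario_catalog() -> list[InterventionSpec]:
    """The preset scenario grid: one base case, 18 weight-reduction
    intensities, 10 ergonomic scenarios (5 coverages + 5 group
    targets; group 3 is already at reference risk), and 10 exercise
    scenarios (5 coverages x {rr, vas}) — 39 scenarios in all."""
    specs = [InterventionSpec(id="base", type="base")]
    bmi_levels = [round(0.1 * k, 1) for k in range(1, 10)] + [
        1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0
    ]
    for lv in bmi_levels:
        specs.append(
            InterventionSpec(
                id=f"bmi_{lv}", type="bmi_reduction", level=lv, target="all_overweight"
            )
        )
    for cov in (0.2, 0.4, 0.6, 0.8, 1.0):
        specs.append(
            InterventionSpec(
                id=f"ergo_{int(cov*100)}", type="ergonomic", level=cov,
                target="all_workers",
            )
        )
    for groups in (("group_1",), ("group_2",), ("group_4", "group_5"),
                   ("group_6",), ("group_7",)):
        gid = "&".join(g.split("_")[1] for g in groups)
        specs.append(
            InterventionSpec(id=f"ergo_group_{gid}", type="ergonomic", target=groups)
        )
    for mode in ("rr", "vas"):
        for cov in (0.2, 0.4, 0.6, 0.8, 1.0):
            specs.append(
                InterventionSpec(
                    id=f"exercise_{mode}_{int(cov*100)}", type="exercise",
                    level=cov, target="eligible_patients",
                    exercise_effect_mode=mode,
                )
            )
    return specs


def catalog_frame(specs: Sequence[InterventionSpec] | None = None) -> pd.DataFrame:
    """Tabular export of a scenario catalog."""
    specs = scenario_catalog() if specs is None else list(specs)
    return pd.DataFrame([s.to_dict() for s in specs])
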