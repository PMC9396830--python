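"""Open-population demography: aging, mortality, entry and exit.

The adult population is open: people enter by turning 20 or by
immigration and leave by emigration or death.  Mortality comes from an
(age, sex, year) schedule; entry/exit flows are usually not observed
directly and are instead *calibrated* so that a deterministic
cohort-component projection of weighted totals reproduces target
age/sex population totals year by year.

Within a simulated year events are applied in a fixed order —
mortality, emigration, aging, entries — so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthpop import PopulationMargins, sample_covariates

__all__ = [
    "AGE_MAX",
    "SEXES",
    "ScheduleError",
    "MortalitySchedule",
    "FlowSchedule",
    "gompertz_mortality",
    "advance_demography",
    "project_totals",
    "totals_from_roster",
    "calibrate_flows",
    "growth_targets",
]

AGE_MAX = 110
SEXES = ("male", "female")


class ScheduleError(KeyError):
    """A demographic schedule is missing a required (age, sex, year) cell."""


class MortalitySchedule:
    """Annual death probabilities by age, sex and calendar year.

    Stored as per-sex arrays over single ages; a schedule built without
    a year dimension applies to every simulated year.
    """

    def __init__(self, q_by_sex: dict[str, np.ndarray],
                 q_by_year: dict[tuple[int, str], np.ndarray] | None = None):
        for sex, q in q_by_sex.items():
            q = np.asarray(q, float)
            if q.shape != (AGE_MAX + 1,):
                raise ValueError(f"q[{sex}] must cover ages 0..{AGE_MAX}")
            if np.any((q < 0) | (q > 1)):
                raise ValueError(f"q[{sex}] has entries outside [0, 1]")
            q_by_sex[sex] = q
        self._base = q_by_sex
        self._by_year = q_by_year or {}

    def q(self, year: int, sex: str, ages: np.ndarray) -> np.ndarray:
        tab = self._by_year.get((year, sex), self._base.get(sex))
        if tab is None:
            raise ScheduleError(f"no mortality for sex={sex!r}, year={year}")
        ages = np.asarray(ages)
        if np.any(ages > AGE_MAX) or np.any(ages < 0):
            bad = int(ages[(ages > AGE_MAX) | (ages < 0)][0])
            raise ScheduleError(
                f"mortality schedule has no cell for age={bad}, sex={sex!r}, year={year}"
            )
        return tab[ages]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, q in self._base.items():
            for age, v in enumerate(q):
                rows.append((-1, sex, age, v))
        for (year, sex), q in self._by_year.items():
            for age, v in enumerate(q):
                rows.append((year, sex, age, v))
        return pd.DataFrame(rows, columns=["year", "sex", "age", "q"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MortalitySchedule":
        need = {"year", "sex", "age", "q"}
        if not need <= set(df.columns):
            raise ValueError(f"mortality table needs columns {sorted(need)}")
        base: dict[str, np.ndarray] = {}
        by_year: dict[tuple[int, str], np.ndarray] = {}
        for (year, sex), g in df.groupby(["year", "sex"]):
            q = np.zeros(AGE_MAX + 1)
            q[g["age"].to_numpy()] = g["q"].to_numpy()
            if year == -1:
                base[sex] = q
            else:
                by_year[(int(year), sex)] = q
        return cls(base, by_year)


def gompertz_mortality(
    life_expectancy: dict[str, float] | None = None, b: float = 0.095
) -> MortalitySchedule:
    """Gompertz preset q(age) = min(1, a·e^{b·age}) with the sex-specific
    level ``a`` solved numerically so period life expectancy at birth
    matches the target (defaults ~80 male / ~84 female)."""
    life_expectancy = life_expectancy or {"male": 80.0, "female": 84.0}
    ages = np.arange(AGE_MAX + 1)

    def e0(a: float) -> float:
        q = np.minimum(1.0, a * np.exp(b * ages))
        surv = np.concatenate([[1.0], np.cumprod(1 - q)])
        # person-years: survivors live half the year of death on average
        return float(np.sum((surv[:-1] + surv[1:]) / 2))

    out = {}
    for sex, target in life_expectancy.items():
        lo, hi = 1e-8, 1e-2
        for _ in range(80):  # bisection on log-level
            mid = np.sqrt(lo * hi)
            if e0(mid) > target:
                lo = mid
            else:
                hi = mid
        out[sex] = np.minimum(1.0, np.sqrt(lo * hi) * np.exp(b * ages))
    return MortalitySchedule(out)


@dataclass
class FlowSchedule:
    """Calibrated population flows.

    ``entries``: weighted entrant counts by (year, sex, age) — age-20
    entries are cohorts aging in, older ages are immigrants.
    ``exit_prob``: annual emigration probabilities by (year, sex, age).
    """

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["year", "sex", "age", "count"])
    )
    exit_prob: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["year", "sex", "age", "prob"])
    )

    def __post_init__(self) -> None:
        if len(self.entries) and (self.entries["count"] < 0).any():
            raise ValueError("entry counts must be non-negative")
        if len(self.exit_prob):
            p = self.exit_prob["prob"]
            if ((p < 0) | (p > 1)).any():
                raise ValueError("exit probabilities must lie in [0, 1]")
        self._entry_idx = (
            self.entries.set_index(["year", "sex", "age"])["count"]
            if len(self.entries) else pd.Series(dtype=float)
        )
        self._exit_idx = (
            self.exit_prob.set_index(["year", "sex", "age"])["prob"]
            if len(self.exit_prob) else pd.Series(dtype=float)
        )

    def entries_for(self, year: int) -> pd.DataFrame:
        if not len(self.entries):
            return self.entries
        return self.entries[self.entries["year"] == year]

    def exit_for(self, year: int, sex: str, ages: np.ndarray) -> np.ndarray:
        out = np.zeros(len(ages))
        if not len(self._exit_idx):
            return out
        for i, a in enumerate(np.asarray(ages)):
            out[i] = self._exit_idx.get((year, sex, int(a)), 0.0)
        return out

    def exit_lookup(self, year: int) -> dict[str, np.ndarray]:
        """Dense per-sex exit-probability arrays for one year."""
        out = {s: np.zeros(AGE_MAX + 1) for s in SEXES}
        if len(self.exit_prob):
            g = self.exit_prob[self.exit_prob["year"] == year]
            for sex, gg in g.groupby("sex"):
                out[sex][gg["age"].to_numpy()] = gg["prob"].to_numpy()
        return out


def totals_from_roster(roster: pd.DataFrame) -> pd.DataFrame:
    """Weighted (sex, age) population totals of the active roster."""
    active = roster[roster["active"]]
    g = (
        active.groupby(["sex", "age"], observed=True)["survey_weight"]
        .sum()
        .reset_index()
        .rename(columns={"survey_weight": "total"})
    )
    return g


def _totals_to_arrays(totals: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {s: np.zeros(AGE_MAX + 1) for s in SEXES}
    for sex, g in totals.groupby("sex"):
        out[sex][g["age"].to_numpy()] += g["total"].to_numpy()
    return out


def project_totals(
    initial: pd.DataFrame,
    mortality: MortalitySchedule,
    flows: FlowSchedule,
    years: range,
) -> pd.DataFrame:
    """Deterministic cohort-component projection of weighted totals.

    Applies, in expectation, the same event order as the stochastic
    step: mortality, emigration, aging, entries.  Returns long-format
    totals with the initial year included.
    """
    arr = _totals_to_arrays(initial)
    rows = []
    y0 = years[0]
    for sex in SEXES:
        for age in range(AGE_MAX + 1):
            if arr[sex][age] > 0:
                rows.append((y0, sex, age, arr[sex][age]))
    ages = np.arange(AGE_MAX + 1)
    for year in years[:-1]:
        exit_p = flows.exit_lookup(year)
        nxt = {s: np.zeros(AGE_MAX + 1) for s in SEXES}
        for sex in SEXES:
            q = mortality.q(year, sex, ages)
            surv = arr[sex] * (1 - q) * (1 - exit_p[sex])
            nxt[sex][1:] = surv[:-1]
            nxt[sex][AGE_MAX] += surv[AGE_MAX]  # terminal age bin
        ent = flows.entries_for(year + 1)
        for _, r in ent.iterrows():
            nxt[r["sex"]][int(r["age"])] += r["count"]
        arr = nxt
        for sex in SEXES:
            for age in range(AGE_MAX + 1):
                if arr[sex][age] > 0:
                    rows.append((year + 1, sex, age, arr[sex][age]))
    return pd.DataFrame(rows, columns=["year", "sex", "age", "total"])


def calibrate_flows(
    initial_totals: pd.DataFrame,
    mortality: MortalitySchedule,
    targets: pd.DataFrame,
    *,
    tol: float = 1e-9,
) -> FlowSchedule:
    """Solve entry counts and exit probabilities reproducing target totals.

    For each (year, sex, age) cell the survivors of the previous year's
    total are compared with the target: a shortfall becomes a weighted
    entry count, an excess becomes an emigration probability.  The
    resulting schedule reproduces the targets exactly (to float
    precision) when projected in expectation mode, and calibration is
    idempotent.

    ``targets`` is long-format (year, sex, age, total) covering every
    year after the initial one.
    """
    if (targets["total"] < 0).any():
        bad = targets[targets["total"] < 0].iloc[0]
        raise ValueError(
            f"infeasible target: negative total at year={int(bad['year'])}, "
            f"sex={bad['sex']!r}, age={int(bad['age'])}"
        )
    arr = _totals_to_arrays(initial_totals)
    years = sorted(targets["year"].unique())
    entries, exits = [], []
    ages = np.arange(AGE_MAX + 1)
    for year in years:
        tgt = _totals_to_arrays(
            targets[targets["year"] == year].rename(columns={"total": "total"})
        )
        nxt = {s: np.zeros(AGE_MAX + 1) for s in SEXES}
        for sex in SEXES:
            q = mortality.q(year - 1, sex, ages)
            surv_noexit = arr[sex] * (1 - q)
            aged = np.zeros(AGE_MAX + 1)
            aged[1:] = surv_noexit[:-1]
            aged[AGE_MAX] += surv_noexit[AGE_MAX]
            for age in range(AGE_MAX + 1):
                t, s0 = tgt[sex][age], aged[age]
                if t >= s0 - tol:
                    gap = max(0.0, t - s0)
                    if gap > tol:
                        entries.append((year, sex, age, gap))
                    nxt[sex][age] = t
                else:
                    # excess: emigrate at the pre-aging cell (age-1 in year-1)
                    p = 1.0 - t / s0
                    src_age = age - 1 if age > 0 else 0
                    exits.append((year - 1, sex, src_age, p))
                    nxt[sex][age] = t
        arr = nxt
    return FlowSchedule(
        entries=pd.DataFrame(entries, columns=["year", "sex", "age", "count"]),
        exit_prob=pd.DataFrame(exits, columns=["year", "sex", "age", "prob"])
        .groupby(["year", "sex", "age"], as_index=False)["prob"].max(),
    )


def growth_targets(
    initial_totals: pd.DataFrame,
    mortality: MortalitySchedule,
    years: range,
    annual_growth: float = 0.004,
    entry_age_profile: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Build target totals: survivors of the previous year plus entrants
    scaled so the overall population grows by ``annual_growth`` per year.

    Entrants are spread over an entry-age profile (default: 60% aging in
    at age 20, the rest immigrating at ages 21-49), split evenly by sex.
    """
    if entry_age_profile is None:
        entry_age_profile = {20: 0.60}
        for a in range(21, 50):
            entry_age_profile[a] = 0.40 / 29
    arr = _totals_to_arrays(initial_totals)
    total0 = sum(a.sum() for a in arr.values())
    rows = []
    ages = np.arange(AGE_MAX + 1)
    for k, year in enumerate(years[1:], start=1):
        nxt = {s: np.zeros(AGE_MAX + 1) for s in SEXES}
        for sex in SEXES:
            q = mortality.q(year - 1, sex, ages)
            surv = arr[sex] * (1 - q)
            nxt[sex][1:] = surv[:-1]
            nxt[sex][AGE_MAX] += surv[AGE_MAX]
        target_total = total0 * (1 + annual_growth) ** k
        deficit = target_total - sum(a.sum() for a in nxt.values())
        if deficit > 0:
            for age, share in entry_age_profile.items():
                for sex in SEXES:
                    nxt[sex][age] += deficit * share / 2.0
        arr = nxt
        for sex in SEXES:
            for age in range(AGE_MAX + 1):
                if arr[sex][age] > 0:
                    rows.append((year, sex, age, arr[sex][age]))
    return pd.DataFrame(rows, columns=["year", "sex", "age", "total"])


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def advance_demography(
    roster: pd.DataFrame,
    year: int,
    mortality: MortalitySchedule,
    flows: FlowSchedule,
    rng: np.random.Generator,
    *,
    entry_margins: PopulationMargins | None = None,
    entry_sampler=None,
) -> pd.DataFrame:
    """One annual demographic step, in place on a copy of the roster.

    Order: mortality → emigration → aging → entries.  Deaths and
    emigrations deactivate rows; entrant rows are appended with
    covariates drawn from ``entry_margins`` (their age and sex forced to
    the entry cell).  ``entry_sampler(subroster, rng)``, when given, is
    called on freshly drawn entrants to assign disease state.
    """
    roster = roster.copy()
    active = roster["active"].to_numpy()
    ages = roster["age"].to_numpy()
    sexes = roster["sex"].to_numpy()
    if active.any() and (ages[active] < 20).any():
        raise ValueError("active individuals must be aged 20+")

    # mortality then emigration
    u_death = rng.random(len(roster))
    u_emig = rng.random(len(roster))
    exit_p = flows.exit_lookup(year)
    dead = np.zeros(len(roster), bool)
    emig = np.zeros(len(roster), bool)
    for sex in SEXES:
        m = active & (sexes == sex)
        if m.any():
            q = mortality.q(year, sex, ages[m])
            dead[m] = u_death[m] < q
            emig[m] = (~dead[m]) & (u_emig[m] < exit_p[sex][ages[m]])
    roster.loc[dead | emig, "active"] = False

    # aging
    still = roster["active"].to_numpy()
    roster.loc[still, "age"] = np.minimum(roster.loc[still, "age"] + 1, AGE_MAX)

    # entries
    ent = flows.entries_for(year + 1)
    if len(ent) and entry_margins is not None:
        weight = float(roster["survey_weight"].iloc[0]) if len(roster) else 1.0
        counts = []
        for _, r in ent.iterrows():
            k = _stochastic_round(r["count"] / weight, rng)
            if k > 0:
                counts.append((r["sex"], int(r["age"]), k))
        total_k = sum(k for _, _, k in counts)
        if total_k > 0:
            seed_child = int(rng.integers(0, 2**31 - 1))
            sub = sample_covariates(
                entry_margins, total_k, np.random.default_rng(seed_child)
            )
            pos = 0
            for sex, age, k in counts:
                sub.loc[sub.index[pos : pos + k], "sex"] = sex
                sub.loc[sub.index[pos : pos + k], "age"] = age
                pos += k
            sub["survey_weight"] = weight
            sub["id"] = np.arange(len(sub)) + (roster["id"].max() + 1 if len(roster) else 0)
            if entry_sampler is not None:
                sub = entry_sampler(sub, rng)
            roster = pd.concat([roster, sub], ignore_index=True)
    return roster
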