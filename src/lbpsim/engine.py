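"""Run orchestration: baseline roster, annual loop, scenario catalogs.

A run draws a survey-weighted baseline roster from the bundle's margins
(disease state sampled *conditionally* on covariates, so the cross
section starts at the pain chain's stationary mix), calibrates entry
and exit flows against a slowly growing target population, then steps
annually: demography -> back-problem onset -> interventions -> pain
transitions -> YLD census.

Reproducibility: one RNG stream per stage, all spawned from the master
seed.  Scenario runs at the same seed therefore share demographic and
onset histories with the base case (common random numbers), so
YLDs-averted differences reflect the intervention, not sampling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import YldSeries, compute_ylds, person_years
from .demography import advance_demography, calibrate_flows, growth_targets, totals_from_roster
from .disease import onset, pain_transition
from .interventions import (
    EXERCISE_RR,
    VAS_DECREMENT_LEVELS,
    InterventionSpec,
    apply_bmi_intervention,
    apply_ergonomic_intervention,
    apply_exercise_intervention,
    scenario_catalog,
)
from .synthpop import generate_population, marginal_summary
from .synthetic_data import GroundTruthBundle

__all__ = ["RunConfig", "ScenarioRun", "run_scenario", "run_catalog"]

logger = logging.getLogger("lbpsim")

_STREAMS = ("population", "demography", "onset", "pain", "interventions")


@dataclass(frozen=True)
class RunConfig:
    """Settings shared by all scenarios of one experiment."""

    n: int = 102_761
    seed: int = 0
    start_year: int = 2020
    end_year: int = 2040
    annual_growth: float = 0.004
    correlated_baseline: bool = True

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {k: np.random.default_rng(s) for k, s in zip(_STREAMS, children)}


@dataclass
class ScenarioRun:
    """Output of one scenario: YLD series, exposure trends, final margins."""

    spec: InterventionSpec
    ylds: YldSeries
    exposures: pd.DataFrame
    final_margins: object
    demographic_log: pd.DataFrame


def _exposure_row(roster: pd.DataFrame, year: int) -> dict:
    active = roster[roster["active"]]
    w = active["survey_weight"].to_numpy()
    worker = active["occupation"].isin(
        [f"group_{k}" for k in range(1, 8)]
    ).to_numpy()
    exposed = worker & (active["occupation"].to_numpy() != "group_3") & (
        ~active["ergo_protected"].to_numpy().astype(bool)
    )
    return {
        "year": year,
        "mean_bmi": float(np.average(active["bmi"], weights=w)),
        "pct_exposed": float(100 * w[exposed].sum() / w.sum()),
        "pct_exercising": float(
            100 * w[active["exercising"].to_numpy().astype(bool)].sum() / w.sum()
        ),
        "back_problem_prevalence": float(
            100 * w[active["has_back_problems"].to_numpy()].sum() / w.sum()
        ),
    }


def _apply_interventions(roster, spec, year, rng):
    if spec is None or spec.is_base or not spec.active_in(year):
        if spec is not None and spec.type == "exercise":
            roster = roster.copy()
            roster["exercising"] = False
        return roster
    if spec.type == "bmi_reduction":
        return apply_bmi_intervention(roster, spec, year)
    if spec.type == "ergonomic":
        return apply_ergonomic_intervention(roster, spec, rng)
    if spec.type == "exercise":
        return apply_exercise_intervention(roster, spec, year, rng)
    return roster


def run_scenario(
    config: RunConfig,
    bundle: GroundTruthBundle,
    spec: InterventionSpec | None = None,
) -> ScenarioRun:
    """Simulate one scenario from the baseline year to the horizon.

    ``spec=None`` (or a base-type spec) runs the base case.  The run is
    fully reproducible at a fixed (config, bundle) and shares its
    demographic history with every other scenario at the same seed.
    """
    spec = spec or InterventionSpec(id="base", type="base")
    rngs = config.streams()
    pop_seed = int(rngs["population"].integers(0, 2**31 - 1))
    roster = generate_population(
        bundle.margins, config.n, pop_seed,
        prevalence_model=bundle.prevalence_model if config.correlated_baseline else None,
        pain_model=bundle.pain_model if config.correlated_baseline else None,
        pain_sampler=bundle.census_pain_probs if config.correlated_baseline else None,
    )
    years = range(config.start_year, config.end_year + 1)
    flows = calibrate_flows(
        totals_from_roster(roster),
        bundle.mortality,
        growth_targets(
            totals_from_roster(roster), bundle.mortality, years,
            annual_growth=config.annual_growth,
        ),
    )

    def entry_sampler(sub: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        p = bundle.prevalence_model.predict(sub)
        sub = sub.copy()
        sub["has_back_problems"] = rng.random(len(sub)) < p
        cases = sub.index[sub["has_back_problems"]]
        if len(cases):
            probs = bundle.census_pain_probs(sub.loc[cases])
            u = rng.random(len(cases))
            lv = (u[:, None] > probs.cumsum(axis=1)[:, :-1]).sum(axis=1)
            sub.loc[cases, "pain_level"] = lv.astype(float)
        return sub

    stage = "census"
    ylds, pys, exposures, demo_rows = [], [], [], []
    try:
        ylds.append(compute_ylds(roster, bundle.weights))
        pys.append(person_years(roster))
        exposures.append(_exposure_row(roster, config.start_year))
        demo_rows.append(
            {"year": config.start_year,
             "weighted_total": person_years(roster),
             "n_active": int(roster["active"].sum())}
        )
        for year in years[:-1]:
            stage = "demography"
            roster = advance_demography(
                roster, year, bundle.mortality, flows, rngs["demography"],
                entry_margins=bundle.margins, entry_sampler=entry_sampler,
            )
            demo_rows.append(
                {"year": year + 1, "weighted_total": person_years(roster),
                 "n_active": int(roster["active"].sum())}
            )
            stage = "onset"
            roster = onset(roster, bundle.incidence, bundle.pain_model, rngs["onset"])
            stage = "interventions"
            roster = _apply_interventions(roster, spec, year + 1, rngs["interventions"])
            stage = "pain"
            vas = (
                VAS_DECREMENT_LEVELS
                if spec.type == "exercise" and spec.exercise_effect_mode == "vas"
                else 0.0
            )
            roster = pain_transition(
                roster, bundle.pain_model, rngs["pain"],
                exercise_log_rr=float(np.log(EXERCISE_RR)), vas_decrement=vas,
            )
            stage = "census"
            ylds.append(compute_ylds(roster, bundle.weights))
            pys.append(person_years(roster))
            exposures.append(_exposure_row(roster, year + 1))
    except Exception:
        logger.exception(
            "scenario %s failed at year %s, stage %s", spec.id, year, stage
        )
        raise
    series = YldSeries(
        scenario_id=spec.id,
        years=np.array(list(years)),
        ylds=np.array(ylds),
        person_years=np.array(pys),
    )
    return ScenarioRun(
        spec=spec,
        ylds=series,
        exposures=pd.DataFrame(exposures),
        final_margins=marginal_summary(roster),
        demographic_log=pd.DataFrame(demo_rows),
    )


def run_catalog(
    config: RunConfig,
    bundle: GroundTruthBundle,
    specs: list[InterventionSpec] | None = None,
    window: tuple[int, int] = (2021, 2040),
) -> pd.DataFrame:
    """Run a catalog of scenarios against one common-random-number base.

    Returns a tidy per-year table (scenario, year, ylds, person_years,
    ylds_averted).  A scenario that fails is logged and skipped;
    successful scenarios are still reported.
    """
    specs = scenario_catalog() if specs is None else list(specs)
    if not specs:
        raise ValueError("catalog must contain at least one scenario")
    base = run_scenario(config, bundle, None)
    lo = max(window[0], config.start_year)
    hi = min(window[1], config.end_year)
    frames = []
    for spec in specs:
        try:
            run = base if spec.is_base else run_scenario(config, bundle, spec)
        except Exception:
            logger.exception("scenario %s failed; continuing", spec.id)
            continue
        df = run.ylds.to_frame()
        base_map = dict(zip(base.ylds.years, base.ylds.ylds))
        df["ylds_averted"] = [
            base_map[y] - v if lo <= y <= hi else 0.0
            for y, v in zip(run.ylds.years, run.ylds.ylds)
        ]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["scenario", "year", "ylds", "person_years", "ylds_averted"]]
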