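"""Ground-truth input bundles for fully synthetic, testable runs.

The study this package reimplements drew its inputs from restricted
survey microdata and national demographic projections.  This module
replaces those sources with internally consistent synthetic bundles: a
margins specification, a mortality schedule, a prevalence model with
its calibrated incidence schedule, a pain-transition model whose
cutpoints are calibrated so the stationary pain mix matches the target
margins, and disability weights.  The generating parameter values are
recorded so recovery tests can check them against data simulated from
the bundle itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit

from . import reference
from .burden import DEFAULT_WEIGHTS, DisabilityWeightMap
from .demography import MortalitySchedule, gompertz_mortality
from .disease import (
    IncidenceSchedule,
    PainTransitionModel,
    PrevalenceModel,
    calibrate_incidence,
    calibrate_prevalence_intercept,
)
from .synthpop import PopulationMargins, sample_covariates

__all__ = [
    "CalibrationError",
    "GroundTruthBundle",
    "calibrate_pain_cutpoints",
    "make_table1_bundle",
    "make_stress_bundles",
]


class CalibrationError(RuntimeError):
    """Calibration failed to reach its targets within the iteration budget."""


@dataclass
class GroundTruthBundle:
    """Everything one run needs, with known generating parameters."""

    name: str
    margins: PopulationMargins
    mortality: MortalitySchedule
    prevalence_model: PrevalenceModel
    incidence: IncidenceSchedule
    pain_model: PainTransitionModel
    weights: DisabilityWeightMap = field(default_factory=lambda: DEFAULT_WEIGHTS)
    ground_truth: dict = field(default_factory=dict)

    def case_inflow_rate(self, roster: pd.DataFrame) -> np.ndarray:
        """Annual fraction of each profile's case pool that is newly
        diagnosed: h (1 - p) / p with onset hazard h and prevalence p."""
        p = np.clip(self.prevalence_model.predict(roster), 1e-6, 1 - 1e-6)
        h = np.zeros(len(roster))
        sexes = roster["sex"].to_numpy()
        ages = roster["age"].to_numpy()
        for sex in np.unique(sexes):
            m = sexes == sex
            h[m] = self.incidence.hazard(sex, ages[m])
        return np.clip(h * (1 - p) / p, 0.0, 1.0)

    def census_pain_probs(self, roster: pd.DataFrame) -> np.ndarray:
        """Turnover-adjusted long-run pain distribution per case row."""
        return self.pain_model.quasi_stationary_probs(
            roster, self.case_inflow_rate(roster)
        )

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.margins.save(d / "margins.yaml")
        self.mortality.to_frame().to_csv(d / "mortality.csv", index=False)
        self.incidence.to_frame().to_csv(d / "incidence.csv", index=False)
        self.pain_model.save(d / "pain_model.yaml")
        with open(d / "prevalence_model.yaml", "w") as fh:
            yaml.safe_dump(self.prevalence_model.to_dict(), fh, sort_keys=True)
        with open(d / "meta.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "name": self.name,
                    "disability_weights": list(self.weights.weights),
                    "ground_truth": self.ground_truth,
                },
                fh, sort_keys=True,
            )

    @classmethod
    def load(cls, directory) -> "GroundTruthBundle":
        d = Path(directory)
        with open(d / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        with open(d / "prevalence_model.yaml") as fh:
            prev = PrevalenceModel.from_dict(yaml.safe_load(fh))
        return cls(
            name=meta["name"],
            margins=PopulationMargins.load(d / "margins.yaml"),
            mortality=MortalitySchedule.from_frame(pd.read_csv(d / "mortality.csv")),
            prevalence_model=prev,
            incidence=IncidenceSchedule.from_frame(pd.read_csv(d / "incidence.csv")),
            pain_model=PainTransitionModel.load(d / "pain_model.yaml"),
            weights=DisabilityWeightMap(tuple(meta["disability_weights"])),
            ground_truth=meta.get("ground_truth", {}),
        )


def _profile_sample(
    margins: PopulationMargins, n: int, seed: int
) -> pd.DataFrame:
    """Deterministic covariate sample used as a calibration quadrature."""
    rng = np.random.default_rng(seed)
    df = sample_covariates(margins, n, rng)
    df["ergo_protected"] = False
    return df


def calibrate_pain_cutpoints(
    model: PainTransitionModel,
    margins: PopulationMargins,
    *,
    prevalence_model: PrevalenceModel | None = None,
    incidence: IncidenceSchedule | None = None,
    n_profiles: int = 6000,
    tol: float = 0.001,
    max_iter: int = 200,
    damping: float = 0.6,
    seed: int = 1234,
) -> PainTransitionModel:
    """Tune cutpoints so the simulated census pain mix hits its targets.

    Damped fixed-point iteration on the logit scale: for each threshold
    k, the achieved population-average census P(level >= k) is compared
    with the target cumulative share and the cutpoint nudged by the
    damped logit difference.  The population average is taken over a
    fixed covariate quadrature sampled from the margins; each profile's
    long-run pain distribution is solved exactly from its 5-state annual
    chain, including case-pool turnover (newly diagnosed cases always
    enter with pain) when a prevalence model and incidence schedule are
    supplied, and profiles are weighted by their case probability.
    Tolerance is 0.1 percentage points per share.
    """
    target = np.asarray(margins.pain_level_shares, float)
    target_ge = 1.0 - np.cumsum(target)[:-1]  # P(>=1..4)
    profiles = _profile_sample(margins, n_profiles, seed)
    if prevalence_model is not None:
        case_w = prevalence_model.predict(profiles)
    else:
        case_w = np.ones(len(profiles))
    case_w = case_w / case_w.sum()
    if prevalence_model is not None and incidence is not None:
        tmp = GroundTruthBundle(
            name="_cal", margins=margins, mortality=None,  # type: ignore[arg-type]
            prevalence_model=prevalence_model, incidence=incidence,
            pain_model=model,
        )
        inflow = tmp.case_inflow_rate(profiles)
    else:
        inflow = np.zeros(len(profiles))
    c = np.asarray(model.cutpoints, float).copy()
    for _ in range(max_iter):
        m = PainTransitionModel(
            cutpoints=tuple(c),
            beta_age=model.beta_age,
            beta_male=model.beta_male,
            beta_college=model.beta_college,
            beta_bmi=model.beta_bmi,
            ar_offsets=model.ar_offsets,
            occupation_rr=model.occupation_rr,
        )
        pi = case_w @ m.quasi_stationary_probs(profiles, inflow)
        ge = 1.0 - np.cumsum(pi)[:-1]
        if np.max(np.abs(pi - target)) < tol:
            return m
        c = c + damping * (logit(ge) - logit(target_ge))
        c = np.maximum.accumulate(c + np.arange(4) * 1e-9)  # keep ordered
    raise CalibrationError(
        f"pain cutpoint calibration did not converge: last mix {pi}, "
        f"target {target}"
    )


def make_table1_bundle(
    seed: int = 0,
    *,
    population_total: float = reference.CANADA_ADULT_POPULATION_2020,
    bmi_or_per_5: float = 1.14,
) -> GroundTruthBundle:
    """Default bundle calibrated to the published 2020 margins.

    Prevalence: logistic model with preset age/sex/education slopes and
    the BMI slope ln(1.14)/5; intercept solved so the population-average
    prevalence is 20.7%.  Pain: autoregressive proportional-odds model
    with preset slopes and previous-pain offsets, cutpoints calibrated
    so the stationary mix among cases is 57.7/10.3/11.6/11.4/9.0%.
    Incidence: backed out of the prevalence curve under life-long
    duration.  Mortality: Gompertz preset (life expectancy ~80/84).
    """
    margins = reference.syl2020_margins(population_total=population_total)
    beta_bmi = float(np.log(bmi_or_per_5) / 5.0)
    prev = calibrate_prevalence_intercept(
        PrevalenceModel(
            intercept=0.0, beta_age=0.015, beta_male=-0.10,
            beta_bmi=beta_bmi, beta_college=-0.20,
        ),
        margins,
        margins.back_problem_prevalence,
    )
    incidence = calibrate_incidence(prev, margins)
    pain = calibrate_pain_cutpoints(
        PainTransitionModel(
            cutpoints=(0.0, 1.0, 2.0, 3.0),
            beta_age=0.008, beta_male=-0.10, beta_college=-0.15,
            beta_bmi=beta_bmi,
            ar_offsets=(0.5, 1.0, 1.5, 2.0),
        ),
        margins,
        prevalence_model=prev,
        incidence=incidence,
        seed=seed + 101,
    )
    return GroundTruthBundle(
        name="table1",
        margins=margins,
        mortality=gompertz_mortality(),
        prevalence_model=prev,
        incidence=incidence,
        pain_model=pain,
        weights=DEFAULT_WEIGHTS,
        ground_truth={
            "beta_bmi_per_unit": beta_bmi,
            "bmi_or_per_5": bmi_or_per_5,
            "target_prevalence": float(margins.back_problem_prevalence),
            "target_pain_mix": [float(x) for x in margins.pain_level_shares],
        },
    )


def make_stress_bundles(seed: int = 0) -> list[GroundTruthBundle]:
    """Edge-case bundles for property tests.

    * ``zero_prevalence`` — nobody has, or ever develops, back problems;
    * ``painless`` — nonzero prevalence but the pain chain sits at level
      0 (cutpoints far above any reachable predictor);
    * ``group6_only`` — every worker is in occupation group 6, so a
      group-6 ergonomic scenario equals a 100%-coverage one;
    * ``lean`` — an extreme low-BMI population (nobody overweight).
    """
    base = make_table1_bundle(seed)
    bundles = []

    zero_m = reference.syl2020_margins()
    zero_m.back_problem_prevalence = 0.0
    zero_prev = PrevalenceModel(-30.0, 0.0, 0.0, 0.0, 0.0)
    bundles.append(
        GroundTruthBundle(
            name="zero_prevalence", margins=zero_m, mortality=base.mortality,
            prevalence_model=zero_prev,
            incidence=calibrate_incidence(zero_prev, zero_m),
            pain_model=base.pain_model, weights=base.weights,
        )
    )

    painless = PainTransitionModel(
        cutpoints=(30.0, 31.0, 32.0, 33.0),
        beta_bmi=base.pain_model.beta_bmi,
        ar_offsets=(0.0, 0.0, 0.0, 0.0),
        occupation_rr=base.pain_model.occupation_rr,
    )
    pm = reference.syl2020_margins()
    pm.pain_level_shares = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    bundles.append(
        GroundTruthBundle(
            name="painless", margins=pm, mortality=base.mortality,
            prevalence_model=base.prevalence_model, incidence=base.incidence,
            pain_model=painless, weights=base.weights,
        )
    )

    g6 = reference.syl2020_margins()
    g6.occupation_shares = {g: 0.0 for g in g6.occupation_shares}
    g6.occupation_shares["group_6"] = 0.65
    g6.occupation_shares["not_working"] = 0.35
    bundles.append(
        GroundTruthBundle(
            name="group6_only", margins=g6, mortality=base.mortality,
            prevalence_model=base.prevalence_model, incidence=base.incidence,
            pain_model=base.pain_model, weights=base.weights,
        )
    )

    lean = reference.syl2020_margins(bmi_sd=1.5)
    lean.bmi_mean = 21.0
    bundles.append(
        GroundTruthBundle(
            name="lean", margins=lean, mortality=base.mortality,
            prevalence_model=base.prevalence_model, incidence=base.incidence,
            pain_model=base.pain_model, weights=base.weights,
        )
    )
    return bundles
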