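"""Chronic back-problem dynamics: prevalence, incidence, pain trajectories.

Three linked models drive the disease layer:

* a logistic **prevalence model** for ever having chronic back problems
  given age, sex, BMI and education (education proxies socio-economic
  status);
* an **incidence schedule** derived from the prevalence model under the
  assumption that back problems, once present, are life-long: with no
  differential mortality the cohort recursion
  ``i(a) = (p(a+1) - p(a)) / (1 - p(a))`` recovers the annual onset
  hazard from the cross-sectional prevalence curve;
* an autoregressive **proportional-odds pain model** for the ordinal
  pain level 0-4 among cases.  One linear predictor (age, sex,
  education, BMI, occupation-group offsets, previous year's pain level,
  and any intervention offset) shifts all four cumulative log-odds
  thresholds equally:  P(level >= k) = expit(eta - c_k).

Occupational and intervention relative risks enter the linear predictor
as log-RR offsets; the BMI effect is the published odds ratio per 5
units converted to a per-unit log-odds slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .synthpop import OCCUPATION_GROUPS

__all__ = [
    "AGE_REF",
    "BMI_REF",
    "DEFAULT_OCCUPATION_RR",
    "PrevalenceModel",
    "IncidenceSchedule",
    "PainTransitionModel",
    "proportional_odds_probs",
    "sample_ordinal",
    "pain_transition",
    "onset",
    "calibrate_incidence",
    "calibrate_prevalence_intercept",
]

#: Centering constants for linear predictors (do not change fitted
#: slopes, only make intercepts/cutpoints interpretable).
AGE_REF = 50.0
BMI_REF = 26.0

#: GBD ergonomic-exposure relative risks of LBP by 1-digit occupational
#: group (group 3, clerical, is the 1.0 reference; adults not in the
#: labour force carry no occupational exposure).
DEFAULT_OCCUPATION_RR: dict[str, float] = {
    "group_1": 1.17,
    "group_2": 1.08,
    "group_3": 1.00,
    "group_4": 1.37,
    "group_5": 1.53,
    "group_6": 3.78,
    "group_7": 2.37,
    "not_working": 1.00,
}


def _covariate_arrays(roster: pd.DataFrame) -> tuple[np.ndarray, ...]:
    age = roster["age"].to_numpy(float)
    male = (roster["sex"].to_numpy() == "male").astype(float)
    college = (roster["education"].to_numpy() == "college+").astype(float)
    bmi = roster["bmi"].to_numpy(float)
    return age, male, college, bmi


@dataclass
class PrevalenceModel:
    """Logistic model for chronic back-problem prevalence.

    Coefficients are on the log-odds scale; age and BMI are centred at
    ``AGE_REF`` / ``BMI_REF`` years and kg/m².
    """

    intercept: float
    beta_age: float
    beta_male: float
    beta_bmi: float
    beta_college: float

    def linear_predictor(self, roster: pd.DataFrame) -> np.ndarray:
        age, male, college, bmi = _covariate_arrays(roster)
        return (
            self.intercept
            + self.beta_age * (age - AGE_REF)
            + self.beta_male * male
            + self.beta_bmi * (bmi - BMI_REF)
            + self.beta_college * college
        )

    def predict(self, roster: pd.DataFrame) -> np.ndarray:
        """Probability of having chronic back problems, in (0, 1)."""
        return expit(self.linear_predictor(roster))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PrevalenceModel":
        return cls(**dict(d))


class IncidenceSchedule:
    """Annual back-problem onset hazards by (age, sex)."""

    def __init__(self, hazards: dict[str, np.ndarray], age_min: int = 20):
        self.age_min = age_min
        for sex, h in hazards.items():
            h = np.asarray(h, float)
            if np.any((h < 0) | (h > 1)):
                raise ValueError(f"hazards[{sex}] outside [0, 1]")
            hazards[sex] = h
        self.hazards = hazards

    def hazard(self, sex: str, ages: np.ndarray) -> np.ndarray:
        h = self.hazards[sex]
        idx = np.clip(np.asarray(ages) - self.age_min, 0, len(h) - 1)
        return h[idx]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sex, self.age_min + i, v)
            for sex, h in self.hazards.items()
            for i, v in enumerate(h)
        ]
        return pd.DataFrame(rows, columns=["sex", "age", "hazard"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceSchedule":
        age_min = int(df["age"].min())
        hazards = {
            sex: g.sort_values("age")["hazard"].to_numpy()
            for sex, g in df.groupby("sex")
        }
        return cls(hazards, age_min=age_min)


def proportional_odds_probs(eta, cutpoints) -> np.ndarray:
    """Level probabilities of a proportional-odds model.

    ``P(level >= k) = expit(eta - c_k)`` for k = 1..4; returns an array
    with a trailing dimension of 5 (levels 0..4) that sums to one and is
    stochastically increasing in ``eta``.
    """
    c = np.asarray(cutpoints, float)
    if c.shape != (4,) or np.any(np.diff(c) <= 0):
        raise ValueError("cutpoints must be 4 strictly increasing values")
    eta = np.asarray(eta, float)
    ge = expit(eta[..., None] - c)  # P(>=1..4)
    cum = np.concatenate(
        [np.ones_like(eta)[..., None], ge, np.zeros_like(eta)[..., None]], axis=-1
    )
    return -np.diff(cum, axis=-1)


def sample_ordinal(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw of ordinal levels from per-row probability vectors."""
    u = rng.random(probs.shape[0])
    return (u[:, None] > probs.cumsum(axis=1)[:, :-1]).sum(axis=1)


@dataclass
class PainTransitionModel:
    """Autoregressive proportional-odds model for annual pain levels.

    ``cutpoints`` are the four ordered thresholds on the latent
    log-odds scale.  ``ar_offsets`` shift the linear predictor per
    previous-year pain level 1..4 (level 0 is the reference), making
    each case's trajectory autocorrelated.  ``occupation_rr`` holds
    relative risks entered as ln(RR) offsets; the BMI slope defaults to
    ln(1.14)/5 per kg/m² (odds ratio 1.14 per 5 BMI units).
    """

    cutpoints: tuple[float, float, float, float]
    beta_age: float = 0.0
    beta_male: float = 0.0
    beta_college: float = 0.0
    beta_bmi: float = float(np.log(1.14) / 5.0)
    ar_offsets: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    occupation_rr: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPATION_RR)
    )

    def __post_init__(self) -> None:
        c = np.asarray(self.cutpoints, float)
        if c.shape != (4,) or np.any(np.diff(c) <= 0):
            raise ValueError("cutpoints must be 4 strictly increasing values")
        self.cutpoints = tuple(float(x) for x in c)
        rr = dict(self.occupation_rr)
        unknown = set(rr) - set(OCCUPATION_GROUPS)
        if unknown:
            raise ValueError(f"unknown occupation groups: {sorted(unknown)}")
        if abs(rr.get("group_3", 1.0) - 1.0) > 1e-12:
            raise ValueError("group_3 is the reference and must have RR = 1")
        self.occupation_rr = rr
        self.ar_offsets = tuple(float(x) for x in np.asarray(self.ar_offsets, float))

    # -- linear predictor ---------------------------------------------
    def occupation_offset(self, roster: pd.DataFrame) -> np.ndarray:
        occ = roster["occupation"].to_numpy()
        log_rr = np.zeros(len(roster))
        for g, rr in self.occupation_rr.items():
            log_rr[occ == g] = np.log(rr)
        if "ergo_protected" in roster:
            log_rr[roster["ergo_protected"].to_numpy().astype(bool)] = 0.0
        return log_rr

    def linear_predictor(
        self,
        roster: pd.DataFrame,
        prev_pain: np.ndarray | None = None,
        extra_offset: np.ndarray | float = 0.0,
    ) -> np.ndarray:
        age, male, college, bmi = _covariate_arrays(roster)
        eta = (
            self.beta_age * (age - AGE_REF)
            + self.beta_male * male
            + self.beta_college * college
            + self.beta_bmi * (bmi - BMI_REF)
            + self.occupation_offset(roster)
            + extra_offset
        )
        if prev_pain is not None:
            ar = np.concatenate([[0.0], np.asarray(self.ar_offsets)])
            eta = eta + ar[np.asarray(prev_pain, int)]
        return eta

    def transition_matrix(self, eta0: float) -> np.ndarray:
        """5x5 annual transition matrix for a fixed covariate profile
        with pre-AR linear predictor ``eta0``."""
        ar = np.concatenate([[0.0], np.asarray(self.ar_offsets)])
        return proportional_odds_probs(eta0 + ar, self.cutpoints)

    def stationary_for_eta(self, eta0) -> np.ndarray:
        """Stationary pain-level distribution(s) of the annual chain."""
        eta0 = np.atleast_1d(np.asarray(eta0, float))
        out = np.empty((eta0.size, 5))
        for i, e in enumerate(eta0):
            T = self.transition_matrix(e)
            A = np.vstack([T.T - np.eye(5), np.ones(5)])
            b = np.concatenate([np.zeros(5), [1.0]])
            out[i] = np.linalg.lstsq(A, b, rcond=None)[0]
        return np.clip(out, 0.0, None) / out.sum(axis=1, keepdims=True)

    def stationary_distribution(self, roster: pd.DataFrame) -> np.ndarray:
        """Per-individual stationary pain distributions (rounded eta grid
        for speed: profiles sharing a predictor value share a solve)."""
        eta0 = self.linear_predictor(roster)
        grid = np.round(eta0, 2)
        uniq, inv = np.unique(grid, return_inverse=True)
        return self.stationary_for_eta(uniq)[inv]

    def quasi_stationary_probs(
        self, roster: pd.DataFrame, inflow_rate: np.ndarray | float
    ) -> np.ndarray:
        """Census pain distributions with case-pool turnover.

        A case pool is not closed: every year a fraction ``inflow_rate``
        of it consists of newly diagnosed cases, who always enter with
        pain (levels 1-4, renormalised).  The long-run census mix of a
        profile solves pi = (1-f) T' pi + f nu, with T the annual
        transition matrix and nu the onset distribution.  ``inflow_rate``
        of 0 recovers the plain stationary distribution.
        """
        eta0 = self.linear_predictor(roster)
        n = eta0.size
        f = np.broadcast_to(np.asarray(inflow_rate, float), (n,)).astype(float)
        ar = np.concatenate([[0.0], np.asarray(self.ar_offsets)])
        T = proportional_odds_probs(eta0[:, None] + ar[None, :], self.cutpoints)
        nu = np.zeros((n, 5))
        onset_p = proportional_odds_probs(eta0, self.cutpoints)[:, 1:]
        nu[:, 1:] = onset_p / onset_p.sum(axis=1, keepdims=True)
        A = np.eye(5)[None, :, :] - (1 - f)[:, None, None] * T.transpose(0, 2, 1)
        b = f[:, None] * nu
        # replace one (redundant) equation with the normalisation
        A[:, 4, :] = 1.0
        b[:, 4] = 1.0
        pi = np.linalg.solve(A, b[..., None])[..., 0]
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum(axis=1, keepdims=True)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            **{f"cutpoint_{k+1}": float(c) for k, c in enumerate(self.cutpoints)},
            "beta_age": self.beta_age,
            "beta_male": self.beta_male,
            "beta_college": self.beta_college,
            "beta_bmi_per_unit": self.beta_bmi,
            **{f"rr_{g}": float(v) for g, v in self.occupation_rr.items()},
            **{f"ar_offset_level_{k+1}": float(v) for k, v in enumerate(self.ar_offsets)},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PainTransitionModel":
        d = dict(d)
        return cls(
            cutpoints=tuple(d[f"cutpoint_{k}"] for k in range(1, 5)),
            beta_age=d["beta_age"],
            beta_male=d["beta_male"],
            beta_college=d["beta_college"],
            beta_bmi=d["beta_bmi_per_unit"],
            ar_offsets=tuple(d[f"ar_offset_level_{k}"] for k in range(1, 5)),
            occupation_rr={
                g: d[f"rr_{g}"] for g in OCCUPATION_GROUPS if f"rr_{g}" in d
            },
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PainTransitionModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def pain_transition(
    roster: pd.DataFrame,
    model: PainTransitionModel,
    rng: np.random.Generator,
    *,
    exercise_log_rr: float = float(np.log(0.71)),
    vas_decrement: float = 0.0,
) -> pd.DataFrame:
    """Advance every active case's pain level by one year.

    Exercising participants either receive ``exercise_log_rr`` as an
    offset to the linear predictor (relative-risk mode) or, in VAS mode
    (``vas_decrement`` > 0), a deterministic decrement on the continuous
    latent pain scale before discretisation.
    """
    roster = roster.copy()
    mask = (roster["active"] & roster["has_back_problems"]).to_numpy()
    if not mask.any():
        return roster
    cases = roster[mask]
    prev = cases["pain_level"].to_numpy()
    if np.isnan(prev).any():
        raise ValueError("back-problem case with missing pain level")
    exercising = cases["exercising"].to_numpy().astype(bool)
    offset = np.where(exercising & (vas_decrement == 0.0), exercise_log_rr, 0.0)
    eta = model.linear_predictor(cases, prev_pain=prev.astype(int), extra_offset=offset)
    if vas_decrement > 0.0:
        latent = eta + _logistic_noise(rng, mask.sum())
        cont = _latent_to_continuous(latent, np.asarray(model.cutpoints))
        cont = cont - np.where(exercising, vas_decrement, 0.0)
        new = np.clip(np.round(cont), 0, 4).astype(int)
    else:
        probs = proportional_odds_probs(eta, model.cutpoints)
        new = sample_ordinal(probs, rng)
    roster.loc[mask, "pain_level"] = new.astype(float)
    return roster


def _logistic_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    u = rng.random(n)
    return np.log(u / (1 - u))


def _latent_to_continuous(latent: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    """Map latent log-odds values to a continuous 0-4 pain scale.

    The four cutpoints are the level boundaries and map to 0.5, 1.5,
    2.5, 3.5; between cutpoints the map is linear, beyond the extremes
    it extrapolates with the adjacent slope.  Rounding the result
    reproduces the proportional-odds discretisation exactly.
    """
    y_knots = np.array([0.5, 1.5, 2.5, 3.5])
    out = np.interp(latent, cutpoints, y_knots)
    lo = latent < cutpoints[0]
    hi = latent > cutpoints[-1]
    slope_lo = (y_knots[1] - y_knots[0]) / (cutpoints[1] - cutpoints[0])
    slope_hi = (y_knots[3] - y_knots[2]) / (cutpoints[3] - cutpoints[2])
    out[lo] = y_knots[0] + (latent[lo] - cutpoints[0]) * slope_lo
    out[hi] = y_knots[3] + (latent[hi] - cutpoints[3]) * slope_hi
    return out


def onset(
    roster: pd.DataFrame,
    schedule: IncidenceSchedule,
    model: PainTransitionModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Annual back-problem onset among active non-cases.

    Newly diagnosed cases always start with pain: the initial level is
    drawn from the proportional-odds probabilities with level 0 removed
    and the rest renormalised.
    """
    roster = roster.copy()
    mask = (roster["active"] & ~roster["has_back_problems"]).to_numpy()
    if not mask.any():
        return roster
    sub = roster[mask]
    h = np.zeros(len(sub))
    sexes = sub["sex"].to_numpy()
    for sex in np.unique(sexes):
        m = sexes == sex
        h[m] = schedule.hazard(sex, sub["age"].to_numpy()[m])
    new = rng.random(len(sub)) < h
    if new.any():
        idx = sub.index[new]
        eta = model.linear_predictor(roster.loc[idx], prev_pain=None)
        probs = proportional_odds_probs(eta, model.cutpoints)
        probs = probs[:, 1:] / probs[:, 1:].sum(axis=1, keepdims=True)
        levels = sample_ordinal(probs, rng) + 1
        roster.loc[idx, "has_back_problems"] = True
        roster.loc[idx, "pain_level"] = levels.astype(float)
    return roster


def _quadrature_profiles(
    margins, sex: str, age: int, n_bmi: int = 16
) -> tuple[pd.DataFrame, np.ndarray]:
    """Deterministic covariate quadrature at one (age, sex): BMI on
    equal-probability log-normal quantiles crossed with education."""
    from .synthpop import lognormal_params

    mu, sigma = lognormal_params(margins.bmi_mean, margins.bmi_sd)
    qs = (np.arange(n_bmi) + 0.5) / n_bmi
    from scipy.stats import norm

    bmi = np.exp(mu + sigma * norm.ppf(qs))
    rows, wts = [], []
    for edu, p_edu in [("college+", margins.college_share),
                       ("less-than-college", 1 - margins.college_share)]:
        for b in bmi:
            rows.append((age, sex, edu, b))
            wts.append(p_edu / n_bmi)
    df = pd.DataFrame(rows, columns=["age", "sex", "education", "bmi"])
    return df, np.asarray(wts)


def expected_prevalence_by_age(
    model: PrevalenceModel, margins, ages: np.ndarray, sex: str
) -> np.ndarray:
    """Prevalence curve p(a) averaged over the BMI/education margins."""
    out = np.empty(len(ages))
    for i, a in enumerate(ages):
        prof, w = _quadrature_profiles(margins, sex, int(a))
        out[i] = float(np.dot(w, model.predict(prof)))
    return out


def calibrate_incidence(
    model: PrevalenceModel,
    margins,
    *,
    age_min: int = 20,
    age_max: int = 100,
) -> IncidenceSchedule:
    """Back out annual onset hazards from the prevalence model.

    Under life-long duration and no differential mortality a cohort's
    prevalence obeys ``p(a+1) = p(a) + i(a) (1 - p(a))``, so
    ``i(a) = (p(a+1) - p(a)) / (1 - p(a))``.  Decreasing stretches of
    p(a) are floored at hazard 0 with a warning.
    """
    ages = np.arange(age_min, age_max + 2)
    hazards = {}
    floored = False
    for sex in ("male", "female"):
        p = expected_prevalence_by_age(model, margins, ages, sex)
        if np.any(p >= 1.0):
            raise ValueError(f"prevalence reaches 1 for sex={sex}")
        i = (p[1:] - p[:-1]) / (1.0 - p[:-1])
        if np.any(i < -1e-12):
            floored = True
        hazards[sex] = np.clip(i, 0.0, 1.0)
    if floored:
        warnings.warn(
            "prevalence decreases with age in places; onset hazard floored at 0",
            stacklevel=2,
        )
    return IncidenceSchedule(hazards, age_min=age_min)


def calibrate_prevalence_intercept(
    model: PrevalenceModel, roster_or_margins, target: float
) -> PrevalenceModel:
    """Return a copy of ``model`` with the intercept tuned so the
    population-average predicted prevalence equals ``target``.

    Accepts either a roster (averaged with survey weights) or margins
    (averaged over a deterministic covariate quadrature crossed with the
    age/sex margins).
    """
    if isinstance(roster_or_margins, pd.DataFrame):
        roster = roster_or_margins
        w = roster["survey_weight"].to_numpy()

        def mean_prev(b0: float) -> float:
            m = PrevalenceModel(b0, model.beta_age, model.beta_male,
                                model.beta_bmi, model.beta_college)
            return float(np.average(m.predict(roster), weights=w))
    else:
        margins = roster_or_margins
        from .synthpop import AGE_BANDS

        profs, wts = [], []
        for (lo, hi), share in zip(AGE_BANDS, margins.age_band_shares):
            mid = (lo + hi) // 2
            for sex, p_sex in [("male", margins.male_share),
                               ("female", 1 - margins.male_share)]:
                prof, w = _quadrature_profiles(margins, sex, mid)
                profs.append(prof)
                wts.append(w * share * p_sex)
        prof_all = pd.concat(profs, ignore_index=True)
        w_all = np.concatenate(wts)

        def mean_prev(b0: float) -> float:
            m = PrevalenceModel(b0, model.beta_age, model.beta_male,
                                model.beta_bmi, model.beta_college)
            return float(np.dot(w_all, m.predict(prof_all)) / w_all.sum())

    b0 = brentq(lambda b: mean_prev(b) - target, -20.0, 20.0, xtol=1e-10)
    return PrevalenceModel(
        float(b0), model.beta_age, model.beta_male, model.beta_bmi, model.beta_college
    )
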