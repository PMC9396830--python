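"""Synthetic survey-weighted baseline populations.

The simulated roster stands in for a national health-survey sample of
adults aged 20+: each row is one individual carrying demographics
(age, sex, education), exposures (BMI, occupation group), chronic
back-problem status, and — for cases — an ordinal pain level 0–4.
A constant survey weight maps the sample to the represented
population. Rosters are plain pandas DataFrames so downstream modules
can operate on them with vectorised numpy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AGE_BANDS",
    "OCCUPATION_GROUPS",
    "PAIN_LEVELS",
    "MarginsError",
    "PopulationMargins",
    "generate_population",
    "marginal_summary",
    "save_roster",
    "load_roster",
]

#: Ten-year age bands; the open-ended top band is modelled as 80-100.
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (20, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 100),
)

#: Occupation categories: seven 1-digit occupational groups plus adults
#: not in the labour force.  Group 3 (clerical) is the low-risk reference.
OCCUPATION_GROUPS: tuple[str, ...] = (
    "group_1", "group_2", "group_3", "group_4",
    "group_5", "group_6", "group_7", "not_working",
)

PAIN_LEVELS = (0, 1, 2, 3, 4)

#: Geometric taper ratio for single ages inside the open 80+ band.
_TAPER = 0.82

ROSTER_COLUMNS = [
    "id", "survey_weight", "age", "sex", "education", "bmi", "occupation",
    "has_back_problems", "pain_level", "exercising", "ergo_protected",
    "active",
]


class MarginsError(ValueError):
    """Raised when a marginal-distribution specification is invalid."""


def _check_simplex(name: str, shares: np.ndarray) -> np.ndarray:
    shares = np.asarray(shares, dtype=float)
    if np.any(shares < -1e-12) or np.any(shares > 1 + 1e-12):
        raise MarginsError(f"{name}: entries must lie in [0, 1], got {shares}")
    if abs(shares.sum() - 1.0) > 1e-9:
        raise MarginsError(
            f"{name}: shares must sum to 1 (got {shares.sum():.12f})"
        )
    return np.clip(shares, 0.0, 1.0)


@dataclass
class PopulationMargins:
    """Target marginal distributions for a synthetic adult roster.

    Shares are population (survey-weighted) proportions; `pain_level_shares`
    is conditional on having back problems.
    """

    age_band_shares: Sequence[float]
    male_share: float
    college_share: float
    bmi_mean: float
    bmi_sd: float
    occupation_shares: Mapping[str, float]
    back_problem_prevalence: float
    pain_level_shares: Sequence[float]
    population_total: float

    def __post_init__(self) -> None:
        self.age_band_shares = _check_simplex(
            "age_band_shares", np.asarray(self.age_band_shares, float)
        )
        if len(self.age_band_shares) != len(AGE_BANDS):
            raise MarginsError(
                f"age_band_shares needs {len(AGE_BANDS)} entries"
            )
        for name, p in [
            ("male_share", self.male_share),
            ("college_share", self.college_share),
            ("back_problem_prevalence", self.back_problem_prevalence),
        ]:
            if not 0.0 <= p <= 1.0:
                raise MarginsError(f"{name} must be in [0, 1], got {p}")
        if self.bmi_mean <= 10 or self.bmi_sd < 0:
            raise MarginsError(
                "bmi_mean must exceed 10 and bmi_sd be non-negative"
            )
        occ = dict(self.occupation_shares)
        unknown = set(occ) - set(OCCUPATION_GROUPS)
        if unknown:
            raise MarginsError(f"unknown occupation groups: {sorted(unknown)}")
        vec = np.array([occ.get(g, 0.0) for g in OCCUPATION_GROUPS])
        _check_simplex("occupation_shares", vec)
        self.occupation_shares = {g: float(v) for g, v in zip(OCCUPATION_GROUPS, vec)}
        self.pain_level_shares = _check_simplex(
            "pain_level_shares", np.asarray(self.pain_level_shares, float)
        )
        if len(self.pain_level_shares) != 5:
            raise MarginsError("pain_level_shares needs 5 entries (levels 0-4)")
        if self.population_total <= 0:
            raise MarginsError("population_total must be positive")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_band_shares"] = [float(x) for x in self.age_band_shares]
        d["pain_level_shares"] = [float(x) for x in self.pain_level_shares]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationMargins":
        return cls(**dict(d))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PopulationMargins":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _band_age_probs(lo: int, hi: int) -> np.ndarray:
    """Within-band single-age probabilities: uniform for closed bands,
    geometric taper for the open-ended top band."""
    ages = np.arange(lo, hi + 1)
    if hi - lo == 9:
        return np.full(ages.size, 1.0 / ages.size)
    w = _TAPER ** (ages - lo)
    return w / w.sum()


def sample_ages(
    band_shares: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw integer ages: band by target share, single age within band."""
    bands = rng.choice(len(AGE_BANDS), size=n, p=band_shares)
    ages = np.empty(n, dtype=np.int64)
    for i, (lo, hi) in enumerate(AGE_BANDS):
        m = bands == i
        if m.any():
            ages[m] = rng.choice(
                np.arange(lo, hi + 1), size=int(m.sum()), p=_band_age_probs(lo, hi)
            )
    return ages


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def sample_covariates(
    margins: PopulationMargins, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Demographics and exposures only; disease state left unset."""
    mu, sigma = lognormal_params(margins.bmi_mean, margins.bmi_sd)
    occ_names = list(OCCUPATION_GROUPS)
    occ_p = np.array([margins.occupation_shares[g] for g in occ_names])
    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "survey_weight": np.full(n, margins.population_total / n),
            "age": sample_ages(np.asarray(margins.age_band_shares), n, rng),
            "sex": np.where(rng.random(n) < margins.male_share, "male", "female"),
            "education": np.where(
                rng.random(n) < margins.college_share, "college+", "less-than-college"
            ),
            "bmi": np.maximum(rng.lognormal(mu, sigma, size=n), 10.5),
            "occupation": np.asarray(occ_names, dtype=object)[
                rng.choice(len(occ_names), size=n, p=occ_p)
            ],
        }
    )
    df["has_back_problems"] = False
    df["pain_level"] = np.nan
    df["exercising"] = False
    df["ergo_protected"] = False
    df["active"] = True
    return df


def generate_population(
    margins: PopulationMargins,
    n: int,
    seed: int,
    *,
    prevalence_model=None,
    pain_model=None,
    pain_sampler=None,
) -> pd.DataFrame:
    """Generate a synthetic roster of ``n`` adults from marginal targets.

    In the default *fast mode*, back-problem status and pain level are
    sampled independently from the configured margins.  In *correlated
    mode* (both models supplied), back problems follow the logistic
    prevalence model given each individual's covariates and pain levels
    are drawn from the stationary distribution of that individual's
    pain-transition chain, so baseline disease state is consistent with
    the dynamics that will evolve it.

    Survey weights are constant, ``population_total / n``, and sum to the
    population total exactly.  The draw is deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    roster = sample_covariates(margins, n, rng)

    if prevalence_model is not None:
        p = prevalence_model.predict(roster)
    else:
        p = np.full(n, margins.back_problem_prevalence)
    roster["has_back_problems"] = rng.random(n) < p

    cases = roster.index[roster["has_back_problems"]]
    if len(cases):
        if pain_sampler is not None:
            probs = pain_sampler(roster.loc[cases])
        elif pain_model is not None:
            probs = pain_model.stationary_distribution(roster.loc[cases])
        else:
            probs = np.tile(np.asarray(margins.pain_level_shares), (len(cases), 1))
        u = rng.random(len(cases))
        levels = (u[:, None] > probs.cumsum(axis=1)[:, :-1]).sum(axis=1)
        roster.loc[cases, "pain_level"] = levels.astype(float)
    return roster


def marginal_summary(roster: pd.DataFrame) -> PopulationMargins:
    """Weighted empirical margins of a roster, in the target's shape.

    Inverse of :func:`generate_population` up to Monte-Carlo error; used
    for validation tables comparing simulated against target margins.
    """
    active = roster[roster["active"]]
    if len(active) == 0:
        raise ValueError("cannot summarise an empty roster")
    w = active["survey_weight"].to_numpy()
    total = w.sum()
    age = active["age"].to_numpy()
    band_shares = [
        w[(age >= lo) & (age <= hi)].sum() / total for lo, hi in AGE_BANDS
    ]
    # top band is open-ended in summaries
    band_shares[-1] = w[age >= AGE_BANDS[-1][0]].sum() / total
    occ = {
        g: w[active["occupation"].to_numpy() == g].sum() / total
        for g in OCCUPATION_GROUPS
    }
    cases = active["has_back_problems"].to_numpy()
    wc = w[cases].sum()
    if wc > 0:
        lv = active["pain_level"].to_numpy()[cases]
        pain = [w[cases][lv == k].sum() / wc for k in PAIN_LEVELS]
    else:
        pain = [1.0, 0.0, 0.0, 0.0, 0.0]
    # normalise away float round-off so the result validates
    band_shares = list(np.asarray(band_shares) / np.sum(band_shares))
    s = sum(occ.values())
    occ = {g: v / s for g, v in occ.items()}
    pain = list(np.asarray(pain) / np.sum(pain))
    return PopulationMargins(
        age_band_shares=band_shares,
        male_share=float(w[active["sex"].to_numpy() == "male"].sum() / total),
        college_share=float(w[active["education"].to_numpy() == "college+"].sum() / total),
        bmi_mean=float(np.average(active["bmi"], weights=w)),
        bmi_sd=float(
            np.sqrt(np.average((active["bmi"] - np.average(active["bmi"], weights=w)) ** 2, weights=w))
        ),
        occupation_shares=occ,
        back_problem_prevalence=float(w[cases].sum() / total),
        pain_level_shares=pain,
        population_total=float(total),
    )


def save_roster(roster: pd.DataFrame, path) -> None:
    roster.to_csv(path, index=False, lineterminator="\n")


def load_roster(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"roster file missing columns: {sorted(missing)}")
    return df


def roster_bytes(roster: pd.DataFrame) -> bytes:
    """Canonical CSV serialisation, for byte-level determinism checks."""
    buf = io.StringIO()
    save_roster(roster, buf)
    return buf.getvalue().encode()
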