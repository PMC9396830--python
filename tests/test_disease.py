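"""Prevalence, incidence calibration, and the proportional-odds pain model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lbpsim.disease import (
    IncidenceSchedule,
    PainTransitionModel,
    PrevalenceModel,
    calibrate_incidence,
    calibrate_prevalence_intercept,
    onset,
    pain_transition,
    proportional_odds_probs,
    sample_ordinal,
)
from lbpsim.synthpop import generate_population, sample_covariates


def _profile(**over):
    base = dict(age=[50], sex=["female"], education=["college+"], bmi=[26.0],
                occupation=["group_3"], ergo_protected=[False])
    base.update({k: [v] for k, v in over.items()})
    return pd.DataFrame(base)


class TestPrevalence:
    def test_null_model_gives_half(self):
        m = PrevalenceModel(0.0, 0.0, 0.0, 0.0, 0.0)
        assert m.predict(_profile())[0] == pytest.approx(0.5)

    def test_bmi_monotonicity(self):
        m = PrevalenceModel(-1.0, 0.0, 0.0, np.log(1.14) / 5, 0.0)
        lo = m.predict(_profile(bmi=25.0))[0]
        hi = m.predict(_profile(bmi=30.0))[0]
        assert hi > lo
        # +5 BMI multiplies the odds by exactly the configured OR
        assert (hi / (1 - hi)) / (lo / (1 - lo)) == pytest.approx(1.14)

    def test_intercept_calibration_hits_target(self, margins):
        m = calibrate_prevalence_intercept(
            PrevalenceModel(0.0, 0.015, -0.1, 0.026, -0.2), margins, 0.207
        )
        roster = generate_population(margins, 200_000, 5, prevalence_model=m)
        prev = roster["has_back_problems"].mean()
        se = np.sqrt(0.207 * 0.793 / 200_000)
        assert abs(prev - 0.207) < 3 * se


class TestIncidenceCalibration:
    def test_constant_prevalence_means_zero_incidence(self, margins):
        m = PrevalenceModel(-1.34, 0.0, 0.0, 0.0, 0.0)  # age-flat
        sched = calibrate_incidence(m, margins)
        assert np.allclose(sched.hazards["male"], 0.0, atol=1e-12)

    def test_exponential_onset_closed_form(self):
        """p(a) = 1 - e^{-h(a-20)} implies a constant hazard 1 - e^{-h}."""
        h = 0.03
        ages = np.arange(20, 102)
        p = 1 - np.exp(-h * (ages - 20))
        i = (p[1:] - p[:-1]) / (1 - p[:-1])
        assert np.allclose(i, 1 - np.exp(-h), atol=1e-6)

    def test_cohort_recursion_reproduces_prevalence_curve(self, bundle, margins):
        """Simulating onset with the calibrated hazards keeps a cohort on
        the prevalence model's age curve."""
        from lbpsim.disease import expected_prevalence_by_age

        rng = np.random.default_rng(3)
        n = 40_000
        prof = sample_covariates(margins, n, rng)
        prof["age"] = 30
        prof["sex"] = "female"
        p30 = expected_prevalence_by_age(
            bundle.prevalence_model, margins, np.array([30]), "female"
        )[0]
        prof["has_back_problems"] = rng.random(n) < bundle.prevalence_model.predict(prof)
        prof.loc[prof["has_back_problems"], "pain_level"] = 1.0
        for age in range(30, 60):
            prof = onset(prof, bundle.incidence, bundle.pain_model, rng)
            prof["age"] += 1
        p60 = expected_prevalence_by_age(
            bundle.prevalence_model, margins, np.array([60]), "female"
        )[0]
        got = prof["has_back_problems"].mean()
        se = np.sqrt(p60 * (1 - p60) / n)
        # cohort-vs-margins BMI quadrature differences leave a small bias
        assert abs(got - p60) < 4 * se + 0.005


class TestProportionalOdds:
    def test_boundary_eta(self):
        p = proportional_odds_probs(-50.0, (-1, 0, 1, 2))
        assert np.allclose(p, [1, 0, 0, 0, 0], atol=1e-12)

    def test_median_cutpoint_exact_half(self):
        p = proportional_odds_probs(0.0, (-1, 0, 1, 2))
        assert p[2:].sum() == pytest.approx(0.5)  # P(level >= 2) at c2 = 0

    def test_cumulative_odds_ratio_identity(self):
        """Adding ln(1.14) to eta multiplies every cumulative odds by 1.14."""
        c = (-1.0, 0.2, 1.1, 2.5)
        p0 = proportional_odds_probs(0.3, c)
        p1 = proportional_odds_probs(0.3 + np.log(1.14), c)
        for k in range(1, 5):
            odds0 = p0[k:].sum() / p0[:k].sum()
            odds1 = p1[k:].sum() / p1[:k].sum()
            assert odds1 / odds0 == pytest.approx(1.14, rel=1e-9)

    def test_non_increasing_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            proportional_odds_probs(0.0, (0, 0, 1, 2))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        eta=st.floats(-20, 20),
        c1=st.floats(-5, 5),
        gaps=st.tuples(*[st.floats(0.01, 3)] * 3),
    )
    def test_probability_conservation(self, eta, c1, gaps):
        c = np.concatenate([[c1], c1 + np.cumsum(gaps)])
        p = proportional_odds_probs(eta, c)
        assert np.all(p >= -1e-15)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(eta=st.floats(-4, 4), delta=st.floats(0.01, 2))
    def test_stochastically_increasing_in_eta(self, eta, delta):
        c = (-1.0, 0.0, 1.0, 2.0)
        lo = proportional_odds_probs(eta, c)
        hi = proportional_odds_probs(eta + delta, c)
        lo_tail = lo[::-1].cumsum()[::-1]  # P(level >= k), k = 0..4
        hi_tail = hi[::-1].cumsum()[::-1]
        assert np.all(hi_tail >= lo_tail - 1e-15)


class TestPainTransition:
    def test_extreme_cutpoints_pin_level_zero(self, rng):
        m = PainTransitionModel(cutpoints=(50, 51, 52, 53), beta_bmi=0.0)
        roster = _profile()
        roster["has_back_problems"] = True
        roster["pain_level"] = 3.0
        roster["exercising"] = False
        roster["active"] = True
        roster["survey_weight"] = 1.0
        out = pain_transition(roster, m, rng)
        assert out["pain_level"].iloc[0] == 0.0

    def test_missing_pain_level_rejected(self, rng):
        m = PainTransitionModel(cutpoints=(0, 1, 2, 3))
        roster = _profile()
        roster["has_back_problems"] = True
        roster["pain_level"] = np.nan
        roster["exercising"] = False
        roster["active"] = True
        with pytest.raises(ValueError):
            pain_transition(roster, m, rng)

    def test_long_run_matches_analytic_stationary(self, rng):
        """Empirical occupancy of one profile's chain converges to the
        eigenvector stationary distribution."""
        m = PainTransitionModel(
            cutpoints=(0.5, 1.2, 2.0, 3.0), ar_offsets=(0.4, 0.8, 1.2, 1.6),
            beta_bmi=0.0,
        )
        pi = m.stationary_for_eta(0.0)[0]
        # simulate one long chain via the transition matrix
        T = m.transition_matrix(0.0)
        n_steps = 200_000
        states = np.empty(n_steps, dtype=int)
        s = 0
        u = rng.random(n_steps)
        cumT = T.cumsum(axis=1)
        for t in range(n_steps):
            s = int(np.searchsorted(cumT[s], u[t]))
            states[t] = s
        emp = np.bincount(states[1000:], minlength=5) / (n_steps - 1000)
        # autocorrelated chain: allow a generous effective-sample factor
        se = np.sqrt(pi * (1 - pi) / (n_steps / 20))
        assert np.all(np.abs(emp - pi) < 3 * se + 1e-3)


class TestOnset:
    def _noncases(self, margins, n, rng):
        prof = sample_covariates(margins, n, rng)
        prof["has_back_problems"] = False
        prof["pain_level"] = np.nan
        return prof

    def test_zero_hazard_changes_nothing(self, margins, bundle, rng):
        sched = IncidenceSchedule({"male": np.zeros(81), "female": np.zeros(81)})
        prof = self._noncases(margins, 2000, rng)
        out = onset(prof, sched, bundle.pain_model, rng)
        assert not out["has_back_problems"].any()

    def test_certain_onset_always_painful(self, margins, bundle, rng):
        sched = IncidenceSchedule({"male": np.ones(81), "female": np.ones(81)})
        prof = self._noncases(margins, 2000, rng)
        out = onset(prof, sched, bundle.pain_model, rng)
        assert out["has_back_problems"].all()
        assert (out["pain_level"] >= 1).all()

    def test_onset_pain_distribution_chisquare(self, bundle, rng):
        """Initial pain levels follow the renormalised proportional-odds
        probabilities (chi-square GOF at n = 50k, one fixed profile)."""
        from scipy.stats import chisquare

        n = 50_000
        prof = _profile().loc[_profile().index.repeat(n)].reset_index(drop=True)
        prof["has_back_problems"] = False
        prof["pain_level"] = np.nan
        prof["active"] = True
        sched = IncidenceSchedule({"male": np.ones(81), "female": np.ones(81)})
        out = onset(prof, sched, bundle.pain_model, rng)
        eta = bundle.pain_model.linear_predictor(prof.iloc[[0]])[0]
        p = proportional_odds_probs(eta, bundle.pain_model.cutpoints)
        expected = p[1:] / p[1:].sum() * n
        observed = np.bincount(out["pain_level"].astype(int), minlength=5)[1:]
        stat, pval = chisquare(observed, expected)
        assert pval > 1e-4

    def test_back_problems_absorbing(self, bundle, margins, rng):
        """Nobody ever reverts to not having back problems."""
        roster = generate_population(
            margins, 3000, 8,
            prevalence_model=bundle.prevalence_model,
            pain_model=bundle.pain_model,
        )
        ever = roster["has_back_problems"].copy()
        for _ in range(5):
            roster = onset(roster, bundle.incidence, bundle.pain_model, rng)
            roster = pain_transition(roster, bundle.pain_model, rng)
            assert (roster["has_back_problems"] | ~ever).all()
            ever = roster["has_back_problems"].copy()


def test_group3_reference_enforced():
    with pytest.raises(ValueError):
        PainTransitionModel(cutpoints=(0, 1, 2, 3), occupation_rr={"group_3": 1.5})


def test_pain_model_roundtrip(tmp_path, bundle):
    p = tmp_path / "pain.yaml"
    bundle.pain_model.save(p)
    loaded = PainTransitionModel.load(p)
    assert loaded.cutpoints == pytest.approx(bundle.pain_model.cutpoints)
    assert loaded.beta_bmi == pytest.approx(np.log(1.14) / 5)
    assert loaded.ar_offsets == pytest.approx(bundle.pain_model.ar_offsets)
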