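"""Open-population dynamics and flow calibration."""

import numpy as np
import pandas as pd
import pytest

from lbpsim.demography import (
    AGE_MAX,
    FlowSchedule,
    MortalitySchedule,
    advance_demography,
    calibrate_flows,
    gompertz_mortality,
    growth_targets,
    project_totals,
    totals_from_roster,
)
from lbpsim.synthpop import generate_population


NO_FLOWS = FlowSchedule()


def constant_mortality(q):
    arr = np.full(AGE_MAX + 1, q)
    return MortalitySchedule({"male": arr.copy(), "female": arr.copy()})


@pytest.fixture()
def roster(margins):
    return generate_population(margins, 5000, 5)


def test_zero_mortality_zero_flows_is_pure_aging(roster, rng):
    out = advance_demography(roster, 2020, constant_mortality(0.0), NO_FLOWS, rng)
    assert out["active"].all()
    assert (out["age"].to_numpy() == np.minimum(roster["age"] + 1, AGE_MAX)).all()


def test_certain_death_empties_population(roster, rng):
    out = advance_demography(roster, 2020, constant_mortality(1.0), NO_FLOWS, rng)
    assert not out["active"].any()


def test_underage_roster_rejected(roster, rng):
    bad = roster.copy()
    bad.loc[bad.index[0], "age"] = 15
    with pytest.raises(ValueError):
        advance_demography(bad, 2020, constant_mortality(0.0), NO_FLOWS, rng)


def test_missing_schedule_cell_named(roster, rng):
    q = {"male": np.full(AGE_MAX + 1, 0.01)}  # no female table
    sched = MortalitySchedule(q)
    with pytest.raises(KeyError, match="female"):
        advance_demography(roster, 2020, sched, NO_FLOWS, rng)


def test_constant_hazard_survival_matches_binomial(margins):
    """Ten years at q = 0.01: weighted survivors ~ total x 0.99^10."""
    n, q, steps = 50_000, 0.01, 10
    roster = generate_population(margins, n, 6)
    rng = np.random.default_rng(6)
    sched = constant_mortality(q)
    for year in range(2020, 2020 + steps):
        roster = advance_demography(roster, year, sched, NO_FLOWS, rng)
    total = margins.population_total
    expected = total * (1 - q) ** steps
    # binomial SE on the number of survivors, scaled by the weight
    p = (1 - q) ** steps
    se = total * np.sqrt(p * (1 - p) / n)
    got = roster.loc[roster["active"], "survey_weight"].sum()
    assert abs(got - expected) < 3 * se


def test_gompertz_life_expectancy_and_monotonicity():
    sched = gompertz_mortality()
    for sex, target in [("male", 80.0), ("female", 84.0)]:
        q = sched.q(2020, sex, np.arange(AGE_MAX + 1))
        assert np.all(np.diff(q[40:]) >= 0), "q must not decrease above 40"
        surv = np.concatenate([[1.0], np.cumprod(1 - q)])
        e0 = np.sum((surv[:-1] + surv[1:]) / 2)
        assert e0 == pytest.approx(target, abs=0.5)


class TestCalibration:
    def test_self_consistent_target_needs_no_flows(self, roster):
        mort = constant_mortality(0.01)
        years = range(2020, 2026)
        proj = project_totals(totals_from_roster(roster), mort, NO_FLOWS, years)
        targets = proj[proj["year"] > 2020]
        flows = calibrate_flows(totals_from_roster(roster), mort, targets)
        assert flows.entries["count"].sum() == pytest.approx(0.0, abs=1e-6)
        assert len(flows.exit_prob) == 0 or flows.exit_prob["prob"].max() < 1e-12

    def test_growth_target_recovered_within_tolerance(self, roster):
        """2%/year net inflow: re-projection reproduces targets to 0.1%."""
        mort = constant_mortality(0.01)
        years = range(2020, 2031)
        init = totals_from_roster(roster)
        targets = growth_targets(init, mort, years, annual_growth=0.02)
        flows = calibrate_flows(init, mort, targets)
        proj = project_totals(init, mort, flows, years)
        for year in range(2021, 2031):
            want = targets.loc[targets["year"] == year, "total"].sum()
            got = proj.loc[proj["year"] == year, "total"].sum()
            assert got == pytest.approx(want, rel=1e-3)

    def test_idempotence(self, roster):
        mort = constant_mortality(0.005)
        years = range(2020, 2026)
        init = totals_from_roster(roster)
        targets = growth_targets(init, mort, years, annual_growth=0.01)
        flows1 = calibrate_flows(init, mort, targets)
        proj = project_totals(init, mort, flows1, years)
        flows2 = calibrate_flows(init, mort, proj[proj["year"] > 2020])
        merged = flows1.entries.merge(
            flows2.entries, on=["year", "sex", "age"], how="outer"
        ).fillna(0.0)
        assert np.allclose(merged["count_x"], merged["count_y"], rtol=1e-6, atol=1e-6)

    def test_infeasible_target_rejected(self, roster):
        mort = constant_mortality(0.01)
        targets = pd.DataFrame(
            [(2021, "male", 30, -5.0)], columns=["year", "sex", "age", "total"]
        )
        with pytest.raises(ValueError, match="year=2021"):
            calibrate_flows(totals_from_roster(roster), mort, targets)


def test_stochastic_mean_matches_expectation(margins):
    """Expectation-mode projection equals the stochastic mean: the mean
    weighted total over seeded replicates lies within 3 SE."""
    n = 4000
    mort = constant_mortality(0.02)
    roster0 = generate_population(margins, n, 77)
    init = totals_from_roster(roster0)
    years = range(2020, 2026)
    targets = growth_targets(init, mort, years, annual_growth=0.01)
    flows = calibrate_flows(init, mort, targets)
    proj = project_totals(init, mort, flows, years)
    expected = proj.loc[proj["year"] == 2025, "total"].sum()

    totals = []
    for seed in range(30):
        roster = roster0.copy()
        rng = np.random.default_rng(1000 + seed)
        for year in range(2020, 2025):
            roster = advance_demography(
                roster, year, mort, flows, rng, entry_margins=margins
            )
        totals.append(roster.loc[roster["active"], "survey_weight"].sum())
    totals = np.asarray(totals)
    se = totals.std(ddof=1) / np.sqrt(len(totals))
    assert abs(totals.mean() - expected) < 3 * se
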