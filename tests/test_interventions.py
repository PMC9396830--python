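"""Intervention mechanics and the scenario catalog."""

import numpy as np
import pytest

from lbpsim.interventions import (
    BMI_FLOOR,
    InterventionSpec,
    apply_bmi_intervention,
    apply_ergonomic_intervention,
    apply_exercise_intervention,
    exercise_eligible,
    scenario_catalog,
)
from lbpsim.synthpop import generate_population


@pytest.fixture()
def roster(margins, bundle):
    return generate_population(
        margins, 20_000, 13,
        prevalence_model=bundle.prevalence_model, pain_model=bundle.pain_model,
    )


class TestBmi:
    def test_zero_level_is_identity(self, roster):
        spec = InterventionSpec(id="b0", type="bmi_reduction", level=0.0)
        out = apply_bmi_intervention(roster, spec, 2021)
        assert np.array_equal(out["bmi"], roster["bmi"])

    def test_eligibility_rechecked(self, roster):
        spec = InterventionSpec(id="b5", type="bmi_reduction", level=5.0)
        r = roster.copy()
        r.loc[r.index[0], "bmi"] = 26.0
        out = apply_bmi_intervention(r, spec, 2021)
        assert out["bmi"].iloc[0] == pytest.approx(21.0)
        out2 = apply_bmi_intervention(out, spec, 2022)
        assert out2["bmi"].iloc[0] == pytest.approx(21.0)  # now below 25

    def test_hard_floor(self, roster):
        spec = InterventionSpec(id="b9", type="bmi_reduction", level=9.0)
        out = apply_bmi_intervention(roster, spec, 2021)
        assert out["bmi"].min() >= min(BMI_FLOOR, roster["bmi"].min())

    def test_under_25_untouched(self, roster):
        spec = InterventionSpec(id="b2", type="bmi_reduction", level=2.0)
        lean = roster["bmi"] < 25
        out = apply_bmi_intervention(roster, spec, 2021)
        assert np.array_equal(out.loc[lean, "bmi"], roster.loc[lean, "bmi"])

    def test_outside_horizon_is_identity(self, roster):
        spec = InterventionSpec(id="b2", type="bmi_reduction", level=2.0)
        out = apply_bmi_intervention(roster, spec, 2019)
        assert np.array_equal(out["bmi"], roster["bmi"])


class TestErgonomic:
    def test_zero_coverage(self, roster, rng):
        spec = InterventionSpec(id="e0", type="ergonomic", level=0.0,
                                target="all_workers")
        out = apply_ergonomic_intervention(roster, spec, rng)
        assert not out["ergo_protected"].any()

    def test_full_coverage_protects_all_workers(self, roster, rng):
        spec = InterventionSpec(id="e1", type="ergonomic", level=1.0,
                                target="all_workers")
        out = apply_ergonomic_intervention(roster, spec, rng)
        worker = out["occupation"] != "not_working"
        assert out.loc[worker, "ergo_protected"].all()
        assert not out.loc[~worker, "ergo_protected"].any()

    def test_half_coverage_binomial(self, roster, rng):
        spec = InterventionSpec(id="e5", type="ergonomic", level=0.5,
                                target="all_workers")
        out = apply_ergonomic_intervention(roster, spec, rng)
        worker = out["occupation"] != "not_working"
        n_w = int(worker.sum())
        share = out.loc[worker, "ergo_protected"].mean()
        assert abs(share - 0.5) < 3 * np.sqrt(0.25 / n_w) + 1.0 / n_w

    def test_group_targeting(self, roster, rng):
        spec = InterventionSpec(id="eg6", type="ergonomic",
                                target=("group_6",))
        out = apply_ergonomic_intervention(roster, spec, rng)
        g6 = out["occupation"] == "group_6"
        assert out.loc[g6, "ergo_protected"].all()
        assert not out.loc[~g6, "ergo_protected"].any()

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            InterventionSpec(id="bad", type="ergonomic", target=("group_9",))

    def test_protection_zeroes_pain_offset(self, roster, bundle, rng):
        spec = InterventionSpec(id="e1", type="ergonomic", level=1.0,
                                target="all_workers")
        out = apply_ergonomic_intervention(roster, spec, rng)
        off = bundle.pain_model.occupation_offset(out)
        assert np.allclose(off, 0.0)


class TestExercise:
    def test_zero_coverage(self, roster, rng):
        spec = InterventionSpec(id="x0", type="exercise", level=0.0,
                                target="eligible_patients")
        out = apply_exercise_intervention(roster, spec, 2021, rng)
        assert not out["exercising"].any()

    def test_coverage_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            InterventionSpec(id="x2", type="exercise", level=1.5,
                             target="eligible_patients")

    def test_full_coverage_hits_every_eligible(self, roster, rng):
        spec = InterventionSpec(id="x1", type="exercise", level=1.0,
                                target="eligible_patients")
        out = apply_exercise_intervention(roster, spec, 2021, rng)
        elig = exercise_eligible(out)
        assert out.loc[elig, "exercising"].all()
        assert not out.loc[~elig, "exercising"].any()

    def test_ineligible_drop_out(self, roster, rng):
        spec = InterventionSpec(id="x1", type="exercise", level=1.0,
                                target="eligible_patients")
        out = apply_exercise_intervention(roster, spec, 2021, rng)
        out.loc[out["exercising"], "pain_level"] = 4.0  # everyone deteriorates
        spec0 = InterventionSpec(id="x0", type="exercise", level=0.0,
                                 target="eligible_patients")
        out2 = apply_exercise_intervention(out, spec0, 2022, rng)
        assert not out2["exercising"].any()

    def test_rr_mode_multiplies_cumulative_odds(self, roster, bundle):
        """An exercising participant's cumulative odds of pain >= k are
        multiplied by exactly 0.71 at every threshold."""
        from lbpsim.disease import proportional_odds_probs

        m = bundle.pain_model
        prof = roster.iloc[[0]]
        eta = m.linear_predictor(prof, prev_pain=np.array([2]))[0]
        p0 = proportional_odds_probs(eta, m.cutpoints)
        p1 = proportional_odds_probs(eta + np.log(0.71), m.cutpoints)
        for k in range(1, 5):
            ratio = (p1[k:].sum() / p1[:k].sum()) / (p0[k:].sum() / p0[:k].sum())
            assert ratio == pytest.approx(0.71, rel=1e-9)


class TestCatalog:
    def test_exactly_one_base_case(self):
        cat = scenario_catalog()
        assert sum(s.is_base for s in cat) == 1

    def test_39_scenarios(self):
        assert len(scenario_catalog()) == 39

    def test_group3_not_targeted(self):
        for s in scenario_catalog():
            if isinstance(s.target, tuple):
                assert "group_3" not in s.target

    def test_coverages_within_unit_interval(self):
        for s in scenario_catalog():
            if s.type in ("ergonomic", "exercise") and not isinstance(s.target, tuple):
                assert 0.0 <= s.level <= 1.0

    def test_printed_bmi_levels_present(self):
        bmi = {s.level for s in scenario_catalog() if s.type == "bmi_reduction"}
        assert {0.1, 0.3, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0} <= bmi
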