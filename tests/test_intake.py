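"""Added-intake arithmetic, supplement conversion, and coverage metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fortisim import (
    THRESHOLD_PRESETS,
    CoverageMetrics,
    DietaryRecord,
    DomainError,
    FortificationPlan,
    SupplementScenario,
    Thresholds,
    added_vitamin_d,
    coverage_metrics,
    total_intake,
)
from fortisim.errors import EmptyInputError
from fortisim.intake import population_intakes


def _rec(baseline=0.0, grams=None):
    return DietaryRecord("r", 40, "F", 2000.0, baseline, 0.0, grams or {})


class TestAddedVitaminD:
    def test_hand_arithmetic(self, toy_record):
        plan = FortificationPlan({"milk": 3.0, "bread": 2.0})
        assert added_vitamin_d(toy_record, plan) == pytest.approx(8.0)

    def test_zero_plan_adds_nothing(self, toy_record):
        assert added_vitamin_d(toy_record, FortificationPlan({"milk": 0.0, "bread": 0.0})) == 0.0

    def test_uniform_3_over_eight_100g_vehicles_gives_24ug(self):
        grams = {f"food{i}": 100.0 for i in range(8)}
        plan = FortificationPlan.uniform(3.0, grams)
        assert added_vitamin_d(_rec(grams=grams), plan) == pytest.approx(24.0)

    def test_vehicle_missing_from_record_contributes_zero(self):
        plan = FortificationPlan({"milk": 4.0, "kashk": 4.0})
        assert added_vitamin_d(_rec(grams={"milk": 50.0}), plan) == pytest.approx(2.0)

    def test_negative_level_rejected(self, toy_record):
        with pytest.raises(DomainError):
            added_vitamin_d(toy_record, FortificationPlan({"milk": -1.0}))

    @given(
        grams=st.lists(st.floats(0, 1000), min_size=1, max_size=6),
        levels=st.lists(st.floats(0, 10), min_size=6, max_size=6),
        scale=st.floats(0.1, 5),
    )
    def test_oracle_equivalence_and_linearity(self, grams, levels, scale):
        """Matches an independently coded double loop; linear in levels."""
        names = [f"v{i}" for i in range(len(grams))]
        record = _rec(grams=dict(zip(names, grams)))
        plan = FortificationPlan(dict(zip(names, levels[: len(grams)])))
        oracle = 0.0
        for name in names:  # independent summation
            oracle += record.grams[name] * plan.levels[name]
        oracle /= 100.0
        got = added_vitamin_d(record, plan)
        assert got == pytest.approx(oracle, abs=1e-9)
        scaled = FortificationPlan({k: v * scale for k, v in plan.levels.items()})
        assert added_vitamin_d(record, scaled) == pytest.approx(scale * got, rel=1e-9, abs=1e-9)


class TestTotalIntake:
    def test_additivity_without_supplement(self, toy_record):
        toy_record.baseline_vitd = 4.0
        plan = FortificationPlan({"milk": 3.0, "bread": 2.0})
        assert total_intake(toy_record, plan, SupplementScenario.none()) == pytest.approx(12.0)

    def test_400iu_supplement_converts_at_40_iu_per_ug(self):
        rec = _rec(baseline=4.0)
        assert total_intake(rec, FortificationPlan({}), SupplementScenario.dose(400)) == pytest.approx(14.0)

    def test_zero_everything(self):
        assert total_intake(_rec(), FortificationPlan({}), SupplementScenario.none()) == 0.0

    def test_excluded_supplement_ignored(self):
        scenario = SupplementScenario(dose_iu=1000.0, include_supplement=False)
        assert total_intake(_rec(baseline=4.0), FortificationPlan({}), scenario) == pytest.approx(4.0)

    def test_population_vector_matches_per_record(self, small_population):
        plan = FortificationPlan.uniform(2.0, sorted(small_population[0].grams))
        scenario = SupplementScenario.dose(400)
        vec = population_intakes(small_population, plan, scenario)
        per_record = [total_intake(r, plan, scenario) for r in small_population]
        np.testing.assert_allclose(vec, per_record, rtol=1e-12)


class TestCoverage:
    def test_enumeration_oracle(self):
        m = coverage_metrics([5.0, 15.0, 300.0], Thresholds(10.0, 250.0))
        assert m.frac_below_ri == pytest.approx(1 / 3)
        assert m.frac_within == pytest.approx(1 / 3)
        assert m.frac_above_ul == pytest.approx(1 / 3)
        assert m.max_intake == 300.0

    def test_boundaries_count_as_within(self):
        thr = Thresholds(10.0, 100.0)
        m = coverage_metrics([10.0, 10.0, 100.0], thr)
        assert m.frac_within == 1.0

    def test_unfortified_cohort_mean_sits_below_ri(self):
        m = coverage_metrics([4.0], THRESHOLD_PRESETS["iom"])
        assert m.frac_below_ri == 1.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            coverage_metrics([], Thresholds(10.0, 100.0))

    @given(
        intakes=st.lists(st.floats(0, 500), min_size=1, max_size=200),
        ri=st.floats(1, 50),
        span=st.floats(1, 300),
    )
    def test_partition_sums_to_exactly_one(self, intakes, ri, span):
        m = coverage_metrics(intakes, Thresholds(ri, ri + span))
        assert m.frac_below_ri + m.frac_above_ul + m.frac_within == 1.0
        for frac in (m.frac_below_ri, m.frac_above_ul, m.frac_within):
            assert 0.0 <= frac <= 1.0


@given(level=st.floats(0, 4), bump=st.floats(0.01, 4))
def test_raising_a_level_weakly_improves_adequacy(small_population, level, bump):
    """Monotonicity: a higher level never increases the below-RI fraction."""
    names = sorted(small_population[0].grams)
    thr = THRESHOLD_PRESETS["iom"]
    lo = coverage_metrics(
        population_intakes(small_population, FortificationPlan.uniform(level, names)), thr
    )
    hi = coverage_metrics(
        population_intakes(small_population, FortificationPlan.uniform(level + bump, names)), thr
    )
    assert hi.frac_below_ri <= lo.frac_below_ri
    assert hi.frac_above_ul >= lo.frac_above_ul
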