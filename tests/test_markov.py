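import math

import numpy as np
import pytest

from hba1c_cea.core import State
from hba1c_cea.lifetable import LifeTable
from hba1c_cea.markov import (
    ModelSettings,
    mortality_probability,
    run_cohort,
    run_cohort_batch,
    step,
)

IDENTITY = np.eye(2)


def zero_mortality_table(age_min=40, age_max=100):
    ages = np.arange(age_min, age_max + 1)
    return LifeTable(ages, np.zeros_like(ages, dtype=float))


def constant_hazard_table(rate, age_min=40, age_max=200):
    ages = np.arange(age_min, age_max + 1)
    return LifeTable(ages, np.full(ages.shape, rate, dtype=float))


class TestMortalityProbability:
    def test_zero_rate_gives_zero(self):
        lt = zero_mortality_table()
        assert mortality_probability(50, State.UNCONTROLLED, lt, rr=2.0) == 0.0

    def test_null_relative_risk_equalizes_states(self, life_table):
        q_c = mortality_probability(60, State.CONTROLLED, life_table, rr=1.0)
        q_u = mortality_probability(60, State.UNCONTROLLED, life_table, rr=1.0)
        assert q_c == q_u

    def test_hazard_scale_closed_form(self):
        lt = constant_hazard_table(0.02, 40, 100)
        q = mortality_probability(50, State.UNCONTROLLED, lt, rr=1.30)
        assert q == pytest.approx(1.0 - math.exp(-0.026), rel=1e-12)

    def test_forced_absorption_beyond_table(self, life_table):
        assert mortality_probability(100, State.CONTROLLED, life_table, rr=1.3) == 1.0


class TestStep:
    def test_all_dead_is_absorbing_with_zero_increments(self, life_table):
        settings = ModelSettings()
        occ, inc = step([0.0, 0.0, 1.0], 50, IDENTITY, settings, life_table, (100.0, 200.0), 1)
        np.testing.assert_allclose(occ, [0.0, 0.0, 1.0])
        assert inc["ly"] == inc["qaly"] == inc["cost"] == 0.0

    def test_unit_rewards_without_mortality_or_discounting(self):
        settings = ModelSettings(discount_rate=0.0, utility_controlled=1.0, utility_uncontrolled=1.0)
        lt = zero_mortality_table()
        _, inc = step([0.16, 0.84, 0.0], 50, IDENTITY, settings, lt, (0.0, 0.0), 1)
        assert inc["ly"] == pytest.approx(1.0)
        assert inc["qaly"] == pytest.approx(1.0)

    def test_one_cycle_hand_matrix_product(self):
        # annual matrix: c->u 0.58, u->c 0.17; zero mortality
        annual = np.array([[0.42, 0.58], [0.17, 0.83]])
        settings = ModelSettings(discount_rate=0.0)
        occ, _ = step([0.16, 0.84, 0.0], 40, annual, settings, zero_mortality_table(), (0.0, 0.0), 1)
        expected_c = 0.16 * 0.42 + 0.84 * 0.17
        np.testing.assert_allclose(occ, [expected_c, 1.0 - expected_c, 0.0], atol=1e-12)

    def test_invalid_occupancy_rejected(self, life_table):
        with pytest.raises(ValueError, match="sum to 1"):
            step([0.5, 0.4, 0.0], 50, IDENTITY, ModelSettings(), life_table, (0.0, 0.0), 1)


class TestRunCohort:
    def test_zero_cycles_when_max_age_equals_start_age(self, life_table):
        settings = ModelSettings(start_age=40, max_age=40)
        res = run_cohort("annual", IDENTITY, life_table, settings, (100.0, 100.0))
        assert res.lys == res.qalys == res.cost == 0.0

    def test_annuity_limit_without_mortality(self):
        settings = ModelSettings(
            start_age=40, max_age=100, discount_rate=0.0, utility_controlled=1.0, utility_uncontrolled=1.0
        )
        res = run_cohort("annual", IDENTITY, zero_mortality_table(), settings, (0.0, 0.0))
        assert res.lys == pytest.approx(60.0)
        assert res.qalys == pytest.approx(60.0)

    def test_geometric_life_expectancy_closed_form(self):
        # constant per-cycle death probability q -> undiscounted LYs = (1-q)/q
        q = 0.1
        rate = -math.log(1.0 - q)
        horizon = int(10 / q)
        lt = constant_hazard_table(rate, 40, 40 + horizon + 1)
        settings = ModelSettings(
            start_age=40, max_age=40 + horizon, discount_rate=0.0, rr_mortality_uncontrolled=1.0,
            utility_controlled=1.0, utility_uncontrolled=1.0,
        )
        res = run_cohort("annual", IDENTITY, lt, settings, (0.0, 0.0))
        truncation = (1 - q) ** (horizon + 1) / q
        assert res.lys_undiscounted == pytest.approx((1 - q) / q, abs=max(1e-9, 2 * truncation))

    def test_uncovered_life_table_rejected(self):
        lt = zero_mortality_table(40, 80)
        with pytest.raises(ValueError, match="cover"):
            run_cohort("annual", IDENTITY, lt, ModelSettings(max_age=100), (0.0, 0.0))


class TestCohortProperties:
    def test_probability_conservation_and_monotone_dead_fraction(self, config, life_table):
        res = run_cohort(
            "6-monthly", config.annual_matrix("6-monthly"), life_table, config.model_settings(), (1000.0, 1100.0)
        )
        occ = res.trace.occupancy()
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(occ[:, 2]) >= -1e-12)
        assert occ.min() >= -1e-12

    def test_discounted_totals_nonincreasing_in_discount_rate(self, config, life_table):
        totals = []
        for rate in (0.0, 0.03, 0.05):
            settings = ModelSettings(discount_rate=rate)
            res = run_cohort("annual", config.annual_matrix("annual"), life_table, settings, (1000.0, 1100.0))
            totals.append((res.cost, res.qalys, res.lys))
        for a, b in zip(totals, totals[1:]):
            assert all(x >= y for x, y in zip(a, b))

    def test_qalys_increase_with_control_gains(self, config, life_table):
        settings = config.model_settings()
        base = config.annual_matrix("annual")
        better = base.copy()
        better[1, 0] += 0.05
        better[1, 1] -= 0.05
        q_base = run_cohort("a", base, life_table, settings, (0.0, 0.0)).qalys
        q_better = run_cohort("b", better, life_table, settings, (0.0, 0.0)).qalys
        assert q_better > q_base

    def test_unit_utilities_make_qalys_equal_lys(self, config, life_table):
        settings = ModelSettings(utility_controlled=1.0, utility_uncontrolled=1.0)
        res = run_cohort("annual", config.annual_matrix("annual"), life_table, settings, (0.0, 0.0))
        assert res.qalys == pytest.approx(res.lys, rel=1e-12)
        assert res.qalys_undiscounted == pytest.approx(res.lys_undiscounted, rel=1e-12)

    def test_batch_engine_matches_scalar_engine(self, config, life_table):
        settings = config.model_settings()
        matrix = config.annual_matrix("3-monthly")
        scalar = run_cohort("3-monthly", matrix, life_table, settings, (950.0, 1050.0))
        batch = run_cohort_batch(matrix[None], life_table, settings, np.array([[950.0, 1050.0]]))
        assert batch["cost_disc"][0] == pytest.approx(scalar.cost, rel=1e-12)
        assert batch["qalys_disc"][0] == pytest.approx(scalar.qalys, rel=1e-12)
        assert batch["lys"][0] == pytest.approx(scalar.lys_undiscounted, rel=1e-12)

    def test_half_cycle_correction_reduces_first_year_weighting(self, config, life_table):
        base = run_cohort("annual", config.annual_matrix("annual"), life_table, config.model_settings(), (1000.0, 1100.0))
        settings_hcc = ModelSettings(half_cycle_correction=True)
        hcc = run_cohort("annual", config.annual_matrix("annual"), life_table, settings_hcc, (1000.0, 1100.0))
        # averaging with the (larger) start-of-cycle living mass raises totals
        assert hcc.lys > base.lys
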