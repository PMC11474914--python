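import numpy as np
import pandas as pd
import pytest

from hba1c_cea.config import StudyConfig
from hba1c_cea.pipeline import run_base_case
from hba1c_cea.sensitivity import (
    ceac,
    fit_distribution,
    one_way,
    run_psa,
    se_from_ci,
    tornado,
)


class TestFitDistribution:
    def test_gamma_moment_algebra(self):
        mean = 244.66
        dist = fit_distribution(mean, sd=0.25 * mean, family="gamma")
        assert dist.params["shape"] == pytest.approx(16.0)
        assert dist.params["scale"] == pytest.approx(mean / 16.0)

    def test_se_recovered_from_ci(self):
        assert se_from_ci(0.22, 0.27) == pytest.approx(0.05 / 3.92)
        dist = fit_distribution(0.24, ci=(0.22, 0.27), family="beta")
        assert dist.sd == pytest.approx(0.05 / 3.92)

    @pytest.mark.parametrize(
        "family,mean,sd", [("gamma", 9.0, 14.0), ("beta", 0.71, 0.013), ("beta", 0.24, 0.0128)]
    )
    def test_round_trip_moments(self, family, mean, sd):
        dist = fit_distribution(mean, sd=sd, family=family)
        if family == "gamma":
            fitted_mean = dist.params["shape"] * dist.params["scale"]
            fitted_var = dist.params["shape"] * dist.params["scale"] ** 2
        else:
            a, b = dist.params["a"], dist.params["b"]
            fitted_mean = a / (a + b)
            fitted_var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert fitted_mean == pytest.approx(mean, abs=1e-9)
        assert fitted_var == pytest.approx(sd * sd, abs=1e-9)

    def test_zero_sd_is_fixed_point_mass(self):
        dist = fit_distribution(5.0, sd=0.0)
        rng = np.random.default_rng(0)
        assert np.all(dist.draw(rng, 10) == 5.0)

    def test_infeasible_beta_variance_shrunk(self, caplog):
        dist = fit_distribution(0.5, sd=0.6, family="beta")
        bound = np.sqrt(0.25)
        assert dist.sd == pytest.approx(0.95 * bound)

    def test_invalid_means_rejected(self):
        with pytest.raises(ValueError, match="gamma mean"):
            fit_distribution(-1.0, sd=1.0, family="gamma")
        with pytest.raises(ValueError, match="beta mean"):
            fit_distribution(1.2, sd=0.1, family="beta")


class TestOneWay:
    def test_degenerate_bounds_give_zero_width(self, config, life_table):
        base = config.unit_costs.cost_per_inpatient_day
        res = one_way(config, life_table, "unit_costs.cost_per_inpatient_day", base, base)
        assert res.width == 0.0

    def test_inpatient_cost_range_moves_icer(self, config, life_table):
        base = config.unit_costs.cost_per_inpatient_day
        res = one_way(config, life_table, "unit_costs.cost_per_inpatient_day", 0.75 * base, 1.25 * base)
        assert res.width > 0.0  # utilization differs by state

    def test_discounting_monotonicity_on_qalys(self, config, life_table):
        def qalys_annual(cfg, lt):
            return run_base_case(cfg, lt)[0].qalys

        res = one_way(config, life_table, "engine.discount_rate", 0.0, 0.05, outcome=qalys_annual)
        assert res.outcome_low > res.outcome_high

    def test_unknown_parameter_lists_valid_names(self, config, life_table):
        with pytest.raises(ValueError, match="cost_per_inpatient_day"):
            one_way(config, life_table, "unit_costs.bogus", 0.0, 1.0)

    def test_tornado_sorted_by_width(self, config, life_table):
        df = tornado(config, life_table)
        assert (df["width"].diff().dropna() <= 1e-12).all()
        assert df["width"].iloc[0] > 0


class TestPSA:
    def test_degenerate_psa_reproduces_deterministic_base_case(self, life_table):
        data = StudyConfig().model_dump()
        data["psa"]["default_cv"] = 0.0
        for state in ("controlled", "uncontrolled"):
            for f in ("inpatient_days_sd", "clinic_visits_sd", "ed_outpatient_visits_sd"):
                data["utilization"][state][f] = 0.0
            data["utilities"][f"{state}_sd"] = 0.0
            tr = data["transitions"]
        for block in tr.values():
            for p in block.values():
                p["lower"] = p["upper"] = p["mean"]
        config = StudyConfig(**data)
        res = run_psa(config, life_table, n_iterations=1, seed=0)
        det = run_base_case(config, life_table)
        for j, r in enumerate(det):
            assert res.costs[0, j] == pytest.approx(r.cost, rel=1e-12)
            assert res.qalys[0, j] == pytest.approx(r.qalys, rel=1e-12)

    def test_same_seed_gives_identical_matrices(self, config, life_table):
        a = run_psa(config, life_table, n_iterations=200, seed=11)
        b = run_psa(config, life_table, n_iterations=200, seed=11)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)
        pd.testing.assert_frame_equal(a.ceac, b.ceac)

    def test_psa_means_near_deterministic(self, config, life_table):
        res = run_psa(config, life_table, n_iterations=3000, seed=1)
        det = run_base_case(config, life_table)
        n = res.costs.shape[0]
        for j, r in enumerate(det):
            se_cost = res.costs[:, j].std(ddof=1) / np.sqrt(n)
            assert abs(res.costs[:, j].mean() - r.cost) < 3 * se_cost


class TestCeac:
    def test_single_iteration_is_indicator(self):
        costs = np.array([[10.0, 20.0]])
        qalys = np.array([[1.0, 2.0]])
        out = ceac(costs, qalys, [0.0, 100.0], ["a", "b"])
        assert out.loc[0, "a"] == 1.0 and out.loc[0, "b"] == 0.0
        assert out.loc[1, "b"] == 1.0  # 100/QALY > ICER of 10

    def test_zero_threshold_rewards_cheapest(self, config, life_table):
        res = run_psa(config, life_table, n_iterations=500, seed=2)
        row0 = res.ceac.iloc[0]
        assert row0["lambda"] == 0.0
        assert row0["annual"] == max(row0[list(res.strategies)])

    def test_rows_sum_to_one_with_tie_splitting(self):
        costs = np.array([[10.0, 10.0, 30.0]])
        qalys = np.array([[1.0, 1.0, 1.5]])
        out = ceac(costs, qalys, [0.0], ["a", "b", "c"])
        assert out.loc[0, "a"] == out.loc[0, "b"] == 0.5
        assert out[["a", "b", "c"]].sum(axis=1).iloc[0] == pytest.approx(1.0)
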