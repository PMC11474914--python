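"""One-way and probabilistic sensitivity analyses.

One-way analysis reruns the deterministic model with a single parameter
at its low/high bound (cost parameters at ±25% of base, probabilities at
their confidence bounds, discount rate over 0–5%) and reports the output
at each bound; the tornado table sorts parameters by output range.

The probabilistic analysis draws every uncertain parameter at once —
beta distributions for probabilities and utilities, gamma for costs and
utilization, hyperparameters matched to the published mean and SD (or a
standard error recovered from a 95% CI as width/3.92) by method of
moments — and propagates each draw through all four strategies on the
batch cohort engine (common random numbers across strategies).
Parameters without a published SD default to a coefficient of variation
of 0.25.  Testing-panel costs for the four testing frequencies share one
multiplicative gamma factor: they are built from the same component unit
costs, and independent draws would break the monotone panel-cost
invariant.  The cost-effectiveness acceptability curve reports, per
threshold, the fraction of draws in which each strategy attains the
maximum net monetary benefit (ties split equally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig
from .core import STRATEGIES, STRATEGY_TESTS_PER_YEAR
from .lifetable import LifeTable
from .markov import run_cohort_batch

logger = logging.getLogger(__name__)

__all__ = ["ParamDist", "fit_distribution", "se_from_ci", "OneWayResult", "one_way", "tornado", "PSAResult", "run_psa", "ceac"]


# --------------------------------------------------------------------------
# distribution fitting

@dataclass(frozen=True)
class ParamDist:
    """A fitted parameter distribution with moment-matched hyperparameters."""

    family: str  # "gamma" | "beta" | "fixed"
    mean: float
    sd: float
    params: dict = field(default_factory=dict)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(size, self.mean)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size)
        if self.family == "beta":
            return rng.beta(self.params["a"], self.params["b"], size)
        raise ValueError(f"unknown family {self.family!r}")


def se_from_ci(lower: float, upper: float) -> float:
    """Standard error recovered from a normal-approximation 95% CI."""
    if upper < lower:
        raise ValueError("upper CI bound below lower bound")
    return (upper - lower) / 3.92


def fit_distribution(
    mean: float,
    sd: float | None = None,
    ci: tuple[float, float] | None = None,
    family: str = "gamma",
) -> ParamDist:
    """Method-of-moments gamma/beta hyperparameters from mean and SD/CI.

    Gamma: shape = (mean/sd)^2, scale = sd^2/mean (mean > 0 required).
    Beta: a = mean*(mean(1-mean)/var - 1), b = (1-mean)*(...); mean must
    lie in (0, 1) and an infeasible variance (>= mean(1-mean)) is shrunk
    to 95% of the feasibility bound with a warning.  sd = 0 (or a missing
    SD and CI) yields a degenerate point mass treated as fixed.
    """
    if sd is None:
        sd = se_from_ci(*ci) if ci is not None else 0.0
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return ParamDist("fixed", mean, 0.0)
    if family == "gamma":
        if mean <= 0:
            raise ValueError("gamma mean must be > 0")
        shape = (mean / sd) ** 2
        return ParamDist("gamma", mean, sd, {"shape": shape, "scale": sd * sd / mean})
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
        bound = mean * (1 - mean)
        var = sd * sd
        if var >= bound:
            sd = 0.95 * np.sqrt(bound)
            var = sd * sd
            logger.warning("beta variance infeasible for mean %.3f; SD shrunk to %.4f", mean, sd)
        nu = bound / var - 1.0
        return ParamDist("beta", mean, sd, {"a": mean * nu, "b": (1 - mean) * nu})
    raise ValueError(f"unknown family {family!r}")


# --------------------------------------------------------------------------
# one-way sensitivity

@dataclass(frozen=True)
class OneWayResult:
    parameter: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _set_by_path(data: dict, path: str, value) -> None:
    keys = path.split(".")
    node = data
    for k in keys[:-1]:
        if not isinstance(node, dict) or k not in node:
            raise KeyError(path)
        node = node[k]
    if not isinstance(node, dict) or keys[-1] not in node:
        raise KeyError(path)
    node[keys[-1]] = value


def _resolved_dump(config: StudyConfig) -> dict:
    """Config dump with the calibrated inpatient factor frozen in.

    One-way perturbations must not silently recalibrate the factor, or
    inpatient-side variation would be absorbed by the calibration.
    """
    data = config.model_dump()
    if data["utilization"]["inpatient_annualization_factor"] is None:
        data["utilization"]["inpatient_annualization_factor"] = (
            config.utilization_obj().inpatient_annualization_factor
        )
    return data


def _perturbed(config: StudyConfig, param: str, value: float) -> StudyConfig:
    data = _resolved_dump(config)
    try:
        _set_by_path(data, param, value)
    except KeyError:
        valid = sorted(_leaf_paths(data))
        raise ValueError(f"unknown parameter {param!r}; valid names include: {valid}") from None
    return StudyConfig(**data)


def _leaf_paths(data: dict, prefix: str = "") -> list[str]:
    out = []
    for k, v in data.items():
        path = f"{prefix}{k}"
        if isinstance(v, dict):
            out.extend(_leaf_paths(v, path + "."))
        elif isinstance(v, (int, float)) and not isinstance(v, bool):
            out.append(path)
    return out


def icer_6m_vs_annual(config: StudyConfig, life_table: LifeTable) -> float:
    """Deterministic ICER (USD/QALY) of 6-monthly vs annual monitoring."""
    from .pipeline import run_base_case

    results = {r.strategy: r for r in run_base_case(config, life_table)}
    a, b = results["annual"], results["6-monthly"]
    return (b.cost - a.cost) / (b.qalys - a.qalys)


def one_way(
    config: StudyConfig,
    life_table: LifeTable,
    param: str,
    low: float,
    high: float,
    outcome: Callable[[StudyConfig, LifeTable], float] = icer_6m_vs_annual,
) -> OneWayResult:
    """Rerun the deterministic model at each parameter bound."""
    if low > high:
        raise ValueError("low bound exceeds high bound")
    out_low = outcome(_perturbed(config, param, low), life_table)
    out_high = outcome(_perturbed(config, param, high), life_table)
    return OneWayResult(param, low, high, out_low, out_high)


#: Parameters swept by the standard tornado: ±25% cost/utilization
#: ranges, CI bounds for probabilities and the relative risk, 0–5% for
#: the discount rate.
def _tornado_params(config: StudyConfig) -> list[tuple[str, float, float]]:
    def pm25(path: str, base: float) -> tuple[str, float, float]:
        return (path, 0.75 * base, 1.25 * base)

    uc = config.unit_costs
    ut = config.utilization
    params = [
        pm25("unit_costs.cost_per_inpatient_day", uc.cost_per_inpatient_day),
        pm25("unit_costs.cost_per_clinic_visit", uc.cost_per_clinic_visit),
        pm25("unit_costs.cost_per_ed_outpatient_visit", uc.cost_per_ed_outpatient_visit),
        pm25("unit_costs.avg_treatment_cost", uc.avg_treatment_cost),
        pm25("unit_costs.complications_cost_controlled", uc.complications_cost_controlled),
        pm25("unit_costs.complications_cost_uncontrolled", uc.complications_cost_uncontrolled),
        pm25("utilization.controlled.inpatient_days_mean", ut.controlled.inpatient_days_mean),
        pm25("utilization.uncontrolled.inpatient_days_mean", ut.uncontrolled.inpatient_days_mean),
        pm25("utilization.controlled.ed_outpatient_visits_mean", ut.controlled.ed_outpatient_visits_mean),
        pm25("utilization.uncontrolled.ed_outpatient_visits_mean", ut.uncontrolled.ed_outpatient_visits_mean),
        ("engine.discount_rate", 0.0, 0.05),
        ("rr_mortality.mean", config.rr_mortality.lower, config.rr_mortality.upper),
        ("transitions.six_monthly.p_u_to_c.mean", config.transitions.six_monthly.p_u_to_c.lower, config.transitions.six_monthly.p_u_to_c.upper),
        ("transitions.annual.p_u_to_c.mean", config.transitions.annual.p_u_to_c.lower, config.transitions.annual.p_u_to_c.upper),
    ]
    return params


def tornado(
    config: StudyConfig,
    life_table: LifeTable,
    outcome: Callable[[StudyConfig, LifeTable], float] = icer_6m_vs_annual,
) -> pd.DataFrame:
    """Standard one-way sweep, sorted by descending output range."""
    base_value = outcome(StudyConfig(**_resolved_dump(config)), life_table)
    rows = []
    for param, low, high in _tornado_params(config):
        res = one_way(config, life_table, param, low, high, outcome)
        rows.append(
            {
                "parameter": res.parameter,
                "low": res.low,
                "high": res.high,
                "outcome_low": res.outcome_low,
                "outcome_high": res.outcome_high,
                "width": res.width,
                "outcome_base": base_value,
            }
        )
    return pd.DataFrame(rows).sort_values("width", ascending=False, ignore_index=True)


# --------------------------------------------------------------------------
# probabilistic sensitivity

@dataclass
class PSAResult:
    """Iteration x strategy PSA output with acceptability curves."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_iterations, n_strategies), discounted USD
    qalys: np.ndarray  # (n_iterations, n_strategies)
    lambda_grid: np.ndarray
    ceac: pd.DataFrame  # columns: lambda, one per strategy
    renormalized_rows: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategies,
                "mean_cost": self.costs.mean(axis=0),
                "mean_qalys": self.qalys.mean(axis=0),
                "sd_cost": self.costs.std(axis=0, ddof=1) if len(self.costs) > 1 else 0.0,
                "sd_qalys": self.qalys.std(axis=0, ddof=1) if len(self.qalys) > 1 else 0.0,
            }
        )


def _psa_distributions(config: StudyConfig) -> dict[str, ParamDist]:
    """Every uncertain parameter's fitted sampling distribution.

    The PSA propagates uncertainty in the parameter *means*.  Transition
    probabilities carry confidence intervals, which already measure that
    uncertainty; the trial-derived utilization and utility rows publish
    patient-level SDs instead, so those are converted to standard errors
    of the mean via SD/sqrt(trial n).  Mixing the two scales would weight
    utilities thousands of times more heavily than transitions.
    """
    cv = config.psa.default_cv
    root_n = float(np.sqrt(config.psa.trial_n))
    uc = config.unit_costs
    ut = config.utilization
    dists: dict[str, ParamDist] = {}
    for name, base in [
        ("cost_per_inpatient_day", uc.cost_per_inpatient_day),
        ("cost_per_clinic_visit", uc.cost_per_clinic_visit),
        ("cost_per_ed_outpatient_visit", uc.cost_per_ed_outpatient_visit),
        ("avg_treatment_cost", uc.avg_treatment_cost),
        ("complications_cost_controlled", uc.complications_cost_controlled),
        ("complications_cost_uncontrolled", uc.complications_cost_uncontrolled),
    ]:
        dists[name] = fit_distribution(base, sd=cv * base, family="gamma")
    dists["testing_panel_scale"] = fit_distribution(1.0, sd=cv, family="gamma")
    for state, cfg in [("controlled", ut.controlled), ("uncontrolled", ut.uncontrolled)]:
        dists[f"inpatient_days_{state}"] = fit_distribution(cfg.inpatient_days_mean, sd=cfg.inpatient_days_sd / root_n, family="gamma")
        dists[f"clinic_visits_{state}"] = fit_distribution(cfg.clinic_visits_mean, sd=cfg.clinic_visits_sd / root_n, family="gamma")
        dists[f"ed_outpatient_visits_{state}"] = fit_distribution(
            cfg.ed_outpatient_visits_mean, sd=cfg.ed_outpatient_visits_sd / root_n, family="gamma"
        )
    dists["utility_controlled"] = fit_distribution(
        config.utilities.controlled, sd=config.utilities.controlled_sd / root_n, family="beta"
    )
    dists["utility_uncontrolled"] = fit_distribution(
        config.utilities.uncontrolled, sd=config.utilities.uncontrolled_sd / root_n, family="beta"
    )
    for strategy in STRATEGIES:
        tr = config.transitions.for_strategy(strategy)
        dists[f"p_u_to_c_{strategy}"] = fit_distribution(
            tr.p_u_to_c.mean, ci=(tr.p_u_to_c.lower, tr.p_u_to_c.upper), family="beta"
        )
        dists[f"p_c_to_u_{strategy}"] = fit_distribution(
            tr.p_c_to_u.mean, ci=(tr.p_c_to_u.lower, tr.p_c_to_u.upper), family="beta"
        )
    return dists


def run_psa(
    config: StudyConfig,
    life_table: LifeTable | None = None,
    n_iterations: int | None = None,
    seed: int | None = None,
    lambda_grid: Sequence[float] | None = None,
) -> PSAResult:
    """Joint Monte-Carlo sampling of all uncertain parameters.

    Each iteration draws one value per parameter and runs all four
    strategies on that same draw; output matrices are deterministic for a
    fixed seed.  The relative risk of mortality is held at its base value
    (it is examined in the one-way analysis instead).
    """
    if life_table is None:
        life_table = config.make_life_table()
    n = config.psa.n_iterations if n_iterations is None else int(n_iterations)
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    seed = config.psa.seed if seed is None else seed
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, config.psa.lambda_grid_max + 1e-9, config.psa.lambda_grid_step)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be nonempty")

    rng = np.random.default_rng(seed)
    dists = _psa_distributions(config)
    draws = {name: dist.draw(rng, n) for name, dist in dists.items()}

    factor = config.utilization_obj().inpatient_annualization_factor
    settings = config.model_settings()
    utilities = np.stack([draws["utility_controlled"], draws["utility_uncontrolled"]], axis=1)

    renormalized = 0
    costs_out = np.empty((n, len(STRATEGIES)))
    qalys_out = np.empty((n, len(STRATEGIES)))
    for j, strategy in enumerate(STRATEGIES):
        p_uc = draws[f"p_u_to_c_{strategy}"]
        p_cu = draws[f"p_c_to_u_{strategy}"]
        trans = np.empty((n, 2, 2))
        trans[:, 0, 0], trans[:, 0, 1] = 1 - p_cu, p_cu
        trans[:, 1, 0], trans[:, 1, 1] = p_uc, 1 - p_uc
        rowsum = trans.sum(axis=2)
        bad = np.abs(rowsum - 1.0) > 1e-9
        if bad.any():  # cannot occur for two living states, kept for safety
            renormalized += int(bad.any(axis=1).sum())
            trans /= rowsum[..., None]

        panel_cost = config.unit_costs.testing_panel_cost_by_n_tests[STRATEGY_TESTS_PER_YEAR[strategy]]
        state_costs = np.empty((n, 2))
        for i, state in enumerate(("controlled", "uncontrolled")):
            state_costs[:, i] = (
                panel_cost * draws["testing_panel_scale"]
                + draws["avg_treatment_cost"]
                + draws[f"clinic_visits_{state}"] * draws["cost_per_clinic_visit"]
                + draws[f"ed_outpatient_visits_{state}"] * draws["cost_per_ed_outpatient_visit"]
                + draws[f"inpatient_days_{state}"] * factor * draws["cost_per_inpatient_day"]
                + draws[f"complications_cost_{state}"]
            )
        totals = run_cohort_batch(trans, life_table, settings, state_costs, utilities=utilities)
        costs_out[:, j] = totals["cost_disc"]
        qalys_out[:, j] = totals["qalys_disc"]

    ceac_df = ceac(costs_out, qalys_out, lambda_grid, STRATEGIES)
    if renormalized:
        logger.warning("renormalized %d transition rows during PSA draws", renormalized)
    return PSAResult(tuple(STRATEGIES), costs_out, qalys_out, lambda_grid, ceac_df, renormalized)


def ceac(
    costs: np.ndarray,
    qalys: np.ndarray,
    lambda_grid: Sequence[float],
    strategies: Sequence[str] = STRATEGIES,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA matrices.

    At each threshold, each strategy's probability is the fraction of
    iterations in which it attains the maximum net monetary benefit,
    ties split equally; rows therefore sum to one.
    """
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    grid = np.asarray(lambda_grid, dtype=float)
    rows = []
    for lam in grid:
        nmb = qalys * lam - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        rows.append([lam, *share.mean(axis=0)])
    return pd.DataFrame(rows, columns=["lambda", *strategies])
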