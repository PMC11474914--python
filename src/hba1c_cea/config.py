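"""Study configuration: schema, defaults, validation, loading.

The schema mirrors the model's published input table block by block —
utilization, quality-of-life utilities, unit costs, testing-panel costs,
the cost-effectiveness threshold, annual transition probabilities per
monitoring strategy, and the initial state split — plus engine settings
and sensitivity-analysis controls.  Field defaults are the published
base-case values, so an empty YAML file loads the base case; every
override is validated with the constraint and field path reported.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import ClassVar, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import costs as costs_mod
from .core import STRATEGIES
from .markov import ModelSettings

__all__ = ["StudyConfig", "load_and_validate"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProbabilityCI(_Block):
    mean: float = Field(ge=0.0, le=1.0)
    lower: float = Field(ge=0.0, le=1.0)
    upper: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.lower <= self.mean <= self.upper:
            raise ValueError(f"need lower <= mean <= upper, got ({self.lower}, {self.mean}, {self.upper})")
        return self


class StrategyTransitions(_Block):
    """Annual transition probabilities for one monitoring strategy."""

    p_u_to_c: ProbabilityCI
    p_c_to_u: ProbabilityCI

    def annual_matrix(self):
        import numpy as np

        return np.array(
            [
                [1 - self.p_c_to_u.mean, self.p_c_to_u.mean],
                [self.p_u_to_c.mean, 1 - self.p_u_to_c.mean],
            ]
        )


class StateUtilizationCfg(_Block):
    inpatient_days_mean: float = Field(ge=0)
    inpatient_days_sd: float = Field(ge=0)
    clinic_visits_mean: float = Field(ge=0)
    clinic_visits_sd: float = Field(ge=0)
    ed_outpatient_visits_mean: float = Field(ge=0)
    ed_outpatient_visits_sd: float = Field(ge=0)


class UtilizationCfg(_Block):
    controlled: StateUtilizationCfg = StateUtilizationCfg(
        inpatient_days_mean=7.0, inpatient_days_sd=10.0,
        clinic_visits_mean=4.0, clinic_visits_sd=1.0,
        ed_outpatient_visits_mean=0.75, ed_outpatient_visits_sd=2.56,
    )
    uncontrolled: StateUtilizationCfg = StateUtilizationCfg(
        inpatient_days_mean=9.0, inpatient_days_sd=14.0,
        clinic_visits_mean=4.0, clinic_visits_sd=1.0,
        ed_outpatient_visits_mean=0.77, ed_outpatient_visits_sd=3.07,
    )
    # None -> calibrate so the weighted 1-test annual cost hits the target below
    inpatient_annualization_factor: Optional[float] = Field(default=None, ge=0.0, le=1.0)


class UtilitiesCfg(_Block):
    controlled: float = Field(default=0.75, ge=0.0, le=1.0)
    controlled_sd: float = Field(default=0.35, ge=0.0)
    uncontrolled: float = Field(default=0.71, ge=0.0, le=1.0)
    uncontrolled_sd: float = Field(default=0.34, ge=0.0)


class UnitCostsCfg(_Block):
    cost_per_inpatient_day: float = Field(default=244.66, ge=0)
    cost_per_clinic_visit: float = Field(default=38.97, ge=0)
    cost_per_ed_outpatient_visit: float = Field(default=81.55, ge=0)
    avg_treatment_cost: float = Field(default=59.31, ge=0)
    complications_cost_controlled: float = Field(default=398.53, ge=0)
    complications_cost_uncontrolled: float = Field(default=510.12, ge=0)
    testing_panel_cost_by_n_tests: dict[int, float] = Field(
        default_factory=lambda: {1: 106.46, 2: 116.11, 3: 125.75, 4: 135.40}
    )


class TransitionsCfg(_Block):
    annual: StrategyTransitions = StrategyTransitions(
        p_u_to_c=ProbabilityCI(mean=0.17, lower=0.15, upper=0.19),
        p_c_to_u=ProbabilityCI(mean=0.58, lower=0.53, upper=0.63),
    )
    six_monthly: StrategyTransitions = StrategyTransitions(
        p_u_to_c=ProbabilityCI(mean=0.24, lower=0.22, upper=0.27),
        p_c_to_u=ProbabilityCI(mean=0.67, lower=0.62, upper=0.71),
    )
    four_monthly: StrategyTransitions = StrategyTransitions(
        p_u_to_c=ProbabilityCI(mean=0.26, lower=0.23, upper=0.29),
        p_c_to_u=ProbabilityCI(mean=0.69, lower=0.65, upper=0.73),
    )
    three_monthly: StrategyTransitions = StrategyTransitions(
        p_u_to_c=ProbabilityCI(mean=0.28, lower=0.24, upper=0.30),
        p_c_to_u=ProbabilityCI(mean=0.69, lower=0.64, upper=0.73),
    )

    _BY_STRATEGY: ClassVar[dict[str, str]] = {
        "annual": "annual",
        "6-monthly": "six_monthly",
        "4-monthly": "four_monthly",
        "3-monthly": "three_monthly",
    }

    def for_strategy(self, name: str) -> StrategyTransitions:
        return getattr(self, self._BY_STRATEGY[name])


class MedicationMixCfg(_Block):
    one_oral: float = 0.22
    two_plus_oral: float = 0.27
    oral_plus_insulin: float = 0.41
    insulin_only: float = 0.09

    @model_validator(mode="after")
    def _sums_to_one(self):
        costs_mod.MedicationMix(**self.model_dump())  # delegates range/sum checks
        return self


class CostAdjustmentCfg(_Block):
    exchange_rate_zar_per_usd: float = Field(default=14.45, gt=0)
    base_year: int = 2019
    cpi_index_by_year: dict[int, float] = Field(default_factory=lambda: {2019: 100.0})


class RRMortalityCfg(_Block):
    mean: float = Field(default=1.30, gt=0)
    lower: float = Field(default=1.08, gt=0)
    upper: float = Field(default=1.55, gt=0)


class EngineCfg(_Block):
    start_age: int = 40
    max_age: int = 100
    discount_rate: float = Field(default=0.03, ge=0.0)
    half_cycle_correction: bool = False
    death_first: bool = True


class LifeTableCfg(_Block):
    """Gompertz–Makeham parameters for the synthetic life table."""

    makeham: float = 0.003
    gompertz_scale: float = 3e-5
    gompertz_shape: float = 0.095


class PSACfg(_Block):
    n_iterations: int = Field(default=10_000, ge=1)
    seed: int = 42
    default_cv: float = Field(default=0.25, ge=0)  # for parameters without a printed SD
    # sample size behind the trial-derived utilization/utility means; their
    # published patient-level SDs become standard errors via SD/sqrt(n)
    trial_n: int = Field(default=632, ge=1)
    lambda_grid_max: float = 10_000.0
    lambda_grid_step: float = 100.0


class StudyConfig(_Block):
    """Full study configuration; defaults are the published base case."""

    utilization: UtilizationCfg = UtilizationCfg()
    utilities: UtilitiesCfg = UtilitiesCfg()
    unit_costs: UnitCostsCfg = UnitCostsCfg()
    transitions: TransitionsCfg = TransitionsCfg()
    medication_mix: MedicationMixCfg = MedicationMixCfg()
    cost_adjustment: CostAdjustmentCfg = CostAdjustmentCfg()
    rr_mortality: RRMortalityCfg = RRMortalityCfg()
    engine: EngineCfg = EngineCfg()
    life_table: LifeTableCfg = LifeTableCfg()
    psa: PSACfg = PSACfg()
    cet: float = Field(default=2661.97, ge=0)
    initial_controlled: float = Field(default=0.16, ge=0.0, le=1.0)
    # headline cohort-average annual cost at 1 test/year used for calibration
    calibration_target_annual_cost: float = Field(default=1004.39, gt=0)

    # ---- conversions to the computational layer ----

    def unit_costs_obj(self) -> costs_mod.UnitCosts:
        return costs_mod.UnitCosts(**self.unit_costs.model_dump())

    def utilization_obj(self, calibrate: bool = True) -> costs_mod.UtilizationProfile:
        def su(cfg: StateUtilizationCfg) -> costs_mod.StateUtilization:
            return costs_mod.StateUtilization(**cfg.model_dump())

        factor = self.utilization.inpatient_annualization_factor
        profile = costs_mod.UtilizationProfile(
            controlled=su(self.utilization.controlled),
            uncontrolled=su(self.utilization.uncontrolled),
            inpatient_annualization_factor=factor if factor is not None else 1.0,
        )
        if factor is None and calibrate:
            profile = costs_mod.calibrate_inpatient_factor(
                self.unit_costs_obj(),
                profile,
                (self.initial_controlled, 1 - self.initial_controlled),
                self.calibration_target_annual_cost,
                n_tests=1,
            )
        return profile

    def medication_mix_obj(self) -> costs_mod.MedicationMix:
        return costs_mod.MedicationMix(**self.medication_mix.model_dump())

    def cost_adjustment_obj(self) -> costs_mod.CostAdjustment:
        return costs_mod.CostAdjustment(**self.cost_adjustment.model_dump())

    def model_settings(self, initial_distribution: tuple[float, float] | None = None) -> ModelSettings:
        if initial_distribution is None:
            initial_distribution = (self.initial_controlled, 1 - self.initial_controlled)
        return ModelSettings(
            start_age=self.engine.start_age,
            max_age=self.engine.max_age,
            discount_rate=self.engine.discount_rate,
            initial_distribution=initial_distribution,
            rr_mortality_uncontrolled=self.rr_mortality.mean,
            utility_controlled=self.utilities.controlled,
            utility_uncontrolled=self.utilities.uncontrolled,
            half_cycle_correction=self.engine.half_cycle_correction,
            death_first=self.engine.death_first,
        )

    def make_life_table(self):
        from .lifetable import make_life_table

        return make_life_table(
            makeham=self.life_table.makeham,
            gompertz_scale=self.life_table.gompertz_scale,
            gompertz_shape=self.life_table.gompertz_shape,
            age_min=min(40, self.engine.start_age),
            age_max=self.engine.max_age,
        )

    def annual_matrix(self, strategy: str):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
        return self.transitions.for_strategy(strategy).annual_matrix()

    def config_hash(self) -> str:
        """Stable hash of the fully-resolved configuration."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_and_validate(path: str | Path | None = None) -> StudyConfig:
    """Load a YAML/JSON config; missing fields take base-case defaults.

    An absent or empty file yields the fully-defaulted base case.
    Validation errors report the offending field path and constraint
    (pydantic's behaviour).
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return StudyConfig(**data)
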