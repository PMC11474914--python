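"""Annual per-patient cost of diabetes management.

Costs are built from a provider perspective in 2019 USD: the testing
panel (whose price grows with the number of HbA1c tests per year),
average medication cost, routine clinic visits, emergency/outpatient
visits, inpatient days, and state-specific complication management.

Published unit costs and utilization means do not decompose exactly into
the published headline annual total, so an explicit inpatient
annualization factor bridges the two: it is calibrated so that the
cohort-weighted annual cost at one test per year reproduces the headline
figure while every unit cost stays at its published value.  The
calibration is a closed-form linear solve and is logged when applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .core import State

logger = logging.getLogger(__name__)

__all__ = [
    "UnitCosts",
    "StateUtilization",
    "UtilizationProfile",
    "MedicationMix",
    "CostAdjustment",
    "annual_state_cost",
    "cohort_average_annual_cost",
    "cpi_adjust",
    "zar_to_usd",
    "calibrate_inpatient_factor",
]


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs in 2019 USD."""

    cost_per_inpatient_day: float = 244.66
    cost_per_clinic_visit: float = 38.97
    cost_per_ed_outpatient_visit: float = 81.55
    avg_treatment_cost: float = 59.31
    complications_cost_controlled: float = 398.53
    complications_cost_uncontrolled: float = 510.12
    testing_panel_cost_by_n_tests: Mapping[int, float] = field(
        default_factory=lambda: {1: 106.46, 2: 116.11, 3: 125.75, 4: 135.40}
    )

    def __post_init__(self) -> None:
        scalars = (
            self.cost_per_inpatient_day,
            self.cost_per_clinic_visit,
            self.cost_per_ed_outpatient_visit,
            self.avg_treatment_cost,
            self.complications_cost_controlled,
            self.complications_cost_uncontrolled,
        )
        if any(v < 0 for v in scalars):
            raise ValueError("unit costs must be >= 0")
        panel = dict(self.testing_panel_cost_by_n_tests)
        if any(v < 0 for v in panel.values()):
            raise ValueError("testing panel costs must be >= 0")
        keys = sorted(panel)
        if any(panel[a] > panel[b] for a, b in zip(keys, keys[1:])):
            raise ValueError("testing panel cost must be nondecreasing in tests/year")
        object.__setattr__(self, "testing_panel_cost_by_n_tests", panel)

    def testing_panel_cost(self, n_tests: int) -> float:
        try:
            return self.testing_panel_cost_by_n_tests[n_tests]
        except KeyError:
            raise ValueError(
                f"no testing panel cost for {n_tests} tests/year "
                f"(known: {sorted(self.testing_panel_cost_by_n_tests)})"
            ) from None

    def complications_cost(self, state: State) -> float:
        return (
            self.complications_cost_controlled
            if State(state) is State.CONTROLLED
            else self.complications_cost_uncontrolled
        )


@dataclass(frozen=True)
class StateUtilization:
    """Mean (SD) annual health-service use in one glycaemic state."""

    inpatient_days_mean: float
    inpatient_days_sd: float
    clinic_visits_mean: float
    clinic_visits_sd: float
    ed_outpatient_visits_mean: float
    ed_outpatient_visits_sd: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.__dict__.values()):
            raise ValueError("utilization means and SDs must be >= 0")


@dataclass(frozen=True)
class UtilizationProfile:
    """Per-state utilization plus the inpatient annualization factor.

    The factor multiplies mean inpatient days before costing; see the
    module docstring for why it exists and how it is calibrated.
    """

    controlled: StateUtilization = StateUtilization(7.0, 10.0, 4.0, 1.0, 0.75, 2.56)
    uncontrolled: StateUtilization = StateUtilization(9.0, 14.0, 4.0, 1.0, 0.77, 3.07)
    inpatient_annualization_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inpatient_annualization_factor <= 1.0:
            raise ValueError("inpatient annualization factor must lie in [0, 1]")

    def for_state(self, state: State) -> StateUtilization:
        return self.controlled if State(state) is State.CONTROLLED else self.uncontrolled


@dataclass(frozen=True)
class MedicationMix:
    """Treatment-regimen proportions; documentation/sensitivity only.

    Costing uses the single published average treatment cost, so the mix
    does not enter `annual_state_cost` arithmetic.
    """

    one_oral: float = 0.22
    two_plus_oral: float = 0.27
    oral_plus_insulin: float = 0.41
    insulin_only: float = 0.09

    def __post_init__(self) -> None:
        props = (self.one_oral, self.two_plus_oral, self.oral_plus_insulin, self.insulin_only)
        if any(not 0 <= p <= 1 for p in props):
            raise ValueError("medication proportions must lie in [0, 1]")
        # tolerance admits the published proportions, which sum to 0.99
        if abs(sum(props) - 1.0) > 0.02:
            raise ValueError(f"medication proportions must sum to ~1, got {sum(props)}")


@dataclass(frozen=True)
class CostAdjustment:
    """Currency conversion and CPI re-basing parameters."""

    exchange_rate_zar_per_usd: float = 14.45
    base_year: int = 2019
    cpi_index_by_year: Mapping[int, float] = field(default_factory=lambda: {2019: 100.0})

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.cpi_index_by_year.values()):
            raise ValueError("CPI indices must be > 0")
        object.__setattr__(self, "cpi_index_by_year", dict(self.cpi_index_by_year))


def annual_state_cost(
    state: State,
    n_tests: int,
    unit_costs: UnitCosts,
    utilization: UtilizationProfile,
    mix: MedicationMix | None = None,
) -> float:
    """Annual per-patient cost (USD/year) of management in one state.

    Sum of the testing panel at ``n_tests`` HbA1c tests/year, average
    treatment cost, clinic and emergency/outpatient visits at their unit
    costs, annualized inpatient days, and state-specific complications.
    """
    use = utilization.for_state(state)
    return (
        unit_costs.testing_panel_cost(n_tests)
        + unit_costs.avg_treatment_cost
        + use.clinic_visits_mean * unit_costs.cost_per_clinic_visit
        + use.ed_outpatient_visits_mean * unit_costs.cost_per_ed_outpatient_visit
        + use.inpatient_days_mean
        * utilization.inpatient_annualization_factor
        * unit_costs.cost_per_inpatient_day
        + unit_costs.complications_cost(state)
    )


def cohort_average_annual_cost(
    weights: Sequence[float],
    n_tests: int,
    unit_costs: UnitCosts,
    utilization: UtilizationProfile,
    mix: MedicationMix | None = None,
) -> float:
    """Weighted mean annual cost over (controlled, uncontrolled)."""
    w_c, w_u = float(weights[0]), float(weights[1])
    if w_c < 0 or w_u < 0 or abs(w_c + w_u - 1.0) > 1e-9:
        raise ValueError(f"state weights must be nonnegative and sum to 1, got ({w_c}, {w_u})")
    return w_c * annual_state_cost(State.CONTROLLED, n_tests, unit_costs, utilization, mix) + w_u * annual_state_cost(
        State.UNCONTROLLED, n_tests, unit_costs, utilization, mix
    )


def calibrate_inpatient_factor(
    unit_costs: UnitCosts,
    utilization: UtilizationProfile,
    weights: Sequence[float],
    target_annual_cost: float,
    n_tests: int = 1,
) -> UtilizationProfile:
    """Solve for the inpatient annualization factor hitting a target cost.

    The cohort-average annual cost is affine in the factor, so the solve
    is closed-form.  Returns a profile with the calibrated factor; raises
    if no factor in [0, 1] can reach the target.
    """
    base = replace(utilization, inpatient_annualization_factor=0.0)
    full = replace(utilization, inpatient_annualization_factor=1.0)
    at0 = cohort_average_annual_cost(weights, n_tests, unit_costs, base)
    at1 = cohort_average_annual_cost(weights, n_tests, unit_costs, full)
    slope = at1 - at0
    if slope <= 0:
        raise ValueError("inpatient term contributes nothing; cannot calibrate")
    factor = (target_annual_cost - at0) / slope
    if not 0.0 <= factor <= 1.0:
        raise ValueError(
            f"target annual cost {target_annual_cost} needs factor {factor:.4f} outside [0, 1]"
        )
    logger.info(
        "calibrated inpatient annualization factor to %.6f so that the "
        "%.2f/%.2f-weighted annual cost at %d test(s)/year equals %.2f",
        factor, weights[0], weights[1], n_tests, target_annual_cost,
    )
    return replace(utilization, inpatient_annualization_factor=factor)


def cpi_adjust(amount: float, from_year: int, to_year: int, adjustment: CostAdjustment) -> float:
    """Re-base a cost between years via the CPI ratio."""
    idx = adjustment.cpi_index_by_year
    for year in (from_year, to_year):
        if year not in idx:
            raise ValueError(f"year {year} missing from CPI index")
    return amount * idx[to_year] / idx[from_year]


def zar_to_usd(amount_zar: float, adjustment: CostAdjustment) -> float:
    """Convert South African Rand to USD at the configured average rate."""
    if adjustment.exchange_rate_zar_per_usd <= 0:
        raise ValueError("exchange rate must be > 0")
    return amount_zar / adjustment.exchange_rate_zar_per_usd
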