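"""Shared vocabulary: health states and monitoring strategies.

The model tracks two living glycaemic states — "controlled" (HbA1c < 7%)
and "uncontrolled" (HbA1c >= 7%) — plus an absorbing "dead" state handled
by the cohort engine.  A monitoring strategy is identified by the spacing
of HbA1c tests (months between tests), which fixes the number of tests
billed per year.
"""

from __future__ import annotations

from enum import Enum


class State(str, Enum):
    """Living glycaemic-control states."""

    CONTROLLED = "controlled"
    UNCONTROLLED = "uncontrolled"


LIVING_STATES = (State.CONTROLLED, State.UNCONTROLLED)

#: Strategy name -> months between HbA1c tests.
STRATEGY_INTERVAL_MONTHS: dict[str, int] = {
    "annual": 12,
    "6-monthly": 6,
    "4-monthly": 4,
    "3-monthly": 3,
}

#: Strategy name -> HbA1c tests billed per year.
STRATEGY_TESTS_PER_YEAR: dict[str, int] = {
    "annual": 1,
    "6-monthly": 2,
    "4-monthly": 3,
    "3-monthly": 4,
}

#: Canonical order: ascending testing frequency.
STRATEGIES = tuple(STRATEGY_INTERVAL_MONTHS)


def tests_per_year(interval_months: int) -> int:
    """Number of tests per year implied by a monitoring interval."""
    if 12 % interval_months:
        raise ValueError(f"interval of {interval_months} months does not divide a year")
    return 12 // interval_months


def strategy_for_interval(interval_months: int) -> str:
    for name, months in STRATEGY_INTERVAL_MONTHS.items():
        if months == interval_months:
            return name
    raise ValueError(f"no monitoring strategy with a {interval_months}-month interval")
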