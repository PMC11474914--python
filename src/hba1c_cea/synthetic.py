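"""Synthetic study inputs with known ground truth.

The real analysis drew on restricted laboratory panel data (interval-
spaced HbA1c observations with deaths), a national life table, and trial
utilization/quality-of-life measurements.  None of those are shipped;
this module generates statistically faithful stand-ins so every
downstream stage — transition estimation, costing, the cohort model, the
sensitivity analyses — runs end-to-end against a known truth.

Patients in a simulated panel are observed exactly every monitoring
interval.  Between visits they first face an interval-death risk derived
from the life table (relative risk applied while uncontrolled) and, if
they survive, change glycaemic state according to the interval-root of
the annual transition matrix, so that annualising the interval dynamics
recovers the generating annual matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import fractional_matrix_power

from .core import State, strategy_for_interval
from .lifetable import LifeTable

__all__ = [
    "SyntheticTruth",
    "PanelDataset",
    "default_truth",
    "interval_root",
    "simulate_panel",
    "simulate_utilization_and_utility",
]

PANEL_COLUMNS = ["patient_id", "age_at_obs", "obs_time_months", "hba1c_state", "died_before_next"]


def _check_stochastic(matrix: np.ndarray, name: str = "matrix") -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got {m.shape}")
    if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
        raise ValueError(f"{name} entries must lie in [0, 1]: {m.tolist()}")
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError(f"{name} rows must sum to 1: {m.tolist()}")
    return np.clip(m, 0.0, 1.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth used to generate panels and utilization draws.

    ``annual_matrices`` maps strategy name -> 2x2 annual transition matrix
    over (controlled, uncontrolled), row-stochastic.  Utilization and
    utility parameters are (mean, sd) pairs per state.
    """

    annual_matrices: Mapping[str, np.ndarray]
    rr_mortality: float = 1.30
    initial_controlled_fraction: float = 0.16
    utilization_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "controlled": {"inpatient_days": (7.0, 10.0), "clinic_visits": (4.0, 1.0), "ed_outpatient_visits": (0.75, 2.56)},
            "uncontrolled": {"inpatient_days": (9.0, 14.0), "clinic_visits": (4.0, 1.0), "ed_outpatient_visits": (0.77, 3.07)},
        }
    )
    utility_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"controlled": (0.75, 0.35), "uncontrolled": (0.71, 0.34)}
    )

    def __post_init__(self) -> None:
        mats = {k: _check_stochastic(v, f"annual matrix for {k}") for k, v in self.annual_matrices.items()}
        object.__setattr__(self, "annual_matrices", mats)
        if self.rr_mortality <= 0:
            raise ValueError("rr_mortality must be > 0")
        if not 0.0 <= self.initial_controlled_fraction <= 1.0:
            raise ValueError("initial_controlled_fraction must lie in [0, 1]")
        for state, (mean, sd) in self.utility_params.items():
            if not 0.0 < mean < 1.0:
                raise ValueError(f"utility mean for {state} must lie in (0, 1)")
            if sd < 0:
                raise ValueError("utility SD must be >= 0")


def default_truth() -> SyntheticTruth:
    """Truth mirroring the base-case annual transition probabilities."""
    def mat(p_c_to_u: float, p_u_to_c: float) -> np.ndarray:
        return np.array([[1 - p_c_to_u, p_c_to_u], [p_u_to_c, 1 - p_u_to_c]])

    return SyntheticTruth(
        annual_matrices={
            "annual": mat(0.58, 0.17),
            "6-monthly": mat(0.67, 0.24),
            "4-monthly": mat(0.69, 0.26),
            "3-monthly": mat(0.69, 0.28),
        }
    )


def interval_root(annual_matrix: np.ndarray, interval_months: int) -> np.ndarray:
    """Real ``(12/interval)``-th root of an annual transition matrix.

    Computed by eigendecomposition (fractional matrix power).  Raises if
    the root is complex or not a valid stochastic matrix, naming the
    offending matrix — not every annual matrix embeds in a finer
    discrete-time chain.
    """
    annual = _check_stochastic(annual_matrix, "annual matrix")
    steps_per_year = 12 / interval_months
    if abs(steps_per_year - round(steps_per_year)) > 1e-12:
        raise ValueError(f"interval of {interval_months} months does not divide a year")
    root = fractional_matrix_power(annual, 1.0 / steps_per_year)
    if np.iscomplexobj(root):
        if np.max(np.abs(root.imag)) > 1e-10:
            raise ValueError(f"annual matrix {annual.tolist()} has no real {steps_per_year:.0f}-th root")
        root = root.real
    if np.any(root < -1e-9) or np.any(root > 1 + 1e-9) or np.any(np.abs(root.sum(axis=1) - 1) > 1e-9):
        raise ValueError(
            f"annual matrix {annual.tolist()} has no stochastic {steps_per_year:.0f}-th root: {root.tolist()}"
        )
    root = np.clip(root, 0.0, 1.0)
    return root / root.sum(axis=1, keepdims=True)


@dataclass
class PanelDataset:
    """Interval-observed HbA1c panel with death indicators."""

    frame: pd.DataFrame
    monitoring_interval_months: int

    def __post_init__(self) -> None:
        if self.monitoring_interval_months not in (3, 4, 6, 12):
            raise ValueError("monitoring interval must be one of 3, 4, 6, 12 months")
        self.frame = self.frame.reindex(columns=PANEL_COLUMNS)

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on violation."""
        df = self.frame
        bad_states = set(df["hba1c_state"].unique()) - {s.value for s in State}
        if bad_states:
            raise ValueError(f"unknown HbA1c states: {sorted(bad_states)}")
        step = self.monitoring_interval_months
        for pid, grp in df.groupby("patient_id", sort=False):
            times = grp["obs_time_months"].to_numpy()
            if np.any(np.diff(times) != step):
                raise ValueError(f"patient {pid}: observation times not spaced {step} months apart")
            died = grp["died_before_next"].to_numpy()
            if died[:-1].any():
                raise ValueError(f"patient {pid}: observations recorded after death")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, monitoring_interval_months: int) -> "PanelDataset":
        df = pd.read_csv(path)
        missing = set(PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
        df["died_before_next"] = df["died_before_next"].astype(bool)
        return cls(df, monitoring_interval_months)


def simulate_panel(
    truth: SyntheticTruth,
    interval_months: int,
    n_patients: int,
    n_years: float,
    seed: int,
    life_table: LifeTable | None = None,
    entry_age_range: tuple[int, int] = (40, 65),
) -> PanelDataset:
    """Simulate an interval-observed HbA1c panel from known truth.

    Within each interval, death (life-table hazard scaled to the
    interval, relative risk applied while uncontrolled) precedes the
    HbA1c transition, matching the cohort engine's event order.  Entry
    ages are uniform over ``entry_age_range``; follow-up length and the
    age distribution are free parameters since neither is dictated by the
    emulated data source.  Reproducible for a fixed seed.
    """
    strategy = strategy_for_interval(interval_months)
    if strategy not in truth.annual_matrices:
        raise ValueError(f"truth has no annual matrix for strategy {strategy!r}")
    if life_table is None:
        from .lifetable import make_life_table

        life_table = make_life_table()
    root = interval_root(truth.annual_matrices[strategy], interval_months)
    n_visits = int(round(n_years * 12 / interval_months)) + 1
    rng = np.random.default_rng(seed)

    if n_patients == 0:
        return PanelDataset(pd.DataFrame(columns=PANEL_COLUMNS), interval_months)

    entry_age = rng.integers(entry_age_range[0], entry_age_range[1] + 1, size=n_patients)
    state = (rng.random(n_patients) >= truth.initial_controlled_fraction).astype(int)  # 0=c, 1=u
    alive = np.ones(n_patients, dtype=bool)
    dt_years = interval_months / 12.0

    pid_col, age_col, time_col, state_col, died_col = [], [], [], [], []
    ids = np.arange(n_patients)
    for visit in range(n_visits):
        t_months = visit * interval_months
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        age_now = entry_age[idx] + t_months // 12
        last_visit = visit == n_visits - 1
        if last_visit:
            dies = np.zeros(idx.size, dtype=bool)
        else:
            capped = np.minimum(age_now, life_table.max_age)
            rates = np.array([life_table.rate(a) for a in capped])
            rr = np.where(state[idx] == 1, truth.rr_mortality, 1.0)
            q = 1.0 - np.exp(-rates * rr * dt_years)
            q[age_now >= life_table.max_age] = 1.0
            dies = rng.random(idx.size) < q
        pid_col.append(ids[idx])
        age_col.append(age_now)
        time_col.append(np.full(idx.size, t_months))
        state_col.append(state[idx].copy())
        died_col.append(dies)
        if not last_visit:
            alive[idx[dies]] = False
            surv = idx[~dies]
            p_stay = np.where(state[surv] == 0, root[0, 0], root[1, 1])
            moved = rng.random(surv.size) >= p_stay
            state[surv[moved]] = 1 - state[surv[moved]]

    frame = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid_col),
            "age_at_obs": np.concatenate(age_col),
            "obs_time_months": np.concatenate(time_col),
            "hba1c_state": np.where(np.concatenate(state_col) == 0, State.CONTROLLED.value, State.UNCONTROLLED.value),
            "died_before_next": np.concatenate(died_col),
        }
    ).sort_values(["patient_id", "obs_time_months"], kind="stable", ignore_index=True)
    return PanelDataset(frame, interval_months)


def simulate_utilization_and_utility(
    truth: SyntheticTruth, state: State, n: int, seed: int
) -> pd.DataFrame:
    """Draw per-patient annual utilization and EQ-5D utility for a state.

    Utilization uses gamma distributions (nonnegative, right-skewed) and
    utility a beta distribution (bounded in [0, 1]), each matched to the
    target mean/SD by method of moments; an infeasible beta SD is shrunk
    to 95% of the feasibility bound.  SD = 0 yields constant draws.
    """
    from .sensitivity import fit_distribution

    state = State(state)
    rng = np.random.default_rng(seed)
    out = {}
    for name, (mean, sd) in truth.utilization_params[state.value].items():
        out[name] = fit_distribution(mean, sd=sd, family="gamma").draw(rng, n)
    u_mean, u_sd = truth.utility_params[state.value]
    out["utility"] = fit_distribution(u_mean, sd=u_sd, family="beta").draw(rng, n)
    return pd.DataFrame(out)
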