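"""Annual HbA1c transition probabilities from interval-observed panels.

Patients are observed exactly at their monitoring interval, so the
natural estimator is the discrete-time Markov MLE at that interval
(row-normalised transition counts over consecutive surviving visit
pairs), annualised by raising the interval matrix to the number of
intervals per year.  Pairs where the patient dies before the next visit
are dropped: background mortality enters the cohort model through the
life table and a relative risk, not through the panel, and keeping such
pairs would double-count death.

Confidence intervals come from a nonparametric bootstrap over patients
(percentile method), since resampling visits would break within-patient
dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import State, strategy_for_interval, tests_per_year
from .synthetic import PanelDataset, _check_stochastic

logger = logging.getLogger(__name__)

__all__ = ["TransitionEstimate", "count_interval_transitions", "annualize", "estimate"]

_STATE_INDEX = {State.CONTROLLED.value: 0, State.UNCONTROLLED.value: 1}


@dataclass(frozen=True)
class TransitionEstimate:
    """Annual transition probabilities for one monitoring strategy."""

    strategy: str
    p_u_to_c: float
    p_c_to_u: float
    ci_u_to_c: tuple[float, float] | None
    ci_c_to_u: tuple[float, float] | None
    n_transitions: np.ndarray  # 2x2 interval-level counts (rows: from c, from u)

    def annual_matrix(self) -> np.ndarray:
        return np.array(
            [[1 - self.p_c_to_u, self.p_c_to_u], [self.p_u_to_c, 1 - self.p_u_to_c]]
        )

    def to_dict(self) -> dict:
        def block(p, ci):
            return {"point": p, "lower": ci[0] if ci else None, "upper": ci[1] if ci else None}

        return {
            "strategy": self.strategy,
            "p_u_to_c": block(self.p_u_to_c, self.ci_u_to_c),
            "p_c_to_u": block(self.p_c_to_u, self.ci_c_to_u),
            "n_transitions": self.n_transitions.tolist(),
        }


def _pair_table(panel: PanelDataset) -> pd.DataFrame:
    """Consecutive-visit state pairs among visits surviving to the next."""
    df = panel.frame.sort_values(["patient_id", "obs_time_months"], kind="stable")
    nxt = df.groupby("patient_id", sort=False)["hba1c_state"].shift(-1)
    keep = nxt.notna() & ~df["died_before_next"].astype(bool)
    pairs = pd.DataFrame(
        {
            "patient_id": df.loc[keep, "patient_id"],
            "from": df.loc[keep, "hba1c_state"].map(_STATE_INDEX),
            "to": nxt[keep].map(_STATE_INDEX),
        }
    )
    if pairs[["from", "to"]].isna().any().any():
        raise ValueError("panel contains states outside {controlled, uncontrolled}")
    return pairs.astype({"from": int, "to": int})


def count_interval_transitions(panel: PanelDataset) -> np.ndarray:
    """2x2 count matrix of interval transitions among the living states.

    Rows index the origin state (controlled, uncontrolled).  Raises if
    either origin state has no observed pair, since its row would be
    inestimable.
    """
    pairs = _pair_table(panel)
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (pairs["from"].to_numpy(), pairs["to"].to_numpy()), 1)
    for i, state in enumerate(("controlled", "uncontrolled")):
        if counts[i].sum() == 0:
            raise ValueError(f"no observed transition pairs out of the {state} state")
    return counts


def annualize(interval_matrix: np.ndarray, interval_months: int) -> np.ndarray:
    """Raise an interval transition matrix to the annual time scale."""
    m = _check_stochastic(interval_matrix, "interval matrix")
    power = tests_per_year(interval_months)
    return np.linalg.matrix_power(m, power)


def _counts_to_annual(counts: np.ndarray, interval_months: int) -> np.ndarray:
    mle = counts / counts.sum(axis=1, keepdims=True)
    return annualize(mle, interval_months)


def estimate(
    panel: PanelDataset,
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> TransitionEstimate:
    """Annual transition probabilities with bootstrap CIs from a panel.

    Point estimate: interval-level MLE annualised by matrix power.
    ``n_bootstrap = 0`` skips CIs.  A degenerate origin row (all pairs to
    one state) still yields a 0/1 point estimate with a warning; an empty
    origin row raises.
    """
    strategy = strategy_for_interval(panel.monitoring_interval_months)
    counts = count_interval_transitions(panel)
    if np.any(counts.sum(axis=1) > 0) and np.any((counts == 0) & (counts.sum(axis=1, keepdims=True) > 0)):
        if np.any(np.sort(counts, axis=1)[:, 0] == 0):
            logger.warning("degenerate transition row (all pairs to one state); estimate clamped to 0/1")
    annual = _counts_to_annual(counts, panel.monitoring_interval_months)
    p_c_to_u, p_u_to_c = float(annual[0, 1]), float(annual[1, 0])

    ci_uc = ci_cu = None
    if n_bootstrap > 0:
        pairs = _pair_table(panel)
        # per-patient 2x2 count vectors -> weighted bootstrap via multinomial
        flat = pairs["from"].to_numpy() * 2 + pairs["to"].to_numpy()
        per_patient = (
            pd.crosstab(pairs["patient_id"], flat)
            .reindex(columns=range(4), fill_value=0)
            .to_numpy()
        )
        n_pat = per_patient.shape[0]
        rng = np.random.default_rng(seed)
        weights = rng.multinomial(n_pat, np.full(n_pat, 1.0 / n_pat), size=n_bootstrap)
        boot_counts = weights @ per_patient  # (B, 4)
        boot = boot_counts.reshape(-1, 2, 2).astype(float)
        rowsums = boot.sum(axis=2, keepdims=True)
        valid = np.flatnonzero((rowsums > 0).all(axis=(1, 2)))
        if valid.size < n_bootstrap:
            logger.warning("dropped %d bootstrap resamples with an empty origin row", n_bootstrap - valid.size)
        mle = boot[valid] / rowsums[valid]
        power = tests_per_year(panel.monitoring_interval_months)
        annual_b = mle
        for _ in range(power - 1):
            annual_b = annual_b @ mle
        alpha = (1.0 - ci_level) / 2.0
        lo_uc, hi_uc = np.quantile(annual_b[:, 1, 0], [alpha, 1 - alpha])
        lo_cu, hi_cu = np.quantile(annual_b[:, 0, 1], [alpha, 1 - alpha])
        ci_uc = (float(np.clip(lo_uc, 0, 1)), float(np.clip(hi_uc, 0, 1)))
        ci_cu = (float(np.clip(lo_cu, 0, 1)), float(np.clip(hi_cu, 0, 1)))

    return TransitionEstimate(
        strategy=strategy,
        p_u_to_c=p_u_to_c,
        p_c_to_u=p_c_to_u,
        ci_u_to_c=ci_uc,
        ci_c_to_u=ci_cu,
        n_transitions=counts,
    )
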