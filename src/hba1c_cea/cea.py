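"""Cost-effectiveness frontier: dominance, ICERs, net monetary benefit.

Strategies are ordered by ascending cost.  A strategy is *absolutely
dominated* if some alternative costs no more and yields at least as much
effect (one comparison strict); it is *extended dominated* if its
incremental cost-effectiveness ratio against the previous undominated
option exceeds that of a more effective option — equivalently, it falls
off the lower convex hull of the cost-effect cloud.  Surviving frontier
ICERs are strictly increasing by construction, and the strategy chosen
at a willingness-to-pay threshold coincides with the maximiser of net
monetary benefit (effect·λ − cost) among frontier members.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import STRATEGY_TESTS_PER_YEAR
from .markov import StrategyResult

logger = logging.getLogger(__name__)

__all__ = ["CEAFrontier", "icer", "nmb", "dominance_frontier", "decide"]

UNDOMINATED = "undominated"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


def icer(result_a, result_b, effect: str = "qalys") -> float:
    """Incremental cost per incremental effect unit, b relative to a.

    Accepts `StrategyResult`s or plain (cost, effect) pairs.  Equal
    effects make the ratio undefined; dominance handling is responsible
    for never requesting it, so this raises.
    """
    c_a, e_a = _cost_effect(result_a, effect)
    c_b, e_b = _cost_effect(result_b, effect)
    if e_b == e_a:
        raise ZeroDivisionError("ICER undefined for equal effects; resolve via dominance")
    return (c_b - c_a) / (e_b - e_a)


def nmb(cost: float, effect: float, lam: float) -> float:
    """Net monetary benefit at willingness-to-pay ``lam`` (USD/effect)."""
    if lam < 0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    return effect * lam - cost


def _cost_effect(result, effect: str) -> tuple[float, float]:
    if isinstance(result, StrategyResult):
        return result.cost, getattr(result, effect)
    cost, eff = result
    return float(cost), float(eff)


@dataclass
class CEAFrontier:
    """Ranked strategies with dominance labels, frontier ICERs and NMBs."""

    table: pd.DataFrame  # columns: strategy, cost, effect, label, icer, nmb
    effect_kind: str
    lam: float

    @property
    def undominated(self) -> pd.DataFrame:
        return self.table[self.table["label"] == UNDOMINATED]


def _sort_key(name: str, cost: float, order: dict[str, int]):
    # ties in cost resolve toward fewer tests per year (less intervention)
    return (cost, STRATEGY_TESTS_PER_YEAR.get(name, math.inf), order[name])


def dominance_frontier(
    results: Iterable[StrategyResult] | Sequence[tuple[str, float, float]],
    effect_kind: str = "qalys",
    lam: float = 2661.97,
) -> CEAFrontier:
    """Label strategies and compute ICERs along the efficiency frontier."""
    entries = []
    for r in results:
        if isinstance(r, StrategyResult):
            entries.append((r.strategy, r.cost, getattr(r, effect_kind)))
        else:
            name, cost, eff = r
            entries.append((str(name), float(cost), float(eff)))
    if len(entries) < 2:
        raise ValueError("dominance analysis needs at least 2 strategies")
    order = {name: i for i, (name, _, _) in enumerate(entries)}
    entries.sort(key=lambda e: _sort_key(e[0], e[1], order))
    labels = {name: UNDOMINATED for name, _, _ in entries}
    seen: set[tuple[float, float]] = set()
    for name, cost, eff in entries:
        if (cost, eff) in seen:  # duplicate point: keep the lower-intensity one
            labels[name] = DOMINATED
            logger.warning("duplicate (cost, effect) for %s; keeping the lower-intensity strategy", name)
        seen.add((cost, eff))
    # absolute dominance: another option costs <= and yields >= (one strict)
    for name, cost, eff in entries:
        if labels[name] == DOMINATED:
            continue
        for oname, ocost, oeff in entries:
            if oname != name and ocost <= cost and oeff >= eff and (ocost < cost or oeff > eff):
                labels[name] = DOMINATED
                break

    # extended dominance: lower convex hull with strictly increasing ICERs
    frontier = [e for e in entries if labels[e[0]] == UNDOMINATED]
    hull: list[tuple[str, float, float]] = []
    for e in frontier:
        hull.append(e)
        while len(hull) >= 3:
            a, b, c = hull[-3], hull[-2], hull[-1]
            icer_ab = (b[1] - a[1]) / (b[2] - a[2])
            icer_bc = (c[1] - b[1]) / (c[2] - b[2])
            if icer_bc <= icer_ab:  # strict-increase rule: collinear drops too
                labels[b[0]] = EXTENDED_DOMINATED
                del hull[-2]
            else:
                break

    icers: dict[str, float] = {}
    for prev, cur in zip(hull, hull[1:]):
        icers[cur[0]] = (cur[1] - prev[1]) / (cur[2] - prev[2])

    rows = [
        {
            "strategy": name,
            "cost": cost,
            "effect": eff,
            "label": labels[name],
            "icer": icers.get(name, math.nan),
            "nmb": nmb(cost, eff, lam),
        }
        for name, cost, eff in entries
    ]
    return CEAFrontier(pd.DataFrame(rows), effect_kind, lam)


def decide(frontier: CEAFrontier, lam: float | None = None) -> str:
    """Most effective frontier strategy whose ICER is within the threshold.

    The least costly frontier member qualifies unconditionally, so a
    threshold of zero returns it; an unbounded threshold returns the most
    effective undominated strategy.  Equivalent to the max-NMB frontier
    member (property-tested).
    """
    lam = frontier.lam if lam is None else lam
    best = None
    for row in frontier.undominated.itertuples():
        if math.isnan(row.icer) or row.icer <= lam:
            best = row.strategy
    assert best is not None  # frontier always keeps its cheapest member
    return best
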