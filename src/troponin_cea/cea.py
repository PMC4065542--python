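"""Incremental cost-effectiveness analysis: ICERs, dominance, net benefit.

Strategies are ordered by ascending expected cost.  Every costlier strategy
is compared pairwise against every cheaper one (the published presentation
style: each new technology vs the reference, and the costlier new
technology vs the cheaper new one), with dominance flagged rather than
dropped.  A separate frontier pass marks strong dominance (costlier, no
more effective) and extended dominance (bypassed by a cheaper mixture with
a better ICER ordering), so ICERs along the remaining frontier are
non-decreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .tree import StrategyResult

__all__ = ["CEARow", "CEATable", "icer", "incremental_analysis", "nmb"]


@dataclass(frozen=True)
class CEARow:
    """One pairwise comparison: increments and ICER or a dominance flag."""

    comparison: str
    delta_cost: float
    delta_effect: float
    icer: float  # NaN when flagged
    flag: str = ""  # "", "dominant", "dominated"


@dataclass(frozen=True)
class CEATable:
    """Strategies sorted by cost with all pairwise incremental rows."""

    effect_measure: str  # "ly" or "qaly"
    strategies: tuple[StrategyResult, ...]
    rows: tuple[CEARow, ...]
    frontier: tuple[str, ...]  # non-dominated strategy names, by cost
    extended_dominated: tuple[str, ...]

    def reference(self) -> str:
        """Cheapest strategy; reported as the reference, not self-compared."""
        return self.strategies[0].name

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": r.comparison,
                "delta_cost": r.delta_cost,
                f"delta_{self.effect_measure}": r.delta_effect,
                "icer": r.icer,
                "flag": r.flag,
            }
            for r in self.rows
        ]
        return pd.DataFrame(rows)


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio on unrounded increments.

    A zero effect difference has no defined ICER and returns NaN.
    """
    if delta_effect == 0.0:
        return math.nan
    return delta_cost / delta_effect


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit: wtp x effect - cost."""
    if wtp < 0:
        raise ValueError(f"willingness to pay {wtp} < 0")
    return wtp * effect - cost


def _effect(r: StrategyResult, measure: str) -> float:
    if measure == "ly":
        return r.expected_ly
    if measure == "qaly":
        return r.expected_qaly
    raise ValueError(f"unknown effect measure {measure!r}")


def incremental_analysis(
    results: list[StrategyResult], effect_measure: str = "qaly"
) -> CEATable:
    """Full incremental analysis over two or more strategies.

    Pairwise rows compare each costlier strategy with each cheaper one; a
    comparison with higher cost and no greater effect is flagged
    "dominated", one with lower-or-equal cost and greater effect
    "dominant".  The frontier removes strongly dominated strategies, then
    iteratively removes extendedly dominated ones until successive ICERs
    are non-decreasing.
    """
    if len(results) < 2:
        raise ValueError("incremental analysis needs at least two strategies")
    names = [r.name for r in results]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strategy names in {names}")

    # Stable sort by cost, then effect, so permuting the input cannot change
    # the table.
    ordered = sorted(
        results, key=lambda r: (r.expected_cost, _effect(r, effect_measure), r.name)
    )

    rows: list[CEARow] = []
    for j in range(1, len(ordered)):
        for i in range(j):
            hi, lo = ordered[j], ordered[i]
            d_cost = hi.expected_cost - lo.expected_cost
            d_eff = _effect(hi, effect_measure) - _effect(lo, effect_measure)
            flag = ""
            if d_cost > 0 and d_eff <= 0:
                flag = "dominated"
            elif d_cost <= 0 and d_eff > 0:
                flag = "dominant"
            rows.append(
                CEARow(
                    comparison=f"{hi.name} vs {lo.name}",
                    delta_cost=d_cost,
                    delta_effect=d_eff,
                    icer=math.nan if flag else icer(d_cost, d_eff),
                    flag=flag,
                )
            )

    # Frontier: drop strongly dominated, then extendedly dominated.
    def strongly_dominated(r: StrategyResult) -> bool:
        return any(
            o.expected_cost <= r.expected_cost
            and _effect(o, effect_measure) >= _effect(r, effect_measure)
            and (
                o.expected_cost < r.expected_cost
                or _effect(o, effect_measure) > _effect(r, effect_measure)
            )
            for o in ordered
            if o is not r
        )

    frontier = [r for r in ordered if not strongly_dominated(r)]
    extended: list[str] = []
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        icers = [
            icer(
                frontier[k].expected_cost - frontier[k - 1].expected_cost,
                _effect(frontier[k], effect_measure) - _effect(frontier[k - 1], effect_measure),
            )
            for k in range(1, len(frontier))
        ]
        for k in range(len(icers) - 1):
            if icers[k] > icers[k + 1]:
                extended.append(frontier[k + 1].name)
                del frontier[k + 1]
                changed = True
                break

    return CEATable(
        effect_measure=effect_measure,
        strategies=tuple(ordered),
        rows=tuple(rows),
        frontier=tuple(r.name for r in frontier),
        extended_dominated=tuple(extended),
    )
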