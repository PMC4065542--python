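"""Discounted life-year, QALY and lifetime-cost accrual for a single pathway.

Conventions (annual cycles): the first year of survival is undiscounted,
year t receives weight (1 + rate)^-(t-1), and a fractional final year is
pro-rated.  There is no half-cycle correction.  Diagnostic test costs fall
at time zero and are never discounted.  Patients who die in hospital accrue
zero life years; whether they accrue the first-year treatment cost is a
model-configuration choice applied by the tree engine, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CostStream",
    "discounted_life_years",
    "discounted_lifetime_cost",
    "expected_test_cost",
    "qalys",
]


@dataclass(frozen=True)
class CostStream:
    """Per-patient cost components for one pathway.

    test_cost falls at time zero; first_year_cost in year 1 (treated or
    missed AMI only); subsequent_annual_cost in years 2..life-expectancy.
    """

    test_cost: float
    first_year_cost: float = 0.0
    subsequent_annual_cost: float = 0.0

    def __post_init__(self) -> None:
        if min(self.test_cost, self.first_year_cost, self.subsequent_annual_cost) < 0:
            raise ValueError("cost components must be non-negative")


def _year_weights(le: float) -> list[float]:
    """Pro-rated exposure of each model year t = 1..ceil(le)."""
    return [min(1.0, le - (t - 1)) for t in range(1, math.ceil(le) + 1)]


def discounted_life_years(le: float, rate: float) -> float:
    """Present value of ``le`` years of life at an annual discount rate.

    Sum over years t of w_t (1+rate)^-(t-1) with w_t = min(1, le-(t-1)), so a
    zero rate returns ``le`` exactly and the first year is undiscounted.
    """
    if le < 0:
        raise ValueError(f"life expectancy {le} < 0")
    if rate < 0:
        raise ValueError(f"discount rate {rate} < 0")
    return sum(w * (1.0 + rate) ** -(t - 1) for t, w in enumerate(_year_weights(le), 1))


def discounted_lifetime_cost(
    stream: CostStream, le: float, rate: float, died_in_hospital: bool
) -> float:
    """Discounted lifetime cost of one pathway.

    The test cost always accrues.  An in-hospital death accrues only the
    test and first-year costs (life expectancy is irrelevant); a survivor
    additionally accrues the subsequent annual cost over years 2..le,
    discounted and pro-rated like life years.
    """
    if died_in_hospital:
        return stream.test_cost + stream.first_year_cost
    if le < 0:
        raise ValueError(f"life expectancy {le} < 0")
    if rate < 0:
        raise ValueError(f"discount rate {rate} < 0")
    tail = sum(
        w * stream.subsequent_annual_cost * (1.0 + rate) ** -(t - 1)
        for t, w in enumerate(_year_weights(le), 1)
        if t >= 2
    )
    return stream.test_cost + stream.first_year_cost + tail


def expected_test_cost(strategy, paths) -> float:
    """Expected diagnostic testing cost per presenting patient.

    Everyone receives the stage-1 test; stage-2 testing falls on the
    retested fraction of stage-1 negatives, whose mass is recovered from
    the pathway profiles (the late and never-positive labels all descend
    from a stage-1 negative).
    """
    stage1_negative_labels = ("TP_LATE", "FN_MISSED", "FP_LATE", "TN")
    p_neg1 = sum(p.probability for p in paths if p.label in stage1_negative_labels)
    frac_retested = getattr(strategy, "retest_fraction", 1.0)
    return strategy.stage1_test_cost + p_neg1 * frac_retested * strategy.stage2_test_cost


def qalys(ly: float, utility: float) -> float:
    """Quality-adjust discounted life years by a constant utility weight."""
    if ly < 0:
        raise ValueError(f"life years {ly} < 0")
    if not 0.0 <= utility <= 1.0:
        raise ValueError(f"utility {utility} outside [0, 1]")
    return ly * utility
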