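"""One-way deterministic sensitivity analysis and tornado ranking.

Each non-fixed parameter is set in turn to the low and high end of its
configured range with every other parameter held at its point estimate; the
model is re-evaluated and the ICER of the requested comparison recorded.
The tornado ranking orders parameters by the absolute ICER span they
induce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cea import icer
from .parameters import ParameterSet
from .tree import ModelConfig, evaluate_all

__all__ = ["OWSARow", "run_owsa", "tornado_rank"]

DEFAULT_COMPARISON = ("hsTnT", "cTnT")


@dataclass(frozen=True)
class OWSARow:
    """ICER of one comparison at a parameter's range endpoints."""

    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        if math.isnan(self.icer_at_low) or math.isnan(self.icer_at_high):
            return math.nan
        return abs(self.icer_at_high - self.icer_at_low)


def _comparison_icer(
    params: ParameterSet,
    comparison: tuple[str, str],
    effect_measure: str,
    config: ModelConfig,
) -> float:
    results = {r.name: r for r in evaluate_all(params, config)}
    for name in comparison:
        if name not in results:
            raise ValueError(f"unknown strategy {name!r}; have {sorted(results)}")
    hi, lo = (results[comparison[0]], results[comparison[1]])
    d_cost = hi.expected_cost - lo.expected_cost
    if effect_measure == "ly":
        d_eff = hi.expected_ly - lo.expected_ly
    elif effect_measure == "qaly":
        d_eff = hi.expected_qaly - lo.expected_qaly
    else:
        raise ValueError(f"unknown effect measure {effect_measure!r}")
    return icer(d_cost, d_eff)


def run_owsa(
    params: ParameterSet,
    comparison: tuple[str, str] = DEFAULT_COMPARISON,
    effect_measure: str = "qaly",
    config: ModelConfig | None = None,
) -> list[OWSARow]:
    """One row per non-fixed parameter; the input set is never mutated."""
    config = config or ModelConfig()
    _ = _comparison_icer(params, comparison, effect_measure, config)  # validates names
    rows = []
    for name, p in params.items():
        if p.dist.family == "fixed":
            continue
        lo, hi = p.dist.low, p.dist.high
        rows.append(
            OWSARow(
                parameter=name,
                low_value=lo,
                high_value=hi,
                icer_at_low=_comparison_icer(
                    params.with_value(name, lo), comparison, effect_measure, config
                ),
                icer_at_high=_comparison_icer(
                    params.with_value(name, hi), comparison, effect_measure, config
                ),
            )
        )
    return rows


def tornado_rank(rows: list[OWSARow], top_n: int = 10) -> list[OWSARow]:
    """Rows sorted by descending ICER span, truncated to ``top_n``.

    Ties (and NaN spans, sorted last) break stably by parameter name.
    """
    if not rows:
        raise ValueError("no sensitivity rows to rank")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    key = lambda r: (math.isnan(r.span), -(0.0 if math.isnan(r.span) else r.span), r.parameter)
    return sorted(rows, key=key)[:top_n]


def owsa_frame(rows: list[OWSARow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "low": [r.low_value for r in rows],
            "high": [r.high_value for r in rows],
            "icer_low": [r.icer_at_low for r in rows],
            "icer_high": [r.icer_at_high for r in rows],
            "span": [r.span for r in rows],
        }
    )
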