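"""Probabilistic sensitivity analysis and acceptability curves.

Each Monte-Carlo iteration draws every non-fixed parameter once from its
fitted distribution (a single joint draw shared by all three strategies),
re-evaluates the decision tree, and records expected cost, life years and
QALYs per strategy.  Acceptability at a willingness-to-pay threshold is the
fraction of iterations in which a strategy attains the strictly highest net
monetary benefit, with exact ties split equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet, sample_parameter_set
from .tree import ModelConfig, evaluate_all

__all__ = ["PSAResult", "CEACCurve", "run_psa", "ceac", "psa_summary", "default_wtp_grid"]

#: Draws violating probability constraints (e.g. risk ratio x baseline > 1)
#: are rejected and redrawn; this cap surfaces misconfiguration.
MAX_REJECTIONS = 10_000


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration expected (cost, ly, qaly) for each strategy."""

    n_iter: int
    seed: int
    strategies: tuple[str, ...]
    cost: np.ndarray  # (n_iter, n_strategies)
    ly: np.ndarray
    qaly: np.ndarray
    n_rejected: int = 0

    def effect(self, measure: str) -> np.ndarray:
        if measure == "ly":
            return self.ly
        if measure == "qaly":
            return self.qaly
        raise ValueError(f"unknown effect measure {measure!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy draws: one row per (iteration, strategy)."""
        rows = []
        for k, name in enumerate(self.strategies):
            rows.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_iter),
                        "strategy": name,
                        "cost": self.cost[:, k],
                        "ly": self.ly[:, k],
                        "qaly": self.qaly[:, k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class CEACCurve:
    """Acceptability probability per strategy over a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    strategies: tuple[str, ...]
    probability: np.ndarray  # (n_grid, n_strategies), rows sum to 1

    def best_at(self, wtp: float) -> str:
        i = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        return self.strategies[int(np.argmax(self.probability[i]))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, name in enumerate(self.strategies):
            rows.append(
                pd.DataFrame(
                    {"wtp": self.wtp_grid, "strategy": name, "probability": self.probability[:, k]}
                )
            )
        return pd.concat(rows, ignore_index=True)


def default_wtp_grid() -> np.ndarray:
    """0 to 20,000 euros per QALY in 500-euro steps."""
    return np.arange(0.0, 20_000.0 + 1.0, 500.0)


def _draw_valid(params: ParameterSet, rng: np.random.Generator, budget: list[int]) -> ParameterSet:
    while True:
        drawn = sample_parameter_set(params, rng)
        baseline = max(
            drawn.value("early_ppci_mortality"), drawn.value("delayed_ppci_mortality")
        )
        if drawn.value("missed_ami_mortality_ratio") * baseline <= 1.0:
            return drawn
        budget[0] += 1
        if budget[0] > MAX_REJECTIONS:
            raise RuntimeError(
                f"more than {MAX_REJECTIONS} rejected parameter draws; "
                "check the configured ranges"
            )


def run_psa(
    params: ParameterSet,
    n_iter: int = 1000,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> PSAResult:
    """Joint Monte-Carlo over all uncertain parameters.

    A pure function of (params, n_iter, seed, config): the same seed gives
    a bit-identical result.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    rejected = [0]

    names: tuple[str, ...] | None = None
    cost = np.empty((n_iter, 3))
    ly = np.empty((n_iter, 3))
    qaly = np.empty((n_iter, 3))
    for i in range(n_iter):
        drawn = _draw_valid(params, rng, rejected)
        results = evaluate_all(drawn, config)
        if names is None:
            names = tuple(r.name for r in results)
        cost[i] = [r.expected_cost for r in results]
        ly[i] = [r.expected_ly for r in results]
        qaly[i] = [r.expected_qaly for r in results]
    assert names is not None
    return PSAResult(
        n_iter=n_iter,
        seed=seed,
        strategies=names,
        cost=cost,
        ly=ly,
        qaly=qaly,
        n_rejected=rejected[0],
    )


def ceac(
    psa: PSAResult, wtp_grid=None, effect_measure: str = "qaly"
) -> CEACCurve:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each threshold, each strategy's acceptability is the fraction of
    iterations in which it attains the highest net monetary benefit; exact
    ties split equally among the tied strategies, so the probabilities sum
    to one at every grid point.
    """
    if psa.n_iter == 0:
        raise ValueError("empty PSA result")
    grid = np.asarray(default_wtp_grid() if wtp_grid is None else wtp_grid, dtype=float)
    if grid.size == 0 or (grid < 0).any():
        raise ValueError("willingness-to-pay grid must be non-empty and non-negative")
    effect = psa.effect(effect_measure)  # (n_iter, k)
    prob = np.empty((grid.size, len(psa.strategies)))
    for i, lam in enumerate(grid):
        benefit = lam * effect - psa.cost
        best = benefit.max(axis=1, keepdims=True)
        winners = benefit == best
        prob[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CEACCurve(wtp_grid=grid, strategies=psa.strategies, probability=prob)


def psa_summary(psa: PSAResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strategy means with 2.5-97.5 percentile intervals, plus the
    pairwise incremental (delta-cost, delta-effect) cloud for scatter plots."""
    if psa.n_iter < 2:
        raise ValueError("summary needs at least two iterations")
    rows = []
    for k, name in enumerate(psa.strategies):
        for q_name, arr in (("cost", psa.cost), ("ly", psa.ly), ("qaly", psa.qaly)):
            lo, hi = np.percentile(arr[:, k], [2.5, 97.5])
            rows.append(
                {
                    "strategy": name,
                    "quantity": q_name,
                    "mean": arr[:, k].mean(),
                    "p2.5": lo,
                    "p97.5": hi,
                }
            )
    summary = pd.DataFrame(rows)

    cloud_rows = []
    for j in range(1, len(psa.strategies)):
        for i in range(j):
            cloud_rows.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(psa.n_iter),
                        "comparison": f"{psa.strategies[j]} vs {psa.strategies[i]}",
                        "delta_cost": psa.cost[:, j] - psa.cost[:, i],
                        "delta_ly": psa.ly[:, j] - psa.ly[:, i],
                        "delta_qaly": psa.qaly[:, j] - psa.qaly[:, i],
                    }
                )
            )
    return summary, pd.concat(cloud_rows, ignore_index=True)
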