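"""Patient-level Monte-Carlo microsimulation: an independent oracle for the
analytic decision tree.

Each simulated patient draws Bernoulli disease status at the configured
prevalence, Bernoulli test results at the stage-wise accuracies, and a
Bernoulli in-hospital death at the pathway-specific mortality; costs and
(discounted) life years are then accrued with the *same* functions the
analytic tree uses (:func:`troponin_cea.tree.path_cost_stream`,
:func:`troponin_cea.tree.path_life_years`), so the only difference between
the two is sampling noise.  Cohort means therefore converge to the tree's
expectations by the law of large numbers, which is what the validation
report checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcomes import CostStream, discounted_lifetime_cost
from .parameters import ParameterSet
from .tree import (
    ModelConfig,
    StrategyResult,
    StrategySpec,
    evaluate_strategy,
    path_cost_stream,
    path_death_probability,
    path_life_years,
    path_probabilities,
)

__all__ = ["CohortSummary", "simulate_cohort", "compare_to_tree"]

#: Per-patient table exports are capped to keep artifacts desk-scale.
MAX_RECORD_EXPORT = 100_000

#: Below this cohort size the standard errors are too wide for the
#: tree-agreement check to have useful power; the report says so.
LOW_POWER_N = 10_000


@dataclass(frozen=True)
class CohortSummary:
    """Cohort means with Monte-Carlo standard errors and pathway counts."""

    strategy: str
    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_ly: float
    se_ly: float
    mean_qaly: float
    se_qaly: float
    pathway_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert sum(self.pathway_counts.values()) == self.n


def simulate_cohort(
    params: ParameterSet,
    strategy: StrategySpec,
    n: int,
    seed: int,
    config: ModelConfig | None = None,
    return_records: bool = False,
) -> CohortSummary | tuple[CohortSummary, pd.DataFrame]:
    """Simulate ``n`` patients through one diagnostic strategy.

    Deterministic under a fixed seed.  With ``return_records`` the
    per-patient table (capped at :data:`MAX_RECORD_EXPORT` rows) is
    returned alongside the summary.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)

    # Terminal pathway membership is multinomial over the tree's joint
    # pathway probabilities -- the same Bernoulli cascade (disease, test 1,
    # retest, test 2) expressed in one draw -- so the stochastic layer can
    # never disagree with the tree's Bayesian revision.
    paths = path_probabilities(params.value("prevalence"), strategy, config)
    probs = np.array([p.probability for p in paths])
    path_idx = rng.choice(len(paths), size=n, p=probs)

    death_probs = np.array(
        [path_death_probability(p.label, params, config) for p in paths]
    )
    died = rng.random(n) < death_probs[path_idx]

    # Expected tests on a mixed pathway are fractional; per patient the
    # count is 1 or 2, drawn so its mean matches the pathway's expectation.
    n_tests_exp = np.array([p.n_tests for p in paths])
    n_tests = 1 + (rng.random(n) < (n_tests_exp[path_idx] - 1.0)).astype(int)

    rate_c = params.value("cost_discount_rate")
    le = params.value("life_expectancy")
    utility = params.value("utility")

    # Per-(pathway, n_tests, died) accrual via the shared implementation.
    cost_lut = np.empty((len(paths), 2, 2))
    ly_lut = np.empty((len(paths), 2))
    for i, p in enumerate(paths):
        horizon = le if p.is_ami else config.nonami_life_years
        for t in (1, 2):
            stream = path_cost_stream(p.label, float(t), strategy, params, config)
            dead_stream = (
                stream if config.first_year_cost_for_deaths else CostStream(stream.test_cost)
            )
            cost_lut[i, t - 1, 0] = discounted_lifetime_cost(stream, horizon, rate_c, False)
            cost_lut[i, t - 1, 1] = discounted_lifetime_cost(dead_stream, horizon, rate_c, True)
        ly_lut[i] = [
            path_life_years(p.label, False, params, config),
            path_life_years(p.label, True, params, config),
        ]

    cost = cost_lut[path_idx, n_tests - 1, died.astype(int)]
    ly = ly_lut[path_idx, died.astype(int)]
    qaly = ly * utility

    counts = {p.label: int((path_idx == i).sum()) for i, p in enumerate(paths)}
    sqrt_n = float(np.sqrt(n))
    summary = CohortSummary(
        strategy=strategy.name,
        n=n,
        seed=seed,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / sqrt_n) if n > 1 else 0.0,
        mean_ly=float(ly.mean()),
        se_ly=float(ly.std(ddof=1) / sqrt_n) if n > 1 else 0.0,
        mean_qaly=float(qaly.mean()),
        se_qaly=float(qaly.std(ddof=1) / sqrt_n) if n > 1 else 0.0,
        pathway_counts=counts,
    )
    if not return_records:
        return summary
    m = min(n, MAX_RECORD_EXPORT)
    labels = np.array([paths[i].label for i in path_idx[:m]])
    test1_positive = np.isin(labels, ("TP_EARLY", "FP_EARLY"))
    # Stage-2 result is defined only for retested stage-1 negatives.
    test2_positive = pd.array(np.isin(labels, ("TP_LATE", "FP_LATE")), dtype="boolean")
    test2_positive[test1_positive | (n_tests[:m] == 1)] = pd.NA
    records = pd.DataFrame(
        {
            "id": np.arange(m),
            "has_ami": np.array([paths[i].is_ami for i in path_idx[:m]]),
            "pathway": labels,
            "test1_positive": test1_positive,
            "test2_positive": test2_positive,
            "n_tests": n_tests[:m],
            "died_in_hospital": died[:m],
            "discounted_cost": cost[:m],
            "discounted_ly": ly[:m],
            "discounted_qaly": qaly[:m],
        }
    )
    return summary, records


def compare_to_tree(
    cohort: CohortSummary, tree: StrategyResult, z_threshold: float = 3.0
) -> dict:
    """Validation report: z-scores of cohort means against tree expectations.

    Passes when every |z| is at or below the threshold.  A zero standard
    error with a mismatch is a hard failure (infinite z); small cohorts are
    flagged as low-power.
    """
    if cohort.strategy != tree.name:
        raise ValueError(
            f"strategy mismatch: cohort {cohort.strategy!r} vs tree {tree.name!r}"
        )
    quantities = {
        "cost": (cohort.mean_cost, cohort.se_cost, tree.expected_cost),
        "ly": (cohort.mean_ly, cohort.se_ly, tree.expected_ly),
        "qaly": (cohort.mean_qaly, cohort.se_qaly, tree.expected_qaly),
    }
    z_scores = {}
    for name, (mean, se, expected) in quantities.items():
        diff = mean - expected
        if se == 0.0:
            z_scores[name] = 0.0 if diff == 0.0 else float("inf")
        else:
            z_scores[name] = diff / se
    passed = all(abs(z) <= z_threshold for z in z_scores.values())
    return {
        "strategy": tree.name,
        "n": cohort.n,
        "z_scores": z_scores,
        "z_threshold": z_threshold,
        "low_power": cohort.n < LOW_POWER_N,
        "passed": passed,
    }


def validate_all(
    params: ParameterSet,
    n: int,
    seed: int,
    config: ModelConfig | None = None,
) -> list[dict]:
    """Run the cohort-vs-tree check for all three strategies."""
    from .tree import build_strategies

    config = config or ModelConfig()
    reports = []
    for k, strat in enumerate(build_strategies(params, config)):
        cohort = simulate_cohort(params, strat, n, seed + k, config)
        tree = evaluate_strategy(strat, params, config)
        reports.append(compare_to_tree(cohort, tree))
    return reports
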