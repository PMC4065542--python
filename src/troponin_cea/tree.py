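"""Decision-tree engine for the three-strategy AMI diagnostic model.

Each strategy tests presenting chest-pain patients at <=6 h from symptom
onset and retests stage-1 negatives at <=12 h; patients negative on both
tests are considered AMI-free and discharged.  Bayes' theorem combined with
prevalence and the stage-wise sensitivities/specificities yields the joint
probability of six terminal pathways:

========== =============================================================
TP_EARLY   AMI, detected at stage 1; PPCI within 4 h (early mortality)
TP_LATE    AMI, missed at stage 1, detected at stage 2; delayed PPCI
FN_MISSED  AMI, negative on both tests; discharged untreated
FP_EARLY   no AMI, positive at stage 1
FP_LATE    no AMI, negative then positive
TN         no AMI, negative on both tests
========== =============================================================

Treated AMI combines disease mortality with PPCI procedural mortality as
independent risks; missed AMI dies at a risk-ratio multiple of a baseline
in-hospital mortality.  Expected costs, (discounted) life years and QALYs
are probability-weighted sums over the pathways, with all accrual rules
delegated to :mod:`troponin_cea.outcomes` so that the analytic tree and the
patient-level microsimulation share a single implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .outcomes import (
    CostStream,
    discounted_life_years,
    discounted_lifetime_cost,
    expected_test_cost,
    qalys,
)
from .parameters import ParameterSet

__all__ = [
    "PATH_LABELS",
    "ModelConfig",
    "StrategySpec",
    "PathProfile",
    "StrategyResult",
    "build_strategies",
    "path_probabilities",
    "combine_mortality",
    "missed_mortality",
    "evaluate_strategy",
    "evaluate_all",
]

PATH_LABELS = ("TP_EARLY", "TP_LATE", "FN_MISSED", "FP_EARLY", "FP_LATE", "TN")

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Structural modelling choices left open by the published description.

    retest_fraction
        Fraction of stage-1 negatives that receive the stage-2 test
        ("continuing symptoms"); 1.0 retests everyone.
    stage2_reading
        "conditional": the <=12 h accuracies are conditional on a negative
        stage-1 test given disease status.  "cumulative": they describe the
        probability of having tested positive (resp. negative) at least once
        by 12 h, and are converted to conditional stage-2 probabilities.
    mortality_combination
        "multiplicative" combines disease and procedural mortality as
        independent risks, "additive" simply sums them.
    missed_baseline
        Which treated-AMI mortality the missed-AMI risk ratio multiplies:
        "early" or "delayed".
    fp_gets_ppci
        If true, false positives undergo PPCI: they face procedural
        mortality and accrue the first-year treatment cost.
    fp_workup_cost
        Extra time-zero cost per false-positive patient (default none).
    missed_accrue_costs
        If true, missed-AMI patients accrue the same treatment-cost stream
        as treated AMI (they have the disease and are assumed eventually
        treated); if false they accrue testing costs only.
    first_year_cost_for_deaths
        If true, in-hospital deaths among treated (and cost-accruing
        missed) AMI still accrue the first-year cost.
    nonami_life_years
        Undiscounted life years credited to surviving non-AMI patients
        (default 0: effectiveness is measured over AMI patients only).
    """

    retest_fraction: float = 1.0
    stage2_reading: str = "conditional"
    mortality_combination: str = "multiplicative"
    missed_baseline: str = "early"
    fp_gets_ppci: bool = False
    fp_workup_cost: float = 0.0
    missed_accrue_costs: bool = True
    first_year_cost_for_deaths: bool = True
    nonami_life_years: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.retest_fraction <= 1.0:
            raise ValueError("retest_fraction outside [0, 1]")
        if self.stage2_reading not in ("conditional", "cumulative"):
            raise ValueError(f"unknown stage2_reading {self.stage2_reading!r}")
        if self.mortality_combination not in ("multiplicative", "additive"):
            raise ValueError(
                f"unknown mortality_combination {self.mortality_combination!r}"
            )
        if self.missed_baseline not in ("early", "delayed"):
            raise ValueError(f"unknown missed_baseline {self.missed_baseline!r}")


@dataclass(frozen=True)
class StrategySpec:
    """A diagnostic strategy: per-stage test costs and accuracies."""

    name: str
    stage1_test_cost: float
    stage2_test_cost: float
    se6: float
    sp6: float
    se12: float
    sp12: float
    retest_fraction: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("se6", "sp6", "se12", "sp12"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr} = {v} outside [0, 1]")
        if min(self.stage1_test_cost, self.stage2_test_cost) < 0:
            raise ValueError(f"{self.name}: negative test cost")


@dataclass(frozen=True)
class PathProfile:
    """One terminal pathway: joint probability and attached event data."""

    label: str
    probability: float
    n_tests: float  # expected number of tests on this pathway (1 or 2 when everyone retests)
    is_ami: bool
    death_prob: float = 0.0


@dataclass(frozen=True)
class StrategyResult:
    """Expected discounted cost, life years and QALYs for one strategy."""

    name: str
    expected_cost: float
    expected_ly: float
    expected_qaly: float
    ami_survival: float
    paths: tuple[PathProfile, ...] = field(default=(), repr=False, compare=False)


def combine_mortality(m_ami: float, m_proc: float, how: str = "multiplicative") -> float:
    """Combine disease and procedural in-hospital mortality.

    Independent risks: 1 - (1 - m_ami)(1 - m_proc); the additive variant
    caps the sum at 1.
    """
    for m in (m_ami, m_proc):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"mortality {m} outside [0, 1]")
    if how == "multiplicative":
        return 1.0 - (1.0 - m_ami) * (1.0 - m_proc)
    if how == "additive":
        return min(1.0, m_ami + m_proc)
    raise ValueError(f"unknown combination {how!r}")


def missed_mortality(rr: float, baseline: float = 0.062) -> float:
    """In-hospital mortality of inappropriately discharged (missed) AMI.

    The risk-adjusted ratio ``rr`` multiplies a treated baseline mortality;
    the product must remain a valid probability.
    """
    if rr <= 0:
        raise ValueError(f"risk ratio {rr} must be positive")
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline mortality {baseline} outside [0, 1]")
    m = rr * baseline
    if m > 1.0:
        raise ValueError(f"rr x baseline = {m:.4g} exceeds 1")
    return m


def _conditional_stage2(strategy: StrategySpec, reading: str) -> tuple[float, float]:
    """Stage-2 sensitivity/specificity conditional on a stage-1 negative.

    Under the cumulative reading the <=12 h figures describe the test ever
    being positive (AMI) or never positive (no AMI) by 12 h, so
    se2 = (se12 - se6) / (1 - se6) and sp2 = sp12 / sp6.
    """
    if reading == "conditional":
        return strategy.se12, strategy.sp12
    if strategy.se12 < strategy.se6:
        raise ValueError(
            f"{strategy.name}: cumulative reading requires se12 >= se6"
        )
    if strategy.sp12 > strategy.sp6:
        raise ValueError(
            f"{strategy.name}: cumulative reading requires sp12 <= sp6"
        )
    se2 = 0.0 if strategy.se6 == 1.0 else (strategy.se12 - strategy.se6) / (1.0 - strategy.se6)
    sp2 = 1.0 if strategy.sp6 == 0.0 else strategy.sp12 / strategy.sp6
    return se2, sp2


def path_probabilities(
    prevalence: float,
    strategy: StrategySpec,
    config: ModelConfig | None = None,
) -> list[PathProfile]:
    """Joint terminal-pathway probabilities (Bayesian revision of the tree).

    The two testing stages are conditionally independent given disease
    status.  With retest fraction f and conditional stage-2 accuracies
    (se2, sp2):

        P(TP_EARLY)  = p se6
        P(TP_LATE)   = p (1-se6) f se2
        P(FN_MISSED) = p (1-se6) (1 - f se2)
        P(FP_EARLY)  = (1-p)(1-sp6)
        P(FP_LATE)   = (1-p) sp6 f (1-sp2)
        P(TN)        = (1-p) sp6 (1 - f (1-sp2))

    The six probabilities sum to one identically.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence {prevalence} outside (0, 1)")
    config = config or ModelConfig()
    f = config.retest_fraction
    se2, sp2 = _conditional_stage2(strategy, config.stage2_reading)
    p, se6, sp6 = prevalence, strategy.se6, strategy.sp6

    # Expected tests on mixed pathways (FN/TN pool retested and non-retested
    # stage-1 negatives when f < 1).
    fn_mass = p * (1.0 - se6) * (1.0 - f * se2)
    fn_tests = 1.0 if fn_mass == 0 else (
        p * (1.0 - se6) * ((1.0 - f) + 2.0 * f * (1.0 - se2)) / fn_mass
    )
    tn_mass = (1.0 - p) * sp6 * (1.0 - f * (1.0 - sp2))
    tn_tests = 1.0 if tn_mass == 0 else (
        (1.0 - p) * sp6 * ((1.0 - f) + 2.0 * f * sp2) / tn_mass
    )

    return [
        PathProfile("TP_EARLY", p * se6, 1.0, True),
        PathProfile("TP_LATE", p * (1.0 - se6) * f * se2, 2.0, True),
        PathProfile("FN_MISSED", fn_mass, fn_tests, True),
        PathProfile("FP_EARLY", (1.0 - p) * (1.0 - sp6), 1.0, False),
        PathProfile("FP_LATE", (1.0 - p) * sp6 * f * (1.0 - sp2), 2.0, False),
        PathProfile("TN", tn_mass, tn_tests, False),
    ]


def build_strategies(params: ParameterSet, config: ModelConfig | None = None) -> list[StrategySpec]:
    """The three modelled strategies, built from the parameter inventory."""
    config = config or ModelConfig()
    f = config.retest_fraction
    c_hs = params.value("hstnt_test_cost")
    c_combo = c_hs + params.value("hfabp_marginal_cost")
    out = []
    for name, cost in (("cTnT", params.value("ctnt_test_cost")), ("hsTnT", c_hs), ("hsTnT+H-FABP", c_combo)):
        key = {"cTnT": "ctnt", "hsTnT": "hstnt", "hsTnT+H-FABP": "combo"}[name]
        out.append(
            StrategySpec(
                name=name,
                stage1_test_cost=cost,
                stage2_test_cost=cost,
                se6=params.value(f"{key}_se6"),
                sp6=params.value(f"{key}_sp6"),
                se12=params.value(f"{key}_se12"),
                sp12=params.value(f"{key}_sp12"),
                retest_fraction=f,
            )
        )
    return out


def path_death_probability(
    label: str, params: ParameterSet, config: ModelConfig
) -> float:
    """In-hospital death probability attached to a terminal pathway."""
    m_proc = params.value("procedural_mortality")
    how = config.mortality_combination
    if label == "TP_EARLY":
        return combine_mortality(params.value("early_ppci_mortality"), m_proc, how)
    if label == "TP_LATE":
        return combine_mortality(params.value("delayed_ppci_mortality"), m_proc, how)
    if label == "FN_MISSED":
        baseline = params.value(
            "early_ppci_mortality" if config.missed_baseline == "early" else "delayed_ppci_mortality"
        )
        return missed_mortality(params.value("missed_ami_mortality_ratio"), baseline)
    if label in ("FP_EARLY", "FP_LATE"):
        return m_proc if config.fp_gets_ppci else 0.0
    if label == "TN":
        return 0.0
    raise ValueError(f"unknown pathway label {label!r}")


def path_cost_stream(
    label: str, n_tests: float, strategy: StrategySpec, params: ParameterSet, config: ModelConfig
) -> CostStream:
    """Cost components attached to a terminal pathway.

    The per-pathway test cost uses the expected number of tests on that
    pathway; summed over pathways this equals stage-1 cost plus the
    stage-2 cost on the retested stage-1 negatives.
    """
    test = strategy.stage1_test_cost + (n_tests - 1.0) * strategy.stage2_test_cost
    first = params.value("ami_first_year_cost")
    sub = params.value("ami_subsequent_year_cost")
    if label in ("TP_EARLY", "TP_LATE"):
        return CostStream(test, first, sub)
    if label == "FN_MISSED":
        if config.missed_accrue_costs:
            return CostStream(test, first, sub)
        return CostStream(test)
    if label in ("FP_EARLY", "FP_LATE"):
        extra_first = first if config.fp_gets_ppci else 0.0
        return CostStream(test + config.fp_workup_cost, extra_first)
    return CostStream(test)


def path_life_years(label: str, died: bool, params: ParameterSet, config: ModelConfig) -> float:
    """Discounted life years credited to one pathway outcome."""
    if died:
        return 0.0
    rate = params.value("effect_discount_rate")
    if label in ("TP_EARLY", "TP_LATE", "FN_MISSED"):
        return discounted_life_years(params.value("life_expectancy"), rate)
    if config.nonami_life_years > 0.0:
        return discounted_life_years(config.nonami_life_years, rate)
    return 0.0


def evaluate_strategy(
    strategy: StrategySpec,
    params: ParameterSet,
    config: ModelConfig | None = None,
) -> StrategyResult:
    """Expected discounted cost, life years and QALYs for one strategy.

    In-hospital deaths contribute zero life years; surviving AMI patients
    live the discounted post-AMI life expectancy; non-AMI patients
    contribute zero by default.  A first-year cost for in-hospital deaths
    is applied per the model configuration.
    """
    config = config or ModelConfig()
    paths = path_probabilities(params.value("prevalence"), strategy, config)
    paths = [
        PathProfile(
            p.label, p.probability, p.n_tests, p.is_ami,
            path_death_probability(p.label, params, config),
        )
        for p in paths
    ]
    total = sum(p.probability for p in paths)
    assert abs(total - 1.0) < _PROB_TOL

    rate_c = params.value("cost_discount_rate")
    le = params.value("life_expectancy")
    utility = params.value("utility")

    e_cost = e_ly = 0.0
    ami_death = ami_mass = 0.0
    for p in paths:
        stream = path_cost_stream(p.label, p.n_tests, strategy, params, config)
        accrues_first_on_death = config.first_year_cost_for_deaths
        dead_stream = stream if accrues_first_on_death else CostStream(stream.test_cost)
        horizon = le if p.is_ami else config.nonami_life_years
        cost_dead = discounted_lifetime_cost(dead_stream, horizon, rate_c, True)
        cost_alive = discounted_lifetime_cost(stream, horizon, rate_c, False)
        e_cost += p.probability * (
            p.death_prob * cost_dead + (1.0 - p.death_prob) * cost_alive
        )
        e_ly += p.probability * (1.0 - p.death_prob) * path_life_years(
            p.label, False, params, config
        )
        if p.is_ami:
            ami_mass += p.probability
            ami_death += p.probability * p.death_prob

    return StrategyResult(
        name=strategy.name,
        expected_cost=e_cost,
        expected_ly=e_ly,
        expected_qaly=qalys(e_ly, utility),
        ami_survival=1.0 - ami_death / ami_mass if ami_mass > 0 else 1.0,
        paths=tuple(paths),
    )


def evaluate_all(
    params: ParameterSet, config: ModelConfig | None = None
) -> list[StrategyResult]:
    """Evaluate the conventional, high-sensitive and combination strategies."""
    config = config or ModelConfig()
    return [evaluate_strategy(s, params, config) for s in build_strategies(params, config)]


def load_model_config(config_path) -> ModelConfig:
    """Read the optional ``model:`` section of a parameter config file."""
    import yaml
    from pathlib import Path

    raw = yaml.safe_load(Path(config_path).read_text())
    section: Mapping = raw.get("model", {}) if isinstance(raw, dict) else {}
    return ModelConfig(**section)
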