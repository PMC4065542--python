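"""Model parameter inventory: definition, validation, loading and sampling.

The model is driven by a fixed inventory of 26 parameters: unit costs of the
diagnostic assays, first-year and subsequent-year treatment costs of acute
myocardial infarction (AMI), the post-AMI utility weight, annual discount
rates for costs and effects, AMI prevalence among chest-pain presenters, the
excess-mortality ratio for inappropriately discharged (missed) AMI, the life
expectancy of an AMI survivor, three in-hospital mortality probabilities
(early PPCI, delayed PPCI, procedural), and a 2x2x3 block of diagnostic
accuracies: sensitivity and specificity at <=6 h and <=12 h from symptom
onset for each of the three assay strategies.

Each parameter carries a point estimate, a (low, high) range on its natural
scale, and a sampling-distribution family used by the probabilistic
sensitivity analysis:

* ``fixed``      -- degenerate; always returns the point estimate.
* ``beta``       -- Beta on [0, 1], moment-matched to the point estimate and
                    the range read as a 95% confidence interval.
* ``beta_pert``  -- classical Beta-PERT (lambda = 4) on [low, high] with the
                    point estimate as the mode.
* ``gamma``      -- Gamma on (0, inf), moment-matched like ``beta``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "DistributionSpec",
    "Parameter",
    "ParameterSet",
    "ParameterValidationError",
    "SchemaError",
    "REQUIRED_PARAMETERS",
    "default_parameters",
    "load_parameters",
    "default_config_path",
    "pert_shape",
    "beta_from_mean_ci",
    "gamma_from_mean_range",
    "sample_parameter",
    "sample_parameter_set",
]

#: Width of a central 95% normal interval in standard deviations; printed
#: (min-max) ranges are read as 95% intervals, so sd = (high - low) / 3.92.
_CI95_WIDTH_SD = 3.92

FAMILIES = ("fixed", "beta", "beta_pert", "gamma")


class ParameterValidationError(ValueError):
    """A parameter value violates its domain invariants."""


class SchemaError(ValueError):
    """A parameter config file does not match the documented schema."""


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling-distribution family and range bounds on the natural scale."""

    family: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterValidationError(
                f"unknown distribution family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.low > self.high:
            raise ParameterValidationError(
                f"range low {self.low} exceeds high {self.high}"
            )
        if self.family != "fixed" and self.low == self.high:
            raise ParameterValidationError(
                f"family {self.family!r} needs a non-degenerate range"
            )


@dataclass(frozen=True)
class Parameter:
    """A named model input with point estimate, units and sampling spec."""

    name: str
    value: float
    units: str  # "euros", "probability", "utility", "years", "ratio", "rate"
    dist: DistributionSpec

    def __post_init__(self) -> None:
        v = self.value
        if self.units in ("probability", "utility") and not 0.0 <= v <= 1.0:
            raise ParameterValidationError(
                f"{self.name}: {self.units} {v} outside [0, 1]"
            )
        if self.units in ("euros", "rate") and v < 0:
            raise ParameterValidationError(f"{self.name}: {self.units} {v} < 0")
        if self.units == "years" and v <= 0:
            raise ParameterValidationError(f"{self.name}: years {v} <= 0")
        if self.units == "ratio" and v <= 0:
            raise ParameterValidationError(f"{self.name}: ratio {v} <= 0")
        if not self.dist.low <= v <= self.dist.high:
            raise ParameterValidationError(
                f"{self.name}: value {v} outside range [{self.dist.low}, {self.dist.high}]"
            )


#: name -> units for the complete inventory; the config must contain exactly
#: these names.
REQUIRED_PARAMETERS: dict[str, str] = {
    "ctnt_test_cost": "euros",
    "hstnt_test_cost": "euros",
    "hfabp_marginal_cost": "euros",
    "ami_first_year_cost": "euros",
    "ami_subsequent_year_cost": "euros",
    "utility": "utility",
    "cost_discount_rate": "rate",
    "effect_discount_rate": "rate",
    "prevalence": "probability",
    "missed_ami_mortality_ratio": "ratio",
    "life_expectancy": "years",
    "early_ppci_mortality": "probability",
    "delayed_ppci_mortality": "probability",
    "procedural_mortality": "probability",
    "ctnt_se6": "probability",
    "ctnt_se12": "probability",
    "ctnt_sp6": "probability",
    "ctnt_sp12": "probability",
    "hstnt_se6": "probability",
    "hstnt_se12": "probability",
    "hstnt_sp6": "probability",
    "hstnt_sp12": "probability",
    "combo_se6": "probability",
    "combo_se12": "probability",
    "combo_sp6": "probability",
    "combo_sp12": "probability",
}


class ParameterSet(Mapping[str, Parameter]):
    """Immutable mapping of the full parameter inventory.

    Construction validates every parameter invariant and checks that all
    required names are present exactly once and no unknown names appear.
    """

    def __init__(self, parameters: Mapping[str, Parameter] | list[Parameter]):
        if not isinstance(parameters, Mapping):
            parameters = {p.name: p for p in parameters}
        unknown = set(parameters) - set(REQUIRED_PARAMETERS)
        if unknown:
            raise SchemaError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(REQUIRED_PARAMETERS) - set(parameters)
        if missing:
            raise SchemaError(f"missing required parameter(s): {sorted(missing)}")
        for name, p in parameters.items():
            if p.name != name:
                raise SchemaError(f"key {name!r} does not match parameter name {p.name!r}")
            if p.units != REQUIRED_PARAMETERS[name]:
                raise SchemaError(
                    f"{name}: expected units {REQUIRED_PARAMETERS[name]!r}, got {p.units!r}"
                )
        self._params: dict[str, Parameter] = {n: parameters[n] for n in REQUIRED_PARAMETERS}

    # Mapping interface -------------------------------------------------
    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self._params == other._params

    # Convenience --------------------------------------------------------
    def value(self, name: str) -> float:
        return self._params[name].value

    def values_dict(self) -> dict[str, float]:
        return {n: p.value for n, p in self._params.items()}

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Return a copy with one point estimate replaced.

        The replacement is *not* required to lie inside the printed range
        (sensitivity analyses set parameters to the range endpoints and
        probabilistic draws may leave the printed 95% interval); domain
        invariants (probabilities in [0,1], costs >= 0, ...) still apply.
        """
        p = self._params[name]
        lo = min(p.dist.low, value)
        hi = max(p.dist.high, value)
        new = replace(p, value=value, dist=replace(p.dist, low=lo, high=hi))
        d = dict(self._params)
        d[name] = new
        return ParameterSet(d)

    def with_values(self, values: Mapping[str, float]) -> "ParameterSet":
        ps = self
        for name, v in values.items():
            ps = ps.with_value(name, v)
        return ps


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------

def pert_shape(low: float, mode: float, high: float) -> tuple[float, float]:
    """Classical Beta-PERT shape parameters (lambda = 4).

    alpha = 1 + 4 (mode - low) / (high - low)
    beta  = 1 + 4 (high - mode) / (high - low)

    A draw is Beta(alpha, beta) rescaled to [low, high]; the distribution's
    mode is ``mode`` and its mean is (low + 4 mode + high) / 6.
    """
    if low >= high:
        raise ValueError(f"PERT requires low < high, got [{low}, {high}]")
    if not low <= mode <= high:
        raise ValueError(f"PERT mode {mode} outside [{low}, {high}]")
    span = high - low
    return 1.0 + 4.0 * (mode - low) / span, 1.0 + 4.0 * (high - mode) / span


def beta_from_mean_ci(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Method-of-moments Beta fit from a mean and a 95% interval.

    sd = (hi - lo) / 3.92, alpha = mean (mean (1 - mean) / sd^2 - 1),
    beta = alpha (1 - mean) / mean.  The fitted mean equals ``mean`` exactly.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean {mean} outside (0, 1)")
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid interval [{lo}, {hi}]")
    var = ((hi - lo) / _CI95_WIDTH_SD) ** 2
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible moments: variance {var:.6g} >= mean(1-mean) {mean * (1 - mean):.6g}"
        )
    alpha = mean * (mean * (1.0 - mean) / var - 1.0)
    return alpha, alpha * (1.0 - mean) / mean


def gamma_from_mean_range(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Method-of-moments Gamma fit (shape, scale) from a mean and 95% range."""
    if mean <= 0:
        raise ValueError(f"mean {mean} must be positive")
    if not 0.0 <= lo < hi:
        raise ValueError(f"invalid range [{lo}, {hi}]")
    sd = (hi - lo) / _CI95_WIDTH_SD
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


def sample_parameter(param: Parameter, rng: np.random.Generator) -> float:
    """Draw one value from the parameter's fitted sampling distribution."""
    d = param.dist
    if d.family == "fixed":
        return param.value
    if d.family == "beta_pert":
        a, b = pert_shape(d.low, param.value, d.high)
        return d.low + (d.high - d.low) * float(
            stats.beta.rvs(a, b, random_state=rng)
        )
    if d.family == "beta":
        a, b = beta_from_mean_ci(param.value, d.low, d.high)
        return float(stats.beta.rvs(a, b, random_state=rng))
    if d.family == "gamma":
        shape, scale = gamma_from_mean_range(param.value, d.low, d.high)
        return float(stats.gamma.rvs(shape, scale=scale, random_state=rng))
    raise ValueError(f"unknown family {d.family!r}")  # pragma: no cover


def sample_parameter_set(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """Draw every non-fixed parameter once; fixed parameters pass through.

    Parameters are sampled independently in the canonical inventory order,
    so identical generator state yields an identical draw.
    """
    return params.with_values(
        {
            name: sample_parameter(p, rng)
            for name, p in params.items()
            if p.dist.family != "fixed"
        }
    )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_RECORD_KEYS = {"value", "low", "high", "family", "units"}


def default_config_path() -> Path:
    """Path of the shipped default parameter config."""
    return Path(str(resources.files("troponin_cea").joinpath("data/params_table1.yaml")))


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Load and validate a parameter config (YAML or JSON).

    Schema: a mapping ``name -> {value, low, high, family, units}`` covering
    the full inventory; an optional ``model:`` section (consumed by the tree
    engine's configuration loader) is ignored here.
    """
    path = Path(config_path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    raw = {k: v for k, v in raw.items() if k != "model"}
    params: dict[str, Parameter] = {}
    for name, rec in raw.items():
        if name not in REQUIRED_PARAMETERS:
            raise SchemaError(f"unknown parameter name: {name!r}")
        if not isinstance(rec, dict) or not {"value", "family"} <= set(rec):
            raise SchemaError(f"{name}: record must provide at least value and family")
        extra = set(rec) - _RECORD_KEYS
        if extra:
            raise SchemaError(f"{name}: unknown keys {sorted(extra)}")
        value = float(rec["value"])
        low = float(rec.get("low", value))
        high = float(rec.get("high", value))
        units = rec.get("units", REQUIRED_PARAMETERS[name])
        params[name] = Parameter(
            name=name,
            value=value,
            units=units,
            dist=DistributionSpec(family=str(rec["family"]), low=low, high=high),
        )
    missing = set(REQUIRED_PARAMETERS) - set(params)
    if missing:
        raise SchemaError(f"missing required parameter(s): {sorted(missing)}")
    return ParameterSet(params)


def default_parameters() -> ParameterSet:
    """The shipped default parameter inventory."""
    return load_parameters(default_config_path())
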