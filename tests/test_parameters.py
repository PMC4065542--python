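"""Parameter inventory: validation, distribution fitting and sampling."""

import math

import numpy as np
import pytest
import yaml
from scipy import stats

from troponin_cea.parameters import (
    Parameter,
    ParameterValidationError,
    SchemaError,
    beta_from_mean_ci,
    default_config_path,
    default_parameters,
    gamma_from_mean_range,
    load_parameters,
    pert_shape,
    sample_parameter,
    sample_parameter_set,
)


class TestDefaultInventory:
    def test_headline_values(self, params):
        prev = params["prevalence"]
        assert prev.value == 0.30
        assert (prev.dist.low, prev.dist.high) == (0.23, 0.38)
        assert prev.dist.family == "beta_pert"
        assert params.value("ctnt_test_cost") == 17.11
        # The high-sensitive assay costs 4.39 euros more per test.
        assert params.value("hstnt_test_cost") - params.value("ctnt_test_cost") == pytest.approx(
            4.39, abs=1e-12
        )

    def test_discount_rates_are_fixed_percentages(self, params):
        assert params["cost_discount_rate"].dist.family == "fixed"
        assert params.value("cost_discount_rate") == 0.04
        assert params.value("effect_discount_rate") == 0.015

    def test_all_accuracies_are_beta_probabilities(self, params):
        for key in ("ctnt", "hstnt", "combo"):
            for acc in ("se6", "se12", "sp6", "sp12"):
                p = params[f"{key}_{acc}"]
                assert p.dist.family == "beta"
                assert 0.0 <= p.dist.low < p.value < p.dist.high <= 1.0


class TestLoading:
    def test_shipped_config_roundtrip(self, params):
        assert load_parameters(default_config_path()) == params

    def test_invalid_probability_rejected(self, tmp_path, params):
        raw = yaml.safe_load(default_config_path().read_text())
        raw["prevalence"]["value"] = 1.3
        raw["prevalence"]["high"] = 1.5
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(ParameterValidationError, match="prevalence"):
            load_parameters(bad)

    def test_missing_parameter_named_in_error(self, tmp_path):
        raw = yaml.safe_load(default_config_path().read_text())
        del raw["utility"]
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(SchemaError, match="utility"):
            load_parameters(bad)

    def test_unknown_parameter_rejected(self, tmp_path):
        raw = yaml.safe_load(default_config_path().read_text())
        raw["mystery_cost"] = {"value": 1.0, "low": 0.5, "high": 2.0, "family": "gamma"}
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(SchemaError, match="mystery_cost"):
            load_parameters(bad)

    def test_inverted_range_rejected(self, tmp_path):
        raw = yaml.safe_load(default_config_path().read_text())
        raw["utility"].update(low=0.9, high=0.5, value=0.725)
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(ParameterValidationError, match="low"):
            load_parameters(bad)


class TestPertShape:
    @pytest.mark.parametrize(
        "low,mode,high,expected",
        [
            (0.0, 0.5, 1.0, (3.0, 3.0)),
            (0.23, 0.30, 0.38, (2.8666666666666667, 3.1333333333333333)),
            (0.0, 0.0, 1.0, (1.0, 5.0)),
        ],
    )
    def test_shapes(self, low, mode, high, expected):
        a, b = pert_shape(low, mode, high)
        assert a == pytest.approx(expected[0], rel=1e-12)
        assert b == pytest.approx(expected[1], rel=1e-12)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            pert_shape(1.0, 1.0, 1.0)


class TestBetaFit:
    def test_symmetric_interval_gives_equal_shapes(self):
        sd = 0.1
        a, b = beta_from_mean_ci(0.5, 0.5 - 1.96 * sd, 0.5 + 1.96 * sd)
        assert a == pytest.approx(b, rel=1e-12)

    def test_ctnt_sensitivity_fit(self):
        # Frozen from the moment formulas: sd = 0.24/3.92, var = sd^2,
        # alpha = 0.44 (0.44*0.56/var - 1), beta = alpha*0.56/0.44.
        a, b = beta_from_mean_ci(0.44, 0.32, 0.56)
        assert a == pytest.approx(28.482979555555545, rel=1e-12)
        assert b == pytest.approx(36.25106488888888, rel=1e-12)

    def test_fitted_mean_matches(self):
        a, b = beta_from_mean_ci(0.725, 0.544, 0.906)
        assert a / (a + b) == pytest.approx(0.725, abs=1e-12)

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_mean_ci(0.01, 0.0, 1.0)


class TestGammaFit:
    def test_first_year_cost_fit(self):
        shape, scale = gamma_from_mean_range(12446, 9334, 15557)
        assert shape == pytest.approx(61.465599999999995, rel=1e-9)
        assert scale == pytest.approx(202.4872448979592, rel=1e-9)

    @pytest.mark.parametrize("mean,lo,hi", [(12446, 9334, 15557), (2092, 1569, 2615)])
    def test_mean_identity(self, mean, lo, hi):
        shape, scale = gamma_from_mean_range(mean, lo, hi)
        assert shape * scale == pytest.approx(mean, rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_mean_range(0.0, 0.0, 1.0)


class TestSampling:
    def test_fixed_returns_point_value(self, params, rng):
        p = params["cost_discount_rate"]
        assert all(sample_parameter(p, rng) == 0.04 for _ in range(10))

    def test_pert_draws_respect_support(self, params, rng):
        p = params["prevalence"]
        draws = np.array([sample_parameter(p, rng) for _ in range(2000)])
        assert draws.min() >= 0.23 and draws.max() <= 0.38

    def test_beta_draws_stay_probabilities(self, params, rng):
        p = params["hstnt_se6"]
        draws = np.array([sample_parameter(p, rng) for _ in range(2000)])
        assert draws.min() >= 0.0 and draws.max() <= 1.0

    def test_pert_mean_identity_monte_carlo(self, params):
        # PERT mean is (low + 4 mode + high) / 6; check within 3 standard
        # errors at a modest sample size.
        p = params["prevalence"]
        a, b = pert_shape(0.23, 0.30, 0.38)
        rng = np.random.default_rng(5)
        draws = 0.23 + 0.15 * stats.beta.rvs(a, b, size=50_000, random_state=rng)
        expected = (0.23 + 4 * 0.30 + 0.38) / 6
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_same_seed_identical_draws(self, params):
        a = sample_parameter_set(params, np.random.default_rng(11))
        b = sample_parameter_set(params, np.random.default_rng(11))
        assert a.values_dict() == b.values_dict()

    def test_joint_draw_keeps_fixed_parameters(self, params, rng):
        drawn = sample_parameter_set(params, rng)
        assert drawn.value("cost_discount_rate") == 0.04
        assert drawn.value("effect_discount_rate") == 0.015
        # non-fixed parameters actually moved
        assert drawn.value("prevalence") != params.value("prevalence")


def test_parameter_domain_invariants():
    from troponin_cea.parameters import DistributionSpec

    with pytest.raises(ParameterValidationError):
        Parameter("utility", 1.2, "utility", DistributionSpec("beta", 0.0, 1.0))
    with pytest.raises(ParameterValidationError):
        Parameter("ctnt_test_cost", -1.0, "euros", DistributionSpec("fixed", -1.0, -1.0))
    with pytest.raises(ParameterValidationError):
        Parameter("life_expectancy", 8.3, "years", DistributionSpec("beta_pert", 9.0, 10.0))
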