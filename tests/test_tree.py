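"""Decision-tree engine: Bayesian pathway probabilities, mortality
combination, and expected values per strategy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from troponin_cea.tree import (
    ModelConfig,
    StrategySpec,
    build_strategies,
    combine_mortality,
    evaluate_all,
    evaluate_strategy,
    missed_mortality,
    path_probabilities,
)


def probs_by_label(paths):
    return {p.label: p.probability for p in paths}


class TestPathProbabilities:
    def test_base_case_joint_probabilities(self, strategies):
        got = probs_by_label(path_probabilities(0.30, strategies["cTnT"]))
        assert got["TP_EARLY"] == pytest.approx(0.1320, abs=1e-12)
        assert got["TP_LATE"] == pytest.approx(0.15624, abs=1e-12)
        assert got["FN_MISSED"] == pytest.approx(0.01176, abs=1e-12)

    def test_perfect_test_concentrates_mass(self):
        perfect = StrategySpec("p", 1.0, 1.0, se6=1.0, sp6=1.0, se12=1.0, sp12=1.0)
        got = probs_by_label(path_probabilities(0.30, perfect))
        assert got["TP_EARLY"] == pytest.approx(0.30)
        assert got["TN"] == pytest.approx(0.70)
        assert got["TP_LATE"] == got["FN_MISSED"] == got["FP_EARLY"] == got["FP_LATE"] == 0.0

    def test_prevalence_domain(self, strategies):
        for bad in (0.0, 1.0, -0.1, 1.7):
            with pytest.raises(ValueError):
                path_probabilities(bad, strategies["cTnT"])

    @given(
        p=st.floats(min_value=1e-6, max_value=1 - 1e-6),
        se6=st.floats(min_value=0, max_value=1),
        sp6=st.floats(min_value=0, max_value=1),
        se12=st.floats(min_value=0, max_value=1),
        sp12=st.floats(min_value=0, max_value=1),
        f=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=200, deadline=None)
    def test_probabilities_sum_to_one(self, p, se6, sp6, se12, sp12, f):
        s = StrategySpec("s", 1.0, 1.0, se6=se6, sp6=sp6, se12=se12, sp12=sp12, retest_fraction=f)
        paths = path_probabilities(p, s, ModelConfig(retest_fraction=f))
        total = sum(q.probability for q in paths)
        assert abs(total - 1.0) < 1e-12
        assert all(0.0 <= q.probability <= 1.0 for q in paths)

    def test_no_retest_sends_stage1_negatives_home(self, strategies):
        cfg = ModelConfig(retest_fraction=0.0)
        got = probs_by_label(path_probabilities(0.30, strategies["cTnT"], cfg))
        assert got["TP_LATE"] == 0.0
        assert got["FN_MISSED"] == pytest.approx(0.3 * 0.56)
        assert got["TN"] == pytest.approx(0.7 * 0.92)

    def test_cumulative_reading_reduces_late_detection(self, strategies):
        cond = probs_by_label(path_probabilities(0.30, strategies["cTnT"]))
        cum = probs_by_label(
            path_probabilities(0.30, strategies["cTnT"], ModelConfig(stage2_reading="cumulative"))
        )
        # Under the cumulative reading P(detected by 12h | AMI) = se12 = 0.93
        assert cum["TP_EARLY"] + cum["TP_LATE"] == pytest.approx(0.3 * 0.93, abs=1e-12)
        assert cum["TP_LATE"] < cond["TP_LATE"]


class TestMortality:
    def test_independent_risks_combination(self):
        assert combine_mortality(0.062, 0.0072) == pytest.approx(0.0687536, abs=1e-10)

    @given(m=st.floats(min_value=0, max_value=1))
    @settings(max_examples=50, deadline=None)
    def test_zero_and_absorbing_limits(self, m):
        assert combine_mortality(m, 0.0) == pytest.approx(m)
        assert combine_mortality(1.0, m) == pytest.approx(1.0)

    def test_missed_mortality_product(self):
        assert missed_mortality(1.9, 0.062) == pytest.approx(0.1178, abs=1e-12)
        assert missed_mortality(1.0, 0.5) == 0.5

    def test_missed_mortality_must_stay_probability(self):
        with pytest.raises(ValueError):
            missed_mortality(1.9, 0.6)


class TestEvaluateStrategy:
    def test_qaly_is_utility_times_ly(self, params, strategies):
        for s in strategies.values():
            r = evaluate_strategy(s, params)
            assert r.expected_qaly == pytest.approx(0.725 * r.expected_ly, rel=1e-14)

    def test_no_deaths_no_discounting_forces_prevalence_times_le(self, params, strategies):
        zeroed = params.with_values(
            {
                "early_ppci_mortality": 0.0,
                "delayed_ppci_mortality": 0.0,
                "procedural_mortality": 0.0,
                "missed_ami_mortality_ratio": 1e-9,
                "effect_discount_rate": 0.0,
            }
        )
        for s in build_strategies(zeroed):
            r = evaluate_strategy(s, zeroed)
            assert r.expected_ly == pytest.approx(0.30 * 8.3, rel=1e-12)
            assert r.ami_survival == pytest.approx(1.0)

    def test_deterministic(self, params, strategies):
        a = evaluate_strategy(strategies["hsTnT"], params)
        b = evaluate_strategy(strategies["hsTnT"], params)
        assert (a.expected_cost, a.expected_ly, a.expected_qaly) == (
            b.expected_cost,
            b.expected_ly,
            b.expected_qaly,
        )

    def test_perfect_test_survival_limit(self, params):
        perfect = StrategySpec("p", 1.0, 1.0, se6=1.0, sp6=1.0, se12=1.0, sp12=1.0)
        r = evaluate_strategy(perfect, params)
        assert r.ami_survival == pytest.approx(1.0 - combine_mortality(0.062, 0.0072), rel=1e-12)

    def test_life_years_monotone_in_sensitivity(self, params):
        # Early treatment is safest (0.0688 < 0.1095 < 0.1178), so raising
        # either sensitivity can never lose life years.
        base = evaluate_strategy(build_strategies(params)[0], params)
        for name, step in (("ctnt_se6", 0.05), ("ctnt_se12", 0.02)):
            prev_ly = base.expected_ly
            for k in range(1, 4):
                bumped = params.with_value(name, params.value(name) + k * step)
                r = evaluate_strategy(build_strategies(bumped)[0], bumped)
                assert r.expected_ly >= prev_ly - 1e-15
                prev_ly = r.expected_ly

    def test_false_positives_can_be_charged_for_ppci(self, params, strategies):
        base = evaluate_strategy(strategies["hsTnT"], params)
        charged = evaluate_strategy(
            strategies["hsTnT"], params, ModelConfig(fp_gets_ppci=True)
        )
        assert charged.expected_cost > base.expected_cost
        # procedural risk does not touch AMI patients' survival
        assert charged.ami_survival == pytest.approx(base.ami_survival)


class TestEvaluateAll:
    def test_declared_order_and_ranking(self, params):
        results = evaluate_all(params)
        assert [r.name for r in results] == ["cTnT", "hsTnT", "hsTnT+H-FABP"]
        # the high-sensitive assay finds (and treats) more AMI earlier
        assert results[1].expected_ly >= results[0].expected_ly
        assert results[1].ami_survival > results[0].ami_survival

    def test_identical_strategies_give_identical_results(self, params):
        tied = params.with_values(
            {
                "hstnt_test_cost": 17.11,
                "hfabp_marginal_cost": 0.0,
                **{f"hstnt_{a}": params.value(f"ctnt_{a}") for a in ("se6", "se12", "sp6", "sp12")},
                **{f"combo_{a}": params.value(f"ctnt_{a}") for a in ("se6", "se12", "sp6", "sp12")},
            }
        )
        r = evaluate_all(tied)
        for other in r[1:]:
            assert other.expected_cost == pytest.approx(r[0].expected_cost, rel=1e-14)
            assert other.expected_ly == pytest.approx(r[0].expected_ly, rel=1e-14)

    def test_pathway_sums_hold_across_random_draws(self, params):
        # vectorised sweep across many random valid parameter sets
        from troponin_cea.parameters import sample_parameter_set

        rng = np.random.default_rng(3)
        for _ in range(200):
            drawn = sample_parameter_set(params, rng)
            for s in build_strategies(drawn):
                total = sum(p.probability for p in path_probabilities(drawn.value("prevalence"), s))
                assert abs(total - 1.0) < 1e-12
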