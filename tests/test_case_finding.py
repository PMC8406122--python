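"""Risk scoring, prioritization, sample frames, and simulated testing."""

import numpy as np
import pytest
from scipy.stats import binom

from medsentinel import TestProtocol as Protocol
from medsentinel import (
    EffectConfig,
    ValidationError,
    assign_true_quality,
    build_sample_frame,
    case_finding_yield,
    compute_risk_indices,
    default_scoring_rules,
    risk_index,
    score_indicator,
    select_for_sampling,
    simulate_testing,
)
from medsentinel.case_finding import draw_from_frame
from medsentinel.scoring import Band, ScoringRule
from medsentinel._rng import child_rng


class TestScoreIndicator:
    @pytest.mark.parametrize(
        "decile,points", [(1, 3), (2, 2), (3, 2), (4, 2), (5, 1), (6, 1), (7, 0), (10, 0)]
    )
    def test_default_price_rule_decile_points(self, decile, points):
        rule = default_scoring_rules()["price_ratio"]
        assert score_indicator(decile, rule) == points

    def test_ratio_above_median_scores_zero(self):
        """A product priced above the market median is not irrationally cheap:
        it is ineligible for deciles and scores no risk points."""
        rule = default_scoring_rules()["price_ratio"]
        assert score_indicator(None, rule) == 0

    def test_threshold_and_flag_rules(self):
        rules = default_scoring_rules()
        assert score_indicator(36.0, rules["months_since_inspection"]) == 2
        assert score_indicator(0.0, rules["warnings_count"]) == 0
        assert score_indicator("unstable", rules["stability_class"]) == 3
        assert score_indicator("remote", rules["accessibility_class"]) == 2

    def test_value_outside_bands_is_an_error(self):
        rule = ScoringRule("stability_class", "flag", (Band(points=0, flag="stable"),))
        with pytest.raises(ValidationError, match="partition"):
            score_indicator("granite", rule)

    def test_decile_bands_must_partition(self):
        with pytest.raises(ValidationError):
            ScoringRule("price_ratio", "decile", (Band(points=3, lo=1, hi=5),))

    def test_default_rules_monotone_in_risk_direction(self):
        """Riskier decile never yields fewer points."""
        rule = default_scoring_rules()["price_ratio"]
        pts = [score_indicator(d, rule) for d in range(1, 11)]
        assert pts == sorted(pts, reverse=True)


class TestRiskIndex:
    def test_zero_points_zero_total(self):
        assert risk_index("P", "substandard", {"a": 0, "b": 0}).total == 0

    def test_unweighted_sum(self):
        ri = risk_index("P", "substandard", {"a": 3, "b": 2, "c": 1})
        assert ri.total == 6

    def test_weighted_sum_upweights_brand_indicators(self):
        ri = risk_index("P", "substandard", {"a": 3, "b": 1}, weights={"a": 2, "b": 1})
        assert ri.total == 7

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            risk_index("P", "substandard", {"a": 1}, weights={"a": -1})

    def test_total_decomposes_into_weighted_parts(self, market):
        for ri in compute_risk_indices(market, "substandard", weights={"price_ratio": 2.0}):
            manual = sum(ri.weights.get(k, 1.0) * v for k, v in ri.points.items())
            assert ri.total == pytest.approx(manual, abs=1e-12)


class TestSelectForSampling:
    def test_census_when_budget_exceeds_n(self):
        idx = [risk_index(p, "substandard", {"a": v}) for p, v in [("A", 1), ("B", 3)]]
        assert select_for_sampling(idx, 10) == ["B", "A"]

    def test_tie_broken_by_product_id(self):
        idx = [
            risk_index("A", "substandard", {"a": 3, "b": 3}),
            risk_index("B", "substandard", {"a": 2, "b": 2}),
            risk_index("C", "substandard", {"a": 3, "b": 3}),
        ]
        assert select_for_sampling(idx, 2) == ["A", "C"]

    def test_budget_one_is_argmax(self):
        idx = [risk_index(p, "substandard", {"a": v}) for p, v in [("A", 1), ("B", 3), ("C", 2)]]
        assert select_for_sampling(idx, 1) == ["B"]


class TestSampleFrame:
    def test_equal_weights_give_uniform_frame(self, toy_market):
        frame = build_sample_frame(["A", "B", "C"], toy_market)
        assert len(frame.entries) == 4  # the four stocked pairs
        assert np.allclose(frame.normalized_weights, 0.25)

    def test_remote_outlets_carry_double_weight(self, toy_market):
        frame = build_sample_frame(
            ["A", "B"], toy_market, geography_weights={"accessible": 1.0, "remote": 2.0}
        )
        w = dict(((p, o), wt) for p, o, wt in frame.entries)
        assert w[("B", "O2")] == 2 * w[("B", "O1")]  # O2 is remote

    def test_empty_selection_empty_frame(self, toy_market):
        assert build_sample_frame([], toy_market).entries == []

    def test_unstocked_product_warned_and_excluded(self, toy_market):
        del toy_market.stock[("C", "O2")]
        with pytest.warns(UserWarning, match="C"):
            frame = build_sample_frame(["A", "C"], toy_market)
        assert all(p != "C" for p, _, _ in frame.entries)


class TestSimulateTesting:
    @pytest.fixture
    def truth(self, market):
        effects = EffectConfig(
            beta0_substandard=np.log(0.3 / 0.7), beta0_falsified=-30.0
        )
        return assign_true_quality(market, effects)

    def _draws(self, market, n):
        pairs = market.stocked_pairs()
        rng = child_rng(4, "draws")
        idx = rng.choice(len(pairs), size=n, replace=True)
        return [(pairs[i][0], pairs[i][1]) for i in idx]

    def test_perfect_test_reproduces_true_statuses(self, market, truth):
        protocol = Protocol(1.0, 1.0, 1.0, 1.0)
        res = simulate_testing(
            self._draws(market, 100), market, truth, protocol, "substandard", seed=1
        )
        df = res.records
        assert (df["test_positive"] == (df["true_status"] == "substandard")).all()

    def test_zero_sensitivity_detects_nothing(self, market, truth):
        protocol = Protocol(assay_sensitivity=0.0, assay_specificity=1.0)
        res = simulate_testing(
            self._draws(market, 200), market, truth, protocol, "substandard", seed=2
        )
        assert not res.records["test_positive"].any()

    def test_positive_count_within_binomial_99_interval(self, market, truth):
        """With known truth, sens 0.9 / spec 0.95, the positive count must land
        in the exact binomial 99% interval of its expectation."""
        protocol = Protocol(assay_sensitivity=0.9, assay_specificity=0.95)
        draws = self._draws(market, 1000)
        res = simulate_testing(draws, market, truth, protocol, "substandard", seed=3)
        df = res.records
        n_true = int((df["true_status"] == "substandard").sum())
        n_false = len(df) - n_true
        pos = int(df["test_positive"].sum())
        # sum of two binomials; bound with conservative envelope of each part
        lo = binom.ppf(0.005, n_true, 0.9) + binom.ppf(0.005, n_false, 0.05)
        hi = binom.ppf(0.995, n_true, 0.9) + binom.ppf(0.995, n_false, 0.05)
        assert lo <= pos <= hi

    def test_stream_protocol_mismatch_rejected(self, market, truth):
        with pytest.raises(ValidationError):
            simulate_testing([], market, truth, Protocol(), "bogus", seed=0)


class TestYieldMetrics:
    def _results(self, records, stream="substandard"):
        import pandas as pd

        from medsentinel.case_finding import TestResultSet

        df = pd.DataFrame(
            [
                {
                    "product_id": f"P{i}",
                    "outlet_id": "O",
                    "stream": stream,
                    "true_status": ts,
                    "test_positive": tp,
                }
                for i, (ts, tp) in enumerate(records)
            ]
        )
        return TestResultSet(records=df)

    def test_all_positive_yield_one(self):
        res = self._results([("substandard", True)] * 4)
        assert case_finding_yield(res)["yield"] == 1.0

    def test_three_positives_in_five_tests(self):
        res = self._results(
            [("substandard", True)] * 3 + [("compliant", False)] * 2
        )
        assert case_finding_yield(res)["yield"] == 0.6

    def test_ppv_matches_brute_force_tally(self):
        records = [
            ("substandard", True),
            ("substandard", True),
            ("compliant", True),   # false positive
            ("compliant", False),
            ("substandard", False),
        ]
        res = self._results(records)
        tp = sum(1 for ts, tp_ in records if ts == "substandard" and tp_)
        pos = sum(1 for _, tp_ in records if tp_)
        assert case_finding_yield(res)["ppv"] == pytest.approx(tp / pos)

    def test_zero_tests_is_an_error(self):
        with pytest.raises(ValidationError):
            case_finding_yield(self._results([]))


class TestWeightTuning:
    def test_grid_search_picks_highest_retrospective_yield(self, market):
        from medsentinel import tune_weights
        from medsentinel.evaluation import strong_effects

        truth = assign_true_quality(market, strong_effects())
        candidates = [
            {},  # simple unweighted index
            {"price_ratio": 3.0},  # upweight the brand-level indicator
            {"price_ratio": 0.0, "months_since_inspection": 0.0,
             "warnings_count": 0.0, "producer_years_on_molecule": 0.0,
             "ma_holder_years": 0.0, "stability_class": 0.0,
             "accessibility_class": 0.0},  # degenerate: ignore all indicators
        ]
        best, best_yield = tune_weights(
            market, truth, "substandard", candidates, budget=40, seed=8
        )
        yields = []
        from medsentinel import run_case_finding

        for w in candidates:
            _, m = run_case_finding(
                market, truth, "substandard", 40, weights=w, seed=8
            )
            yields.append(m["yield"])
        assert best_yield == max(yields)

    def test_empty_candidate_list_rejected(self, market):
        from medsentinel import tune_weights
        from medsentinel.evaluation import strong_effects

        truth = assign_true_quality(market, strong_effects())
        with pytest.raises(ValidationError):
            tune_weights(market, truth, "substandard", [], budget=5)


class TestScoringRuleConfig:
    def test_yaml_style_override_replaces_default(self):
        from medsentinel import scoring_rules_from_config

        rules = scoring_rules_from_config(
            {
                "warnings_count": {
                    "kind": "threshold",
                    "bands": [
                        {"points": 0, "hi": 2.0},
                        {"points": 3, "lo": 2.0},
                    ],
                }
            }
        )
        assert score_indicator(1.0, rules["warnings_count"]) == 0
        assert score_indicator(2.0, rules["warnings_count"]) == 3
        # untouched indicators keep their defaults
        assert score_indicator(1, rules["price_ratio"]) == 3


class TestDrawFromFrame:
    def test_draws_without_replacement(self, toy_market):
        frame = build_sample_frame(["A", "B", "C"], toy_market)
        draws = draw_from_frame(frame, 4, child_rng(0, "x"))
        assert len(set(draws)) == len(draws) == 4

    def test_deterministic_given_seed(self, toy_market):
        frame = build_sample_frame(["A", "B", "C"], toy_market)
        d1 = draw_from_frame(frame, 2, child_rng(9, "x"))
        d2 = draw_from_frame(frame, 2, child_rng(9, "x"))
        assert d1 == d2
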