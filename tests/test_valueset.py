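"""Value-set construction: averaging, cumulation, adjustment, enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dlqivalue as dv
from dlqivalue import reference
from dlqivalue.valueset import (
    ValueSet,
    _round_half_up,
    adjust_for_nontraders,
    average_models,
    build_value_set,
    concavity_summary,
    cumulate,
    enumerate_distribution,
    enumerate_levels,
    predict_utility,
)

W = reference.REFERENCE_W


def count_by_score(weights=None):
    """DP oracle: number of 10-tuples over {0..3} per total score — the
    coefficients of (1 + x + x^2 + x^3)^10."""
    poly = np.array([1], dtype=object)
    for _ in range(10):
        poly = np.convolve(poly, np.ones(4, dtype=object))
    return poly  # length 31


class TestAverageModels:
    def test_published_intercept_average(self):
        fits = reference.reference_fit_results()
        alpha, incr = average_models(fits)
        assert alpha == pytest.approx(0.8489, abs=1e-9)
        assert round(alpha, 3) == 0.849
        assert incr[(1, 3)] == pytest.approx(-0.0221, abs=1e-9)

    def test_identical_fits_average_to_themselves(self):
        f = reference.reference_fit_results()[0]
        alpha, incr = average_models([f, f])
        assert alpha == f.alpha and incr == f.beta

    def test_mismatched_dummy_sets_rejected(self):
        a, b = reference.reference_fit_results()
        import dataclasses

        b = dataclasses.replace(b, beta={(1, 3): -0.01},
                                design=dv.DummyDesign.full().subset([(1, 3)]))
        with pytest.raises(ValueError, match="mismatch"):
            average_models([a, b])


class TestCumulate:
    def test_q9_two_active_levels(self, final_design):
        incr = {d: 0.0 for d in final_design.active}
        incr[(9, 1)], incr[(9, 2)] = -0.0332, -0.0211
        cum = cumulate(incr, final_design)
        assert np.allclose(cum[8], [0, -0.0332, -0.0543, -0.0543])

    def test_single_level_one_dummy_propagates(self, final_design):
        incr = {d: 0.0 for d in final_design.active}
        incr[(3, 1)] = -0.025
        cum = cumulate(incr, final_design)
        assert np.allclose(cum[2], [0, -0.025, -0.025, -0.025])

    def test_zero_effects(self, final_design):
        cum = cumulate({d: 0.0 for d in final_design.active}, final_design)
        assert np.allclose(cum, 0.0)

    def test_inactive_dummy_rejected(self, final_design):
        with pytest.raises(ValueError, match="inactive"):
            cumulate({(1, 1): -0.1}, final_design)


class TestAdjustment:
    def test_published_adjustment(self):
        trader, adjusted = reference.reference_value_set()
        assert round(adjusted.intercept, 3) == 0.873
        # Q2 L3: trader -0.040 -> adjusted -0.034
        assert round(trader.cumulative[1, 3], 3) == -0.040
        assert round(adjusted.cumulative[1, 3], 3) == -0.034

    def test_w_zero_identity(self):
        trader, _ = reference.reference_value_set()
        same = adjust_for_nontraders(trader, 0.0)
        assert same.intercept == trader.intercept
        assert np.allclose(same.cumulative, trader.cumulative)

    def test_invalid_w_rejected(self):
        trader, _ = reference.reference_value_set()
        with pytest.raises(ValueError):
            adjust_for_nontraders(trader, 1.5)

    @given(levels=st.lists(st.integers(0, 3), min_size=10, max_size=10),
           w=st.floats(0.0, 1.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_adjust_commutes_with_predict(self, levels, w):
        """w * 1 + (1 - w) * prediction == prediction under the adjusted set."""
        trader, _ = reference.reference_value_set()
        adjusted = adjust_for_nontraders(trader, w)
        lv = np.array(levels)
        a = w + (1.0 - w) * predict_utility(lv, trader)
        b = predict_utility(lv, adjusted)
        assert abs(a - b) < 1e-12


class TestPrediction:
    def test_zero_state_is_intercept(self):
        _, adjusted = reference.reference_value_set()
        assert round(predict_utility(np.zeros(10, dtype=int), adjusted), 3) == 0.873

    def test_worst_state(self):
        _, adjusted = reference.reference_value_set()
        expected = adjusted.intercept + adjusted.cumulative[:, 3].sum()
        assert predict_utility(np.full(10, 3), adjusted) == pytest.approx(expected)
        # summing the rounded published cells gives 0.873 - 0.298 = 0.575; the
        # unrounded chain may differ by the accumulated display rounding
        assert expected == pytest.approx(0.575, abs=2e-3)

    @given(levels=st.lists(st.integers(0, 3), min_size=10, max_size=10),
           item=st.integers(0, 9))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_severity(self, levels, item):
        _, adjusted = reference.reference_value_set()
        lv = np.array(levels)
        lv[item] = min(lv[item], 2)
        hi = lv.copy()
        hi[item] += 1
        assert predict_utility(hi, adjusted) <= predict_utility(lv, adjusted) + 1e-12

    def test_validation_of_value_set_invariants(self):
        pos = np.zeros((10, 4))
        pos[:, 1:] = 0.1
        with pytest.raises(ValueError, match="non-positive"):
            ValueSet(0.9, pos)
        bad = np.zeros((10, 4))
        bad[0] = [0, -0.3, -0.2, -0.2]  # increases from level 1 to 2
        with pytest.raises(ValueError, match="non-increasing"):
            ValueSet(0.9, bad)


class TestEnumeration:
    def test_counts_match_dp_oracle(self):
        counts = count_by_score()
        levels = enumerate_levels()
        scores = levels.sum(axis=1)
        for s in (0, 1, 10, 15, 30):
            assert int(counts[s]) == int((scores == s).sum())
        assert int(sum(counts)) == 4**10

    def test_extreme_scores_are_singletons(self):
        _, adjusted = reference.reference_value_set()
        d0 = enumerate_distribution(adjusted, total_score=0)
        d30 = enumerate_distribution(adjusted, total_score=30)
        assert d0["count"] == 1 and d30["count"] == 1
        assert d0["percentiles"][50] == pytest.approx(adjusted.intercept)

    def test_invalid_score_rejected(self):
        _, adjusted = reference.reference_value_set()
        with pytest.raises(ValueError):
            enumerate_distribution(adjusted, total_score=31)


class TestConcavity:
    def test_linear_value_set_has_zero_second_differences(self):
        design = dv.DummyDesign.full()
        incr = {d: -0.01 for d in design.active}
        vs = build_value_set(0.9, incr, design)
        prof = concavity_summary(vs)
        assert np.allclose(prof["mean_utility"], 0.9 - 0.01 * prof["total_score"])
        inner = prof["second_difference"].iloc[1:-1]
        assert np.allclose(inner, 0.0, atol=1e-12)

    def test_single_dummy_profile_matches_conditional_probability(self):
        """Mean utility at score s = intercept + effect * P(Q3 >= 1 | score s),
        with the conditional probability from the DP count oracle."""
        design = dv.DummyDesign.full().subset([(3, 1)])
        vs = build_value_set(0.9, {(3, 1): -0.2}, design)
        prof = concavity_summary(vs)
        counts_10 = count_by_score()
        # states with Q3 = 0 at total score s: coefficient of x^s in (1+..+x^3)^9
        poly9 = np.array([1], dtype=object)
        for _ in range(9):
            poly9 = np.convolve(poly9, np.ones(4, dtype=object))
        for s in (0, 1, 5, 13, 27, 30):
            p_q3_zero = (float(poly9[s]) if s < len(poly9) else 0.0) / float(counts_10[s])
            expected = 0.9 - 0.2 * (1.0 - p_q3_zero)
            assert prof.loc[s, "mean_utility"] == pytest.approx(expected, abs=1e-12)

    def test_published_set_mostly_concave(self):
        _, adjusted = reference.reference_value_set()
        second = concavity_summary(adjusted)["second_difference"].iloc[1:-1]
        assert (second <= 1e-9).mean() > 0.8  # reported as predominantly concave


class TestRounding:
    def test_half_away_from_zero(self):
        assert _round_half_up(np.array(-0.0185), 3) == pytest.approx(-0.019)
        assert _round_half_up(np.array(0.0185), 3) == pytest.approx(0.019)
        assert _round_half_up(np.array(-0.0184), 3) == pytest.approx(-0.018)

    def test_table_frame_layout(self):
        trader, adjusted = reference.reference_value_set()
        frame = adjusted.to_frame(digits=3)
        assert list(frame.columns) == ["level_1", "level_2", "level_3"]
        assert frame.loc["Q9", "level_2"] == pytest.approx(-0.046)
        assert frame.loc["Intercept", "level_1"] == pytest.approx(0.873)
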