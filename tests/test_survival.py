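"""Kaplan-Meier curves, survival lookup, regression and rank tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppientropy.errors import DegenerateDistributionError, ValidationError
from ppientropy.survival import (
    bin_patients_by_survival,
    entropy_survival_regression,
    km_curve,
    kruskal_wallis,
    pairwise_rank_tests,
    survival_rate_at,
)


def records(times, events, cohort="X"):
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(len(times))],
            "event": events,
            "time_days": times,
            "cohort": cohort,
        }
    )


@pytest.fixture
def hand_curve():
    """Times (5,10,10,15), events (1,1,0,1): S = 3/4, 1/2, 0."""
    return km_curve(records([5, 10, 10, 15], [1, 1, 0, 1]))


class TestKMCurve:
    def test_hand_product_limit_example(self, hand_curve):
        lookup = dict(zip(hand_curve.times, hand_curve.survival))
        assert lookup[5] == pytest.approx(0.75)
        assert lookup[10] == pytest.approx(0.50)
        assert lookup[15] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        curve = km_curve(records([10, 20, 30], [0, 0, 0]))
        assert np.all(curve.survival == 1.0)

    def test_single_subject_event(self):
        curve = km_curve(records([100], [1]))
        assert survival_rate_at(curve, 100) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        times = [3, 7, 7, 12, 20]
        curve = km_curve(records(times, [1] * 5))
        for t in (3, 7, 12, 19, 20):
            empirical = 100 * np.mean(np.array(times) > t)
            assert survival_rate_at(curve, t) == pytest.approx(empirical)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            km_curve(records([], []))


class TestSurvivalRateAt:
    def test_step_lookup_between_events(self, hand_curve):
        assert survival_rate_at(hand_curve, 12) == pytest.approx(50.0)

    def test_before_first_event(self, hand_curve):
        assert survival_rate_at(hand_curve, 1) == 100.0

    def test_beyond_last_time_carries_forward(self, hand_curve):
        assert survival_rate_at(hand_curve, 9999) == 0.0

    def test_flat_curve(self):
        curve = km_curve(records([10, 20], [0, 0]))
        assert survival_rate_at(curve, 1825) == 100.0

    def test_non_increasing_in_time(self, hand_curve):
        rates = [survival_rate_at(hand_curve, t) for t in (1, 5, 8, 10, 14, 15, 30)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestRegression:
    def line(self, x):
        return -0.004 * x + 2.507

    def test_collinear_points_return_generating_line(self):
        pts = [(x, self.line(x)) for x in (35.0, 60.0, 95.0)]
        res = entropy_survival_regression(pts)
        assert res.slope == pytest.approx(-0.004, abs=1e-12)
        assert res.intercept == pytest.approx(2.507, abs=1e-9)
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_two_points_rejected(self):
        with pytest.raises(ValidationError):
            entropy_survival_regression([(1.0, 1.0), (2.0, 2.0)])

    def test_identical_x_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            entropy_survival_regression([(5.0, 1.0), (5.0, 2.0), (5.0, 3.0)])

    def test_slope_within_its_confidence_interval(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(35, 100, 9)
        y = self.line(x) + rng.normal(0, 0.03, 9)
        res = entropy_survival_regression(list(zip(x, y)))
        assert res.slope_ci_low <= res.slope <= res.slope_ci_high

    def test_scale_consistency(self):
        rng = np.random.default_rng(1)
        pts = [(x, self.line(x) + rng.normal(0, 0.05)) for x in np.linspace(30, 95, 8)]
        base = entropy_survival_regression(pts)
        scaled = entropy_survival_regression([(x, 3.0 * y) for x, y in pts])
        assert scaled.slope == pytest.approx(3.0 * base.slope)
        assert scaled.intercept == pytest.approx(3.0 * base.intercept)
        assert scaled.r == pytest.approx(base.r)
        assert scaled.p_value == pytest.approx(base.p_value)


def kw_statistic(groups):
    return kruskal_wallis(groups).kw_statistic


class TestKruskalWallis:
    def test_nine_groups_have_df_eight(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(i, 1, 10).tolist() for i in range(9)]
        assert kruskal_wallis(groups).kw_df == 8

    def test_identical_groups_score_zero(self):
        assert kw_statistic([[1, 2, 3], [1, 2, 3], [1, 2, 3]]) == pytest.approx(0.0)

    def test_separated_groups_are_permutation_extreme(self):
        """For {1,2} vs {10,11} the observed statistic must sit in the
        2/6 extreme tail of the exhaustive relabeling distribution."""
        pooled = [1.0, 2.0, 10.0, 11.0]
        observed = kw_statistic([[1.0, 2.0], [10.0, 11.0]])
        stats_all = []
        for first in combinations(range(4), 2):
            rest = [i for i in range(4) if i not in first]
            stats_all.append(
                kw_statistic([[pooled[i] for i in first], [pooled[i] for i in rest]])
            )
        tail = sum(s >= observed - 1e-12 for s in stats_all) / len(stats_all)
        assert tail == pytest.approx(2 / 6)
        assert observed == pytest.approx(max(stats_all), abs=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3], [5]])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(i, 1, 12).tolist() for i in range(4)]
        raw = kw_statistic(groups)
        transformed = kw_statistic([[np.exp(v) for v in g] for g in groups])
        assert transformed == pytest.approx(raw, abs=1e-12)


class TestPairwiseRankTests:
    def test_identical_groups_give_p_one(self):
        p = pairwise_rank_tests([[1, 2, 3], [1, 2, 3]], ["a", "b"])
        assert p[("a", "b")] == pytest.approx(1.0)

    def test_separated_groups_significant_after_holm(self):
        p = pairwise_rank_tests(
            [list(range(1, 11)), list(range(100, 111))], ["lo", "hi"]
        )
        assert p[("lo", "hi")] < 0.01
        # exact two-sided rank-sum tail for complete separation
        assert p[("lo", "hi")] == pytest.approx(
            float(
                stats.mannwhitneyu(
                    range(1, 11), range(100, 111), alternative="two-sided"
                ).pvalue
            )
        )

    def test_none_correction_returns_raw(self):
        groups = [[1, 2, 3, 4], [2, 3, 4, 5], [10, 11, 12, 13]]
        raw = pairwise_rank_tests(groups, ["a", "b", "c"], correction="none")
        expected = float(
            stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided").pvalue
        )
        assert raw[("a", "b")] == pytest.approx(expected)

    def test_unknown_correction_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_rank_tests([[1, 2], [3, 4]], ["a", "b"], correction="fdr?")

    def test_matrix_is_symmetric(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(i, 1, 8).tolist() for i in range(3)]
        p = pairwise_rank_tests(groups, ["a", "b", "c"])
        assert p[("a", "c")] == p[("c", "a")]


class TestSurvivalBinning:
    def test_boundary_81_maps_to_top_interval(self):
        bins = bin_patients_by_survival([("p1", 81.0)])
        assert bins["100%-81%"]["patients"] == ["p1"]

    def test_80_point_5_maps_below(self):
        bins = bin_patients_by_survival([("p1", 80.5)])
        assert bins["80%-61%"]["patients"] == ["p1"]

    def test_empty_input_all_ineligible(self):
        bins = bin_patients_by_survival([])
        assert all(not interval["eligible"] for interval in bins.values())

    def test_each_patient_lands_in_exactly_one_interval(self):
        rng = np.random.default_rng(0)
        pts = [(f"p{i}", float(r)) for i, r in enumerate(rng.uniform(0.01, 100, 200))]
        bins = bin_patients_by_survival(pts)
        total = sum(len(b["patients"]) for b in bins.values())
        assert total == 200

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValidationError):
            bin_patients_by_survival([("p1", 0.0)])
        with pytest.raises(ValidationError):
            bin_patients_by_survival([("p1", 101.0)])

    def test_eligibility_rule(self):
        pts = [(f"p{i}", 90.0) for i in range(3)] + [("q", 50.0)]
        bins = bin_patients_by_survival(pts)
        assert bins["100%-81%"]["eligible"]
        assert not bins["60%-41%"]["eligible"]
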