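import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from epimark.errors import ContractError, DegenerateSplitError, UndefinedValueError
from epimark.simulate import gen_cohort
from epimark.survival import (
    best_cutoff_scan,
    km_estimate,
    logrank_test,
    records_from_frame,
    split_by_mean,
    survival_at,
)

from conftest import make_records


class TestKaplanMeier:
    def test_three_events_product_limit_by_hand(self):
        curve = km_estimate(make_records([1, 2, 3], [1, 1, 1]))
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_all_censored_is_flat_one(self):
        curve = km_estimate(make_records([5, 10, 15], [0, 0, 0]))
        assert len(curve.event_times) == 0
        assert survival_at(curve, 12).probability == 1.0

    def test_tie_rule_events_before_censorings(self):
        # (1 event, 2 censored, 3 event): S(1)=2/3, S(3)=0
        curve = km_estimate(make_records([1, 2, 3], [1, 0, 1]))
        assert curve.survival == pytest.approx([2 / 3, 0.0])
        assert curve.event_times.tolist() == [1.0, 3.0]

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=200) + 0.01
        curve = km_estimate(make_records(times, np.ones(200)))
        for t in (1.0, 5.0, 10.0, 20.0):
            assert survival_at(curve, t).probability == pytest.approx(
                np.mean(times > t)
            )

    def test_matches_lifelines(self, rng):
        times = rng.exponential(10, size=100) + 0.01
        events = (rng.random(100) > 0.3).astype(int)
        curve = km_estimate(make_records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                kmf.survival_function_at_times(t).iloc[0], abs=1e-10
            )

    def test_survival_is_non_increasing(self, rng):
        times = rng.exponential(5, size=150) + 0.01
        events = (rng.random(150) > 0.4).astype(int)
        s = km_estimate(make_records(times, events)).survival
        assert np.all(np.diff(s) <= 1e-12)

    def test_non_positive_time_rejected(self):
        with pytest.raises(ContractError):
            make_records([0.0], [1])


class TestSurvivalAt:
    def test_step_lookup_between_event_times(self):
        curve = km_estimate(make_records([1, 2, 3], [1, 1, 1]))
        assert survival_at(curve, 2.5).probability == pytest.approx(1 / 3)

    def test_horizon_zero_is_one(self):
        curve = km_estimate(make_records([1, 2], [1, 1]))
        assert survival_at(curve, 0).probability == 1.0

    def test_extrapolation_flag(self):
        curve = km_estimate(make_records([1, 2], [1, 0]))
        assert not survival_at(curve, 2).extrapolated
        assert survival_at(curve, 3).extrapolated

    def test_exponential_cohort_five_year_survival(self):
        rng = np.random.default_rng(60)
        times = rng.exponential(60 / np.log(2), size=2000) + 1e-9
        curve = km_estimate(make_records(times, np.ones(2000)))
        assert survival_at(curve, 60).probability == pytest.approx(0.5, abs=0.03)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = make_records([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test(g, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        a = make_records(rng.exponential(10, 30) + 0.01, (rng.random(30) > 0.2))
        b = make_records(rng.exponential(5, 30) + 0.01, (rng.random(30) > 0.2))
        assert logrank_test(a, b).statistic == pytest.approx(
            logrank_test(b, a).statistic
        )

    def test_matches_lifelines_statistic(self, rng):
        for _ in range(5):
            a = make_records(rng.exponential(10, 40) + 0.01, rng.random(40) > 0.3)
            b = make_records(rng.exponential(6, 35) + 0.01, rng.random(35) > 0.3)
            mine = logrank_test(a, b)
            ta, ea = [r.time for r in a], [r.event for r in a]
            tb, eb = [r.time for r in b], [r.event for r in b]
            theirs = ll_logrank(ta, tb, ea, eb)
            assert mine.statistic == pytest.approx(theirs.test_statistic, abs=1e-8)
            assert mine.p_value == pytest.approx(theirs.p_value, abs=1e-8)

    def test_no_events_is_undefined(self):
        a = make_records([1, 2], [0, 0])
        b = make_records([3, 4], [0, 0])
        with pytest.raises(UndefinedValueError):
            logrank_test(a, b)

    def test_power_at_hazard_ratio_two(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 50
        for _ in range(n_rep):
            a = make_records(rng.exponential(10, 200) + 1e-9, np.ones(200))
            b = make_records(rng.exponential(5, 200) + 1e-9, np.ones(200))
            if logrank_test(a, b).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep >= 0.9


class TestSplits:
    def test_mean_split_threshold_and_sizes(self):
        recs = make_records([5, 6, 7], [1, 1, 1], [0.1, 0.2, 0.6])
        res = split_by_mean(recs)
        assert res.threshold == pytest.approx(0.3)
        assert (res.n_low, res.n_high) == (2, 1)
        assert res.threshold_percent == pytest.approx(30.0)

    def test_degenerate_covariate_rejected(self):
        recs = make_records([1, 2, 3], [1, 1, 1], [0.5, 0.5, 0.5])
        with pytest.raises(DegenerateSplitError):
            split_by_mean(recs)

    def test_mean_split_separates_bimodal_modes(self):
        rng = np.random.default_rng(3)
        lo = 0.1 + 0.05 * rng.random(50)
        hi = 0.7 + 0.05 * rng.random(50)
        cov = np.concatenate([lo, hi])
        recs = make_records(rng.exponential(10, 100) + 0.01, np.ones(100), cov)
        res = split_by_mean(recs)
        assert res.n_low == 50 and res.n_high == 50

    def test_two_point_covariate_selects_only_split(self):
        rng = np.random.default_rng(4)
        cov = [0.0] * 15 + [1.0] * 15
        recs = make_records(rng.exponential(10, 30) + 0.01, np.ones(30), cov)
        res = best_cutoff_scan(recs)
        assert res.threshold == 1.0
        assert (res.n_low, res.n_high) == (15, 15)

    def test_best_cutoff_recovers_planted_step(self):
        df, truth = gen_cohort(17, 500, cutoff=0.30, hazard_ratio=3.0)
        recs = records_from_frame(df, covariate_col="beta", id_col="subject_id")
        res = best_cutoff_scan(recs)
        assert abs(res.threshold - truth.truth["cutoff"]) <= 0.05
        assert res.method == "best_cutoff" and res.p_unadjusted

    def test_small_cohort_warns(self):
        rng = np.random.default_rng(5)
        recs = make_records(
            rng.exponential(10, 10) + 0.01, np.ones(10), rng.random(10)
        )
        with pytest.warns(UserWarning):
            best_cutoff_scan(recs)

    def test_null_scan_inflates_minimum_p(self):
        """Minimum unadjusted p over many thresholds rejects far more often
        than its nominal level under the null — the selection bias the
        unadjusted flag warns about."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            df, _ = gen_cohort(40_000 + rep, 60, hazard_ratio=1.0)
            recs = records_from_frame(df, covariate_col="beta", id_col="subject_id")
            if best_cutoff_scan(recs).p_value < 0.05:
                hits += 1
        assert hits / n_rep > 0.15
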