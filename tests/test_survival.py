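"""Kaplan-Meier estimation, log-rank testing, extreme-rank stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xsub import (
    SurvivalRecord,
    km_curve,
    logrank_test,
    select_extremes,
    stratify_and_compare,
)


def rec(i, t, e, ds="D1"):
    return SurvivalRecord(f"s{i}", float(t), e, ds)


def brute_km(records):
    """Hand product-limit: S(t) = prod over event times <= t of (1 - d/n)."""
    times = sorted({r.time for r in records if r.event == 1})
    surv = {}
    s = 1.0
    for t in times:
        n = sum(1 for r in records if r.time >= t)
        d = sum(1 for r in records if r.time == t and r.event == 1)
        s *= 1.0 - d / n
        surv[t] = s
    return surv


def brute_logrank(high, low):
    """Explicit per-event-time O/E/V risk-table enumeration."""
    event_times = sorted({r.time for r in list(high) + list(low) if r.event == 1})
    O = E = V = 0.0
    for t in event_times:
        n1 = sum(1 for r in high if r.time >= t)
        n2 = sum(1 for r in low if r.time >= t)
        d1 = sum(1 for r in high if r.time == t and r.event == 1)
        d2 = sum(1 for r in low if r.time == t and r.event == 1)
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, float(stats.chi2.sf(chi2, 1))


def make_ranking(scores, datasets=None):
    samples = list(scores)
    return pd.DataFrame({
        "sample_id": samples,
        "dataset": [datasets[s] for s in samples] if datasets else "",
        "score": [scores[s] for s in samples],
    }).sort_values("score", ascending=False)


class TestKmCurve:
    def test_uncensored_closed_form(self):
        curve = km_curve([rec(i, t, 1) for i, t in enumerate([1, 2, 3, 4])])
        np.testing.assert_allclose(curve.survival, [0.75, 0.50, 0.25, 0.0])
        assert curve.median == 2.0

    def test_all_censored_median_not_reached(self):
        curve = km_curve([rec(i, t, 0) for i, t in enumerate([5, 10, 15])])
        np.testing.assert_allclose(curve.survival, 1.0)
        assert curve.median is None

    def test_mixed_fixture_hand_computation(self):
        # events at 10 and 20, censor at 15: S(10)=2/3, risk set at 20 is 1, S(20)=0
        curve = km_curve([rec(0, 10, 1), rec(1, 15, 0), rec(2, 20, 1)])
        assert curve.at(10) == pytest.approx(2 / 3)
        assert curve.at(20) == pytest.approx(0.0)
        assert curve.at_risk[list(curve.times).index(20.0)] == 1

    def test_matches_brute_force_product_limit(self, rng):
        records = [rec(i, rng.exponential(100.0), int(rng.random() < 0.7))
                   for i in range(40)]
        curve = km_curve(records)
        for t, s in brute_km(records).items():
            assert curve.at(t) == pytest.approx(s, abs=1e-12)

    def test_curve_is_a_nonincreasing_step_from_one(self, rng):
        records = [rec(i, rng.exponential(50.0), int(rng.random() < 0.5))
                   for i in range(30)]
        curve = km_curve(records)
        assert curve.at(0) == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_censoring_the_last_record_only_removes_its_own_step(self):
        # flipping the latest record from event to censored leaves the curve
        # unchanged at every earlier event time
        with_event = [rec(0, 3, 1), rec(1, 6, 1), rec(2, 9, 1), rec(3, 100, 1)]
        censored = with_event[:3] + [rec(3, 100, 0)]
        c1, c2 = km_curve(with_event), km_curve(censored)
        for t in (3, 6, 9):
            assert c2.at(t) == pytest.approx(c1.at(t), abs=1e-12)
        assert c1.at(100) == 0.0
        assert c2.at(100) == pytest.approx(c2.at(9))


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        group = [rec(i, t, 1) for i, t in enumerate([5, 10, 15, 20])]
        mirror = [SurvivalRecord(f"m{r.sample_id}", r.time, r.event, r.dataset) for r in group]
        chi2, p = logrank_test(group, mirror)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_under_group_swap(self, rng):
        h = [rec(i, rng.exponential(50.0), 1) for i in range(15)]
        l = [rec(100 + i, rng.exponential(120.0), 1) for i in range(15)]
        assert logrank_test(h, l) == pytest.approx(logrank_test(l, h))

    def test_matches_brute_force_risk_table(self, rng):
        high = [rec(i, rng.exponential(100.0 / 2.5), 1) for i in range(20)]
        low = [rec(100 + i, rng.exponential(100.0), 1) for i in range(20)]
        chi2, p = logrank_test(high, low)
        chi2_ref, p_ref = brute_logrank(high, low)
        assert chi2 == pytest.approx(chi2_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_invariant_under_monotone_time_relabeling(self, rng):
        high = [rec(i, rng.exponential(40.0), int(rng.random() < 0.8)) for i in range(20)]
        low = [rec(100 + i, rng.exponential(80.0), int(rng.random() < 0.8)) for i in range(20)]
        warped_h = [SurvivalRecord(r.sample_id, np.log1p(r.time), r.event) for r in high]
        warped_l = [SurvivalRecord(r.sample_id, np.log1p(r.time), r.event) for r in low]
        assert logrank_test(high, low) == pytest.approx(logrank_test(warped_h, warped_l))

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="event"):
            logrank_test([rec(0, 5, 0)], [rec(1, 7, 0)])


class TestSelectExtremes:
    def test_nine_samples_one_third_selects_three_per_end(self):
        scores = {f"s{i}": float(-i) for i in range(9)}
        records = [rec(i, 10 + i, 1) for i in range(9)]
        cohort = select_extremes(make_ranking(scores), records)
        assert {r.sample_id for r in cohort.group_high} == {"s0", "s1", "s2"}
        assert {r.sample_id for r in cohort.group_low} == {"s6", "s7", "s8"}

    def test_fifty_nine_samples_select_nineteen(self):
        scores = {f"s{i:02d}": float(-i) for i in range(59)}
        records = [SurvivalRecord(f"s{i:02d}", 10.0 + i, 1, "D1") for i in range(59)]
        cohort = select_extremes(make_ranking(scores), records)
        assert len(cohort.group_high) == len(cohort.group_low) == 19

    def test_per_dataset_floors_pool_across_datasets(self):
        scores = {f"a{i}": float(-i) for i in range(10)}
        scores.update({f"b{i}": float(-i) for i in range(7)})
        datasets = {s: ("DA" if s.startswith("a") else "DB") for s in scores}
        records = ([SurvivalRecord(s, 10.0, 1, datasets[s]) for s in scores])
        cohort = select_extremes(make_ranking(scores, datasets), records)
        assert len(cohort.group_high) == len(cohort.group_low) == 5  # 3 + 2
        assert cohort.per_dataset_counts == {"DA": 3, "DB": 2}

    def test_groups_are_disjoint(self):
        scores = {f"s{i}": float(i) for i in range(12)}
        records = [rec(i, 5 + i, 1) for i in range(12)]
        cohort = select_extremes(make_ranking(scores), records)
        assert not ({r.sample_id for r in cohort.group_high}
                    & {r.sample_id for r in cohort.group_low})

    def test_tiny_dataset_skipped_with_warning(self):
        scores = {"s0": 1.0, "s1": 0.0}
        records = [rec(0, 5, 1), rec(1, 6, 1)]
        with pytest.warns(UserWarning, match="too few samples"):
            with pytest.raises(ValueError, match="large enough"):
                select_extremes(make_ranking(scores), records)

    def test_missing_survival_record_is_an_error(self):
        scores = {"s0": 1.0, "s1": 0.0, "s2": -1.0}
        with pytest.raises(ValueError, match="without survival"):
            select_extremes(make_ranking(scores), [rec(0, 5, 1)])

    @pytest.mark.parametrize("fraction", [0.0, 0.6, -0.1])
    def test_fraction_out_of_range_is_an_error(self, fraction):
        scores = {"s0": 1.0, "s1": 0.0}
        with pytest.raises(ValueError, match="fraction"):
            select_extremes(make_ranking(scores), [rec(0, 5, 1), rec(1, 6, 1)], fraction)


class TestStratifyAndCompare:
    def test_end_to_end_composition(self, rng):
        n = 30
        scores = {f"s{i}": float(n - i) for i in range(n)}
        # top-ranked patients die early (hazard ratio > 1), bottom-ranked late
        records = [rec(i, rng.exponential(40.0 if i < n // 2 else 160.0) + 0.1, 1)
                   for i in range(n)]
        report = stratify_and_compare(make_ranking(scores), records)
        assert len(report.cohort.group_high) == 10
        chi2_ref, _ = brute_logrank(report.cohort.group_high, report.cohort.group_low)
        assert report.chi_square == pytest.approx(chi2_ref, abs=1e-9)
        assert report.median_high is not None and report.median_low is not None
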