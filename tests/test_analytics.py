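"""Analytics: rates, timing, Kaplan-Meier, percentiles, paired comparison."""

import math
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from fedaccess import analytics
from fedaccess.analytics import (
    EmptyInput,
    InsufficientPairs,
    KMCurve,
    NoCompletions,
    completion_time_stats,
    compute_rates,
    exclude_nodes,
    km_uncompleted,
    paired_class_comparison,
    per_node_curves,
    percentile_time,
    rate_percent,
    split_classes,
    yearly_summary,
)
from fedaccess.eventlog import records_from_events
from fedaccess.model import KPICategory, ProvenanceEvent
from fedaccess.simulate import make_fixture_log, paper_like_config, simulate_network
from fedaccess.states import QueryState

T0 = datetime(2020, 1, 6, 12, 0, tzinfo=timezone.utc)
DAY = timedelta(days=1)


@pytest.fixture(scope="module")
def simulated_records():
    config = paper_like_config(seed=13, n_nodes=10)
    config.n_single_requests = 150
    config.n_series = 8
    records, _ = records_from_events(simulate_network(config))
    return records, config.window_end


def chain(node, qid, *steps):
    """Build a record from (state, timestamp) steps starting at retrieval."""
    events = [ProvenanceEvent(steps[0][1], node, qid, None,
                              QueryState.RETRIEVED, "system")]
    prev = QueryState.RETRIEVED
    for state, ts in steps[1:]:
        events.append(ProvenanceEvent(ts, node, qid, prev, state, "user"))
        prev = state
    return events


def completed_record(node, qid, t0, elapsed):
    return chain(
        node, qid,
        (QueryState.RETRIEVED, t0),
        (QueryState.SEEN, t0),
        (QueryState.ACCEPTED, t0),
        (QueryState.PROCESSING, t0 + elapsed),
        (QueryState.COMPLETED, t0 + elapsed),
    )


class TestRates:
    def test_simple_fraction(self):
        rows = [("N1", f"q{i}#0", KPICategory.COMPLETED, 0) for i in range(8)]
        rows += [("N1", f"u{i}#0", KPICategory.UNANSWERED, None) for i in range(2)]
        records, _ = records_from_events(make_fixture_log(rows))
        rates = compute_rates(records, records[0].retrieved_at + 5 * DAY)
        assert rates["individual"]["rates"]["COMPLETED"] == 80.0
        assert rates["individual"]["counts"]["COMPLETED"] == 8

    def test_round_half_up_single_decimal(self):
        assert rate_percent(3234, 4053) == 79.8
        assert rate_percent(1, 800) == 0.1  # 0.125 rounds up
        assert rate_percent(1, 3) == 33.3
        assert rate_percent(5, 10000) == 0.1  # exactly 0.05 rounds half-up

    def test_rates_sum_to_100_within_rounding(self, simulated_records):
        records, cutoff = simulated_records
        rates = compute_rates(records, cutoff)
        for cls in ("individual", "periodic", "all"):
            total = sum(rates[cls]["rates"].values())
            assert total == pytest.approx(100.0, abs=0.3)
            assert sum(rates[cls]["counts"].values()) == rates[cls]["total"]

    def test_empty_input(self):
        with pytest.raises(EmptyInput):
            compute_rates([], T0)


class TestExcludeNodes:
    def test_identity_on_empty_set(self, simulated_records):
        records, _ = simulated_records
        kept, dropped = exclude_nodes(records, set())
        assert kept == list(records) and dropped == 0

    def test_counts(self):
        rows = [("A", f"a{i}#0", KPICategory.COMPLETED, 0) for i in range(5)]
        rows += [("B", f"b{i}#0", KPICategory.COMPLETED, 0) for i in range(7)]
        records, _ = records_from_events(make_fixture_log(rows))
        kept, dropped = exclude_nodes(records, {"A"})
        assert (len(kept), dropped) == (7, 5)

    def test_excluding_all_nodes_errors_downstream(self):
        rows = [("A", "a#0", KPICategory.COMPLETED, 0)]
        records, _ = records_from_events(make_fixture_log(rows))
        kept, _ = exclude_nodes(records, {"A"})
        with pytest.raises(EmptyInput):
            compute_rates(kept, T0)


class TestCompletionTiming:
    def test_floor_convention(self):
        records, _ = records_from_events(
            completed_record("N1", "q#0", T0, timedelta(days=4, hours=14))
        )
        stats = completion_time_stats(records)
        assert stats.median_days == 4
        assert stats.min_days == stats.max_days == 4

    def test_day_zero_completion(self):
        records, _ = records_from_events(
            completed_record("N1", "q#0", T0, timedelta(seconds=30))
        )
        assert completion_time_stats(records).median_days == 0

    def test_no_completions(self):
        records, _ = records_from_events(
            make_fixture_log([("N1", "q#0", KPICategory.UNANSWERED, None)])
        )
        with pytest.raises(NoCompletions):
            completion_time_stats(records)

    def test_matches_brute_force_recomputation(self, simulated_records):
        """Stats agree with an independent pass over raw timestamps."""
        records, _ = simulated_records
        completed = []
        rejected = []
        for record in records:
            t0 = record.history[0].timestamp
            for ev in record.history:
                if ev.to_state is QueryState.COMPLETED:
                    completed.append(
                        math.floor((ev.timestamp - t0).total_seconds() / 86400)
                    )
                    break
                if ev.to_state is QueryState.REJECTED:
                    rejected.append(
                        math.floor((ev.timestamp - t0).total_seconds() / 86400)
                    )
                    break
        assert len(completed) > 50
        stats = completion_time_stats(records)
        assert stats.n_completed == len(completed)
        assert stats.mean_days == pytest.approx(np.mean(completed))
        assert stats.sd_days == pytest.approx(np.std(completed, ddof=1))
        assert stats.median_days == pytest.approx(np.median(completed))
        assert (stats.min_days, stats.max_days) == (min(completed), max(completed))
        if rejected:
            assert stats.rejection_median_days == pytest.approx(np.median(rejected))


class TestKaplanMeier:
    def test_hand_worked_four_records(self):
        """Completions day 1 and 2, censorings day 1 and 3:
        S(1) = 1 - 1/4 = 0.75, S(2) = 0.75 * (1 - 1/2) = 0.375."""
        curve = KMCurve.from_durations([1, 2], [1, 3])
        assert curve.survival_at(1) == pytest.approx(0.75)
        assert curve.survival_at(2) == pytest.approx(0.375)
        assert curve.survival_at(0.5) == 1.0
        assert curve.at_risk.tolist() == [4, 2, 1]
        assert (curve.at_risk[:-1] - curve.events[:-1] - curve.censored[:-1]
                == curve.at_risk[1:]).all()

    def test_no_completions_flat_at_one(self):
        curve = KMCurve.from_durations([], [2, 5, 9])
        assert (curve.survival == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(8)
        days = rng.integers(0, 50, size=200).tolist()
        curve = KMCurve.from_durations(days, [])
        arr = np.asarray(days)
        for t in sorted(set(days)):
            assert curve.survival_at(t) == pytest.approx((arr > t).mean())

    def test_matches_lifelines(self):
        """Independent cross-check against lifelines on censored data."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(21)
        durations = rng.integers(0, 40, size=300)
        observed = rng.random(300) < 0.7
        curve = KMCurve.from_durations(
            durations[observed].tolist(), durations[~observed].tolist()
        )
        km = KaplanMeierFitter().fit(durations, observed)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(km.survival_function_at_times(t).iloc[0])
            )

    def test_survival_non_increasing(self):
        curve = KMCurve.from_durations([1, 1, 3, 7, 7, 20], [2, 5, 30])
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_late_censoring_never_decreases_survival(self):
        """Appending an observation censored after the last event only adds
        at-risk weight, so no S(t_i) can decrease."""
        base_events, base_cens = [1, 2, 5], [3]
        before = KMCurve.from_durations(base_events, base_cens)
        after = KMCurve.from_durations(base_events, base_cens + [50])
        for t in before.times:
            assert after.survival_at(t) >= before.survival_at(t) - 1e-12

    def test_km_from_records_censors_rejection_failure_and_open(self):
        rows = [
            ("N1", "c1#0", KPICategory.COMPLETED, 1),
            ("N1", "c2#0", KPICategory.COMPLETED, 2),
            ("N1", "r1#0", KPICategory.REJECTED, 1),
            ("N1", "u1#0", KPICategory.UNANSWERED, None),
        ]
        records, _ = records_from_events(make_fixture_log(rows, base=T0))
        cutoff = T0 + 3 * DAY
        curve = km_uncompleted(records, cutoff)
        # completions at 1 and 2; rejection censored at 1; open censored at 3
        assert curve.survival_at(1) == pytest.approx(0.75)
        assert curve.survival_at(2) == pytest.approx(0.375)

    def test_completion_after_cutoff_is_censored_at_cutoff(self):
        records, _ = records_from_events(
            completed_record("N1", "q#0", T0, timedelta(days=10))
        )
        curve = km_uncompleted(records, T0 + 4 * DAY)
        assert curve.events.sum() == 0
        assert curve.censored.tolist() == [1]
        assert curve.times.tolist() == [4]


class TestPerNodeCurves:
    def test_single_node_equals_pooled(self):
        rows = [("N1", f"q{i}#0", KPICategory.COMPLETED, i) for i in range(5)]
        records, _ = records_from_events(make_fixture_log(rows, base=T0))
        cutoff = T0 + 30 * DAY
        curves = per_node_curves(records, cutoff)
        pooled = km_uncompleted(records, cutoff)
        assert list(curves) == ["N1"]
        assert np.allclose(curves["N1"].survival, pooled.survival)

    def test_pooled_between_disjoint_nodes(self):
        fast = [("F", f"f{i}#0", KPICategory.COMPLETED, 1) for i in range(10)]
        slow = [("S", f"s{i}#0", KPICategory.COMPLETED, 20) for i in range(10)]
        records, _ = records_from_events(make_fixture_log(fast + slow, base=T0))
        cutoff = T0 + 40 * DAY
        curves = per_node_curves(records, cutoff)
        pooled = km_uncompleted(records, cutoff)
        for t in (1, 5, 20):
            lo = min(curves["F"].survival_at(t), curves["S"].survival_at(t))
            hi = max(curves["F"].survival_at(t), curves["S"].survival_at(t))
            assert lo <= pooled.survival_at(t) <= hi

    def test_all_censored_node_flat_at_one(self):
        rows = [("N1", f"q{i}#0", KPICategory.UNANSWERED, None) for i in range(3)]
        records, _ = records_from_events(make_fixture_log(rows, base=T0))
        curves = per_node_curves(records, T0 + 5 * DAY)
        assert (curves["N1"].survival == 1.0).all()


class TestYearlySummary:
    def test_attribution_by_retrieval_year_and_activity(self):
        t2019 = datetime(2019, 6, 1, tzinfo=timezone.utc)
        events = chain("N1", "a#0", (QueryState.RETRIEVED, t2019),
                       (QueryState.SEEN, t2019.replace(year=2021)))
        events += make_fixture_log(
            [("N2", "b#0", KPICategory.COMPLETED, 3)],
            base=datetime(2021, 3, 1, tzinfo=timezone.utc),
        )
        records, _ = records_from_events(events)
        summary = yearly_summary(records)
        assert summary[2019] == {"queries": 1, "active_nodes": 1}
        assert 2020 not in summary
        assert summary[2021] == {"queries": 1, "active_nodes": 2}

    def test_volumes_sum_to_total(self, simulated_records):
        records, _ = simulated_records
        summary = yearly_summary(records)
        assert sum(v["queries"] for v in summary.values()) == len(records)


class TestPercentile:
    def test_midpoint_interpolation(self):
        rows = [("N1", f"q{i}#0", KPICategory.COMPLETED, d)
                for i, d in enumerate([0, 2, 4, 100])]
        records, _ = records_from_events(make_fixture_log(rows, base=T0))
        assert percentile_time(records, 50) == pytest.approx(3.0)
        assert percentile_time(records, 100) == pytest.approx(100.0)

    def test_matches_sort_and_index_brute_force(self, simulated_records):
        records, _ = simulated_records
        days = sorted(
            math.floor((t - r.history[0].timestamp).total_seconds() / 86400)
            for r in records
            for t in [r.terminal_time()]
            if t is not None
        )
        assert len(days) > 300
        for q in (25, 50, 75, 90):
            h = (len(days) - 1) * q / 100
            lo, hi = math.floor(h), math.ceil(h)
            expected = days[lo] + (h - lo) * (days[hi] - days[lo])
            assert percentile_time(records, q) == pytest.approx(expected)


class TestPairedComparison:
    def build(self, per_node_days):
        rows = []
        for node, (ind_days, per_days) in per_node_days.items():
            for i, d in enumerate(ind_days):
                rows.append((node, f"i-{node}-{i}#0", KPICategory.COMPLETED, d))
            for i, d in enumerate(per_days):
                # two emissions mark the request as periodic
                rows.append((node, f"p-{node}-{i}#0", KPICategory.COMPLETED, d))
                rows.append((node, f"p-{node}-{i}#1", KPICategory.COMPLETED, d))
        records, _ = records_from_events(make_fixture_log(rows, base=T0))
        return records

    def test_identical_means_give_t_zero(self):
        records = self.build({"A": ([3], [3]), "B": ([5], [5])})
        out = paired_class_comparison(records)
        assert out["t"] == 0.0 and out["p"] == 1.0 and out["n_pairs"] == 2

    def test_constant_shift_degenerates_to_p_zero(self):
        records = self.build({"A": ([6], [3]), "B": ([8], [5]), "C": ([4], [1])})
        out = paired_class_comparison(records)
        assert math.isinf(out["t"]) and out["t"] > 0
        assert out["p"] == 0.0

    def test_matches_scipy_ttest_rel(self):
        from scipy import stats as sps

        per_node = {
            "A": ([10, 14], [2]), "B": ([3], [1, 5]), "C": ([20], [4]),
            "D": ([7, 9], [6]), "E": ([12], [0]),
        }
        records = self.build(per_node)
        out = paired_class_comparison(records)
        ind = [np.mean(v[0]) for v in per_node.values()]
        per = [np.mean([d for d in v[1] for _ in (0, 1)])
               for v in per_node.values()]
        expected = sps.ttest_rel(ind, per)
        assert out["n_pairs"] == 5
        assert out["t"] == pytest.approx(expected.statistic)
        assert out["p"] == pytest.approx(expected.pvalue)

    def test_insufficient_pairs(self):
        records = self.build({"A": ([3], [3])})
        with pytest.raises(InsufficientPairs):
            paired_class_comparison(records)


class TestClassSplit:
    def test_series_detected_by_multiple_emissions(self):
        rows = [
            ("N1", "R1#0", KPICategory.COMPLETED, 0),
            ("N1", "R2#0", KPICategory.COMPLETED, 0),
            ("N1", "R2#1", KPICategory.COMPLETED, 0),
        ]
        records, _ = records_from_events(make_fixture_log(rows, base=T0))
        classes = split_classes(records)
        assert {r.query.query_id for r in classes["individual"]} == {"R1#0"}
        assert len(classes["periodic"]) == 2
        assert len(classes["all"]) == 3

    def test_explicit_override(self):
        rows = [("N1", "R1#0", KPICategory.COMPLETED, 0)]
        records, _ = records_from_events(make_fixture_log(rows, base=T0))
        classes = split_classes(records, periodic_requests={"R1"})
        assert classes["individual"] == [] and len(classes["periodic"]) == 1
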