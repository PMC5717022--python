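import numpy as np
import pytest

from conftest import make_series
from gfstrack.core_io import ConfigurationError, FeatureSeries, GroundTruthTimeline
from gfstrack.highlights import (
    HighlightEvent,
    detect_excursions,
    event_vs_nonevent_test,
    grand_average,
    match_events,
    moving_average,
    resample_to_grid,
    subject_mean_variability,
    threshold_lines,
)
from oracles import mean_sd_two_pass, paired_t_direct


def _truth(mode_a=35.0, mode_b=85.0, n=5, duration=120.0):
    picks = []
    for r in range(n):
        picks.append((f"r{r}", "c", mode_a))
        picks.append((f"r{r}", "c", mode_b))
    return GroundTruthTimeline(picks=picks, bin_width=10.0, clip_duration=duration)


def _event(t, value=-1.0, width=2.0, polarity="below"):
    return HighlightEvent(
        start=t - width / 2, end=t + width / 2, polarity=polarity,
        extremum_time=t, extremum_value=value,
    )


class TestGrandAverage:
    def test_identical_series_unchanged(self, rng):
        s = make_series(rng.normal(size=50))
        out = grand_average([s, s, s])
        assert np.allclose(out.values, s.values)

    def test_opposite_series_cancel(self, rng):
        v = rng.normal(size=30)
        out = grand_average([make_series(v), make_series(-v)])
        assert np.allclose(out.values, 0.0)

    def test_pointwise_mean_oracle(self, rng):
        stack = rng.normal(size=(10, 40))
        series = [make_series(row, subject=f"s{i}") for i, row in enumerate(stack)]
        out = grand_average(series)
        assert np.max(np.abs(out.values - stack.mean(axis=0))) < 1e-12

    def test_gap_excluded_pointwise(self):
        a = make_series([1.0, np.nan, 3.0])
        b = make_series([3.0, 4.0, 5.0])
        out = grand_average([a, b])
        assert np.allclose(out.values, [2.0, 4.0, 4.0])

    def test_mismatched_grid_rejected(self, rng):
        a = make_series(rng.normal(size=10), dt=1.0)
        b = make_series(rng.normal(size=10), dt=2.0)
        with pytest.raises(ConfigurationError, match="grid"):
            grand_average([a, b])

    def test_resample_helper_aligns(self, rng):
        a = make_series(np.arange(10.0), dt=1.0)
        grid = np.arange(0.5, 8.5, 1.0)
        out = resample_to_grid(a, grid)
        assert np.allclose(out.values, grid)  # linear fn preserved


class TestMovingAverage:
    def test_constant_unchanged(self):
        s = make_series(np.full(30, 2.5))
        assert np.allclose(moving_average(s, 10).values, 2.5)

    def test_impulse_spreads_to_tenth(self):
        v = np.zeros(40)
        v[20] = 1.0
        out = moving_average(make_series(v), 10).values
        covered = slice(16, 26)  # windows of full length containing index 20
        assert np.allclose(out[covered], 0.1)
        assert np.allclose(out[:10], 0.0)

    def test_ramp_interior_unchanged(self):
        v = np.arange(50, dtype=float)
        out = moving_average(make_series(v), 10).values
        # centered boxcar of even length shifts an affine trend by half a step
        assert np.allclose(out[10:-10], v[10:-10] - 0.5)

    def test_output_length_and_edges_shrink(self):
        v = np.arange(20, dtype=float)
        out = moving_average(make_series(v), 10)
        assert len(out) == 20
        assert out.values[0] == pytest.approx(np.mean(v[:5]))

    def test_invalid_points_rejected(self):
        with pytest.raises(ConfigurationError):
            moving_average(make_series(np.zeros(5)), 0)


class TestThresholdLines:
    def test_arithmetic_example(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=400)
        v = 0.5 + 0.01 * (v - v.mean()) / v.std(ddof=1)
        upper, lower = threshold_lines(make_series(v), k=1.96)
        assert upper == pytest.approx(0.5196, abs=1e-9)
        assert lower == pytest.approx(0.4804, abs=1e-9)

    def test_k_zero_collapses_to_mean(self, rng):
        v = rng.normal(size=100)
        upper, lower = threshold_lines(make_series(v), k=0.0)
        assert upper == lower == pytest.approx(np.mean(v))

    def test_matches_two_pass_oracle(self, rng):
        v = rng.normal(2.0, 0.3, size=333)
        upper, lower = threshold_lines(make_series(v), k=1.96)
        m, sd = mean_sd_two_pass(v)
        assert upper == pytest.approx(m + 1.96 * sd, abs=1e-12)
        assert lower == pytest.approx(m - 1.96 * sd, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ConfigurationError):
            threshold_lines(make_series(np.full(10, 1.0)))


class TestDetectExcursions:
    def test_no_crossing_gives_empty(self, rng):
        s = make_series(rng.uniform(0.5, 0.6, size=50))
        assert detect_excursions(s, 0.4, "below") == []

    def test_rectangular_dip(self):
        v = np.full(60, 1.0)
        v[20:26] = -1.0  # 6-s dip at 1 Hz sampling
        events = detect_excursions(make_series(v), 0.0, "below", min_duration=2.0)
        assert len(events) == 1
        e = events[0]
        assert e.start == 20.0 and e.end == 26.0
        assert e.extremum_value == -1.0

    def test_merge_gap_controls_merging(self):
        v = np.full(60, 1.0)
        v[20:23] = -1.0
        v[24:27] = -1.0  # 1-s gap between dips
        s = make_series(v)
        merged = detect_excursions(s, 0.0, "below", min_duration=1.0, merge_gap=2.0)
        split = detect_excursions(s, 0.0, "below", min_duration=1.0, merge_gap=0.5)
        assert len(merged) == 1
        assert len(split) == 2

    def test_min_duration_drops_blips(self):
        v = np.full(60, 1.0)
        v[30] = -1.0
        assert detect_excursions(make_series(v), 0.0, "below", min_duration=2.0) == []

    def test_above_polarity(self):
        v = np.zeros(40)
        v[10:15] = 2.0
        events = detect_excursions(make_series(v), 1.0, "above", min_duration=1.0)
        assert len(events) == 1 and events[0].polarity == "above"

    def test_intervals_disjoint_ordered_extremum_violates(self, rng):
        v = rng.normal(size=300)
        events = detect_excursions(make_series(v), -1.0, "below",
                                   min_duration=1.0, merge_gap=2.0)
        assert events, "seeded series should produce excursions"
        for a, b in zip(events, events[1:]):
            assert a.end <= b.start
        for e in events:
            assert e.extremum_value < -1.0


class TestMatchEvents:
    def test_events_at_modes_all_hit(self):
        report = match_events([_event(35.0), _event(85.0)], _truth(), tolerance=10.0)
        assert (report.hits, report.misses, report.false_alarms) == (2, 0, 0)

    def test_no_events_all_missed(self):
        report = match_events([], _truth(), tolerance=10.0)
        assert (report.hits, report.misses, report.false_alarms) == (0, 2, 0)
        assert report.hits + report.misses == len(report.modes)

    def test_event_between_modes_matches_nearer(self):
        report = match_events([_event(78.0)], _truth(35.0, 85.0), tolerance=60.0)
        assert report.matches[0]["matched_mode"] == 85.0

    def test_equidistant_tie_breaks_to_earlier_mode(self):
        report = match_events([_event(60.0)], _truth(35.0, 85.0), tolerance=60.0)
        assert report.matches[0]["matched_mode"] == 35.0

    def test_far_event_is_false_alarm(self):
        report = match_events([_event(5.0)], _truth(), tolerance=10.0)
        assert (report.hits, report.misses, report.false_alarms) == (0, 2, 1)

    def test_empty_truth_rejected(self):
        with pytest.raises(ConfigurationError):
            match_events([_event(1.0)], GroundTruthTimeline(picks=[]), 5.0)


class TestEventVsNonEventTest:
    def _subjects(self, rows, dt=1.0):
        return [make_series(r, dt=dt, subject=f"s{i}") for i, r in enumerate(rows)]

    def test_identical_means_give_t0_p1(self):
        rows = [np.full(20, c) for c in (0.4, 0.5, 0.6)]
        res = event_vs_nonevent_test(self._subjects(rows), [_event(10.0, width=4.0)])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_difference_flags_degenerate(self):
        rows = []
        for c in (0.4, 0.5, 0.6):
            v = np.full(20, c)
            v[8:13] -= 0.1  # same in-event drop for everyone
            rows.append(v)
        res = event_vs_nonevent_test(self._subjects(rows), [_event(10.0, width=4.0)])
        assert res.degenerate and res.p == 0.0

    def test_matches_textbook_oracle(self, rng):
        rows = rng.normal(0.5, 0.05, size=(5, 40))
        for r in rows:
            r[10:16] -= rng.uniform(0.05, 0.15)
        subjects = self._subjects(rows)
        ev = [HighlightEvent(start=10.0, end=15.0, polarity="below",
                             extremum_time=12.0, extremum_value=0.0)]
        res = event_vs_nonevent_test(subjects, ev)
        ins = [np.mean(r[10:16]) for r in rows]
        outs = [np.mean(np.concatenate([r[:10], r[16:]])) for r in rows]
        t_ref, p_ref = paired_t_direct(ins, outs)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        assert res.df == 4

    def test_secondary_events_excluded_from_both_sets(self, rng):
        rows = rng.normal(size=(3, 40))
        subjects = self._subjects(rows)
        ev = [_event(10.0, width=4.0)]
        gray = [HighlightEvent(start=20.0, end=30.0, polarity="below",
                               extremum_time=25.0, extremum_value=0.0)]
        res = event_vs_nonevent_test(subjects, ev, secondary_events=gray)
        # non-event mean must ignore the gray interval entirely
        r = rows[0]
        t = subjects[0].times
        out_mask = ~(((t >= 8.0) & (t <= 12.0)) | ((t >= 20.0) & (t <= 30.0)))
        assert res.pairs[0][2] == pytest.approx(np.mean(r[out_mask]))

    def test_too_few_subjects_rejected(self, rng):
        subjects = self._subjects(rng.normal(size=(2, 20)))
        with pytest.raises(ConfigurationError):
            event_vs_nonevent_test(subjects, [_event(10.0)])

    def test_subject_without_in_event_samples_named(self, rng):
        subjects = self._subjects(rng.normal(size=(3, 20)))
        with pytest.raises(ConfigurationError, match="s0"):
            event_vs_nonevent_test(subjects, [_event(100.0)])


class TestSubjectMeanVariability:
    def test_constant_subjects(self):
        series = [make_series(np.full(10, 0.47), subject=f"s{i}") for i in range(4)]
        m, sd = subject_mean_variability(series)
        assert m == pytest.approx(0.47) and sd == 0.0

    def test_two_subject_closed_form(self):
        a, b = 0.4, 0.5
        series = [make_series(np.full(10, a)), make_series(np.full(10, b))]
        m, sd = subject_mean_variability(series)
        assert m == pytest.approx((a + b) / 2)
        assert sd == pytest.approx(abs(a - b) / np.sqrt(2))

    def test_matches_two_pass_oracle(self, rng):
        rows = rng.normal(0.5, 0.1, size=(10, 30))
        series = [make_series(r, subject=f"s{i}") for i, r in enumerate(rows)]
        m, sd = subject_mean_variability(series)
        m_ref, sd_ref = mean_sd_two_pass(rows.mean(axis=1))
        assert m == pytest.approx(m_ref, abs=1e-12)
        assert sd == pytest.approx(sd_ref, abs=1e-12)
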