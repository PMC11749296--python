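"""Episode detection, alarm-event matching and every reported metric."""

import numpy as np
import pytest
from conftest import make_trace
from oracles import brute_force_match, mae_loop, nearest_rank_quartiles

from pbhforecast.alarm_engine import AlarmRecord
from pbhforecast.evaluation import (
    MatchResult,
    detect_episodes,
    fp_per_day,
    glucometrics,
    mae,
    mage,
    match_alarms,
    precision_recall_f1,
    time_gain_summary,
)
from pbhforecast.forecasters import ForecastVector


def trace_with_dip(pre, dip, post, dip_value=48.0, base=100.0):
    vals = [base] * pre + [dip_value] * dip + [base] * post
    return make_trace(vals)


class TestDetectEpisodes:
    def test_five_samples_below_threshold_is_25_min_episode(self):
        eps = detect_episodes(trace_with_dip(10, 5, 10))
        assert len(eps) == 1
        assert eps[0].duration_min == 25
        assert (eps[0].onset, eps[0].end) == (10, 14)

    def test_ten_minutes_below_threshold_is_no_episode(self):
        assert detect_episodes(trace_with_dip(10, 2, 10)) == []

    def test_brief_rebound_merges_runs(self):
        vals = [100.0] * 5 + [48.0] * 3 + [60.0] + [48.0] * 3 + [100.0] * 5
        eps = detect_episodes(make_trace(vals))
        assert len(eps) == 1
        assert (eps[0].onset, eps[0].end) == (5, 11)

    def test_long_rebound_keeps_runs_separate(self):
        vals = [100.0] * 5 + [48.0] * 3 + [60.0] * 3 + [48.0] * 3 + [100.0] * 5
        eps = detect_episodes(make_trace(vals))
        assert len(eps) == 2

    def test_missing_samples_never_count_as_hypo(self):
        vals = [100.0] * 5 + [np.nan] * 5 + [100.0] * 5
        assert detect_episodes(make_trace(vals)) == []

    def test_invariant_to_normo_padding(self, rng):
        core = [48.0] * 4 + [100.0] * 10 + [48.0] * 5
        eps1 = detect_episodes(make_trace(core))
        eps2 = detect_episodes(make_trace([120.0] * 7 + core + [120.0] * 9))
        assert [(e.end - e.onset) for e in eps1] == [(e.end - e.onset) for e in eps2]
        assert [e.onset + 7 for e in eps1] == [e.onset for e in eps2]


class TestMatchAlarms:
    def alarm(self, t_min):
        return AlarmRecord(time=int(t_min // 5), predicted_value=40.0)

    def episode_at(self, onset_min, trace_len=400):
        vals = [100.0] * trace_len
        onset = int(onset_min // 5)
        for i in range(onset, onset + 5):
            vals[i] = 48.0
        return detect_episodes(make_trace(vals))

    def test_alarm_30_min_before_onset_is_tp(self):
        eps = self.episode_at(630)
        m = match_alarms([self.alarm(600)], eps)
        assert (m.tp_alarms, m.fp_alarms, m.fn_events) == (1, 0, 0)
        assert m.time_gains == [30.0]

    def test_alarm_50_min_before_onset_is_fp(self):
        eps = self.episode_at(650)
        m = match_alarms([self.alarm(600)], eps)
        assert (m.tp_alarms, m.fp_alarms) == (0, 1)
        assert m.fn_events == 1  # no alarm inside the event's pre-window

    def test_event_without_alarm_is_fn(self):
        m = match_alarms([], self.episode_at(630))
        assert m.fn_events == 1 and m.detected_events == 0

    def test_alarm_at_onset_does_not_count(self):
        # onset must lie strictly after the alarm: (s, s+45]
        eps = self.episode_at(600)
        m = match_alarms([self.alarm(600)], eps)
        assert m.tp_alarms == 0 and m.fn_events == 1

    def test_time_gain_uses_earliest_alarm_in_window(self):
        eps = self.episode_at(630)
        m = match_alarms([self.alarm(590), self.alarm(615)], eps)
        assert m.time_gains == [40.0]
        assert m.tp_alarms == 2

    def test_brute_force_oracle_on_random_instances(self, rng):
        """1000 random small instances against the exhaustive matcher."""
        for _ in range(1000):
            n_alarms = int(rng.integers(0, 11))
            n_events = int(rng.integers(0, 6))
            alarm_t = sorted(rng.choice(np.arange(0, 500) * 5.0, n_alarms, replace=False))
            onset_t = sorted(rng.choice(np.arange(0, 500) * 5.0, n_events, replace=False))
            alarms = [AlarmRecord(time=int(t // 5), predicted_value=0) for t in alarm_t]
            episodes = self_episodes(onset_t)
            m = match_alarms(alarms, episodes)
            tp, fp, fn, det, gains = brute_force_match(list(alarm_t), list(onset_t))
            assert (m.tp_alarms, m.fp_alarms, m.fn_events, m.detected_events) == (
                tp, fp, fn, det,
            )
            assert sorted(m.time_gains) == gains

    def test_labels_assigned_on_records(self):
        eps = self.episode_at(630)
        alarms = [self.alarm(600), self.alarm(100)]
        match_alarms(alarms, eps)
        labels = {a.time_min: a.label for a in alarms}
        assert labels[600.0] == "TP" and labels[100.0] == "FP"

    def test_every_time_gain_within_window(self, rng):
        for _ in range(50):
            alarm_t = sorted(rng.choice(np.arange(0, 300) * 5.0, 8, replace=False))
            onset_t = sorted(rng.choice(np.arange(0, 300) * 5.0, 4, replace=False))
            alarms = [AlarmRecord(time=int(t // 5), predicted_value=0) for t in alarm_t]
            m = match_alarms(alarms, self_episodes(onset_t))
            assert all(0 < g <= 45 for g in m.time_gains)


def self_episodes(onset_times_min):
    from pbhforecast.evaluation import HypoEpisode

    return [HypoEpisode(onset=int(o // 5), end=int(o // 5) + 4) for o in onset_times_min]


class TestMetrics:
    def test_published_operating_point_recomputes_to_its_f1(self):
        """A precision/recall pair of 64.38/84.43 has harmonic mean 73.06."""
        m = MatchResult(
            tp_alarms=6438, fp_alarms=10000 - 6438,
            detected_events=8443, fn_events=10000 - 8443,
        )
        prf = precision_recall_f1(m)
        assert prf.precision == pytest.approx(64.38)
        assert prf.recall == pytest.approx(84.43)
        assert round(prf.f1, 2) == 73.05  # 2PR/(P+R) = 73.0543

    def test_equal_precision_recall(self):
        m = MatchResult(tp_alarms=1, fp_alarms=1, detected_events=1, fn_events=1)
        prf = precision_recall_f1(m)
        assert (prf.precision, prf.recall, prf.f1) == (50.0, 50.0, 50.0)

    def test_zero_denominators_flagged(self):
        m = MatchResult(tp_alarms=0, fp_alarms=0, detected_events=0, fn_events=0)
        prf = precision_recall_f1(m)
        assert prf == (0.0, 0.0, 0.0, True)

    def test_f1_bounded_by_arithmetic_mean(self, rng):
        for _ in range(200):
            m = MatchResult(
                tp_alarms=int(rng.integers(0, 50)),
                fp_alarms=int(rng.integers(0, 50)),
                detected_events=int(rng.integers(0, 50)),
                fn_events=int(rng.integers(0, 50)),
            )
            prf = precision_recall_f1(m)
            assert 0 <= prf.f1 <= 100
            assert prf.f1 <= (prf.precision + prf.recall) / 2 + 1e-12

    def test_fp_per_day(self):
        m = MatchResult(1, 1, 0, 0, monitored_days=6.0)
        assert fp_per_day(m) == pytest.approx(1 / 6, abs=1e-4)
        m0 = MatchResult(1, 0, 0, 0, monitored_days=6.0)
        assert fp_per_day(m0) == 0.0
        with pytest.raises(ValueError):
            fp_per_day(MatchResult(0, 0, 0, 0))

    def test_fp_rate_of_0p17_means_one_alarm_every_6_days(self):
        m = MatchResult(tp_alarms=0, fp_alarms=17, detected_events=0,
                        fn_events=0, monitored_days=100.0)
        assert round(1.0 / fp_per_day(m)) == 6


class TestTimeGain:
    def test_median_and_quartiles_nearest_rank(self):
        m = MatchResult(3, 0, 0, 3, time_gains=[5.0, 10.0, 15.0])
        tg = time_gain_summary(m)
        assert (tg.median, tg.q25, tg.q75) == (10.0, 5.0, 15.0)

    def test_single_gain(self):
        tg = time_gain_summary(MatchResult(1, 0, 0, 1, time_gains=[20.0]))
        assert (tg.median, tg.q25, tg.q75) == (20.0, 20.0, 20.0)

    def test_empty_is_undefined_not_zero(self):
        assert time_gain_summary(MatchResult(0, 1, 1, 0)) is None

    def test_random_multiset_matches_sort_oracle(self, rng):
        for _ in range(100):
            gains = list(rng.choice(np.arange(1, 10) * 5.0, int(rng.integers(1, 12))))
            tg = time_gain_summary(MatchResult(0, 0, 0, 0, time_gains=gains))
            q25, med, q75 = nearest_rank_quartiles(gains)
            assert (tg.q25, tg.median, tg.q75) == (q25, med, q75)


class TestMAE:
    def forecasts_for(self, vals, offset=0.0):
        return [
            ForecastVector(origin_index=t, predicted=vals[t + 1 : t + 7] + offset)
            for t in range(len(vals) - 6)
        ]

    def test_perfect_forecasts_give_zero(self, glucose_series):
        trace = make_trace(glucose_series)
        assert mae(trace, self.forecasts_for(glucose_series), 25) == 0.0

    def test_constant_offset_gives_that_offset(self, glucose_series):
        trace = make_trace(glucose_series)
        fcs = self.forecasts_for(glucose_series, offset=7.5)
        for ph in (15, 20, 25, 30):
            assert mae(trace, fcs, ph) == pytest.approx(7.5)

    def test_matches_loop_oracle_and_skips_missing_targets(self, rng):
        vals = rng.uniform(60, 200, 120)
        fcs = [
            ForecastVector(origin_index=t, predicted=rng.uniform(60, 200, 6))
            for t in range(114)
        ]
        vals_missing = vals.copy()
        vals_missing[[30, 31, 60]] = np.nan
        trace = make_trace(vals_missing)
        assert mae(trace, fcs, 25) == pytest.approx(
            mae_loop(vals_missing, fcs, 25), abs=1e-12
        )

    def test_no_valid_origins_is_an_error(self):
        trace = make_trace([100.0] * 10)
        with pytest.raises(ValueError):
            mae(trace, [], 25)


class TestGlucometrics:
    def test_constant_trace(self):
        g = glucometrics(make_trace(np.full(300, 100.0)))
        assert (g.sd, g.mage) == (0.0, 0.0)
        assert g.pct_in_70_180 == 100.0
        assert g.n_episodes == 0

    def test_square_wave_mage(self):
        vals = np.tile([80.0] * 6 + [160.0] * 6, 30)
        g = glucometrics(make_trace(vals))
        assert g.mean == pytest.approx(120.0)
        assert g.pct_in_70_180 == 100.0
        assert g.mage == pytest.approx(80.0)  # amplitude 80 > SD ~40

    def test_small_wiggles_do_not_count_toward_mage(self):
        # one large excursion, many sub-SD wiggles
        base = np.tile([100.0, 102.0], 200)
        base[100:110] = [100, 130, 160, 190, 160, 130, 100, 102, 100, 102]
        assert mage(base) > 50

    def test_needs_a_day_of_data(self):
        with pytest.raises(ValueError):
            glucometrics(make_trace([100.0] * 100))

    def test_time_in_ranges_partition(self, rng):
        vals = rng.uniform(45, 350, 400)
        g = glucometrics(make_trace(vals))
        assert g.pct_below_70 + g.pct_in_70_180 + g.pct_above_180 == pytest.approx(100.0)
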