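"""Night-window assignment, nightly/volunteer aggregation, circular clock mean."""

from datetime import date, datetime, time, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from somnocohort.ingest import SleepSession, parse_sleep_log
from somnocohort.sleep import (
    assign_sessions_to_nights,
    circular_clock_mean,
    derive_cohort_summary,
    summarize_night,
    summarize_volunteer,
)


def _session(start, asleep, in_bed=None, wakes=0, vid="v1"):
    in_bed = in_bed or asleep
    return SleepSession(vid, start, start + timedelta(minutes=in_bed),
                        asleep, in_bed, wakes)


class TestNightAssignment:
    @pytest.mark.parametrize(
        "start,expected_night",
        [
            (datetime(2016, 1, 1, 23, 30), date(2016, 1, 1)),
            (datetime(2016, 1, 2, 2, 15), date(2016, 1, 1)),   # spans midnight
            (datetime(2016, 1, 1, 20, 0), date(2016, 1, 1)),   # window opens at 20:00
            (datetime(2016, 1, 2, 7, 59), date(2016, 1, 1)),
        ],
    )
    def test_window_membership(self, start, expected_night):
        by_night, naps = assign_sessions_to_nights([_session(start, 300)])
        assert list(by_night) == [expected_night] and not naps

    @pytest.mark.parametrize(
        "start",
        [datetime(2016, 1, 1, 14, 0),   # afternoon nap
         datetime(2016, 1, 1, 8, 0),    # half-open: exactly 08:00 excluded
         datetime(2016, 1, 1, 19, 59)],
    )
    def test_naps_unassigned(self, start):
        by_night, naps = assign_sessions_to_nights([_session(start, 60)])
        assert not by_night and len(naps) == 1


class TestSummarizeNight:
    def test_sum_and_unweighted_mean(self):
        s1 = _session(datetime(2016, 1, 1, 22, 0), 300, in_bed=int(300 / 0.95), wakes=1)
        s2 = _session(datetime(2016, 1, 2, 4, 0), 120, in_bed=int(round(120 / 0.85)),
                      wakes=2)
        night = summarize_night(date(2016, 1, 1), [s1, s2])
        assert night.tst_minutes == 420
        assert night.se_pct == pytest.approx((s1.efficiency_pct + s2.efficiency_pct) / 2)
        assert night.awakenings == 3 and night.n_sessions == 2

    def test_single_session_identity(self):
        s = _session(datetime(2016, 1, 1, 23, 0), 388, in_bed=419, wakes=2)
        night = summarize_night(date(2016, 1, 1), [s])
        assert night.tst_minutes == 388
        assert night.se_pct == pytest.approx(100 * 388 / 419)
        assert night.awakenings == 2

    def test_zero_wakes(self):
        ss = [_session(datetime(2016, 1, 1, 21, i), 30) for i in range(3)]
        assert summarize_night(date(2016, 1, 1), ss).awakenings == 0

    def test_empty_night_rejected(self):
        with pytest.raises(ValueError):
            summarize_night(date(2016, 1, 1), [])


def _oracle_minutes_after(origin: time, t: time) -> int:
    """Brute-force: step forward minute by minute from the origin until t."""
    cur = datetime(2000, 1, 1, origin.hour, origin.minute)
    for k in range(1440):
        if cur.time() == t:
            return k
        cur += timedelta(minutes=1)
    raise AssertionError("unreachable")


def _oracle_mean(times, origin=time(20, 0)) -> time:
    offsets = [_oracle_minutes_after(origin, t) for t in times]
    mean = round(sum(offsets) / len(offsets))
    out = datetime(2000, 1, 1, origin.hour, origin.minute) + timedelta(minutes=mean)
    return out.time()


class TestCircularClockMean:
    def test_midnight_spanning_pair(self):
        # 23:00 and 01:00 are 180 and 300 min past 20:00; mean 240 -> 00:00
        assert circular_clock_mean([time(23, 0), time(1, 0)]) == time(0, 0)
        assert _oracle_mean([time(23, 0), time(1, 0)]) == time(0, 0)

    def test_identity_and_ties(self):
        assert circular_clock_mean([time(22, 0)]) == time(22, 0)
        assert circular_clock_mean([time(20, 0), time(20, 0)]) == time(20, 0)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no times"):
            circular_clock_mean([])

    @given(st.integers(0, 143), st.integers(0, 143))
    def test_agrees_with_brute_force_on_10min_grid(self, i, j):
        """All 2-element pairs on a 10-minute grid across the 24-h window."""
        t1 = time((20 + (i * 10) // 60) % 24, (i * 10) % 60)
        t2 = time((20 + (j * 10) // 60) % 24, (j * 10) % 60)
        assert circular_clock_mean([t1, t2]) == _oracle_mean([t1, t2])


class TestSummarizeVolunteer:
    def test_tst_mean_in_hours(self):
        nights = [
            summarize_night(date(2016, 1, d), [_session(datetime(2016, 1, d, 23, 0), m)])
            for d, m in [(1, 360), (2, 480)]
        ]
        summ = summarize_volunteer(nights, [])
        assert summ.tst_hours == pytest.approx(7.0)

    def test_short_session_counts_in_tst_but_not_sleep_hour(self):
        long_s = _session(datetime(2016, 1, 1, 23, 30), 420)
        short_s = _session(datetime(2016, 1, 2, 22, 0), 120)  # 2 h: TST only
        nights = [
            summarize_night(date(2016, 1, 1), [long_s]),
            summarize_night(date(2016, 1, 2), [short_s]),
        ]
        summ = summarize_volunteer(nights, [long_s, short_s])
        assert summ.tst_hours == pytest.approx((420 + 120) / 2 / 60)
        assert summ.sleep_hour == time(23, 30)  # short session excluded

    def test_single_night_identity(self):
        s = _session(datetime(2016, 1, 1, 23, 30), 420)
        night = summarize_night(date(2016, 1, 1), [s])
        summ = summarize_volunteer([night], [s])
        assert summ.sleep_hour == time(23, 30)
        assert summ.wake_hour == time(6, 30)

    def test_no_long_session_flags_missing_hours(self):
        s = _session(datetime(2016, 1, 1, 23, 0), 100)
        summ = summarize_volunteer([summarize_night(date(2016, 1, 1), [s])], [s])
        assert summ.sleep_hour is None and summ.wake_hour is None


def test_tst_conservation_and_nap_exclusion(small_bundle):
    """Sum of nightly TST equals sum of assigned session minutes; nap minutes
    never enter TST."""
    for vid in list(small_bundle.sleep_json)[:20]:
        sessions = list(parse_sleep_log(small_bundle.sleep_json[vid], vid))
        by_night, naps = assign_sessions_to_nights(sessions)
        nightly = [summarize_night(d, by_night[d]) for d in by_night]
        assigned_total = sum(s.minutes_asleep for ss in by_night.values() for s in ss)
        assert sum(n.tst_minutes for n in nightly) == assigned_total
        total = sum(s.minutes_asleep for s in sessions)
        assert assigned_total == total - sum(n.minutes_asleep for n in naps)


def test_se_normalization_bound(small_bundle):
    """Volunteer SE lies in [0, 100]; perfect-efficiency sessions give 100."""
    summary = derive_cohort_summary(
        {vid: list(parse_sleep_log(small_bundle.sleep_json[vid], vid))
         for vid in list(small_bundle.sleep_json)[:20]}
    )
    assert summary["se_pct"].between(0, 100).all()

    perfect = [_session(datetime(2016, 1, d, 23, 0), 400, in_bed=400)
               for d in (1, 2, 3)]
    summary = derive_cohort_summary({"v1": perfect})
    assert summary["se_pct"].iloc[0] == pytest.approx(100.0)
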