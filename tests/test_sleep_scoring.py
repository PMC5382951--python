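"""Epoch scoring, modal aggregation, episodes, onset/offset, no-sleep rule."""

from datetime import date, datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tuskrest import sleep_scoring as ss
from tuskrest.timebase_io import AnalysisNight

from conftest import minute_series


class TestScoreEpochs:
    def test_any_count_above_zero_is_active(self):
        active = ss.score_epochs(minute_series("2014-04-14 12:00", [0, 3, 0]))
        assert list(active) == [False, True, False]

    def test_all_zero_is_all_inactive(self):
        active = ss.score_epochs(minute_series("2014-04-14 12:00", [0] * 10))
        assert not active.any()

    def test_threshold_is_strict(self):
        active = ss.score_epochs(minute_series("2014-04-14 12:00", [3, 6]),
                                 active_threshold=5)
        assert list(active) == [False, True]

    def test_wrong_cadence_rejected(self):
        df = minute_series("2014-04-14 12:00", [1, 2, 3])
        df.loc[2, "timestamp"] += pd.Timedelta(seconds=30)
        with pytest.raises(ValueError, match="cadence"):
            ss.score_epochs(df)


class TestAggregateModal:
    def _blocks(self, pattern):  # pattern: 1 = active minute
        active = ss.score_epochs(minute_series("2014-04-14 12:00", pattern))
        return ss.aggregate_modal(active)

    def test_four_of_five_inactive_is_inactive(self):
        blocks = self._blocks([0, 0, 0, 7, 0])
        assert list(blocks) == [True]

    def test_three_of_five_active_is_active(self):
        blocks = self._blocks([4, 2, 9, 0, 0])
        assert list(blocks) == [False]

    def test_even_block_length_rejected(self):
        active = ss.score_epochs(minute_series("2014-04-14 12:00", [0] * 10))
        with pytest.raises(ValueError, match="odd"):
            ss.aggregate_modal(active, block_min=4)

    def test_partial_blocks_discarded_and_clock_aligned(self):
        # starts at 12:03 -> first two minutes belong to a partial block
        active = ss.score_epochs(minute_series("2014-04-14 12:03", [0] * 12))
        blocks = ss.aggregate_modal(active)
        assert list(blocks.index) == [pd.Timestamp("2014-04-14 12:05"),
                                      pd.Timestamp("2014-04-14 12:10")]

    @given(st.lists(st.integers(0, 3), min_size=600, max_size=600))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_per_block_majority_oracle(self, counts):
        active = ss.score_epochs(minute_series("2014-04-14 12:00", counts))
        blocks = ss.aggregate_modal(active)
        arr = np.asarray(counts) == 0
        expected = [arr[i:i + 5].sum() > 2 for i in range(0, 600, 5)]
        assert list(blocks) == expected


def plant_blocks(night, segments):
    """Boolean block series over a night; segments are (clock, n_blocks) sleep runs."""
    idx = pd.date_range(night.window_start, night.window_end, freq="5min",
                        inclusive="left")
    s = pd.Series(False, index=idx, name="inactive")
    for clock, n in segments:
        start = night.clock_datetime(clock)
        for i in range(n):
            s[start + pd.Timedelta(minutes=5 * i)] = True
    return s


class TestEpisodes:
    def test_maximal_runs_with_earliest_longest_main(self, night):
        blocks = plant_blocks(night, [("01:00", 2), ("02:00", 1), ("03:00", 2)])
        eps = ss.detect_episodes(blocks, night)
        assert [(e.duration_min, e.is_main) for e in eps] == [
            (10.0, True), (5.0, False), (10.0, False)]

    def test_all_active_gives_no_episodes(self, night):
        assert ss.detect_episodes(plant_blocks(night, []), night) == []

    def test_planted_edges_recovered_exactly(self, night):
        blocks = plant_blocks(night, [("22:30", 4)])
        (ep,) = ss.detect_episodes(blocks, night)
        assert ep.start == datetime(2014, 4, 14, 22, 30)
        assert ep.end == datetime(2014, 4, 14, 22, 50)


class TestOnsetOffset:
    def test_onset_skips_unconsolidated_episodes(self, night, astro_lookup):
        # 10 min does not exceed 10 min; the 25-min episode qualifies
        blocks = plant_blocks(night, [("20:00", 2), ("23:00", 5)])
        eps = ss.detect_episodes(blocks, night)
        onset = ss.detect_onset(eps, astro_lookup, night)
        assert onset == datetime(2014, 4, 14, 23, 0)

    def test_offset_is_last_consolidated_end_before_sunrise(self, night, astro_lookup):
        blocks = plant_blocks(night, [("02:00", 4), ("04:40", 4), ("06:25", 3)])
        eps = ss.detect_episodes(blocks, night)
        # the 06:25 episode ends after the 06:30 sunrise and cannot qualify
        assert ss.detect_offset(eps, astro_lookup, night) == datetime(2014, 4, 15, 5, 0)

    def test_no_consolidated_episode_is_undefined(self, night, astro_lookup):
        blocks = plant_blocks(night, [("01:00", 2)])
        eps = ss.detect_episodes(blocks, night)
        assert ss.detect_onset(eps, astro_lookup, night) is None
        assert ss.detect_offset(eps, astro_lookup, night) is None

    def test_onset_never_precedes_sunset(self, night, astro_lookup):
        # afternoon nap before sunset must not become the onset
        blocks = plant_blocks(night, [("14:00", 4), ("22:00", 4)])
        eps = ss.detect_episodes(blocks, night)
        assert ss.detect_onset(eps, astro_lookup, night) == datetime(2014, 4, 14, 22, 0)


class TestNoSleep:
    def test_two_isolated_blocks_count_as_no_sleep(self, night):
        assert ss.classify_no_sleep(plant_blocks(night, [("18:30", 1), ("03:00", 1)]),
                                    night)

    def test_zero_inactivity_is_no_sleep(self, night):
        assert ss.classify_no_sleep(plant_blocks(night, []), night)

    def test_normal_sleep_is_not_no_sleep(self, night):
        blocks = plant_blocks(night, [("01:00", 40)])  # 3.3 h
        assert not ss.classify_no_sleep(blocks, night)


class TestSummaryProperties:
    def test_tst_equals_sum_of_episode_durations(self, night, astro_lookup):
        blocks = plant_blocks(night, [("22:00", 3), ("01:00", 8), ("04:00", 2)])
        eps = ss.detect_episodes(blocks, night)
        summary = ss.night_summary(eps, astro_lookup, night)
        assert summary.tst_h * 60 == pytest.approx(sum(e.duration_min for e in eps))
        assert summary.n_episodes == 3

    def test_raising_threshold_never_decreases_tst(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 6, 1440)
        df = minute_series("2014-04-14 12:00", counts)
        night = AnalysisNight(date(2014, 4, 15))
        tsts = []
        for thr in (0, 1, 2, 4):
            blocks = ss.aggregate_modal(ss.score_epochs(df, thr))
            eps = ss.detect_episodes(blocks, night)
            tsts.append(sum(e.duration_min for e in eps))
        assert tsts == sorted(tsts)

    def test_nocturnality_of_fully_nocturnal_sleep_is_one(self, night, astro_lookup):
        blocks = plant_blocks(night, [("22:00", 6), ("03:00", 6)])
        assert ss.nocturnality(blocks, astro_lookup, [night]) == 1.0

    def test_nocturnality_counts_day_blocks(self, night, astro_lookup):
        # 19 nocturnal + 1 diurnal block = 0.95
        blocks = plant_blocks(night, [("23:00", 19), ("10:00", 1)])
        frac = ss.nocturnality(blocks, astro_lookup, [night])
        assert frac == pytest.approx(0.95)
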