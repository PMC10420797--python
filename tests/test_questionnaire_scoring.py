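"""Unit and property tests for the instrument scorers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chronodiet.questionnaire_scoring import (
    MctqConfig,
    PsqiResponse,
    SleepScheduleRaw,
    bmi_percentile_from_arrays,
    load_lms_reference,
    score_anthropometrics,
    score_mctq,
    score_psqi,
    score_zsds,
    zsds_level_from_index,
)

# ---------------------------------------------------------------- MCTQ


class TestMctq:
    def test_identical_schedules_have_zero_social_jetlag(self):
        m = score_mctq(SleepScheduleRaw(23.0, 7.0, 23.0, 7.0, 2))
        assert m.sld == 8.0
        assert m.sjl == 0.0
        assert m.msf == m.msf_sc == 3.0

    def test_weekly_duration_is_free_day_weighted_mean(self):
        # SlD_W = 7 h, SlD_F = 9 h, FD = 2 -> (7*5 + 9*2)/7
        m = score_mctq(SleepScheduleRaw(24.0, 7.0, 25.0, 10.0, 2))
        assert m.sld == pytest.approx((7 * 5 + 9 * 2) / 7)

    def test_hand_worked_after_midnight_schedule(self):
        # MSW = 3.5, MSF = 5.5 -> SJL = 2; corrected chronotype
        # 5.5 - 0.5*(9 - 7.5714) = 4.7857
        m = score_mctq(SleepScheduleRaw(24.0, 7.0, 25.0, 10.0, 2))
        assert m.sjl == pytest.approx(2.0)
        assert m.msf_sc == pytest.approx(5.5 - 0.5 * (9 - (7 * 5 + 9 * 2) / 7))

    def test_sleep_debt_correction_requires_longer_free_sleep_and_no_alarm(self):
        short_free = SleepScheduleRaw(23.0, 7.0, 25.0, 31.0, 2)  # SlD_F 6 < 8
        assert score_mctq(short_free).msf_sc == score_mctq(short_free).msf
        alarm = SleepScheduleRaw(24.0, 7.0, 25.0, 10.0, 2, alarm_free_days=True)
        assert score_mctq(alarm).msf_sc == score_mctq(alarm).msf
        cfg = MctqConfig(msfsc_correction="unconditional")
        assert score_mctq(alarm, cfg).msf_sc < score_mctq(alarm).msf

    def test_sleep_efficiency_formula_switch(self):
        s = SleepScheduleRaw(23.0, 7.0, 23.0, 7.0, 2,
                             time_in_bed_work=9.0, time_in_bed_free=9.0)
        assert score_mctq(s).sle == pytest.approx(8 / 9 * 100)
        printed = MctqConfig(sle_formula="as_printed")
        assert score_mctq(s, printed).sle == pytest.approx(9 / 8 * 100)

    def test_signed_vs_absolute_social_jetlag(self):
        advanced = SleepScheduleRaw(24.0, 8.0, 22.0, 6.0, 2)  # earlier free sleep
        assert score_mctq(advanced).sjl == pytest.approx(-2.0)
        assert score_mctq(
            advanced, MctqConfig(sjl_absolute=True)
        ).sjl == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(onset_work=23.0, wake_work=7.0, onset_free=23.0,
                  wake_free=7.0, free_days_per_week=9), "0..7"),
            (dict(onset_work=50.0, wake_work=7.0, onset_free=23.0,
                  wake_free=7.0, free_days_per_week=2), r"\[0, 48\)"),
        ],
    )
    def test_invalid_schedules_are_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            score_mctq(SleepScheduleRaw(**kwargs))

    @given(
        onset=st.floats(20.0, 27.0),
        dur=st.floats(4.0, 11.0),
        fd=st.integers(0, 7),
    )
    @settings(max_examples=100, deadline=None)
    def test_identical_work_free_schedule_implies_sjl_zero(self, onset, dur, fd):
        m = score_mctq(
            SleepScheduleRaw(onset, (onset + dur) % 24, onset,
                             (onset + dur) % 24, fd)
        )
        assert m.sjl == pytest.approx(0.0, abs=1e-9)
        assert m.msf_sc == pytest.approx(m.msf)

    @given(
        dw=st.floats(4.0, 11.0), df=st.floats(4.0, 11.0), fd=st.integers(0, 7)
    )
    @settings(max_examples=100, deadline=None)
    def test_weekly_duration_lies_between_day_type_durations(self, dw, df, fd):
        m = score_mctq(SleepScheduleRaw(23.0, (23 + dw) % 24, 23.0,
                                        (23 + df) % 24, fd))
        lo, hi = min(dw, df), max(dw, df)
        assert lo - 1e-9 <= m.sld <= hi + 1e-9
        if fd == 0:
            assert m.sld == pytest.approx(dw)
        if fd == 7:
            assert m.sld == pytest.approx(df)


# ---------------------------------------------------------------- PSQI

_BEST = dict(bedtime=23.0, latency_minutes=5.0, wake_time=7.0,
             hours_slept=7.5, trouble_30min=0, disturbances=[0] * 9,
             quality=0, medication=0, daytime_sleepy=0, daytime_enthusiasm=0)
_WORST = dict(bedtime=23.0, latency_minutes=90.0, wake_time=9.0,
              hours_slept=4.0, trouble_30min=3, disturbances=[3] * 9,
              quality=3, medication=3, daytime_sleepy=3, daytime_enthusiasm=3)


class TestPsqi:
    def test_best_answers_score_zero(self):
        s = score_psqi(PsqiResponse(**_BEST))
        assert s.global_score == 0 and s.quality_flag == 0

    def test_worst_answers_score_twentyone(self):
        s = score_psqi(PsqiResponse(**_WORST))
        assert s.components == (3,) * 7
        assert s.global_score == 21 and s.quality_flag == 1

    def test_hand_scored_fixture_components(self):
        # quality 1; latency 20 min -> 1; 6.5 h slept -> 1; 6.5 h of a
        # 6.5 h time in bed -> efficiency 100% -> 0; one mild disturbance
        # -> 1; no medication -> 0; daytime sum 1 -> 1
        resp = PsqiResponse(
            bedtime=23.0, latency_minutes=20.0, wake_time=5.5,
            hours_slept=6.5, trouble_30min=0,
            disturbances=[1, 0, 0, 0, 0, 0, 0, 0, 0],
            quality=1, medication=0, daytime_sleepy=1, daytime_enthusiasm=0,
        )
        s = score_psqi(resp)
        assert s.components == (1, 1, 1, 0, 1, 0, 1)
        assert s.global_score == 5
        assert s.quality_flag == 0  # 5 is still good-quality sleep

    def test_global_equals_component_sum_on_random_fixtures(self, rng):
        for _ in range(50):
            resp = PsqiResponse(
                bedtime=float(rng.uniform(21, 26)),
                latency_minutes=float(rng.uniform(0, 120)),
                wake_time=float(rng.uniform(5, 11)),
                hours_slept=float(rng.uniform(3, 10)),
                trouble_30min=int(rng.integers(0, 4)),
                disturbances=rng.integers(0, 4, 9).tolist(),
                quality=int(rng.integers(0, 4)),
                medication=int(rng.integers(0, 4)),
                daytime_sleepy=int(rng.integers(0, 4)),
                daytime_enthusiasm=int(rng.integers(0, 4)),
            )
            s = score_psqi(resp)
            assert s.global_score == sum(s.components)
            assert 0 <= s.global_score <= 21
            assert s.quality_flag == int(s.global_score > 5)

    def test_out_of_range_item_is_rejected(self):
        bad = dict(_BEST, quality=4)
        with pytest.raises(ValueError, match="quality"):
            score_psqi(PsqiResponse(**bad))


# ---------------------------------------------------------------- ZSDS

_REVERSE = (2, 5, 6, 11, 12, 14, 16, 17, 18, 20)


def _answers_for_keyed(keyed_value: int) -> list[int]:
    """Answers giving the same keyed score on every item."""
    return [
        5 - keyed_value if i + 1 in _REVERSE else keyed_value
        for i in range(20)
    ]


class TestZsds:
    def test_minimum_raw_maps_to_index_25(self):
        s = score_zsds(_answers_for_keyed(1))
        assert s.raw == 20 and s.index == 25.0 and s.level == 1

    def test_maximum_raw_maps_to_index_100(self):
        s = score_zsds(_answers_for_keyed(4))
        assert s.raw == 80 and s.index == 100.0 and s.level == 4

    def test_raw_48_sits_on_moderate_band_edge(self):
        items = _answers_for_keyed(2)  # raw 40
        # push eight straight items up by one keyed point -> raw 48
        straight = [i for i in range(20) if i + 1 not in _REVERSE]
        for i in straight[:8]:
            items[i] += 1
        s = score_zsds(items)
        assert s.raw == 48
        assert s.index == 60.0
        assert s.level == 3 and s.level_flag == 1

    def test_band_edges_follow_printed_levels(self):
        # 50 -> I, 51.25 -> II, 58.75 -> II, 60 -> III, 68.75 -> III, 70 -> IV
        assert list(zsds_level_from_index([50, 51.25, 58.75, 60, 68.75, 70])) \
            == [1, 2, 2, 3, 3, 4]

    def test_index_strictly_increasing_in_raw(self):
        indices = [score_zsds(_answers_for_keyed(1)[:k] +
                              _answers_for_keyed(2)[k:]).index
                   for k in range(21)]
        # swapping straight/reverse mix keeps monotonicity in the raw sum
        raws = [score_zsds(_answers_for_keyed(1)[:k] +
                           _answers_for_keyed(2)[k:]).raw for k in range(21)]
        order = np.argsort(raws)
        assert np.all(np.diff(np.array(indices)[order]) >= 0)

    def test_wrong_item_count_and_codes_rejected(self):
        with pytest.raises(ValueError, match="20 items"):
            score_zsds([1] * 19)
        with pytest.raises(ValueError, match="1..4"):
            score_zsds([0] + [1] * 19)


# ------------------------------------------------------- anthropometrics


class TestAnthropometrics:
    def test_bmi_arithmetic(self):
        a = score_anthropometrics(1.80, 64.8, 80.0, 18.0, "male")
        assert a.bmi == pytest.approx(20.0)

    def test_whtr_half_flags_central_adiposity(self):
        a = score_anthropometrics(1.80, 64.8, 90.0, 18.0, "male")
        assert a.whtr == pytest.approx(0.5)
        assert a.central_adiposity_flag == 1
        assert a.whtr_category == 3

    def test_bmi_at_reference_median_gives_percentile_50(self):
        ref = load_lms_reference()
        row = ref[(ref.sex == 1) & (ref.age_months == 216)].iloc[0]
        pct = bmi_percentile_from_arrays([row.M], [18.0], [1], ref)
        assert pct[0] == pytest.approx(50.0, abs=1e-9)

    def test_percentile_monotone_in_bmi(self):
        ref = load_lms_reference()
        bmis = np.linspace(15, 35, 30)
        pct = bmi_percentile_from_arrays(bmis, [20.0] * 30, [2] * 30, ref)
        assert np.all(np.diff(pct) > 0)

    def test_adult_ages_use_oldest_reference_column(self):
        ref = load_lms_reference()
        p24 = bmi_percentile_from_arrays([21.0], [24.0], [1], ref)[0]
        p19 = bmi_percentile_from_arrays([21.0], [19.0], [1], ref)[0]
        assert p24 == pytest.approx(p19)

    def test_age_below_coverage_raises(self):
        ref = load_lms_reference()
        with pytest.raises(ValueError, match="coverage"):
            bmi_percentile_from_arrays([20.0], [10.0], [1], ref)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            score_anthropometrics(1.80, -64.8, 80.0, 18.0, "male")
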