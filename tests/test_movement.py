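"""ENMO classification, valid-day filtering and exclusion-flow accounting."""

import numpy as np
import pandas as pd
import pytest

from coda24.coda import ZeroPartError
from coda24.movement import (
    DaySummary,
    EpochRecord,
    InclusionFlow,
    IntensityClass,
    classify_epoch,
    classify_epochs,
    filter_valid,
    inclusion_flow,
    multiplicative_replacement,
    participant_composition,
    summarise_day,
)


def _day(pid="P1", day=1, wear=17.0, sleep=480.0, sed=650.0, lpa=250.0, mvpa=40.0):
    return DaySummary(
        participant_id=pid,
        day_index=day,
        sed_min=sed,
        lpa_min=lpa,
        mpa_min=mvpa,
        vpa_min=0.0,
        sleep_min=sleep,
        wear_hours=wear,
    )


class TestClassifyEpoch:
    @pytest.mark.parametrize(
        "enmo, expected",
        [
            (0.0, IntensityClass.SED),
            (30.0, IntensityClass.SED),
            (35.6, IntensityClass.LPA),  # left-closed boundary
            (100.0, IntensityClass.LPA),
            (201.4, IntensityClass.MPA),
            (300.0, IntensityClass.MPA),
            (707.0, IntensityClass.VPA),
            (800.0, IntensityClass.VPA),
        ],
    )
    def test_cutpoints(self, enmo, expected):
        assert classify_epoch(enmo) is expected

    def test_negative_enmo_errors(self):
        with pytest.raises(ValueError):
            classify_epoch(-0.1)
        with pytest.raises(ValueError):
            classify_epochs(np.array([10.0, -1.0]))

    def test_monotone_step_function(self):
        """Intensity class never decreases as ENMO increases."""
        grid = np.linspace(0, 1000, 5000)
        codes = classify_epochs(grid)
        assert (np.diff(codes) >= 0).all()
        order = [IntensityClass.SED, IntensityClass.LPA, IntensityClass.MPA, IntensityClass.VPA]
        scalar = [order.index(classify_epoch(e)) for e in grid[::50]]
        assert np.array_equal(scalar, codes[::50])


class TestSummariseDay:
    def test_full_day_sedentary(self):
        epochs = [EpochRecord("P1", 1, 10.0, 30.0) for _ in range(2880)]
        day = summarise_day(epochs, sleep_minutes=0.0)
        assert day.sed_min == 1440.0
        assert day.lpa_min == day.mvpa_min == 0.0

    def test_hand_tally_mixed_day(self):
        # 120 sedentary + 60 light + 30 moderate + 10 vigorous minutes
        epochs = (
            [EpochRecord("P1", 1, 5.0, 60.0) for _ in range(120)]
            + [EpochRecord("P1", 1, 100.0, 60.0) for _ in range(60)]
            + [EpochRecord("P1", 1, 400.0, 60.0) for _ in range(30)]
            + [EpochRecord("P1", 1, 900.0, 60.0) for _ in range(10)]
        )
        day = summarise_day(epochs, sleep_minutes=480.0)
        assert (day.sed_min, day.lpa_min, day.mpa_min, day.vpa_min) == (120, 60, 30, 10)
        assert day.mvpa_min == 40
        assert np.isclose(day.wear_hours, 220 / 60)

    def test_empty_epochs_flagged_non_wear(self):
        day = summarise_day([], sleep_minutes=400.0)
        assert day.non_wear and day.wear_hours == 0.0
        assert day.sed_min == day.lpa_min == day.mvpa_min == 0.0

    def test_time_conservation(self, rng):
        enmo = rng.exponential(60, size=1500)
        epochs = [EpochRecord("P1", 1, float(e), 30.0) for e in enmo]
        day = summarise_day(epochs, sleep_minutes=100.0)
        total = day.sed_min + day.lpa_min + day.mpa_min + day.vpa_min
        assert np.isclose(total, 1500 * 30 / 60)

    def test_mixed_participants_error(self):
        epochs = [EpochRecord("P1", 1, 10.0), EpochRecord("P2", 1, 10.0)]
        with pytest.raises(ValueError):
            summarise_day(epochs, sleep_minutes=0.0)


class TestFilterValid:
    def test_three_days_one_under_wear_excluded(self):
        days = [_day(day=i, wear=w) for i, w in enumerate([17, 17, 15])]
        res = filter_valid(days)
        assert not res.included
        assert res.reason == "fewer_than_3_valid_days"
        assert res.n_valid == 2

    def test_seven_good_days_included(self):
        days = [_day(day=i) for i in range(7)]
        res = filter_valid(days)
        assert res.included and res.n_valid == 7 and res.reason is None

    def test_zero_sleep_invalidates_a_day(self):
        days = [_day(day=1), _day(day=2), _day(day=3, sleep=0.0)]
        res = filter_valid(days)
        assert not res.included and res.n_valid == 2

    def test_all_days_under_wear_reported_as_wear_failure(self):
        days = [_day(day=i, wear=12.0) for i in range(5)]
        assert filter_valid(days).reason == "under_16h_wear"

    def test_idempotent_and_order_independent(self):
        days = [_day(day=i, wear=w) for i, w in enumerate([17, 15, 18, 20, 12])]
        a = filter_valid(days)
        b = filter_valid(list(reversed(days)))
        assert a.included == b.included
        assert {d.day_index for d in a.valid_days} == {d.day_index for d in b.valid_days}
        again = filter_valid(a.valid_days)
        assert {d.day_index for d in again.valid_days} == {
            d.day_index for d in a.valid_days
        }

    def test_empty_input(self):
        res = filter_valid([])
        assert not res.included and res.n_valid == 0


class TestParticipantComposition:
    def test_identical_days_closed_to_1440(self):
        days = [_day(day=i, sleep=480, sed=700, lpa=230, mvpa=30) for i in range(3)]
        comp = participant_composition(days)
        assert np.isclose(comp.values.sum(), 1440)
        assert np.allclose(comp.values / comp.values[3], [16, 700 / 30, 230 / 30, 1])

    def test_hand_mean_of_two_days(self):
        d1 = _day(day=1, sleep=480, sed=700, lpa=230, mvpa=30)
        d2 = _day(day=2, sleep=460, sed=660, lpa=270, mvpa=50)
        comp = participant_composition([d1, d2])
        means = np.array([470.0, 680.0, 250.0, 40.0])
        assert np.allclose(comp.values, means * 1440 / means.sum())

    def test_short_day_rescaled_ratios_preserved(self):
        day = _day(sleep=430, sed=600, lpa=240, mvpa=30)  # sums to 1300
        comp = participant_composition([day])
        assert np.isclose(comp.values.sum(), 1440)
        assert np.isclose(comp.values[0] / comp.values[1], 430 / 600)

    def test_zero_part_directs_to_replacement(self):
        day = _day(mvpa=0.0)
        with pytest.raises(ZeroPartError, match="multiplicative_replacement"):
            participant_composition([day])

    def test_no_days_errors(self):
        with pytest.raises(ValueError):
            participant_composition([])


class TestMultiplicativeReplacement:
    def test_no_zeros_is_identity(self):
        vals = [480.0, 700.0, 230.0, 30.0]
        assert np.allclose(multiplicative_replacement(vals), vals)

    def test_zero_replaced_total_preserved(self):
        out = multiplicative_replacement([480, 730, 230, 0], minimum=1.0)
        assert out[3] == 1.0
        assert np.isclose(out.sum(), 1440)
        assert np.isclose(out[0] / out[1], 480 / 730)


class TestInclusionFlow:
    def test_study_flow_arithmetic(self):
        flow = InclusionFlow(
            enrolled=193,
            device_missing=5,
            fewer_than_3_valid_days=30,
            under_16h_wear=30,
            invalid_wellbeing=4,
        )
        assert flow.final == 124
        assert flow.insufficient_accelerometer == 60
        assert round(flow.retention_pct, 1) == 64.2
        assert round(flow.pct(flow.insufficient_accelerometer), 1) == 31.1
        assert round(flow.pct(flow.device_missing), 1) == 2.6
        assert round(flow.pct(flow.invalid_wellbeing), 1) == 2.1

    def test_no_exclusions(self):
        flow = InclusionFlow(50, 0, 0, 0, 0)
        assert flow.final == 50 and flow.retention_pct == 100.0

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            InclusionFlow(10, -1, 0, 0, 0)
        with pytest.raises(ValueError):
            InclusionFlow(10, 8, 3, 0, 0)  # exclusions exceed enrolment

    def test_tally_from_roster(self):
        roster = pd.DataFrame(
            {
                "status": ["included"] * 4
                + ["device_missing"]
                + ["fewer_than_3_valid_days"] * 2
                + ["under_16h_wear"]
                + ["invalid_wellbeing"]
            }
        )
        flow = inclusion_flow(roster)
        assert flow.enrolled == 9 and flow.final == 4

    def test_unknown_status_errors(self):
        with pytest.raises(ValueError, match="unknown roster status"):
            inclusion_flow(pd.DataFrame({"status": ["lost_to_followup"]}))
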