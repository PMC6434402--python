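import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patx import (
    Bout,
    ZoneParams,
    daily_zone_params,
    detect_bouts,
    estimate_rhr,
    in_zone_mask,
    karvonen_zone,
    target_minutes,
)

from conftest import make_day
from oracles import bouts_brute


class TestKarvonenZone:
    def test_formula(self):
        zone = karvonen_zone(rhr=60, max_hr=190, y=0.5)
        assert zone.hrr == 130
        assert zone.zone_min == 125

    def test_y_one_boundary_equals_max_hr(self):
        assert karvonen_zone(60, 190, y=1.0).zone_min == 190

    def test_rhr_at_or_above_max_hr_rejected(self):
        with pytest.raises(ValueError):
            karvonen_zone(70, 70)

    @pytest.mark.parametrize("rhr,max_hr", [(20, 190), (60, 240)])
    def test_bounds_enforced(self, rhr, max_hr):
        with pytest.raises(ValueError):
            karvonen_zone(rhr, max_hr)

    def test_zone_min_strictly_between_rhr_and_max(self):
        zone = karvonen_zone(55, 200, y=0.5)
        assert zone.rhr < zone.zone_min < zone.max_hr


class TestDailyZoneParams:
    def test_age_predicted_max_hr(self):
        day = make_day(70.0)
        zone = daily_zone_params(day, subject_age=18, rhr=62, y=0.5)
        assert zone.max_hr == 202
        assert zone.zone_min == pytest.approx(132)

    def test_explicit_max_hr_overrides_age(self):
        zone = daily_zone_params(make_day(70.0), subject_age=18, rhr=62, max_hr=195)
        assert zone.max_hr == 195

    def test_fallback_rhr_on_constant_day(self):
        day = make_day(60.0)
        assert estimate_rhr(day) == 60.0
        zone = daily_zone_params(day, subject_age=20)
        assert zone.rhr == 60.0

    def test_fallback_uses_lowest_30_minutes(self):
        hr = np.full(1440, 100.0)
        hr[:30] = 50.0
        assert estimate_rhr(make_day(hr)) == 50.0

    def test_too_few_minutes_for_fallback_rejected(self):
        day = make_day(60.0, missing=range(10, 1440))
        with pytest.raises(ValueError, match="30"):
            daily_zone_params(day, subject_age=20)


class TestInZoneMask:
    def test_inclusive_lower_bound_and_missing_false(self):
        zone = karvonen_zone(60, 190, y=0.5)  # zone_min 125
        hr = np.full(1440, 100.0)
        hr[0], hr[1], hr[2] = 130.0, 125.0, np.nan
        day = make_day(hr)
        day.hr[2] = np.nan
        mask = in_zone_mask(day, zone)
        assert mask[0] and mask[1]
        assert not mask[2]
        assert not mask[3]


def _mask(*intervals, n=1440):
    m = np.zeros(n, dtype=bool)
    for s, e in intervals:
        m[s:e] = True
    return m


class TestDetectBouts:
    def test_twelve_consecutive_minutes_is_one_bout(self):
        (bout,) = detect_bouts(_mask((100, 112)))
        assert (bout.start_slot, bout.end_slot, bout.duration_minutes) == (100, 112, 12)

    def test_nine_minutes_is_no_bout(self):
        assert detect_bouts(_mask((100, 109))) == []

    def test_single_minute_dip_merges_to_elapsed_13(self):
        (bout,) = detect_bouts(_mask((100, 106), (107, 113)))
        assert bout.duration_minutes == 13
        assert bout.in_zone_minutes == 12

    def test_two_minute_gap_does_not_merge(self):
        assert detect_bouts(_mask((100, 106), (108, 114))) == []

    def test_chain_of_single_gaps_collapses(self):
        bouts = detect_bouts(_mask((10, 16), (17, 23), (24, 30)))
        assert [(b.start_slot, b.end_slot) for b in bouts] == [(10, 30)]

    def test_strict_convention_merges_only_qualifying_runs(self):
        mask = _mask((100, 106), (107, 113))  # 6+6 runs
        assert detect_bouts(mask, merge_before_filter=False) == []
        mask2 = _mask((100, 111), (112, 123))  # 11+11 runs
        (bout,) = detect_bouts(mask2, merge_before_filter=False)
        assert (bout.start_slot, bout.end_slot) == (100, 123)

    def test_merge_gap_zero_disables_merging(self):
        mask = _mask((100, 106), (107, 113))
        assert detect_bouts(mask, merge_gap=0) == []

    def test_invariant_under_out_of_zone_padding(self):
        inner = _mask((50, 70), n=200)
        with_pad = np.concatenate([np.zeros(30, bool), inner, np.zeros(30, bool)])
        a = detect_bouts(inner)
        b = detect_bouts(with_pad)
        assert [(x.start_slot + 30, x.end_slot + 30) for x in a] == [
            (x.start_slot, x.end_slot) for x in b
        ]

    @pytest.mark.parametrize("merge_before_filter", [True, False])
    def test_agrees_with_brute_force_enumerator(self, merge_before_filter):
        """Exhaustive check against the naive run-merge-filter oracle on
        10,000 random masks of varied length and density."""
        rng = np.random.default_rng(2024)
        for _ in range(10_000):
            n = int(rng.integers(1, 201))
            density = rng.uniform(0.1, 0.95)
            mask = rng.random(n) < density
            got = [
                (b.start_slot, b.end_slot)
                for b in detect_bouts(mask, merge_before_filter=merge_before_filter)
            ]
            want = bouts_brute(mask, merge_before_filter=merge_before_filter)
            assert got == want, f"mask={mask.astype(int).tolist()}"

    @given(st.lists(st.booleans(), min_size=1, max_size=120))
    @settings(max_examples=300, deadline=None)
    def test_merge_rule_never_decreases_target_minutes(self, bits):
        merged = detect_bouts(bits, merge_gap=1)
        unmerged = detect_bouts(bits, merge_gap=0)
        assert target_minutes(merged) >= target_minutes(unmerged)

    def test_lowering_zone_min_never_decreases_target_minutes(self):
        rng = np.random.default_rng(5)
        hr = 100 + 40 * rng.random(1440)
        day = make_day(hr)
        prev = -1
        for zone_min in [135.0, 125.0, 115.0, 105.0]:
            zone = ZoneParams(rhr=60, max_hr=190, y=(zone_min - 60) / 130)
            tm = target_minutes(detect_bouts(in_zone_mask(day, zone)))
            assert tm >= prev
            prev = tm


class TestTargetMinutes:
    def test_sums_durations(self):
        bouts = [
            Bout(0, 12, in_zone_minutes=12),
            Bout(100, 115, in_zone_minutes=15),
        ]
        assert target_minutes(bouts) == 27

    def test_empty_is_zero(self):
        assert target_minutes([]) == 0

    def test_whole_day_bout(self):
        assert target_minutes([Bout(0, 1440, in_zone_minutes=1440)]) == 1440

    def test_bridged_minute_conventions(self):
        (bout,) = detect_bouts(_mask((100, 106), (107, 113)))
        assert target_minutes([bout], count_bridged=True) == 13
        assert target_minutes([bout], count_bridged=False) == 12

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            target_minutes([Bout(0, 20, 20), Bout(10, 40, 30)])
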