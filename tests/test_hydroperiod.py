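"""Hydroperiod counting, classification, averaging and cycle masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wetbird.grids import (
    HYDRO_NONE,
    HYDRO_SEASONAL,
    HYDRO_SEMI_PERMANENT,
    HYDRO_TEMPORARY,
    AnnualCycle,
    GridGeometry,
    MonthCountGrid,
)
from wetbird.hydroperiod import (
    classify_hydroperiod,
    count_inundated_months,
    cycle_hydroperiod,
    cycle_water_mask,
    mean_condition_hydroperiod,
)

from conftest import make_stack


def classify_scalar(count: int) -> int:
    """Independent statement of the class rule for single counts."""
    if count == 0:
        return HYDRO_NONE
    if count <= 2:
        return HYDRO_TEMPORARY
    if count <= 8:
        return HYDRO_SEASONAL
    return HYDRO_SEMI_PERMANENT


class TestCounting:
    def test_wet_january_to_september_counts_nine(self):
        water = np.zeros((1, 12, 2, 2), dtype=np.uint8)
        water[0, :9, 0, 0] = 1
        stack = make_stack(water, [2010])
        counts = count_inundated_months(stack, 2010)
        assert counts.counts[0, 0] == 9
        assert counts.counts[1, 1] == 0

    def test_missing_year_raises(self, random_stack):
        with pytest.raises(KeyError, match="1999"):
            count_inundated_months(random_stack, 1999)

    def test_counts_match_per_pixel_loop(self, random_stack):
        counts = count_inundated_months(random_stack, 2010)
        for r in range(20):
            for c in range(20):
                expected = sum(
                    int(random_stack.water[0, m, r, c]) for m in range(12)
                )
                assert counts.counts[r, c] == expected


class TestClassification:
    @pytest.mark.parametrize(
        "count,expected",
        [
            (0, HYDRO_NONE),
            (1, HYDRO_TEMPORARY),
            (2, HYDRO_TEMPORARY),  # boundary: 'flooded < 2' read inclusively
            (3, HYDRO_SEASONAL),
            (5, HYDRO_SEASONAL),  # 'more than 2 but < 8'
            (8, HYDRO_SEASONAL),  # boundary: not 'more than 8'
            (9, HYDRO_SEMI_PERMANENT),  # 'flooded more than 8 months'
            (12, HYDRO_SEMI_PERMANENT),
        ],
    )
    def test_class_boundaries(self, count, expected):
        geom = GridGeometry(1, 1)
        counts = MonthCountGrid(np.array([[count]]), geom)
        assert classify_hydroperiod(counts).classes[0, 0] == expected

    def test_count_out_of_range_raises(self):
        geom = GridGeometry(1, 1)
        with pytest.raises(ValueError):
            classify_hydroperiod(MonthCountGrid(np.array([[13]]), geom))

    def test_partition_and_monotonicity_on_random_counts(self, rng):
        counts = rng.integers(0, 13, size=(30, 30))
        geom = GridGeometry(30, 30)
        classes = classify_hydroperiod(MonthCountGrid(counts, geom)).classes
        wet = (counts >= 1).sum()
        assert (classes != HYDRO_NONE).sum() == wet
        bumped = classify_hydroperiod(
            MonthCountGrid(np.minimum(counts + 1, 12), geom)
        ).classes
        assert np.all(bumped >= classes)  # codes ordered by persistence

    @given(count=st.integers(0, 12))
    @settings(deadline=None, max_examples=13)
    def test_matches_scalar_rule(self, count):
        geom = GridGeometry(1, 1)
        got = classify_hydroperiod(MonthCountGrid(np.array([[count]]), geom))
        assert got.classes[0, 0] == classify_scalar(count)


class TestMeanCondition:
    def test_stationary_patch_matches_single_year(self, wet_patch_config):
        from wetbird.synth import generate_water_stack

        stack = generate_water_stack(wet_patch_config)
        multi = mean_condition_hydroperiod(stack, (1984, 2023))
        single = classify_hydroperiod(count_inundated_months(stack, 1990))
        np.testing.assert_array_equal(multi.classes, single.classes)

    def test_alternating_8_and_10_rounds_to_semi_permanent(self):
        water = np.zeros((2, 12, 1, 1), dtype=np.uint8)
        water[0, :8, 0, 0] = 1
        water[1, :10, 0, 0] = 1
        stack = make_stack(water, [2000, 2001])
        hydro = mean_condition_hydroperiod(stack, (2000, 2001))
        assert hydro.classes[0, 0] == HYDRO_SEMI_PERMANENT  # mean 9

    def test_half_ties_round_up(self):
        water = np.zeros((2, 12, 1, 1), dtype=np.uint8)
        water[0, :2, 0, 0] = 1
        water[1, :3, 0, 0] = 1
        stack = make_stack(water, [2000, 2001])
        hydro = mean_condition_hydroperiod(stack, (2000, 2001))
        assert hydro.classes[0, 0] == HYDRO_SEASONAL  # mean 2.5 -> 3

    def test_empty_range_raises(self, random_stack):
        with pytest.raises(ValueError):
            mean_condition_hydroperiod(random_stack, (2011, 2010))

    def test_matches_average_then_classify_oracle(self, rng):
        water = (rng.random((5, 12, 15, 15)) < 0.4).astype(np.uint8)
        stack = make_stack(water, list(range(2000, 2005)))
        got = mean_condition_hydroperiod(stack, (2000, 2004)).classes
        oracle = np.zeros((15, 15), dtype=int)
        for r in range(15):
            for c in range(15):
                counts = [water[y, :, r, c].sum() for y in range(5)]
                mean = int(np.floor(np.mean(counts) + 0.5))
                oracle[r, c] = classify_scalar(mean)
        np.testing.assert_array_equal(got, oracle)


class TestCycleMask:
    def test_pixel_wet_in_cycle_month_is_available(self):
        water = np.zeros((1, 12, 1, 1), dtype=np.uint8)
        water[0, 5, 0, 0] = 1  # June
        stack = make_stack(water, [2010])
        cyc = AnnualCycle("s", "breeding", (6,))
        assert cycle_water_mask(stack, cyc, (2010, 2010))[0, 0]

    def test_pixel_wet_outside_cycle_months_is_unavailable(self):
        water = np.zeros((2, 12, 1, 1), dtype=np.uint8)
        water[0, 5, 0, 0] = 1  # June only
        stack = make_stack(water, [2010, 2011])
        cyc = AnnualCycle("s", "nonbreeding", (12, 1))
        assert not cycle_water_mask(stack, cyc, (2010, 2010))[0, 0]

    def test_december_january_wrap_pairs_adjacent_years(self):
        # wet only Dec 1990 and Jan 1991: the Dec-Jan cycle of year 1990
        # sees both months; the cycle of 1991 sees neither
        water = np.zeros((3, 12, 1, 1), dtype=np.uint8)
        years = [1989, 1990, 1991]
        water[1, 11, 0, 0] = 1  # Dec 1990
        water[2, 0, 0, 0] = 1  # Jan 1991
        stack = make_stack(water, years)
        cyc = AnnualCycle("s", "nonbreeding", (12, 1))
        assert cycle_water_mask(stack, cyc, (1990, 1990))[0, 0]
        assert not cycle_water_mask(stack, cyc, (1989, 1989))[0, 0]

    def test_wrap_beyond_final_year_is_dropped(self, caplog):
        water = np.zeros((1, 12, 1, 1), dtype=np.uint8)
        water[0, 11, 0, 0] = 1  # Dec only
        stack = make_stack(water, [2010])
        cyc = AnnualCycle("s", "nonbreeding", (12, 1))
        # January 2011 does not exist; December alone still qualifies
        assert cycle_water_mask(stack, cyc, (2010, 2010))[0, 0]

    def test_min_months_threshold(self, random_stack):
        cyc = AnnualCycle("s", "breeding", tuple(range(1, 13)))
        loose = cycle_water_mask(random_stack, cyc, (2010, 2010), min_months=1)
        strict = cycle_water_mask(random_stack, cyc, (2010, 2010), min_months=6)
        assert strict.sum() <= loose.sum()
        np.testing.assert_array_equal(
            loose, random_stack.water[0].sum(axis=0) >= 1
        )


class TestCycleHydroperiod:
    def test_all_true_mask_is_identity(self, random_stack):
        hydro = classify_hydroperiod(count_inundated_months(random_stack, 2010))
        out = cycle_hydroperiod(hydro, np.ones((20, 20), dtype=bool))
        np.testing.assert_array_equal(out.classes, hydro.classes)

    def test_all_false_mask_gives_none(self, random_stack):
        hydro = classify_hydroperiod(count_inundated_months(random_stack, 2010))
        out = cycle_hydroperiod(hydro, np.zeros((20, 20), dtype=bool))
        assert np.all(out.classes == HYDRO_NONE)

    def test_checkerboard_mask_halves_class_histogram(self):
        geom_side = 20
        counts = np.full((geom_side, geom_side), 5)  # all seasonal
        geom = GridGeometry(geom_side, geom_side)
        hydro = classify_hydroperiod(MonthCountGrid(counts, geom))
        mask = np.indices((geom_side, geom_side)).sum(axis=0) % 2 == 0
        out = cycle_hydroperiod(hydro, mask)
        assert out.histogram()["seasonal"] == geom_side * geom_side // 2

    def test_shape_mismatch_raises(self, random_stack):
        hydro = classify_hydroperiod(count_inundated_months(random_stack, 2010))
        with pytest.raises(ValueError):
            cycle_hydroperiod(hydro, np.ones((5, 5), dtype=bool))
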