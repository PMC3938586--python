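"""Physiological filtering, CL intersections and the expanded-grid rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from apopcal import (
    GridSpec,
    ModelInputError,
    PhysRange,
    biomarker_histogram,
    extend_apd_ranges,
    filter_physiological,
    intersect_across_cls,
    level_distribution,
    propose_expanded_grid,
)
from apopcal.core import CONDUCTANCES, SCALE_COLUMNS


def _records(rows):
    """Biomarker table stub: (scales, apd50, apd90, steady) per row."""
    data = []
    for scales, apd50, apd90, steady in rows:
        row = dict(zip(SCALE_COLUMNS, scales))
        row.update(apd50=apd50, apd90=apd90, steady=steady, degenerate=False)
        data.append(row)
    return pd.DataFrame(data)


CONTROL = (1.0,) * 6


class TestFilter:
    def test_in_range_record_passes_at_cl400(self):
        table = _records([(CONTROL, 120.0, 160.0, True)])
        assert filter_physiological(table, PhysRange.table1(), 400) == {CONTROL}

    def test_apd90_above_upper_bound_fails(self):
        table = _records([(CONTROL, 120.0, 190.0, True)])
        assert filter_physiological(table, PhysRange.table1(), 400) == set()

    def test_bounds_are_inclusive(self):
        table = _records([(CONTROL, 104.0, 185.0, True)])
        assert filter_physiological(table, PhysRange.table1(), 400) == {CONTROL}

    def test_non_steady_and_undefined_records_fail(self):
        table = _records(
            [
                (CONTROL, 120.0, 160.0, False),
                ((0.7,) * 6, np.nan, 160.0, True),
            ]
        )
        assert filter_physiological(table, PhysRange.table1(), 400) == set()

    def test_empty_table_gives_empty_set(self):
        assert filter_physiological(_records([]), PhysRange.table1(), 400) == set()

    def test_unknown_cl_rejected(self):
        with pytest.raises(ModelInputError):
            filter_physiological(_records([]), PhysRange.table1(), 500)

    def test_filter_is_order_independent_and_idempotent(self, rng):
        rows = [
            (tuple(rng.choice([0.7, 1.0, 1.3], size=6)), a, b, True)
            for a, b in zip(rng.uniform(90, 150, 40), rng.uniform(130, 200, 40))
        ]
        table = _records(rows)
        shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        first = filter_physiological(table, PhysRange.table1(), 400)
        assert filter_physiological(shuffled, PhysRange.table1(), 400) == first
        survivors = table[
            [tuple(r) in first for r in table[list(SCALE_COLUMNS)].to_numpy()]
        ]
        assert filter_physiological(survivors, PhysRange.table1(), 400) == first

    def test_shrinking_ranges_never_grows_the_passing_set(self, rng):
        rows = [
            (tuple(rng.choice([0.7, 1.0, 1.3], size=6)), a, b, True)
            for a, b in zip(rng.uniform(90, 150, 60), rng.uniform(130, 200, 60))
        ]
        table = _records(rows)
        wide = PhysRange.table1()
        narrow = PhysRange(
            bounds={cl: (lo + 5, hi - 5, lo2 + 5, hi2 - 5)
                    for cl, (lo, hi, lo2, hi2) in wide.bounds.items()}
        )
        assert filter_physiological(table, narrow, 400) <= filter_physiological(
            table, wide, 400
        )


class TestIntersections:
    def test_identical_sets_intersect_to_themselves(self):
        s = {CONTROL, (0.7,) * 6}
        result = intersect_across_cls({400: s, 600: s, 1000: s})
        assert result[(400, 600, 1000)] == s
        assert result[(400, 1000)] == s

    def test_disjoint_sets_intersect_to_nothing(self):
        result = intersect_across_cls({400: {CONTROL}, 600: {(0.7,) * 6}})
        assert result[(400, 600)] == set()

    def test_matches_brute_force_on_random_sets(self, rng):
        def random_set():
            return {
                tuple(rng.choice([0.7, 0.85, 1.0, 1.15, 1.3], size=6))
                for _ in range(100)
            }

        sets = {400: random_set(), 600: random_set(), 1000: random_set()}
        result = intersect_across_cls(sets)
        for k in (2, 3):
            for combo in itertools.combinations(sorted(sets), k):
                brute = {
                    tup
                    for tup in sets[combo[0]]
                    if all(tup in sets[cl] for cl in combo[1:])
                }
                assert result[combo] == brute

    def test_single_cl_rejected(self):
        with pytest.raises(ModelInputError):
            intersect_across_cls({400: {CONTROL}})


class TestLevelDistribution:
    def test_empty_set_gives_all_zero_counts(self, tiny_grid):
        counts = level_distribution(set(), tiny_grid)
        assert all(c == 0 for axis in counts.values() for c in axis.values())

    def test_full_grid_gives_uniform_counts(self, tiny_grid):
        from apopcal import build_grid

        passing = {s.as_tuple() for s in build_grid(tiny_grid)}
        counts = level_distribution(passing, tiny_grid)
        for axis in counts.values():
            assert list(axis.values()) == [32, 32]

    def test_hand_built_set(self, tiny_grid):
        passing = {
            (0.85, 0.85, 0.85, 0.85, 0.85, 0.85),
            (1.15, 0.85, 0.85, 0.85, 0.85, 0.85),
            (1.15, 1.15, 0.85, 0.85, 0.85, 0.85),
        }
        counts = level_distribution(passing, tiny_grid)
        assert counts["to"] == {0.85: 1, 1.15: 2}
        assert counts["Kr"] == {0.85: 2, 1.15: 1}
        assert counts["Ks"] == {0.85: 3, 1.15: 0}
        assert sum(counts["NaK"].values()) == len(passing)


class TestRangeExtension:
    def test_ten_percent_extension_arithmetic(self):
        extended = extend_apd_ranges(PhysRange.table1(), 0.10)
        a_lo, a_hi, b_lo, b_hi = extended.bounds[400]
        assert (b_lo, b_hi) == (pytest.approx(127.8), pytest.approx(203.5))
        assert (a_lo, a_hi) == (pytest.approx(93.6), pytest.approx(148.5))

    def test_zero_extension_is_identity(self):
        assert extend_apd_ranges(PhysRange.table1(), 0.0).bounds == PhysRange.table1().bounds

    def test_full_extension_zeroes_lower_bounds_with_warning(self):
        with pytest.warns(UserWarning):
            extended = extend_apd_ranges(PhysRange.table1(), 1.0)
        assert extended.bounds[400][0] == pytest.approx(0.0)

    def test_midpoint_mode_preserves_the_midpoint(self):
        extended = extend_apd_ranges(PhysRange.table1(), 0.10, mode="midpoint")
        lo, hi, *_ = extended.bounds[400]
        assert (lo + hi) / 2 == pytest.approx((104 + 135) / 2)
        assert hi - lo == pytest.approx((135 - 104) * 1.10)


class TestExpandedGrid:
    def test_centred_passers_leave_the_grid_unchanged(self):
        grid = GridSpec.default()
        passing = {CONTROL}
        assert propose_expanded_grid(passing, grid).levels == grid.levels

    def test_passers_at_one_extreme_shift_that_axis_by_four_steps(self):
        grid = GridSpec.default()
        passing = {(1.30, 1.0, 1.0, 1.0, 1.0, 1.0)}  # s_to at the top level
        new = propose_expanded_grid(passing, grid, step=0.15, gain=2.0)
        assert new.levels["to"] == tuple(
            pytest.approx(lvl + 4 * 0.15) for lvl in grid.levels["to"]
        )
        for name in CONDUCTANCES[1:]:
            assert new.levels[name] == grid.levels[name]

    def test_symmetric_passers_give_zero_shift(self):
        grid = GridSpec.default()
        passing = {
            (0.70, 1.0, 1.0, 1.0, 1.0, 1.0),
            (1.30, 1.0, 1.0, 1.0, 1.0, 1.0),
        }
        assert propose_expanded_grid(passing, grid).levels == grid.levels

    def test_empty_passing_set_rejected(self):
        with pytest.raises(ModelInputError):
            propose_expanded_grid(set(), GridSpec.default())


class TestHistogram:
    def test_single_record_lands_in_one_bin(self):
        table = pd.DataFrame({"apd90": [150.0]})
        counts, edges = biomarker_histogram(table, "apd90", 5.0)
        assert counts.sum() == 1 and counts.max() == 1

    def test_counts_sum_to_finite_record_count(self, rng):
        table = pd.DataFrame({"apd90": np.append(rng.uniform(100, 200, 50), np.nan)})
        counts, _ = biomarker_histogram(table, "apd90", 10.0)
        assert counts.sum() == 50

    def test_hand_binned_values(self):
        values = [100.0, 101.0, 104.9, 105.0, 109.0, 110.0, 112.0, 114.9, 115.0, 119.0]
        table = pd.DataFrame({"apd50": values})
        counts, edges = biomarker_histogram(table, "apd50", 5.0)
        assert edges[0] == pytest.approx(100.0)
        assert list(counts) == [3, 2, 3, 2]
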