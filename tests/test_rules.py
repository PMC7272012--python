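"""Anhøj limits, region geometry, and series classification."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from runbox import (Box, CutRegion, anhoej_box, anhoej_crossings_limit,
                    anhoej_longest_run_limit, classify, count_crossings,
                    longest_run, useful_observations)


class TestLimits:
    def test_worked_limits_n20(self):
        assert anhoej_crossings_limit(20) == 6
        assert anhoej_longest_run_limit(20) == 7

    def test_crossings_limit_small_cases(self):
        # n=10: P(C<=1) = 10/512 < 0.05 <= P(C<=2) = 46/512
        assert anhoej_crossings_limit(10) == 2
        assert anhoej_crossings_limit(11) == 2

    def test_run_limit_exact_power_of_two(self):
        assert anhoej_longest_run_limit(32) == 8  # log2(32) + 3 exactly

    def test_limits_match_published_table(self, table1):
        for _, row in table1.iterrows():
            n = int(row.n)
            assert anhoej_crossings_limit(n) == int(row.c_anhoej), n
            assert anhoej_longest_run_limit(n) == int(row.l_anhoej), n

    def test_box_assembly(self):
        assert anhoej_box(11) == Box(2, 6)
        assert anhoej_box(20) == Box(6, 7)
        assert anhoej_box(100) == Box(41, 10)

    @pytest.mark.parametrize("fn", [anhoej_crossings_limit,
                                    anhoej_longest_run_limit, anhoej_box])
    def test_degenerate_n_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0)

    def test_outside_validated_range_warns_but_computes(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="runbox.rules"):
            box = anhoej_box(150)
        assert box.c_min > 0 and box.l_max == round(math.log2(150) + 3)
        assert any("validated range" in r.message for r in caplog.records)


class TestRegions:
    def test_box_predicate_and_corner(self):
        box = Box(2, 6)
        assert box.corner == (2, 6)
        assert box.accepts(2, 6) and box.accepts(5, 1)
        assert box.signals(1, 6) and box.signals(2, 7)

    def test_cut_region_predicate_n11(self):
        region = CutRegion(Box(3, 7), cbord=4, lbord=6)
        assert region.cut_cells() == {(3, 7)}
        assert region.signals(3, 7)          # the cut corner
        assert region.accepts(4, 7) and region.accepts(3, 6)
        assert region.signals(2, 5)          # outside the box entirely

    def test_cut_region_row_and_column(self):
        region = CutRegion(Box(5, 7), cbord=6, lbord=5)  # published N=19 cut
        assert region.cut_cells() == {(5, 7), (5, 6)}
        assert region.signals(5, 6) and region.accepts(6, 7)

    def test_uncut_region_equals_box(self):
        region = CutRegion(Box(3, 6))
        assert not region.is_cut and region.cut_cells() == set()
        assert region.accepts(3, 6)

    @pytest.mark.parametrize("kwargs", [
        dict(cbord=4, lbord=None),          # jointly present or absent
        dict(cbord=3, lbord=6),             # cbord must exceed c_min
        dict(cbord=4, lbord=7),             # lbord must be below l_max
    ])
    def test_inconsistent_borders_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CutRegion(Box(3, 7), **kwargs)


class TestSeriesStatistics:
    def test_centre_points_excluded(self):
        assert useful_observations([1, 2, 3], centre=2) == [-1, 1]

    def test_all_on_centre_unanalyzable(self):
        with pytest.raises(ValueError):
            useful_observations([2.0, 2.0], centre=2.0)

    def test_counting_extremes(self):
        alternating = [1, -1] * 5
        assert count_crossings(alternating) == 9
        assert longest_run(alternating) == 1
        constant = [1] * 11
        assert count_crossings(constant) == 0
        assert longest_run(constant) == 11

    def test_hand_counted_pattern(self):
        sides = [1, 1, -1, -1, -1, 1]
        assert count_crossings(sides) == 2
        assert longest_run(sides) == 3

    @given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=60))
    @settings(max_examples=200, derandomize=True)
    def test_runs_equal_crossings_plus_one(self, sides):
        n_runs = 1 + sum(1 for a, b in zip(sides, sides[1:]) if a != b)
        assert n_runs == count_crossings(sides) + 1
        assert 1 <= longest_run(sides) <= len(sides)
        assert longest_run(sides) >= math.ceil(
            len(sides) / (count_crossings(sides) + 1))


class TestClassify:
    def test_published_n11_example(self):
        # engineered series: C = 3, L = 7 with centre 0.  The cell (3, 7)
        # lies inside the best box but outside both the Anhøj box (L > 6)
        # and the cut box (the cut corner): the regions are not nested.
        values = [1, 1, 1, 1, 1, 1, 1, -1, 1, -1, -1]
        result = classify(values, centre=0,
                          rule_set=("anhoej", "bestbox", "cutbox"))
        assert (result.crossings, result.longest_run) == (3, 7)
        assert result.verdicts == {"anhoej": True, "bestbox": False,
                                   "cutbox": True}

    def test_too_few_crossings_signals_everywhere(self):
        # C = 1 <= all three lower limits for n = 11
        values = [1, 1, 1, 1, 1, 1, -1, -1, -1, -1, -1]
        result = classify(values, centre=0,
                          rule_set=("anhoej", "bestbox", "cutbox"))
        assert result.crossings == 1
        assert all(result.verdicts.values())

    def test_random_variation_n20(self):
        # C = 9, L = 4: random under the Anhøj rules for N = 20
        # run lengths 4,1,2,2,1,2,2,3,1,2 -> 10 runs, longest 4
        sides = [1, 1, 1, 1, -1, 1, 1, -1, -1, 1,
                 -1, -1, 1, 1, -1, -1, -1, 1, -1, -1]
        result = classify([10 + s for s in sides], centre=10, rule_set="anhoej")
        assert (result.crossings, result.longest_run) == (9, 4)
        assert result.verdicts == {"anhoej": False}

    def test_centre_defaults_to_median(self):
        values = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0, 5.0]
        result = classify(values, rule_set="anhoej")
        import statistics
        assert result.centre == statistics.median(values)

    def test_monotone_transform_invariance(self):
        values = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0, 5.5, 3.5, 5.2]
        centre = 4.0
        base = classify(values, centre=centre, rule_set="anhoej")
        transformed = classify([math.exp(v) for v in values],
                               centre=math.exp(centre), rule_set="anhoej")
        assert base.verdicts == transformed.verdicts
        assert (base.crossings, base.longest_run) == (
            transformed.crossings, transformed.longest_run)

    def test_explicit_limits_and_unknown_rule_set(self):
        values = [1, -1] * 6
        result = classify(values, centre=0, rule_set="anhoej",
                          limits=Box(3, 5))
        assert result.verdicts == {"anhoej": False}
        with pytest.raises(ValueError):
            classify(values, centre=0, rule_set="nonsense")

    def test_short_series_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="runbox.rules"):
            classify([1, -1, 1, -1, 1], centre=0, rule_set="anhoej")
        assert any("useful points" in r.message for r in caplog.records)

    def test_serialization_includes_limits(self):
        values = [1, 1, 1, 1, 1, 1, 1, -1, 1, -1, -1]
        result = classify(values, centre=0, rule_set=("anhoej", "cutbox"))
        payload = result.to_dict()
        assert payload["limits"]["cutbox"] == {"c_min": 3, "l_max": 7,
                                               "cbord": 4, "lbord": 6}
        assert payload["n_useful"] == 11
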