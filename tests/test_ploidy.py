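"""Frequency classes, the 50%-of-peak averaging rule, and the C-value ladder."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dapicyto.ploidy import (
    all_nuclei_mean,
    assign_c_class,
    build_frequency_distribution,
    class_fraction_flags,
    peak_class_mean,
    pg_to_mb,
    stage_ratio,
)
from dapicyto.synthetic import ComponentSpec, SyntheticSceneSpec, gen_intensity_table
from oracles import oracle_included_range, oracle_peak_class_mean


def dist_from_counts(counts, width=0.1, start_k=6):
    """Build a distribution whose class counts are exactly `counts`."""
    values = []
    for i, c in enumerate(counts):
        center = (start_k + i) * width + width / 2
        values.extend([center] * c)
    return build_frequency_distribution(np.array(values), class_width=width)


class TestFrequencyDistribution:
    def test_small_example(self):
        d = build_frequency_distribution([0.7, 0.7, 0.8], class_width=0.1)
        assert list(d.counts) == [2, 1]
        assert d.edges[0] == pytest.approx(0.7)
        assert d.edges[-1] == pytest.approx(0.9)

    def test_every_value_assigned_once(self):
        values = np.linspace(0.55, 12.45, 300)
        d = build_frequency_distribution(values, class_width=0.1)
        assert len(d.counts) == 120
        assert d.counts.sum() == 300
        for v, k in zip(d.values, d.class_index):
            assert d.edges[k] - 1e-9 <= v < d.edges[k + 1] + 1e-9

    def test_empty_and_bad_width(self):
        with pytest.raises(ValueError):
            build_frequency_distribution([], 0.1)
        with pytest.raises(ValueError):
            build_frequency_distribution([1.0], 0.0)

    @given(
        st.lists(st.floats(0.05, 20.0, allow_nan=False), min_size=1, max_size=300),
        st.sampled_from([0.05, 0.1, 0.25]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_conservation_property(self, values, width):
        d = build_frequency_distribution(values, class_width=width)
        assert d.counts.sum() == len(values)
        widths = np.diff(d.edges)
        assert np.allclose(widths, width)


class TestPeakClassMean:
    def test_worked_example(self):
        # peak 40 at 0.75; 30 > 20 included; 10 and 5 excluded
        est = peak_class_mean(dist_from_counts([5, 40, 30, 10]))
        assert est.included_class_indices == (1, 2)
        assert est.mean_pg == pytest.approx((40 * 0.75 + 30 * 0.85) / 70, abs=1e-9)
        assert est.n_included == 70
        assert est.n_total == 85

    def test_single_class(self):
        est = peak_class_mean(build_frequency_distribution([0.72, 0.74, 0.76], 0.1))
        assert est.mean_pg == pytest.approx(0.74)
        assert est.fraction_included == 1.0

    def test_tied_peaks_form_one_region(self):
        est = peak_class_mean(dist_from_counts([10, 10]))
        assert est.included_class_indices == (0, 1)
        assert est.n_included == 20

    def test_gap_between_tied_peaks_included(self):
        # classes between tied maxima belong to the peak region regardless of count
        est = peak_class_mean(dist_from_counts([10, 4, 10]))
        assert est.included_class_indices == (0, 2)

    def test_exactly_half_is_excluded(self):
        # the rule is strictly "above 50%"
        est = peak_class_mean(dist_from_counts([20, 40, 21]))
        assert est.included_class_indices == (1, 2)

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=20).filter(lambda c: max(c) > 0))
    @settings(max_examples=300, derandomize=True)
    def test_matches_bruteforce_oracle(self, counts):
        d = dist_from_counts(counts)
        est = peak_class_mean(d)
        # the oracle indexes nonempty-trimmed distributions; align via edges
        lo, hi = oracle_included_range(list(d.counts))
        assert est.included_class_indices == (lo, hi)
        expected = oracle_peak_class_mean(
            list(d.values), list(d.edges), list(d.counts)
        )
        assert est.mean_pg == pytest.approx(expected)

    def test_single_class_limit_equals_all_nuclei_mean(self, rng):
        values = rng.normal(1.5, 0.2, 400)
        # width above the largest value puts everything in one anchored class
        wide = build_frequency_distribution(values, class_width=float(values.max()) * 1.01)
        est = peak_class_mean(wide)
        mean, _ = all_nuclei_mean(values)
        assert est.mean_pg == pytest.approx(mean)
        assert est.fraction_included == 1.0

    def test_midpoint_mode_close_to_value_mode(self, rng):
        values = rng.normal(1.5, 0.2, 500)
        d = build_frequency_distribution(values, 0.1)
        a = peak_class_mean(d).mean_pg
        b = peak_class_mean(d, use_midpoints=True).mean_pg
        assert abs(a - b) < 0.05


class TestAllNucleiMean:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 1, 1], (1.0, 0.0)),
            ([0.7, 0.9], (0.8, np.std([0.7, 0.9], ddof=1))),
            ([2.5], (2.5, 0.0)),
        ],
    )
    def test_closed_forms(self, values, expected):
        mean, sd = all_nuclei_mean(values)
        assert mean == pytest.approx(expected[0])
        assert sd == pytest.approx(expected[1])

    def test_zoospore_simulation_recovers_mean(self):
        spec = SyntheticSceneSpec(
            components=[ComponentSpec("z", 0.76, 0.07 / 0.76, 387)], n_standard=0, seed=17
        )
        t = gen_intensity_table(spec)
        mean, _ = all_nuclei_mean(t["true_pg"])
        assert abs(mean - 0.76) <= 2 * 0.07 / math.sqrt(387)


class TestCClassLadder:
    def test_identity_is_1C(self):
        call = assign_c_class(0.76, 0.76)
        assert call.c_class == 1
        assert call.ratio_to_1C == 1.0
        assert call.in_tolerance

    def test_meristoderm_vs_zoospore_is_2C(self):
        call = assign_c_class(1.51, 0.76)
        assert call.ratio_to_1C == pytest.approx(1.99, abs=0.005)
        assert call.c_class == 2

    @pytest.mark.parametrize("mult", [1, 2, 4, 8, 16])
    def test_exact_ladder_points_idempotent(self, mult):
        call = assign_c_class(0.76 * mult, 0.76)
        assert call.c_class == mult
        assert call.in_tolerance

    def test_geometric_midpoint_boundaries(self):
        s = math.sqrt(2)
        assert assign_c_class(s * 0.999, 1.0).c_class == 1
        assert assign_c_class(s * 1.001, 1.0).c_class == 2
        assert assign_c_class(4 * s * 0.999, 1.0).c_class == 4
        assert assign_c_class(4 * s * 1.001, 1.0).c_class == 8

    @given(st.lists(st.floats(0.01, 40.0), min_size=2, max_size=50))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_pg(self, pgs):
        calls = [assign_c_class(p, 0.76).c_class for p in sorted(pgs)]
        assert all(a <= b for a, b in zip(calls, calls[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            assign_c_class(0.0, 0.76)
        with pytest.raises(ValueError):
            assign_c_class(1.0, 0.0)

    def test_out_of_tolerance_flagged(self):
        # 2.6x the reference sits between 2C and 4C: called but flagged
        call = assign_c_class(2.0, 0.76)
        assert not call.in_tolerance


class TestFlags:
    def _calls(self, fracs, n=1000):
        calls = []
        for c, f in fracs.items():
            calls += [assign_c_class(0.76 * c, 0.76)] * int(round(f * n))
        return calls

    def test_pure_population_no_flags(self):
        flags = class_fraction_flags(self._calls({1: 1.0}), main_class=1)
        assert all(v == "" for v in flags.values())

    def test_minor_fraction_single_plus(self):
        flags = class_fraction_flags(self._calls({1: 0.97, 4: 0.03}), main_class=1)
        assert flags[4] == "+"
        assert flags[2] == ""

    def test_abundant_fraction_double_plus(self):
        flags = class_fraction_flags(self._calls({1: 0.88, 4: 0.12}), main_class=1)
        assert flags[4] == "++"

    def test_only_classes_above_main_reported(self):
        flags = class_fraction_flags(self._calls({2: 1.0}), main_class=2)
        assert set(flags) == {4, 8, 16}


class TestConversions:
    @pytest.mark.parametrize("pg,mb", [(1.0, 980.0), (0.0, 0.0), (0.76, 744.8)])
    def test_pg_to_mb(self, pg, mb):
        assert pg_to_mb(pg) == pytest.approx(mb)

    def test_pg_to_mb_rejects_negative(self):
        with pytest.raises(ValueError):
            pg_to_mb(-0.1)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (2.01, 0.76, 2.6),  # male gametophytes vs zoospores
            (2.27, 0.76, 3.0),  # female gametophytes
            (1.64, 0.76, 2.2),  # embryonic sporophytes
            (0.76, 0.76, 1.0),
            (1.25, 1.0, 1.3),  # half rounds away from zero
        ],
    )
    def test_stage_ratio(self, a, b, expected):
        assert stage_ratio(a, b) == expected

    def test_stage_ratio_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            stage_ratio(1.0, 0.0)
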