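"""TPS formula, category boundaries, depth profile, heterogeneity summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tps3d import TPSCategory, categorize, compute_tps, depth_profile, heterogeneity_summary
from tps3d.tps import BinStat, TPSProfile

from oracles import recount_tps, truth_bin_counts


def cell_table(z, tumor, positive):
    return pd.DataFrame({"z_um": z, "is_tumor": tumor, "is_pdl1_positive": positive})


class TestComputeTPS:
    def test_direct_formula(self):
        cells = cell_table([0.0] * 100, [True] * 100, [True] * 5 + [False] * 95)
        assert compute_tps(cells) == pytest.approx(5.0)

    def test_zero_positive(self):
        cells = cell_table([0.0] * 50, [True] * 50, [False] * 50)
        assert compute_tps(cells) == 0.0

    def test_empty_is_undefined(self):
        assert compute_tps(cell_table([], [], [])) is None

    def test_non_tumor_input_is_contract_violation(self):
        cells = cell_table([0.0, 0.0], [True, False], [False, False])
        with pytest.raises(ValueError):
            compute_tps(cells)

    @settings(max_examples=100, derandomize=True)
    @given(flags=st.lists(st.booleans(), min_size=1, max_size=60))
    def test_matches_bruteforce_recount(self, flags):
        cells = cell_table([1.0] * len(flags), [True] * len(flags), flags)
        assert compute_tps(cells) == pytest.approx(recount_tps(cells))


class TestCategorize:
    @pytest.mark.parametrize(
        "tps,expected",
        [
            (0.0, TPSCategory.LT1),
            (0.5, TPSCategory.LT1),
            (0.999, TPSCategory.LT1),
            (1.0, TPSCategory.MID),
            (49.99, TPSCategory.MID),
            (50.0, TPSCategory.GE50),
            (100.0, TPSCategory.GE50),
        ],
    )
    def test_boundaries(self, tps, expected):
        assert categorize(tps) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(-0.1)
        with pytest.raises(ValueError):
            categorize(100.1)

    @settings(max_examples=100, derandomize=True)
    @given(tps=st.floats(0, 100))
    def test_partition_is_total(self, tps):
        assert categorize(tps) in TPSCategory


class TestDepthProfile:
    def test_single_bin_example(self):
        cells = cell_table([2.0] * 10, [True] * 10, [True] * 5 + [False] * 5)
        prof = depth_profile(cells, depth_um=5.0, bin_um=5.0)
        assert prof.average_tps == pytest.approx(50.0)
        assert prof.max_minus_min == 0.0
        assert prof.category_of_average is TPSCategory.GE50

    def test_count_conservation(self, small_phantom):
        _, truth = small_phantom
        cells = truth.cells.rename(columns={})
        prof = depth_profile(cells, depth_um=truth.depth_um, bin_um=5.0)
        assert sum(b.n_tumor for b in prof.bins) == int(truth.cells.is_tumor.sum())
        assert sum(b.n_positive for b in prof.bins) == int(truth.cells.is_pdl1_positive.sum())

    def test_bins_match_truth_recount(self, small_phantom):
        _, truth = small_phantom
        prof = depth_profile(truth.cells, depth_um=truth.depth_um, bin_um=5.0)
        for k, (n_tum, n_pos) in truth_bin_counts(truth, 5.0).items():
            assert prof.bins[k].n_tumor == n_tum
            assert prof.bins[k].n_positive == n_pos

    def test_undefined_bins_excluded_from_summaries(self):
        # tumor cells only in bins 0 and 2; bin 1 must not enter max/min
        cells = cell_table([1.0, 1.0, 12.0, 12.0], [True] * 4, [True, True, False, False])
        prof = depth_profile(cells, depth_um=15.0, bin_um=5.0)
        assert prof.bins[1].tps is None
        assert prof.max_tps == 100.0
        assert prof.min_tps == 0.0
        assert prof.average_tps == pytest.approx(50.0)
        assert prof.crosses_category

    def test_cell_exactly_at_full_depth_goes_to_last_bin(self):
        cells = cell_table([15.0], [True], [True])
        prof = depth_profile(cells, depth_um=15.0, bin_um=5.0)
        assert prof.bins[-1].n_tumor == 1

    def test_excluded_cells_dropped(self):
        cells = cell_table([1.0, 1.0], [True, True], [True, False])
        cells["excluded"] = [False, True]
        prof = depth_profile(cells, depth_um=5.0, bin_um=5.0)
        assert prof.bins[0].n_tumor == 1
        assert prof.bins[0].tps == 100.0

    def test_no_tumor_cells_profile_undefined(self):
        cells = cell_table([1.0], [False], [False])
        prof = depth_profile(cells, depth_um=5.0, bin_um=5.0)
        assert prof.average_tps is None
        assert prof.max_minus_min is None

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            depth_profile(cell_table([], [], []), depth_um=10.0, bin_um=0.0)


def constant_profile(values, bin_um=5.0, n_tumor=100):
    bins = [
        BinStat(k * bin_um, (k + 1) * bin_um, n_tumor, int(round(v * n_tumor / 100)))
        for k, v in enumerate(values)
    ]
    return TPSProfile(bins=bins, bin_um=bin_um)


class TestHeterogeneitySummary:
    def test_two_profile_example(self):
        p1 = constant_profile([10, 12, 14])  # spread 4
        p2 = constant_profile([10, 20, 26])  # spread 16
        summary = heterogeneity_summary([p1, p2])
        assert summary["mean_max_minus_min"] == pytest.approx(10.0)
        assert summary["n_spread_gt_10"] == 1
        assert summary["frac_spread_gt_10"] == pytest.approx(0.5)

    def test_constant_profiles(self):
        profiles = [constant_profile([30, 30, 30]) for _ in range(3)]
        summary = heterogeneity_summary(profiles)
        assert summary["mean_max_minus_min"] == 0.0
        assert summary["n_crossing_category"] == 0

    def test_boundary_breakdown(self):
        crosses_1 = constant_profile([0, 3])       # straddles the 1 % cut
        crosses_50 = constant_profile([40, 60])    # straddles the 50 % cut
        summary = heterogeneity_summary([crosses_1, crosses_50])
        assert summary["n_crossing_category"] == 2
        assert summary["n_crossing_1pct"] == 1
        assert summary["n_crossing_50pct"] == 1

    def test_synthetic_cohort_matches_truth_recount(self, small_phantom):
        _, truth = small_phantom
        prof = depth_profile(truth.cells, depth_um=truth.depth_um, bin_um=5.0)
        summary = heterogeneity_summary([prof])
        vals = [
            100.0 * p / t for t, p in truth_bin_counts(truth, 5.0).values() if t > 0
        ]
        assert summary["mean_max_minus_min"] == pytest.approx(max(vals) - min(vals))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_summary([])
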