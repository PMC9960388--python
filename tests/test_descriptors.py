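"""Descriptor curation: scaling, replicate-stability filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnlri import (
    DescriptorTable,
    apply_curation,
    minmax_scale,
    stability_filter,
)


def table(values: dict, compounds=None, replicate_id=None):
    frame = pd.DataFrame(values)
    frame.index = pd.Index(compounds or [f"c{i}" for i in range(len(frame))])
    return DescriptorTable(frame, replicate_id=replicate_id)


class TestMinMaxScale:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([0.0, 5.0, 10.0], [0.0, 0.5, 1.0]),
            ([-2.0, 0.0, 2.0], [0.0, 0.5, 1.0]),
        ],
    )
    def test_maps_to_unit_interval(self, column, expected):
        scaled, params = minmax_scale(table({"d": column}))
        assert scaled.frame["d"].tolist() == pytest.approx(expected)
        assert params["d"] == (min(column), max(column))

    def test_constant_column_maps_to_zero(self):
        scaled, params = minmax_scale(table({"d": [3.0, 3.0, 3.0]}))
        assert scaled.frame["d"].tolist() == [0.0, 0.0, 0.0]
        assert params["d"] == (3.0, 3.0)

    def test_fitted_extremes_map_to_0_and_1(self):
        rng = np.random.default_rng(0)
        t = table({f"d{j}": rng.normal(size=20) for j in range(5)})
        scaled, _ = minmax_scale(t)
        for col in scaled.frame:
            assert scaled.frame[col].min() == pytest.approx(0.0, abs=1e-12)
            assert scaled.frame[col].max() == pytest.approx(1.0, abs=1e-12)

    def test_all_missing_column_errors(self):
        with pytest.raises(ValueError, match="bad"):
            minmax_scale(table({"bad": [np.nan, np.nan]}))


class TestStabilityFilter:
    def test_identical_replicates_all_kept(self):
        t = table({"a": [0.0, 1.0, 2.0], "b": [5.0, 6.0, 7.0]})
        report = stability_filter([t, t, t])
        assert report.kept == ["a", "b"]
        assert report.dropped_unstable == {}

    def test_hand_computed_variance_drops_descriptor(self):
        # one compound, scaled replicate values (0, 1, 0):
        # sample variance = ((0-1/3)^2 + (2/3)^2 + (1/3)^2) / 2 = 1/3 > 0.01
        reps = [
            table({"d": [0.0]}, ["c0"]),
            table({"d": [1.0]}, ["c0"]),
            table({"d": [0.0]}, ["c0"]),
        ]
        report = stability_filter(reps)
        assert report.kept == []
        assert report.dropped_unstable["d"] == pytest.approx(1 / 3)

    def test_threshold_is_strict(self):
        # scaled values (0, 1, 0.5) -> sample variance exactly 0.25;
        # at threshold 0.25 the descriptor must still be dropped
        reps = [
            table({"d": [0.0]}, ["c0"]),
            table({"d": [1.0]}, ["c0"]),
            table({"d": [0.5]}, ["c0"]),
        ]
        report = stability_filter(reps, threshold=0.25)
        assert "d" in report.dropped_unstable
        assert stability_filter(reps, threshold=0.25 + 1e-9).kept == ["d"]

    def test_mismatched_compounds_error_lists_difference(self):
        a = table({"d": [1.0, 2.0]}, ["c0", "c1"])
        b = table({"d": [1.0, 2.0]}, ["c0", "c2"])
        with pytest.raises(ValueError, match="c1"):
            stability_filter([a, b])

    def test_partition_property(self, small_world):
        report = stability_filter(small_world.replicate_tables)
        all_names = set(small_world.replicate_tables[0].descriptors)
        assert set(report.kept) | set(report.dropped_unstable) | set(
            report.dropped_nonfinite
        ) == all_names
        assert not set(report.kept) & set(report.dropped_unstable)

    def test_designed_unstable_descriptors_dropped(self, small_world):
        report = stability_filter(small_world.replicate_tables, threshold=0.01)
        assert set(report.dropped_unstable) == set(small_world.unstable_descriptors)

    def test_nonconverged_compounds_dropped_rowwise(self):
        a = table({"d": [1.0, np.nan, 3.0], "e": [0.0, 1.0, 2.0]})
        b = table({"d": [1.0, 2.0, 3.0], "e": [0.0, 1.0, 2.0]})
        report = stability_filter([a, b])
        assert report.dropped_compounds == ["c1"]
        assert set(report.kept) == {"d", "e"}

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_filter_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        reps = [
            table({f"d{j}": rng.normal(size=6) for j in range(8)}) for _ in range(3)
        ]
        lo = stability_filter(reps, threshold=0.005)
        hi = stability_filter(reps, threshold=0.05)
        assert set(lo.kept) <= set(hi.kept)


class TestApplyCuration:
    @pytest.fixture
    def report(self):
        reps = [
            table({"d": [0.0, 10.0], "e": [1.0, 2.0]}),
            table({"d": [0.0, 10.0], "e": [1.0, 2.0]}),
        ]
        return stability_filter(reps)

    def test_out_of_range_values_not_clipped(self, report):
        new = table({"d": [20.0], "e": [1.5]}, ["x"])
        curated = apply_curation(new, report)
        assert curated.frame.loc["x", "d"] == pytest.approx(2.0)

    def test_missing_kept_column_errors(self, report):
        with pytest.raises(ValueError, match="e"):
            apply_curation(table({"d": [1.0]}), report)

    def test_idempotent_on_training_replicate(self, small_world):
        report = stability_filter(small_world.replicate_tables)
        rep1 = small_world.replicate_tables[0]
        once = apply_curation(rep1, report)
        twice = apply_curation(rep1, report)
        pd.testing.assert_frame_equal(once.frame, twice.frame)
        assert list(once.frame.columns) == report.kept
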