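"""CNL computation and ternary grid encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnlri import (
    CNLGrid,
    Spectrum,
    build_feature_matrix,
    compute_cnls,
    encode_row,
)


def spec(spectrum_id, precursor, frag_mzs):
    return Spectrum(
        spectrum_id, precursor, tuple((mz, 1.0) for mz in frag_mzs)
    )


def oracle_bin(mass, step=0.01):
    """Independent binning rule: nearest center, floor at half-step."""
    return int(np.floor(mass / step + 0.5))


class TestComputeCnls:
    def test_losses_are_precursor_minus_fragment(self):
        c = compute_cnls(spec("s", 200.0, [182.0, 100.0]))
        assert sorted(c.losses) == pytest.approx([18.0, 100.0])
        assert c.n_excluded == 0

    def test_water_loss_collapses_to_single_value(self):
        # fragments of different precursors give the same 18 Da loss variable
        a = compute_cnls(spec("a", 300.0, [282.0]))
        b = compute_cnls(spec("b", 500.0, [482.0]))
        assert a.losses == pytest.approx((18.0,))
        assert b.losses == pytest.approx((18.0,))

    def test_fragment_above_precursor_excluded_and_counted(self):
        c = compute_cnls(spec("s", 200.0, [210.0, 150.0]))
        assert c.losses == pytest.approx((50.0,))
        assert c.n_excluded == 1

    def test_empty_fragment_list_rejected(self):
        with pytest.raises(ValueError):
            compute_cnls(Spectrum("s", 200.0, ()))

    def test_zero_loss_is_valid(self):
        c = compute_cnls(spec("s", 200.0, [200.0]))
        assert c.losses == pytest.approx((0.0,))


class TestEncodeRow:
    def test_grid_has_exactly_100000_bins(self):
        assert CNLGrid().n_bins == 100_000

    def test_loss_18_lands_in_bin_1800(self):
        row = encode_row(compute_cnls(spec("s", 300.0, [282.0])))
        assert row.one_bins == (1800,)
        assert row.vector[1800] == 1

    def test_losses_within_tolerance_share_a_bin(self):
        # 18.000 and 18.004 are both within 5 mDa of the 18.00 center
        a = encode_row(compute_cnls(spec("a", 300.0, [282.000])))
        b = encode_row(compute_cnls(spec("b", 300.0, [281.996])))
        assert a.one_bins == b.one_bins == (1800,)

    def test_impossible_region_count_for_precursor_250(self):
        """Brute-force scan: bins with center > 250.00 Da are -1."""
        row = encode_row(compute_cnls(spec("s", 250.0, [100.0])))
        v = row.vector
        centers = np.arange(100_000) * 0.01
        assert np.array_equal(np.flatnonzero(v == -1), np.flatnonzero(centers > 250.0))
        assert int((v == -1).sum()) == 100_000 - (25_000 + 1)

    def test_empty_loss_set_gives_no_ones(self):
        grid = CNLGrid()
        from cnlri.cnl import CNLSet

        row = encode_row(CNLSet("s", 500.0, ()), grid)
        v = row.vector
        assert not (v == 1).any()
        assert (v[: 50_001] == 0).all()

    def test_offgrid_loss_dropped_with_count(self):
        row = encode_row(compute_cnls(spec("s", 1500.0, [100.0, 1400.0])))
        assert row.n_offgrid == 1
        assert row.one_bins == (oracle_bin(100.0),)

    def test_precursor_mass_feature_carried(self):
        row = encode_row(compute_cnls(spec("s", 321.25, [100.0])))
        assert row.precursor_mass_feature == 321.25

    @settings(max_examples=100, deadline=None)
    @given(
        precursor=st.floats(50.0, 999.0),
        losses=st.lists(st.floats(0.0, 49.0), min_size=1, max_size=8),
    )
    def test_ternary_closure_and_disjointness(self, precursor, losses):
        """Every entry is in {-1,0,1}; a loss bin is never in the -1 band;
        the -1 band depends only on the precursor."""
        frags = [precursor - l for l in losses]
        v = encode_row(compute_cnls(spec("s", precursor, frags))).vector
        assert set(np.unique(v)) <= {-1, 0, 1}
        other = encode_row(compute_cnls(spec("t", precursor, [precursor]))).vector
        assert np.array_equal(v == -1, other == -1)

    @settings(max_examples=100, deadline=None)
    @given(
        k=st.integers(0, 99_998),
        eps=st.floats(-0.00499, 0.00499),
    )
    def test_tolerance_property(self, k, eps):
        """A loss within 5 mDa of a center maps to that center's bin."""
        grid = CNLGrid()
        mass = k * 0.01 + eps
        if mass < 0:
            mass = 0.0
        assert grid.bin_index(mass) == k or abs(mass - k * 0.01) > 0.005 - 1e-9


class TestFeatureMatrix:
    def test_shape_and_column_contract(self):
        spectra = [spec(f"s{i}", 200.0 + i, [150.0, 100.0]) for i in range(3)]
        m = build_feature_matrix(spectra)
        assert m.n_rows == 3
        assert m.n_columns == 100_001

    def test_duplicate_spectra_give_identical_rows(self):
        s = spec("dup", 250.0, [232.0, 100.0])
        dup = Spectrum("dup2", s.precursor_mz, s.fragments)
        m = build_feature_matrix([s, dup])
        assert m.n_rows == 2
        assert np.array_equal(m.row(0).vector, m.row(1).vector)

    def test_row_sum_matches_independent_binning_oracle(self):
        # off-boundary losses: exact half-step ties follow the documented
        # round-half-to-even rule and are not probed by this oracle
        losses = [18.011, 46.006, 56.063, 65.97, 155.00]
        s = spec("s", 400.0, [400.0 - l for l in losses])
        m = build_feature_matrix([s])
        expected_bins = sorted({oracle_bin(l) for l in losses})
        assert list(m.row(0).one_bins) == expected_bins
        assert int((m.row(0).vector == 1).sum()) == 5

    def test_rejected_spectra_listed_not_silent(self):
        good = spec("good", 200.0, [150.0])
        bad = Spectrum("bad", 200.0, ())
        with pytest.raises(ValueError, match="bad"):
            build_feature_matrix([good, bad])
        m = build_feature_matrix([good, bad], skip_invalid=True)
        assert m.rejected == ["bad"]
        assert m.n_rows == 1

    def test_encoding_is_deterministic(self):
        s = spec("s", 321.5, [300.0, 250.123, 100.009])
        a = encode_row(compute_cnls(s))
        b = encode_row(compute_cnls(s))
        assert a == b

    def test_export_load_roundtrip(self, tmp_path):
        spectra = [spec(f"s{i}", 300.0 + i, [282.0 + i, 150.0]) for i in range(4)]
        m = build_feature_matrix(spectra)
        m.export(tmp_path / "mat")
        from cnlri.cnl import CNLFeatureMatrix

        back = CNLFeatureMatrix.load(tmp_path / "mat")
        assert back.n_rows == m.n_rows
        assert np.array_equal(back.ones.toarray(), m.ones.toarray())
        assert np.array_equal(back.neg_start, m.neg_start)
        assert back.spectrum_ids == m.spectrum_ids

    def test_model_frame_ternary_values(self):
        s1 = spec("s1", 100.0, [82.0])   # loss 18, short -1 band start
        s2 = spec("s2", 500.0, [350.0])  # loss 150
        frame = build_feature_matrix([s1, s2]).to_model_frame()
        assert frame.loc["s1", "cnl_01800"] == 1
        # bin 15000 (150 Da) exceeds s1's precursor of 100 -> impossible
        assert frame.loc["s1", "cnl_15000"] == -1
        assert frame.loc["s2", "cnl_15000"] == 1
        assert frame.loc["s2", "cnl_01800"] == 0
        assert frame.loc["s2", "precursor_mz"] == 500.0
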