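import numpy as np
import pytest

from upffs.dfcn import (
    DFCN,
    RoiTimeSeries,
    SlidingWindowSpec,
    build_ho_dfcn,
    build_lo_dfcn,
    fc_sequence,
    sliding_windows,
)


def brute_force_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook cov / (sigma * sigma) with population normalization."""
    am, bm = a - a.mean(), b - b.mean()
    return float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "t, w, s, expected_k, first, last",
        [
            (100, 60, 2, 21, (0, 60), (40, 100)),
            (60, 60, 10, 1, (0, 60), (0, 60)),
            (145, 60, 10, 9, (0, 60), (80, 140)),
        ],
    )
    def test_window_count_and_bounds(self, t, w, s, expected_k, first, last):
        wins = sliding_windows(t, SlidingWindowSpec(w, s))
        assert len(wins) == expected_k
        assert wins[0] == first and wins[-1] == last
        assert all(b - a == w for a, b in wins)

    def test_series_shorter_than_window_errors(self):
        with pytest.raises(ValueError, match="shorter than window"):
            sliding_windows(59, SlidingWindowSpec(60, 2))

    def test_count_formula_matches_enumeration_over_grid(self):
        for t in (60, 61, 100, 137, 200):
            for w in (2, 10, 60):
                for s in (1, 2, 10, 17):
                    if t < w:
                        continue
                    starts = [m for m in range(0, t) if m % s == 0 and m + w <= t]
                    wins = sliding_windows(t, SlidingWindowSpec(w, s))
                    assert len(wins) == (t - w) // s + 1 == len(starts)
                    assert [a for a, _ in wins] == starts


class TestLoDfcn:
    def test_matches_per_window_pearson_oracle(self, rng):
        ts = RoiTimeSeries("s", rng.standard_normal((80, 3)))
        spec = SlidingWindowSpec(20, 7)
        lo = build_lo_dfcn(ts, spec)
        for k, (a, b) in enumerate(sliding_windows(80, spec)):
            seg = ts.data[a:b]
            for i in range(3):
                for j in range(3):
                    expected = 1.0 if i == j else brute_force_pearson(seg[:, i], seg[:, j])
                    assert lo.tensor[k, i, j] == pytest.approx(expected, abs=1e-10)

    def test_identical_columns_give_unit_correlation(self, rng):
        col = rng.standard_normal(50)
        ts = RoiTimeSeries("s", np.column_stack([col, col]))
        lo = build_lo_dfcn(ts, SlidingWindowSpec(10, 5))
        assert np.allclose(lo.tensor, 1.0)

    def test_full_series_window_reduces_to_static_network(self, rng):
        data = rng.standard_normal((40, 4))
        lo = build_lo_dfcn(RoiTimeSeries("s", data), SlidingWindowSpec(40, 1))
        assert lo.n_windows == 1
        assert np.allclose(lo.tensor[0], np.corrcoef(data, rowvar=False), atol=1e-12)

    def test_zero_variance_column_names_window_and_roi(self, rng):
        data = rng.standard_normal((30, 3))
        data[10:20, 1] = 5.0  # constant inside the second window
        with pytest.raises(ValueError, match=r"\[1\].*window 1"):
            build_lo_dfcn(RoiTimeSeries("s", data), SlidingWindowSpec(10, 10))

    def test_slices_symmetric_bounded(self, small_lo):
        assert np.max(np.abs(small_lo.tensor - small_lo.tensor.transpose(0, 2, 1))) == 0.0
        assert np.all(small_lo.tensor >= -1.0) and np.all(small_lo.tensor <= 1.0)

    def test_periodic_series_gives_identical_slices(self):
        base = np.sin(np.arange(10)[:, None] * np.array([1.0, 2.0, 3.0]))
        data = np.tile(base, (6, 1))  # period 10
        lo = build_lo_dfcn(RoiTimeSeries("s", data), SlidingWindowSpec(20, 10))
        assert np.allclose(lo.tensor, lo.tensor[0])

    def test_fisher_z_flag_transforms_off_diagonal(self, gaussian_ts):
        spec = SlidingWindowSpec(20, 10)
        raw = build_lo_dfcn(gaussian_ts, spec)
        z = build_lo_dfcn(gaussian_ts, spec, fisher_z=True)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(z.tensor[:, off], np.arctanh(raw.tensor[:, off]), atol=1e-9)


class TestHoDfcn:
    def test_matches_profile_correlation_oracle(self, small_lo):
        ho = build_ho_dfcn(small_lo)
        m = small_lo.n_rois
        for k in range(small_lo.n_windows):
            r = small_lo.tensor[k]
            for i in range(m):
                for j in range(i + 1, m):
                    mask = [x for x in range(m) if x not in (i, j)]
                    expected = brute_force_pearson(r[i, mask], r[j, mask])
                    assert ho.tensor[k, i, j] == pytest.approx(expected, abs=1e-10)

    def test_identical_profiles_give_plus_one_and_negated_minus_one(self):
        # hand-built symmetric slice where ROIs 0 and 1 have identical
        # profiles over ROIs {2,3,4}, and ROIs 2,3 have exactly negated ones
        r = np.eye(5)
        prof = np.array([0.5, -0.2, 0.3])
        r[0, 2:], r[1, 2:] = prof, prof
        r[2, [0, 1, 4]] = np.array([0.5, 0.1, 0.6])
        r[3, [0, 1, 4]] = -r[2, [0, 1, 4]]
        r = np.triu(r, 1) + np.triu(r, 1).T + np.eye(5)
        lo = DFCN("lo", r[None], SlidingWindowSpec(10, 1))
        ho = build_ho_dfcn(lo)
        assert ho.tensor[0, 0, 1] == pytest.approx(1.0)
        assert ho.tensor[0, 2, 3] == pytest.approx(-1.0)

    def test_zero_variance_profile_set_to_zero(self, caplog):
        r = np.full((5, 5), 0.3)
        np.fill_diagonal(r, 1.0)  # every profile is constant
        lo = DFCN("lo", r[None], SlidingWindowSpec(10, 1))
        ho = build_ho_dfcn(lo)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(ho.tensor[0][off], 0.0)

    def test_commutes_with_roi_relabeling(self, small_lo, rng):
        perm = rng.permutation(small_lo.n_rois)
        permuted_lo = DFCN(
            "lo", small_lo.tensor[:, perm][:, :, perm], small_lo.window_spec
        )
        ho = build_ho_dfcn(small_lo)
        ho_perm = build_ho_dfcn(permuted_lo)
        assert np.allclose(ho_perm.tensor, ho.tensor[:, perm][:, :, perm], atol=1e-12)

    def test_requires_lo_kind_and_min_size(self, small_lo):
        ho = build_ho_dfcn(small_lo)
        with pytest.raises(ValueError, match="low-order"):
            build_ho_dfcn(ho)
        tiny = DFCN("lo", np.eye(4)[None], SlidingWindowSpec(10, 1))
        with pytest.raises(ValueError, match="M >= 5"):
            build_ho_dfcn(tiny)


class TestFCSequence:
    def test_symmetric_request_and_tensor_slice(self, small_lo):
        fwd = fc_sequence(small_lo, 1, 3)
        rev = fc_sequence(small_lo, 3, 1)
        assert fwd.unit == rev.unit == (1, 3)
        assert np.array_equal(fwd.values, rev.values)
        assert np.array_equal(fwd.values, small_lo.tensor[:, 1, 3])

    def test_single_window_sequence_is_static_edge(self, rng):
        data = rng.standard_normal((30, 3))
        lo = build_lo_dfcn(RoiTimeSeries("s", data), SlidingWindowSpec(30, 1))
        seq = fc_sequence(lo, 0, 2)
        assert len(seq) == 1
        assert seq.values[0] == pytest.approx(np.corrcoef(data[:, 0], data[:, 2])[0, 1])

    def test_diagonal_is_not_a_unit(self, small_lo):
        with pytest.raises(ValueError, match="i != j"):
            fc_sequence(small_lo, 2, 2)
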