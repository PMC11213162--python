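"""Taper construction, sliding-window FC against its brute-force oracle, and
the group rank-sum sparsification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfcband.dynfc import (FCMatrix, build_taper, edge_rank_tests,
                           group_sparse_adjacency, sliding_window_fc)
from gfcband.synthetic import SubjectTimeSeries

from .oracles import ranksum_p, sliding_window_median_fc


class TestTaper:
    def test_default_shape(self):
        """Rectangle 50 convolved with a +/-4-sigma Gaussian (sigma 3) gives
        a unimodal symmetric window of length 74."""
        taper = build_taper(50, 3.0)
        w = taper.weights
        assert taper.width == 50 + 2 * 12
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        peak = np.argmax(w)
        assert np.all(np.diff(w[:peak + 1]) >= -1e-15)
        assert np.all(np.diff(w[peak:]) <= 1e-15)

    def test_delta_kernel_limit_recovers_rectangle(self):
        w = build_taper(50, 1e-6).weights
        inner = w[w > 1e-9]
        assert inner.size == 50
        np.testing.assert_allclose(inner, 1.0 / 50, atol=1e-9)

    @given(st.integers(2, 80), st.floats(0.2, 8.0))
    @settings(max_examples=30, deadline=None)
    def test_normalization(self, width, sigma):
        assert build_taper(width, sigma).weights.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("kwargs", [dict(rect_width=1), dict(gauss_sigma=0.0)])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            build_taper(**{"rect_width": 50, "gauss_sigma": 3.0, **kwargs})


class TestSlidingWindowFC:
    def test_identical_rois_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        data = np.vstack([base, base, rng.normal(size=100)])
        fc = sliding_window_fc(data, build_taper(20, 2.0))
        assert fc.values[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=100)
        data = np.vstack([base, -base])
        fc = sliding_window_fc(data, build_taper(20, 2.0))
        assert fc.values[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_brute_force_oracle(self):
        """T=135, W=74, shift 1: 62 windows; median FC equals an explicit
        loop over windows with the scalar weighted-correlation formula."""
        rng = np.random.default_rng(42)
        data = rng.normal(size=(3, 135))
        taper = build_taper(50, 3.0)
        assert (135 - taper.width) // 1 + 1 == 62
        fc = sliding_window_fc(data, taper)
        expected = sliding_window_median_fc(data, taper.weights)
        np.testing.assert_allclose(fc.values, expected, atol=1e-10)

    @pytest.mark.parametrize("shift", [1, 3])
    def test_oracle_equivalence_various_sizes(self, shift):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(5, 90))
        taper = build_taper(12, 1.5)
        fc = sliding_window_fc(data, taper, shift=shift)
        expected = sliding_window_median_fc(data, taper.weights, shift=shift)
        np.testing.assert_allclose(fc.values, expected, atol=1e-10)

    def test_median_within_per_window_bounds(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(4, 80))
        taper = build_taper(15, 2.0)
        fc = sliding_window_fc(data, taper)
        width = taper.width
        from .oracles import weighted_corr
        for i in range(4):
            for j in range(i + 1, 4):
                per_window = [weighted_corr(data[i, s:s + width],
                                            data[j, s:s + width], taper.weights)
                              for s in range(80 - width + 1)]
                assert min(per_window) - 1e-12 <= fc.values[i, j] <= max(per_window) + 1e-12

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_window_fc(np.zeros((3, 10)) + np.arange(10), build_taper(20, 2.0))

    def test_zero_variance_roi_policy(self):
        data = np.vstack([np.ones(60), np.random.default_rng(0).normal(size=60)])
        taper = build_taper(10, 1.0)
        with pytest.raises(ValueError, match="no valid window"):
            sliding_window_fc(data, taper)
        fc = sliding_window_fc(data, taper, undefined="zero")
        assert fc.values[0, 1] == 0.0


def _fc_list(values, band="ffb"):
    return [FCMatrix(values=v, band=band, subject_id=f"s{i}")
            for i, v in enumerate(values)]


def _random_fcs(n, m, rng, loc=0.0):
    out = []
    for _ in range(n):
        a = np.triu(np.tanh(rng.normal(loc, 0.3, size=(m, m))), k=1)
        out.append(a + a.T)
    return out


class TestGroupSparseAdjacency:
    def test_identical_groups_give_empty_mask(self):
        rng = np.random.default_rng(0)
        vals = _random_fcs(4, 5, rng)
        mask, _ = group_sparse_adjacency(_fc_list(vals), _fc_list(vals))
        assert not mask.any()

    def test_planted_edge_detected(self):
        """Group means r = 0.6 vs 0.0 (sd 0.1) at one edge, n = 20/20."""
        rng = np.random.default_rng(1)
        m = 6
        a_vals, b_vals = [], []
        for _ in range(20):
            base = np.triu(rng.normal(0, 0.1, size=(m, m)), k=1)
            a = base.copy()
            a[0, 1] += 0.6
            a_vals.append(np.clip(a + a.T, -1, 1))
            b = np.triu(rng.normal(0, 0.1, size=(m, m)), k=1)
            b_vals.append(np.clip(b + b.T, -1, 1))
        mask, adjs = group_sparse_adjacency(_fc_list(a_vals), _fc_list(b_vals))
        assert mask[0, 1]
        # cross-check the p-value machinery against a hand-rolled rank-sum
        pmat = edge_rank_tests(_fc_list(a_vals), _fc_list(b_vals))
        x = np.array([v[0, 1] for v in a_vals])
        y = np.array([v[0, 1] for v in b_vals])
        assert pmat[0, 1] == pytest.approx(ranksum_p(x, y), abs=1e-10)

    def test_rank_sum_matches_oracle_on_random_edges(self):
        rng = np.random.default_rng(2)
        a_vals = _random_fcs(8, 5, rng)
        b_vals = _random_fcs(9, 5, rng, loc=0.2)
        pmat = edge_rank_tests(_fc_list(a_vals), _fc_list(b_vals))
        for i in range(5):
            for j in range(i + 1, 5):
                x = np.array([v[i, j] for v in a_vals])
                y = np.array([v[i, j] for v in b_vals])
                assert pmat[i, j] == pytest.approx(ranksum_p(x, y), abs=1e-10)

    def test_masks_shared_and_values_subject_specific(self):
        rng = np.random.default_rng(3)
        a_vals = _random_fcs(6, 5, rng)
        b_vals = _random_fcs(6, 5, rng, loc=0.4)
        mask, adjs = group_sparse_adjacency(_fc_list(a_vals), _fc_list(b_vals),
                                            alpha=0.5)
        assert mask.any()
        for adj in adjs:
            np.testing.assert_array_equal(adj.mask, mask)
            assert np.all(adj.values[~mask] == 0)
        assert not np.array_equal(adjs[0].values, adjs[1].values)

    def test_small_groups_rejected(self):
        rng = np.random.default_rng(4)
        vals = _random_fcs(3, 4, rng)
        with pytest.raises(ValueError, match="at least 2"):
            group_sparse_adjacency(_fc_list(vals[:1]), _fc_list(vals[1:]))


class TestFCMatrixContracts:
    def test_asymmetric_rejected(self):
        bad = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            FCMatrix(values=bad)

    def test_diagonal_zeroed(self):
        v = np.array([[1.0, 0.2], [0.2, 1.0]])
        fc = FCMatrix(values=v)
        assert np.all(np.diag(fc.values) == 0)
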