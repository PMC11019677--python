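"""Percentile normalizer, coordinate grids, plane selection, subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sirenstack.preprocessing import (CoordinateSample, NormalizationParams,
                                      apply_normalizer, fit_normalizer,
                                      invert_normalizer, make_grid,
                                      select_planes, subsample_pixels)
from sirenstack.stacks import ImageStack


class TestNormalizer:
    def test_constant_stack_maps_to_zero(self):
        stack = ImageStack(np.full((3, 8, 8), 7.0))
        params = fit_normalizer(stack)
        out = apply_normalizer(stack, params)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_percentiles_match_sorted_array_oracle(self, rng):
        values = rng.uniform(0, 1000, size=(4, 16, 16))
        params = fit_normalizer(ImageStack(values))
        # independent oracle: linear-interpolated percentile on sorted copy
        flat = np.sort(values.ravel())
        for q, got in [(2.0, params.p_low_value), (99.9, params.p_high_value)]:
            pos = q / 100 * (flat.size - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expect = flat[lo] + (pos - lo) * (flat[hi] - flat[lo])
            assert got == pytest.approx(expect, rel=1e-12)

    def test_no_clipping_outside_unit_interval(self, rng):
        values = rng.normal(0, 1, size=(3, 32, 32))
        params = fit_normalizer(ImageStack(values))
        out = apply_normalizer(ImageStack(values), params)
        assert out.data.min() < 0          # values below P2 go negative
        assert out.data.max() > 1.0        # values above P99.9 exceed 1

    def test_apply_invert_round_trip(self, rng):
        values = rng.uniform(0, 500, size=(3, 16, 16))
        params = fit_normalizer(ImageStack(values))
        back = invert_normalizer(apply_normalizer(ImageStack(values), params),
                                 params)
        assert np.max(np.abs(back.data - values)) < 1e-6 * values.max()

    def test_identity_params(self):
        params = NormalizationParams(0.0, 1.0)
        x = np.array([[[0.25, 0.75]]])
        out = apply_normalizer(ImageStack(x), params)
        np.testing.assert_allclose(out.data, x, rtol=1e-12)

    def test_high_percentile_maps_to_one(self, rng):
        values = rng.uniform(0, 10, size=(2, 16, 16))
        params = fit_normalizer(ImageStack(values))
        y = np.array([[[params.p_high_value]]])
        out = apply_normalizer(ImageStack(y), params)
        assert out.data.ravel()[0] == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_order_preserving(self, seed):
        values = np.random.default_rng(seed).uniform(0, 100, size=256)
        params = fit_normalizer(values.reshape(4, 8, 8))
        out = apply_normalizer(values, params)
        order = np.argsort(values)
        assert np.all(np.diff(out[order]) >= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NormalizationParams(2.0, 1.0)
        with pytest.raises(ValueError):
            NormalizationParams(0.0, 1.0, epsilon=0.0)


class TestMakeGrid:
    def test_2x2x2_endpoints(self):
        coords = make_grid((2, 2, 2))
        expect = {(-1.0, -1.0, -1.0), (-1.0, -1.0, 1.0), (-1.0, 1.0, -1.0),
                  (-1.0, 1.0, 1.0), (1.0, -1.0, -1.0), (1.0, -1.0, 1.0),
                  (1.0, 1.0, -1.0), (1.0, 1.0, 1.0)}
        assert {tuple(c) for c in coords} == expect

    def test_degenerate_z_axis_maps_to_zero(self):
        coords = make_grid((1, 3, 3))
        assert np.all(coords[:, 0] == 0.0)

    def test_full_frame_z_coordinate_shared(self):
        # 20-plane stack: plane 10 must get the same z-coordinate whether it
        # appears in a training grid or a prediction grid
        train = make_grid((10, 2, 2), z_indices=np.arange(0, 20, 2),
                          n_z_total=20)
        pred = make_grid((1, 2, 2), z_indices=[10], n_z_total=20)
        expect = 10 / 19 * 2 - 1
        assert pred[0, 0] == pytest.approx(expect, abs=1e-7)
        z_vals = np.unique(train[:, 0])
        assert z_vals[5] == pytest.approx(expect, abs=1e-7)

    def test_affine_inverse_recovers_indices(self):
        nz, ny, nx = 5, 7, 9
        coords = make_grid((nz, ny, nx)).reshape(nz, ny, nx, 3)
        iz = np.round((coords[..., 0] + 1) / 2 * (nz - 1)).astype(int)
        assert np.array_equal(iz, np.broadcast_to(
            np.arange(nz)[:, None, None], (nz, ny, nx)))


class TestSelectPlanes:
    def test_skip1_n20_enumeration(self):
        sel = select_planes(20, 1)
        assert list(sel.train_plane_indices) == list(range(0, 20, 2))
        assert list(sel.held_out_plane_indices) == list(range(1, 18, 2))
        assert list(sel.trailing_plane_indices) == [19]

    def test_skip0_trains_all(self):
        sel = select_planes(10, 0)
        assert list(sel.train_plane_indices) == list(range(10))
        assert len(sel.held_out_plane_indices) == 0

    def test_skip7_n17_enumeration(self):
        sel = select_planes(17, 7)
        assert list(sel.train_plane_indices) == [0, 8, 16]
        assert list(sel.held_out_plane_indices) == \
            list(range(1, 8)) + list(range(9, 16))

    def test_partition_property(self):
        for n, skip in [(20, 1), (17, 7), (23, 3), (11, 2)]:
            sel = select_planes(n, skip)
            union = np.concatenate([sel.train_plane_indices,
                                    sel.held_out_plane_indices,
                                    sel.trailing_plane_indices])
            assert sorted(union) == list(range(n))
            diffs = np.diff(sel.train_plane_indices)
            assert np.all(diffs == skip + 1)

    def test_too_few_planes_rejected(self):
        with pytest.raises(ValueError):
            select_planes(8, 7)

    def test_large_skip_warns(self):
        with pytest.warns(UserWarning):
            select_planes(30, 9)


class TestSubsample:
    def _sample(self, n=1000):
        coords = make_grid((10, 10, 10))
        return CoordinateSample(coords, np.arange(n, dtype=float), (10, 10, 10))

    def test_fraction_one_is_identity_as_set(self):
        s = self._sample()
        out = subsample_pixels(s, 1.0, seed=0)
        assert len(out) == len(s)
        assert set(out.targets.ravel()) == set(s.targets.ravel())

    def test_half_fraction_is_exact_subset(self):
        s = self._sample()
        out = subsample_pixels(s, 0.5, seed=1)
        assert len(out) == 500
        assert set(out.targets.ravel()) <= set(s.targets.ravel())

    def test_seed_determinism_and_overlap(self):
        s = self._sample()
        a = subsample_pixels(s, 0.5, seed=2)
        a2 = subsample_pixels(s, 0.5, seed=2)
        np.testing.assert_array_equal(a.targets, a2.targets)
        b = subsample_pixels(s, 0.5, seed=3)
        overlap = len(set(a.targets.ravel()) & set(b.targets.ravel()))
        # hypergeometric: E = 250, sd ~ 11; allow 5 sd
        assert abs(overlap - 250) < 56

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            subsample_pixels(self._sample(), 0.0, seed=0)
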