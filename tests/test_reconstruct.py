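"""Heat-map binarization and 3D reconstruction by back-projection."""

import numpy as np
import pytest

from petcam import PetVolume, dice
from petcam.phantom import _gaussian_blob, gt_mask_from_component, tumor_bounding_cuboid
from petcam.reconstruct import (
    TumorMask3D,
    binarize_heatmap,
    reconstruct_3d,
    refine_by_suv,
)

RNG = np.random.default_rng(41)


class TestBinarize:
    def test_matches_bruteforce_threshold(self):
        h = RNG.random((10, 8))
        mask = binarize_heatmap(h, 0.5, keep_largest=False)
        oracle = np.zeros_like(h, dtype=bool)
        for r in range(10):
            for c in range(8):
                oracle[r, c] = h[r, c] >= 0.5 * h.max()
        np.testing.assert_array_equal(mask, oracle)

    def test_constant_positive_map_gives_all_ones(self):
        mask = binarize_heatmap(np.full((5, 5), 0.3), 0.4)
        assert mask.all()

    def test_threshold_near_one_shrinks_to_peak(self):
        h = RNG.random((6, 6))
        h[2, 3] = 2.0
        mask = binarize_heatmap(h, 0.999)
        assert mask.sum() == 1 and mask[2, 3]

    def test_all_zero_map_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="all-zero"):
            mask = binarize_heatmap(np.zeros((4, 4)), 0.4)
        assert not mask.any()

    def test_keeps_largest_connected_component(self):
        h = np.zeros((8, 8))
        h[0, 0] = 1.0  # single-pixel decoy blob
        h[4:7, 4:7] = 0.9  # larger tumor blob
        mask = binarize_heatmap(h, 0.5)
        assert mask[5, 5] and not mask[0, 0]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="rel_threshold"):
            binarize_heatmap(np.ones((3, 3)), 1.5)


class TestReconstruct3d:
    def test_rectangles_give_cuboid(self):
        nx, ny, nz = 6, 7, 8
        cor = np.zeros((nz, nx), dtype=bool)
        sag = np.zeros((nz, ny), dtype=bool)
        cor[2:5, 1:4] = True
        sag[2:5, 3:6] = True
        out = reconstruct_3d(cor, sag, (nx, ny, nz))
        expected = np.zeros((nx, ny, nz), dtype=bool)
        expected[1:4, 3:6, 2:5] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_empty_view_gives_empty_mask(self):
        cor = np.zeros((8, 6), dtype=bool)
        sag = RNG.random((8, 7)) > 0.5
        assert not reconstruct_3d(cor, sag, (6, 7, 8)).data.any()

    def test_matches_triple_loop_oracle_on_random_masks(self):
        for _ in range(5):
            cor = RNG.random((8, 8)) > 0.6
            sag = RNG.random((8, 8)) > 0.6
            out = reconstruct_3d(cor, sag, (8, 8, 8)).data
            oracle = np.zeros((8, 8, 8), dtype=bool)
            for x in range(8):
                for y in range(8):
                    for z in range(8):
                        oracle[x, y, z] = cor[z, x] and sag[z, y]
            np.testing.assert_array_equal(out, oracle)

    def test_shape_inconsistency_rejected(self):
        with pytest.raises(ValueError, match="coronal"):
            reconstruct_3d(np.zeros((5, 5), bool), np.zeros((8, 7), bool), (6, 7, 8))

    def test_exact_for_cuboid_tumors(self):
        """With the truth's own projections as 2D masks, a cuboid tumor
        is reconstructed with dice exactly 1."""
        truth = np.zeros((10, 11, 12), dtype=bool)
        truth[2:6, 4:9, 3:10] = True
        cor = truth.max(axis=1).T  # (z, x)
        sag = truth.max(axis=0).T  # (z, y)
        out = reconstruct_3d(cor, sag, truth.shape)
        assert dice(out.data, truth) == 1.0

    def test_superset_property_for_convex_blobs(self):
        """The back-projected intersection always contains the true shape
        when the 2D masks contain the true projections."""
        x, y, z = np.ogrid[:12, :12, :12]
        truth = ((x - 6) ** 2 / 9 + (y - 5) ** 2 / 4 + (z - 6) ** 2 / 16) <= 1.0
        out = reconstruct_3d(truth.max(axis=1).T, truth.max(axis=0).T, truth.shape)
        assert np.all(out.data[truth])  # superset
        assert out.data.sum() >= truth.sum()


class TestRefineBySuv:
    def _blob_volume(self):
        shape = (20, 20, 24)
        center, sigma = (9.5, 10.2, 12.0), (3.0, 2.5, 3.5)
        tumor = _gaussian_blob(shape, center, sigma, amplitude=10.0)
        return PetVolume(tumor, (2.0, 2.0, 2.0)), center, sigma

    def test_uniform_region_unchanged(self):
        vol = PetVolume(np.ones((6, 6, 6)), (2.0, 2.0, 2.0))
        mask = TumorMask3D(np.zeros((6, 6, 6), bool))
        mask.data[1:4, 1:4, 1:4] = True
        out = refine_by_suv(mask, vol)
        np.testing.assert_array_equal(out.data, mask.data)

    def test_idempotent(self):
        vol, _, _ = self._blob_volume()
        mask = TumorMask3D(vol.data > 0.1)
        once = refine_by_suv(mask, vol)
        twice = refine_by_suv(once, vol)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_gaussian_tumor_matches_40pct_oracle_within_prism(self):
        vol, center, sigma = self._blob_volume()
        prism = np.zeros(vol.shape, dtype=bool)
        prism[4:16, 5:16, 5:20] = True
        refined = refine_by_suv(TumorMask3D(prism), vol)
        peak = vol.data[prism].max()
        oracle = prism & (vol.data >= 0.4 * peak)
        np.testing.assert_array_equal(refined.data, oracle)

    def test_empty_mask_warns_and_returns_unchanged(self):
        vol = PetVolume(np.ones((4, 4, 4)), (2.0, 2.0, 2.0))
        empty = TumorMask3D(np.zeros((4, 4, 4), bool))
        with pytest.warns(UserWarning, match="empty"):
            out = refine_by_suv(empty, vol)
        assert not out.data.any()


def test_mip_mask_reconstruct_roundtrip_on_single_blobs():
    """Project a lone Gaussian tumor to both MIPs, binarize at the default
    threshold, back-project: overlap with the 40% truth stays high."""
    rng = np.random.default_rng(17)
    shape = (24, 24, 32)
    scores = []
    for _ in range(5):
        center = (rng.uniform(8, 16), rng.uniform(8, 16), rng.uniform(12, 20))
        sigma = tuple(rng.uniform(2.5, 4.5, 3))
        blob = _gaussian_blob(shape, center, sigma, amplitude=10.0)
        cuboid = tumor_bounding_cuboid(center, sigma, shape)
        truth = gt_mask_from_component(blob, cuboid)
        vol = PetVolume(blob, (2.0, 2.0, 2.0))
        from petcam import compute_mip

        cor = binarize_heatmap(compute_mip(vol, "coronal").data, 0.4)
        sag = binarize_heatmap(compute_mip(vol, "sagittal").data, 0.4)
        out = reconstruct_3d(cor, sag, shape)
        scores.append(dice(out.data, truth))
    assert np.mean(scores) >= 0.7
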