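"""Astrocyte morphometry: segmentation, Sholl, hulls, counting, vimentin."""

import numpy as np
import pytest

from synastro import morph, synthio


class TestClassify:
    def test_phantom_tube_dice_at_snr_10(self):
        voxel = (0.5, 0.5, 0.5)
        center = (15.0, 55.0, 55.0)
        cell = synthio.CellSpec(center, [np.array([center, (15.0, 55.0, 105.0)])])
        stack, truth = synthio.gen_astro_stack(
            (61, 221, 221), [cell], voxel_um_zyx=voxel, noise_sd=10.0, seed=0
        )
        mask = morph.classify_gfap_pixels(stack)
        tm = truth.cells[0]["mask"]
        dice = 2 * np.logical_and(mask, tm).sum() / (mask.sum() + tm.sum())
        assert dice >= 0.9

    def test_empty_channel_rejected(self):
        stack = morph.AstroStack({"gfap": np.zeros((5, 5, 5))}, (0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="empty"):
            morph.classify_gfap_pixels(stack)

    def test_zero_absolute_threshold_keeps_all_nonzero(self):
        img = np.zeros((5, 8, 8))
        img[2, 2:5, 2:5] = 7.0
        stack = morph.AstroStack({"gfap": img}, (0.5, 0.5, 0.5))
        mask = morph.classify_gfap_pixels(stack, absolute_threshold=0.0, min_size_voxels=1)
        np.testing.assert_array_equal(mask, img > 0)


class TestCentroids:
    def test_single_blob_centroid_within_a_voxel(self):
        voxel = (0.5, 0.5, 0.5)
        cell = synthio.CellSpec((6.0, 10.0, 12.0), [])
        stack, _ = synthio.gen_astro_stack((25, 41, 49), [cell], voxel_um_zyx=voxel, seed=0)
        cents = morph.nucleus_centroids(stack)
        assert len(cents) == 1
        np.testing.assert_allclose(cents[0], (6.0, 10.0, 12.0), atol=0.5)

    def test_two_separated_blobs(self):
        voxel = (0.5, 0.5, 0.5)
        cells = [synthio.CellSpec((6.0, 8.0, 8.0), []), synthio.CellSpec((6.0, 24.0, 24.0), [])]
        stack, _ = synthio.gen_astro_stack((25, 65, 65), cells, voxel_um_zyx=voxel, seed=0)
        assert len(morph.nucleus_centroids(stack)) == 2

    def test_empty_channel_yields_empty_list(self):
        stack = morph.AstroStack({"dapi": np.zeros((5, 5, 5))}, (0.5, 0.5, 0.5))
        assert morph.nucleus_centroids(stack) == []


class TestSplitAndBorder:
    def test_disjoint_cells_match_connected_components(self):
        voxel = (0.5, 0.5, 0.5)
        c1, c2 = (7.0, 10.0, 10.0), (7.0, 30.0, 30.0)
        cells = [synthio.CellSpec(c1, []), synthio.CellSpec(c2, [])]
        _, truth = synthio.gen_astro_stack((29, 81, 81), cells, voxel_um_zyx=voxel, seed=0)
        mask = truth.cells[0]["mask"] | truth.cells[1]["mask"]
        labeled = morph.split_cells(mask, [c1, c2], voxel)
        assert set(np.unique(labeled)) == {0, 1, 2}
        np.testing.assert_array_equal(labeled == 1, truth.cells[0]["mask"])
        np.testing.assert_array_equal(labeled == 2, truth.cells[1]["mask"])

    def test_touching_cells_split_near_contact_plane(self):
        # two identical somata touching at the y = 20 um plane
        voxel = (0.5, 0.5, 0.5)
        c1, c2 = (7.0, 14.0, 15.0), (7.0, 26.0, 15.0)
        cells = [
            synthio.CellSpec(c1, [], soma_radius_um=6.0),
            synthio.CellSpec(c2, [], soma_radius_um=6.0),
        ]
        stack, truth = synthio.gen_astro_stack((29, 81, 61), cells, voxel_um_zyx=voxel, seed=0)
        mask = truth.cells[0]["mask"] | truth.cells[1]["mask"]
        labeled = morph.split_cells(mask, [c1, c2], voxel, cx43=stack.channels["cx43"])
        boundary_y_um = 20.0
        ys = np.nonzero(labeled == 1)[1] * voxel[1]
        assert np.percentile(ys, 99) <= boundary_y_um + 2 * voxel[1]
        ys2 = np.nonzero(labeled == 2)[1] * voxel[1]
        assert np.percentile(ys2, 1) >= boundary_y_um - 2 * voxel[1]

    def test_no_valid_seed_is_error(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="seed"):
                morph.split_cells(mask, [(10.0, 10.0, 10.0)], (0.5, 0.5, 0.5))

    def test_border_exclusion(self):
        labeled = np.zeros((10, 10, 10), dtype=int)
        labeled[4:6, 4:6, 4:6] = 1  # interior
        labeled[0, 7:9, 7:9] = 2  # touches top z-face only
        out, excluded = morph.exclude_border_cells(labeled)
        assert excluded == [2]
        assert set(np.unique(out)) == {0, 1}
        assert morph.count_gfap_cells(out) == 1

    def test_counts(self):
        labeled = np.zeros((6, 6, 6), dtype=int)
        assert morph.count_gfap_cells(labeled) == 0
        labeled[2, 2, 2] = 1
        labeled[3, 3, 3] = 2
        labeled[4, 4, 4] = 3
        assert morph.count_gfap_cells(labeled) == 3


class TestSholl:
    def test_straight_process_all_ones(self, straight_phantom):
        _, truth, center, voxel = straight_phantom
        profile = morph.sholl(truth.cells[0]["mask"], center, voxel)
        np.testing.assert_array_equal(profile.intersections, 1)
        assert profile.radii_um[0] == 7.0 and profile.radii_um[-1] == 45.0
        assert profile.radii_um.size == 20

    def test_y_branch_profile_matches_skeleton_oracle(self, y_branch_phantom):
        _, truth, center, voxel = y_branch_phantom
        cell = truth.cells[0]
        profile = morph.sholl(cell["mask"], center, voxel)
        np.testing.assert_array_equal(profile.intersections, cell["sholl_truth"])
        # bifurcation at 20 um: 1 crossing below, 2 above
        np.testing.assert_array_equal(profile.intersections[profile.radii_um < 20], 1)
        np.testing.assert_array_equal(profile.intersections[profile.radii_um > 20], 2)

    def test_empty_mask_all_zero(self):
        profile = morph.sholl(np.zeros((20, 50, 50), bool), (5.0, 12.0, 12.0), (0.5, 0.5, 0.5))
        np.testing.assert_array_equal(profile.intersections, 0)

    def test_clipped_shells_flagged_truncated(self):
        mask = np.zeros((11, 41, 41), bool)
        mask[5, 20, 20:30] = True
        profile = morph.sholl(mask, (2.5, 10.0, 10.0), (0.5, 0.5, 0.5))
        assert profile.truncated

    def test_rotation_robustness(self, y_branch_phantom):
        _, truth, center, voxel = y_branch_phantom
        mask = truth.cells[0]["mask"]
        rot = np.rot90(mask, k=1, axes=(1, 2))  # 90 deg about z
        cz, cy, cx = center
        ny = mask.shape[1]
        rot_center = (cz, (mask.shape[2] - 1) * voxel[2] - cx, cy)
        a = morph.sholl(mask, center, voxel).intersections
        b = morph.sholl(rot, rot_center, voxel).intersections
        assert np.mean(a == b) >= 0.95
        va, _ = morph.hull_volume(mask, voxel)
        vb, _ = morph.hull_volume(rot, voxel)
        assert vb == pytest.approx(va, rel=0.05)


class TestHull:
    def test_solid_cuboid_volume(self):
        mask = np.zeros((30, 30, 30), bool)
        mask[5:26, 5:26, 5:26] = True  # voxel centers span 10 um per axis
        vol, degen = morph.hull_volume(mask, (0.5, 0.5, 0.5))
        assert not degen
        assert vol == pytest.approx(1000.0, abs=160.0)  # one voxel-shell tolerance

    def test_tetrahedron_determinant_formula(self):
        mask = np.zeros((25, 25, 25), bool)
        verts = [(0, 0, 0), (20, 0, 0), (0, 20, 0), (0, 0, 20)]
        for v in verts:
            mask[v] = True
        vol, degen = morph.hull_volume(mask, (0.5, 0.5, 0.5))
        edges = np.array(verts[1:], dtype=float) * 0.5
        expected = abs(np.linalg.det(edges)) / 6.0
        assert not degen
        assert vol == pytest.approx(expected, rel=0.02)

    def test_single_voxel_degenerate(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        vol, degen = morph.hull_volume(mask, (0.5, 0.5, 0.5))
        assert degen and vol == 0.0

    def test_coplanar_mask_degenerate(self):
        mask = np.zeros((5, 9, 9), bool)
        mask[2, 1:8, 1:8] = True
        _, degen = morph.hull_volume(mask, (0.5, 0.5, 0.5))
        assert degen

    def test_adding_voxels_never_shrinks_hull(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((12, 12, 12), bool)
        idx = rng.integers(2, 10, size=(10, 3))
        mask[tuple(idx.T)] = True
        v1, _ = morph.hull_volume(mask, (0.5, 0.5, 0.5))
        grown = mask.copy()
        grown[tuple(rng.integers(0, 12, size=(15, 3)).T)] = True
        v2, _ = morph.hull_volume(grown, (0.5, 0.5, 0.5))
        assert v2 >= v1 - 1e-9


class TestVimentin:
    def _stack(self, proj):
        return morph.AstroStack({"vimentin": proj[None, :, :]}, (0.25, 0.25, 0.25))

    def test_two_blobs_summed(self):
        img = np.zeros((100, 100))
        img[10:15, 10:20] = 20.0  # 50 px, total 1000
        img[60:65, 60:70] = 20.0
        res = morph.vimentin_signal(self._stack(img), threshold=1.0, size_bounds_px=(10, 500))
        assert res.total_signal_au == pytest.approx(2000.0)
        assert res.n_rois == 2

    def test_large_elongated_vessel_excluded(self):
        img = np.zeros((200, 200))
        img[20:120, 50:55] = 10.0  # 500 px elongated band
        res = morph.vimentin_signal(self._stack(img), threshold=1.0, size_bounds_px=(10, 400))
        assert res.total_signal_au == 0.0
        assert res.n_rejected == 1

    def test_mixed_case_sums_retained_only(self):
        img = np.zeros((200, 200))
        img[10:15, 10:20] = 20.0  # kept: 1000
        img[100:180, 100:104] = 5.0  # rejected by size: 320 px > 300
        img[50:53, 50:53] = 30.0  # rejected by size: 9 px < 10
        res = morph.vimentin_signal(self._stack(img), threshold=1.0, size_bounds_px=(10, 300))
        assert res.total_signal_au == pytest.approx(1000.0)
        assert res.n_rois == 1 and res.n_rejected == 2


def test_analyze_cells_reports_border_and_morphometry(straight_phantom):
    stack, truth, center, voxel = straight_phantom
    mask = truth.cells[0]["mask"]
    labeled = mask.astype(int)
    cells = morph.analyze_cells(stack, labeled, [center])
    assert len(cells) == 1 and not cells[0].border_touching
    assert cells[0].hull_volume_um3 > 0
    flagged = morph.analyze_cells(stack, labeled, [center], border_excluded=[1])
    assert flagged[0].border_touching and flagged[0].sholl is None
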