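"""Z-buffer segmentation: seeds, region growing, bubble and hole filling."""

import numpy as np
import pytest

from vesseltort.grid import ImageVolume, Segmentation
from vesseltort.segment import (SeedSet, fill_bubbles,
                                fill_edge_holes, grow_region, zbs_detect_seeds,
                                zbs_segment)


def _cylinder_volume():
    """Bright capped cylinder along z in a zero background."""
    data = np.zeros((24, 24, 30))
    i, j = np.meshgrid(np.arange(24), np.arange(24), indexing="ij")
    inside = (i - 12) ** 2 + (j - 12) ** 2 <= 5 ** 2
    data[inside, 4:26] = 200.0
    return ImageVolume(data), inside


class TestSeeds:
    def test_seeds_inside_bright_cylinder(self):
        vol, inside = _cylinder_volume()
        seeds = zbs_detect_seeds(vol)
        assert len(seeds) > 0
        assert inside[seeds.seeds[:, 0], seeds.seeds[:, 1]].all()
        assert np.all(seeds.intensities == 200.0)

    def test_isolated_bright_voxel_excluded(self):
        data = np.zeros((30, 30, 10))
        data[2:12, 5:8, 3:6] = 180.0   # tube 1
        data[18:28, 20:23, 3:6] = 180.0  # tube 2
        data[15, 15, 5] = 250.0        # speckle
        seeds = zbs_detect_seeds(ImageVolume(data), min_cluster=5)
        assert not np.any(np.all(seeds.seeds == (15, 15, 5), axis=1))

    def test_constant_volume_raises(self):
        with pytest.raises(ValueError, match="no seed"):
            zbs_detect_seeds(ImageVolume(np.full((8, 8, 8), 7.0)))

    def test_noisy_helix_seeds_mostly_in_mask(self, rng):
        import math
        from vesseltort.phantoms import PhantomSpec, make_phantom
        spec = PhantomSpec(kind="helix", helix_radius=25.0,
                           pitch=12.0 * 2 * math.pi, turns=1.0,
                           tube_radius=3.0, noise_sd=10.0)
        ph = make_phantom(spec, seed=5)
        seeds = zbs_detect_seeds(ph.volume)
        s = seeds.seeds
        inside = ph.mask.mask[s[:, 0], s[:, 1], s[:, 2]]
        assert inside.mean() >= 0.95


class TestGrowRegion:
    def test_threshold_is_seed_percentile(self):
        vol, _ = _cylinder_volume()
        seeds = SeedSet(np.argwhere(vol.data == 200.0)[:10],
                        np.arange(10.0, 101.0, 10.0))
        seg = grow_region(vol, seeds, percentile=20.0)
        assert seg.provenance["threshold"] == np.percentile(
            np.arange(10.0, 101.0, 10.0), 20)

    def test_binary_phantom_grows_full_component(self):
        vol, inside = _cylinder_volume()
        seeds = zbs_detect_seeds(vol)
        for pct in (5.0, 20.0, 90.0):
            seg = grow_region(vol, seeds, pct)
            np.testing.assert_array_equal(seg.mask, vol.data == 200.0)

    def test_noise_free_helix_recovers_truth(self, small_helix):
        seeds = zbs_detect_seeds(small_helix.volume)
        seg = grow_region(small_helix.volume, seeds)
        truth = small_helix.mask.mask
        recovered = (seg.mask & truth).sum() / truth.sum()
        assert recovered >= 0.999
        assert (seg.mask & ~truth).sum() == 0

    def test_empty_seed_set_rejected(self):
        vol, _ = _cylinder_volume()
        with pytest.raises(ValueError, match="empty seed"):
            grow_region(vol, SeedSet(np.empty((0, 3), int), np.empty(0)))


class TestFillBubbles:
    def test_hollow_sphere_becomes_solid(self):
        g = np.arange(20)
        i, j, k = np.meshgrid(g, g, g, indexing="ij")
        r2 = (i - 10) ** 2 + (j - 10) ** 2 + (k - 10) ** 2
        shell = (r2 <= 8 ** 2) & (r2 >= 5 ** 2)
        ball = r2 <= 8 ** 2
        out = fill_bubbles(Segmentation(shell))
        np.testing.assert_array_equal(out.mask, ball)

    def test_solid_cylinder_unchanged(self, straight_tube):
        out = fill_bubbles(straight_tube.mask)
        np.testing.assert_array_equal(out.mask, straight_tube.mask.mask)

    def test_torus_hole_stays_open(self):
        # the torus hole connects to the outside: background component
        # through the hole touches the volume boundary
        g = np.arange(28)
        i, j, k = np.meshgrid(g, g, g, indexing="ij")
        ring = (np.sqrt((i - 14.0) ** 2 + (j - 14.0) ** 2) - 8.0) ** 2 + \
            (k - 14.0) ** 2 <= 3.0 ** 2
        seg = Segmentation(ring)
        out = fill_bubbles(seg)
        np.testing.assert_array_equal(out.mask, ring)
        assert not out.mask[14, 14, 14]

    def test_monotone_and_idempotent(self, rng):
        mask = rng.random((15, 15, 15)) > 0.6
        once = fill_bubbles(Segmentation(mask))
        assert np.all(once.mask >= mask)
        twice = fill_bubbles(once)
        np.testing.assert_array_equal(once.mask, twice.mask)


class TestFillEdgeHoles:
    def test_face_pit_not_filled(self):
        # a single-voxel pit on a flat face: census of the 26 ray directions
        # finds hits only in the inward half-space -> 17 < 24
        block = np.zeros((20, 20, 20), bool)
        block[2:18, 2:18, 2:10] = True
        pit = (10, 10, 9)
        block[pit] = False
        dirs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
                for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
        hits = 0
        for d in dirs:
            for step in range(1, 9):
                p = tuple(np.add(pit, np.multiply(d, step)))
                if all(0 <= x < 20 for x in p) and block[p]:
                    hits += 1
                    break
        assert hits == 17
        out = fill_edge_holes(Segmentation(block))
        assert not out.mask[pit]

    def test_interior_cavity_filled_first_iteration(self):
        block = np.zeros((16, 16, 16), bool)
        block[3:13, 3:13, 3:13] = True
        block[8, 8, 8] = False
        out = fill_edge_holes(Segmentation(block), iterations=1)
        assert out.mask[8, 8, 8]

    def test_empty_mask_unchanged(self):
        seg = Segmentation(np.zeros((6, 6, 6), bool))
        assert fill_edge_holes(seg).n_voxels == 0

    def test_too_many_directions_rejected(self):
        with pytest.raises(ValueError, match="26"):
            fill_edge_holes(Segmentation(np.ones((4, 4, 4), bool)),
                            directions_required=27)

    def test_monotone(self, rng):
        mask = rng.random((14, 14, 14)) > 0.4
        out = fill_edge_holes(Segmentation(mask))
        assert np.all(out.mask >= mask)


class TestZbsSegment:
    def test_noise_free_helix_dice(self, small_helix):
        seg = zbs_segment(small_helix.volume)
        truth = small_helix.mask.mask
        dice = 2 * (seg.mask & truth).sum() / (seg.mask.sum() + truth.sum())
        assert dice >= 0.99

    def test_superset_of_grown_region(self, small_helix):
        seeds = zbs_detect_seeds(small_helix.volume)
        grown = grow_region(small_helix.volume, seeds)
        seg = zbs_segment(small_helix.volume)
        assert np.all(seg.mask >= grown.mask)

    def test_no_enclosed_cavities_after_pipeline(self, small_helix):
        from scipy import ndimage
        seg = zbs_segment(small_helix.volume)
        bg_labels, n = ndimage.label(~seg.mask)
        boundary_labels = set(np.unique(bg_labels[0])) | set(np.unique(bg_labels[-1])) \
            | set(np.unique(bg_labels[:, 0])) | set(np.unique(bg_labels[:, -1])) \
            | set(np.unique(bg_labels[:, :, 0])) | set(np.unique(bg_labels[:, :, -1]))
        enclosed = set(range(1, n + 1)) - boundary_labels
        assert enclosed == set()

    def test_all_zero_volume_fails_with_stage_tag(self):
        with pytest.raises(ValueError, match="seed detection"):
            zbs_segment(ImageVolume(np.zeros((10, 10, 10))))
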