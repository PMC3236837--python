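"""Cost fields: DFE, MDFE and the center-of-mass collapse costs."""

import numpy as np
import pytest

from vesseltort.costs import (compute_com_cost, compute_cost, compute_dfe,
                              compute_mdfe_cost, _normalize_travel)
from vesseltort.grid import Segmentation


def _cylinder_mask(radius=4, length=30, pad=3):
    n = 2 * (radius + pad) + 1
    mask = np.zeros((length + 2 * pad, n, n), bool)
    c = radius + pad
    j, k = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disc = (j - c) ** 2 + (k - c) ** 2 <= radius ** 2
    mask[pad:pad + length, disc] = True
    return Segmentation(mask), c


class TestDfe:
    def test_isolated_voxel(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert compute_dfe(Segmentation(m))[2, 2, 2] == 1.0

    def test_slab_center_plane(self):
        m = np.zeros((9, 9, 9), bool)
        m[1:8] = True  # 7-voxel slab; other axes wrap to the border
        dfe = compute_dfe(Segmentation(m))
        # brute force: distance from the center voxel to every background voxel
        bg = np.argwhere(~m)
        brute = np.min(np.linalg.norm(bg - np.array([4, 4, 4]), axis=1))
        assert dfe[4, 4, 4] == brute == 4.0

    @pytest.mark.parametrize("R", [3, 6, 10])
    def test_digital_ball_max(self, R):
        n = 2 * R + 5
        g = np.arange(n) - n // 2
        i, j, k = np.meshgrid(g, g, g, indexing="ij")
        ball = i ** 2 + j ** 2 + k ** 2 <= R ** 2
        dfe = compute_dfe(Segmentation(ball))
        assert R <= dfe.max() <= R + 1

    def test_anisotropic_spacing_in_mm(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        dfe = compute_dfe(Segmentation(m, spacing=(2.0, 3.0, 4.0)))
        assert dfe[2, 2, 2] == 2.0  # nearest background along the finest axis


class TestComCost:
    def test_cube_center_stationary_corners_move(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        _, trace = compute_com_cost(Segmentation(m), iterations=1,
                                    return_trace=True)
        coords = np.argwhere(m)
        center = np.all(coords == 2, axis=1)
        corner = np.all((coords == 1) | (coords == 3), axis=1)
        assert np.allclose(trace.displacement[0][center], 0.0, atol=1e-12)
        assert np.all(trace.displacement[0][corner] >
                      trace.displacement[0][center] + 1e-6)

    def test_cylinder_cost_increases_off_axis(self):
        seg, c = _cylinder_mask(radius=4)
        cost = compute_com_cost(seg)
        coords = np.argwhere(seg.mask)
        rho = np.hypot(coords[:, 1] - c, coords[:, 2] - c)
        vals = cost.values[seg.mask]
        sel = (coords[:, 0] >= 10) & (coords[:, 0] < 25)  # avoid end caps
        # rank correlation between radius and cost must be strongly positive
        from scipy.stats import spearmanr
        r, _ = spearmanr(rho[sel], vals[sel])
        assert r > 0.9
        # axis voxels are the per-section minimum
        for x in (12, 18, 24):
            s = coords[:, 0] == x
            assert rho[s][np.argmin(vals[s])] <= 1.0

    def test_cubed_normalization(self):
        travel = np.array([0.5, 1.0, 0.0])
        np.testing.assert_allclose(_normalize_travel(travel), [1.0, 8.0, 0.0])

    def test_single_voxel_warns_and_zero(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        with pytest.warns(RuntimeWarning, match="no voxel moved"):
            cost = compute_com_cost(Segmentation(m))
        assert cost.values[1, 1, 1] == 0.0

    def test_collapse_toward_centroid_on_convex_objects(self):
        # per-iteration positions never move away from the object centroid
        for build in ("ball", "box"):
            m = np.zeros((11, 11, 11), bool)
            if build == "ball":
                g = np.arange(11) - 5
                i, j, k = np.meshgrid(g, g, g, indexing="ij")
                m[i ** 2 + j ** 2 + k ** 2 <= 16] = True
            else:
                m[2:9, 3:8, 4:7] = True
            seg = Segmentation(m)
            coords = np.argwhere(m).astype(float)
            centroid = coords.mean(axis=0)
            from vesseltort.costs import _neighbor_table
            _, nbr = _neighbor_table(m)
            valid = nbr >= 0
            safe = np.where(valid, nbr, 0)
            pos = coords.copy()
            prev_d = np.linalg.norm(pos - centroid, axis=1)
            for _ in range(10):
                num = pos.copy()
                den = np.ones(len(pos))
                for k in range(26):
                    num += np.where(valid[k][:, None], pos[safe[k]], 0.0)
                    den += valid[k]
                pos = num / den[:, None]
                d = np.linalg.norm(pos - centroid, axis=1)
                assert np.all(d <= prev_d + 1e-9)
                prev_d = d


class TestMdfe:
    def test_ties_broken_by_neighborhood(self):
        # an L-shaped slab: equal-DFE voxels near/away from the corner get
        # distinct costs, lower where the neighborhood is deeper on average
        m = np.zeros((12, 12, 3), bool)
        m[2:10, 2:5, 1] = True
        m[2:5, 2:10, 1] = True
        seg = Segmentation(m)
        dfe = compute_dfe(seg)
        cost = compute_mdfe_cost(seg).values
        same = np.argwhere(m & (dfe == dfe[3, 3, 1]))
        vals = cost[same[:, 0], same[:, 1], same[:, 2]]
        assert len(np.unique(np.round(vals, 12))) > 1

    def test_cylinder_axis_minimal_per_section(self):
        seg, c = _cylinder_mask(radius=4)
        cost = compute_mdfe_cost(seg)
        coords = np.argwhere(seg.mask)
        vals = cost.values[seg.mask]
        rho = np.hypot(coords[:, 1] - c, coords[:, 2] - c)
        for x in (10, 15, 20):
            s = coords[:, 0] == x
            assert rho[s][np.argmin(vals[s])] == 0.0

    def test_single_voxel_cost_zero(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert compute_mdfe_cost(Segmentation(m)).values[1, 1, 1] == 0.0

    def test_tie_term_smaller_than_base_gap(self):
        seg, _ = _cylinder_mask(radius=3, length=12)
        dfe = compute_dfe(seg)
        cost = compute_mdfe_cost(seg).values
        # ordering of distinct DFE levels is never flipped by the tie term
        d = dfe[seg.mask]
        v = cost[seg.mask]
        for a, b in [(d.max(), d.min())]:
            assert v[d == a].max() < v[d == b].min()


class TestDispatch:
    def test_field_defined_on_mask_only(self, comb_phantom):
        cost = compute_cost(comb_phantom.mask, "DFE_COM")
        assert np.all(cost.values[~comb_phantom.mask.mask] == 0)
        on = cost.on_mask()
        assert np.all(np.isfinite(on)) and np.all(on >= 0)

    def test_com_and_dfecom_differ_at_junction(self, comb_phantom):
        com = compute_cost(comb_phantom.mask, "COM")
        dfecom = compute_cost(comb_phantom.mask, "DFE_COM")
        assert not np.allclose(com.values, dfecom.values)

    def test_unknown_method_rejected(self, straight_tube):
        with pytest.raises(ValueError, match="unknown cost method"):
            compute_cost(straight_tube.mask, "frangi")

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_cost(Segmentation(np.zeros((4, 4, 4), bool)), "COM")

    def test_deterministic_bit_identical(self, straight_tube):
        a = compute_cost(straight_tube.mask, "DFE_COM")
        b = compute_cost(straight_tube.mask, "DFE_COM")
        np.testing.assert_array_equal(a.values, b.values)
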