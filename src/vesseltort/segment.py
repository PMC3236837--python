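"""Z-buffer segmentation (ZBS) of bright tubular structures.

ZBS assumes arteries are the brightest, sparse, spatially coherent
structures in the volume.  Rays cast along the z axis record the position
of the brightest voxel in each (x, y) column; spatial clusters of those
bright points seed a region growing whose intensity threshold is a low
percentile of the seed intensities.  Enclosed dark "bubbles" (slow or
recirculating blood) are filled by connected-component analysis, and small
edge holes by iterative directional reclassification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .grid import ImageVolume, Segmentation

__all__ = ["SeedSet", "zbs_detect_seeds", "grow_region", "fill_bubbles",
           "fill_edge_holes", "zbs_segment", "ZbsParams"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_DIRECTIONS26 = np.array([o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)],
                         dtype=np.int64)


@dataclass
class SeedSet:
    """Region-growing seed voxels with their source intensities."""

    seeds: np.ndarray        # (K, 3) voxel indices
    intensities: np.ndarray  # (K,) source intensity per seed

    def __post_init__(self):
        self.seeds = np.asarray(self.seeds, dtype=np.int64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if len(self.seeds) != len(self.intensities):
            raise ValueError("seeds and intensities lengths differ")

    def __len__(self):
        return len(self.seeds)


def zbs_detect_seeds(vol: ImageVolume, cluster_radius: float = 3.0,
                     min_cluster: int = 5) -> SeedSet:
    """Seed detection by z-axis ray casting.

    For every (x, y) column the position of the brightest voxel is recorded.
    Points from columns whose maximum is below an Otsu split of the
    brightest-voxel image are discarded (background columns), the remaining
    3-D points are clustered by chessboard proximity (<= ``cluster_radius``),
    and clusters with at least ``min_cluster`` members become seeds.
    """
    data = vol.data
    zmax = np.argmax(data, axis=2)
    vmax = np.take_along_axis(data, zmax[..., None], axis=2)[..., 0]
    if np.ptp(vmax) == 0:
        raise ValueError("no seed clusters: all ray maxima are identical")
    bright = vmax > threshold_otsu(vmax)
    xy = np.argwhere(bright)
    if len(xy) == 0:
        raise ValueError("no seed clusters: no bright columns found")
    pts = np.column_stack([xy, zmax[bright]])

    tree = cKDTree(pts.astype(np.float64))
    pairs = tree.query_pairs(r=float(cluster_radius), p=np.inf, output_type="ndarray")
    m = len(pts)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m))
    n_comp, labels = connected_components(adj, directed=False)
    counts = np.bincount(labels, minlength=n_comp)
    keep = counts[labels] >= int(min_cluster)
    seeds = pts[keep]
    if len(seeds) == 0:
        raise ValueError("no seed clusters: all clusters below min_cluster size")
    return SeedSet(seeds, data[seeds[:, 0], seeds[:, 1], seeds[:, 2]])


def grow_region(vol: ImageVolume, seeds: SeedSet, percentile: float = 20.0) -> Segmentation:
    """Percentile-threshold region growing from the seed voxels.

    The threshold is the given percentile (linear interpolation between
    order statistics) of the seed intensities; the mask is the union of
    26-connected components of above-threshold voxels that contain seeds.
    """
    if len(seeds) == 0:
        raise ValueError("empty seed set")
    tau = float(np.percentile(seeds.intensities, percentile, method="linear"))
    above = vol.data >= tau
    labels, _ = ndimage.label(above, structure=_STRUCT26)
    seed_labels = np.unique(labels[seeds.seeds[:, 0], seeds.seeds[:, 1],
                                   seeds.seeds[:, 2]])
    seed_labels = seed_labels[seed_labels > 0]
    mask = np.isin(labels, seed_labels)
    if not mask.any():
        raise ValueError("region growing produced an empty segmentation")
    return Segmentation(mask, vol.spacing, vol.origin,
                        provenance={"threshold": tau, "percentile": percentile,
                                    "n_seeds": len(seeds), "connectivity": 26})


def fill_bubbles(seg: Segmentation) -> Segmentation:
    """Fill enclosed background cavities (6-connected components that do not
    reach the volume boundary)."""
    filled = ndimage.binary_fill_holes(seg.mask)
    return seg.with_mask(filled, bubbles_filled=int(filled.sum() - seg.mask.sum()))


def _shift(arr: np.ndarray, offset) -> np.ndarray:
    """Shift with zero fill (no wraparound)."""
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, o in enumerate(offset):
        o = int(o)
        if o > 0:
            dst[ax] = slice(o, None)
            src[ax] = slice(None, -o)
        elif o < 0:
            dst[ax] = slice(None, o)
            src[ax] = slice(-o, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _reach(mask: np.ndarray, direction, span: int) -> np.ndarray:
    """True where an object voxel occurs within 1..span steps along direction."""
    d = np.asarray(direction, dtype=int)
    acc = mask.copy()
    step = 1
    while step < span:
        acc |= _shift(acc, -d * step)
        step *= 2
    if step > span:  # trim overshoot from doubling
        acc = mask.copy()
        for k in range(1, span):
            acc |= _shift(mask, -d * k)
        return _shift(acc, -d)
    return _shift(acc, -d)


def fill_edge_holes(seg: Segmentation, iterations: int = 3, ray_span: int = 8,
                    directions_required: int = 24) -> Segmentation:
    """Directional hole filling at the segmentation edge.

    In each iteration every background voxel casts rays along the 26
    discrete neighbor directions; a direction hits if an object voxel lies
    within ``ray_span`` steps.  Voxels hit in at least
    ``directions_required`` directions become object.  Iterations apply
    sequentially on the updated mask.
    """
    if directions_required > 26:
        raise ValueError("directions_required cannot exceed 26")
    mask = seg.mask.copy()
    for _ in range(int(iterations)):
        if not mask.any():
            break
        hits = np.zeros(mask.shape, dtype=np.uint8)
        for d in _DIRECTIONS26:
            hits += _reach(mask, d, int(ray_span))
        mask |= (~mask) & (hits >= directions_required)
    return seg.with_mask(mask, edge_holes_params=(iterations, ray_span,
                                                  directions_required))


@dataclass
class ZbsParams:
    """Tunable parameters of the full ZBS pipeline."""

    percentile: float = 20.0
    cluster_radius: float = 3.0
    min_cluster: int = 5
    fill_iterations: int = 3
    ray_span: int = 8
    directions_required: int = 24


def zbs_segment(vol: ImageVolume, params: ZbsParams | None = None) -> Segmentation:
    """Full Z-buffer segmentation.

    Pipeline: seed detection -> percentile region growing -> bubble filling
    -> directional edge-hole filling -> bubble filling again.  Stage
    failures are re-raised with the stage name.
    """
    p = params or ZbsParams()
    stages = [
        ("seed detection", lambda _: zbs_detect_seeds(vol, p.cluster_radius,
                                                      p.min_cluster)),
        ("region growing", lambda seeds: grow_region(vol, seeds, p.percentile)),
        ("bubble filling", fill_bubbles),
        ("edge hole filling", lambda s: fill_edge_holes(
            s, p.fill_iterations, p.ray_span, p.directions_required)),
        ("final bubble filling", fill_bubbles),
    ]
    state = None
    for name, stage in stages:
        try:
            state = stage(state)
        except ValueError as exc:
            raise ValueError(f"ZBS stage '{name}' failed: {exc}") from exc
    return state
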