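"""Per-voxel cost functions driving lowest-cost-path centerline extraction.

Four costs are supported:

``DFE``
    Euclidean distance from each object voxel to the nearest background
    voxel (large at vessel centers).  Used directly it is a distance map,
    not yet a cost; its inversion underlies the MDFE.
``MDFE``
    Inverted DFE plus a sub-voxel tie-breaking term from the neighborhood
    mean DFE, so adjacent voxels that are equally deep acquire distinct
    costs favoring the more central neighborhood.
``COM``
    Each object voxel carries a continuous position, initially its center.
    Every iteration moves each position to the mean of its 26-neighborhood's
    positions (Jacobi update), collapsing the object inward; the cumulative
    distance traveled, divided by the minimum positive travel and cubed, is
    the cost.  Edge voxels travel far (high cost), central voxels barely
    move (low cost).
``DFE_COM``
    The COM collapse with each neighbor weighted by its DFE, giving deep
    voxels more pull and stabilizing the collapse toward the vessel axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .grid import Segmentation

__all__ = ["CostField", "ComTrace", "compute_dfe", "compute_com_cost",
           "compute_mdfe_cost", "compute_cost", "METHODS"]

METHODS = ("DFE", "MDFE", "COM", "DFE_COM")

#: the 26 neighbor offsets (chessboard shell of radius 1)
OFFSETS26 = np.array([o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)],
                     dtype=np.int64)


@dataclass
class CostField:
    """Nonnegative scalar per object voxel; lower cost means more central."""

    values: np.ndarray          # full-grid float array, 0 outside mask
    mask: Segmentation
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.mask.shape:
            raise ValueError("cost grid and mask shapes differ")
        on = self.values[self.mask.mask]
        if on.size and (not np.all(np.isfinite(on)) or on.min() < 0):
            raise ValueError("cost values must be finite and nonnegative on the mask")

    def on_mask(self) -> np.ndarray:
        return self.values[self.mask.mask]

    @property
    def spacing(self):
        return self.mask.spacing


@dataclass
class ComTrace:
    """Cumulative distance moved per voxel over the collapse iterations."""

    displacement: np.ndarray    # (iterations, N) cumulative travel, mm
    iterations: int


def _check_nonempty(seg: Segmentation):
    if seg.n_voxels == 0:
        raise ValueError("segmentation mask is empty")


def compute_dfe(seg: Segmentation, spacing=None) -> np.ndarray:
    """Distance from edge: per-voxel Euclidean distance to background, mm.

    Returns a full-grid array (0 on background).  An isolated object voxel
    has DFE equal to one voxel spacing (its nearest background neighbor).
    """
    _check_nonempty(seg)
    sampling = seg.spacing if spacing is None else spacing
    return ndimage.distance_transform_edt(seg.mask, sampling=sampling)


def _neighbor_table(mask: np.ndarray):
    """Flat object-voxel ids of each voxel's 26 neighbors (-1 off-object)."""
    ids = np.full(mask.shape, -1, dtype=np.int64)
    n = int(mask.sum())
    ids[mask] = np.arange(n)
    coords = np.argwhere(mask)
    nbr = np.full((len(OFFSETS26), n), -1, dtype=np.int64)
    shape = np.array(mask.shape)
    for k, off in enumerate(OFFSETS26):
        pos = coords + off
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        nbr[k, ok] = ids[pos[ok, 0], pos[ok, 1], pos[ok, 2]]
    return coords, nbr


def _normalize_travel(travel: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Divide by the minimum positive cumulative travel and cube."""
    positive = travel[travel > tol]
    if positive.size == 0:
        warnings.warn("no voxel moved during the collapse; uniform zero cost",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(travel)
    out = travel / positive.min()
    out[travel <= tol] = 0.0
    return out ** 3


def compute_com_cost(seg: Segmentation, iterations: int = 30,
                     dfe_weights: np.ndarray | None = None,
                     return_trace: bool = False):
    """Center-of-mass collapse cost (COM, or DFE-COM when weighted).

    Parameters
    ----------
    seg
        Object mask.
    iterations
        Number of synchronous collapse iterations (30 suffices for the
        object sizes considered here).
    dfe_weights
        Optional full-grid weight array (typically the DFE map); when given
        the neighborhood mean is weighted by each neighbor's value, yielding
        the DFE-COM cost.
    return_trace
        Also return a :class:`ComTrace` with per-iteration cumulative travel.
    """
    _check_nonempty(seg)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mask = seg.mask
    spacing = np.asarray(seg.spacing)
    coords, nbr = _neighbor_table(mask)
    n = len(coords)

    w_vox = np.ones(n) if dfe_weights is None else \
        np.asarray(dfe_weights, dtype=np.float64)[mask]
    if np.any(w_vox < 0):
        raise ValueError("collapse weights must be nonnegative")

    valid = nbr >= 0
    safe = np.where(valid, nbr, 0)
    # neighborhood includes the voxel itself
    wk = [np.where(valid[k], w_vox[safe[k]], 0.0) for k in range(len(OFFSETS26))]
    den = w_vox + sum(wk)
    den[den == 0] = 1.0  # isolated voxel with zero weight: stays put

    pos = coords * spacing
    travel = np.zeros(n)
    trace = np.empty((iterations, n)) if return_trace else None
    for it in range(iterations):
        num = w_vox[:, None] * pos
        for k in range(len(OFFSETS26)):
            num += wk[k][:, None] * pos[safe[k]]
        new = num / den[:, None]
        travel += np.linalg.norm(new - pos, axis=1)
        pos = new
        if return_trace:
            trace[it] = travel

    values = np.zeros(mask.shape)
    values[mask] = _normalize_travel(travel)
    method = "COM" if dfe_weights is None else "DFE_COM"
    cf = CostField(values, seg, method)
    if return_trace:
        return cf, ComTrace(trace, iterations)
    return cf


def compute_mdfe_cost(seg: Segmentation, spacing=None) -> CostField:
    """Modified-DFE cost: inverted DFE with deterministic tie-breaking.

    Base cost is ``max(DFE) - DFE``.  A tie-breaking term proportional to
    the (inverted, rescaled) 26-neighborhood mean DFE is added, scaled to be
    strictly smaller than the smallest gap between distinct base costs, so
    equal-DFE neighbors are ordered by how central their neighborhoods are
    without ever reordering distinct DFE levels.
    """
    dfe = compute_dfe(seg, spacing)
    mask = seg.mask
    base = np.zeros(mask.shape)
    d_on = dfe[mask]
    base[mask] = d_on.max() - d_on

    # neighborhood mean DFE over the full 3x3x3 box (self included;
    # background and out-of-bounds count as depth 0), so a voxel whose
    # surroundings are deeper scores higher than an equally deep voxel
    # near the edge even when every object neighbor has the same DFE
    footprint = np.ones((3, 3, 3))
    summed = ndimage.convolve(np.where(mask, dfe, 0.0), footprint, mode="constant")
    nmean = np.zeros(mask.shape)
    nmean[mask] = summed[mask] / footprint.size

    uniq = np.unique(base[mask])
    gap = np.diff(uniq).min() if len(uniq) > 1 else 1.0
    m_on = nmean[mask]
    span = m_on.max() - m_on.min()
    tie = np.zeros(mask.shape)
    if span > 0:
        tie[mask] = 0.5 * gap * (m_on.max() - m_on) / span

    return CostField(base + tie, seg, "MDFE")


def compute_cost(seg: Segmentation, method: str = "DFE_COM",
                 iterations: int = 30) -> CostField:
    """Dispatch to the requested cost function.

    ``DFE_COM`` computes the DFE map first and uses it to weight the COM
    collapse.  ``DFE`` returns the inverted distance map (``max - DFE``) so
    that, like the others, lower cost means more central.
    """
    method = method.upper().replace("-", "_")
    if method not in METHODS:
        raise ValueError(f"unknown cost method {method!r}; choose from {METHODS}")
    if method == "DFE":
        dfe = compute_dfe(seg)
        values = np.zeros(seg.shape)
        values[seg.mask] = dfe[seg.mask].max() - dfe[seg.mask]
        return CostField(values, seg, "DFE")
    if method == "MDFE":
        return compute_mdfe_cost(seg)
    if method == "COM":
        return compute_com_cost(seg, iterations)
    return compute_com_cost(seg, iterations, dfe_weights=compute_dfe(seg))
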