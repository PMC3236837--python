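"""Numeric tube phantoms with known ground-truth centerlines.

Phantoms start from a continuous parametric centerline (helix, comb or
Y-branching tree), which is rasterized into a binary tube of fixed radius:
every voxel whose center lies within ``tube_radius`` of the continuous curve
becomes an object voxel.  The discretized centerline is kept as the positive
control against which extracted centerlines are scored.

The helix family follows ``h(t) = [r cos t, r sin t, p t / (2 pi)]`` so the
tube rises by the pitch ``p`` (in voxels) per full turn.  Pitches are
conventionally quoted as multiples of ``2 pi`` (a pitch of ``5 * 2 pi``
climbs ~31.4 voxels per coil).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import ImageVolume, Segmentation

__all__ = [
    "ParametricCenterline",
    "PhantomSpec",
    "Phantom",
    "generate_helix_centerline",
    "generate_comb_centerline",
    "generate_y_centerlines",
    "rasterize_tube",
    "make_phantom",
    "helix_arc_length",
    "helix_peak_dfm_continuous",
]

#: default voxel intensities for object and background
FOREGROUND = 200.0
BACKGROUND = 0.0


@dataclass
class ParametricCenterline:
    """Densely sampled continuous centerline in (fractional) voxel units."""

    points: np.ndarray          # (N, 3) float, consecutive points < 1 voxel apart
    arc_parameter: np.ndarray   # (N,) strictly increasing parameter

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.arc_parameter = np.asarray(self.arc_parameter, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centerline needs at least two 3-D points")
        if len(self.points) != len(self.arc_parameter):
            raise ValueError("points and arc_parameter lengths differ")
        if not np.all(np.diff(self.arc_parameter) > 0):
            raise ValueError("arc_parameter must be strictly increasing")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive centerline points must be distinct")

    @property
    def length(self) -> float:
        """Polyline arc length (voxel units)."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def translated(self, offset) -> "ParametricCenterline":
        return ParametricCenterline(self.points + np.asarray(offset, float),
                                    self.arc_parameter)


@dataclass
class PhantomSpec:
    """Geometry and imaging parameters of a numeric phantom."""

    kind: str                       # helix | comb | branching
    helix_radius: float = 100.0     # voxels
    pitch: float = 40.0 * 2 * math.pi  # z rise per turn, voxels
    turns: float = 1.0
    tube_radius: float = 6.0        # voxels
    spine_length: float = 100.0     # comb
    tooth_length: float = 40.0
    n_teeth: int = 5
    tooth_spacing: float = 20.0
    trunk_length: float = 40.0      # branching (Y)
    arm_length: float = 40.0
    arm_angle_deg: float = 40.0
    noise_sd: float = 0.0           # intensity units
    psf_sigma: float | None = None  # imaging point-spread blur, voxels;
                                    # None -> 1.0 when noisy, 0 when noise-free
    margin: float = 5.0             # empty border, voxels
    foreground: float = FOREGROUND
    background: float = BACKGROUND

    def __post_init__(self):
        if self.kind not in ("helix", "comb", "branching"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.tube_radius < 1:
            raise ValueError("tube_radius must be >= 1 voxel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kind == "helix" and self.turns <= 0:
            raise ValueError("helix needs turns > 0")


@dataclass
class Phantom:
    """Rasterized tube phantom: image, mask and ground-truth centerline."""

    volume: ImageVolume
    mask: Segmentation
    truth: np.ndarray                     # (N, 3) int voxel indices, deduplicated
    truth_branches: list = field(default_factory=list)  # per-branch voxel paths
    spec: PhantomSpec | None = None


# ---------------------------------------------------------------------------
# parametric generators
# ---------------------------------------------------------------------------

def helix_arc_length(r: float, p: float, turns: float = 1.0) -> float:
    """Continuous arc length of a helix: ``2 pi turns sqrt(r^2 + (p/2pi)^2)``."""
    c = p / (2 * math.pi)
    return 2 * math.pi * turns * math.hypot(r, c)


def helix_peak_dfm_continuous(r: float, p: float) -> float:
    """Closed-form peak of the continuous helix tortuosity curve.

    The distance factor metric L/d measured from t=0 is stationary at every
    full turn, where the curve returns over its start and the chord is purely
    axial; there it equals ``sqrt(r^2 + c^2) / c`` with ``c = p / 2 pi``.
    """
    c = p / (2 * math.pi)
    return math.hypot(r, c) / c


def generate_helix_centerline(r: float, p: float, turns: float,
                              samples_per_turn: int | None = None
                              ) -> ParametricCenterline:
    """Sample ``h(t) = [r cos t, r sin t, p t / 2pi]`` for t in [0, 2 pi turns].

    The curve is translated into a nonnegative frame (offset ``(r, r, 0)``)
    and sampled densely enough that consecutive points are < 1 voxel apart
    (about half a voxel by default).
    """
    if r <= 0 or p <= 0 or turns <= 0:
        raise ValueError("helix radius, pitch and turns must be positive")
    if samples_per_turn is None:
        arc_per_turn = helix_arc_length(r, p, 1.0)
        samples_per_turn = max(16, int(math.ceil(arc_per_turn / 0.5)))
    if samples_per_turn < 16:
        raise ValueError("samples_per_turn must be >= 16")
    n = int(math.ceil(samples_per_turn * turns)) + 1
    t = np.linspace(0.0, 2 * math.pi * turns, n)
    c = p / (2 * math.pi)
    pts = np.column_stack([r * np.cos(t) + r, r * np.sin(t) + r, c * t])
    return ParametricCenterline(pts, t)


def _sample_segment(a, b, step: float = 0.5) -> np.ndarray:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = max(2, int(math.ceil(np.linalg.norm(b - a) / step)) + 1)
    return a + np.linspace(0.0, 1.0, n)[:, None] * (b - a)


def _polyline(points, step: float = 0.5) -> ParametricCenterline:
    segs = [_sample_segment(points[i], points[i + 1], step) for i in range(len(points) - 1)]
    pts = np.vstack([s if i == 0 else s[1:] for i, s in enumerate(segs)])
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return ParametricCenterline(pts, arc)


def generate_comb_centerline(spine_length: float, tooth_length: float,
                             n_teeth: int, tooth_spacing: float
                             ) -> list[ParametricCenterline]:
    """Comb-shaped centerline: straight spine plus perpendicular teeth.

    Teeth attach at ``x = 0, s, 2s, ...`` so the spine extends beyond the last
    tooth like a comb handle.  Returns one polyline branch per segment
    (spine first), sharing junction points.
    """
    if n_teeth < 1:
        raise ValueError("need at least one tooth")
    if n_teeth > 1 and tooth_spacing <= 0:
        raise ValueError("teeth with zero spacing overlap")
    if tooth_spacing * (n_teeth - 1) > spine_length:
        raise ValueError("teeth extend beyond the spine")
    branches = [_polyline([(0.0, 0.0, 0.0), (spine_length, 0.0, 0.0)])]
    for i in range(n_teeth):
        x = i * tooth_spacing
        branches.append(_polyline([(x, 0.0, 0.0), (x, tooth_length, 0.0)]))
    return branches


def generate_y_centerlines(trunk_length: float = 40.0, arm_length: float = 40.0,
                           arm_angle_deg: float = 40.0) -> list[ParametricCenterline]:
    """Y-shaped branching centerline: a trunk splitting into two arms.

    The tree lies flat in the x-y plane (the z extent of the rasterized
    phantom is just the tube diameter), which keeps the chords seen by
    z-axis ray casting short, as for arteries running across the slab.
    """
    if trunk_length <= 0 or arm_length <= 0:
        raise ValueError("trunk and arm lengths must be positive")
    a = math.radians(arm_angle_deg)
    j = np.zeros(3)
    branches = [
        _polyline([(-trunk_length, 0.0, 0.0), tuple(j)]),
        _polyline([tuple(j), (arm_length * math.cos(a), arm_length * math.sin(a), 0.0)]),
        _polyline([tuple(j), (arm_length * math.cos(a), -arm_length * math.sin(a), 0.0)]),
    ]
    return branches


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _discretize(points: np.ndarray) -> np.ndarray:
    """Nearest-voxel discretization, consecutive duplicates removed."""
    vox = np.rint(points).astype(np.int64)
    keep = np.ones(len(vox), dtype=bool)
    keep[1:] = np.any(np.diff(vox, axis=0) != 0, axis=1)
    return vox[keep]


MAX_GRID_VOXELS = 60_000_000  # sizing guard for a single phantom volume


def rasterize_tube(centerlines, tube_radius: float, margin: float = 5.0,
                   foreground: float = FOREGROUND, background: float = BACKGROUND,
                   noise_sd: float = 0.0, psf_sigma: float | None = None,
                   seed: int | None = None,
                   spec: PhantomSpec | None = None) -> Phantom:
    """Rasterize continuous centerlines into a binary tube phantom.

    Object voxels are those whose center lies within ``tube_radius`` of the
    sampled centerline (a fast distance transform pre-screens the grid and a
    KD-tree refines the boundary shell against the continuous samples).

    Phantoms that model an acquisition (``noise_sd > 0``) are blurred with a
    Gaussian point-spread of ``psf_sigma`` voxels before i.i.d. Gaussian
    noise is added and clipped at zero, reproducing the partial-volume
    intensity falloff at vessel rims that intensity-threshold segmentation
    relies on.  Noise-free geometry phantoms stay exactly two-valued.
    ``psf_sigma=None`` selects 1.0 for noisy phantoms and 0 otherwise.
    """
    if tube_radius < 1:
        raise ValueError("tube_radius must be >= 1 voxel")
    if margin < 1:
        raise ValueError("margin must be >= 1 voxel")
    if isinstance(centerlines, ParametricCenterline):
        centerlines = [centerlines]
    all_pts = np.vstack([c.points for c in centerlines])
    lo = all_pts.min(axis=0)
    hi = all_pts.max(axis=0)
    shift = margin + tube_radius - lo
    shape = tuple(int(math.floor(x)) + 1
                  for x in (hi + shift + tube_radius + margin))
    if int(np.prod(shape)) > MAX_GRID_VOXELS:
        raise ValueError(
            f"phantom grid {shape} exceeds {MAX_GRID_VOXELS} voxels; "
            "reduce the geometry or margin")

    shifted = [c.translated(shift) for c in centerlines]
    samples = np.vstack([c.points for c in shifted])

    # coarse mask: distance to the discretized centerline voxels
    cl_vox = np.rint(samples).astype(np.int64)
    cl_mask = np.zeros(shape, dtype=bool)
    cl_mask[cl_vox[:, 0], cl_vox[:, 1], cl_vox[:, 2]] = True
    coarse = ndimage.distance_transform_edt(~cl_mask)

    # refine the boundary shell against the continuous samples
    mask = coarse <= tube_radius - 1.0
    band = (coarse > tube_radius - 1.0) & (coarse <= tube_radius + 1.0)
    band_idx = np.argwhere(band)
    if len(band_idx):
        tree = cKDTree(samples)
        d, _ = tree.query(band_idx.astype(np.float64), workers=-1)
        mask[band_idx[:, 0], band_idx[:, 1], band_idx[:, 2]] = d <= tube_radius

    data = np.where(mask, float(foreground), float(background))
    if psf_sigma is None:
        psf_sigma = 1.0 if noise_sd > 0 else 0.0
    if psf_sigma > 0:
        data = ndimage.gaussian_filter(data, psf_sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = np.clip(data + rng.normal(0.0, noise_sd, size=shape), 0.0, None)

    truth_branches = [_discretize(c.points) for c in shifted]
    concat = np.vstack(truth_branches)
    _, first = np.unique(concat, axis=0, return_index=True)
    truth = concat[np.sort(first)]

    volume = ImageVolume(data)
    seg = Segmentation(mask, provenance={
        "source": "phantom", "tube_radius": tube_radius,
        "noise_sd": noise_sd, "seed": seed})
    return Phantom(volume=volume, mask=seg, truth=truth,
                   truth_branches=truth_branches, spec=spec)


def make_phantom(spec: PhantomSpec, seed: int | None = None) -> Phantom:
    """Generate a phantom from its specification."""
    if spec.kind == "helix":
        lines = [generate_helix_centerline(spec.helix_radius, spec.pitch, spec.turns)]
    elif spec.kind == "comb":
        lines = generate_comb_centerline(spec.spine_length, spec.tooth_length,
                                         spec.n_teeth, spec.tooth_spacing)
    else:
        lines = generate_y_centerlines(spec.trunk_length, spec.arm_length,
                                       spec.arm_angle_deg)
    return rasterize_tube(lines, spec.tube_radius, spec.margin,
                          spec.foreground, spec.background,
                          spec.noise_sd, spec.psf_sigma, seed=seed, spec=spec)
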