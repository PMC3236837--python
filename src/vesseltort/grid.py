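"""Core in-memory containers shared by every pipeline stage.

An :class:`ImageVolume` is a 3-D scalar grid with anisotropic voxel spacing;
a :class:`Segmentation` is a binary mask on the same grid.  Voxel indices are
0-based ``(i, j, k)`` triples; physical coordinates are in millimetres and
follow ``origin + index * spacing`` (a diagonal NIfTI affine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "Segmentation"]


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(x) for x in np.atleast_1d(spacing))
    if len(s) == 1:
        s = (s[0], s[0], s[0])
    if len(s) != 3 or any(x <= 0 for x in s):
        raise ValueError(f"spacing must be three positive floats, got {spacing!r}")
    return s


@dataclass
class ImageVolume:
    """3-D grayscale image with per-axis voxel size in mm.

    Parameters
    ----------
    data
        3-D array of intensities (arbitrary units).  Stored as float.
    spacing
        Per-axis voxel size in mm, default isotropic 1 mm.
    origin
        Physical offset (mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(x) for x in self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_mm(self, index) -> np.ndarray:
        """Physical coordinates (mm) of one or many voxel indices."""
        idx = np.asarray(index, dtype=np.float64)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mm_to_index(self, xyz) -> np.ndarray:
        """Continuous voxel index of one or many physical points (mm)."""
        p = np.asarray(xyz, dtype=np.float64)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same grid, new intensities."""
        return ImageVolume(data, self.spacing, self.origin)


@dataclass
class Segmentation:
    """Binary object mask aligned to an :class:`ImageVolume` grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.mask.shape}")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(x) for x in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def index_to_mm(self, index) -> np.ndarray:
        idx = np.asarray(index, dtype=np.float64)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains(self, index) -> bool:
        i, j, k = (int(x) for x in index)
        shape = self.mask.shape
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
            return False
        return bool(self.mask[i, j, k])

    def with_mask(self, mask: np.ndarray, **provenance) -> "Segmentation":
        prov = dict(self.provenance)
        prov.update(provenance)
        return Segmentation(mask, self.spacing, self.origin, prov)
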