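"""NIfTI volume I/O, landmark files and measurement/curve export."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import ImageVolume, Segmentation

__all__ = ["read_volume", "write_volume", "write_mask", "read_mask",
           "read_landmarks", "write_landmarks", "write_curves",
           "write_measurements", "write_tree"]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(data, spacing, origin)


def write_volume(vol: ImageVolume, path, dtype=np.float32) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data.astype(dtype), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def write_mask(seg: Segmentation, path, sidecar: dict | None = None) -> Path:
    """Write a mask as uint8 NIfTI plus a provenance JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(seg.mask.astype(np.uint8),
                          _affine(seg.spacing, seg.origin))
    nib.save(img, str(path))
    meta = dict(seg.provenance)
    if sidecar:
        meta.update(sidecar)
    sidecar_path = path.with_suffix("").with_suffix("")  # strip .nii.gz
    Path(str(sidecar_path) + ".json").write_text(
        json.dumps(meta, indent=2, default=str))
    return path


def read_mask(path) -> Segmentation:
    vol = read_volume(path)
    return Segmentation(vol.data > 0, vol.spacing, vol.origin,
                        provenance={"source": str(path)})


def read_landmarks(path) -> dict:
    """Named points from JSON: ``{"name": {"voxel": [i,j,k]}}`` or ``{"mm": ...}``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed landmarks JSON at line "
                         f"{exc.lineno}: {exc.msg}") from exc
    out = {}
    for name, entry in raw.items():
        if not isinstance(entry, dict) or not ({"voxel", "mm"} & set(entry)):
            raise ValueError(f"{path}: landmark {name!r} needs a 'voxel' or 'mm' entry")
        out[name] = {k: tuple(float(x) for x in v) if k in ("voxel", "mm") else v
                     for k, v in entry.items()}
    return out


def write_landmarks(landmarks: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(landmarks, indent=2, default=list))
    return path


def write_curves(curves: dict, path) -> Path:
    """Tortuosity curves as one long-format CSV (label, point, L_mm, d_mm, DFM)."""
    frames = []
    for label, curve in curves.items():
        df = curve.to_frame()
        df.insert(0, "label", label)
        frames.append(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def write_measurements(measurements: list, path, config_hash: str = "") -> Path:
    rows = [{"subject": m.subject, "artery": m.artery, "mode": m.mode,
             "value": m.value, "config_hash": config_hash}
            for m in measurements]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_tree_vtk(tree, path) -> Path:
    """Centerline tree as legacy ASCII VTK polylines, for visualization."""
    pts = np.vstack([b.coords_mm for b in tree.branches]) if tree.branches \
        else np.empty((0, 3))
    lines = []
    offset = 0
    for b in tree.branches:
        n = len(b)
        lines.append([n] + list(range(offset, offset + n)))
        offset += n
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncenterline tree\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        total = sum(len(l) for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(x) for x in l) + "\n")
    return path


def write_tree(tree, path, config_hash: str = "") -> Path:
    """Centerline tree as JSON: per-branch voxel lists and lengths."""
    payload = {
        "goal": list(tree.goal),
        "config_hash": config_hash,
        "branches": [{"voxels": b.voxels.tolist(),
                      "length_mm": b.length} for b in tree.branches],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))
    return path
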