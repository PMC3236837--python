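"""Pipeline configuration: every stage parameter with a recorded default.

Defaults follow the source method where it states them (median kernel 5,
region-growing percentile 20, 30 collapse iterations, hole filling with 3
iterations / 8-step rays / 24 of 26 directions) and recorded design choices
elsewhere (26-connectivity, pruning factor 3, peak-search chord floor).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # optional preprocessing
    median_kernel: int | None = None          # odd, >= 3; None disables
    target_spacing: tuple | None = None       # mm triple; None disables

    # segmentation: "zbs" (full pipeline), "threshold" (fixed cut),
    # "none" (volume > background midpoint; for noise-free binary phantoms)
    segmentation: str = "zbs"
    threshold: float | None = None            # used by "threshold" mode
    percentile: float = 20.0
    cluster_radius: float = 3.0
    min_cluster: int = 5
    fill_iterations: int = 3
    ray_span: int = 8
    directions_required: int = 24

    # cost and centerline extraction
    cost_method: str = "DFE_COM"
    com_iterations: int = 30
    prune_factor: float = 3.0
    min_branch_length: float | None = None
    goal: str | tuple = "auto"                # "auto" or a voxel index triple

    # measurement
    measurement_mode: str = "peak"            # end | peak
    start: tuple | None = None                # voxel index endpoints for the
    end: tuple | None = None                  # measured path; None -> longest branch

    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.median_kernel is not None and (
                self.median_kernel % 2 == 0 or self.median_kernel < 3):
            raise ValueError(f"median kernel must be odd >= 3, got {self.median_kernel}")
        if self.segmentation not in ("zbs", "threshold", "none"):
            raise ValueError(f"unknown segmentation mode {self.segmentation!r}")
        if self.measurement_mode not in ("end", "peak"):
            raise ValueError(f"unknown measurement mode {self.measurement_mode!r}")
        if not 0 <= self.percentile <= 100:
            raise ValueError("percentile must be in [0, 100]")
        if self.directions_required > 26:
            raise ValueError("directions_required cannot exceed 26")
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end endpoints must be given together")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in d.items()})
        return cfg.validate()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        """Stable short hash embedded in every output artifact."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
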