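"""End-to-end measurement pipeline.

Stage sequence: optional sinc interpolation, optional median-filter
subtraction, segmentation (full ZBS, a fixed threshold, or none for binary
noise-free phantoms), cost-field computation, centerline extraction, DFM
curve and score readout.  Every stage is logged with voxel counts and
timing, and failures carry the stage name.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .centerline import CenterlineTree, extract_tree, path_between, select_goal
from .config import PipelineConfig
from .costs import compute_cost
from .grid import ImageVolume, Segmentation
from .preprocess import median_subtract, sinc_interpolate
from .segment import ZbsParams, zbs_segment
from .tortuosity import TortuosityCurve, TortuosityMeasurement, dfm_curve, \
    read_measurement

log = logging.getLogger("vesseltort")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    measurements: list
    curves: dict
    tree: CenterlineTree | None
    segmentation: Segmentation | None
    artifacts: dict = field(default_factory=dict)
    config_hash: str = ""


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are attached."""

    def __init__(self, stage, exc, artifacts):
        super().__init__(f"pipeline stage '{stage}' failed: {exc}")
        self.stage = stage
        self.artifacts = artifacts


def _segment(vol: ImageVolume, cfg: PipelineConfig) -> Segmentation:
    if cfg.segmentation == "zbs":
        return zbs_segment(vol, ZbsParams(cfg.percentile, cfg.cluster_radius,
                                          cfg.min_cluster, cfg.fill_iterations,
                                          cfg.ray_span, cfg.directions_required))
    if cfg.segmentation == "threshold":
        tau = cfg.threshold
        if tau is None:
            lo, hi = float(vol.data.min()), float(vol.data.max())
            tau = 0.5 * (lo + hi)
        return Segmentation(vol.data >= tau, vol.spacing, vol.origin,
                            provenance={"threshold": tau, "mode": "fixed"})
    # "none": binary phantom, object = above the background/foreground midpoint
    lo, hi = float(vol.data.min()), float(vol.data.max())
    return Segmentation(vol.data > 0.5 * (lo + hi), vol.spacing, vol.origin,
                        provenance={"mode": "binary-phantom"})


def run_pipeline(config: PipelineConfig, volume: ImageVolume) -> PipelineResult:
    """Run the configured stage sequence on one volume."""
    cfg = config.validate()
    artifacts: dict = {}
    chash = cfg.config_hash()

    def stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(*args)
        except Exception as exc:
            raise StageError(name, exc, artifacts) from exc
        log.info("stage %-22s %6.2fs", name, time.perf_counter() - t0)
        return out

    if cfg.target_spacing is not None:
        volume = stage("sinc interpolation", sinc_interpolate, volume,
                       cfg.target_spacing)
        artifacts["interpolated"] = volume
    if cfg.median_kernel is not None:
        volume = stage("median subtraction", median_subtract, volume,
                       cfg.median_kernel)
        artifacts["filtered"] = volume

    seg = stage("segmentation", _segment, volume, cfg)
    artifacts["segmentation"] = seg
    log.info("segmentation: %d object voxels", seg.n_voxels)

    cost = stage("cost field", compute_cost, seg, cfg.cost_method,
                 cfg.com_iterations)
    artifacts["cost"] = cost

    goal = (select_goal(seg, cost) if cfg.goal == "auto"
            else select_goal(seg, cost, "user", cfg.goal))
    tree = None
    if cfg.start is not None:
        path = stage("path extraction", path_between, cost, cfg.start, cfg.end)
    else:
        tree = stage("tree extraction", extract_tree, cost, goal,
                     cfg.min_branch_length, cfg.prune_factor)
        if not tree.branches:
            raise StageError("tree extraction", "no branches extracted", artifacts)
        path = max(tree.branches, key=lambda b: b.length)

    curve: TortuosityCurve = stage("tortuosity curve", dfm_curve, path)
    meas: TortuosityMeasurement = read_measurement(curve, cfg.measurement_mode)
    meas.provenance["config_hash"] = chash
    return PipelineResult([meas], {"path": curve}, tree, seg, artifacts, chash)
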