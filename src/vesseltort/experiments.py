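"""Canonical phantom experiments: the helix tortuosity table and the
branch-count checks.

These functions fix the study conditions — helix radius 100 voxels, tube
radius 6, pitches 5/10/20/40 (in units of 2 pi) with 8/4/2/1 turns for
equal axial extent; a five-tooth comb of tube radius 3; a Y-branching
phantom with additive Gaussian noise — and run the full measurement chain
on them.  A ``scale`` factor shrinks the helices geometrically (the DFM is
scale invariant, so a half-scale run reproduces the same scores and ratios
at a fraction of the cost).
"""

from __future__ import annotations

import math

import pandas as pd

from .centerline import extract_tree, path_between
from .costs import compute_cost
from .phantoms import (Phantom, PhantomSpec, helix_peak_dfm_continuous,
                       make_phantom)
from .segment import zbs_segment
from .tortuosity import dfm_curve, read_measurement

__all__ = ["HELIX_PITCHES_2PI", "HELIX_TURNS", "helix_spec", "helix_peak_dfm",
           "helix_table", "comb_tree_count", "branching_tree_count"]

#: pitch multipliers (units of 2 pi voxels) and matching turn counts;
#: turns halve as pitch doubles so all four helices span the same z extent
HELIX_PITCHES_2PI = (5.0, 10.0, 20.0, 40.0)
HELIX_TURNS = (8.0, 4.0, 2.0, 1.0)


def helix_spec(pitch_2pi: float, turns: float, scale: float = 1.0) -> PhantomSpec:
    """Helix phantom specification (radius 100, tube radius 6, scaled)."""
    return PhantomSpec(kind="helix",
                       helix_radius=100.0 * scale,
                       pitch=pitch_2pi * 2 * math.pi * scale,
                       turns=turns,
                       tube_radius=max(1.0, 6.0 * scale))


def _tube_end_voxels(phantom: Phantom):
    """Truth voxels at the two ends of a single-branch phantom."""
    branch = phantom.truth_branches[0]
    return tuple(branch[0]), tuple(branch[-1])


def helix_peak_dfm(spec: PhantomSpec) -> tuple[float, int]:
    """Peak DFM along the DFE-COM centerline between the helix tube ends.

    Returns the peak score and the number of object voxels processed.
    Noise-free binary phantoms skip segmentation: the rasterized mask is
    the segmentation.
    """
    phantom = make_phantom(spec)
    cost = compute_cost(phantom.mask, "DFE_COM")
    start, end = _tube_end_voxels(phantom)
    path = path_between(cost, start, end)
    peak = read_measurement(dfm_curve(path), "peak")
    return float(peak.value), phantom.mask.n_voxels


def helix_table(scale: float = 1.0) -> pd.DataFrame:
    """Peak DFM of the four standard helix phantoms plus ratio columns.

    Ratios are taken against the loosest (pitch 40 x 2 pi, one-coil) helix.
    The ``continuous`` column is the closed-form peak of the continuous
    curve, a lower anchor unaffected by voxelization.
    """
    rows = []
    for pitch, turns in zip(HELIX_PITCHES_2PI, HELIX_TURNS):
        spec = helix_spec(pitch, turns, scale)
        peak, n = helix_peak_dfm(spec)
        rows.append({"pitch_2pi": pitch, "turns": turns, "peak_dfm": peak,
                     "continuous": helix_peak_dfm_continuous(
                         spec.helix_radius, spec.pitch),
                     "n_voxels": n})
    df = pd.DataFrame(rows)
    df["ratio"] = df["peak_dfm"] / df["peak_dfm"].iloc[-1]
    return df


def comb_tree_count(scale: float = 1.0) -> tuple[int, Phantom]:
    """Branch count of the DFE-COM centerline tree on the five-tooth comb."""
    spec = PhantomSpec(kind="comb", tube_radius=max(1.0, 3.0 * scale),
                       spine_length=100.0 * scale, tooth_length=40.0 * scale,
                       n_teeth=5, tooth_spacing=20.0 * scale)
    phantom = make_phantom(spec)
    cost = compute_cost(phantom.mask, "DFE_COM")
    tree = extract_tree(cost)
    return tree.n_trees, phantom


def branching_tree_count(noise_sd: float = 10.0, seed: int = 0,
                         method: str = "DFE_COM") -> tuple[int, Phantom]:
    """Branch count on the noisy Y phantom after full ZBS segmentation."""
    spec = PhantomSpec(kind="branching", tube_radius=3.0, noise_sd=noise_sd)
    phantom = make_phantom(spec, seed=seed)
    seg = zbs_segment(phantom.volume)
    cost = compute_cost(seg, method)
    tree = extract_tree(cost)
    return tree.n_trees, phantom
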