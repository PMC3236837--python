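"""Accuracy and stability metrics for centerline algorithms.

Accuracy is the root-mean-square distance from extracted centerline voxels
to the nearest ground-truth centerline voxel of a phantom.  Stability is
the tolerance-overlap agreement between centerlines extracted from
different goal nodes: for each ordered pair of runs, the fraction of one
run's voxels lying within a tolerance of the other, averaged over pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .centerline import extract_tree, select_goal
from .costs import compute_cost, compute_dfe
from .phantoms import Phantom

__all__ = ["ValidationReport", "centerline_rmse", "centerline_stability",
           "validate_algorithm"]


@dataclass
class ValidationReport:
    """One row of an algorithm-comparison table."""

    algorithm: str
    n_trees: int
    stability: float | None     # None when fewer than 2 goal runs
    rmse: float                 # voxels
    n_goals: int = 1

    def __str__(self):
        stab = "-" if self.stability is None else f"{self.stability:.3f}"
        return (f"{self.algorithm}\ttrees={self.n_trees}\tstability={stab}\t"
                f"rmse={self.rmse:.3f}")


def centerline_rmse(computed, truth) -> float:
    """RMS distance (voxels) from computed centerline voxels to the truth.

    Directed computed -> truth, since the truth centerline is densely
    sampled while the computed one may legitimately stop short of tips.
    """
    computed = np.atleast_2d(np.asarray(computed, dtype=np.float64))
    truth = np.atleast_2d(np.asarray(truth, dtype=np.float64))
    if computed.size == 0 or truth.size == 0:
        raise ValueError("empty centerline")
    d, _ = cKDTree(truth).query(computed, workers=-1)
    return float(np.sqrt(np.mean(d ** 2)))


def centerline_stability(runs: list, tolerance: float = 1.0) -> float:
    """Mean symmetric tolerance-overlap between pairs of centerline runs.

    For runs A and B, the fraction of A's voxels within ``tolerance`` of B
    and vice versa; averaged over all unordered pairs.  1.0 means every run
    reproduces every other within the tolerance.
    """
    if len(runs) < 2:
        raise ValueError("stability needs at least 2 runs")
    runs = [np.atleast_2d(np.asarray(r, dtype=np.float64)) for r in runs]
    trees = [cKDTree(r) for r in runs]
    fracs = []
    for i, j in combinations(range(len(runs)), 2):
        dij, _ = trees[j].query(runs[i], workers=-1)
        dji, _ = trees[i].query(runs[j], workers=-1)
        fracs.append(0.5 * (np.mean(dij <= tolerance) + np.mean(dji <= tolerance)))
    return float(np.mean(fracs))


def validate_algorithm(phantom: Phantom, method: str = "DFE_COM",
                       n_goals: int = 3, seed: int = 0,
                       tolerance: float = 1.0) -> ValidationReport:
    """Tree count, stability and accuracy of one cost method on a phantom.

    The canonical run uses the automatically selected goal; additional runs
    restart the extraction from ``n_goals - 1`` alternative goals drawn
    deterministically (seeded) from the most central voxels (DFE within 80%
    of its maximum).  The tree count is the mode across runs; RMSE is
    scored on the canonical run against the phantom truth.
    """
    if phantom.truth is None or len(phantom.truth) == 0:
        raise ValueError("phantom has no ground-truth centerline")
    seg = phantom.mask
    cost = compute_cost(seg, method)
    dfe = compute_dfe(seg)

    goals = [select_goal(seg, cost)]
    if n_goals > 1:
        central = np.argwhere(dfe >= 0.8 * dfe.max())
        rng = np.random.default_rng(seed)
        extra = min(n_goals - 1, len(central))
        picks = central[rng.choice(len(central), size=extra, replace=False)]
        goals += [tuple(int(x) for x in p) for p in picks]

    runs, counts = [], []
    for goal in goals:
        tree = extract_tree(cost, goal, dfe=dfe)
        runs.append(tree.all_voxels())
        counts.append(tree.n_trees)

    stability = centerline_stability(runs, tolerance) if len(runs) >= 2 else None
    rmse = centerline_rmse(runs[0], phantom.truth)
    n_trees = int(np.bincount(counts).argmax())
    return ValidationReport(method, n_trees, stability, rmse, n_goals=len(goals))
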