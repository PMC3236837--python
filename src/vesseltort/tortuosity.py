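"""Distance-factor-metric tortuosity curves and group comparisons.

The DFM at a point i along a centerline is ``L_i / d_i``: the arc length
from the start divided by the straight-line distance from the start.  A
straight vessel has DFM 1 everywhere; coiling drives it up.  Evaluating the
DFM at every point yields a tortuosity curve whose end value or maximum
("peak") is the reported score, depending on the artery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .centerline import CenterlinePath

__all__ = ["TortuosityCurve", "TortuosityMeasurement", "dfm_curve",
           "read_measurement", "aggregate_arteries", "compare_groups",
           "bonferroni_threshold", "GroupComparison"]


@dataclass
class TortuosityCurve:
    """Per-point cumulative length L, chord d and DFM = L/d along a path."""

    L: np.ndarray            # (N,) cumulative arc length, mm
    d: np.ndarray            # (N,) straight-line distance from start, mm
    dfm: np.ndarray          # (N,) L/d, with DFM = 1 at the start by convention
    voxel_diagonal: float = math.sqrt(3.0)   # mm, used for the peak-search floor
    start_mm: np.ndarray | None = None

    def __len__(self):
        return len(self.L)

    def to_frame(self) -> pd.DataFrame:
        """Curve as a table indexed by point, for export on either axis."""
        return pd.DataFrame({"point": np.arange(len(self.L)),
                             "L_mm": self.L, "d_mm": self.d, "DFM": self.dfm})


@dataclass
class TortuosityMeasurement:
    """A single DFM readout from a tortuosity curve."""

    value: float
    mode: str                       # end | peak
    artery: str = ""
    subject: str = ""
    start_mm: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("end", "peak"):
            raise ValueError(f"unknown measurement mode {self.mode!r}")


def dfm_curve(path: CenterlinePath) -> TortuosityCurve:
    """Tortuosity curve of one centerline path.

    ``L_i`` accumulates segment lengths, ``d_i`` is the chord back to the
    first point and ``DFM_i = L_i / d_i``; at the start, where both vanish,
    the DFM is defined as 1.
    """
    if len(path) < 2:
        raise ValueError("tortuosity curve needs a path with at least 2 points")
    coords = path.coords_mm
    L = path.cumulative_length
    d = np.linalg.norm(coords - coords[0], axis=1)
    dfm = np.ones(len(L))
    pos = d > 0
    dfm[pos] = L[pos] / d[pos]
    diag = float(np.linalg.norm(path.spacing))
    return TortuosityCurve(L, d, dfm, voxel_diagonal=diag, start_mm=coords[0])


def read_measurement(curve: TortuosityCurve, mode: str = "peak",
                     artery: str = "", subject: str = "") -> TortuosityMeasurement:
    """Read one DFM score from a curve.

    ``end`` returns the final DFM.  ``peak`` returns the curve maximum,
    excluding points whose chord d is below two voxel diagonals where L/d is
    near-singular; if no point clears the floor the end value is used.
    """
    if len(curve) == 0:
        raise ValueError("empty tortuosity curve")
    if mode == "end":
        value = float(curve.dfm[-1])
    elif mode == "peak":
        ok = curve.d >= 2.0 * curve.voxel_diagonal
        value = float(curve.dfm[ok].max()) if np.any(ok) else float(curve.dfm[-1])
    else:
        raise ValueError(f"unknown measurement mode {mode!r}")
    return TortuosityMeasurement(value, mode, artery=artery, subject=subject,
                                 start_mm=curve.start_mm)


# ---------------------------------------------------------------------------
# aggregation and statistics
# ---------------------------------------------------------------------------

def aggregate_arteries(measurements: list) -> pd.DataFrame:
    """Mean DFM per subject and artery group.

    Multiple measurements of the same artery label within a subject (for
    example several prominent lenticulostriate arteries) are averaged.
    """
    if not measurements:
        raise ValueError("no measurements to aggregate")
    rows = [{"subject": m.subject, "artery": m.artery,
             "mode": m.mode, "value": m.value} for m in measurements]
    df = pd.DataFrame(rows)
    return (df.groupby(["subject", "artery", "mode"], as_index=False)["value"]
              .mean())


def leftmost(measurements: list) -> TortuosityMeasurement:
    """Measurement whose path starts at the smallest x coordinate."""
    return min(measurements, key=lambda m: float(m.start_mm[0]))


def rightmost(measurements: list) -> TortuosityMeasurement:
    return max(measurements, key=lambda m: float(m.start_mm[0]))


def bonferroni_threshold(alpha: float = 0.05, n_comparisons: int = 1) -> float:
    """Corrected per-test significance level ``beta = alpha / n``."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


#: tests available in :func:`compare_groups`
TESTS = ("wilcoxon_2sided", "wilcoxon_1sided", "wilcoxon_paired", "anova", "f_var")

#: above this combined sample size the rank-sum test switches from the exact
#: null distribution to the tie-corrected normal approximation
EXACT_N_MAX = 25


@dataclass
class GroupComparison:
    p_values: dict
    bonferroni: float
    alpha: float
    n_comparisons: int
    methods: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def significant(self, test: str) -> bool:
        return self.p_values[test] < self.bonferroni


def _f_test_variances(a, b):
    """Two-sided F test for equality of variances."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    f = np.var(a, ddof=1) / np.var(b, ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.sf(f, dfa, dfb), stats.f.cdf(f, dfa, dfb))
    return f, min(p, 1.0)


def compare_groups(group_a, group_b, tests=("wilcoxon_2sided",),
                   alpha: float = 0.05, n_comparisons: int = 1) -> GroupComparison:
    """Standard two-group comparisons with a Bonferroni-corrected threshold.

    Rank-sum tests use the exact null distribution for combined n up to
    :data:`EXACT_N_MAX` and the tie-corrected normal approximation beyond;
    the choice is recorded per test.  The paired rank test requires groups
    of equal length.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    result = GroupComparison({}, bonferroni_threshold(alpha, n_comparisons),
                             alpha, n_comparisons)
    method = "exact" if a.size + b.size <= EXACT_N_MAX else "asymptotic"
    for test in tests:
        if test not in TESTS:
            raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
        try:
            if test == "wilcoxon_2sided":
                r = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
                result.p_values[test] = float(min(r.pvalue, 1.0))
                result.methods[test] = method
            elif test == "wilcoxon_1sided":
                r = stats.mannwhitneyu(a, b, alternative="greater", method=method)
                result.p_values[test] = float(min(r.pvalue, 1.0))
                result.methods[test] = method
            elif test == "wilcoxon_paired":
                if a.size != b.size:
                    raise ValueError("paired test requires equal group sizes")
                r = stats.wilcoxon(a, b)
                result.p_values[test] = float(r.pvalue)
                result.methods[test] = "signed-rank"
            elif test == "anova":
                r = stats.f_oneway(a, b)
                result.p_values[test] = float(r.pvalue)
                result.methods[test] = "one-way"
            elif test == "f_var":
                _, p = _f_test_variances(a, b)
                result.p_values[test] = float(p)
                result.methods[test] = "two-sided F"
        except ValueError as exc:
            result.notes[test] = f"insufficient data: {exc}"
    return result
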