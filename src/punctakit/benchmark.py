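"""Call-set matching and performance metrics.

A call matches a reference entry when it lies within 4 voxel units in xy
(Euclidean, inclusive) and 2 z planes; candidate pairs are accepted
closest-first (xy distance, then |dz|, then call order) with each call and
each reference used at most once.  Recall, precision and F-score follow the
standard definitions; PR-AUC is the trapezoidal area of the polygon through
all recall/precision points extrapolated to the axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stack import FilteredStack

__all__ = [
    "MatchResult",
    "PRPoint",
    "match_calls",
    "precision_recall_fscore",
    "pr_auc",
    "snr",
    "spot_density",
    "zero_voxel_proportion",
    "trim_xy_border",
]

XY_TOLERANCE = 4.0
Z_TOLERANCE = 2.0
SIMULATED_BORDER_TRIM = 7  # px removed from all x/y edges of simulated images
ZVP_FILTER_CUTOFF = 0.7


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (call idx, ref idx, xy distance)
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    recall: float | None
    precision: float | None
    f_score: float | None


def candidate_pairs(
    calls: pd.DataFrame,
    ref: pd.DataFrame,
    xy_tol: float = XY_TOLERANCE,
    z_tol: float = Z_TOLERANCE,
) -> list[tuple[float, float, int, int]]:
    """All (xy distance, |dz|, call idx, ref idx) within tolerance, sorted.

    Sorted ascending by xy distance, then |dz|, then call index — the
    acceptance order for greedy matching.
    """
    if len(calls) == 0 or len(ref) == 0:
        return []
    cxy = calls[["x", "y"]].to_numpy(dtype=float)
    rxy = ref[["x", "y"]].to_numpy(dtype=float)
    cz = calls["z"].to_numpy(dtype=float)
    rz = ref["z"].to_numpy(dtype=float)
    tree = cKDTree(rxy)
    neighbours = tree.query_ball_point(cxy, r=xy_tol)
    pairs = []
    for ci, refs in enumerate(neighbours):
        for ri in refs:
            dz = abs(cz[ci] - rz[ri])
            if dz <= z_tol:
                d = float(np.hypot(*(cxy[ci] - rxy[ri])))
                pairs.append((d, dz, ci, ri))
    pairs.sort()
    return pairs


def match_calls(
    calls: pd.DataFrame,
    ref: pd.DataFrame,
    xy_tol: float = XY_TOLERANCE,
    z_tol: float = Z_TOLERANCE,
) -> MatchResult:
    """Greedy one-to-one matching of calls to reference entries."""
    pairs = candidate_pairs(calls, ref, xy_tol, z_tol)
    used_call = np.zeros(len(calls), dtype=bool)
    used_ref = np.zeros(len(ref), dtype=bool)
    accepted = []
    for d, dz, ci, ri in pairs:
        if used_call[ci] or used_ref[ri]:
            continue
        used_call[ci] = True
        used_ref[ri] = True
        accepted.append((ci, ri, d))
    tp = len(accepted)
    return MatchResult(
        pairs=accepted, tp=tp, fp=len(calls) - tp, fn=len(ref) - tp
    )


def precision_recall_fscore(
    m: MatchResult, threshold: float = float("nan")
) -> PRPoint:
    """Recall, precision and F-score for one match result.

    Undefined ratios (0/0) are reported as ``None``; F is 0 when both
    recall and precision are 0, and an error is raised when both
    denominators are zero.
    """
    denom_r = m.tp + m.fn
    denom_p = m.tp + m.fp
    if denom_r == 0 and denom_p == 0:
        raise ValueError("no calls and no reference entries: metrics undefined")
    recall = m.tp / denom_r if denom_r > 0 else None
    precision = m.tp / denom_p if denom_p > 0 else None
    f = None
    if recall is not None and precision is not None:
        f = 0.0 if (recall + precision) == 0 else 2 * recall * precision / (recall + precision)
    return PRPoint(threshold=threshold, recall=recall, precision=precision, f_score=f)


def pr_auc(points: list[PRPoint]) -> float:
    """Area of the recall/precision polygon extrapolated to the axes.

    Unique (recall, precision) points are sorted by recall, extended with a
    horizontal segment to recall 0 at the first point's precision and a
    vertical drop to precision 0 at the last point's recall, then integrated
    trapezoidally over recall.  Clipped to [0, 1].
    """
    rp = sorted(
        {
            (p.recall, p.precision)
            for p in points
            if p.recall is not None and p.precision is not None
        }
    )
    if not rp:
        return 0.0
    recalls = [0.0] + [r for r, _ in rp] + [rp[-1][0]]
    precisions = [rp[0][1]] + [p for _, p in rp] + [0.0]
    area = float(np.trapezoid(precisions, recalls))
    return float(np.clip(area, 0.0, 1.0))


def pr_sweep(
    calls: pd.DataFrame,
    ref: pd.DataFrame,
    thresholds,
    xy_tol: float = XY_TOLERANCE,
    z_tol: float = Z_TOLERANCE,
) -> list[PRPoint]:
    """Precision/recall/F at every threshold of an intensity sweep.

    ``calls`` are the base maxima with filtered intensities; at each
    threshold only calls with intensity >= t are considered.  Candidate
    pairs are computed once; the greedy closest-first matching is re-run per
    threshold over the surviving pairs, which is exactly equivalent to
    matching the retained call set from scratch.
    """
    intens = calls["intensity"].to_numpy(dtype=float) if len(calls) else np.empty(0)
    pairs = candidate_pairs(calls, ref, xy_tol, z_tol)
    pair_arr = [(ci, ri) for _, _, ci, ri in pairs]
    n_ref = len(ref)
    sorted_intens = np.sort(intens)
    points = []
    used_ref = np.zeros(n_ref, dtype=bool)
    for t in thresholds:
        n_calls = int(len(intens) - np.searchsorted(sorted_intens, t, side="left"))
        used_call = set()
        used_ref[:] = False
        tp = 0
        for ci, ri in pair_arr:
            if intens[ci] < t or used_ref[ri] or ci in used_call:
                continue
            used_call.add(ci)
            used_ref[ri] = True
            tp += 1
        if n_ref == 0 and n_calls == 0:
            continue
        m = MatchResult(pairs=[], tp=tp, fp=n_calls - tp, fn=n_ref - tp)
        points.append(precision_recall_fscore(m, threshold=float(t)))
    return points


def snr(mean_amplitude: float, background_sd: float) -> float:
    """Signal-to-noise ratio: mean spot amplitude over background SD."""
    if background_sd <= 0:
        raise ValueError("background SD must be positive")
    return mean_amplitude / background_sd


def spot_density(total_spots: float, width: float, height: float, depth: float) -> float:
    """Average spots per 9 x 9 x 5 voxel box."""
    if width <= 0 or height <= 0 or depth <= 0:
        raise ValueError("dimensions must be positive")
    return total_spots / ((width / 9.0) * (height / 9.0) * (depth / 5.0))


def zero_voxel_proportion(f: FilteredStack) -> tuple[float, bool]:
    """Zero-voxel proportion of the filtered stack and its quality flag.

    Simulated images with ZVP at or above 0.7 are flagged as too clean /
    artificial and filtered from performance summaries.
    """
    zvp = float(np.mean(f.voxels == 0))
    return zvp, zvp >= ZVP_FILTER_CUTOFF


def trim_xy_border(
    table: pd.DataFrame, width: int, height: int, margin: int = SIMULATED_BORDER_TRIM
) -> pd.DataFrame:
    """Drop calls within ``margin`` px of any x/y edge (analysis-region trim)."""
    keep = (
        (table["x"] >= margin)
        & (table["x"] <= width - 1 - margin)
        & (table["y"] >= margin)
        & (table["y"] <= height - 1 - margin)
    )
    return table.loc[keep].reset_index(drop=True)
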