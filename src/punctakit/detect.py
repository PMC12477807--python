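"""Threshold scan-range suggestion, 3D maxima extraction, count curves.

Detection runs once at the scan floor: all 26-connected local maxima of the
filtered stack (8-connected for a single plane) that clear the per-slice
mean filter are recorded with their filtered intensities, and the
spot-count-versus-threshold curve is then obtained by counting how many of
those base maxima survive each tested threshold.  Zeroing sub-threshold
voxels removes competitors but never creates new maxima, so this sweep is
exactly equivalent to re-running maxima detection per threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack import FilteredStack, new_call_table

__all__ = [
    "ScanRange",
    "SpotCountCurve",
    "suggest_scan_range",
    "find_local_maxima_3d",
    "counts_vs_threshold",
]


@dataclass(frozen=True)
class ScanRange:
    """Inclusive integer threshold scan interval."""

    t_min: int
    t_max: int
    step: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.t_min <= self.t_max) or self.step < 1:
            raise ValueError(f"invalid scan range {self}")

    def thresholds(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + 1, self.step)


@dataclass
class SpotCountCurve:
    """Retained-spot count as a function of threshold."""

    thresholds: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds)
        self.counts = np.asarray(self.counts)
        if self.thresholds.shape != self.counts.shape:
            raise ValueError("thresholds and counts must align")

    def __len__(self) -> int:
        return len(self.thresholds)


# Leeway applied above the 99.9th percentile for the scan maximum.
TOP_PERCENTILE_LEEWAY = 0.10


def suggest_scan_range(f: FilteredStack) -> ScanRange:
    """Suggest the intensity-threshold scan range for a filtered stack.

    The floor defaults to 10 a.u., dropping to 5 or 1 for dim images whose
    80th-percentile filtered intensity falls below 10 or 5.  The ceiling is
    the default 500 a.u. unless the smaller of (1.1 x the 99.9th percentile)
    and (max / 10) exceeds it.
    """
    v = f.voxels
    if v.size == 0 or not np.any(v > 0):
        warnings.warn("empty or zero filtered image; using default scan range")
        return ScanRange(1, 500, 1)
    p80 = float(np.percentile(v, 80))
    if p80 < 5:
        t_min = 1
    elif p80 < 10:
        t_min = 5
    else:
        t_min = 10
    q = float(np.percentile(v, 99.9))
    cand_a = int(np.ceil((1.0 + TOP_PERCENTILE_LEEWAY) * q))
    cand_b = int(np.floor(float(v.max()) / 10.0))
    auto_max = min(cand_a, cand_b) if cand_a <= cand_b else cand_b
    t_max = max(500, auto_max)
    return ScanRange(t_min, t_max, 1)


def find_local_maxima_3d(
    f: FilteredStack, t_min: int = 1
) -> pd.DataFrame:
    """Find 3D local maxima of the filtered stack as a call table.

    A voxel qualifies when its value is >= all 26 neighbours (8 for a
    depth-1 stack), >= ``t_min`` and strictly above the recorded mean of its
    filtered z plane.  Plateaus of equal-valued connected voxels collapse to
    one call at the rounded centroid.
    """
    v = f.voxels
    depth = v.shape[0]
    if depth == 1:
        footprint = np.ones((1, 3, 3), dtype=bool)
    else:
        footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = v >= ndimage.maximum_filter(
        v, footprint=footprint, mode="constant", cval=0.0
    )
    candidate = local_max & (v >= t_min)
    candidate &= v > f.slice_means[:, None, None]
    if not candidate.any():
        return new_call_table()

    labels, n = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=bool))
    centroids = ndimage.center_of_mass(candidate, labels, np.arange(1, n + 1))
    zs, ys, xs, vals = [], [], [], []
    for cz, cy, cx in centroids:
        z = int(round(cz))
        y = int(round(cy))
        x = int(round(cx))
        zs.append(z)
        ys.append(y)
        xs.append(x)
        vals.append(float(v[z, y, x]))
    calls = new_call_table(x=xs, y=ys, z=zs, intensity=vals)
    return calls.sort_values(
        ["z", "y", "x"], ignore_index=True
    )


def counts_vs_threshold(calls: pd.DataFrame, scan: ScanRange) -> SpotCountCurve:
    """Count retained base maxima at every threshold in the scan."""
    thresholds = scan.thresholds()
    if len(calls) == 0:
        return SpotCountCurve(thresholds, np.zeros_like(thresholds))
    intens = np.sort(np.asarray(calls["intensity"], dtype=float))
    # count(t) = number of intensities >= t
    counts = len(intens) - np.searchsorted(intens, thresholds, side="left")
    return SpotCountCurve(thresholds, counts)
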