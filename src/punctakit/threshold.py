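"""Automatic intensity-threshold selection from a spot count curve.

The selector looks for the abrupt levelling-out ("elbow") of the spot count
versus threshold curve.  Pipeline:

1. Take the absolute first-difference of the count curve and trim leading
   thresholds so the diff curve starts at its peak.
2. Slide Fano-factor windows (variance / mean) of several widths across the
   diff curve; each width yields one transformed "window score" curve.
3. On the log10 projection of each transformed curve, collect candidate
   thresholds two ways: the lowest threshold whose score falls at or below
   median + k * MAD for a grid of MAD factors k, and the breakpoint /
   curve-intersection of an exhaustive two-piece linear fit.
4. Pool all candidates and report a weighted average (rounded) plus pool
   statistics; precision/recall presets shift the pick by a multiple of the
   pool standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import SpotCountCurve

__all__ = [
    "ThresholdingError",
    "TransformedCurve",
    "Candidate",
    "ThresholdResult",
    "diff_and_trim",
    "fano_window_scores",
    "mad_candidates",
    "two_piece_fit_candidates",
    "select_threshold",
    "PRESET_LAMBDA",
]

DEFAULT_WINDOW_SIZES = (5, 10, 15, 20)
DEFAULT_MAD_FACTORS = tuple(np.arange(-1.0, 1.01, 0.25))

#: Preset name -> multiple of the pool SD added to the pool mean.
PRESET_LAMBDA = {
    "recall-strong": -1.0,
    "recall": -0.5,
    "default": 0.0,
    "precision": 0.5,
    "precision-strong": 1.0,
}


class ThresholdingError(RuntimeError):
    """Raised when a curve cannot be auto-thresholded."""


@dataclass
class TransformedCurve:
    """Window-score (Fano) curve for one window size."""

    thresholds: np.ndarray
    values: np.ndarray
    window_size: int

    @property
    def log10_values(self) -> np.ndarray:
        return np.log10(self.values + 1.0)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class Candidate:
    threshold: float
    source: str  # 'mad' | 'fit_breakpoint' | 'fit_intersection'
    window_size: int
    mad_factor: float | None = None


@dataclass
class ThresholdResult:
    selected: int
    pool_min: float
    pool_max: float
    pool_mean: float
    pool_std: float
    preset: str
    candidates: list[Candidate] = field(default_factory=list)


def diff_and_trim(curve: SpotCountCurve) -> tuple[np.ndarray, np.ndarray]:
    """Absolute first-difference of the count curve, trimmed to its peak.

    Returns ``(thresholds, d)`` where ``d[i] = |count(t_{i+1}) - count(t_i)|``
    is indexed by the left threshold, with everything before the first peak
    of ``d`` removed so the curve begins at its highest point.
    """
    if len(curve) < 3:
        raise ThresholdingError("count curve too short to threshold")
    d = np.abs(np.diff(curve.counts.astype(float)))
    if not np.any(d > 0):
        raise ThresholdingError("flat spot count curve: nothing to threshold")
    peak = int(np.argmax(d))
    return curve.thresholds[peak : len(d)].copy(), d[peak:]


def _fano(window: np.ndarray) -> float:
    m = window.mean()
    if m == 0:
        return 0.0
    return float(window.var() / m)  # population variance


def fano_window_scores(
    thresholds: np.ndarray,
    d: np.ndarray,
    window_sizes=DEFAULT_WINDOW_SIZES,
) -> list[TransformedCurve]:
    """Sliding-window Fano factor of the diff curve, one curve per width.

    Windows are centred and shrink at the curve boundaries.
    """
    n = len(d)
    out = []
    for w in window_sizes:
        if w < 2 or w > n:
            continue
        half = w // 2
        values = np.empty(n)
        for i in range(n):
            lo = max(0, i - half)
            hi = min(n, i - half + w)
            values[i] = _fano(d[lo:hi])
        out.append(TransformedCurve(np.asarray(thresholds), values, w))
    if not out:
        raise ThresholdingError(
            f"no usable window size for a diff curve of length {n}"
        )
    return out


def mad_candidates(
    tc: TransformedCurve, k_set=DEFAULT_MAD_FACTORS
) -> list[Candidate]:
    """Median/MAD candidates on the log10 projection of a window-score curve.

    For each factor ``k`` the candidate is the lowest threshold whose score
    falls at or below ``median(y) + k * MAD(y)`` (MAD unscaled); factors with
    no qualifying point emit nothing.
    """
    if len(tc) == 0:
        return []
    y = tc.log10_values
    med = float(np.median(y))
    mad = float(np.median(np.abs(y - med)))
    cands = []
    for k in k_set:
        cutoff = med + k * mad
        idx = np.nonzero(y <= cutoff)[0]
        if idx.size:
            cands.append(
                Candidate(
                    threshold=float(tc.thresholds[idx[0]]),
                    source="mad",
                    window_size=tc.window_size,
                    mad_factor=float(k),
                )
            )
    return cands


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, SSE)."""
    coeffs, residuals, *_ = np.polyfit(x, y, 1, full=True)
    sse = float(residuals[0]) if residuals.size else 0.0
    return float(coeffs[0]), float(coeffs[1]), sse


def two_piece_fit_candidates(
    tc: TransformedCurve,
    original: SpotCountCurve,
    use_log: bool = True,
) -> list[Candidate]:
    """Two-piece linear fit of the L-shaped window-score curve.

    The breakpoint is chosen by exhaustive search minimising the summed SSE
    of independent lines fit to the left and right segments (each segment
    keeps at least 3 points).  Emits the breakpoint's threshold and the
    leftmost threshold where the right-hand line first meets or crosses the
    (log10-projected) original count curve.
    """
    n = len(tc)
    if n < 5:
        return []
    x = np.asarray(tc.thresholds, dtype=float)
    y = tc.log10_values if use_log else tc.values.astype(float)

    best = None
    for b in range(2, n - 2):
        _, _, sse_l = _line_fit(x[: b + 1], y[: b + 1])
        slope_r, icept_r, sse_r = _line_fit(x[b:], y[b:])
        total = sse_l + sse_r
        if best is None or total < best[0]:
            best = (total, b, slope_r, icept_r)
    _, b, slope_r, icept_r = best

    cands = [
        Candidate(
            threshold=float(x[b]),
            source="fit_breakpoint",
            window_size=tc.window_size,
        )
    ]
    # Leftmost meeting/crossing of the right-hand line with the original
    # count curve (same projection as the fit).
    ot = np.asarray(original.thresholds, dtype=float)
    oc = original.counts.astype(float)
    oy = np.log10(oc + 1.0) if use_log else oc
    line = slope_r * ot + icept_r
    gap = line - oy
    crossing = None
    for i in range(len(ot)):
        if gap[i] == 0:
            crossing = ot[i]
            break
        if i > 0 and np.sign(gap[i]) != np.sign(gap[i - 1]):
            crossing = ot[i]
            break
    if crossing is not None:
        cands.append(
            Candidate(
                threshold=float(crossing),
                source="fit_intersection",
                window_size=tc.window_size,
            )
        )
    return cands


DEFAULT_SOURCE_WEIGHTS = {
    "mad": 1.0,
    "fit_breakpoint": 1.0,
    "fit_intersection": 1.0,
}


def select_threshold(
    curve: SpotCountCurve,
    preset: str = "default",
    window_sizes=DEFAULT_WINDOW_SIZES,
    mad_factors=DEFAULT_MAD_FACTORS,
    source_weights: dict[str, float] | None = None,
    use_log_fit: bool = True,
) -> ThresholdResult:
    """Pool candidates from every window size and strategy; pick one value.

    The default pick is the rounded weighted mean of the pool (equal weights
    unless per-source weights are given).  Precision/recall presets shift
    the pick to ``mean + lambda * SD`` with ``lambda`` from
    :data:`PRESET_LAMBDA`, clipped to the pool extremes.
    """
    if preset not in PRESET_LAMBDA:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESET_LAMBDA)}")
    weights_by_source = dict(DEFAULT_SOURCE_WEIGHTS)
    if source_weights:
        weights_by_source.update(source_weights)

    thresholds, d = diff_and_trim(curve)
    pool: list[Candidate] = []
    for tc in fano_window_scores(thresholds, d, window_sizes):
        pool.extend(mad_candidates(tc, mad_factors))
        pool.extend(two_piece_fit_candidates(tc, curve, use_log=use_log_fit))

    # Fit candidates can stray outside the scanned interval; keep the pool
    # inside the scan range.
    lo_t, hi_t = float(curve.thresholds[0]), float(curve.thresholds[-1])
    pool = [c for c in pool if lo_t <= c.threshold <= hi_t]
    if not pool:
        raise ThresholdingError("auto thresholding failed: empty candidate pool")

    values = np.array([c.threshold for c in pool], dtype=float)
    wts = np.array([weights_by_source.get(c.source, 1.0) for c in pool])
    if not np.any(wts > 0):
        raise ThresholdingError("auto thresholding failed: zero total weight")
    mean = float(np.average(values, weights=wts))
    std = float(np.sqrt(np.average((values - mean) ** 2, weights=wts)))
    lam = PRESET_LAMBDA[preset]
    raw = mean + lam * std
    pool_min = float(values.min())
    pool_max = float(values.max())
    selected = int(round(min(max(raw, pool_min), pool_max)))
    return ThresholdResult(
        selected=selected,
        pool_min=pool_min,
        pool_max=pool_max,
        pool_mean=mean,
        pool_std=std,
        preset=preset,
        candidates=pool,
    )
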