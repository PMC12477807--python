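"""End-to-end orchestration: preprocess -> detect -> threshold -> quantify.

The pipeline mirrors batch use: each input image is cleaned, filtered,
swept over the suggested threshold range, auto-thresholded (or given a
fixed override, e.g. a batch-mean threshold), and optionally quantified
against cell masks.  Every parameter and derived decision is logged so
threshold selections stay auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .detect import (
    ScanRange,
    SpotCountCurve,
    counts_vs_threshold,
    find_local_maxima_3d,
    suggest_scan_range,
)
from .preprocess import find_and_clean_dead_pixels, log_filter, rescale_if_low_range
from .quantify import count_per_cell, fit_spot, integrate_signal, on_cell_stats
from .stack import ImageStack, LabelMask
from .threshold import ThresholdResult, select_threshold

logger = logging.getLogger("punctakit")

__all__ = ["RunConfig", "ImageResult", "run_pipeline", "detect_image",
           "batch_threshold_stats"]


@dataclass
class RunConfig:
    inputs: list
    channel: int = 0
    t_min: int | None = None
    t_max: int | None = None
    preset: str = "default"
    fixed_threshold: int | None = None
    quantify: bool = False
    cell_mask: str | None = None
    nuclei_mask: str | None = None
    on_cutoff: int = 2
    output_dir: str | None = None
    seed: int = 0


@dataclass
class ImageResult:
    path: str
    scan: ScanRange
    curve: SpotCountCurve
    calls: pd.DataFrame              # base maxima with intensities
    threshold: ThresholdResult | None
    selected_threshold: int
    retained_calls: pd.DataFrame
    cells: list | None = None
    background_calls: int | None = None
    spots: list = field(default_factory=list)
    error: str | None = None


def detect_image(
    stack: ImageStack,
    t_min: int | None = None,
    t_max: int | None = None,
):
    """Preprocess and detect: returns (filtered, scan, calls, curve)."""
    cleaned, dead = find_and_clean_dead_pixels(stack)
    if dead:
        logger.info("repaired %d dead pixel(s)", len(dead))
    rescaled = rescale_if_low_range(cleaned)
    filtered = log_filter(rescaled)
    filtered.rescale_applied = rescaled is not cleaned
    scan = suggest_scan_range(filtered)
    if t_min is not None or t_max is not None:
        scan = ScanRange(t_min or scan.t_min, t_max or scan.t_max, scan.step)
    logger.info("scan range %d..%d", scan.t_min, scan.t_max)
    calls = find_local_maxima_3d(filtered, t_min=scan.t_min)
    curve = counts_vs_threshold(calls, scan)
    return filtered, scan, calls, curve


def _process_one(stack: ImageStack, cfg: RunConfig, path: str) -> ImageResult:
    filtered, scan, calls, curve = detect_image(stack, cfg.t_min, cfg.t_max)
    if cfg.fixed_threshold is not None:
        thresh_result = None
        selected = int(cfg.fixed_threshold)
        logger.info("%s: fixed threshold override %d", path, selected)
    else:
        thresh_result = select_threshold(curve, preset=cfg.preset)
        selected = thresh_result.selected
        logger.info(
            "%s: selected threshold %d (pool %g..%g mean %.2f sd %.2f)",
            path, selected, thresh_result.pool_min, thresh_result.pool_max,
            thresh_result.pool_mean, thresh_result.pool_std,
        )
    retained = calls.loc[calls["intensity"] >= selected].reset_index(drop=True)
    result = ImageResult(
        path=path, scan=scan, curve=curve, calls=calls,
        threshold=thresh_result, selected_threshold=selected,
        retained_calls=retained,
    )
    if cfg.quantify:
        spots = []
        for row in retained.itertuples(index=False):
            spot = fit_spot(stack, (int(row.x), int(row.y), int(row.z)))
            spot.total_signal = integrate_signal(stack, spot)
            spots.append(spot)
        result.spots = spots
        if cfg.cell_mask is not None:
            cells = pio.read_label_mask(cfg.cell_mask)
            nuclei = (
                pio.read_label_mask(cfg.nuclei_mask)
                if cfg.nuclei_mask
                else None
            )
            cell_stats, bg = count_per_cell(
                retained, cells, nuclei, cutoff=cfg.on_cutoff
            )
            result.cells = cell_stats
            result.background_calls = bg
            prop, mean_on = on_cell_stats(cell_stats)
            logger.info(
                "%s: %d cells, ON proportion %.3f, mean per ON cell %s",
                path, len(cell_stats), prop,
                "n/a" if mean_on is None else f"{mean_on:.2f}",
            )
    return result


def run_pipeline(cfg: RunConfig) -> list[ImageResult]:
    """Run the full pipeline over a batch of inputs.

    Inputs may be file paths or in-memory :class:`ImageStack` objects.
    Per-image failures are logged and recorded; a batch where every image
    fails raises ``RuntimeError``.
    """
    results = []
    for item in cfg.inputs:
        path = str(item)
        try:
            stack = (
                item
                if isinstance(item, ImageStack)
                else pio.read_stack(item, cfg.channel)
            )
            result = _process_one(stack, cfg, path)
        except Exception as exc:  # batch mode: log and continue
            logger.error("%s failed: %s", path, exc)
            results.append(
                ImageResult(
                    path=path, scan=ScanRange(1, 2),
                    curve=SpotCountCurve(np.array([1]), np.array([0])),
                    calls=pd.DataFrame(), threshold=None,
                    selected_threshold=0,
                    retained_calls=pd.DataFrame(), error=str(exc),
                )
            )
            continue
        results.append(result)
        if cfg.output_dir is not None:
            out = Path(cfg.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            stem = Path(path).stem or "image"
            pio.write_call_table(out / f"{stem}_calls.csv", result.retained_calls)
            pd.DataFrame(
                {"threshold": result.curve.thresholds, "count": result.curve.counts}
            ).to_csv(out / f"{stem}_curve.csv", index=False)
    if results and all(r.error is not None for r in results):
        raise RuntimeError("all images in the batch failed")
    return results


def batch_threshold_stats(
    results: list[ImageResult] | list[float],
) -> tuple[float, float, np.ndarray]:
    """Batch mean, coefficient of variation and normalized thresholds.

    Accepts pipeline results or raw threshold values; needs at least two.
    CV is (population) SD over mean; normalized thresholds divide by the
    batch mean.
    """
    values = np.array(
        [
            r.selected_threshold if isinstance(r, ImageResult) else r
            for r in results
            if not (isinstance(r, ImageResult) and r.error)
        ],
        dtype=float,
    )
    if len(values) < 2:
        raise ValueError("batch statistics need at least 2 results")
    mean = float(values.mean())
    if mean == 0:
        raise ValueError("batch mean threshold is zero")
    cv = float(values.std(ddof=1) / mean)
    return mean, cv, values / mean
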