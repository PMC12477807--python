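# punctakit

Automated detection, thresholding and quantification of diffraction-limited
fluorescent puncta in 2D images and 3D image stacks — the kind of data
produced by single-molecule RNA-FISH, immunofluorescence of chromatin marks,
or GFP-tagged protein imaging. It is aimed at labs that need to count
transcripts (or similar puncta) per cell across large image batches without
hand-picking an intensity threshold for every image, and it ships with a
synthetic-image simulator so the whole pipeline can be exercised and
benchmarked against a known ground truth without any external data.

## Method

**Detection.** Each z slice of the (dead-pixel-repaired, optionally
rescaled) stack is band-pass filtered with a Laplacian of Gaussian: a
normalized truncated Gaussian kernel of side `2r+1` (default `r = 7`, width
`a = 2`),

```
g(x, y) ∝ exp(−((x−x₀)² + (y−y₀)²) / 2a²),   Σ g = 1,
```

followed by a 3×3 edge-detection kernel (−1 everywhere, +8 at the centre).
A border of width `r` is zeroed and negative responses are floored at 0.
Local maxima of the filtered stack are found in 3D (26-connectivity) and
kept when they exceed the mean of their filtered z slice; sweeping an
intensity threshold `t` over an automatically suggested range gives the
spot-count curve `N(t)`.

**Threshold selection.** The selector looks for the levelling-out of
`N(t)`. It trims the absolute difference curve `d(t) = |N(t+1) − N(t)|` so
it starts at its peak, slides Fano-factor windows (`σ²/μ`) of several
widths across `d`, and on the `log₁₀(y+1)` projection of each window-score
curve collects candidate thresholds two ways: the lowest `t` with score at
or below `median + k·MAD` for `k ∈ {−1, −0.75, …, +1}`, and the breakpoint
and curve-intersection of an exhaustive two-piece linear fit. The rounded
weighted mean of the pooled candidates is the selected threshold;
precision/recall presets shift the pick by ±½ or ±1 pool SD.

**Quantification.** Each retained call is fitted slice-by-slice with a 2D
Gaussian inside a 9×9×5 crop; the integrated, background-subtracted signal
is summed over the fitted ellipsoid (FWHM lateral radii). Calls are
assigned to cells via label masks, and a cell is "ON" when its count
reaches a channel-specific cutoff (e.g. ≥ 8 or ≥ 2 transcripts).

**Benchmarking.** A call matches a reference spot when it lies within 4
voxel units in xy and 2 z planes (one-to-one, closest first). Recall
`R = TP/(TP+FN)`, precision `P = TP/(TP+FP)` and `F = 2RP/(R+P)` are
computed per threshold; PR-AUC is the area of the recall–precision polygon
extrapolated to the axes.

## Worked example

```python
from punctakit import SimParams, simulate_stack, select_threshold
from punctakit.pipeline import detect_image

stack, truth = simulate_stack(SimParams(width=192, height=192, depth=12,
                                        n_spots=60, seed=9))
_, _, calls, curve = detect_image(stack)
result = select_threshold(curve)
print(result.selected, int((calls.intensity >= result.selected).sum()))
```

prints `60 58`: the selector picked 60 a.u. from a candidate pool spanning
30–273 a.u., and 58 calls survive that threshold — within two of the 60
simulated spots (the remainder sit too close to the frame edge or to a
brighter neighbour to be resolved). The scripts in `examples/` walk through
each capability the same way — simulation, detection, threshold presets,
per-cell quantification, benchmarking against ground truth, degradation
filters and the 3D-vs-projection comparison — each printing the numbers it
computes and what they mean. A thin CLI mirrors the library
(`punctakit simulate|detect|threshold|quantify|benchmark|mip|pipeline`).

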