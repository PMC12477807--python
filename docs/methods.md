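# Methods

This note records the models, parameter choices and numerical conventions
behind punctakit, including the places where the design was genuinely open
and what was decided.

## Detection model

Puncta are modelled as diffraction-limited 3D Gaussian intensity bumps on a
noisy background. Detection filters each z slice independently with a
Laplacian of Gaussian built from two convolutions:

1. a truncated Gaussian kernel of side `2r+1` per axis with unnormalized
   weights `exp(−(Δx²+Δy²)/2a²)`, normalized to sum 1. Any constant
   leading factor cancels under normalization, so only the width `a`
   matters. Defaults `r = 7`, `a = 2` are used for every image;
2. the 3×3 edge kernel (−1 everywhere, +8 centre, zero-sum).

Both convolutions replicate edge values. A plain zero pad would leave a
ring of spurious positive response in the first untrimmed row/column (a
constant image would not filter to exactly zero there), so replication is
used and the border of width `r` is then zeroed outright. Negative
responses are floored at 0 so integer intensity thresholds (≥ 1 a.u.)
remain meaningful, and float residue below 1e−9 is snapped to zero.
Per-slice means of the filtered image — used by the detection-stage
slice-mean filter — are computed once over all voxels including the
trimmed zeros and held fixed across the threshold sweep.

Dead pixels (camera defects) are repaired first: a non-border (x, y)
position is dead when its edge-filtered value reaches the filtered plane's
mean + 3 SD on at least half of `max(6, ⌈D/4⌉)` evenly spaced sample
planes (all planes when D < 6). Planes whose filtered values have zero
spread are skipped — on a featureless plane nothing is anomalous.
Replacement is the 8-neighbour in-plane mean of the original values.
Images whose intensity range is narrower than 256 are linearly rescaled to
0–511 before filtering.

Local maxima are voxels ≥ all 26 neighbours (8 for a single plane);
equal-valued connected plateaus collapse to one call at the rounded
centroid, so saturated spots are not silently dropped. The
count-versus-threshold curve is computed by counting base maxima with
intensity ≥ t; zeroing sub-threshold voxels removes competitors but never
creates maxima, so this is exactly equivalent to re-running detection per
threshold (verified exhaustively on 16³ stacks).

The scan range defaults to 10–500 a.u.; the floor drops to 5 or 1 when the
80th-percentile filtered intensity falls below 10 or 5, and the ceiling
rises above 500 when the smaller of 1.1× the 99.9th percentile (the "top
0.1 %" with 10 % leeway) and max/10 exceeds it.

## Threshold selection

Tunable parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| window sizes | 5, 10, 15, 20 | Fano sliding-window widths (threshold units) |
| MAD factors | −1.0 … +1.0 step 0.25 | cutoffs `median + k·MAD` on the log-projected score curve |
| source weights | equal | per-source weights in the candidate pool average |
| preset λ | −1, −0.5, 0, +0.5, +1 | pool-SD multiples for recall-strong … precision-strong |

Open choices and their resolutions:

* the log projection is `log₁₀(y+1)` so zero scores are representable.
  The +1 costs exact invariance of MAD candidates under count rescaling
  (a pure log would shift all values by a constant); in practice the
  selected threshold stays inside the same elbow interval across two
  decades of scaling, which is what the tests assert;
* MAD is the unscaled median absolute deviation (no 1.4826 factor);
* Fano windows are centred and shrink at the curve boundaries;
* the two-piece fit runs on the log projection by default (the raw curve
  is available via `use_log=False`); the breakpoint search is exhaustive
  with at least 3 points per segment, and the second candidate is the
  leftmost threshold where the right-hand line meets the log-projected
  original count curve;
* candidates falling outside the scanned interval are discarded; the
  final pick is clipped to the pool extremes so presets cannot escape the
  candidate range;
* a curve with zero diff everywhere (flat) raises an explicit
  auto-thresholding failure rather than returning a guess.

Degenerate input worth knowing about: an image with *exactly* zero
background noise produces a count curve that begins on a flat plateau, so
the diff curve has no noise-collapse peak and the trim step anchors on the
signal-death drop instead — selection then lands inside the signal drop.
Such sterile images are exactly what the zero-voxel-proportion quality
metric (filter at ≥ 0.7) is designed to exclude; with any realistic noise
floor the selector behaves as intended, which is what the clean-limit test
exercises (noise SD 5 under amplitude 700).

## Quantification

Each call is fitted inside a crop of xy radius 4 and z radius 2 (clipped
at edges). Every crop plane gets an independent least-squares fit of
`A·exp(−((x−x₀)²+(y−y₀)²)/2a²) + c`. The mapping from per-slice 2D fits
to a 3D spot is an open design point; the implementation takes lateral
centre and width from the brightest-slice fit, the axial centre as the
amplitude-weighted mean plane, and the axial extent as the interpolated
FWHM of the per-slice amplitude profile. Local background is the median
of the crop's boundary voxels. Non-convergent fits fall back to the raw
maximum with a default PSF width of 1.3 px, flagged. Integration sums
`max(I − b, 0)` over the ellipsoid with lateral semi-axes at the fitted
FWHM (`2√(2 ln 2)·a`) and axial semi-axis `max(z_extent/2, 1)`.

Per-cell counts assign each call to the mask label under its voxel;
label-0 calls are reported separately and counts are conserved. The ON
cutoff is inclusive ("at least"), defaults 8 (channel 1) and 2
(channel 2).

Background masks come from the z standard-deviation projection of a
transmission stack. The projection histogram is taken as bimodal only
when two peaks are separated by a valley deeper than half the smaller
peak — wiggles on a unimodal noise histogram must not trigger the bimodal
path — and is then thresholded at the valley; otherwise the projection is
min-max stretched and the threshold is placed where the smoothed
histogram's first-difference, after the peak, falls below its first local
minimum divided by a constant (default 2, configurable). Holes smaller
than 64 px are filled and the mask is forced disjoint from the cell mask.

## Benchmarking

Matching is greedy closest-first: candidate pairs within Euclidean xy
distance ≤ 4 and |Δz| ≤ 2 (both inclusive) are accepted in
(xy distance, |Δz|, call order) order, one-to-one. Greedy matching is a
maximal, not maximum, matching: on crossing configurations it can match
one pair fewer than an optimal assignment. This is intentional — it is
the stated matching rule — and on well-separated spot sets the two
coincide, which the tests verify by brute force. PR-AUC sorts unique
(recall, precision) points by recall, prepends (0, P_first), appends
(R_last, 0) and integrates trapezoidally over recall, clipped to [0, 1].
For simulated images a 7-px xy border is trimmed from both call and
reference sets before matching.

## Simulator

`simulate_stack` emulates single-channel FISH-like stacks: constant
background plus Gaussian read noise (clipped at 0), anisotropic 3D
Gaussian spots with subpixel centres, uniform relative amplitude jitter,
optional clustering around shared centres, and uint16 quantization.
Default conditions are the standard benchmark batch: 512×512×16 voxels,
background 500 a.u., noise SD 50, per-spot amplitude uniform on 8–20×
the noise SD (mean 700, relative jitter 3/7), PSF σ 1.3 px laterally and
0.9 planes axially. Spot centres keep a 7-px margin from the x/y edges
(matching the analysis-region trim) and stay within planes [1, D−2] so
the fitting crop is never more than half-truncated axially.

Three degradation filters emulate common real-image imperfections:

* **diffuse blur** — normalized 3D Gaussian, xy radius 7, z radius 2,
  width 4 (dense non-punctate signal, as in GFP-fusion images);
* **edge darkening** — per-plane radial attenuation `1 − f·dist/dist_max`
  with `f ~ U(0.01, 0.10)` and up to 5 % multiplicative noise on the
  filter (uneven illumination). The noise is applied unclipped, so the
  expected value at the plane centre is exactly the raw value; a single
  pixel can brighten by at most 5 %;
* **defocus** — each plane blended with its radius-5 Gaussian-blurred
  version, blend weight `min(1, s(z) − 1)` where the strength `s` ramps
  linearly from 1 at the centre plane to a per-stack maximum
  `~U(1.1, 2.5)` at the extremes. The blur-strength mechanics are an
  interpretation (blend weight derived from the scaled strength) and are
  isolated behind this one function.

What the simulator does *not* reproduce: Poisson shot noise and camera
gain (noise is Gaussian), optical aberrations beyond the three filters,
autofluorescent cellular texture, and dense "cloud" signal that cannot be
decomposed into puncta. Tests passing on simulated data therefore
demonstrate algorithmic correctness and closed-loop detection performance
under controlled conditions, not performance on experimental images with
manually curated reference sets.

## Problem sizes

The standard benchmark batch is forty 512×512×16 stacks — large enough
that per-image PR-AUC and F-score distributions are stable (their spread
across seeds is small compared to the margins of interest) while the whole
batch, detection and scoring included, completes in a few minutes on one
CPU. Exhaustive-oracle property tests run on ≤ 16³ grids and ≤ 8-point
sets, where brute force is tractable. Parameter-recovery statistics use
200 noiseless single-spot images.

## Known limitations

* Cell segmentation itself is out of scope; masks are consumed as input.
* Dense cluster/"cloud" resolution is not implemented; clustered spots
  closer than the matching tolerance merge into single calls.
* Control-image ("noise ceiling") assisted thresholding is an extension
  point only; the selector operates on the count curve alone.
* Threshold selection assumes the count curve has a noise-collapse
  segment; perfectly sterile images (see above) violate that assumption
  and are flagged by the ZVP quality metric instead.
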