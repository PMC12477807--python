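"""Dead-pixel repair, conditional rescaling and the slice-wise LoG filter.

The band-pass filter that drives detection is a Laplacian-of-Gaussian built
from two pieces applied per z slice: a truncated, normalized Gaussian kernel
of side ``2r + 1`` (width parameter ``a``; the kernel is the normalized
exponential ``exp(-(dx^2 + dy^2) / (2 a^2))``), followed by a 3x3
edge-detection kernel (-1 everywhere, +8 at the centre, zero-sum).  After
filtering, a border of width ``r`` in x and y is zeroed and negative
responses are floored at 0 so intensity thresholds on the result stay
meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack import FilteredStack, ImageStack

__all__ = [
    "EDGE_KERNEL",
    "GaussianKernel",
    "make_gaussian_kernel",
    "find_and_clean_dead_pixels",
    "rescale_if_low_range",
    "log_filter",
]

#: 3x3 edge-detection (discrete Laplacian) kernel; weights sum to zero.
EDGE_KERNEL = np.array(
    [[-1.0, -1.0, -1.0], [-1.0, 8.0, -1.0], [-1.0, -1.0, -1.0]]
)

#: Standard Gaussian parameters used for all detection runs.
DEFAULT_XY_RADIUS = 7
DEFAULT_AMOUNT = 2.0


@dataclass(frozen=True)
class GaussianKernel:
    """Truncated Gaussian smoothing kernel (2D or 3D).

    ``weights`` has side lengths ``2r + 1`` per axis and sums to 1.
    """

    r_x: int
    r_y: int
    amount: float
    weights: np.ndarray
    r_z: int | None = None

    @property
    def is_3d(self) -> bool:
        return self.r_z is not None


def make_gaussian_kernel(
    r_x: int,
    r_y: int | None = None,
    r_z: int | None = None,
    amount: float = DEFAULT_AMOUNT,
) -> GaussianKernel:
    """Build the normalized truncated Gaussian kernel.

    The unnormalized weight at offset ``(dx, dy[, dz])`` is
    ``exp(-(dx^2 + dy^2 [+ dz^2]) / (2 * amount^2))``; any constant leading
    factor cancels under normalization.  ``r_z`` switches to the 3D form.
    """
    if r_y is None:
        r_y = r_x
    if r_x < 1 or r_y < 1 or (r_z is not None and r_z < 1):
        raise ValueError("kernel radii must be >= 1")
    if amount <= 0:
        raise ValueError("amount must be > 0")
    dx = np.arange(-r_x, r_x + 1, dtype=float)
    dy = np.arange(-r_y, r_y + 1, dtype=float)
    two_a2 = 2.0 * amount * amount
    wx = np.exp(-(dx**2) / two_a2)
    wy = np.exp(-(dy**2) / two_a2)
    if r_z is None:
        weights = np.outer(wy, wx)
    else:
        dz = np.arange(-r_z, r_z + 1, dtype=float)
        wz = np.exp(-(dz**2) / two_a2)
        weights = wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
    weights /= weights.sum()
    return GaussianKernel(r_x=r_x, r_y=r_y, r_z=r_z, amount=amount, weights=weights)


def edge_filter_slice(plane: np.ndarray) -> np.ndarray:
    """Apply the 3x3 edge-detection kernel to one plane (replicate padding)."""
    return ndimage.convolve(
        np.asarray(plane, dtype=float), EDGE_KERNEL, mode="nearest"
    )


def _sampled_slice_indices(depth: int) -> np.ndarray:
    """Evenly spaced sample planes for dead-pixel detection.

    Samples ``max(6, ceil(D / 4))`` planes including the first and last;
    all planes when the stack is thinner than 6.
    """
    if depth < 6:
        return np.arange(depth)
    n = max(6, math.ceil(depth / 4))
    n = min(n, depth)
    return np.unique(np.round(np.linspace(0, depth - 1, n)).astype(int))


def find_and_clean_dead_pixels(
    stack: ImageStack,
) -> tuple[ImageStack, list[tuple[int, int]]]:
    """Detect and repair camera-defect (x, y) positions.

    A non-border position is flagged dead when its edge-filtered value is at
    least the filtered plane's mean plus 3 SD on at least half of the sampled
    planes.  Dead positions are replaced plane-by-plane with the mean of the
    8 in-plane neighbours (computed from the original values).  Returns the
    cleaned stack and the list of dead ``(x, y)`` positions.
    """
    v = stack.voxels
    depth, h, w = v.shape
    samples = _sampled_slice_indices(depth)
    hits = np.zeros((h, w), dtype=np.int32)
    for z in samples:
        filt = edge_filter_slice(v[z])
        sd = filt.std()
        if sd == 0:  # featureless plane: nothing is anomalous
            continue
        thresh = filt.mean() + 3.0 * sd
        hits += (filt >= thresh).astype(np.int32)
    dead = hits >= (len(samples) + 1) // 2  # "at least half" of samples
    dead[0, :] = dead[-1, :] = False
    dead[:, 0] = dead[:, -1] = False
    ys, xs = np.nonzero(dead)
    dead_list = [(int(x), int(y)) for y, x in zip(ys, xs)]
    if not dead_list:
        return stack.copy(), []

    cleaned = v.astype(float).copy()
    neighbor_kernel = np.array(
        [[1.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 1.0]]
    ) / 8.0
    for z in range(depth):
        means = ndimage.convolve(
            v[z].astype(float), neighbor_kernel, mode="constant", cval=0.0
        )
        cleaned[z][dead] = means[dead]
    if np.issubdtype(v.dtype, np.integer):
        cleaned = np.round(cleaned).astype(v.dtype)
    return ImageStack(cleaned, stack.voxel_size), dead_list


def rescale_if_low_range(stack: ImageStack) -> ImageStack:
    """Linearly rescale low-dynamic-range images to 0-511.

    Applies only when ``max - min < 256``; constant images pass through
    unchanged.  Output values are ``round((I - min) * 511 / (max - min))``.
    """
    v = stack.voxels
    lo = float(v.min())
    hi = float(v.max())
    span = hi - lo
    if span >= 256 or span == 0:
        return stack
    scaled = np.round((v.astype(float) - lo) * 511.0 / span).astype(np.int64)
    return ImageStack(scaled, stack.voxel_size)


def log_filter(
    stack: ImageStack,
    xy_radius: int = DEFAULT_XY_RADIUS,
    amount: float = DEFAULT_AMOUNT,
) -> FilteredStack:
    """Slice-wise LoG filter: Gaussian smooth, edge-detect, trim, floor.

    Each z plane is convolved with the ``2r+1`` square Gaussian kernel and
    then the 3x3 edge kernel (both with replicated edges, so a constant
    image filters to exactly zero).  A border of width
    ``xy_radius`` in x and y is set to zero, negative responses are floored
    at 0, and per-plane means of the result (all voxels, zeros included) are
    recorded for detection's slice-mean filter.
    """
    v = stack.voxels.astype(float)
    depth, h, w = v.shape
    side = 2 * xy_radius + 1
    if h < side or w < side:
        raise ValueError(
            f"image footprint {w}x{h} smaller than the {side}x{side} kernel"
        )
    kern = make_gaussian_kernel(xy_radius, amount=amount)
    # Separable Gaussian: the normalized 2D kernel is the outer product of
    # the normalized 1D profiles, so two 1D passes are exact.
    prof = kern.weights[xy_radius, :]
    prof = prof / prof.sum()
    smoothed = ndimage.convolve1d(v, prof, axis=2, mode="nearest")
    smoothed = ndimage.convolve1d(smoothed, prof, axis=1, mode="nearest")
    response = ndimage.convolve(
        smoothed, EDGE_KERNEL[np.newaxis, :, :], mode="nearest"
    )
    # snap float-precision residue to zero so constant regions filter to 0
    response[np.abs(response) < 1e-9] = 0.0
    response[:, :xy_radius, :] = 0.0
    response[:, h - xy_radius :, :] = 0.0
    response[:, :, :xy_radius] = 0.0
    response[:, :, w - xy_radius :] = 0.0
    np.maximum(response, 0.0, out=response)
    slice_means = response.reshape(depth, -1).mean(axis=1)
    return FilteredStack(
        voxels=response,
        slice_means=slice_means,
        trim_radius=xy_radius,
        kernel_params={"xy_radius": xy_radius, "amount": amount},
    )
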