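"""Core raster carriers: image stacks, label masks, spot call tables.

Conventions
-----------
Voxel grids are stored as numpy arrays indexed ``[z, y, x]`` (a 2D image is a
depth-1 stack).  All coordinates held in memory are 0-based integer voxel
indices with columns named ``x, y, z``; call tables written to disk are
exported 1-based, declared by a ``coord_base`` header comment (see
:mod:`punctakit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ImageStack", "LabelMask", "FilteredStack", "new_call_table"]

#: Column order for spot call tables.
CALL_COLUMNS = ("x", "y", "z", "intensity")


@dataclass
class ImageStack:
    """A single-channel intensity grid with optional physical spacing.

    Parameters
    ----------
    voxels
        Array of shape ``(D, H, W)`` with finite, non-negative intensities
        in arbitrary units.  2D arrays are promoted to depth 1.
    voxel_size
        Optional ``(x, y, z)`` spacing in nanometres.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim == 2:
            v = v[np.newaxis, :, :]
        if v.ndim != 3:
            raise ValueError(f"expected a 2D or 3D array, got ndim={v.ndim}")
        if v.size == 0:
            raise ValueError("empty image")
        if not np.all(np.isfinite(v)):
            raise ValueError("intensities must be finite")
        if np.any(v < 0):
            raise ValueError("intensities must be non-negative")
        self.voxels = v

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]

    @property
    def height(self) -> int:
        return self.voxels.shape[1]

    @property
    def width(self) -> int:
        return self.voxels.shape[2]

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        """(W, H, D)."""
        d, h, w = self.voxels.shape
        return (w, h, d)

    def slice(self, z: int) -> np.ndarray:
        return self.voxels[z]

    def copy(self) -> "ImageStack":
        return ImageStack(self.voxels.copy(), self.voxel_size)


@dataclass
class LabelMask:
    """Integer label grid: 0 = outside any cell, ``k > 0`` = cell id.

    May be 2D (applies to every z plane) or 3D (must match the stack depth).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim not in (2, 3):
            raise ValueError("label mask must be 2D or 3D")
        if not np.issubdtype(lab.dtype, np.integer):
            if np.any(lab != np.round(lab)):
                raise ValueError("labels must be integers")
            lab = lab.astype(np.int64)
        if np.any(lab < 0):
            raise ValueError("labels must be non-negative")
        self.labels = lab

    @property
    def is_3d(self) -> bool:
        return self.labels.ndim == 3

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def check_compatible(self, stack: ImageStack) -> None:
        if self.labels.shape[-2:] != (stack.height, stack.width):
            raise ValueError(
                f"mask footprint {self.labels.shape[-2:]} does not match "
                f"stack footprint {(stack.height, stack.width)}"
            )
        if self.is_3d and self.labels.shape[0] != stack.depth:
            raise ValueError("3D mask depth does not match stack depth")


@dataclass
class FilteredStack:
    """LoG-filtered stack plus the provenance detection needs.

    ``slice_means`` are the per-plane means of the filtered image (over all
    voxels, trimmed border included) fixed once at filter time; detection's
    slice-mean filter reads them rather than recomputing after thresholding.
    """

    voxels: np.ndarray                      # (D, H, W), >= 0 after flooring
    slice_means: np.ndarray                 # (D,)
    trim_radius: int
    kernel_params: dict = field(default_factory=dict)
    rescale_applied: bool = False

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]


def new_call_table(x=(), y=(), z=(), intensity=(), **extra) -> pd.DataFrame:
    """Build a spot call table with the canonical column order."""
    df = pd.DataFrame(
        {
            "x": np.asarray(x, dtype=np.int64),
            "y": np.asarray(y, dtype=np.int64),
            "z": np.asarray(z, dtype=np.int64),
            "intensity": np.asarray(intensity, dtype=float),
        }
    )
    for name, values in extra.items():
        df[name] = values
    return df
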