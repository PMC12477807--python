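"""Reading and writing stacks, masks and call tables; z projections.

TIFF files are handled through :mod:`tifffile`; pages map to z in their
native order.  Multi-channel files require an explicit channel index — no
auto-guessing.  Call tables are CSV with columns
``x,y,z,intensity[,threshold][,cell_id]``; files written here carry a
``# coord_base=1`` comment line and 1-based coordinates for interchange,
while everything in memory is 0-based.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stack import ImageStack, LabelMask

__all__ = [
    "read_stack",
    "write_stack",
    "read_label_mask",
    "read_call_table",
    "write_call_table",
    "max_intensity_projection",
    "trim_reference_to_z",
]


def read_stack(path, channel_index: int = 0) -> ImageStack:
    """Read a single- or multi-page TIFF as an :class:`ImageStack`.

    Pages become z planes.  If the file carries a channel axis (pages ×
    channels, or an explicit axis in its metadata), ``channel_index``
    selects one channel; an out-of-range index raises a ``ValueError``
    naming the available channels.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes  # e.g. 'YX', 'ZYX', 'CYX', 'ZCYX'
    except (OSError, tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"unreadable image file: {path}: {exc}") from exc

    if data.ndim == 2:
        data = data[np.newaxis]
        n_channels = 1
    elif data.ndim == 3:
        if "C" in axes and "Z" not in axes:
            c_axis = axes.index("C")
            n_channels = data.shape[c_axis]
            if not 0 <= channel_index < n_channels:
                raise ValueError(
                    f"channel {channel_index} out of range; file has "
                    f"channels 0..{n_channels - 1}"
                )
            data = np.take(data, channel_index, axis=c_axis)[np.newaxis]
        else:
            n_channels = 1
    elif data.ndim == 4:
        # Assume one of the two leading axes is channel.
        c_axis = axes.index("C") if "C" in axes else 1
        n_channels = data.shape[c_axis]
        if not 0 <= channel_index < n_channels:
            raise ValueError(
                f"channel {channel_index} out of range; file has "
                f"channels 0..{n_channels - 1}"
            )
        data = np.take(data, channel_index, axis=c_axis)
    else:
        raise ValueError(f"cannot interpret {data.ndim}-D TIFF {path}")

    if data.ndim == 3 and n_channels == 1 and channel_index != 0:
        raise ValueError(
            f"channel {channel_index} out of range; file has channels 0..0"
        )
    return ImageStack(np.asarray(data))


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF, one page per z plane."""
    tifffile.imwrite(Path(path), stack.voxels)


def read_label_mask(path) -> LabelMask:
    """Read a label-image TIFF (2D or multi-page 3D)."""
    data = tifffile.imread(Path(path))
    return LabelMask(np.asarray(data))


def write_call_table(path, calls: pd.DataFrame) -> None:
    """Write a call table CSV with 1-based coordinates.

    The first line is ``# coord_base=1``; x, y, z are shifted by +1 on the
    way out so exported tables line up with 1-based reference sets.
    """
    out = calls.copy()
    for col in ("x", "y", "z"):
        if col in out.columns:
            out[col] = out[col] + 1
    with open(path, "w", newline="") as fh:
        fh.write("# coord_base=1\n")
        out.to_csv(fh, index=False)


def read_call_table(path) -> pd.DataFrame:
    """Read a call table CSV, converting to 0-based coordinates.

    A leading ``# coord_base=<b>`` comment declares the file's base
    (default 1 for headerless interchange files written by this package).
    """
    path = Path(path)
    text = path.read_text()
    base = 1
    lines = text.splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if "coord_base" in line:
                base = int(line.split("=", 1)[1].strip())
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    for col in ("x", "y", "z"):
        if col in df.columns:
            df[col] = df[col] - base
    return df


def max_intensity_projection(
    stack: ImageStack, z_range: tuple[int, int] | None = None
) -> ImageStack:
    """Project a stack to depth 1 by taking the per-(x, y) maximum over z.

    ``z_range`` is an inclusive ``(first, last)`` slice interval; ``None``
    projects the full stack.
    """
    if z_range is None:
        lo, hi = 0, stack.depth - 1
    else:
        lo, hi = z_range
    if not (0 <= lo <= hi < stack.depth):
        raise ValueError(
            f"empty or out-of-bounds z range [{lo}, {hi}] for depth {stack.depth}"
        )
    mip = stack.voxels[lo : hi + 1].max(axis=0, keepdims=True)
    return ImageStack(mip, stack.voxel_size)


def trim_reference_to_z(
    calls: pd.DataFrame, z_lo: int, z_hi: int, slack: int = 2
) -> pd.DataFrame:
    """Restrict a reference call table to a trimmed stack's z interval.

    Calls within ``slack`` planes outside the inclusive ``[z_lo, z_hi]``
    trim window are kept (a call at ``z_lo − slack`` is still comparable to
    detections near the trim edge); everything further out is removed.
    """
    if z_lo > z_hi:
        raise ValueError("z_lo must be <= z_hi")
    keep = (calls["z"] >= z_lo - slack) & (calls["z"] <= z_hi + slack)
    return calls.loc[keep].reset_index(drop=True)
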