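"""Image and table I/O.

Volumes are multi-page TIFF stacks in (z, y, x) order.  Spacing is
taken from OME-XML metadata when present (PhysicalSizeZ/Y/X, assumed
µm); otherwise the caller must supply it.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import tifffile

from mitomorph.errors import ValidationError
from mitomorph.grids import LabelVolume, VoxelGrid, as_spacing

__all__ = [
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
    "ome_spacing",
    "read_image2d",
    "write_image2d",
]


def ome_spacing(path) -> tuple[float, float, float] | None:
    """(z, y, x) µm spacing from OME metadata, if the file carries any."""
    with tifffile.TiffFile(path) as tf:
        xml = tf.ome_metadata
    if not xml:
        return None
    vals = {}
    for ax in "ZYX":
        m = re.search(rf'PhysicalSize{ax}="([\d.eE+-]+)"', xml)
        if m:
            vals[ax] = float(m.group(1))
    if len(vals) == 3:
        return (vals["Z"], vals["Y"], vals["X"])
    return None


def _read_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValidationError(f"{path}: expected a 2D/3D TIFF, got ndim={arr.ndim}")
    return arr


def read_volume(path, spacing=None) -> VoxelGrid:
    """Load an intensity volume; spacing from OME metadata or argument."""
    sp = ome_spacing(path) if spacing is None else spacing
    if sp is None:
        raise ValidationError(
            f"{path}: no OME spacing metadata; pass spacing explicitly"
        )
    return VoxelGrid(_read_stack(path).astype(np.float64), as_spacing(sp))


def read_labels(path, spacing=None) -> LabelVolume:
    sp = ome_spacing(path) if spacing is None else spacing
    if sp is None:
        raise ValidationError(
            f"{path}: no OME spacing metadata; pass spacing explicitly"
        )
    arr = _read_stack(path)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"{path}: label image has non-integer values")
        arr = arr.astype(np.int32)
    return LabelVolume(arr, as_spacing(sp))


def _ome_kwargs(spacing):
    sp = as_spacing(spacing)
    return dict(
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": sp[0], "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": sp[1], "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": sp[2], "PhysicalSizeXUnit": "µm",
        },
    )


def write_volume(path, grid: VoxelGrid) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, grid.values.astype(np.float32), **_ome_kwargs(grid.spacing)
    )


def write_labels(path, labels: LabelVolume) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    arr = labels.labels
    dtype = np.uint16 if arr.max() < 2**16 else np.uint32
    tifffile.imwrite(path, arr.astype(dtype), **_ome_kwargs(labels.spacing))


def read_image2d(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a single-plane 2D image")
    return arr


def write_image2d(path, image: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image), photometric="minisblack")
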