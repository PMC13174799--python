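"""Core array containers shared by all stages.

Axis order is (z, y, x), 0-based; ``spacing`` is given per axis in the
same order, in micrometers per voxel.  Physical measurements always
apply per-axis spacing so anisotropic stacks are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "LabelVolume", "as_spacing"]


def as_spacing(spacing, ndim: int = 3) -> tuple[float, ...]:
    """Validate and normalize a per-axis spacing vector (µm/voxel)."""
    sp = tuple(float(s) for s in np.atleast_1d(np.asarray(spacing, dtype=float)).ravel())
    if len(sp) == 1:
        sp = sp * ndim
    if len(sp) != ndim:
        raise ValueError(f"spacing must have {ndim} components, got {len(sp)}")
    if any(not np.isfinite(s) or s <= 0 for s in sp):
        raise ValueError(f"spacing components must be positive and finite, got {sp}")
    return sp


@dataclass
class VoxelGrid:
    """3D scalar intensity array with per-axis spacing in µm (z, y, x)."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = as_spacing(self.spacing)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Calibrated volume of one voxel, µm³."""
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume:
    """3D integer label array; 0 = background, k > 0 = object id."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    counts: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = as_spacing(self.spacing)
        ids, n = np.unique(self.labels[self.labels > 0], return_counts=True)
        self.counts = dict(zip(ids.tolist(), n.tolist()))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def ids(self) -> list[int]:
        """Sorted nonzero object ids present in the volume."""
        return sorted(self.counts)
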