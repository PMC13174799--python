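"""2D cross-section morphometrics for TEM-style masks.

Perimeter is the total length of the sub-pixel marching-squares
contour at level 0.5 (crack-boundary edge counting would overestimate
circle perimeters by ~27% and is deliberately avoided).  Length is the
maximum Feret diameter taken over the object's pixel centers — the
common ImageJ/FIJI-style convention for "mitochondrial length"; area
is the exact pixel count times the squared pixel size.  Cristae are
supplied as label masks and summarized as per-crista areas plus a
density (crista area / mitochondrion area).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import find_contours

from mitomorph.errors import ContainmentError, MissingObjectError, ValidationError

__all__ = [
    "Contour2D",
    "CristaeMetrics",
    "trace_perimeter",
    "length_and_area",
    "count_and_total_area",
    "crista_metrics",
    "measure_sections",
    "max_feret_diameter",
]


@dataclass
class Contour2D:
    """Closed polygon in µm for one object (outer boundary or hole)."""

    object_id: int
    vertices: np.ndarray  # (n, 2) (row, col) µm; implicitly closed
    is_hole: bool = False

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValidationError("contour needs >= 3 (row, col) vertices")

    def perimeter(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def signed_area(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        x, y = closed[:, 1], closed[:, 0]
        return float(0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


@dataclass
class CristaeMetrics:
    areas_um2: list[float] = field(default_factory=list)
    density: float = 0.0

    @property
    def n_cristae(self) -> int:
        return len(self.areas_um2)


def _as_labels2d(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValidationError("expected a 2D image")
    if arr.dtype == bool:
        lab, _ = ndi.label(arr, structure=np.ones((3, 3), dtype=bool))
        return lab
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError("expected a boolean mask or integer label image")
    return arr


#: Gaussian pre-smoothing (px) of the mask before contour extraction.
#: Marching squares straight on a 0/1 field locks segments to 0/45
#: degree steps and overestimates circle perimeters by ~6%; smoothing
#: restores sub-pixel placement.  Objects small enough to smooth below
#: the iso-level fall back to the raw mask.
DEFAULT_MASK_SIGMA_2D = 0.8


def trace_perimeter(
    mask2d: np.ndarray,
    spacing_um: float = 1.0,
    mask_sigma: float = DEFAULT_MASK_SIGMA_2D,
) -> tuple[list[Contour2D], dict[int, float]]:
    """Sub-pixel contours and per-object perimeters.

    A binary mask is labeled at 8-connectivity first.  For each object
    the marching-squares contour at level 0.5 is extracted from its
    zero-padded (and lightly pre-smoothed) mask; the largest-area
    contour is the outer boundary and contributes the object's
    perimeter, any others are holes and are reported but excluded
    from P.
    """
    if spacing_um <= 0:
        raise ValidationError("spacing must be positive")
    labels = _as_labels2d(mask2d)
    contours: list[Contour2D] = []
    perimeters: dict[int, float] = {}
    pad = max(1, int(np.ceil(3 * mask_sigma)) + 1)
    for oid in np.unique(labels[labels > 0]).tolist():
        obj = labels == oid
        sl = ndi.find_objects(obj.astype(np.int8))[0]
        padded = np.pad(obj[sl].astype(np.float32), pad)
        if mask_sigma > 0:
            smoothed = ndi.gaussian_filter(padded, mask_sigma)
            if smoothed.max() > 0.5:
                padded = smoothed
        offset = np.array([s.start - pad for s in sl], dtype=float)
        found = find_contours(padded, level=0.5)
        polys = [
            Contour2D(oid, (c[:-1] + offset) * spacing_um)  # drop repeated last point
            for c in found
        ]
        outer_idx = int(np.argmax([abs(p.signed_area()) for p in polys]))
        for i, p in enumerate(polys):
            p.is_hole = i != outer_idx
            contours.append(p)
        perimeters[oid] = polys[outer_idx].perimeter()
    return contours, perimeters


def max_feret_diameter(points: np.ndarray) -> float:
    """Largest pairwise distance over a point set (exact).

    Uses the convex hull for large sets — the maximum over hull
    vertices equals the maximum over all points.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 500:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) sets
            pass
    return float(pdist(pts).max())


def length_and_area(
    labels2d: np.ndarray, spacing_um: float, object_id: int
) -> tuple[float, float]:
    """(max Feret length µm, pixel area µm²) of one object."""
    labels = _as_labels2d(labels2d)
    coords = np.argwhere(labels == object_id)
    if coords.size == 0:
        raise MissingObjectError(f"object id {object_id} not present")
    length = max_feret_diameter(coords.astype(float)) * spacing_um
    area = len(coords) * spacing_um**2
    return length, area


def count_and_total_area(labels2d: np.ndarray, spacing_um: float) -> tuple[int, float]:
    """Number of distinct objects and their summed area (µm²)."""
    labels = _as_labels2d(labels2d)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return int(ids.size), float(counts.sum() * spacing_um**2)


def crista_metrics(
    mito_mask: np.ndarray, cristae_labels: np.ndarray, spacing_um: float
) -> CristaeMetrics:
    """Per-crista areas and cristae density within one mitochondrion.

    Every crista pixel must lie inside the mitochondrion mask;
    density = total crista area / mitochondrion area, in [0, 1].
    """
    mito = np.asarray(mito_mask, dtype=bool)
    cristae = _as_labels2d(np.asarray(cristae_labels))
    if cristae.shape != mito.shape:
        raise ValidationError("cristae image shape mismatch")
    if not mito.any():
        raise ValidationError("empty mitochondrion mask")
    if np.any((cristae > 0) & ~mito):
        n_out = int(np.sum((cristae > 0) & ~mito))
        raise ContainmentError(f"{n_out} crista pixels fall outside the mitochondrion")
    ids, counts = np.unique(cristae[cristae > 0], return_counts=True)
    areas = (counts * spacing_um**2).tolist()
    density = float(counts.sum() / mito.sum())
    return CristaeMetrics(areas_um2=areas, density=density)


def measure_sections(
    labels2d: np.ndarray,
    spacing_um: float,
    cristae_labels: np.ndarray | None = None,
    section_thickness_um: float | None = None,
) -> pd.DataFrame:
    """Per-object 2D metrics table: perimeter, Feret length, area, cristae.

    When cristae labels are given, each crista is attributed to the
    object covering it.  Crista "volume" (area x section thickness) is
    emitted only when a thickness is supplied.
    """
    labels = _as_labels2d(labels2d)
    if cristae_labels is not None and np.any(
        (_as_labels2d(np.asarray(cristae_labels)) > 0) & (labels == 0)
    ):
        raise ContainmentError("crista pixels fall outside every mitochondrion")
    _, perims = trace_perimeter(labels, spacing_um)
    rows = []
    for oid in np.unique(labels[labels > 0]).tolist():
        length, area = length_and_area(labels, spacing_um, oid)
        row = {
            "id": oid,
            "perimeter_um": perims[oid],
            "length_um": length,
            "area_um2": area,
            "n_cristae": 0,
            "cristae_density": 0.0,
        }
        if cristae_labels is not None:
            cm = crista_metrics(labels == oid, np.where(labels == oid, cristae_labels, 0), spacing_um)
            row["n_cristae"] = cm.n_cristae
            row["cristae_density"] = cm.density
            if section_thickness_um is not None:
                row["cristae_volume_um3"] = float(
                    sum(cm.areas_um2) * section_thickness_um
                )
        rows.append(row)
    cols = ["id", "perimeter_um", "length_um", "area_um2", "n_cristae", "cristae_density"]
    if cristae_labels is not None and section_thickness_um is not None:
        cols.append("cristae_volume_um3")
    return pd.DataFrame(rows, columns=cols)
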