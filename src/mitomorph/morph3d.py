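"""Per-object 3D morphometrics: volume, surface area, sphericity, MCI.

Volume comes in two forms that are both always reported: the voxel
form N_vox * (x*y*z) and the mesh form, the space enclosed by a
triangulated surface summed over signed tetrahedra.  Surface area is
the sum of triangle areas.  From (V, SA) the dimensionless shape
indices follow:

    sphericity   phi      = pi^(1/3) * (6V)^(2/3) / SA
    complexity   MCI_root = SA^(3/2) / (4 pi V)
                 MCI_sq   = SA^3 / (16 pi^2 V^2)   (= MCI_root^2)

phi is 1 for a perfect sphere and decreases with elongation; MCI is
its reciprocal notion, unbounded above, with the spherical minimum
MCI_sq = 9/(4 pi).  The identity MCI_sq * phi^3 = 9/(4 pi) holds for
any (V, SA) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import marching_cubes

from mitomorph.errors import MeshIntegrityError, MissingObjectError, ValidationError
from mitomorph.grids import LabelVolume

__all__ = [
    "SurfaceMesh",
    "ShapeIndices",
    "SPHERE_MCI_SQ",
    "DEFAULT_MASK_SIGMA",
    "voxel_volume",
    "extract_mesh",
    "mesh_measures",
    "shape_indices",
    "measure_objects",
]

#: MCI_sq of a perfect sphere, 9/(4 pi) — the isoperimetric minimum.
SPHERE_MCI_SQ = 9.0 / (4.0 * math.pi)

#: Gaussian pre-smoothing (in voxels) of the binary mask before
#: iso-surfacing.  Marching cubes straight on a 0/1 field produces
#: staircase facets that overestimate sphere surface area by ~8-9%;
#: sigma = 0.6 brings both SA and V within ~2% for digitized spheres
#: of radius >= 8 voxels.
DEFAULT_MASK_SIGMA = 0.6


class ShapeIndices(NamedTuple):
    sphericity: float
    mci_root: float
    mci_sq: float


@dataclass
class SurfaceMesh:
    """Closed oriented triangle mesh in µm coordinates.

    ``vertices``: (n, 3) float array (z, y, x µm); ``faces``: (m, 3)
    integer vertex triples with consistent winding.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be (m, 3)")

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def signed_volume(self) -> float:
        """Sum of signed tetrahedra taken from the vertex centroid.

        Mathematically independent of the reference point for a closed
        mesh; the centroid is used to reduce floating-point
        cancellation.
        """
        ref = self.vertices.mean(axis=0)
        a = self.vertices[self.faces[:, 0]] - ref
        b = self.vertices[self.faces[:, 1]] - ref
        c = self.vertices[self.faces[:, 2]] - ref
        return float(np.einsum("ij,ij->i", np.cross(a, b), c).sum() / 6.0)

    def boundary_edges(self) -> np.ndarray:
        """Directed edges not matched by an opposite-winding partner."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        fwd = set(map(tuple, e.tolist()))
        bad = [edge for edge in fwd if (edge[1], edge[0]) not in fwd]
        return np.asarray(bad, dtype=np.int64).reshape(-1, 2)

    def is_closed(self) -> bool:
        return len(self.boundary_edges()) == 0


def voxel_volume(labels: LabelVolume, object_id: int) -> float:
    """Voxel-count volume: N_vox times the calibrated voxel volume (µm³)."""
    n = labels.counts.get(int(object_id))
    if n is None:
        raise MissingObjectError(f"object id {object_id} not present")
    return n * labels.voxel_volume


def extract_mesh(
    labels: LabelVolume,
    object_id: int,
    mask_sigma: float = DEFAULT_MASK_SIGMA,
) -> SurfaceMesh:
    """Triangulated surface of one object via marching cubes.

    The object's binary mask is zero-padded (the surface is therefore
    always closed), optionally pre-smoothed by ``mask_sigma`` voxels,
    iso-surfaced at level 0.5, and scaled by the per-axis spacing into
    µm.  Faces are reoriented if needed so the enclosed volume is
    positive.
    """
    if object_id not in labels.counts:
        raise MissingObjectError(f"object id {object_id} not present")
    mask = labels.labels == object_id
    # crop to the bounding box to keep marching cubes cheap on large fields
    pad = max(2, int(math.ceil(3 * mask_sigma)) + 1)
    sl = ndi.find_objects(mask.astype(np.int8))[0]
    field = np.pad(mask[sl].astype(np.float32), pad)
    if mask_sigma > 0:
        smoothed = ndi.gaussian_filter(field, mask_sigma)
        # tiny objects can be smoothed entirely below the iso-level;
        # fall back to the raw mask so they still yield a closed surface
        if smoothed.max() > 0.5:
            field = smoothed
    verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=labels.spacing)
    offset = np.array(
        [(s.start - pad) * sp for s, sp in zip(sl, labels.spacing)]
    )
    mesh = SurfaceMesh(verts + offset, faces)
    if mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]
    return mesh


def mesh_measures(mesh: SurfaceMesh) -> tuple[float, float]:
    """(SA µm², V µm³) of a closed mesh; raises on open meshes."""
    bad = mesh.boundary_edges()
    if len(bad):
        raise MeshIntegrityError(
            f"mesh is not closed: {len(bad)} unmatched directed edges",
            bad_edges=bad.tolist(),
        )
    return float(mesh.face_areas().sum()), abs(mesh.signed_volume())


def shape_indices(V: float, SA: float) -> ShapeIndices:
    """Sphericity and both complexity-index forms from (V, SA)."""
    if V <= 0 or SA <= 0:
        raise ValidationError("V and SA must be positive")
    phi = math.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / SA
    mci_root = SA ** 1.5 / (4.0 * math.pi * V)
    mci_sq = SA**3 / (16.0 * math.pi**2 * V**2)
    return ShapeIndices(phi, mci_root, mci_sq)


METRIC_COLUMNS = [
    "id", "n_vox", "v_voxel_um3", "v_mesh_um3", "sa_um2",
    "sphericity", "mci_root", "mci_sq",
]


def measure_objects(
    labels: LabelVolume,
    volume_source: str = "mesh",
    mask_sigma: float = DEFAULT_MASK_SIGMA,
    include_mci_per_volume: bool = False,
) -> pd.DataFrame:
    """Morphometrics table with one row per labeled object, sorted by id.

    Shape indices use the mesh volume by default (``volume_source`` =
    "voxel" switches them to N_vox * voxel volume); both volumes are
    always reported so either convention can be reproduced downstream.
    """
    if volume_source not in ("mesh", "voxel"):
        raise ValidationError("volume_source must be 'mesh' or 'voxel'")
    rows = []
    for oid in labels.ids():
        v_vox = voxel_volume(labels, oid)
        sa, v_mesh = mesh_measures(extract_mesh(labels, oid, mask_sigma=mask_sigma))
        v_used = v_mesh if volume_source == "mesh" else v_vox
        phi, root, sq = shape_indices(v_used, sa)
        rows.append(
            {
                "id": oid,
                "n_vox": labels.counts[oid],
                "v_voxel_um3": v_vox,
                "v_mesh_um3": v_mesh,
                "sa_um2": sa,
                "sphericity": phi,
                "mci_root": root,
                "mci_sq": sq,
            }
        )
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    if include_mci_per_volume:
        # exploratory normalization; not claimed to match any published plot
        df["mci_sq_per_um3"] = df["mci_sq"] / df[
            "v_mesh_um3" if volume_source == "mesh" else "v_voxel_um3"
        ]
    return df
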