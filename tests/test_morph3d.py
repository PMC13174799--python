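import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomorph.errors import MeshIntegrityError, MissingObjectError, ValidationError
from mitomorph.grids import LabelVolume
from mitomorph.morph3d import (
    SPHERE_MCI_SQ,
    SurfaceMesh,
    extract_mesh,
    measure_objects,
    mesh_measures,
    shape_indices,
    voxel_volume,
)
from mitomorph.phantoms import PrimitiveSpec, analytic_metrics

from conftest import digitized_sphere_labels


def unit_cube_mesh():
    # 8 corners, 12 triangles, outward winding
    v = np.array(
        [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1],
         [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=float
    )
    f = np.array(
        [[0, 1, 3], [0, 3, 2],          # z = 0 face (normal -z)
         [4, 6, 7], [4, 7, 5],          # z = 1 face (+z)
         [0, 4, 5], [0, 5, 1],          # y = 0
         [2, 3, 7], [2, 7, 6],          # y = 1
         [0, 2, 6], [0, 6, 4],          # x = 0
         [1, 5, 7], [1, 7, 3]]          # x = 1
    )
    return SurfaceMesh(v, f)


class TestVoxelVolume:
    def test_direct_product(self):
        arr = np.zeros((10, 10, 10), dtype=np.int32)
        arr.flat[:1000] = 1
        lv = LabelVolume(arr, (0.1, 0.1, 0.1))
        assert voxel_volume(lv, 1) == pytest.approx(1.0, rel=1e-12)

    def test_anisotropic_product(self):
        arr = np.zeros((5, 10, 10), dtype=np.int32)
        arr.flat[:500] = 2
        lv = LabelVolume(arr, (0.09, 0.065, 0.065))
        assert voxel_volume(lv, 2) == pytest.approx(500 * 3.80250e-4, rel=1e-9)

    def test_absent_id_raises(self):
        lv = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), (1, 1, 1))
        with pytest.raises(MissingObjectError):
            voxel_volume(lv, 3)


class TestExtractMesh:
    def test_cube_mesh_closed(self):
        arr = np.zeros((14, 14, 14), dtype=np.int32)
        arr[2:12, 2:12, 2:12] = 1
        mesh = extract_mesh(LabelVolume(arr, (1, 1, 1)), 1)
        assert mesh.is_closed()
        assert mesh.signed_volume() > 0

    def test_translation_leaves_volume_unchanged(self):
        arr = np.zeros((16, 16, 16), dtype=np.int32)
        arr[3:9, 3:9, 3:9] = 1
        mesh = extract_mesh(LabelVolume(arr, (1, 1, 1)), 1)
        _, v0 = mesh_measures(mesh)
        shifted = SurfaceMesh(mesh.vertices + np.array([5.0, 5.0, 5.0]), mesh.faces)
        _, v1 = mesh_measures(shifted)
        assert v1 == pytest.approx(v0, rel=1e-12)

    def test_digitized_sphere_r12_sa_3pct_v_2pct(self, sphere_r12):
        mesh = extract_mesh(sphere_r12, 1)
        sa, v = mesh_measures(mesh)
        assert sa == pytest.approx(4 * math.pi * 144, rel=0.03)
        assert v == pytest.approx(4 / 3 * math.pi * 12**3, rel=0.02)

    def test_single_voxel_yields_closed_surface(self):
        arr = np.zeros((5, 5, 5), dtype=np.int32)
        arr[2, 2, 2] = 1
        mesh = extract_mesh(LabelVolume(arr, (1, 1, 1)), 1)
        assert mesh.is_closed()
        _, v = mesh_measures(mesh)
        assert v > 0

    def test_anisotropic_spacing_scales_volume(self):
        arr = np.zeros((12, 12, 12), dtype=np.int32)
        arr[3:9, 3:9, 3:9] = 1
        iso = extract_mesh(LabelVolume(arr, (1, 1, 1)), 1, mask_sigma=0)
        aniso = extract_mesh(LabelVolume(arr, (2, 1, 1)), 1, mask_sigma=0)
        _, v_iso = mesh_measures(iso)
        _, v_aniso = mesh_measures(aniso)
        assert v_aniso == pytest.approx(2 * v_iso, rel=1e-9)


class TestMeshMeasures:
    def test_unit_cube(self):
        sa, v = mesh_measures(unit_cube_mesh())
        assert sa == pytest.approx(6.0, rel=1e-12)
        assert v == pytest.approx(1.0, rel=1e-12)

    def test_cyclic_vertex_permutation_invariant(self):
        mesh = unit_cube_mesh()
        rolled = SurfaceMesh(mesh.vertices, np.roll(mesh.faces, 1, axis=1))
        assert mesh_measures(rolled) == pytest.approx(mesh_measures(mesh), rel=1e-12)

    def test_icosphere_converges_from_below(self):
        # inscribed polyhedron: SA and V below 4*pi and 4/3*pi, converging
        prev_sa, prev_v = 0.0, 0.0
        for n_sub in (1, 2, 3):
            mesh = _icosphere(n_sub)
            sa, v = mesh_measures(mesh)
            assert sa < 4 * math.pi
            assert v < 4 / 3 * math.pi
            assert sa > prev_sa and v > prev_v
            prev_sa, prev_v = sa, v
        assert prev_sa == pytest.approx(4 * math.pi, rel=0.01)
        assert prev_v == pytest.approx(4 / 3 * math.pi, rel=0.01)

    def test_open_mesh_rejected_with_edge_report(self):
        mesh = unit_cube_mesh()
        open_mesh = SurfaceMesh(mesh.vertices, mesh.faces[:-1])
        with pytest.raises(MeshIntegrityError) as exc:
            mesh_measures(open_mesh)
        assert len(exc.value.bad_edges) == 3


def _icosphere(subdivisions: int) -> SurfaceMesh:
    # icosahedron refined by edge-midpoint subdivision, projected on S2
    t = (1 + math.sqrt(5)) / 2
    verts = np.array(
        [[-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
         [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
         [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], dtype=float
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
         [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
         [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
         [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]]
    )
    for _ in range(subdivisions):
        verts_list = verts.tolist()
        cache: dict[tuple[int, int], int] = {}

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = (np.array(verts_list[a]) + np.array(verts_list[b])) / 2
                m /= np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m.tolist())
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    mesh = SurfaceMesh(verts, faces)
    if mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]
    return mesh


class TestShapeIndices:
    def test_sphere_values_give_phi_one(self):
        phi, _, _ = shape_indices(523.5988, 314.1593)
        assert phi == pytest.approx(1.0, abs=1e-6)

    def test_sphere_values_give_min_mci(self):
        _, _, sq = shape_indices(4 / 3 * math.pi * 125, 4 * math.pi * 25)
        assert sq == pytest.approx(SPHERE_MCI_SQ, abs=1e-12)
        assert SPHERE_MCI_SQ == pytest.approx(0.71620, abs=1e-5)

    @given(v=st.floats(1e-3, 1e6), sa=st.floats(1e-3, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_algebraic_identities(self, v, sa):
        phi, root, sq = shape_indices(v, sa)
        assert sq == pytest.approx(root**2, rel=1e-9)
        assert sq * phi**3 == pytest.approx(SPHERE_MCI_SQ, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            shape_indices(0.0, 1.0)
        with pytest.raises(ValidationError):
            shape_indices(1.0, -1.0)

    def test_capsule_elongation_monotonicity(self):
        # growing L at fixed r: phi strictly down, MCI_sq strictly up
        phis, sqs = [], []
        for L in (1, 2, 4, 8, 16, 32):
            t = analytic_metrics(PrimitiveSpec.capsule((0, 0, 0), 1.0, L, (0, 0, 1)))
            phis.append(t.sphericity)
            sqs.append(t.MCI_sq)
        assert all(a > b for a, b in zip(phis, phis[1:]))
        assert all(a < b for a, b in zip(sqs, sqs[1:]))


class TestMeasureObjects:
    def test_empty_labels_empty_table(self):
        lv = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), (1, 1, 1))
        df = measure_objects(lv)
        assert len(df) == 0
        assert list(df.columns)[:4] == ["id", "n_vox", "v_voxel_um3", "v_mesh_um3"]

    def test_row_count_equals_label_count(self, seeded_field, seeded_field_metrics):
        assert len(seeded_field_metrics) == len(seeded_field.labels.ids())

    def test_five_disjoint_spheres_within_2pct(self):
        from mitomorph.phantoms import rasterize

        sp = 0.1
        specs = [
            PrimitiveSpec.sphere(((12 + 24 * k) * sp, 12 * sp, 12 * sp), 9 * sp)
            for k in range(5)
        ]
        pv = rasterize(specs, sp, (5 * 24, 24, 24))
        df = measure_objects(pv.labels)
        assert len(df) == 5
        for oid, truth in pv.truth.items():
            v = df.loc[df.id == oid, "v_mesh_um3"].item()
            assert v == pytest.approx(truth.V, rel=0.02)

    def test_identities_hold_on_every_row(self, seeded_field_metrics):
        df = seeded_field_metrics
        np.testing.assert_allclose(df.mci_sq, df.mci_root**2, rtol=1e-9)
        np.testing.assert_allclose(
            df.mci_sq * df.sphericity**3, SPHERE_MCI_SQ, rtol=1e-9
        )

    def test_isoperimetric_bound(self, seeded_field_metrics):
        assert (seeded_field_metrics.sphericity <= 1.02).all()
        assert (seeded_field_metrics.mci_sq >= SPHERE_MCI_SQ - 0.02).all()

    def test_mesh_voxel_volume_agreement(self, sphere_r10, sphere_r12):
        for lv, tol in ((sphere_r10, 0.05), (sphere_r12, 0.02)):
            df = measure_objects(lv)
            ratio = df.v_mesh_um3.item() / df.v_voxel_um3.item()
            assert ratio == pytest.approx(1.0, abs=tol)

    def test_parameter_recovery_median_under_3pct(self, seeded_field, seeded_field_metrics):
        df = seeded_field_metrics.set_index("id")
        ev = [abs(df.loc[k, "v_mesh_um3"] / t.V - 1) for k, t in seeded_field.truth.items()]
        es = [abs(df.loc[k, "sa_um2"] / t.SA - 1) for k, t in seeded_field.truth.items()]
        assert np.median(ev) < 0.03
        assert np.median(es) < 0.03

    def test_voxel_volume_source_switch(self, sphere_r12):
        mesh_df = measure_objects(sphere_r12, volume_source="mesh")
        vox_df = measure_objects(sphere_r12, volume_source="voxel")
        expect_phi, _, _ = shape_indices(
            vox_df.v_voxel_um3.item(), vox_df.sa_um2.item()
        )
        assert vox_df.sphericity.item() == pytest.approx(expect_phi, rel=1e-12)
        assert mesh_df.sphericity.item() != vox_df.sphericity.item()

    def test_optional_mci_per_volume_column(self, sphere_r12):
        df = measure_objects(sphere_r12, include_mci_per_volume=True)
        assert "mci_sq_per_um3" in df.columns
        assert df.mci_sq_per_um3.item() == pytest.approx(
            df.mci_sq.item() / df.v_mesh_um3.item(), rel=1e-12
        )
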