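import json

import numpy as np
import pytest

from phytomer3d.core import SemanticPointSet, Skeleton, mesh_area, rotation_about_z
from phytomer3d.errors import FormatError, GeometryError
from phytomer3d.meshio import (
    build_mesh_from_digitized,
    read_obj_groups,
    read_skeleton_csv,
    read_template,
    resample_skeleton,
    write_obj_groups,
    write_skeleton_csv,
    write_template,
)
from phytomer3d.synthetic import default_params_for_type, generate_digitized_phytomer


def _planar_pts(n_rows=3):
    """Flat strip in the XY plane: rows along x, points across y."""
    rows = np.zeros((n_rows, 5, 3))
    for r in range(n_rows):
        rows[r, :, 0] = r * 2.0
        rows[r, :, 1] = np.linspace(-1.0, 1.0, 5) * (1.0 + 0.3 * r)
    roles = np.full((n_rows, 5), "interior", dtype="<U16")
    roles[:, 2] = "vein"
    tip = np.array([n_rows * 2.0, 0.0, 0.0])
    return SemanticPointSet(rows, roles, tip)


class TestTriangulation:
    def test_two_rows_plus_tip_give_twelve_triangles(self):
        mesh = build_mesh_from_digitized(_planar_pts(2))
        assert len(mesh.faces) == 12
        assert mesh.n_vertices == 11

    def test_labels_and_rows_carried_over(self):
        pts = generate_digitized_phytomer(default_params_for_type("below_ear"), 8, seed=0)
        mesh = build_mesh_from_digitized(pts)
        vein = np.flatnonzero(mesh.labels == "vein")
        assert (mesh.row_index[vein] == np.arange(8)).all()
        assert mesh.labels[-1] == "tip"
        # vein vertices are the third points of their rows, in order
        assert np.abs(mesh.vertices[vein] - pts.rows[:, 2, :]).max() == 0.0

    def test_planar_outline_area_matches_shoelace(self):
        pts = _planar_pts(4)
        mesh = build_mesh_from_digitized(pts)
        # outline polygon: first row, then margins up one side, tip, back down
        poly = np.vstack(
            [pts.rows[0], pts.rows[1:, 4], pts.tip[None, :], pts.rows[1:, 0][::-1]]
        )[:, :2]
        x, y = poly[:, 0], poly[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert mesh_area(mesh) == pytest.approx(shoelace, abs=1e-6)

    def test_rigid_equivariance(self):
        pts = _planar_pts(3)
        R = rotation_about_z(37)
        t = np.array([1.0, -2.0, 3.0])
        a = build_mesh_from_digitized(pts.transformed(R, t))
        b = build_mesh_from_digitized(pts).transformed(R, t)
        assert np.abs(a.vertices - b.vertices).max() < 1e-12
        assert (a.faces == b.faces).all()

    def test_single_row_rejected(self):
        with pytest.raises(GeometryError):
            build_mesh_from_digitized(_planar_pts(1))


class TestTemplateIO:
    def test_round_trip(self, tmp_path, default_template):
        path = tmp_path / "tpl.obj"
        write_template(default_template, path)
        back = read_template(path)
        assert back.phytomer_type == default_template.phytomer_type
        for role, c in default_template.components.items():
            d = np.abs(back.components[role].mesh.vertices - c.mesh.vertices)
            assert d.max() < 1e-6
            assert (back.components[role].mesh.faces == c.mesh.faces).all()
            assert np.abs(back.components[role].skeleton.points - c.skeleton.points).max() < 1e-6

    def test_missing_sidecar_is_not_a_template(self, tmp_path, default_template):
        path = tmp_path / "bare.obj"
        write_template(default_template, path)
        path.with_suffix(".json").unlink()
        with pytest.raises(FormatError, match="not a template"):
            read_template(path)

    def test_vertex_count_mismatch_detected(self, tmp_path, default_template):
        path = tmp_path / "tpl.obj"
        write_template(default_template, path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        sidecar["components"]["leaf"]["vertex_count"] += 1
        path.with_suffix(".json").write_text(json.dumps(sidecar))
        with pytest.raises(FormatError, match="vertex count"):
            read_template(path)

    def test_obj_readable_by_trimesh(self, tmp_path, default_template):
        trimesh = pytest.importorskip("trimesh")
        path = tmp_path / "tpl.obj"
        write_template(default_template, path)
        scene = trimesh.load(str(path), process=False)
        got = sum(
            len(g.vertices) for g in (scene.geometry.values() if hasattr(scene, "geometry") else [scene])
        )
        assert got == default_template.n_vertices

    def test_obj_groups_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        groups = [
            ("a", rng.normal(size=(6, 3)), np.array([[0, 1, 2], [3, 4, 5]])),
            ("b", rng.normal(size=(4, 3)), np.array([[0, 1, 2], [0, 2, 3]])),
        ]
        path = tmp_path / "g.obj"
        write_obj_groups(path, groups)
        back = read_obj_groups(path)
        assert [name for name, *_ in back] == ["a", "b"]
        for (_, v0, f0), (_, v1, f1) in zip(groups, back):
            assert np.abs(v0 - v1).max() < 1e-6
            assert (f0 == f1).all()


class TestSkeletonIO:
    def test_csv_round_trip(self, tmp_path):
        s = Skeleton(np.random.default_rng(1).normal(size=(7, 3)), "leaf")
        path = tmp_path / "s.csv"
        write_skeleton_csv(s, path)
        back = read_skeleton_csv(path)
        assert np.abs(back.points - s.points).max() < 1e-9


class TestResampling:
    def test_straight_segment_uniform(self):
        s = Skeleton(np.array([[0.0, 0, 0], [0, 0, 10]]))
        out = resample_skeleton(s, 5)
        assert np.allclose(out.points[:, 2], [0, 2.5, 5, 7.5, 10])
        assert np.abs(out.points[:, :2]).max() == 0.0

    def test_endpoints_preserved_bitwise(self):
        pts = np.random.default_rng(2).normal(size=(9, 3))
        s = Skeleton(pts)
        out = resample_skeleton(s, 17)
        assert (out.points[0] == pts[0]).all() and (out.points[-1] == pts[-1]).all()

    def test_arc_length_preserved_on_dense_resample(self):
        # smooth random space curve (random Fourier coefficients)
        rng = np.random.default_rng(3)
        t = np.linspace(0, 1, 60)[:, None]
        coef = rng.normal(size=(3, 3))
        pts = np.hstack(
            [
                coef[0, i] * np.sin(2 * np.pi * (i + 1) * t)
                + coef[1, i] * np.cos(2 * np.pi * (i + 1) * t)
                + coef[2, i] * t
                for i in range(3)
            ]
        )
        s = Skeleton(pts)
        out = resample_skeleton(s, 200)
        assert out.arc_length == pytest.approx(s.arc_length, rel=0.005)

    def test_identity_on_uniform_polyline(self):
        z = np.linspace(0, 10, 8)
        s = Skeleton(np.column_stack([np.zeros(8), np.zeros(8), z]))
        out = resample_skeleton(s, 8)
        assert np.abs(out.points - s.points).max() < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            resample_skeleton(Skeleton(np.array([[0.0, 0, 0], [1, 0, 0]])), 1)
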