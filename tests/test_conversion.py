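import numpy as np
import pytest
from scipy.spatial import cKDTree

from phytomer3d.core import SemanticMesh, Skeleton, mesh_area, rotation_about_z, rotation_aligning
from phytomer3d.conversion import (
    arap_deform,
    extract_skeleton_laplacian,
    extract_skeleton_semantic,
    laplacian_contraction,
    skeleton_to_mesh,
)
from phytomer3d.errors import ConnectivityError, FormatError, RetrievalError
from phytomer3d.meshio import _skeleton_vertex_indices, build_mesh_from_digitized
from phytomer3d.synthetic import default_params_for_type, generate_digitized_phytomer


class TestSemanticExtraction:
    def test_closed_loop_recovers_the_midrib(self):
        """digitize -> mesh -> semantic skeleton returns the vein samples."""
        pts = generate_digitized_phytomer(default_params_for_type("below_ear"), 9, seed=2)
        mesh = build_mesh_from_digitized(pts)
        skel = extract_skeleton_semantic(mesh)
        expected = np.vstack([pts.rows[:, 2, :], pts.tip[None, :]])
        assert np.abs(skel.points - expected).max() < 1e-6
        assert len(skel.points) == pts.n_rows + 1

    def test_unlabeled_mesh_directed_to_laplacian_path(self):
        mesh = SemanticMesh(np.random.default_rng(0).normal(size=(4, 3)), np.array([[0, 1, 2]]))
        with pytest.raises(FormatError, match="laplacian"):
            extract_skeleton_semantic(mesh)


class TestLaplacianSkeleton:
    def test_cylinder_skeleton_hugs_the_axis(self, cylinder_cloud):
        skel = extract_skeleton_laplacian(cylinder_cloud, k_neighbors=8, iterations=10, seed=0)
        assert np.hypot(skel.points[:, 0], skel.points[:, 1]).max() < 0.15

    def test_quarter_torus_skeleton_follows_the_centre_arc(self):
        rng = np.random.default_rng(1)
        n = 2000
        u = rng.uniform(0, np.pi / 2, n)
        v = rng.uniform(0, 2 * np.pi, n)
        R0, r0 = 10.0, 0.5
        pts = np.column_stack(
            [(R0 + r0 * np.cos(v)) * np.cos(u), (R0 + r0 * np.cos(v)) * np.sin(u), r0 * np.sin(v)]
        )
        skel = extract_skeleton_laplacian(pts)
        d = np.sqrt((np.hypot(skel.points[:, 0], skel.points[:, 1]) - R0) ** 2 + skel.points[:, 2] ** 2)
        assert d.max() < 0.3

    def test_contraction_shrinks_edge_length_monotonically(self, cylinder_cloud):
        _, hist = laplacian_contraction(cylinder_cloud, return_history=True)
        tree = cKDTree(cylinder_cloud)
        _, idx = tree.query(cylinder_cloud, k=9)
        e = np.column_stack([np.repeat(np.arange(len(cylinder_cloud)), 8), idx[:, 1:].reshape(-1)])

        def total(Q):
            return np.linalg.norm(Q[e[:, 0]] - Q[e[:, 1]], axis=1).sum()

        lens = [total(cylinder_cloud)] + [total(h) for h in hist]
        assert all(b < a for a, b in zip(lens, lens[1:]))

    def test_disconnected_cloud_raises(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(60, 3))
        b = rng.normal(size=(60, 3)) + 1000.0
        with pytest.raises(ConnectivityError):
            extract_skeleton_laplacian(np.vstack([a, b]), k_neighbors=4)


class TestARAP:
    def test_identity_when_targets_equal_handles(self, leaf_component):
        handles = _skeleton_vertex_indices(leaf_component.mesh, leaf_component.skeleton)
        out = arap_deform(leaf_component.mesh, handles, leaf_component.mesh.vertices[handles])
        assert np.abs(out.vertices - leaf_component.mesh.vertices).max() < 1e-9

    def test_rigid_targets_recover_the_rigid_motion(self, leaf_component):
        mesh = leaf_component.mesh
        handles = _skeleton_vertex_indices(mesh, leaf_component.skeleton)
        R = rotation_aligning([0.3, 0.1, 1.0], [0, 0, 1]) @ rotation_about_z(40)
        t = np.array([5.0, 2.0, 1.0])
        out = arap_deform(mesh, handles, mesh.vertices[handles] @ R.T + t, max_iters=200)
        expected = mesh.vertices @ R.T + t
        diag = np.linalg.norm(mesh.vertices.max(0) - mesh.vertices.min(0))
        assert np.abs(out.vertices - expected).max() < 1e-3 * diag

    def test_energy_non_increasing(self, leaf_component):
        mesh = leaf_component.mesh
        handles = _skeleton_vertex_indices(mesh, leaf_component.skeleton)
        targets = leaf_component.skeleton.points.copy()
        targets[:, 2] *= 0.7  # flatten the midrib: a genuinely non-rigid edit
        _, energies = arap_deform(mesh, handles, targets, max_iters=60, return_energy=True)
        assert all(b <= a * (1 + 1e-9) for a, b in zip(energies, energies[1:]))

    def test_rigid_equivariance(self, leaf_component):
        mesh = leaf_component.mesh
        handles = _skeleton_vertex_indices(mesh, leaf_component.skeleton)
        targets = leaf_component.skeleton.points.copy()
        targets[:, 0] *= 1.2
        R = rotation_about_z(65)
        t = np.array([1.0, 2.0, 3.0])
        a = arap_deform(mesh, handles, targets, max_iters=100)
        b = arap_deform(mesh, handles, targets @ R.T + t, max_iters=100)
        assert np.abs(b.vertices - (a.vertices @ R.T + t)).max() < 1e-6

    def test_too_few_handles_rejected(self, leaf_component):
        with pytest.raises(ValueError):
            arap_deform(leaf_component.mesh, [0, 1], np.zeros((2, 3)))


class TestSkeletonToMesh:
    def test_self_conversion_returns_the_template(self, solo_db):
        tpl = solo_db.load_phytomer(solo_db.entries[0])
        leaf = tpl.components["leaf"]
        out = skeleton_to_mesh(leaf.skeleton, solo_db)
        assert np.abs(out.vertices - leaf.mesh.vertices).max() < 1e-6

    def test_uniform_scaling_oracle(self, solo_db):
        tpl = solo_db.load_phytomer(solo_db.entries[0])
        leaf = tpl.components["leaf"]
        target = Skeleton(leaf.skeleton.points * 1.5)
        out = skeleton_to_mesh(target, solo_db, max_iters=100)
        got = extract_skeleton_semantic(out)
        assert got.arc_length == pytest.approx(1.5 * leaf.skeleton.arc_length, rel=0.02)
        assert mesh_area(out) == pytest.approx(2.25 * mesh_area(leaf.mesh), rel=0.05)

    def test_distinct_skeletons_share_topology(self, solo_db):
        tpl = solo_db.load_phytomer(solo_db.entries[0])
        leaf = tpl.components["leaf"]
        n = len(leaf.skeleton.points)
        straight = Skeleton(np.column_stack([np.zeros(n), np.zeros(n), np.linspace(12, 70, n)]))
        s = np.linspace(0, 1, n)
        drooping = Skeleton(
            np.column_stack([45 * np.sin(1.9 * s), np.zeros(n), 12 + 35 * s * (1 - 0.8 * s)])
        )
        a = skeleton_to_mesh(straight, solo_db, max_iters=60)
        b = skeleton_to_mesh(drooping, solo_db, max_iters=60)
        assert np.abs(a.vertices - b.vertices).max() > 1.0  # genuinely different shapes
        assert len(a.faces) == len(b.faces) == len(leaf.mesh.faces)
        assert (a.labels == leaf.mesh.labels).all() and (b.labels == leaf.mesh.labels).all()

    def test_converted_mesh_tracks_the_target_skeleton(self, tmp_path):
        """Leaf shape is maintained: the re-extracted skeleton stays within
        1% arc length and 0.5 cm of the requested one."""
        from phytomer3d.database import TemplateDB
        from phytomer3d.synthetic import (
            default_params_for_type,
            generate_phytomer_template,
            morphology_of,
        )

        # strongly curved targets need a finer vein than the default
        # 12-row template provides
        db = TemplateDB.create(tmp_path / "fine_db")
        params = default_params_for_type("below_ear")
        tpl = generate_phytomer_template("below_ear", params, n_rows=16)
        db.add_entry(tpl, "fine-below_ear-000", morphology=morphology_of(params))
        db.save()
        leaf = tpl.components["leaf"]
        n = len(leaf.skeleton.points)
        s = np.linspace(0, 1, n)
        target = Skeleton(
            np.column_stack([50 * np.sin(1.4 * s), 6 * s * s, 12 + 45 * s * (1 - 0.55 * s)])
        )
        out = skeleton_to_mesh(target, db, max_iters=150)
        got = extract_skeleton_semantic(out)
        assert got.arc_length == pytest.approx(target.arc_length, rel=0.01)
        # symmetric Hausdorff distance between the two polylines (curves)
        from phytomer3d.meshio import resample_skeleton

        a = resample_skeleton(got, 500).points
        b = resample_skeleton(target, 500).points
        d = max(cKDTree(a).query(b)[0].max(), cKDTree(b).query(a)[0].max())
        assert d < 0.5

    def test_empty_db_raises(self, tmp_path):
        from phytomer3d.database import TemplateDB

        db = TemplateDB.create(tmp_path / "empty")
        db.save()
        with pytest.raises(RetrievalError):
            skeleton_to_mesh(Skeleton(np.array([[0.0, 0, 0], [0, 0, 1]])), db)
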