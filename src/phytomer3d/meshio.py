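"""Mesh and skeleton I/O plus digitized-point-set triangulation.

Digitized phytomers arrive as ordered rows of five points (plus one tip
point).  :func:`build_mesh_from_digitized` turns such a point set into an
open semantic triangle strip; templates are stored on disk as a Wavefront
OBJ (``v``/``f``/``o`` records, 1-based indices) together with a JSON
sidecar carrying everything OBJ cannot: per-vertex labels and row indices,
skeleton vertex indices, morphological parameters and database keywords.
An OBJ without its sidecar is just a mesh, not a template.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import (
    Component,
    ComponentParams,
    Phytomer,
    SemanticMesh,
    SemanticPointSet,
    Skeleton,
)
from .errors import FormatError, GeometryError

__all__ = [
    "build_mesh_from_digitized",
    "write_template",
    "read_template",
    "write_obj_groups",
    "read_obj_groups",
    "write_skeleton_csv",
    "read_skeleton_csv",
    "resample_skeleton",
    "resample_at_fractions",
]

SIDECAR_SUFFIX = ".json"


def build_mesh_from_digitized(pts: SemanticPointSet) -> SemanticMesh:
    """Triangulate a standards-compliant digitized point set.

    Consecutive rows are joined as quad strips, each quad split along the
    (row r, point k) -> (row r+1, point k+1) diagonal into two triangles
    (8 triangles per row pair); the tip is joined to the last row by a
    4-triangle fan.  Vertex order is acquisition order (row-major, tip
    last), so vertex count equals point count.
    """
    if pts.rows.shape[1] != 5:
        raise FormatError("each acquisition row must contain exactly 5 points")
    n_rows = pts.n_rows
    if n_rows < 2:
        raise GeometryError("need at least 2 rows to build a surface")
    verts = np.vstack([pts.rows.reshape(-1, 3), pts.tip[None, :]])
    labels = np.concatenate([pts.roles.reshape(-1), ["tip"]])
    row_index = np.concatenate([np.repeat(np.arange(n_rows), 5), [-1]])
    faces = []
    for r in range(n_rows - 1):
        a = 5 * r
        b = 5 * (r + 1)
        for k in range(4):
            faces.append((a + k, a + k + 1, b + k + 1))
            faces.append((a + k, b + k + 1, b + k))
    tip = 5 * n_rows
    last = 5 * (n_rows - 1)
    for k in range(4):
        faces.append((last + k, last + k + 1, tip))
    return SemanticMesh(verts, np.array(faces, dtype=np.int64), labels, row_index)


# ---------------------------------------------------------------------------
# OBJ + sidecar templates
# ---------------------------------------------------------------------------

def write_obj_groups(path, groups: list[tuple[str, np.ndarray, np.ndarray]]) -> None:
    """Write named mesh groups to one OBJ file (global 1-based indices)."""
    path = Path(path)
    lines = ["# phytomer3d OBJ"]
    offset = 0
    for name, verts, faces in groups:
        lines.append(f"o {name}")
        for v in np.asarray(verts, dtype=float):
            lines.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
        for f in np.asarray(faces, dtype=np.int64):
            lines.append(f"f {f[0] + 1 + offset} {f[1] + 1 + offset} {f[2] + 1 + offset}")
        offset += len(verts)
    path.write_text("\n".join(lines) + "\n")


def read_obj_groups(path) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Read an OBJ into (name, vertices, faces) groups.

    Faces are re-indexed local to their group; vertices listed before any
    ``o`` record form a group named ``"default"``.  Only the ``v``/``f``/``o``
    subset is interpreted; polygonal faces are fan-triangulated.
    """
    path = Path(path)
    all_verts: list[list[float]] = []
    groups: list[dict] = []

    def _new_group(name: str) -> dict:
        g = {"name": name, "start": len(all_verts), "faces": []}
        groups.append(g)
        return g

    current = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if tok[0] in ("o", "g"):
            current = _new_group(tok[1] if len(tok) > 1 else "unnamed")
        elif tok[0] == "v":
            if current is None:
                current = _new_group("default")
            all_verts.append([float(tok[1]), float(tok[2]), float(tok[3])])
        elif tok[0] == "f":
            if current is None:
                raise FormatError("face record before any vertex")
            idx = []
            for t in tok[1:]:
                i = int(t.split("/")[0])
                if i < 0:
                    i = len(all_verts) + 1 + i
                idx.append(i - 1)
            for k in range(1, len(idx) - 1):
                current["faces"].append((idx[0], idx[k], idx[k + 1]))
    V = np.asarray(all_verts, dtype=float)
    out = []
    bounds = [g["start"] for g in groups] + [len(all_verts)]
    for g, start, end in zip(groups, bounds[:-1], bounds[1:]):
        faces = np.asarray(g["faces"], dtype=np.int64).reshape(-1, 3) - start
        out.append((g["name"], V[start:end].copy(), faces))
    return out


def _skeleton_vertex_indices(mesh: SemanticMesh, skel: Skeleton, tol: float = 1e-6) -> list[int]:
    idx = []
    for pt in skel.points:
        d = np.linalg.norm(mesh.vertices - pt, axis=1)
        i = int(np.argmin(d))
        if d[i] > tol:
            raise GeometryError(
                f"skeleton point {pt} is not a mesh vertex (nearest {d[i]:.2e} cm away)"
            )
        idx.append(i)
    return idx


def write_template(p: Phytomer, path, keywords: dict | None = None) -> None:
    """Store a phytomer template as OBJ + JSON sidecar.

    ``path`` names the OBJ file; the sidecar is written next to it with a
    ``.json`` suffix.  ``keywords`` carries the database keyword groups
    (agronomic, model info, morphological, other) and is stored verbatim.
    """
    path = Path(path)
    roles = sorted(p.components)
    groups = []
    sidecar_components = {}
    for role in roles:
        c = p.components[role]
        groups.append((role, c.mesh.vertices, c.mesh.faces))
        sidecar_components[role] = {
            "vertex_count": int(c.mesh.n_vertices),
            "face_count": int(len(c.mesh.faces)),
            "labels": (None if c.mesh.labels is None else c.mesh.labels.tolist()),
            "row_index": (None if c.mesh.row_index is None else c.mesh.row_index.tolist()),
            "skeleton_indices": _skeleton_vertex_indices(c.mesh, c.skeleton),
            "params": c.params.to_dict(),
        }
    write_obj_groups(path, groups)
    sidecar = {
        "format": "phytomer3d-template",
        "phytomer_type": p.phytomer_type,
        "index_in_shoot": p.index_in_shoot,
        "vertices_number": int(p.n_vertices),
        "mesh_number": int(p.n_faces),
        "components": sidecar_components,
        "keywords": keywords or {},
    }
    path.with_suffix(SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=1))


def read_template(path) -> Phytomer:
    """Read an OBJ + sidecar template back into a :class:`Phytomer`."""
    path = Path(path)
    sidecar_path = path.with_suffix(SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise FormatError(
            f"{path} has no sidecar {sidecar_path.name}: a bare mesh is not a template"
        )
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("format") != "phytomer3d-template":
        raise FormatError(f"{sidecar_path} is not a phytomer template sidecar")
    groups = {name: (v, f) for name, v, f in read_obj_groups(path)}
    comps: dict[str, Component] = {}
    total_v = 0
    for role, meta in sidecar["components"].items():
        if role not in groups:
            raise FormatError(f"sidecar component {role!r} missing from OBJ")
        verts, faces = groups[role]
        if len(verts) != meta["vertex_count"]:
            raise FormatError(
                f"{role}: sidecar vertex count {meta['vertex_count']} != OBJ {len(verts)}"
            )
        total_v += len(verts)
        mesh = SemanticMesh(
            verts,
            faces,
            None if meta["labels"] is None else np.array(meta["labels"]),
            None if meta["row_index"] is None else np.array(meta["row_index"]),
        )
        skel = Skeleton(verts[np.asarray(meta["skeleton_indices"], dtype=int)], role)
        comps[role] = Component(mesh, skel, ComponentParams.from_dict(meta["params"]))
    if total_v != sidecar["vertices_number"]:
        raise FormatError(
            f"sidecar vertices_number {sidecar['vertices_number']} != OBJ total {total_v}"
        )
    return Phytomer(sidecar["phytomer_type"], comps, sidecar.get("index_in_shoot", 0))


# ---------------------------------------------------------------------------
# skeleton I/O and resampling
# ---------------------------------------------------------------------------

def write_skeleton_csv(s: Skeleton, path) -> None:
    import pandas as pd

    pd.DataFrame(s.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_skeleton_csv(path, component_role: str = "leaf") -> Skeleton:
    import pandas as pd

    df = pd.read_csv(path)
    if not {"x", "y", "z"}.issubset(df.columns):
        raise FormatError("skeleton CSV must have columns x, y, z")
    return Skeleton(df[["x", "y", "z"]].to_numpy(dtype=float), component_role)


def resample_at_fractions(s: Skeleton, fractions: np.ndarray) -> Skeleton:
    """Sample a polyline at given normalized arc-length positions in [0, 1]."""
    fr = np.asarray(fractions, dtype=float)
    pts = s.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    target = fr * total
    out = np.column_stack([np.interp(target, cum, pts[:, i]) for i in range(3)])
    # keep exact endpoints where requested
    out[fr <= 0.0] = pts[0]
    out[fr >= 1.0] = pts[-1]
    return Skeleton(out, s.component_role)


def resample_skeleton(s: Skeleton, n: int) -> Skeleton:
    """Resample a skeleton to ``n`` points uniform in arc length.

    The first and last input points are preserved exactly.
    """
    if n < 2:
        raise ValueError("resampling needs n >= 2")
    return resample_at_fractions(s, np.linspace(0.0, 1.0, n))
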