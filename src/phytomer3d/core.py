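"""Core domain types for phytomer-based 3D plant modelling.

A maize shoot is a stack of *phytomers* — repeated structural units each
consisting of a node, the internode above it, and the lateral organs (leaf,
sheath, appendages such as the ear, nodal roots or the terminal tassel)
attached at that node.  A 3D phytomer couples three representations of each
component:

* a triangle **mesh** with per-vertex semantic labels (vein, margin, tip ...),
* an ordered polyline **skeleton** whose points are a subset of the mesh
  vertices (e.g. the leaf midrib or the internode axis), and
* a **morphological parameter set** (lengths, inclinations, diameters ...).

Coordinate convention: right-handed, +Z up, azimuth measured
counter-clockwise from +X when viewed from above.  All lengths are
centimetres; angles are degrees in data structures and files, converted to
radians only inside trigonometric computations.  Phytomer indices are
1-based in user-facing I/O and 0-based internally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import GeometryError, OrderingError

__all__ = [
    "ROLES",
    "PHYTOMER_TYPES",
    "VERTEX_LABELS",
    "ComponentParams",
    "Skeleton",
    "SemanticMesh",
    "SemanticPointSet",
    "Component",
    "Phytomer",
    "PlacementTransform",
    "PhytomerSlot",
    "ShootSpec",
    "PopulationSpec",
    "rotation_about_z",
    "rotation_aligning",
    "classify_phytomer_types",
    "normalize_phytomer",
    "estimate_leaf_area",
    "mesh_area",
]

#: Component roles within a phytomer.
ROLES = ("leaf", "sheath", "internode", "appendage")

#: The five maize phytomer types, by position and appendage.
PHYTOMER_TYPES = ("root", "below_ear", "ear", "above_ear", "tassel")

#: Per-vertex semantic labels.
VERTEX_LABELS = (
    "vein",
    "margin",
    "interior",
    "tip",
    "collar_junction",
    "sheath",
    "internode",
    "appendage",
)


# ---------------------------------------------------------------------------
# rigid-motion helpers
# ---------------------------------------------------------------------------

def rotation_about_z(azimuth_deg: float) -> np.ndarray:
    """3x3 rotation about +Z by ``azimuth_deg`` (CCW seen from above)."""
    a = np.deg2rad(azimuth_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking direction ``a`` onto direction ``b``.

    Both inputs are 3-vectors; the result is the 3x3 rotation about the axis
    ``a x b``.  Antiparallel inputs rotate by pi about a perpendicular axis.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise GeometryError("cannot align zero-length direction")
    a = a / na
    b = b / nb
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        K = np.array(
            [
                [0, -perp[2], perp[1]],
                [perp[2], 0, -perp[0]],
                [-perp[1], perp[0], 0],
            ]
        )
        return np.eye(3) + 2.0 * K @ K
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


def _is_z_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    return abs(R[2, 2] - 1.0) < tol and np.allclose(R[2, :2], 0, atol=tol) and np.allclose(
        R[:2, 2], 0, atol=tol
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ComponentParams:
    """Morphological parameters of one phytomer component.

    Parameters
    ----------
    role:
        One of ``leaf``, ``sheath``, ``internode``, ``appendage``.
    base_height:
        Height of the component base above the plant origin (cm).
    length:
        Component length (cm): leaf midrib length, sheath/internode axial
        length, ear length for the ear appendage.
    inclination:
        Departure angle from the vertical stem axis, degrees.
    azimuth:
        Compass direction (degrees CCW from +X); defined for leaves only.
        ``None`` for other roles.
    diameter_max, diameter_min:
        Largest/smallest diameter of tubular components (cm).
    extras:
        Extensible mapping for additional named scalars, e.g.
        ``leaf_width``, ``tassel_branch_number``, ``ear_diameter_max``.
    """

    role: str
    base_height: float = 0.0
    length: float = 0.0
    inclination: float = 0.0
    azimuth: float | None = None
    diameter_max: float = 0.0
    diameter_min: float = 0.0
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown component role {self.role!r}")
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if not (self.diameter_max >= self.diameter_min >= 0):
            raise ValueError("require diameter_max >= diameter_min >= 0")
        if self.azimuth is not None and self.role != "leaf":
            raise ValueError("azimuth is defined only for leaves")

    def to_dict(self) -> dict:
        d = {
            "role": self.role,
            "base_height": self.base_height,
            "length": self.length,
            "inclination": self.inclination,
            "diameter_max": self.diameter_max,
            "diameter_min": self.diameter_min,
            "extras": dict(self.extras),
        }
        if self.azimuth is not None:
            d["azimuth"] = self.azimuth
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComponentParams":
        return cls(
            role=d["role"],
            base_height=float(d.get("base_height", 0.0)),
            length=float(d.get("length", 0.0)),
            inclination=float(d.get("inclination", 0.0)),
            azimuth=(None if d.get("azimuth") is None else float(d["azimuth"])),
            diameter_max=float(d.get("diameter_max", 0.0)),
            diameter_min=float(d.get("diameter_min", 0.0)),
            extras={k: float(v) for k, v in d.get("extras", {}).items()},
        )


@dataclass
class Skeleton:
    """Ordered base-to-tip polyline abstraction of one component."""

    points: np.ndarray  # (n, 3) float, cm
    component_role: str = "leaf"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise GeometryError("skeleton needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise GeometryError("skeleton has coincident consecutive points")

    @property
    def arc_length(self) -> float:
        """Total polyline length (cm)."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Skeleton":
        return Skeleton(self.points @ R.T + t, self.component_role)


@dataclass
class SemanticMesh:
    """Open triangle surface with per-vertex semantic labels.

    ``row_index`` records, for digitizer-derived meshes, the ordinal of the
    acquisition row each vertex came from (-1 for vertices outside rows,
    e.g. the tip); it is ``None`` for meshes without digitizer provenance.
    """

    vertices: np.ndarray  # (n, 3) float, cm
    faces: np.ndarray  # (m, 3) int
    labels: np.ndarray | None = None  # (n,) unicode
    row_index: np.ndarray | None = None  # (n,) int, -1 = no row

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype="<U16")
        if self.row_index is not None:
            self.row_index = np.asarray(self.row_index, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n = len(self.vertices)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise GeometryError("face index out of range")
        if len(self.faces):
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise GeometryError("degenerate face (repeated vertex index)")
        for arr, name in ((self.labels, "labels"), (self.row_index, "row_index")):
            if arr is not None and len(arr) != n:
                raise GeometryError(f"{name} length != vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "SemanticMesh":
        return SemanticMesh(
            self.vertices @ np.asarray(R).T + np.asarray(t),
            self.faces.copy(),
            None if self.labels is None else self.labels.copy(),
            None if self.row_index is None else self.row_index.copy(),
        )

    def copy(self) -> "SemanticMesh":
        return self.transformed(np.eye(3), np.zeros(3))


@dataclass
class SemanticPointSet:
    """Digitized phytomer point rows following the acquisition standard.

    ``rows[r, k]`` is the k-th of the five points in acquisition row ``r``
    (rows ordered base to tip), and ``tip`` the single leaf-tip point.
    ``roles[r, k]`` carries the semantic tag of each point (margin / vein /
    interior / collar_junction).
    """

    rows: np.ndarray  # (n_rows, 5, 3)
    roles: np.ndarray  # (n_rows, 5) unicode
    tip: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 3 or self.rows.shape[1] != 5 or self.rows.shape[2] != 3:
            raise GeometryError("rows must have shape (n_rows, 5, 3)")
        self.roles = np.asarray(self.roles, dtype="<U16")
        if self.roles.shape != self.rows.shape[:2]:
            raise GeometryError("roles shape must match rows")
        self.tip = np.asarray(self.tip, dtype=float).reshape(3)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_points(self) -> int:
        return self.rows.shape[0] * 5 + 1

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "SemanticPointSet":
        R = np.asarray(R)
        t = np.asarray(t)
        return SemanticPointSet(self.rows @ R.T + t, self.roles.copy(), R @ self.tip + t)

    # -- serialization ------------------------------------------------------

    def to_dataframe(self):
        """Long-form table: row, point_in_row (1-based), role, x, y, z."""
        import pandas as pd

        recs = []
        for r in range(self.n_rows):
            for k in range(5):
                x, y, z = self.rows[r, k]
                recs.append((r + 1, k + 1, self.roles[r, k], x, y, z))
        recs.append((self.n_rows + 1, 1, "tip", *self.tip))
        return pd.DataFrame(recs, columns=["row", "point_in_row", "role", "x", "y", "z"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SemanticPointSet":
        import pandas as pd

        from .errors import FormatError

        df = pd.read_csv(path)
        need = {"row", "point_in_row", "role", "x", "y", "z"}
        if not need.issubset(df.columns):
            raise FormatError(f"point-set CSV must have columns {sorted(need)}")
        tip_rows = df[df["role"] == "tip"]
        if len(tip_rows) != 1:
            raise FormatError("point set must contain exactly one tip point")
        body = df[df["role"] != "tip"].sort_values(["row", "point_in_row"])
        n_rows = body["row"].nunique()
        if len(body) != 5 * n_rows:
            raise FormatError("each acquisition row must contain exactly 5 points")
        rows = body[["x", "y", "z"]].to_numpy().reshape(n_rows, 5, 3)
        roles = body["role"].to_numpy().reshape(n_rows, 5)
        tip = tip_rows[["x", "y", "z"]].to_numpy()[0]
        return cls(rows, roles, tip)

    def to_json(self, path) -> None:
        obj = {
            "rows": self.rows.tolist(),
            "roles": self.roles.tolist(),
            "tip": self.tip.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "SemanticPointSet":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.array(obj["rows"]), np.array(obj["roles"]), np.array(obj["tip"]))


@dataclass
class Component:
    """One phytomer component: mesh + skeleton + parameters."""

    mesh: SemanticMesh
    skeleton: Skeleton
    params: ComponentParams


@dataclass
class Phytomer:
    """A 3D phytomer: the triple (mesh, skeleton, parameters) per component.

    ``index_in_shoot`` is the 1-based ordinal j of the phytomer within its
    shoot (0 for free-standing templates).
    """

    phytomer_type: str
    components: dict[str, Component]
    index_in_shoot: int = 0

    def __post_init__(self) -> None:
        if self.phytomer_type not in PHYTOMER_TYPES:
            raise ValueError(f"unknown phytomer type {self.phytomer_type!r}")
        if self.phytomer_type == "tassel" and (
            "leaf" in self.components or "sheath" in self.components
        ):
            raise OrderingError("a tassel phytomer carries no leaf and no sheath")

    @property
    def n_vertices(self) -> int:
        return sum(c.mesh.n_vertices for c in self.components.values())

    @property
    def n_faces(self) -> int:
        return sum(len(c.mesh.faces) for c in self.components.values())

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Phytomer":
        """Apply a rigid motion, updating placement-coupled parameters.

        Translation changes only vertex coordinates and height-related
        parameters; rotation about +Z additionally updates the leaf azimuth.
        """
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float).reshape(3)
        comps: dict[str, Component] = {}
        dz = float(t[2])
        daz = np.rad2deg(np.arctan2(R[1, 0], R[0, 0])) if _is_z_rotation(R) else None
        for role, c in self.components.items():
            p = replace(c.params, extras=dict(c.params.extras))
            p.base_height += dz
            if daz is not None and p.azimuth is not None:
                p.azimuth = (p.azimuth + daz) % 360.0
            comps[role] = Component(c.mesh.transformed(R, t), c.skeleton.transformed(R, t), p)
        return Phytomer(self.phytomer_type, comps, self.index_in_shoot)

    def check_skeletons_on_mesh(self, tol: float = 1e-6) -> None:
        """Verify every skeleton point coincides with a mesh vertex."""
        for role, c in self.components.items():
            d = np.linalg.norm(
                c.mesh.vertices[None, :, :] - c.skeleton.points[:, None, :], axis=2
            ).min(axis=1)
            if np.any(d > tol):
                raise GeometryError(
                    f"{role} skeleton leaves the mesh vertex set (max {d.max():.2e} cm)"
                )


@dataclass
class PlacementTransform:
    """Rigid placement: rotation about +Z, then translation.

    ``azimuth`` in degrees CCW from +X; ``height`` is the vertical offset in
    cm; ``planar_offset`` the (x, y) ground-plane offset in cm (used for
    population placement, 0 within a shoot).
    """

    azimuth: float = 0.0
    height: float = 0.0
    planar_offset: tuple[float, float] = (0.0, 0.0)

    @property
    def rotation(self) -> np.ndarray:
        return rotation_about_z(self.azimuth)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.planar_offset[0], self.planar_offset[1], self.height])

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix (rotate about Z, then translate)."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def to_dict(self) -> dict:
        return {
            "azimuth": self.azimuth,
            "height": self.height,
            "planar_offset": list(self.planar_offset),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlacementTransform":
        off = d.get("planar_offset", (0.0, 0.0))
        return cls(float(d.get("azimuth", 0.0)), float(d.get("height", 0.0)), (float(off[0]), float(off[1])))


@dataclass
class PhytomerSlot:
    """One phytomer position in a shoot spec: type, placement and the
    morphological parameters used for template retrieval."""

    phytomer_type: str
    placement: PlacementTransform
    target_params: dict[str, float] = field(default_factory=dict)


@dataclass
class ShootSpec:
    """Recipe for assembling one shoot from n phytomers."""

    slots: list[PhytomerSlot]

    def __post_init__(self) -> None:
        types = [s.phytomer_type for s in self.slots]
        for t in types:
            if t not in PHYTOMER_TYPES:
                raise ValueError(f"unknown phytomer type {t!r}")
        if types.count("ear") > 1:
            raise OrderingError("a shoot has at most one ear phytomer")
        if "tassel" in types and types.index("tassel") != len(types) - 1:
            raise OrderingError("the tassel, if present, is the last phytomer")
        heights = [s.placement.height for s in self.slots]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            warnings.warn("phytomer heights are not non-decreasing", stacklevel=2)

    @property
    def n(self) -> int:
        return len(self.slots)

    def to_dict(self) -> dict:
        return {
            "phytomers": [
                {
                    "type": s.phytomer_type,
                    "placement": s.placement.to_dict(),
                    "params": dict(s.target_params),
                }
                for s in self.slots
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ShootSpec":
        slots = [
            PhytomerSlot(
                e["type"],
                PlacementTransform.from_dict(e.get("placement", {})),
                {k: float(v) for k, v in e.get("params", {}).items()},
            )
            for e in d["phytomers"]
        ]
        return cls(slots)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ShootSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PopulationSpec:
    """Planting grid for a canopy of m shoots.

    Rows run along +Y (south to north) with +X pointing east; ``row_distance``
    separates adjacent rows along X and ``plant_spacing`` separates plants
    within a row along Y.  ``azimuths`` is a constant, an explicit per-shoot
    list, or the string ``"random"`` (uniform on [0, 360), drawn with
    ``azimuth_seed``).
    """

    rows: int
    plants_per_row: int
    row_distance: float  # cm
    plant_spacing: float  # cm
    azimuths: float | Sequence[float] | str = 0.0
    azimuth_seed: int | None = None

    def __post_init__(self) -> None:
        from .errors import SpecificationError

        if self.rows < 1 or self.plants_per_row < 1:
            raise SpecificationError("grid dimensions must be >= 1")
        if self.row_distance <= 0 or self.plant_spacing <= 0:
            raise SpecificationError("spacings must be positive")

    @property
    def m(self) -> int:
        return self.rows * self.plants_per_row

    def shoot_azimuths(self) -> np.ndarray:
        if isinstance(self.azimuths, str):
            if self.azimuths != "random":
                raise ValueError("azimuths must be a number, a list or 'random'")
            if self.azimuth_seed is None:
                raise ValueError("random azimuths require azimuth_seed")
            rng = np.random.default_rng(self.azimuth_seed)
            return rng.uniform(0.0, 360.0, self.m)
        if np.isscalar(self.azimuths):
            return np.full(self.m, float(self.azimuths))
        az = np.asarray(self.azimuths, dtype=float)
        if len(az) != self.m:
            raise ValueError("azimuth list length must equal shoot count m")
        return az

    def to_dict(self) -> dict:
        az = self.azimuths if (isinstance(self.azimuths, str) or np.isscalar(self.azimuths)) else list(self.azimuths)
        return {
            "rows": self.rows,
            "plants_per_row": self.plants_per_row,
            "row_distance": self.row_distance,
            "plant_spacing": self.plant_spacing,
            "azimuths": az,
            "azimuth_seed": self.azimuth_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationSpec":
        return cls(
            rows=int(d["rows"]),
            plants_per_row=int(d["plants_per_row"]),
            row_distance=float(d["row_distance"]),
            plant_spacing=float(d["plant_spacing"]),
            azimuths=d.get("azimuths", 0.0),
            azimuth_seed=d.get("azimuth_seed"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def classify_phytomer_types(
    n_total: int,
    n_root: int,
    ear_index: int | None,
    has_tassel: bool,
) -> list[str]:
    """Assign the five phytomer types along a shoot by position.

    Phytomers 1..n_root carry nodal roots; the phytomer at ``ear_index``
    (1-based) is the ear phytomer, those before it below-ear and those after
    it above-ear; the tassel, if present, is the last phytomer.
    """
    if n_total <= 0:
        raise OrderingError("shoot must contain at least one phytomer")
    if not (0 <= n_root < n_total):
        raise OrderingError("require 0 <= n_root < n_total")
    last_vegetative = n_total - 1 if has_tassel else n_total
    if ear_index is not None:
        if not (n_root < ear_index <= last_vegetative):
            raise OrderingError(
                f"ear_index {ear_index} out of range ({n_root} < j <= {last_vegetative})"
            )
    out: list[str] = []
    for j in range(1, n_total + 1):
        if has_tassel and j == n_total:
            out.append("tassel")
        elif j <= n_root:
            out.append("root")
        elif ear_index is not None and j == ear_index:
            out.append("ear")
        elif ear_index is not None and j > ear_index:
            out.append("above_ear")
        else:
            out.append("below_ear")
    return out


def _azimuth_reference(p: Phytomer) -> np.ndarray | None:
    """Horizontal direction defining a phytomer's zero azimuth.

    The leaf midrib direction (tip minus base, projected to XY) when a leaf
    exists; otherwise the appendage skeleton; otherwise the most off-axis
    mesh vertex.  Returns ``None`` when the phytomer is rotationally
    symmetric about Z within tolerance.
    """
    for role in ("leaf", "appendage"):
        c = p.components.get(role)
        if c is None:
            continue
        d = c.skeleton.points[-1] - c.skeleton.points[0]
        if np.hypot(d[0], d[1]) > 1e-9:
            return np.array([d[0], d[1], 0.0])
    best = None
    best_r = 1e-9
    for c in p.components.values():
        xy = c.mesh.vertices[:, :2]
        r = np.hypot(xy[:, 0], xy[:, 1])
        i = int(np.argmax(r))
        if r[i] > best_r:
            best_r = r[i]
            best = np.array([xy[i, 0], xy[i, 1], 0.0])
    return best


def normalize_phytomer(p: Phytomer) -> Phytomer:
    """Standardize a phytomer: node at the origin, internode upright, leaf
    azimuth zero.

    The node (base of the internode skeleton) is translated to the origin
    and the internode base-to-top direction rotated onto +Z; a final
    rotation about Z brings the leaf midrib (or, failing that, the
    appendage) into the +X half-plane so the stored azimuth is 0.  The same
    rigid motion is applied to every component.
    """
    inter = p.components.get("internode")
    if inter is None:
        raise GeometryError("phytomer has no internode component")
    base = inter.skeleton.points[0]
    top = inter.skeleton.points[-1]
    axis = top - base
    if np.linalg.norm(axis) < 1e-9:
        raise GeometryError("degenerate internode: coincident endpoints")
    R1 = rotation_aligning(axis, np.array([0.0, 0.0, 1.0]))
    q = p.transformed(R1, -R1 @ base)
    ref = _azimuth_reference(q)
    if ref is not None:
        ang = np.arctan2(ref[1], ref[0])
        q = q.transformed(rotation_about_z(np.rad2deg(-ang)), np.zeros(3))
    # normalized templates record zero azimuth and zero node height
    for c in q.components.values():
        if c.params.azimuth is not None:
            c.params.azimuth = 0.0
    return q


def estimate_leaf_area(leaf_length: float, leaf_width: float) -> float:
    """Traditional agronomic leaf-area estimate: 0.75 x length x width."""
    if leaf_length < 0 or leaf_width < 0:
        raise ValueError("leaf length and width must be non-negative")
    return 0.75 * leaf_length * leaf_width


def mesh_area(m: SemanticMesh) -> float:
    """Total surface area of a triangle mesh (cm^2); degenerate faces add 0."""
    if len(m.faces) == 0:
        return 0.0
    v = m.vertices
    a = v[m.faces[:, 1]] - v[m.faces[:, 0]]
    b = v[m.faces[:, 2]] - v[m.faces[:, 0]]
    return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())
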