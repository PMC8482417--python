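"""Synthetic digitized phytomers, templates and cultivar databases.

Every downstream stage of the toolkit (meshing, conversion, database
retrieval, assembly, light interception) is exercisable without field data
through this module.  It emulates a 3D-digitizer acquisition campaign:
points are taken in ordered rows from the sheath/node junction to the leaf
tip, five points per row and a single tip point, with the fifth row at the
leaf/sheath collar junction, points 1 and 5 of each row on the margins and
point 3 on the vein.

The parametric organ shapes are deliberately low-order:

* the leaf midrib is a planar curve leaving the collar at the inclination
  angle, with tangent angle increasing quadratically in arc length toward
  the tip (leaves droop progressively);
* the lamina half-width follows a beta-shaped profile ``w(u) ~ u^a (1-u)^b``
  peaking at 35 % of the midrib length.  The exponents are chosen so the
  lamina area integrates to exactly 0.75 x length x width, the classical
  agronomic leaf-area formula — so mesh area and the formula agree for
  synthetic leaves by construction;
* sheath and internode are linear frusta sampled at five points per ring;
* the ear is a capped spheroid of rings, the tassel a central spike with
  curved branches digitized at bottom/middle/top points, and nodal roots
  are short downward spikes.

All stochastic operations take an explicit seed and are reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    Component,
    ComponentParams,
    Phytomer,
    PHYTOMER_TYPES,
    SemanticMesh,
    SemanticPointSet,
    Skeleton,
    normalize_phytomer,
    rotation_about_z,
)
from .errors import ConfigurationError

__all__ = [
    "WIDTH_PEAK_POSITION",
    "WIDTH_EXPONENT_A",
    "WIDTH_EXPONENT_B",
    "lamina_width_profile",
    "CultivarProfile",
    "default_profiles",
    "default_params_for_type",
    "draw_params",
    "generate_digitized_phytomer",
    "generate_phytomer_template",
    "generate_template_database",
]

#: Relative midrib position of the widest lamina cross-section.
WIDTH_PEAK_POSITION = 0.35
#: Beta-profile exponents; solved so that the normalized profile integrates
#: to 0.75, matching the traditional leaf-area formula 0.75 * L * W.
WIDTH_EXPONENT_A = 0.3873598763056213
WIDTH_EXPONENT_B = WIDTH_EXPONENT_A * (1 - WIDTH_PEAK_POSITION) / WIDTH_PEAK_POSITION

#: Default droop: additional tangent angle (degrees) accumulated from collar
#: to tip on top of the collar inclination.
DEFAULT_DROOP_DEG = 50.0


def lamina_width_profile(u, width: float):
    """Lamina width at relative midrib position ``u`` in [0, 1].

    Normalized so the maximum (at ``u = WIDTH_PEAK_POSITION``) equals
    ``width`` and the integral over [0, 1] equals ``0.75 * width``.
    """
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    a, b, p = WIDTH_EXPONENT_A, WIDTH_EXPONENT_B, WIDTH_PEAK_POSITION
    norm = p**a * (1 - p) ** b
    return width * (u**a) * ((1 - u) ** b) / norm


# ---------------------------------------------------------------------------
# midrib and row construction
# ---------------------------------------------------------------------------

def _midrib_points(
    arc_positions: np.ndarray,
    length: float,
    inclination_deg: float,
    droop_deg: float,
    origin: np.ndarray,
) -> np.ndarray:
    """Sample the planar midrib curve at given arc-length positions (cm).

    The curve lies in the XZ plane, starting at ``origin`` with tangent at
    ``inclination_deg`` from +Z, the tangent angle growing quadratically in
    arc length by ``droop_deg`` toward the tip.
    """
    n_dense = 512
    s = np.linspace(0.0, length, n_dense)
    phi = np.deg2rad(inclination_deg) + np.deg2rad(droop_deg) * (s / max(length, 1e-9)) ** 2
    # integrate the unit tangent (sin phi, 0, cos phi) over arc length
    dx = np.sin(phi)
    dz = np.cos(phi)
    x = np.concatenate([[0.0], np.cumsum((dx[1:] + dx[:-1]) / 2 * np.diff(s))])
    z = np.concatenate([[0.0], np.cumsum((dz[1:] + dz[:-1]) / 2 * np.diff(s))])
    xi = np.interp(arc_positions, s, x)
    zi = np.interp(arc_positions, s, z)
    out = np.zeros((len(arc_positions), 3))
    out[:, 0] = xi
    out[:, 2] = zi
    return out + origin


def _sheath_rings(
    sheath_length: float,
    d_max: float,
    d_min: float,
    n_rings: int = 5,
) -> np.ndarray:
    """Half-ring digitizer rows around the sheath tube, node to collar.

    Each ring has 5 points at polar angles +-90, +-45 and 0 degrees around
    the stem axis, point 3 (angle 0, facing the leaf azimuth) lying on the
    vein line that continues into the lamina midrib.
    """
    psi = np.deg2rad([-90.0, -45.0, 0.0, 45.0, 90.0])
    z = np.linspace(0.0, sheath_length, n_rings)
    radii = (d_max - (d_max - d_min) * z / max(sheath_length, 1e-9)) / 2.0
    rows = np.zeros((n_rings, 5, 3))
    for r in range(n_rings):
        rows[r, :, 0] = radii[r] * np.cos(psi)
        rows[r, :, 1] = radii[r] * np.sin(psi)
        rows[r, :, 2] = z[r]
    return rows


def _lamina_row_positions(n_leaf_rows: int) -> np.ndarray:
    """Relative arc positions of lamina rows: uniform in (0, 1) with the row
    nearest the width peak snapped onto it, so the widest cross-section is
    digitized exactly (as a careful operator would)."""
    u = np.arange(1, n_leaf_rows + 1) / (n_leaf_rows + 1.0)
    i = int(np.argmin(np.abs(u - WIDTH_PEAK_POSITION)))
    u[i] = WIDTH_PEAK_POSITION
    return u


def _leaf_sheath_rows(
    leaf: ComponentParams,
    sheath: ComponentParams,
    n_rows: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full digitizer row stack (sheath rings, collar, lamina rows) + tip.

    Returns (rows, roles, tip) in the phytomer frame with azimuth 0.
    """
    n_leaf = n_rows - 5
    rows = np.zeros((n_rows, 5, 3))
    roles = np.full((n_rows, 5), "interior", dtype="<U16")
    rows[:5] = _sheath_rings(sheath.length, sheath.diameter_max, sheath.diameter_min)
    collar_origin = rows[4, 2].copy()  # vein point of the collar ring
    u = _lamina_row_positions(n_leaf)
    L = leaf.length
    width = leaf.extras.get("leaf_width", 0.12 * L)
    droop = leaf.extras.get("droop", DEFAULT_DROOP_DEG)
    mid = _midrib_points(u * L, L, leaf.inclination, droop, collar_origin)
    w = lamina_width_profile(u, width)
    lateral = np.array([0.0, 1.0, 0.0])
    offsets = np.array([-0.5, -0.25, 0.0, 0.25, 0.5])
    for i in range(n_leaf):
        rows[5 + i] = mid[i] + np.outer(offsets * w[i], lateral)
    tip = _midrib_points(np.array([L]), L, leaf.inclination, droop, collar_origin)[0]
    roles[:, 0] = "margin"
    roles[:, 4] = "margin"
    roles[:, 2] = "vein"
    roles[4, 1] = "collar_junction"
    roles[4, 3] = "collar_junction"
    return rows, roles, tip


# ---------------------------------------------------------------------------
# digitized point sets
# ---------------------------------------------------------------------------

def generate_digitized_phytomer(
    params: Mapping[str, ComponentParams],
    n_rows: int,
    seed: int,
    noise_sd: float = 0.0,
) -> SemanticPointSet:
    """Emulate digitizing one leaf+sheath surface following the standard.

    Rows 1-4 ring the sheath, row 5 is the collar junction and the
    remaining rows cross the lamina; the output has exactly ``5 * n_rows + 1``
    points (one tip point).  ``noise_sd`` adds isotropic Gaussian digitizer
    noise in cm (0 by default: points lie exactly on the parametric
    surface).  Deterministic for a fixed seed.
    """
    if n_rows < 6:
        raise ConfigurationError("n_rows must be >= 6 (4 sheath rows, collar, >= 1 leaf row)")
    if "leaf" not in params or "sheath" not in params:
        raise ConfigurationError("digitizing needs 'leaf' and 'sheath' parameters")
    leaf = params["leaf"]
    rows, roles, tip = _leaf_sheath_rows(leaf, params["sheath"], n_rows)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rows = rows + rng.normal(0.0, noise_sd, rows.shape)
        tip = tip + rng.normal(0.0, noise_sd, 3)
    pts = SemanticPointSet(rows, roles, tip)
    az = leaf.azimuth or 0.0
    if az:
        pts = pts.transformed(rotation_about_z(az), np.zeros(3))
    return pts


# ---------------------------------------------------------------------------
# component meshes
# ---------------------------------------------------------------------------

def _strip_mesh(rows: np.ndarray, roles: np.ndarray, row_offset: int = 0) -> SemanticMesh:
    """Open quad-strip mesh over digitizer rows (no tip fan)."""
    n_rows = len(rows)
    verts = rows.reshape(-1, 3)
    labels = roles.reshape(-1)
    row_index = np.repeat(np.arange(row_offset, row_offset + n_rows), 5)
    faces = []
    for r in range(n_rows - 1):
        a, b = 5 * r, 5 * (r + 1)
        for k in range(4):
            faces.append((a + k, a + k + 1, b + k + 1))
            faces.append((a + k, b + k + 1, b + k))
    return SemanticMesh(verts, np.array(faces, dtype=np.int64), labels, row_index)


def _frustum_mesh(
    length: float,
    d_max: float,
    d_min: float,
    label: str,
    n_ring: int = 5,
) -> tuple[SemanticMesh, Skeleton]:
    """Closed frustum with axis cap-centre vertices; skeleton = the axis."""
    psi = np.linspace(0.0, 2 * np.pi, n_ring, endpoint=False)
    r0, r1 = d_max / 2.0, d_min / 2.0
    base = np.column_stack([r0 * np.cos(psi), r0 * np.sin(psi), np.zeros(n_ring)])
    top = np.column_stack([r1 * np.cos(psi), r1 * np.sin(psi), np.full(n_ring, length)])
    verts = np.vstack([[0.0, 0.0, 0.0], base, top, [0.0, 0.0, length]])
    c0, ring0, ring1, c1 = 0, 1, 1 + n_ring, 1 + 2 * n_ring
    faces = []
    for k in range(n_ring):
        kn = (k + 1) % n_ring
        faces.append((ring0 + k, ring0 + kn, ring1 + kn))
        faces.append((ring0 + k, ring1 + kn, ring1 + k))
        faces.append((c0, ring0 + kn, ring0 + k))
        faces.append((c1, ring1 + k, ring1 + kn))
    labels = np.full(len(verts), label, dtype="<U16")
    mesh = SemanticMesh(verts, np.array(faces, dtype=np.int64), labels, None)
    skel = Skeleton(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, length]]), label)
    return mesh, skel


def _ear_mesh(params: ComponentParams) -> tuple[SemanticMesh, Skeleton]:
    """Capped spheroid of five-point rings; axis tilted toward the leaf."""
    L = params.extras.get("ear_length", params.length)
    R = params.extras.get("ear_diameter_max", params.diameter_max) / 2.0
    tilt = np.deg2rad(params.inclination if params.inclination else 25.0)
    axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
    # local frame around the ear axis
    u = np.array([np.cos(tilt), 0.0, -np.sin(tilt)])
    v = np.array([0.0, 1.0, 0.0])
    n_rings = 4
    f = np.arange(1, n_rings + 1) / (n_rings + 1.0)
    radii = R * np.sqrt(np.clip(1.0 - (2 * f - 1.0) ** 2, 0.0, 1.0))
    psi = np.linspace(0.0, 2 * np.pi, 5, endpoint=False)
    verts = [np.zeros(3)]
    for fk, rk in zip(f, radii):
        centre = axis * (fk * L)
        ring = centre + np.outer(rk * np.cos(psi), u) + np.outer(rk * np.sin(psi), v)
        verts.extend(ring)
    verts.append(axis * L)
    verts = np.asarray(verts)
    tip_i = len(verts) - 1
    faces = []
    for k in range(5):
        kn = (k + 1) % 5
        faces.append((0, 1 + kn, 1 + k))
    for r in range(n_rings - 1):
        a, b = 1 + 5 * r, 1 + 5 * (r + 1)
        for k in range(5):
            kn = (k + 1) % 5
            faces.append((a + k, a + kn, b + kn))
            faces.append((a + k, b + kn, b + k))
    last = 1 + 5 * (n_rings - 1)
    for k in range(5):
        kn = (k + 1) % 5
        faces.append((last + k, last + kn, tip_i))
    labels = np.full(len(verts), "appendage", dtype="<U16")
    mesh = SemanticMesh(verts, np.array(faces, dtype=np.int64), labels, None)
    skel = Skeleton(np.array([np.zeros(3), axis * L]), "appendage")
    return mesh, skel


def _spike_mesh(
    base: np.ndarray,
    direction: np.ndarray,
    length: float,
    n_axis: int = 4,
    offset: float = 0.15,
) -> tuple[np.ndarray, list[tuple[int, int, int]], list[int]]:
    """Thin spike: axis polyline plus per-segment lateral offset vertices.

    Returns (vertices, faces, axis indices); the axis points double as the
    skeleton so skeleton points stay mesh vertices.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    axis_pts = base + np.outer(np.linspace(0.0, length, n_axis), direction)
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    side = (axis_pts[:-1] + axis_pts[1:]) / 2 + perp * offset
    verts = np.vstack([axis_pts, side])
    faces = []
    for i in range(n_axis - 1):
        faces.append((i, n_axis + i, i + 1))
    return verts, faces, list(range(n_axis))


def _tassel_mesh(params: ComponentParams) -> tuple[SemanticMesh, Skeleton]:
    """Central spike plus curved branches digitized at bottom/middle/top."""
    L = params.length
    n_branch = int(round(params.extras.get("tassel_branch_number", 8)))
    tilt = np.deg2rad(5.0)  # slight lean so the azimuth reference is defined
    direction = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
    verts, faces, axis_idx = _spike_mesh(np.zeros(3), direction, L)
    verts = list(verts)
    faces = list(faces)
    attach = np.asarray(direction) * (0.3 * L)
    br_len = 0.45 * L
    for i in range(n_branch):
        phi = 2 * np.pi * i / n_branch
        horiz = np.array([np.cos(phi), np.sin(phi), 0.0])
        d_low = horiz * np.cos(np.deg2rad(35)) + np.array([0, 0, np.sin(np.deg2rad(35))])
        d_high = horiz * np.cos(np.deg2rad(60)) + np.array([0, 0, np.sin(np.deg2rad(60))])
        b = attach
        m = attach + d_high * (0.5 * br_len)
        t = attach + d_high * (0.5 * br_len) + d_low * (0.5 * br_len)
        i0 = len(verts)
        verts.extend([b, m, t])
        faces.append((i0, i0 + 1, i0 + 2))
    verts = np.asarray(verts)
    labels = np.full(len(verts), "appendage", dtype="<U16")
    mesh = SemanticMesh(verts, np.array(faces, dtype=np.int64), labels, None)
    skel = Skeleton(verts[np.asarray(axis_idx)], "appendage")
    return mesh, skel


def _nodal_roots_mesh(params: ComponentParams) -> tuple[SemanticMesh, Skeleton]:
    """Three short nodal-root spikes angling down and outward from the node."""
    L = max(params.length, 1.0)
    r0 = params.diameter_max / 2.0 if params.diameter_max else 1.0
    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []
    skel_idx: list[int] = []
    for i in range(3):
        phi = np.deg2rad(20.0 + 120.0 * i)
        horiz = np.array([np.cos(phi), np.sin(phi), 0.0])
        base = horiz * r0 + np.array([0.0, 0.0, 0.5])
        direction = horiz * np.cos(np.deg2rad(50)) - np.array([0, 0, np.sin(np.deg2rad(50))])
        v, f, ax = _spike_mesh(base, direction, L, n_axis=3, offset=0.1)
        off = len(verts)
        verts.extend(v)
        faces.extend([(a + off, b + off, c + off) for a, b, c in f])
        if i == 0:
            skel_idx = [a + off for a in ax]
    verts = np.asarray(verts)
    labels = np.full(len(verts), "appendage", dtype="<U16")
    mesh = SemanticMesh(verts, np.array(faces, dtype=np.int64), labels, None)
    skel = Skeleton(verts[np.asarray(skel_idx)], "appendage")
    return mesh, skel


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def default_params_for_type(phytomer_type: str) -> dict[str, ComponentParams]:
    """Mid-season parameter set for one phytomer of each type (cm/degrees)."""
    if phytomer_type not in PHYTOMER_TYPES:
        raise ConfigurationError(f"unknown phytomer type {phytomer_type!r}")
    leaf = ComponentParams(
        "leaf",
        base_height=12.0,
        length=60.0,
        inclination=35.0,
        azimuth=0.0,
        extras={"leaf_width": 9.0, "droop": DEFAULT_DROOP_DEG},
    )
    sheath = ComponentParams("sheath", length=12.0, diameter_max=3.0, diameter_min=2.2)
    internode = ComponentParams("internode", length=10.0, diameter_max=2.4, diameter_min=2.0)
    out: dict[str, ComponentParams] = {"internode": internode}
    if phytomer_type == "tassel":
        out["appendage"] = ComponentParams(
            "appendage", length=30.0, extras={"tassel_branch_number": 8.0}
        )
        return out
    out["leaf"] = leaf
    out["sheath"] = sheath
    if phytomer_type == "ear":
        out["appendage"] = ComponentParams(
            "appendage",
            length=18.0,
            inclination=25.0,
            diameter_max=5.0,
            extras={"ear_length": 18.0, "ear_diameter_max": 5.0},
        )
    elif phytomer_type == "root":
        out["appendage"] = ComponentParams("appendage", length=4.0, diameter_max=2.6)
    return out


def generate_phytomer_template(
    phytomer_type: str,
    params: Mapping[str, ComponentParams] | None = None,
    seed: int = 0,
    n_rows: int = 12,
) -> Phytomer:
    """Build one normalized phytomer template (< 200 vertices).

    The node sits at the origin with the internode along +Z and the leaf
    (if any) at azimuth 0.  The leaf midrib polyline length matches the
    requested leaf length to within its chordal discretization (< 1 %).
    """
    if phytomer_type not in PHYTOMER_TYPES:
        raise ConfigurationError(f"unknown phytomer type {phytomer_type!r}")
    params = dict(params) if params is not None else default_params_for_type(phytomer_type)
    if phytomer_type == "tassel" and ("leaf" in params or "sheath" in params):
        raise ConfigurationError("a tassel phytomer takes no leaf or sheath parameters")
    if "internode" not in params:
        raise ConfigurationError("every phytomer needs internode parameters")
    comps: dict[str, Component] = {}
    inter = params["internode"]
    mesh, skel = _frustum_mesh(inter.length, inter.diameter_max, inter.diameter_min, "internode")
    comps["internode"] = Component(mesh, skel, inter)

    if phytomer_type != "tassel":
        if "leaf" not in params or "sheath" not in params:
            raise ConfigurationError(f"{phytomer_type} phytomer needs leaf and sheath parameters")
        leaf, sheath = params["leaf"], params["sheath"]
        rows, roles, tip = _leaf_sheath_rows(leaf, sheath, n_rows)
        sheath_mesh = _strip_mesh(rows[:5], roles[:5], row_offset=0)
        sheath_skel = Skeleton(rows[:5, 2, :], "sheath")
        comps["sheath"] = Component(sheath_mesh, sheath_skel, sheath)
        leaf_pts = SemanticPointSet(rows[4:], roles[4:], tip)
        from .meshio import build_mesh_from_digitized

        leaf_mesh = build_mesh_from_digitized(leaf_pts)
        leaf_skel = Skeleton(np.vstack([rows[4:, 2, :], tip[None, :]]), "leaf")
        leaf = ComponentParams(
            "leaf",
            base_height=sheath.length,
            length=leaf.length,
            inclination=leaf.inclination,
            azimuth=0.0,
            diameter_max=leaf.diameter_max,
            diameter_min=leaf.diameter_min,
            extras=dict(leaf.extras),
        )
        comps["leaf"] = Component(leaf_mesh, leaf_skel, leaf)

    if phytomer_type == "ear":
        app = params.get("appendage") or default_params_for_type("ear")["appendage"]
        mesh, skel = _ear_mesh(app)
        comps["appendage"] = Component(mesh, skel, app)
    elif phytomer_type == "tassel":
        app = params.get("appendage") or default_params_for_type("tassel")["appendage"]
        mesh, skel = _tassel_mesh(app)
        comps["appendage"] = Component(mesh, skel, app)
    elif phytomer_type == "root":
        app = params.get("appendage") or default_params_for_type("root")["appendage"]
        mesh, skel = _nodal_roots_mesh(app)
        comps["appendage"] = Component(mesh, skel, app)

    p = Phytomer(phytomer_type, comps)
    return normalize_phytomer(p)


# ---------------------------------------------------------------------------
# cultivar profiles and databases
# ---------------------------------------------------------------------------

@dataclass
class CultivarProfile:
    """Parameter distributions (mean, sd) describing one synthetic cultivar.

    Keys of ``distributions``: leaf_length, leaf_width, leaf_inclination,
    sheath_length, sheath_diameter_max, sheath_diameter_min,
    internode_length, internode_diameter_max, internode_diameter_min,
    tassel_length, tassel_branch_number, ear_length, ear_diameter_max.
    Units cm / degrees / counts.  ``phyllotaxy`` is the leaf alternation
    angle in degrees (maize is alternate, ~180).
    """

    name: str
    growth_period: str = "R1"
    distributions: dict[str, tuple[float, float]] = field(default_factory=dict)
    phyllotaxy_mean: float = 180.0
    phyllotaxy_sd: float = 8.0

    def __post_init__(self) -> None:
        for k, (mu, sd) in self.distributions.items():
            if sd < 0:
                raise ConfigurationError(f"{self.name}: sd of {k} must be >= 0")
            if mu <= 0 and not k.endswith("inclination"):
                raise ConfigurationError(f"{self.name}: mean of {k} must be positive")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "growth_period": self.growth_period,
            "distributions": {k: list(v) for k, v in self.distributions.items()},
            "phyllotaxy_mean": self.phyllotaxy_mean,
            "phyllotaxy_sd": self.phyllotaxy_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CultivarProfile":
        return cls(
            name=d["name"],
            growth_period=d.get("growth_period", "R1"),
            distributions={k: (float(v[0]), float(v[1])) for k, v in d.get("distributions", {}).items()},
            phyllotaxy_mean=float(d.get("phyllotaxy_mean", 180.0)),
            phyllotaxy_sd=float(d.get("phyllotaxy_sd", 8.0)),
        )


_BASE_DIST = {
    "leaf_length": (60.0, 5.0),
    "leaf_width": (9.0, 0.8),
    "leaf_inclination": (35.0, 5.0),
    "sheath_length": (12.0, 1.0),
    "sheath_diameter_max": (3.0, 0.2),
    "sheath_diameter_min": (2.2, 0.15),
    "internode_length": (10.0, 1.2),
    "internode_diameter_max": (2.4, 0.15),
    "internode_diameter_min": (2.0, 0.12),
    "tassel_length": (30.0, 3.0),
    "tassel_branch_number": (8.0, 1.5),
    "ear_length": (18.0, 1.5),
    "ear_diameter_max": (5.0, 0.4),
}


def default_profiles() -> list[CultivarProfile]:
    """Four contrasting synthetic ideotypes.

    They emulate the morphological contrasts one sees among commercial
    maize cultivars: a short plant with wide leaves, a tall one with long
    narrow flat leaves, a mid-height type with long upper internodes, and a
    compact erect-leaved type.
    """

    def scaled(**over) -> dict[str, tuple[float, float]]:
        d = {k: v for k, v in _BASE_DIST.items()}
        for k, (mu, sd) in over.items():
            d[k] = (mu, sd)
        return d

    return [
        CultivarProfile("shortwide", distributions=scaled(
            leaf_length=(55.0, 4.0), leaf_width=(10.5, 0.8),
            internode_length=(7.5, 0.8), leaf_inclination=(40.0, 5.0))),
        CultivarProfile("longnarrow", distributions=scaled(
            leaf_length=(75.0, 5.0), leaf_width=(7.0, 0.6),
            internode_length=(12.5, 1.2), leaf_inclination=(55.0, 5.0))),
        CultivarProfile("tallmid", distributions=scaled(
            leaf_length=(65.0, 5.0), leaf_width=(9.0, 0.7),
            internode_length=(13.0, 1.5), leaf_inclination=(35.0, 5.0))),
        CultivarProfile("compact", distributions=scaled(
            leaf_length=(58.0, 4.0), leaf_width=(9.5, 0.7),
            internode_length=(10.0, 1.0), leaf_inclination=(22.0, 4.0))),
    ]


def _draw(rng: np.random.Generator, mu: float, sd: float) -> float:
    """Gaussian draw clipped at +-3 sd, floored just above zero."""
    x = mu + float(np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd)) if sd > 0 else mu
    return max(x, 1e-3)


def draw_params(
    profile: CultivarProfile,
    phytomer_type: str,
    rng: np.random.Generator,
) -> dict[str, ComponentParams]:
    """Draw one phytomer's component parameters from a cultivar profile."""
    d = dict(_BASE_DIST)
    d.update(profile.distributions)
    g = lambda k: _draw(rng, *d[k])  # noqa: E731
    sd_max = g("sheath_diameter_max")
    sd_min = min(g("sheath_diameter_min"), sd_max)
    id_max = g("internode_diameter_max")
    id_min = min(g("internode_diameter_min"), id_max)
    internode = ComponentParams(
        "internode", length=g("internode_length"), diameter_max=id_max, diameter_min=id_min
    )
    out: dict[str, ComponentParams] = {"internode": internode}
    if phytomer_type == "tassel":
        out["appendage"] = ComponentParams(
            "appendage",
            length=g("tassel_length"),
            extras={"tassel_branch_number": max(1.0, round(g("tassel_branch_number")))},
        )
        return out
    sheath_len = g("sheath_length")
    out["sheath"] = ComponentParams(
        "sheath", length=sheath_len, diameter_max=sd_max, diameter_min=sd_min
    )
    out["leaf"] = ComponentParams(
        "leaf",
        base_height=sheath_len,
        length=g("leaf_length"),
        inclination=g("leaf_inclination"),
        azimuth=0.0,
        extras={"leaf_width": g("leaf_width"), "droop": DEFAULT_DROOP_DEG},
    )
    if phytomer_type == "ear":
        el, ed = g("ear_length"), g("ear_diameter_max")
        out["appendage"] = ComponentParams(
            "appendage", length=el, inclination=25.0, diameter_max=ed,
            extras={"ear_length": el, "ear_diameter_max": ed},
        )
    elif phytomer_type == "root":
        out["appendage"] = ComponentParams("appendage", length=4.0, diameter_max=sd_max)
    return out


def morphology_of(params: Mapping[str, ComponentParams]) -> dict[str, float]:
    """Flatten a component parameter set into database morphology keywords."""
    out: dict[str, float] = {}
    if "leaf" in params:
        leaf = params["leaf"]
        out["leaf_length"] = leaf.length
        out["leaf_inclination"] = leaf.inclination
        out["leaf_azimuth"] = leaf.azimuth or 0.0
        if "leaf_width" in leaf.extras:
            out["leaf_width"] = leaf.extras["leaf_width"]
    if "sheath" in params:
        sh = params["sheath"]
        out["sheath_length"] = sh.length
        out["sheath_diameter_max"] = sh.diameter_max
        out["sheath_diameter_min"] = sh.diameter_min
    if "internode" in params:
        it = params["internode"]
        out["internode_length"] = it.length
        out["internode_diameter_max"] = it.diameter_max
        out["internode_diameter_min"] = it.diameter_min
    if "appendage" in params:
        ap = params["appendage"]
        if "tassel_branch_number" in ap.extras:
            out["tassel_length"] = ap.length
            out["tassel_branch_number"] = ap.extras["tassel_branch_number"]
        if "ear_length" in ap.extras:
            out["ear_length"] = ap.extras["ear_length"]
            out["ear_diameter_max"] = ap.extras.get("ear_diameter_max", ap.diameter_max)
    return out


def generate_template_database(
    profiles: Sequence[CultivarProfile],
    per_type: int,
    seed: int,
    out_dir,
):
    """Generate a keyword-indexed template database on disk.

    Creates ``len(profiles) * 5 * per_type`` entries (one sub-population per
    cultivar and phytomer type) and writes the OBJ+sidecar files plus a
    single JSON index under ``out_dir``.
    """
    from .database import TemplateDB

    if per_type < 1:
        raise ConfigurationError("per_type must be >= 1")
    db = TemplateDB.create(out_dir)
    rng = np.random.default_rng(seed)
    for profile in profiles:
        for ptype in PHYTOMER_TYPES:
            for k in range(per_type):
                params = draw_params(profile, ptype, rng)
                tpl = generate_phytomer_template(ptype, params)
                entry_id = f"{profile.name}-{ptype}-{k:03d}"
                db.add_entry(
                    tpl,
                    entry_id=entry_id,
                    morphology=morphology_of(params),
                    agronomic={
                        "cultivar": profile.name,
                        "growth_period": profile.growth_period,
                        "eco_region": "synthetic",
                        "density": 6.0,
                        "row_distance": 60.0,
                        "treatment": "standard",
                    },
                    other={"template_identifier": entry_id, "acquisition_person": "synthetic"},
                )
    db.save()
    return db
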