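"""Shoot and population assembly by rigid placement of phytomers.

A shoot is the union of its phytomers, each template rigidly placed by a
rotation about +Z (the phytomer azimuth) followed by a translation to the
phytomer's node height; a population is the union of shoots placed on a
planting grid (rows running south to north along +Y, +X east) with a
per-shoot azimuth applied before the planar translation.  Placement is
rigid: within-phytomer geometry is conserved exactly, translation touches
only vertex coordinates and height-related parameters, and rotation
additionally updates azimuth-related parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Phytomer, PlacementTransform, PopulationSpec, ShootSpec
from .database import TemplateDB, select_template
from .errors import SpecificationError

__all__ = [
    "Shoot",
    "Population",
    "placement_matrix",
    "assemble_shoot",
    "assemble_population",
    "grid_spacing_from_density",
    "density_from_spacing",
]


def placement_matrix(t: PlacementTransform) -> np.ndarray:
    """Homogeneous 4x4 rigid matrix: rotate about +Z, then translate."""
    return t.matrix()


@dataclass
class Shoot:
    """An assembled shoot: placed phytomers plus template provenance."""

    phytomers: list[Phytomer]
    template_ids: list[str] = field(default_factory=list)
    spec: ShootSpec | None = None

    @property
    def n(self) -> int:
        return len(self.phytomers)

    @property
    def n_vertices(self) -> int:
        return sum(p.n_vertices for p in self.phytomers)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Shoot":
        return Shoot([p.transformed(R, t) for p in self.phytomers], list(self.template_ids), self.spec)

    def obj_groups(self, prefix: str = "") -> list[tuple[str, np.ndarray, np.ndarray]]:
        groups = []
        for p in self.phytomers:
            j = p.index_in_shoot
            for role in sorted(p.components):
                c = p.components[role]
                groups.append((f"{prefix}phytomer{j}_{role}", c.mesh.vertices, c.mesh.faces))
        return groups


@dataclass
class Population:
    """An assembled canopy: placed shoots on a planting grid."""

    shoots: list[Shoot]
    positions: np.ndarray  # (m, 2) cm
    azimuths: np.ndarray  # (m,) degrees
    spec: PopulationSpec | None = None

    @property
    def m(self) -> int:
        return len(self.shoots)

    @property
    def n_vertices(self) -> int:
        return sum(s.n_vertices for s in self.shoots)

    def obj_groups(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        groups = []
        for i, s in enumerate(self.shoots, start=1):
            groups.extend(s.obj_groups(prefix=f"shoot{i}_"))
        return groups


def assemble_shoot(
    spec: ShootSpec,
    db: TemplateDB,
    rescale: bool = False,
    cumulative_heights: bool = False,
) -> Shoot:
    """Assemble one shoot from a spec and a template database.

    For each phytomer slot the highest-similarity template of the requested
    type is retrieved, optionally uniformly rescaled so its leaf length
    matches the target (``rescale=True``), and rigidly placed.  Heights are
    absolute node z by default; with ``cumulative_heights=True`` each slot
    height is stacked on the previous one.
    """
    placed: list[Phytomer] = []
    ids: list[str] = []
    z_cursor = 0.0
    prev_h = None
    for j, slot in enumerate(spec.slots, start=1):
        entry = select_template(db, slot.phytomer_type, slot.target_params)
        p = db.load_phytomer(entry)
        if rescale and "leaf_length" in slot.target_params and "leaf_length" in entry.morphology:
            s = slot.target_params["leaf_length"] / entry.morphology["leaf_length"]
            p = _uniform_scale(p, s)
        h = slot.placement.height
        if cumulative_heights:
            z_cursor += h
            h = z_cursor
        if prev_h is not None and h < prev_h - 1e-9:
            warnings.warn(
                f"phytomer {j} height {h} below phytomer {j - 1} ({prev_h})", stacklevel=2
            )
        prev_h = h
        t = PlacementTransform(slot.placement.azimuth, h, slot.placement.planar_offset)
        q = p.transformed(t.rotation, t.translation)
        q.index_in_shoot = j
        placed.append(q)
        ids.append(entry.id)
    return Shoot(placed, ids, spec)


def _uniform_scale(p: Phytomer, s: float) -> Phytomer:
    """Uniform scaling about the origin (the phytomer node)."""
    from .core import Component
    from dataclasses import replace

    comps = {}
    for role, c in p.components.items():
        mesh = c.mesh.copy()
        mesh.vertices *= s
        skel = type(c.skeleton)(c.skeleton.points * s, c.skeleton.component_role)
        par = replace(c.params, extras=dict(c.params.extras))
        par.length *= s
        par.base_height *= s
        par.diameter_max *= s
        par.diameter_min *= s
        for k in list(par.extras):
            if k.endswith(("length", "width", "diameter_max", "diameter_min")):
                par.extras[k] *= s
        comps[role] = Component(mesh, skel, par)
    return Phytomer(p.phytomer_type, comps, p.index_in_shoot)


def assemble_population(
    pop: PopulationSpec,
    shoot_source: Shoot | Sequence[Shoot] | Sequence[ShootSpec],
    db: TemplateDB | None = None,
) -> Population:
    """Place m shoots on the planting grid of a population spec.

    ``shoot_source`` may be one prebuilt shoot (replicated across the
    grid), a list of m prebuilt shoots, or a list of m shoot specs (then
    ``db`` must be given).  The per-shoot azimuth rotation is applied
    before the planar translation.
    """
    m = pop.m
    if isinstance(shoot_source, Shoot):
        base = [shoot_source] * m
    else:
        src = list(shoot_source)
        if src and isinstance(src[0], ShootSpec):
            if db is None:
                raise SpecificationError("assembling from shoot specs requires a database")
            src = [assemble_shoot(s, db) for s in src]
        if len(src) == 1:
            src = src * m
        if len(src) != m:
            raise SpecificationError(
                f"shoot count {len(src)} != rows x plants_per_row = {m}"
            )
        base = src
    az = pop.shoot_azimuths()
    xs = (np.arange(pop.rows) - (pop.rows - 1) / 2.0) * pop.row_distance
    ys = (np.arange(pop.plants_per_row) - (pop.plants_per_row - 1) / 2.0) * pop.plant_spacing
    shoots = []
    positions = []
    i = 0
    for r in range(pop.rows):
        for c in range(pop.plants_per_row):
            t = PlacementTransform(az[i], 0.0, (xs[r], ys[c]))
            shoots.append(base[i].transformed(t.rotation, t.translation))
            positions.append((xs[r], ys[c]))
            i += 1
    return Population(shoots, np.asarray(positions, dtype=float), az, pop)


def grid_spacing_from_density(density: float, row_distance: float) -> float:
    """Plant spacing (m) within a row from density (plants/m^2) and row
    distance (m): spacing = 1 / (density * row_distance)."""
    if density <= 0 or row_distance <= 0:
        raise ValueError("density and row distance must be positive")
    return 1.0 / (density * row_distance)


def density_from_spacing(plant_spacing: float, row_distance: float) -> float:
    """Inverse of :func:`grid_spacing_from_density` (plants per m^2)."""
    if plant_spacing <= 0 or row_distance <= 0:
        raise ValueError("spacings must be positive")
    return 1.0 / (plant_spacing * row_distance)
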