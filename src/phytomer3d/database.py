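"""Keyword-indexed 3D phytomer template store.

Each entry couples a stored OBJ+sidecar template with four keyword groups:
agronomic parameters (cultivar, growth period, eco-region, density, row
distance, treatment), 3D model information (storage path, vertex and mesh
counts), morphological parameters (leaf length/width, sheath and internode
dimensions, tassel and ear descriptors) and free-form other information.
The index is one diff-able JSON file; meshes live in per-entry OBJ files.

Template selection for assembly uses z-score-normalized weighted Euclidean
distance over the morphological parameters shared between the query and an
entry, statistics computed within the requested phytomer type's
sub-database.  Missing parameters are skipped with weight renormalization;
ties break toward the lexicographically smaller entry id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import Phytomer, PHYTOMER_TYPES
from .errors import FormatError, RetrievalError, SpecificationError
from .meshio import read_template, write_template

__all__ = ["Entry", "TemplateDB", "select_template", "filter_entries"]

INDEX_NAME = "index.json"


@dataclass
class Entry:
    """One database index record."""

    id: str
    phytomer_type: str
    storage_path: str  # relative to the database root
    vertices_number: int
    mesh_number: int
    morphology: dict[str, float] = field(default_factory=dict)
    agronomic: dict = field(default_factory=dict)
    other: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "phytomer_type": self.phytomer_type,
            "storage_path": self.storage_path,
            "vertices_number": self.vertices_number,
            "mesh_number": self.mesh_number,
            "morphology": dict(self.morphology),
            "agronomic": dict(self.agronomic),
            "other": dict(self.other),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Entry":
        return cls(
            id=d["id"],
            phytomer_type=d["phytomer_type"],
            storage_path=d["storage_path"],
            vertices_number=int(d["vertices_number"]),
            mesh_number=int(d["mesh_number"]),
            morphology={k: float(v) for k, v in d.get("morphology", {}).items()},
            agronomic=dict(d.get("agronomic", {})),
            other=dict(d.get("other", {})),
        )

    def lookup(self, key: str):
        """Resolve a keyword across the top level and keyword groups."""
        if key in ("id", "phytomer_type", "storage_path", "vertices_number", "mesh_number"):
            return getattr(self, key)
        for group in (self.agronomic, self.morphology, self.other):
            if key in group:
                return group[key]
        raise KeyError(key)

    def has_key(self, key: str) -> bool:
        try:
            self.lookup(key)
            return True
        except KeyError:
            return False


class TemplateDB:
    """On-disk template database: a root directory + JSON index."""

    def __init__(self, root, entries: list[Entry] | None = None):
        self.root = Path(root)
        self.entries: list[Entry] = list(entries or [])

    # -- construction and persistence --------------------------------------

    @classmethod
    def create(cls, root) -> "TemplateDB":
        root = Path(root)
        try:
            (root / "entries").mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise FormatError(f"cannot create database directory {root}: {exc}") from exc
        return cls(root)

    @classmethod
    def load(cls, root) -> "TemplateDB":
        root = Path(root)
        index = root / INDEX_NAME
        if not index.exists():
            raise FormatError(f"{root} has no {INDEX_NAME}: not a template database")
        data = json.loads(index.read_text())
        db = cls(root, [Entry.from_dict(e) for e in data["entries"]])
        ids = [e.id for e in db.entries]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate entry ids in index")
        return db

    def save(self) -> None:
        data = {"format": "phytomer3d-db", "entries": [e.to_dict() for e in self.entries]}
        (self.root / INDEX_NAME).write_text(json.dumps(data, indent=1))

    def add_entry(
        self,
        template: Phytomer,
        entry_id: str,
        morphology: Mapping[str, float] | None = None,
        agronomic: Mapping | None = None,
        other: Mapping | None = None,
    ) -> Entry:
        if any(e.id == entry_id for e in self.entries):
            raise SpecificationError(f"duplicate entry id {entry_id!r}")
        rel = f"entries/{entry_id}.obj"
        keywords = {
            "agronomic": dict(agronomic or {}),
            "morphological": dict(morphology or {}),
            "other": dict(other or {}),
        }
        write_template(template, self.root / rel, keywords=keywords)
        entry = Entry(
            id=entry_id,
            phytomer_type=template.phytomer_type,
            storage_path=rel,
            vertices_number=template.n_vertices,
            mesh_number=template.n_faces,
            morphology=dict(morphology or {}),
            agronomic=dict(agronomic or {}),
            other=dict(other or {}),
        )
        self.entries.append(entry)
        return entry

    # -- access -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, entry_id: str) -> Entry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise RetrievalError(f"no entry with id {entry_id!r}")

    def load_phytomer(self, entry: Entry | str) -> Phytomer:
        if isinstance(entry, str):
            entry = self.get(entry)
        return read_template(self.root / entry.storage_path)

    def of_type(self, phytomer_type: str) -> list[Entry]:
        if phytomer_type not in PHYTOMER_TYPES:
            raise SpecificationError(f"unknown phytomer type {phytomer_type!r}")
        return sorted(
            (e for e in self.entries if e.phytomer_type == phytomer_type), key=lambda e: e.id
        )


def filter_entries(db: TemplateDB, criteria: Mapping) -> list[Entry]:
    """Entries matching all keyword criteria, in stable id order.

    Unknown criteria keys (present in no index field of any entry) raise
    :class:`SpecificationError`; criteria matching nothing return an empty
    list.
    """
    for key in criteria:
        if not any(e.has_key(key) for e in db.entries):
            raise SpecificationError(f"unknown index keyword {key!r}")
    out = []
    for e in sorted(db.entries, key=lambda e: e.id):
        ok = True
        for key, val in criteria.items():
            if not e.has_key(key) or e.lookup(key) != val:
                ok = False
                break
        if ok:
            out.append(e)
    return out


def select_template(
    db: TemplateDB,
    phytomer_type: str,
    query: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> Entry:
    """Highest-similarity template of a type for a morphological query.

    Distance is weighted Euclidean over the z-score-normalized shared
    numeric parameters, normalization statistics computed over the type's
    sub-database.  An empty query returns the first entry by id.
    """
    sub = db.of_type(phytomer_type)
    if not sub:
        raise RetrievalError(f"database holds no {phytomer_type!r} template")
    if not query:
        return sub[0]
    keys = [k for k in sorted(query) if any(k in e.morphology for e in sub)]
    if not keys:
        raise SpecificationError(
            f"query shares no morphological parameter with the {phytomer_type!r} sub-database"
        )
    stats = {}
    for k in keys:
        vals = np.array([e.morphology[k] for e in sub if k in e.morphology], dtype=float)
        sd = float(vals.std())
        stats[k] = (float(vals.mean()), sd if sd > 1e-12 else 1.0)
    w = {k: 1.0 for k in keys}
    if weights:
        w.update({k: float(v) for k, v in weights.items() if k in w})
    best: tuple[float, str, Entry] | None = None
    for e in sub:
        num = 0.0
        wsum = 0.0
        for k in keys:
            if k not in e.morphology:
                continue
            _, sd = stats[k]
            d = (float(query[k]) - e.morphology[k]) / sd
            num += w[k] * d * d
            wsum += w[k]
        if wsum == 0.0:
            continue
        dist = np.sqrt(num / wsum)
        cand = (dist, e.id, e)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise SpecificationError("no entry shares parameters with the query")
    return best[2]
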