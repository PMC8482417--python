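"""Conversion between skeleton and mesh representations of phytomer organs.

Mesh to skeleton goes one of two ways.  Semantic meshes built from
digitizer rows carry vein labels and row indices, so the skeleton is read
off directly in acquisition order.  Unordered point clouds (scanner or
multi-view-stereo output) are skeletonized by iterative Laplacian
contraction over a k-nearest-neighbour graph: each iteration solves the
stacked least-squares system

    [ W_L L ] P' = [   0   ]
    [ W_H I ]      [ W_H P ]

with the contraction weight W_L geometrically increased each iteration, so
the cloud collapses onto a curve; contracted points are then ordered along
the chord between the two farthest-apart points and bin-averaged into an
ordered polyline.

Skeleton to mesh retrieves the leaf template with the smallest
morphological distance to the target skeleton (descriptors: arc length,
chord/arc ratio, base inclination), uniform-scales and rigidly aligns it so
vein endpoints match, resamples the target at the template's vein
arc-length fractions for one-to-one correspondence, and runs skeleton-driven
as-rigid-as-possible (ARAP) deformation with the vein vertices as hard
handles.  ARAP alternates per-vertex rotation fitting (SVD of the edge
covariance) with a global sparse cotangent-Laplacian solve; its rigidity
energy is non-increasing over iterations.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .core import SemanticMesh, Skeleton
from .errors import (
    ConnectivityError,
    FormatError,
    NumericalError,
    RetrievalError,
)
from .meshio import resample_at_fractions

__all__ = [
    "extract_skeleton_semantic",
    "extract_skeleton_laplacian",
    "laplacian_contraction",
    "arap_deform",
    "skeleton_to_mesh",
    "skeleton_descriptors",
]


# ---------------------------------------------------------------------------
# semantic skeleton extraction
# ---------------------------------------------------------------------------

def extract_skeleton_semantic(m: SemanticMesh) -> Skeleton:
    """Read the vein polyline off a labelled digitizer mesh.

    The skeleton is the vein-labelled vertices in acquisition-row order,
    followed by the tip vertex when present.
    """
    if m.labels is None or not np.any(m.labels == "vein"):
        raise FormatError(
            "mesh carries no vein labels; use extract_skeleton_laplacian for "
            "unlabelled geometry"
        )
    if m.row_index is None:
        raise FormatError("semantic extraction needs per-vertex row indices")
    vein = np.flatnonzero(m.labels == "vein")
    order = np.argsort(m.row_index[vein], kind="stable")
    pts = [m.vertices[i] for i in vein[order]]
    tip = np.flatnonzero(m.labels == "tip")
    if len(tip):
        pts.append(m.vertices[tip[0]])
    return Skeleton(np.asarray(pts), "leaf")


# ---------------------------------------------------------------------------
# Laplacian contraction
# ---------------------------------------------------------------------------

def _knn_graph(points: np.ndarray, k: int) -> sp.csr_matrix:
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)
    n = len(points)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].reshape(-1)
    A = sp.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)  # symmetrize
    ncomp, _ = sp.csgraph.connected_components(A, directed=False)
    if ncomp > 1:
        raise ConnectivityError(
            f"k-NN graph has {ncomp} components; increase k_neighbors"
        )
    return A


def _local_linearity(P: np.ndarray, k: int) -> float:
    """Median fraction of local PCA variance on the first axis.

    1.0 means every neighbourhood is perfectly one-dimensional, i.e. the
    cloud has collapsed onto a curve.
    """
    tree = cKDTree(P)
    _, idx = tree.query(P, k=min(k + 1, len(P)))
    nb = P[idx[:, 1:]]
    X = nb - nb.mean(axis=1, keepdims=True)
    C = np.einsum("nki,nkj->nij", X, X)
    ev = np.linalg.eigvalsh(C)
    tot = ev.sum(axis=1)
    tot[tot < 1e-18] = 1e-18
    return float(np.median(ev[:, 2] / tot))


def laplacian_contraction(
    points: np.ndarray,
    k_neighbors: int = 8,
    iterations: int = 10,
    w_l0: float = 1.0,
    s_l: float = 2.0,
    w_h: float = 1.0,
    max_amplification: float = 2048.0,
    linearity_stop: float = 0.95,
    return_history: bool = False,
):
    """Contract a point cloud toward its curve skeleton.

    Returns the contracted points, or ``(points, history)`` with the point
    positions after every iteration when ``return_history`` is set.  The
    contraction weight starts at ``w_l0`` and is multiplied by ``s_l``
    each iteration (capped at ``max_amplification`` times the initial
    value); attraction to the previous positions has constant weight
    ``w_h``.  ``iterations`` is an upper bound: iteration stops as soon as
    the cloud is locally one-dimensional (median neighbourhood PCA
    linearity above ``linearity_stop``) — amplifying further would start
    smoothing away genuine skeleton curvature.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(P)
    if n < 50:
        raise ConnectivityError("need at least 50 points for contraction")
    if k_neighbors < 4:
        raise ConnectivityError("k_neighbors must be >= 4")
    A = _knn_graph(P, k_neighbors)
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sp.diags(deg) - A
    wl = float(w_l0)
    wl_max = w_l0 * max_amplification
    history = []
    I = sp.identity(n, format="csr")
    for _ in range(iterations):
        M = (wl * wl) * (L.T @ L) + (w_h * w_h) * I
        try:
            solver = spla.factorized(M.tocsc())
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise NumericalError(f"contraction solve failed: {exc}") from exc
        P = np.column_stack([solver((w_h * w_h) * P[:, i]) for i in range(3)])
        history.append(P.copy())
        if _local_linearity(P, k_neighbors) > linearity_stop:
            break
        wl = min(wl * s_l, wl_max)
    if return_history:
        return P, history
    return P


def _order_along_chord(P: np.ndarray, n_nodes: int) -> np.ndarray:
    """Order contracted points along the chord between the two farthest
    points (two farthest-point passes) and bin-average into ``n_nodes``."""
    c = P.mean(axis=0)
    e1 = int(np.argmax(np.linalg.norm(P - c, axis=1)))
    e2 = int(np.argmax(np.linalg.norm(P - P[e1], axis=1)))
    axis = P[e2] - P[e1]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise NumericalError("contracted cloud collapsed to a point")
    t = (P - P[e1]) @ (axis / norm)
    bins = np.linspace(t.min(), t.max(), n_nodes + 1)
    nodes = []
    for i in range(n_nodes):
        if i < n_nodes - 1:
            mask = (t >= bins[i]) & (t < bins[i + 1])
        else:
            mask = (t >= bins[i]) & (t <= bins[i + 1])
        if mask.any():
            nodes.append(P[mask].mean(axis=0))
    nodes = np.asarray(nodes)
    keep = [0]
    for i in range(1, len(nodes)):
        if np.linalg.norm(nodes[i] - nodes[keep[-1]]) > 1e-9:
            keep.append(i)
    return nodes[keep]


def extract_skeleton_laplacian(
    points: np.ndarray,
    k_neighbors: int = 8,
    iterations: int = 10,
    seed: int = 0,
    n_nodes: int = 20,
    component_role: str = "leaf",
) -> Skeleton:
    """Skeletonize an unordered point cloud by Laplacian contraction.

    ``seed`` is accepted for interface uniformity with the other stochastic
    operations; the contraction itself is deterministic.
    """
    P = laplacian_contraction(points, k_neighbors=k_neighbors, iterations=iterations)
    nodes = _order_along_chord(P, n_nodes)
    if len(nodes) < 2:
        raise NumericalError("contraction produced fewer than 2 skeleton nodes")
    return Skeleton(nodes, component_role)


# ---------------------------------------------------------------------------
# ARAP deformation
# ---------------------------------------------------------------------------

def _cotangent_weights(verts: np.ndarray, faces: np.ndarray) -> sp.csr_matrix:
    """Symmetric cotangent edge weights, clamped at >= 0.

    Thin digitizer strips can produce slightly obtuse triangles whose
    negative cotangents destabilize the solve; clamping keeps the
    Laplacian positive semi-definite.
    """
    n = len(verts)
    Wd: dict[tuple[int, int], float] = {}
    for tri in faces:
        for c in range(3):
            i, j, k = tri[c], tri[(c + 1) % 3], tri[(c + 2) % 3]
            u = verts[i] - verts[k]
            v = verts[j] - verts[k]
            cross = np.linalg.norm(np.cross(u, v))
            cot = float(np.dot(u, v) / cross) if cross > 1e-12 else 0.0
            w = max(0.5 * cot, 0.0)
            Wd[(i, j)] = Wd.get((i, j), 0.0) + w
            Wd[(j, i)] = Wd.get((j, i), 0.0) + w
    if Wd:
        ij = np.array(list(Wd.keys()))
        vals = np.array(list(Wd.values()))
        W = sp.coo_matrix((vals, (ij[:, 0], ij[:, 1])), shape=(n, n)).tocsr()
    else:
        W = sp.csr_matrix((n, n))
    # vertices whose clamped one-ring lost all weight fall back to uniform
    row_sums = np.asarray(W.sum(axis=1)).ravel()
    dead = np.flatnonzero(row_sums < 1e-12)
    if len(dead):
        warnings.warn(
            f"{len(dead)} vertices have degenerate cotangent fans; using uniform weights there",
            stacklevel=2,
        )
        rows = faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1)
        cols = faces[:, [1, 0, 2, 1, 0, 2]].reshape(-1)
        Au = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
        W = W.tolil()
        for i in dead:
            for j in Au[i].nonzero()[1]:
                W[i, j] = 1.0
                W[j, i] = max(W[j, i], 1.0)
        W = W.tocsr()
    return W


def _fit_rotations(
    P: np.ndarray, Pp: np.ndarray, neighbors: list[np.ndarray], wlists: list[np.ndarray]
) -> np.ndarray:
    R = np.empty((len(P), 3, 3))
    for i, (nb, w) in enumerate(zip(neighbors, wlists)):
        E = (P[i] - P[nb]) * w[:, None]
        Ep = Pp[i] - Pp[nb]
        S = E.T @ Ep
        U, _, Vt = np.linalg.svd(S)
        Ri = Vt.T @ U.T
        if np.linalg.det(Ri) < 0:
            Vt2 = Vt.copy()
            Vt2[-1] *= -1
            Ri = Vt2.T @ U.T
        R[i] = Ri
    return R


def _arap_energy(
    P: np.ndarray, Pp: np.ndarray, R: np.ndarray, neighbors, wlists
) -> float:
    e = 0.0
    for i, (nb, w) in enumerate(zip(neighbors, wlists)):
        d = (Pp[i] - Pp[nb]) - (P[i] - P[nb]) @ R[i].T
        e += float(np.sum(w * np.sum(d * d, axis=1)))
    return e


def arap_deform(
    template: SemanticMesh,
    handle_indices: Sequence[int],
    targets: np.ndarray,
    max_iters: int = 50,
    tol: float | None = None,
    return_energy: bool = False,
):
    """As-rigid-as-possible deformation with hard handle constraints.

    Alternates the local step (per-vertex rotation by SVD of the weighted
    edge covariance) and the global step (sparse cotangent-Laplacian solve
    with handle rows eliminated) until the largest vertex move falls below
    ``tol`` (default 1e-6 times the bounding-box diagonal) or ``max_iters``
    is reached.  Returns the deformed mesh (labels and row indices
    preserved), plus the energy history when ``return_energy`` is set.
    """
    handles = np.asarray(handle_indices, dtype=int)
    targets = np.asarray(targets, dtype=float).reshape(-1, 3)
    if len(handles) != len(targets):
        raise ValueError("handles and targets must have equal length")
    if len(handles) < 3:
        raise ValueError("need at least 3 handles")
    if len(np.unique(handles)) != len(handles):
        raise ValueError("handle indices must be distinct")
    P = template.vertices
    n = len(P)
    diag = float(np.linalg.norm(P.max(axis=0) - P.min(axis=0)))
    if tol is None:
        tol = 1e-6 * max(diag, 1e-9)
    W = _cotangent_weights(P, template.faces)
    Lap = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W
    free = np.setdiff1d(np.arange(n), handles)
    neighbors = [W[i].nonzero()[1] for i in range(n)]
    wlists = [np.asarray(W[i, nb].todense()).ravel() for i, nb in enumerate(neighbors)]
    # initialize from the best-fit rigid motion of the handle set (Kabsch);
    # exact when the targets are a rigid motion of the handles
    hp = P[handles]
    mu_p = hp.mean(axis=0)
    mu_t = targets.mean(axis=0)
    U, _, Vt = np.linalg.svd((hp - mu_p).T @ (targets - mu_t))
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R0 = Vt.T @ D @ U.T
    Pp = (P - mu_p) @ R0.T + mu_t
    Pp[handles] = targets
    if len(free):
        Lff = Lap[np.ix_(free, free)].tocsc()
        Lfh = Lap[np.ix_(free, handles)].tocsr()
        try:
            solver = spla.factorized(Lff)
        except RuntimeError as exc:
            raise NumericalError(f"ARAP global solve failed: {exc}") from exc
    energies = []
    for _ in range(max_iters):
        R = _fit_rotations(P, Pp, neighbors, wlists)
        # rhs: b_i = sum_j w_ij/2 (R_i + R_j)(p_i - p_j)
        B = np.zeros((n, 3))
        for i, (nb, w) in enumerate(zip(neighbors, wlists)):
            rot = (R[i][None, :, :] + R[nb]) / 2.0
            d = (P[i] - P[nb])
            B[i] = np.einsum("e,eab,eb->a", w, rot, d)
        Pp_new = Pp.copy()
        if len(free):
            rhs = B[free] - Lfh @ Pp[handles]
            Pp_new[free] = np.column_stack([solver(rhs[:, c]) for c in range(3)])
        energies.append(_arap_energy(P, Pp_new, R, neighbors, wlists))
        move = float(np.abs(Pp_new - Pp).max())
        Pp = Pp_new
        if move < tol:
            break
    out = SemanticMesh(
        Pp,
        template.faces.copy(),
        None if template.labels is None else template.labels.copy(),
        None if template.row_index is None else template.row_index.copy(),
    )
    if return_energy:
        return out, energies
    return out


# ---------------------------------------------------------------------------
# skeleton -> mesh
# ---------------------------------------------------------------------------

def skeleton_descriptors(s: Skeleton) -> np.ndarray:
    """Morphological descriptor vector: arc length, chord/arc ratio,
    base inclination from vertical (degrees)."""
    arc = s.arc_length
    chord = float(np.linalg.norm(s.points[-1] - s.points[0]))
    d = s.points[1] - s.points[0]
    dn = np.linalg.norm(d)
    incl = float(np.rad2deg(np.arccos(np.clip(d[2] / dn, -1.0, 1.0)))) if dn > 0 else 0.0
    return np.array([arc, chord / max(arc, 1e-12), incl])


DESCRIPTOR_WEIGHTS = np.array([1.0, 1.0, 0.5])


def _leaf_candidates(db) -> list[tuple[str, object]]:
    out = []
    for e in sorted(db.entries, key=lambda e: e.id):
        if e.phytomer_type != "tassel":
            p = db.load_phytomer(e)
            if "leaf" in p.components:
                out.append((e.id, p))
    return out


def skeleton_to_mesh(
    target: Skeleton,
    db,
    max_iters: int = 50,
    weights: np.ndarray | None = None,
) -> SemanticMesh:
    """Convert a leaf skeleton to a semantic leaf mesh via the database.

    Pipeline: (i) retrieve the leaf template whose skeleton descriptors
    (z-score normalized over the candidates, weighted 1/1/0.5) are nearest
    the target's; (ii) uniform-scale and rigidly align the template so its
    vein endpoints match the target endpoints; (iii) resample the target at
    the template's vein arc-length fractions; (iv) deform with ARAP using
    the vein vertices as handles.  The result carries the template's
    labels.
    """
    cands = _leaf_candidates(db)
    if not cands:
        raise RetrievalError("database holds no leaf template")
    w = DESCRIPTOR_WEIGHTS if weights is None else np.asarray(weights, dtype=float)
    target_desc = skeleton_descriptors(target)
    descs = np.array([skeleton_descriptors(p.components["leaf"].skeleton) for _, p in cands])
    sd = descs.std(axis=0)
    sd[sd < 1e-12] = 1.0
    mu = descs.mean(axis=0)
    dz = (descs - mu) / sd
    tz = (target_desc - mu) / sd
    dist = np.sqrt(((dz - tz) ** 2 * w).sum(axis=1) / w.sum())
    best = int(np.lexsort((np.array([i for i, _ in cands]), dist))[0])
    _, tpl = cands[best]
    leaf = tpl.components["leaf"]
    mesh = leaf.mesh.copy()
    skel_pts = leaf.skeleton.points

    # (ii) uniform scale + rigid alignment of vein endpoints
    from .core import rotation_aligning
    from .meshio import _skeleton_vertex_indices

    t_chord = target.points[-1] - target.points[0]
    s_chord = skel_pts[-1] - skel_pts[0]
    scale = np.linalg.norm(t_chord) / max(np.linalg.norm(s_chord), 1e-12)
    base = skel_pts[0]
    R = rotation_aligning(s_chord, t_chord)
    mesh.vertices = (mesh.vertices - base) * scale @ R.T + target.points[0]
    skel_scaled = Skeleton((skel_pts - base) * scale @ R.T + target.points[0], "leaf")

    # (iii) resample the target at the template's vein arc fractions
    seg = np.linalg.norm(np.diff(skel_pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    fractions = cum / cum[-1]
    resampled = resample_at_fractions(target, fractions)

    # (iv) skeleton-driven ARAP with vein handles
    handles = _skeleton_vertex_indices(mesh, skel_scaled)
    return arap_deform(mesh, handles, resampled.points, max_iters=max_iters)
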