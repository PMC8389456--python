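"""Geometrical particle picking: derive, seed and filter particle poses.

Rather than template matching, initial subtomogram-averaging poses are
generated from annotated supporting geometries — spheres (vesicles, VLPs)
and arbitrary membrane surfaces — with each particle oriented so its
z-axis is the outward surface normal. Derived operations move poses to
related sites (:func:`subbox`), drop near-coincident picks
(:func:`exclude_duplicates`) and keep only particles sitting on a regular
lattice (:func:`neighbor_filter`).

Orientations are stored as rotation matrices in the "rotate reference onto
particle" sense throughout; Euler triplets appear only at the metadata
boundary (see :mod:`stakit.interop`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ParticlePoseSet",
    "SphereModel",
    "SurfaceAnnotation",
    "TriangleMesh",
    "sphere_from_annotation",
    "seed_sphere",
    "mesh_from_annotation",
    "seed_surface",
    "subbox",
    "exclude_duplicates",
    "neighbor_filter",
]


@dataclass
class ParticlePoseSet:
    """Positions, orientations, tomogram ids, tags and optional scores.

    ``orientations[i]`` rotates the reference frame onto particle ``i``;
    its third column is the particle z-axis in tomogram coordinates.
    """

    positions: np.ndarray                 # (n, 3) voxels
    orientations: np.ndarray              # (n, 3, 3)
    tomogram_ids: np.ndarray              # (n,) int
    tags: np.ndarray                      # (n,) int
    scores: Optional[np.ndarray] = None   # (n,) float

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3, 3)
        n = len(self.positions)
        self.tomogram_ids = np.broadcast_to(
            np.asarray(self.tomogram_ids, dtype=int), (n,)
        ).copy()
        self.tags = np.asarray(self.tags, dtype=int).reshape(n)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float).reshape(n)
        if len(self.orientations) != n:
            raise ValueError("positions and orientations length mismatch")
        for tomo in np.unique(self.tomogram_ids):
            t = self.tags[self.tomogram_ids == tomo]
            if len(np.unique(t)) != len(t):
                raise ValueError(f"duplicate tags within tomogram {tomo}")

    def __len__(self) -> int:
        return len(self.positions)

    def validate_orientations(self, tol: float = 1e-10) -> None:
        r = self.orientations
        defect = np.abs(np.transpose(r, (0, 2, 1)) @ r - np.eye(3)).max()
        det_defect = np.abs(np.linalg.det(r) - 1.0).max() if len(r) else 0.0
        if max(defect, det_defect) > tol:
            raise ValueError(f"orientations not orthonormal det+1 (defect {defect:.2e})")

    def z_vectors(self) -> np.ndarray:
        """(n, 3) particle z-axes in tomogram coordinates."""
        return self.orientations[:, :, 2]

    def select(self, mask: np.ndarray) -> "ParticlePoseSet":
        mask = np.asarray(mask)
        return ParticlePoseSet(
            self.positions[mask],
            self.orientations[mask],
            self.tomogram_ids[mask],
            self.tags[mask],
            None if self.scores is None else self.scores[mask],
        )


@dataclass
class SphereModel:
    """A vesicle-style annotation: a center point and one edge point."""

    center: np.ndarray
    edge_point: np.ndarray
    tomogram_id: int = 1

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.edge_point = np.asarray(self.edge_point, dtype=float).reshape(3)


@dataclass
class SurfaceAnnotation:
    """Points clicked on a surface, grouped by tomographic slice."""

    slices: list = field(default_factory=list)   # list of (m_i, 3) arrays
    tomogram_id: int = 1

    def __post_init__(self) -> None:
        self.slices = [np.atleast_2d(np.asarray(s, dtype=float)) for s in self.slices]

    @property
    def n_points(self) -> int:
        return sum(len(s) for s in self.slices)


@dataclass
class TriangleMesh:
    vertices: np.ndarray    # (v, 3)
    faces: np.ndarray       # (f, 3) int
    normals: np.ndarray     # (f, 3) unit, outward

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def sphere_from_annotation(model: SphereModel) -> tuple[np.ndarray, float]:
    """Center and radius from a center/edge-point annotation."""
    radius = float(np.linalg.norm(model.edge_point - model.center))
    if radius == 0.0:
        raise ValueError("sphere annotation has zero radius (edge point == center)")
    return model.center.copy(), radius


def _orientation_from_normal(normals: np.ndarray, inplane_rad: np.ndarray) -> np.ndarray:
    """Rotation matrices whose third column is the given unit normal.

    The in-plane angle rotates the tangent basis about the normal, so the
    particle x/y axes are seeded at the caller-provided angles.
    """
    n = normals
    # pick a helper axis well away from each normal
    helper = np.where(
        (np.abs(n[:, 2]) < 0.9)[:, None],
        np.broadcast_to([0.0, 0.0, 1.0], n.shape),
        np.broadcast_to([1.0, 0.0, 0.0], n.shape),
    )
    t1 = np.cross(helper, n)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(n, t1)
    ca, sa = np.cos(inplane_rad), np.sin(inplane_rad)
    x = ca[:, None] * t1 + sa[:, None] * t2
    y = -sa[:, None] * t1 + ca[:, None] * t2
    return np.stack([x, y, n], axis=2)


def seed_sphere(
    center,
    radius: float,
    spacing: float,
    rng,
    tomogram_id: int = 1,
) -> ParticlePoseSet:
    """Seed oversampled poses on a sphere with outward-normal orientations.

    Positions form a deterministic equal-area (Fibonacci) spiral lattice
    scaled so nearest-neighbour distances approximate ``spacing``; in-plane
    angles are drawn uniformly from ``rng`` (a seed or Generator).
    """
    if spacing <= 0 or radius <= 0:
        raise ValueError("spacing and radius must be positive")
    rng = np.random.default_rng(rng)
    center = np.asarray(center, dtype=float).reshape(3)
    count = int(round(4.0 * np.pi * radius**2 / spacing**2))
    if count < 2:
        warnings.warn(
            f"spacing {spacing} is large relative to sphere radius {radius}: "
            f"seeding {max(count, 1)} particle(s)",
            stacklevel=2,
        )
        count = max(count, 1)
    k = np.arange(count)
    z = 1.0 - 2.0 * (k + 0.5) / count
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    normals = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    positions = center + radius * normals
    inplane = rng.uniform(0.0, 2.0 * np.pi, count)
    orientations = _orientation_from_normal(normals, inplane)
    return ParticlePoseSet(
        positions, orientations, tomogram_id, np.arange(1, count + 1)
    )


def _order_ring(points: np.ndarray) -> np.ndarray:
    """Order slice points by polar angle about the slice centroid (xy)."""
    centroid = points.mean(axis=0)
    d = points - centroid
    if np.linalg.norm(d[:, :2], axis=1).max() < 1e-12:
        raise ValueError("degenerate slice annotation: points are collinear in z")
    ang = np.arctan2(d[:, 1], d[:, 0])
    return points[np.argsort(ang)]


def mesh_from_annotation(
    ann: SurfaceAnnotation, outside_point=None
) -> TriangleMesh:
    """Banded triangulation between consecutive annotated slices.

    Each slice's points are ordered by polar angle about the slice centroid
    and consecutive rings are zipped into a closed triangle band. Normals
    are oriented toward ``outside_point`` (default: away from the overall
    centroid). All annotated points become mesh vertices, so every input
    point lies exactly on the surface.
    """
    if len(ann.slices) < 2:
        raise ValueError(
            "surface annotation needs points on at least 2 distinct slices"
        )
    if ann.n_points < 3:
        raise ValueError("surface annotation needs at least 3 points")
    rings = []
    for s in ann.slices:
        if len(s) < 3:
            raise ValueError("each annotated slice needs at least 3 points")
        r = _order_ring(s)
        span = r.max(axis=0) - r.min(axis=0)
        if np.sort(span)[1] < 1e-12:   # at most one non-degenerate extent
            raise ValueError("degenerate slice annotation: points are collinear")
        rings.append(r)

    vertices = np.concatenate(rings, axis=0)
    offsets = np.cumsum([0] + [len(r) for r in rings])
    faces: list[tuple[int, int, int]] = []
    for a, b in zip(range(len(rings) - 1), range(1, len(rings))):
        ring_a, ring_b = rings[a], rings[b]
        na, nb = len(ring_a), len(ring_b)
        # align ring b's start to the vertex nearest ring a's start
        shift = int(np.argmin(np.linalg.norm(ring_b - ring_a[0], axis=1)))
        ia = offsets[a] + np.arange(na)
        ib = offsets[b] + (shift + np.arange(nb)) % nb
        # zip the two rings walking both in normalized arc position
        pa = pb = 0
        while pa < na or pb < nb:
            if pb == nb or (pa < na and (pa + 1) / na <= (pb + 1) / nb):
                faces.append((ia[pa % na], ia[(pa + 1) % na], ib[pb % nb]))
                pa += 1
            else:
                faces.append((ia[pa % na], ib[(pb + 1) % nb], ib[pb % nb]))
                pb += 1
    faces_arr = np.asarray(faces, dtype=int)

    v = vertices
    edge1 = v[faces_arr[:, 1]] - v[faces_arr[:, 0]]
    edge2 = v[faces_arr[:, 2]] - v[faces_arr[:, 0]]
    normals = np.cross(edge1, edge2)
    norms = np.linalg.norm(normals, axis=1)
    keep = norms > 1e-12
    faces_arr, normals, norms = faces_arr[keep], normals[keep], norms[keep]
    if len(faces_arr) == 0:
        raise ValueError("degenerate annotation: all faces have zero area")
    normals /= norms[:, None]

    centroids = v[faces_arr].mean(axis=1)
    if outside_point is None:
        outward = centroids - v.mean(axis=0)
    else:
        outward = np.asarray(outside_point, dtype=float) - centroids
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    faces_arr[flip] = faces_arr[flip][:, ::-1]
    normals[flip] *= -1.0
    return TriangleMesh(vertices, faces_arr, normals)


def seed_surface(
    mesh: TriangleMesh,
    spacing: float,
    rng,
    tomogram_id: int = 1,
) -> ParticlePoseSet:
    """Seed poses on mesh faces at ~one particle per ``spacing**2`` area.

    The per-face particle count is allocated deterministically by largest
    remainder; positions within a face and in-plane angles come from
    ``rng``. Each particle's z-axis is its face's outward normal.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(rng)
    areas = mesh.face_areas()
    total_area = areas.sum()
    if total_area <= 0:
        raise ValueError("mesh has zero area")
    n_total = max(1, int(round(total_area / spacing**2)))
    quota = areas / total_area * n_total
    counts = np.floor(quota).astype(int)
    remainder = n_total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:remainder]] += 1

    positions, normals = [], []
    for f, c in enumerate(counts):
        if c == 0:
            continue
        tri = mesh.vertices[mesh.faces[f]]
        u = rng.random((c, 2))
        over = u.sum(axis=1) > 1.0
        u[over] = 1.0 - u[over]
        pts = tri[0] + u[:, :1] * (tri[1] - tri[0]) + u[:, 1:] * (tri[2] - tri[0])
        positions.append(pts)
        normals.append(np.repeat(mesh.normals[f][None], c, axis=0))
    positions = np.concatenate(positions, axis=0)
    normals = np.concatenate(normals, axis=0)
    inplane = rng.uniform(0.0, 2.0 * np.pi, len(positions))
    orientations = _orientation_from_normal(normals, inplane)
    return ParticlePoseSet(
        positions, orientations, tomogram_id, np.arange(1, len(positions) + 1)
    )


def subbox(
    parents: ParticlePoseSet,
    offsets,
    rotations=None,
) -> ParticlePoseSet:
    """Derive child poses at fixed offsets/rotations in each parent's frame.

    ``child_position = parent_position + R_parent @ offset`` and
    ``child_orientation = R_parent @ relative_rotation``. Several
    (offset, rotation) pairs may be given at once; the result is the
    parent x pair cross product in parent-major order.
    """
    offsets = np.atleast_2d(np.asarray(offsets, dtype=float))
    k = len(offsets)
    if rotations is None:
        rotations = np.repeat(np.eye(3)[None], k, axis=0)
    else:
        rotations = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
        if len(rotations) == 1 and k > 1:
            rotations = np.repeat(rotations, k, axis=0)
    if len(rotations) != k:
        raise ValueError("offsets and rotations length mismatch")
    defect = np.abs(np.transpose(rotations, (0, 2, 1)) @ rotations - np.eye(3)).max()
    if defect > 1e-8 or np.abs(np.linalg.det(rotations) - 1.0).max() > 1e-8:
        raise ValueError("relative rotations must be orthonormal with det +1")

    rp = parents.orientations                            # (n, 3, 3)
    child_pos = (
        parents.positions[:, None, :] + np.einsum("nij,kj->nki", rp, offsets)
    ).reshape(-1, 3)
    child_rot = np.einsum("nij,kjl->nkil", rp, rotations).reshape(-1, 3, 3)
    n, kk = len(parents), k
    tomo = np.repeat(parents.tomogram_ids, kk)
    scores = None if parents.scores is None else np.repeat(parents.scores, kk)
    return ParticlePoseSet(
        child_pos, child_rot, tomo, np.arange(1, n * kk + 1), scores
    )


def exclude_duplicates(poses: ParticlePoseSet, min_distance: float) -> ParticlePoseSet:
    """Greedy per-tomogram duplicate removal.

    Particles are visited by descending score (ties: lower tag first) and
    kept unless a previously kept particle of the same tomogram lies
    strictly closer than ``min_distance``.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    n = len(poses)
    if n == 0 or min_distance == 0:
        return poses.select(np.ones(n, dtype=bool))
    scores = poses.scores if poses.scores is not None else np.zeros(n)
    keep = np.zeros(n, dtype=bool)
    for tomo in np.unique(poses.tomogram_ids):
        idx = np.nonzero(poses.tomogram_ids == tomo)[0]
        order = idx[np.lexsort((poses.tags[idx], -scores[idx]))]
        pos = poses.positions[order]
        tree = cKDTree(pos)
        neighbours = tree.query_ball_point(pos, r=min_distance)
        kept_local = np.zeros(len(order), dtype=bool)
        for rank in range(len(order)):
            conflict = any(
                kept_local[j] and np.linalg.norm(pos[rank] - pos[j]) < min_distance
                for j in neighbours[rank]
                if j != rank
            )
            kept_local[rank] = not conflict
        keep[order[kept_local]] = True
    return poses.select(keep)


def neighbor_filter(
    poses: ParticlePoseSet,
    expected_distance: float,
    tolerance: float = 0.2,
    min_neighbors: int = 3,
) -> ParticlePoseSet:
    """Keep particles with enough neighbours at the lattice distance.

    A neighbour counts when it shares the tomogram and its distance lies in
    ``expected_distance * [1 - tolerance, 1 + tolerance]``. Counts are
    taken on the input set in a single pass (removing a particle never
    cascades into removing its neighbours).
    """
    if min_neighbors < 0:
        raise ValueError("min_neighbors must be >= 0")
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    if min_neighbors == 0 or len(poses) == 0:
        return poses.select(np.ones(len(poses), dtype=bool))
    lo = expected_distance * (1.0 - tolerance)
    hi = expected_distance * (1.0 + tolerance)
    keep = np.zeros(len(poses), dtype=bool)
    for tomo in np.unique(poses.tomogram_ids):
        idx = np.nonzero(poses.tomogram_ids == tomo)[0]
        pos = poses.positions[idx]
        tree = cKDTree(pos)
        dist = tree.sparse_distance_matrix(tree, max_distance=hi, output_type="coo_matrix")
        in_band = (dist.data >= lo) & (dist.row != dist.col)
        counts = np.bincount(dist.row[in_band], minlength=len(idx))
        keep[idx[counts >= min_neighbors]] = True
    return poses.select(keep)
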