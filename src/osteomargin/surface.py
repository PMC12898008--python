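"""Closed-surface reconstruction and osteotomy-plane clearance.

The dangerous region's boundary point cloud is turned into a watertight
triangulated surface by Delaunay tetrahedralization followed by alpha-shape
style peeling: boundary tetrahedra whose circumradius exceeds a threshold are
discarded, subject to never losing a point, never disconnecting the kept
complex, and keeping the boundary a single closed 2-manifold.  A *shrink*
knob in [0, 1] interpolates the threshold between the convex hull (0) and the
tightest feasible boundary (1).

Plane clearance answers the planning question directly: is a planned planar
cut entirely outside the dangerous region, and by how many millimetres?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay
from scipy.spatial import QhullError

from .errors import DegenerateGeometryError
from .region import DangerousRegion

__all__ = ["TriangulatedSurface", "Plane", "reconstruct_surface", "plane_clearance"]


@dataclass
class TriangulatedSurface:
    """Closed triangle mesh in world millimetres.

    Invariants: watertight (every edge shared by exactly two faces),
    consistently wound with outward normals, no degenerate faces.
    """

    vertices: np.ndarray = field(repr=False)
    faces: np.ndarray = field(repr=False)
    shrink: float = 1.0

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edge_counts(self) -> np.ndarray:
        """Number of incident faces per undirected edge."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return counts

    @property
    def is_watertight(self) -> bool:
        return bool((self.edge_counts() == 2).all())

    @property
    def area(self) -> float:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    @property
    def volume(self) -> float:
        """Enclosed volume by the divergence theorem (outward orientation)."""
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def winding_number(self, points: np.ndarray) -> np.ndarray:
        """Generalized winding number of query points (~1 inside, ~0 outside)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tri = self.vertices[self.faces]  # (f, 3, 3)
        total = np.zeros(len(points))
        chunk = max(1, int(2e6 // max(len(tri), 1)))
        for s in range(0, len(points), chunk):
            p = points[s : s + chunk]
            a = tri[None, :, 0] - p[:, None]
            b = tri[None, :, 1] - p[:, None]
            c = tri[None, :, 2] - p[:, None]
            la = np.linalg.norm(a, axis=-1)
            lb = np.linalg.norm(b, axis=-1)
            lc = np.linalg.norm(c, axis=-1)
            num = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
            den = (
                la * lb * lc
                + np.einsum("pfi,pfi->pf", a, b) * lc
                + np.einsum("pfi,pfi->pf", b, c) * la
                + np.einsum("pfi,pfi->pf", a, c) * lb
            )
            total[s : s + chunk] = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
        return total

    def encloses(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        """True per point if inside the surface or within ``tol`` of a vertex."""
        from scipy.spatial import cKDTree

        points = np.atleast_2d(np.asarray(points, dtype=float))
        on_vertex = cKDTree(self.vertices).query(points)[0] <= tol
        inside = np.zeros(len(points), dtype=bool)
        if (~on_vertex).any():
            inside[~on_vertex] = self.winding_number(points[~on_vertex]) > 0.5
        return on_vertex | inside


@dataclass(frozen=True)
class Plane:
    """An osteotomy plane: a point on the plane and a unit normal.

    Convention: the dangerous region must lie in the ``-normal`` half-space;
    the ``+normal`` side is the safe (retained) side.
    """

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    name: str = "plane"

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "point", tuple(float(x) for x in self.point))
        object.__setattr__(self, "normal", tuple(n / norm))


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron; inf for (near-)degenerate ones."""
    a = points[simplices[:, 0]]
    rel = points[simplices[:, 1:]] - a[:, None, :]  # (n, 3, 3)
    rhs = 0.5 * np.einsum("nij,nij->ni", rel, rel)
    det = np.linalg.det(rel)
    scale = np.abs(rel).max(axis=(1, 2))
    ok = np.abs(det) > 1e-12 * np.maximum(scale, 1.0) ** 3
    radii = np.full(len(simplices), np.inf)
    if ok.any():
        centers = np.linalg.solve(rel[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def _boundary_faces(tri: Delaunay, kept: np.ndarray) -> np.ndarray:
    """Boundary faces (unoriented) of the kept tetrahedra."""
    faces = []
    simplices = tri.simplices
    neighbors = tri.neighbors
    kept_idx = np.nonzero(kept)[0]
    for opp in range(4):  # face opposite local vertex `opp`
        nb = neighbors[kept_idx, opp]
        on_boundary = (nb == -1) | ~kept[nb]
        tets = kept_idx[on_boundary]
        if len(tets) == 0:
            continue
        cols = [c for c in range(4) if c != opp]
        faces.append(simplices[np.ix_(tets, cols)])
    return np.vstack(faces) if faces else np.empty((0, 3), dtype=int)


def _orient_faces(faces: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Wind an edge-manifold closed face set consistently and outward.

    Winding is propagated combinatorially across shared edges (robust to the
    exactly-degenerate tetrahedra qhull emits for lattice point clouds, where
    geometric per-tet orientation is ill-defined), then the global sign is
    fixed so the enclosed volume is positive.
    """
    n = len(faces)
    edge_key = {}
    adj: list[list[tuple[int, bool]]] = [[] for _ in range(n)]
    for fi in range(n):
        f = faces[fi]
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            forward = a < b
            if key in edge_key:
                fj, fwd_j = edge_key.pop(key)
                # same traversal direction across a shared edge => one flip
                adj[fi].append((fj, forward == fwd_j))
                adj[fj].append((fi, forward == fwd_j))
            else:
                edge_key[key] = (fi, forward)
    flip = np.zeros(n, dtype=bool)
    seen = np.zeros(n, dtype=bool)
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        while stack:
            fi = stack.pop()
            for fj, same_dir in adj[fi]:
                if not seen[fj]:
                    seen[fj] = True
                    flip[fj] = flip[fi] ^ same_dir
                    stack.append(fj)
    out = faces.copy()
    out[flip] = out[flip][:, [0, 2, 1]]
    a, b, c = vertices[out[:, 0]], vertices[out[:, 1]], vertices[out[:, 2]]
    signed_volume = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    if signed_volume < 0:
        out = out[:, [0, 2, 1]]
    return out


def _boundary_is_valid(faces: np.ndarray) -> bool:
    """Boundary must be a single, edge-manifold, closed surface."""
    if len(faces) < 4:
        return False
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, inv, counts = np.unique(edges, axis=0, return_inverse=True, return_counts=True)
    if (counts != 2).any():
        return False
    # single surface component: faces sharing an edge are adjacent
    face_ids = np.repeat(np.arange(len(faces)), 3)
    order = np.argsort(inv, kind="stable")
    pairs = face_ids[order].reshape(-1, 2)  # each edge touches exactly 2 faces
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(len(faces), len(faces))
    )
    n_comp, _ = connected_components(graph, directed=False)
    return n_comp == 1


def _covers_all_points(tri: Delaunay, kept: np.ndarray, n_points: int) -> bool:
    return len(np.unique(tri.simplices[kept])) == n_points


def _single_tet_component(tri: Delaunay, kept: np.ndarray) -> bool:
    kept_idx = np.nonzero(kept)[0]
    if len(kept_idx) == 0:
        return False
    remap = np.full(len(tri.simplices), -1)
    remap[kept_idx] = np.arange(len(kept_idx))
    nb = tri.neighbors[kept_idx]
    src = np.repeat(np.arange(len(kept_idx)), 4)
    dst = nb.ravel()
    ok = (dst != -1) & kept[np.maximum(dst, 0)]
    graph = sparse.coo_matrix(
        (np.ones(ok.sum()), (src[ok], remap[dst[ok]])),
        shape=(len(kept_idx), len(kept_idx)),
    )
    n_comp, _ = connected_components(graph, directed=False)
    return n_comp == 1


def _feasible(tri: Delaunay, kept: np.ndarray, n_points: int) -> bool:
    return (
        _covers_all_points(tri, kept, n_points)
        and _single_tet_component(tri, kept)
        and _boundary_is_valid(_boundary_faces(tri, kept))
    )


def reconstruct_surface(points: np.ndarray, shrink: float = 1.0) -> TriangulatedSurface:
    """Reconstruct a closed surface enclosing a point cloud.

    ``shrink=0`` returns the convex hull; ``shrink=1`` peels Delaunay
    tetrahedra in descending circumradius as far as feasibility allows (all
    points kept, one component, watertight single boundary).  Intermediate
    values interpolate the circumradius threshold.  Thresholding is
    tie-inclusive, so degenerate configurations (e.g. cospherical points with
    one shared circumsphere) fall back to the convex hull.

    Raises :class:`DegenerateGeometryError` for fewer than four unique points
    or a coplanar cloud.
    """
    if not 0.0 <= shrink <= 1.0:
        raise ValueError(f"shrink must lie in [0, 1], got {shrink}")
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 3), axis=0)
    if len(pts) < 4:
        raise DegenerateGeometryError(f"need >= 4 unique points, got {len(pts)}")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point cloud: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("point cloud is coplanar")
    # points qhull merged into hull facets (precision) are enclosed by
    # construction; coverage is over the points used as vertices
    vertex_ids = np.unique(tri.simplices)
    is_vertex = np.zeros(len(pts), dtype=bool)
    is_vertex[vertex_ids] = True
    n_points = len(vertex_ids)
    radii = _circumradii(pts, tri.simplices)
    levels = np.unique(radii)  # ascending candidate thresholds

    # critical level: smallest threshold whose complex covers all points and
    # is a single face-connected component (found by one incremental pass)
    order = np.argsort(radii, kind="stable")
    uf = _UnionFind(len(tri.simplices))
    added = np.zeros(len(tri.simplices), dtype=bool)
    seen_pts = np.zeros(len(pts), dtype=bool)
    comps = 0
    covered = 0
    crit_level_idx = len(levels) - 1
    pos = 0
    for li, level in enumerate(levels):
        while pos < len(order) and radii[order[pos]] <= level:
            t = order[pos]
            pos += 1
            added[t] = True
            comps += 1
            for v in tri.simplices[t]:
                if not seen_pts[v]:
                    seen_pts[v] = True
                    covered += 1
            for nb in tri.neighbors[t]:
                if nb != -1 and added[nb] and uf.union(t, nb):
                    comps -= 1
        if covered == n_points and comps == 1:
            crit_level_idx = li
            break

    # interpolate threshold between critical level (shrink 1) and hull (0)
    target = crit_level_idx + int(round((1.0 - shrink) * (len(levels) - 1 - crit_level_idx)))

    def feasible_at(level_idx: int) -> bool:
        return _feasible(tri, radii <= levels[level_idx], n_points)

    # the hull (last level) is always feasible; find the smallest feasible
    # level >= target by doubling out, then bisecting the bracket
    if not feasible_at(target):
        lo, step = target, 1
        while True:
            hi = min(target + step, len(levels) - 1)
            if feasible_at(hi):
                break
            if hi == len(levels) - 1:
                raise DegenerateGeometryError("no feasible enclosing surface found")
            lo, step = hi, step * 2
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if feasible_at(mid):
                hi = mid
            else:
                lo = mid
        target = hi
    kept = radii <= levels[target]

    faces = _orient_faces(_boundary_faces(tri, kept), pts)
    used = np.unique(faces)
    remap = np.full(len(pts), -1, dtype=int)
    remap[used] = np.arange(len(used))
    return TriangulatedSurface(pts[used], remap[faces], shrink=shrink)


def plane_clearance(region: DangerousRegion, plane: Plane) -> float:
    """Signed clearance (mm) of an osteotomy plane with respect to a region.

    Positive: the entire region lies on the tumor side (``-normal``) of the
    plane, clearing it by the returned distance.  Negative: the plane cuts
    into the region by that depth.  A plane is classified *safe* iff its
    clearance is >= 0.
    """
    pts = region.boundary_points
    if pts is None or len(pts) == 0:
        pts = region.dense_mask.foreground_centers()
    if len(pts) == 0:
        raise ValueError("region is empty")
    signed = (pts - np.asarray(plane.point)) @ np.asarray(plane.normal)
    return float(-signed.max())


def is_safe(clearance_mm: float) -> bool:
    return clearance_mm >= 0.0
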