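"""Triangulated surface meshes and per-vertex scalar maps.

The registration domain is a sphere; anatomical quantities (smoothing,
vertex-voxel distances) live on a mid-thickness surface that shares the
sphere's vertex indexing.  This module provides the mesh/map containers,
icosphere construction, great-circle neighbourhoods, barycentric point
location and resampling on the sphere, and geodesic Gaussian smoothing.

Conventions
-----------
* Vertex indexing is 0-based everywhere, including on-disk formats.
* A map value of NaN and ``valid_mask == False`` are the same statement;
  the containers keep the two views consistent.
* All coordinates are in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .exceptions import ArgumentError, ResourceError, UnsupportedOperationError

logger = logging.getLogger(__name__)

#: Hard cap on icosphere size; protects against runaway subdivision levels.
MAX_ICOSPHERE_VERTICES = 3_000_000

SPHERE = "sphere"
MIDTHICKNESS = "midthickness"


@dataclass
class Mesh:
    """Triangulated surface: ``vertices`` (n, 3) mm, ``faces`` (m, 3) indices.

    ``kind`` is ``"sphere"`` (registration domain; ``radius`` set) or
    ``"midthickness"`` (anatomical surface; ``radius`` is None).
    """

    vertices: np.ndarray
    faces: np.ndarray
    kind: str = SPHERE
    radius: float | None = None
    name: str = "mesh"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ArgumentError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ArgumentError("faces must be (m, 3)")
        if self.kind == SPHERE and self.radius is None:
            self.radius = float(np.linalg.norm(self.vertices, axis=1).mean())

    # -- basic properties -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @cached_property
    def unit_vertices(self) -> np.ndarray:
        """Vertex directions (unit vectors); only meaningful for spheres."""
        norms = np.linalg.norm(self.vertices, axis=1, keepdims=True)
        return self.vertices / norms

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, each row sorted, (n_edges, 2)."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def vertex_faces(self) -> list[np.ndarray]:
        """For each vertex, the indices of its incident faces."""
        order = np.argsort(self.faces.ravel(), kind="stable")
        flat = self.faces.ravel()[order]
        face_of = order // 3
        bounds = np.searchsorted(flat, np.arange(self.n_vertices + 1))
        return [face_of[bounds[i] : bounds[i + 1]] for i in range(self.n_vertices)]

    @cached_property
    def vertex_edges(self) -> list[np.ndarray]:
        """For each vertex, the indices (into ``edges``) of its incident edges."""
        e = self.edges
        order = np.argsort(e.ravel(), kind="stable")
        flat = e.ravel()[order]
        edge_of = order // 2
        bounds = np.searchsorted(flat, np.arange(self.n_vertices + 1))
        return [edge_of[bounds[i] : bounds[i + 1]] for i in range(self.n_vertices)]

    @cached_property
    def kdtree(self) -> cKDTree:
        return cKDTree(self.vertices)

    @cached_property
    def mean_edge_length(self) -> float:
        a, b = self.edges[:, 0], self.edges[:, 1]
        return float(np.linalg.norm(self.vertices[a] - self.vertices[b], axis=1).mean())

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise ``ArgumentError`` on failure."""
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            raise ArgumentError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ArgumentError("degenerate face repeats a vertex")
        if self.kind == SPHERE:
            norms = np.linalg.norm(self.vertices, axis=1)
            if not np.allclose(norms, self.radius, rtol=1e-6, atol=0):
                raise ArgumentError("sphere vertices are not on the stated radius")
        areas = triangle_areas(self.vertices, self.faces)
        if np.any(areas <= 0):
            raise ArgumentError("mesh contains zero-area faces")
        n_edges = self.edges.shape[0]
        rows = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        cols = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        g = coo_matrix(
            (np.ones(2 * n_edges), (rows, cols)), shape=(self.n_vertices,) * 2
        )
        n_comp, _ = connected_components(g, directed=False)
        if n_comp != 1:
            raise ArgumentError(f"mesh has {n_comp} connected components")

    def scaled_to(self, radius: float) -> np.ndarray:
        """Vertex positions re-projected onto a sphere of ``radius``."""
        return self.unit_vertices * radius


@dataclass
class SurfaceMap:
    """Per-vertex scalar field on a :class:`Mesh`.

    ``values`` holds NaN at invalid vertices; ``valid_mask`` is the boolean
    view of the same information.
    """

    values: np.ndarray
    mesh: Mesh
    name: str = "map"
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).copy()
        if self.values.shape != (self.mesh.n_vertices,):
            raise ArgumentError(
                f"map has {self.values.shape[0]} values for a mesh with "
                f"{self.mesh.n_vertices} vertices"
            )
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool).copy()
            self.valid_mask &= np.isfinite(self.values)
        self.values[~self.valid_mask] = np.nan

    def copy(self, values: np.ndarray | None = None, name: str | None = None) -> "SurfaceMap":
        return SurfaceMap(
            values=self.values if values is None else values,
            mesh=self.mesh,
            name=self.name if name is None else name,
            valid_mask=None if values is not None else self.valid_mask,
        )

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


# ---------------------------------------------------------------------------
# icosphere construction
# ---------------------------------------------------------------------------


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    # enforce outward orientation (positive triple product) on every face
    det = np.einsum("ij,ij->i", np.cross(v[f[:, 0]], v[f[:, 1]]), v[f[:, 2]])
    flip = det < 0
    f[flip] = f[flip][:, [0, 2, 1]]
    return v, f


def build_icosphere(subdivision_level: int, radius: float, kind: str = SPHERE,
                    name: str | None = None) -> Mesh:
    """Icosahedron subdivided ``subdivision_level`` times, projected to ``radius``.

    Vertex count is ``10 * 4**level + 2``.  Faces are consistently oriented
    outward (positive scalar triple product).
    """
    if subdivision_level < 0:
        raise ArgumentError("subdivision_level must be >= 0")
    if radius <= 0:
        raise ArgumentError("radius must be positive")
    n_expected = 10 * 4**subdivision_level + 2
    if n_expected > MAX_ICOSPHERE_VERTICES:
        raise ResourceError(
            f"icosphere level {subdivision_level} would have {n_expected} vertices "
            f"(cap {MAX_ICOSPHERE_VERTICES})"
        )
    verts, faces = _icosahedron()
    for _ in range(subdivision_level):
        verts, faces = _subdivide(verts, faces)
    mesh = Mesh(
        vertices=verts * radius,
        faces=faces,
        kind=kind,
        radius=radius if kind == SPHERE else None,
        name=name or f"icosphere{subdivision_level}",
    )
    assert mesh.n_vertices == n_expected
    return mesh


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cache: dict[tuple[int, int], int] = {}
    new_verts = [v for v in verts]

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key not in cache:
            m = new_verts[i] + new_verts[j]
            m /= np.linalg.norm(m)
            cache[key] = len(new_verts)
            new_verts.append(m)
        return cache[key]

    new_faces = np.empty((4 * faces.shape[0], 3), dtype=np.int64)
    for k, (a, b, c) in enumerate(faces):
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces[4 * k: 4 * k + 4] = [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.asarray(new_verts), new_faces


# ---------------------------------------------------------------------------
# great-circle geometry
# ---------------------------------------------------------------------------


def angles_to(mesh: Mesh, direction: np.ndarray) -> np.ndarray:
    """Great-circle angle (radians) from each vertex to a unit ``direction``."""
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    return np.arccos(np.clip(mesh.unit_vertices @ d, -1.0, 1.0))


def geodesic_neighborhood(mesh: Mesh, center: int, angular_radius: float) -> np.ndarray:
    """Vertices within ``angular_radius`` degrees of great-circle angle of ``center``.

    Defined on spheres only; always contains ``center``.
    """
    if mesh.kind != SPHERE:
        raise UnsupportedOperationError(
            "geodesic_neighborhood is defined on the sphere only"
        )
    if not 0 < angular_radius <= 180:
        raise ArgumentError("angular_radius must be in (0, 180] degrees")
    units = mesh.unit_vertices
    ang = np.degrees(np.arccos(np.clip(units @ units[center], -1.0, 1.0)))
    return np.flatnonzero(ang <= angular_radius)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis-handling overhead."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Planar (chord) triangle areas, one per face."""
    a, b, c = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    n = _cross(b - a, c - a)
    return 0.5 * np.sqrt(np.einsum("ij,ij->i", n, n))


def spherical_triangle_areas(positions: np.ndarray, faces: np.ndarray,
                             radius: float) -> np.ndarray:
    """Spherical triangle areas (solid angle x R^2) via Van Oosterom-Strackee.

    ``positions`` need not be exactly on the sphere; directions are used.
    These areas tessellate the full sphere exactly, which makes total-area
    conservation checks exact to rounding.
    """
    u = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    a, b, c = u[faces[:, 0]], u[faces[:, 1]], u[faces[:, 2]]
    num = np.einsum("ij,ij->i", np.cross(a, b), c)
    den = (
        1.0
        + np.einsum("ij,ij->i", a, b)
        + np.einsum("ij,ij->i", b, c)
        + np.einsum("ij,ij->i", c, a)
    )
    omega = 2.0 * np.arctan2(num, den)
    return omega * radius**2


def face_orientations(positions: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Signed triple product per face; positive = outward on the sphere."""
    u = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    return np.einsum(
        "ij,ij->i", np.cross(u[faces[:, 0]], u[faces[:, 1]]), u[faces[:, 2]]
    )


# ---------------------------------------------------------------------------
# spherical point location and barycentric resampling
# ---------------------------------------------------------------------------


class SphericalPointLocator:
    """Locates query directions in the faces of a (possibly warped) sphere mesh.

    ``positions`` defaults to the mesh's own vertices; passing warped vertex
    positions turns this into the interpolator of a deformed sphere, which is
    how registrations are applied and composed.
    """

    #: relative tolerance for accepting a barycentric coordinate as inside
    TOL = 1e-9

    def __init__(self, mesh: Mesh, positions: np.ndarray | None = None):
        self.mesh = mesh
        pos = mesh.vertices if positions is None else np.asarray(positions, float)
        self.units = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        self.tree = cKDTree(self.units)
        # padded incident-face table for vectorised candidate gathering
        vf = mesh.vertex_faces
        width = max(len(f) for f in vf)
        table = np.full((mesh.n_vertices, width), -1, dtype=np.int64)
        for i, f in enumerate(vf):
            table[i, : len(f)] = f
        self._vf_table = table

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Containing face and barycentric weights for each query point.

        Points are normalised to directions first, so any radius is accepted.
        Numerically homeless points snap to the nearest vertex (weight 1 on
        one corner) with a logged warning.
        """
        q = np.asarray(points, dtype=np.float64)
        squeeze = q.ndim == 1
        q = np.atleast_2d(q)
        q = q / np.linalg.norm(q, axis=1, keepdims=True)
        n = q.shape[0]
        face_idx = np.full(n, -1, dtype=np.int64)
        weights = np.zeros((n, 3))
        pending = np.arange(n)
        for k in (1, 8):
            if pending.size == 0:
                break
            kk = min(k, self.mesh.n_vertices)
            _, nn = self.tree.query(q[pending], k=kk)
            nn = nn.reshape(pending.size, kk)
            cand = self._vf_table[nn].reshape(pending.size, -1)
            fi, w = self._best_face(q[pending], cand)
            ok = fi >= 0
            face_idx[pending[ok]] = fi[ok]
            weights[pending[ok]] = w[ok]
            pending = pending[~ok]
        if pending.size:
            logger.warning(
                "%d point(s) not located in any face; snapping to nearest vertex",
                pending.size,
            )
            _, nn = self.tree.query(q[pending], k=1)
            for p, v in zip(pending, np.atleast_1d(nn)):
                faces = self._vf_table[v]
                f = faces[faces >= 0][0]
                face_idx[p] = f
                corner = np.flatnonzero(self.mesh.faces[f] == v)[0]
                weights[p, corner] = 1.0
        if squeeze:
            return face_idx[0], weights[0]
        return face_idx, weights

    def _best_face(self, q: np.ndarray, cand: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Among candidate faces pick the one whose barycentric minimum is
        largest; accept only if that minimum is >= -TOL.

        Barycentric coordinates of the central projection of q onto the
        face plane come from Cramer's rule with scalar triple products:
        w_A = q.(B x C), w_B = q.(C x A), w_C = q.(A x B).
        """
        n, m = cand.shape
        tri = self.mesh.faces[np.where(cand >= 0, cand, 0)]  # (n, m, 3)
        corners = self.units[tri]  # (n, m, 3 corners, 3)
        A, B, C = corners[:, :, 0], corners[:, :, 1], corners[:, :, 2]
        w = np.empty((n, m, 3))
        w[..., 0] = np.einsum("nj,nmj->nm", q, _cross(B, C))
        w[..., 1] = np.einsum("nj,nmj->nm", q, _cross(C, A))
        w[..., 2] = np.einsum("nj,nmj->nm", q, _cross(A, B))
        s = w.sum(axis=-1)
        valid = (cand >= 0) & (s > 1e-12)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = w / s[..., None]
        wmin = np.where(valid, w.min(axis=-1), -np.inf)
        best = np.argmax(wmin, axis=1)
        rows = np.arange(n)
        ok = wmin[rows, best] >= -self.TOL
        fi = np.where(ok, cand[rows, best], -1)
        wbest = np.clip(w[rows, best], 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            wbest = wbest / wbest.sum(axis=1, keepdims=True)
        wbest[~ok] = 0.0
        return fi, np.nan_to_num(wbest)

    def sample(self, values: np.ndarray, points: np.ndarray,
               propagate_invalid: bool = True) -> np.ndarray:
        """Barycentric interpolation of per-vertex ``values`` at ``points``.

        With ``propagate_invalid`` any contributing NaN corner makes the
        output NaN; otherwise NaN corners are treated as 0 with weight 0.
        """
        fi, w = self.locate(points)
        fi = np.atleast_1d(fi)
        w = np.atleast_2d(w)
        corner_vals = values[self.mesh.faces[fi]]  # (n, 3)
        bad = ~np.isfinite(corner_vals)
        if propagate_invalid:
            out = np.einsum("ij,ij->i", np.where(bad, 0.0, corner_vals), w)
            out[np.any(bad & (w > 1e-12), axis=1)] = np.nan
        else:
            ww = np.where(bad, 0.0, w)
            tot = ww.sum(axis=1)
            out = np.einsum("ij,ij->i", np.where(bad, 0.0, corner_vals), ww)
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.where(tot > 1e-12, out / tot, np.nan)
        return out


def barycentric_resample(source: Mesh, source_map: SurfaceMap,
                         target_points: np.ndarray,
                         locator: SphericalPointLocator | None = None) -> np.ndarray:
    """Sample ``source_map`` at arbitrary points on the source sphere."""
    if source.kind != SPHERE:
        raise UnsupportedOperationError("barycentric_resample requires a sphere mesh")
    if source_map.mesh is not source:
        raise ArgumentError("source_map does not live on the source mesh")
    loc = locator or SphericalPointLocator(source)
    return loc.sample(source_map.values, target_points)


# ---------------------------------------------------------------------------
# geodesic smoothing
# ---------------------------------------------------------------------------


def geodesic_smooth(mesh: Mesh, surface_map: SurfaceMap, sigma: float) -> SurfaceMap:
    """Gaussian smoothing over geodesic distance, truncated at 3*sigma.

    On spheres the distance is the exact great-circle arc; on mid-thickness
    meshes it is the Dijkstra distance over the edge graph with Euclidean
    edge lengths.  Weights are renormalised per vertex, and invalid vertices
    are excluded from numerator and denominator alike.
    """
    if sigma < 0:
        raise ArgumentError("sigma must be >= 0")
    if surface_map.mesh is not mesh:
        raise ArgumentError("map does not live on the given mesh")
    if sigma == 0:
        return surface_map.copy()
    dist = _truncated_distances(mesh, cutoff=3.0 * sigma)
    vals = surface_map.values
    valid = surface_map.valid_mask
    out = np.full(mesh.n_vertices, np.nan)
    for i in range(mesh.n_vertices):
        if not valid[i]:
            continue
        nbr, d = dist[i]
        keep = valid[nbr]
        nbr, d = nbr[keep], d[keep]
        w = np.exp(-0.5 * (d / sigma) ** 2)
        out[i] = np.dot(w, vals[nbr]) / w.sum()
    return surface_map.copy(values=out, name=f"{surface_map.name}_s{sigma:g}")


def _truncated_distances(mesh: Mesh, cutoff: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-vertex (neighbour indices, geodesic distances) within ``cutoff`` mm,
    cached on the mesh instance."""
    cache = getattr(mesh, "_dist_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(mesh, "_dist_cache", cache)
    key = round(float(cutoff), 9)
    if key not in cache:
        if mesh.kind == SPHERE:
            cache[key] = _sphere_distances(mesh, cutoff)
        else:
            cache[key] = _graph_distances(mesh, cutoff)
    return cache[key]


def smoothing_operator(mesh: Mesh, sigma: float):
    """Row-normalised truncated-Gaussian smoothing matrix (valid-everywhere
    case); useful for smoothing many noise fields on the same mesh.  Cached
    per (mesh, sigma)."""
    from scipy.sparse import csr_matrix

    cache = getattr(mesh, "_smooth_ops", None)
    if cache is None:
        cache = {}
        mesh._smooth_ops = cache
    key = round(float(sigma), 9)
    if key in cache:
        return cache[key]
    dist = _truncated_distances(mesh, cutoff=3.0 * sigma)
    counts = np.array([len(nbr) for nbr, _ in dist])
    rows = np.repeat(np.arange(mesh.n_vertices), counts)
    cols = np.concatenate([nbr for nbr, _ in dist])
    d = np.concatenate([dd for _, dd in dist])
    w = np.exp(-0.5 * (d / sigma) ** 2)
    sums = np.add.reduceat(w, np.concatenate([[0], np.cumsum(counts)[:-1]]))
    w = w / np.repeat(sums, counts)
    op = csr_matrix((w, (rows, cols)), shape=(mesh.n_vertices,) * 2)
    cache[key] = op
    return op


def _sphere_distances(mesh: Mesh, cutoff: float) -> list[tuple[np.ndarray, np.ndarray]]:
    R = float(mesh.radius)
    max_angle = min(cutoff / R, np.pi)
    chord = 2.0 * R * np.sin(max_angle / 2.0)
    pairs = mesh.kdtree.query_ball_tree(mesh.kdtree, r=chord * (1 + 1e-12))
    units = mesh.unit_vertices
    result = []
    for i, nbr in enumerate(pairs):
        nbr = np.asarray(nbr, dtype=np.int64)
        ang = np.arccos(np.clip(units[nbr] @ units[i], -1.0, 1.0))
        d = R * ang
        keep = d <= cutoff
        result.append((nbr[keep], d[keep]))
    return result


def _graph_distances(mesh: Mesh, cutoff: float) -> list[tuple[np.ndarray, np.ndarray]]:
    e = mesh.edges
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    g = coo_matrix(
        (lengths, (e[:, 0], e[:, 1])), shape=(mesh.n_vertices,) * 2
    ).tocsr()
    dmat = dijkstra(g, directed=False, limit=cutoff)
    result = []
    for i in range(mesh.n_vertices):
        nbr = np.flatnonzero(np.isfinite(dmat[i]))
        result.append((nbr, dmat[i, nbr]))
    return result
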