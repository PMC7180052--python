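"""From volumetric tractograms to cortical-surface tract maps.

A tract's volumetric streamline-visitation image is turned into a
per-vertex surface map by multiplying a distance-weighted vertex-by-voxel
connectivity matrix with the (waytotal-normalized) tractogram, masking out
regions where the projection is unreliable, smoothing on the mid-thickness
surface, and applying a monotone log transform that maps intensities to
[0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .exceptions import ArgumentError, StateError
from .mesh import Mesh, SurfaceMap, geodesic_smooth

logger = logging.getLogger(__name__)


@dataclass
class VolumeGrid:
    """A voxel grid: ``shape`` (3 ints) and a 4x4 voxel-to-mm ``affine``."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ArgumentError("grid shape must be three positive integers")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ArgumentError("affine must be an invertible 4x4 matrix")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_edge(self) -> float:
        """Representative voxel edge length (mm): cube root of voxel volume."""
        return float(abs(np.linalg.det(self.affine[:3, :3])) ** (1.0 / 3.0))

    def voxel_centers(self, flat_indices: np.ndarray | None = None) -> np.ndarray:
        """mm coordinates of voxel centers, for all voxels or a flat subset."""
        if flat_indices is None:
            flat_indices = np.arange(self.n_voxels)
        ijk = np.column_stack(np.unravel_index(flat_indices, self.shape))
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (hom @ self.affine.T)[:, :3]

    def matches(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class Tractogram:
    """Voxelwise streamline visitation values plus the waytotal count."""

    grid: VolumeGrid
    values: np.ndarray
    waytotal: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ArgumentError("tractogram values do not match the grid shape")
        if np.any(self.values < 0):
            raise ArgumentError("tractogram values must be nonnegative")

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(-1)


@dataclass
class VertexVoxelMatrix:
    """Sparse nonnegative connectivity between surface vertices and voxels."""

    matrix: sparse.csr_matrix
    mesh: Mesh
    grid: VolumeGrid
    weighted: bool = False

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        expected = (self.mesh.n_vertices, self.grid.n_voxels)
        if self.matrix.shape != expected:
            raise ArgumentError(
                f"matrix shape {self.matrix.shape} does not match "
                f"mesh x grid {expected}"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ArgumentError("connectivity entries must be nonnegative")


@dataclass
class TractMap:
    """A tract's cortical surface representation (a SurfaceMap with labels)."""

    surface_map: SurfaceMap
    tract_name: str = "tract"
    subject_id: str = "template"
    postprocessed: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.surface_map.values

    @property
    def valid_mask(self) -> np.ndarray:
        return self.surface_map.valid_mask

    @property
    def mesh(self) -> Mesh:
        return self.surface_map.mesh


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_by_waytotal(t: Tractogram) -> Tractogram:
    """Divide visitation counts by the tract's waytotal."""
    if t.normalized:
        raise StateError("tractogram is already normalized")
    if t.waytotal <= 0:
        raise ArgumentError("waytotal must be positive")
    return Tractogram(t.grid, t.values / t.waytotal, t.waytotal, normalized=True)


def distance_weight(m: VertexVoxelMatrix) -> VertexVoxelMatrix:
    """Divide each nonzero entry by the vertex-to-voxel Euclidean distance.

    Distances below half the voxel edge are clamped there, so vertices lying
    inside a voxel do not blow up the weighting.  The sparsity pattern is
    unchanged.
    """
    if m.weighted:
        raise ArgumentError("matrix is already distance-weighted")
    coo = m.matrix.tocoo()
    if coo.nnz == 0:
        return VertexVoxelMatrix(m.matrix.copy(), m.mesh, m.grid, weighted=True)
    centers = m.grid.voxel_centers(coo.col)
    d = np.linalg.norm(m.mesh.vertices[coo.row] - centers, axis=1)
    eps = 0.5 * m.grid.voxel_edge
    n_clamped = int((d < eps).sum())
    if n_clamped:
        logger.warning("%d vertex-voxel distance(s) below %.3g mm clamped", n_clamped, eps)
    d = np.maximum(d, eps)
    out = sparse.csr_matrix(
        (coo.data / d, (coo.row, coo.col)), shape=m.matrix.shape
    )
    return VertexVoxelMatrix(out, m.mesh, m.grid, weighted=True)


def average_matrices(ms: list[VertexVoxelMatrix]) -> VertexVoxelMatrix:
    """Elementwise mean of same-shaped connectivity matrices."""
    if not ms:
        raise ArgumentError("cannot average an empty list of matrices")
    flags = {m.weighted for m in ms}
    if len(flags) > 1:
        raise ArgumentError("cannot mix weighted and unweighted matrices")
    shape = ms[0].matrix.shape
    for m in ms[1:]:
        if m.matrix.shape != shape:
            raise ArgumentError("matrix dimensions differ")
    total = sum((m.matrix for m in ms[1:]), ms[0].matrix.copy())
    return VertexVoxelMatrix(
        total / len(ms), ms[0].mesh, ms[0].grid, weighted=flags.pop()
    )


def project_tractogram(m: VertexVoxelMatrix, t: Tractogram,
                       tract_name: str = "tract",
                       subject_id: str = "template") -> TractMap:
    """Raw tract map: sparse matrix-vector product of connectivity and
    normalized tractogram."""
    if not t.normalized:
        raise ArgumentError("tractogram must be waytotal-normalized first")
    if not m.grid.matches(t.grid):
        raise ArgumentError("tractogram grid does not match the matrix grid")
    vals = m.matrix @ t.flat
    return TractMap(
        SurfaceMap(vals, m.mesh, name=tract_name),
        tract_name=tract_name,
        subject_id=subject_id,
    )


def mask_regions(tract_map: TractMap, masks: list[SurfaceMap]) -> TractMap:
    """Invalidate vertices inside any of the given binary masks (medial wall,
    insula, ...); they are excluded from all downstream statistics."""
    sm = tract_map.surface_map
    valid = sm.valid_mask.copy()
    for mask in masks:
        if mask.mesh is not sm.mesh:
            raise ArgumentError("mask lives on a different mesh")
        valid &= ~(np.nan_to_num(mask.values) > 0.5)
    vals = sm.values.copy()
    vals[~valid] = np.nan
    return TractMap(
        SurfaceMap(vals, sm.mesh, name=sm.name),
        tract_name=tract_map.tract_name,
        subject_id=tract_map.subject_id,
        postprocessed=tract_map.postprocessed,
    )


def lognorm_transform(values: np.ndarray) -> np.ndarray:
    """Monotone log compression to [0, 1]:
    y = log(1 + x/eps) / log(1 + max(x)/eps), eps = max(x) * 1e-3.

    Maps 0 to 0 and the maximum to exactly 1, compresses the heavy right
    tail of tractography intensities, and preserves rank order.  All-zero
    input passes through unchanged.
    """
    finite = np.isfinite(values)
    if np.any(values[finite] < 0):
        raise ArgumentError("lognorm transform requires nonnegative values")
    top = values[finite].max(initial=0.0)
    if top <= 0:
        return values.copy()
    eps = top * 1e-3
    out = np.full_like(values, np.nan, dtype=float)
    out[finite] = np.log1p(values[finite] / eps) / np.log1p(top / eps)
    return out


def postprocess(tract_map: TractMap, sigma: float, mesh: Mesh | None = None) -> TractMap:
    """Geodesic smoothing followed by the lognorm transform.

    ``mesh`` may supply a mid-thickness surface sharing the vertex indexing
    of the map's mesh, on which the smoothing distances are taken; by
    default the map's own mesh is used.
    """
    if sigma < 0:
        raise ArgumentError("sigma must be >= 0")
    sm = tract_map.surface_map
    if np.any(sm.values[sm.valid_mask] < 0):
        raise ArgumentError("raw tract map has negative values")
    smooth_mesh = mesh if mesh is not None else sm.mesh
    if smooth_mesh is not sm.mesh:
        if smooth_mesh.n_vertices != sm.mesh.n_vertices:
            raise ArgumentError("smoothing mesh must share the vertex indexing")
        carrier = SurfaceMap(sm.values, smooth_mesh, name=sm.name)
        smoothed = geodesic_smooth(smooth_mesh, carrier, sigma).values
    else:
        smoothed = geodesic_smooth(sm.mesh, sm, sigma).values
    vals = lognorm_transform(smoothed)
    return TractMap(
        SurfaceMap(vals, sm.mesh, name=sm.name),
        tract_name=tract_map.tract_name,
        subject_id=tract_map.subject_id,
        postprocessed=True,
    )


def group_average(maps: list[TractMap]) -> TractMap:
    """Vertexwise mean over subjects, computed over valid vertices only."""
    if not maps:
        raise ArgumentError("cannot average an empty list of maps")
    mesh = maps[0].mesh
    tract = maps[0].tract_name
    for m in maps[1:]:
        if m.mesh is not mesh:
            raise ArgumentError("maps live on different meshes")
        if m.tract_name != tract:
            raise ArgumentError("maps belong to different tracts")
    stack = np.vstack([m.values for m in maps])
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(stack, axis=0)
    return TractMap(
        SurfaceMap(vals, mesh, name=tract),
        tract_name=tract,
        subject_id="group",
        postprocessed=all(m.postprocessed for m in maps),
    )
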