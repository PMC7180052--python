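"""Tractogram normalization, distance weighting, projection, postprocessing."""

import numpy as np
import pytest
from scipy import sparse

from tractshift.exceptions import ArgumentError, StateError
from tractshift.mesh import SurfaceMap, build_icosphere
from tractshift.tracts import (
    TractMap,
    Tractogram,
    VertexVoxelMatrix,
    VolumeGrid,
    average_matrices,
    distance_weight,
    group_average,
    lognorm_transform,
    mask_regions,
    normalize_by_waytotal,
    postprocess,
    project_tractogram,
)


@pytest.fixture()
def grid():
    # 10 mm isotropic voxels, origin at the corner
    affine = np.diag([10.0, 10.0, 10.0, 1.0])
    return VolumeGrid((4, 4, 4), affine)


def _tractogram(grid, values=None, waytotal=200.0):
    vals = np.zeros(grid.shape) if values is None else values
    return Tractogram(grid, vals, waytotal)


class TestNormalize:
    def test_divides_by_waytotal(self, grid):
        vals = np.zeros(grid.shape)
        vals[1, 2, 3] = 50.0
        out = normalize_by_waytotal(_tractogram(grid, vals, 200.0))
        assert out.values[1, 2, 3] == 0.25
        assert out.normalized

    def test_all_zero_passes(self, grid):
        out = normalize_by_waytotal(_tractogram(grid))
        assert not out.values.any()
        assert out.normalized

    def test_zero_waytotal_rejected(self, grid):
        with pytest.raises(ArgumentError):
            normalize_by_waytotal(_tractogram(grid, waytotal=0.0))

    def test_double_normalization_rejected(self, grid):
        once = normalize_by_waytotal(_tractogram(grid))
        with pytest.raises(StateError):
            normalize_by_waytotal(once)


class TestDistanceWeight:
    def test_hand_computed_entry(self):
        # one connectivity entry at a vertex-voxel distance of 3 mm, with
        # 4 mm voxels so the half-voxel clamp (2 mm) does not engage
        grid = VolumeGrid((4, 4, 4), np.diag([4.0, 4.0, 4.0, 1.0]))
        voxel = 0
        center = grid.voxel_centers(np.array([voxel]))[0]
        mesh = build_icosphere(2, 100.0)
        mesh.vertices[7] = center + np.array([3.0, 0.0, 0.0])
        mat = sparse.csr_matrix(
            ([6.0], ([7], [voxel])), shape=(mesh.n_vertices, grid.n_voxels)
        )
        out = distance_weight(VertexVoxelMatrix(mat, mesh, grid))
        assert out.matrix[7, voxel] == pytest.approx(2.0)
        assert out.weighted

    def test_zero_entries_stay_zero_and_pattern_preserved(self, grid, sphere2, rng):
        mat = sparse.random(
            sphere2.n_vertices, grid.n_voxels, density=0.02,
            random_state=np.random.RandomState(0), format="csr",
        )
        out = distance_weight(VertexVoxelMatrix(mat, sphere2, grid))
        assert np.array_equal(out.matrix.indices, mat.indices)
        assert np.array_equal(out.matrix.indptr, mat.indptr)

    def test_distance_clamped_at_half_voxel(self, grid):
        voxel = 0
        center = grid.voxel_centers(np.array([voxel]))[0]
        mesh = build_icosphere(2, 100.0)
        mesh.vertices[3] = center + np.array([1.0, 0.0, 0.0])  # inside the voxel
        mat = sparse.csr_matrix(
            ([6.0], ([3], [voxel])), shape=(mesh.n_vertices, grid.n_voxels)
        )
        out = distance_weight(VertexVoxelMatrix(mat, mesh, grid))
        assert out.matrix[3, voxel] == pytest.approx(6.0 / 5.0)  # eps = 5 mm

    def test_double_weighting_rejected(self, grid, sphere2):
        m = VertexVoxelMatrix(
            sparse.csr_matrix((sphere2.n_vertices, grid.n_voxels)), sphere2, grid,
            weighted=True,
        )
        with pytest.raises(ArgumentError):
            distance_weight(m)


class TestAverageMatrices:
    def test_single_matrix_is_itself(self, grid, sphere2):
        mat = sparse.csr_matrix(
            ([1.0], ([0], [0])), shape=(sphere2.n_vertices, grid.n_voxels)
        )
        m = VertexVoxelMatrix(mat, sphere2, grid, weighted=True)
        out = average_matrices([m])
        assert (out.matrix != mat).nnz == 0

    def test_elementwise_mean(self, grid, sphere2):
        shape = (sphere2.n_vertices, grid.n_voxels)
        m1 = VertexVoxelMatrix(
            sparse.csr_matrix(([2.0], ([5], [9])), shape=shape), sphere2, grid
        )
        m2 = VertexVoxelMatrix(
            sparse.csr_matrix(([4.0], ([5], [9])), shape=shape), sphere2, grid
        )
        out = average_matrices([m1, m2])
        assert out.matrix[5, 9] == pytest.approx(3.0)

    def test_mixed_weighted_flags_rejected(self, grid, sphere2):
        shape = (sphere2.n_vertices, grid.n_voxels)
        m1 = VertexVoxelMatrix(sparse.csr_matrix(shape), sphere2, grid, weighted=True)
        m2 = VertexVoxelMatrix(sparse.csr_matrix(shape), sphere2, grid, weighted=False)
        with pytest.raises(ArgumentError):
            average_matrices([m1, m2])
        with pytest.raises(ArgumentError):
            average_matrices([])


class TestProject:
    def test_hand_matrix_vector_product(self, sphere2):
        grid = VolumeGrid((3, 1, 1), np.diag([10.0, 10.0, 10.0, 1.0]))
        mat = np.zeros((sphere2.n_vertices, 3))
        mat[0] = [1.0, 0.0, 2.0]
        mat[1] = [0.0, 3.0, 0.0]
        m = VertexVoxelMatrix(sparse.csr_matrix(mat), sphere2, grid, weighted=True)
        t = Tractogram(grid, np.array([0.5, 1.0, 0.25]).reshape(3, 1, 1),
                       waytotal=1.0, normalized=True)
        out = project_tractogram(m, t)
        assert out.values[0] == pytest.approx(1.0)
        assert out.values[1] == pytest.approx(3.0)

    def test_one_hot_tractogram_reads_column(self, sphere2, rng):
        grid = VolumeGrid((2, 2, 2), np.diag([10.0, 10.0, 10.0, 1.0]))
        mat = sparse.random(
            sphere2.n_vertices, 8, density=0.3,
            random_state=np.random.RandomState(2), format="csr",
        )
        m = VertexVoxelMatrix(mat, sphere2, grid, weighted=True)
        one_hot = np.zeros(8)
        one_hot[3] = 1.0
        t = Tractogram(grid, one_hot.reshape(grid.shape), 1.0, normalized=True)
        out = project_tractogram(m, t)
        assert np.allclose(out.values, mat[:, 3].toarray().ravel())

    def test_linearity(self, sphere2, rng):
        grid = VolumeGrid((2, 2, 2), np.diag([10.0, 10.0, 10.0, 1.0]))
        mat = sparse.random(
            sphere2.n_vertices, 8, density=0.4,
            random_state=np.random.RandomState(3), format="csr",
        )
        m = VertexVoxelMatrix(mat, sphere2, grid, weighted=True)
        v1, v2 = rng.random(8), rng.random(8)
        def proj(v):
            t = Tractogram(grid, v.reshape(grid.shape), 1.0, normalized=True)
            return project_tractogram(m, t).values
        assert np.allclose(proj(v1 + v2), proj(v1) + proj(v2), atol=1e-12)

    def test_unnormalized_rejected(self, sphere2):
        grid = VolumeGrid((2, 2, 2), np.diag([10.0, 10.0, 10.0, 1.0]))
        m = VertexVoxelMatrix(
            sparse.csr_matrix((sphere2.n_vertices, 8)), sphere2, grid, weighted=True
        )
        t = Tractogram(grid, np.zeros(grid.shape), 10.0, normalized=False)
        with pytest.raises(ArgumentError):
            project_tractogram(m, t)


class TestMaskRegions:
    def _tract_map(self, mesh, rng):
        return TractMap(SurfaceMap(rng.random(mesh.n_vertices), mesh))

    def test_empty_mask_is_noop(self, sphere2, rng):
        tm = self._tract_map(sphere2, rng)
        out = mask_regions(tm, [SurfaceMap(np.zeros(sphere2.n_vertices), sphere2)])
        assert out.valid_mask.sum() == tm.valid_mask.sum()

    def test_full_mask_invalidates_all(self, sphere2, rng):
        tm = self._tract_map(sphere2, rng)
        out = mask_regions(tm, [SurfaceMap(np.ones(sphere2.n_vertices), sphere2)])
        assert out.valid_mask.sum() == 0

    def test_valid_count_drops_by_mask_size(self, sphere2, rng):
        tm = self._tract_map(sphere2, rng)
        mask = np.zeros(sphere2.n_vertices)
        mask[:17] = 1.0
        out = mask_regions(tm, [SurfaceMap(mask, sphere2)])
        assert out.valid_mask.sum() == tm.valid_mask.sum() - 17


class TestPostprocess:
    def test_all_zero_passes_through(self, sphere2):
        tm = TractMap(SurfaceMap(np.zeros(sphere2.n_vertices), sphere2))
        out = postprocess(tm, 4.0)
        assert not np.nan_to_num(out.values).any()

    def test_maximum_maps_to_one_and_range(self, sphere2, rng):
        tm = TractMap(SurfaceMap(rng.random(sphere2.n_vertices) * 7.3, sphere2))
        out = postprocess(tm, 0.0)
        assert out.values.max() == pytest.approx(1.0)
        assert out.values.min() >= 0.0
        assert out.postprocessed

    def test_monotone_rank_preserving(self, sphere2, rng):
        vals = rng.random(sphere2.n_vertices) * 5
        out = lognorm_transform(vals)
        order_in = np.argsort(vals)
        assert np.all(np.diff(out[order_in]) >= 0)

    def test_negative_values_rejected(self, sphere2):
        vals = -np.ones(sphere2.n_vertices)
        tm = TractMap(SurfaceMap(vals, sphere2))
        with pytest.raises(ArgumentError):
            postprocess(tm, 1.0)


class TestGroupAverage:
    def test_identical_maps_unchanged(self, sphere2, rng):
        m = TractMap(SurfaceMap(rng.random(sphere2.n_vertices), sphere2), "t", "a")
        out = group_average([m, TractMap(m.surface_map, "t", "b")])
        assert np.allclose(out.values, m.values)

    def test_vertexwise_mean(self, sphere2):
        v1 = np.full(sphere2.n_vertices, 0.2)
        v2 = np.full(sphere2.n_vertices, 0.6)
        out = group_average([
            TractMap(SurfaceMap(v1, sphere2), "t", "a"),
            TractMap(SurfaceMap(v2, sphere2), "t", "b"),
        ])
        assert np.allclose(out.values, 0.4)

    def test_valid_only_rule(self, sphere2):
        v1 = np.full(sphere2.n_vertices, 0.8)
        v1[0] = np.nan
        v2 = np.full(sphere2.n_vertices, 0.2)
        out = group_average([
            TractMap(SurfaceMap(v1, sphere2), "t", "a"),
            TractMap(SurfaceMap(v2, sphere2), "t", "b"),
        ])
        assert out.values[0] == pytest.approx(0.2)
        assert out.values[1] == pytest.approx(0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ArgumentError):
            group_average([])


class TestEndToEnd:
    def test_projected_map_concentrates_on_termination_patch(self):
        # streamlines terminating under a known patch: after the full chain
        # (normalize, weight, project, postprocess, threshold at the patch's
        # own coverage) at least 80% of suprathreshold vertices lie within
        # one smoothing kernel of the patch
        from tractshift.synth import TractSpec, make_grid, make_synthetic_tractography
        from tractshift.compare import binarize, coverage_threshold

        mesh = build_icosphere(3, 100.0)
        spec = TractSpec("demo", patch_center=(0.0, 0.0, 1.0), patch_radius=25.0)
        grid = make_grid(mesh, voxel_size=100.0 / 12.0)
        tractogram, matrix, _ = make_synthetic_tractography(mesh, grid, spec, seed=4)
        tract_map = postprocess(
            project_tractogram(
                average_matrices([distance_weight(matrix)]),
                normalize_by_waytotal(tractogram),
            ),
            sigma=4.0,
        )
        patch_fraction = (1 - np.cos(np.radians(spec.patch_radius))) / 2
        t = coverage_threshold(tract_map, patch_fraction)
        covered = np.flatnonzero(
            np.nan_to_num(binarize(tract_map, t).values) > 0.5
        )
        theta = np.degrees(
            np.arccos(np.clip(mesh.unit_vertices[covered] @ np.array([0, 0, 1.0]), -1, 1))
        )
        kernel_deg = np.degrees(3 * 4.0 / 100.0)  # one (3 sigma) kernel
        frac_near = np.mean(theta <= spec.patch_radius + kernel_deg)
        assert frac_near >= 0.8
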