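"""Synthetic-data generator: deformations, myelin maps, tract scenarios,
cohorts, tractography and the assembled study bundle."""

import numpy as np
import pytest

from tractshift.exceptions import ArgumentError, FoldingError
from tractshift.mesh import build_icosphere, spherical_triangle_areas
from tractshift.registration import distortion_map, geodesic_errors
from tractshift.synth import (
    DEFAULT_LANDMARKS,
    Hotspot,
    Landmark,
    NoiseSpec,
    ScenarioSpec,
    SpeciesSpec,
    TractSpec,
    _unit,
    make_cohort,
    make_deformation,
    make_grid,
    make_myelin_map,
    make_study,
    make_synthetic_tractography,
    make_tract_scenario,
)
from tractshift.tracts import normalize_by_waytotal


@pytest.fixture(scope="module")
def src():
    return build_icosphere(3, 50.0, name="src")


@pytest.fixture(scope="module")
def tgt():
    return build_icosphere(3, 100.0, name="tgt")


class TestDeformation:
    def test_empty_hotspots_is_identity(self, src, tgt):
        reg = make_deformation(src, tgt, ())
        expected = src.unit_vertices * tgt.radius
        assert np.allclose(reg.warped_positions, expected, atol=1e-12)

    def test_deterministic(self, src, tgt):
        hs = ScenarioSpec().hotspots
        r1 = make_deformation(src, tgt, hs)
        r2 = make_deformation(src, tgt, hs)
        assert np.array_equal(r1.warped_positions, r2.warped_positions)

    def test_fold_free_and_area_conserving(self, src, tgt):
        reg = make_deformation(src, tgt, ScenarioSpec().hotspots)
        assert reg.folded_faces().size == 0
        d = distortion_map(reg)
        a0 = spherical_triangle_areas(src.vertices, src.faces, src.radius)
        w = np.array([a0[src.vertex_faces[v]].sum() for v in range(src.n_vertices)])
        scale = (tgt.radius / src.radius) ** 2
        mean_ratio = np.sum(w * 2 ** d.values) / np.sum(w) / scale
        assert abs(mean_ratio - 1.0) < 1e-6

    def test_overlarge_magnitude_rejected(self):
        with pytest.raises(ArgumentError, match="fold"):
            Hotspot(center=(0, 0, 1), extent=30.0, magnitude=15.0)


class TestMyelinMap:
    def test_peak_at_bump_center(self, src):
        lm = (Landmark(center=(0.0, 0.0, 1.0), width=15.0, amplitude=1.0),)
        m, _ = make_myelin_map(src, lm, noise_sd=0.0)
        peak = int(np.argmax(m.values))
        assert np.allclose(_unit(src.vertices[peak]), [0, 0, 1], atol=1e-9)
        assert m.values.max() == pytest.approx(1.0)
        assert m.values.min() == pytest.approx(0.0)

    def test_linked_species_correlate_through_truth_warp(self, src, tgt):
        truth = make_deformation(src, tgt, ScenarioSpec().hotspots)
        wu = truth.warped_positions / np.linalg.norm(
            truth.warped_positions, axis=1, keepdims=True
        )
        m_src, _ = make_myelin_map(src, noise_sd=0.0, directions=wu)
        m_tgt, _ = make_myelin_map(tgt, noise_sd=0.0)
        pulled = truth.locator.sample(m_src.values, tgt.vertices,
                                      propagate_invalid=False)
        r = np.corrcoef(pulled, m_tgt.values)[0, 1]
        assert r > 0.95

    def test_seeded_determinism(self, src):
        m1, _ = make_myelin_map(src, noise_sd=0.05, seed=9)
        m2, _ = make_myelin_map(src, noise_sd=0.05, seed=9)
        assert np.array_equal(m1.values, m2.values)

    def test_roi_masks_only_for_sharp_landmarks(self, src):
        _, rois = make_myelin_map(src, DEFAULT_LANDMARKS, noise_sd=0.0)
        assert len(rois) == sum(lm.roi for lm in DEFAULT_LANDMARKS) == 3
        for roi in rois:
            assert set(np.unique(np.nan_to_num(roi.values))) <= {0.0, 1.0}
            assert roi.values.sum() > 0

    def test_duplicate_centers_rejected(self, src):
        lm = (Landmark(center=(0, 0, 1)), Landmark(center=(0, 0, 1)))
        with pytest.raises(ArgumentError):
            make_myelin_map(src, lm)


class TestTractScenario:
    def _truth(self, src, tgt):
        return make_deformation(src, tgt, ScenarioSpec().hotspots)

    def test_relocation_target_equals_warped_source_support(self, src, tgt):
        truth = self._truth(src, tgt)
        spec = TractSpec("t", patch_center=(0.9, 0.1, 0.6))
        src_map, tgt_map, labels = make_tract_scenario(src, tgt, truth, spec, 2.0, 4.0)
        assert labels["scenario"] == "relocation"
        # transport the source support through the truth warp; it must agree
        # with the target support up to one smoothing kernel of boundary
        moved = truth.locator.sample(
            (src_map.values >= 0.5).astype(float), tgt.vertices,
            propagate_invalid=False,
        )
        moved_support = np.nan_to_num(moved) >= 0.5
        tgt_support = np.nan_to_num(tgt_map.values) >= 0.5
        # one 3-sigma kernel plus one inter-vertex spacing (the 0.5-level
        # crossing cannot be located more precisely than the mesh resolves)
        boundary_tol = 3 * 4.0 + tgt.mean_edge_length
        if moved_support.sum():
            mismatched = np.flatnonzero(moved_support != tgt_support)
            if mismatched.size:
                inside = np.flatnonzero(tgt_support)
                units = tgt.unit_vertices
                d = tgt.radius * np.arccos(np.clip(
                    units[mismatched] @ units[inside].T, -1, 1
                )).min(axis=1)
                assert d.max() < boundary_tol

    def test_extension_target_strictly_contains_relocation(self, src, tgt):
        truth = self._truth(src, tgt)
        base = TractSpec("t", patch_center=(0.9, 0.1, 0.6))
        ext = TractSpec("t", patch_center=(0.9, 0.1, 0.6), scenario="extension",
                        extension_center=(-0.9, 0.1, 0.35))
        _, tgt_rel, _ = make_tract_scenario(src, tgt, truth, base, 2.0, 4.0)
        _, tgt_ext, labels = make_tract_scenario(src, tgt, truth, ext, 2.0, 4.0)
        rel_support = np.nan_to_num(tgt_rel.values) >= 0.5
        ext_support = np.nan_to_num(tgt_ext.values) >= 0.5
        assert labels["scenario"] == "extension"
        assert labels["extension_vertices"] > 0
        assert ext_support.sum() > rel_support.sum()
        assert (rel_support & ~ext_support).sum() == 0

    def test_overlapping_extension_rejected(self, src, tgt):
        truth = self._truth(src, tgt)
        bad = TractSpec("t", patch_center=(0.9, 0.1, 0.6), scenario="extension",
                        extension_center=(0.9, 0.1, 0.62))
        with pytest.raises(ArgumentError):
            make_tract_scenario(src, tgt, truth, bad, 2.0, 4.0)


class TestCohort:
    def _template(self, mesh):
        spec = TractSpec("t", patch_center=(0, 0, 1.0))
        truth = make_deformation(mesh, mesh, ())
        src_map, _, _ = make_tract_scenario(mesh, mesh, truth, spec, 2.0, 2.0)
        return src_map

    def test_zero_noise_copies_template(self, src):
        template = self._template(src)
        cohort = make_cohort(template, 3, NoiseSpec(0.0, 0.0), seed=1)
        for m in cohort:
            assert np.allclose(m.values, template.values)
        assert [m.subject_id for m in cohort] == ["sub00", "sub01", "sub02"]

    def test_default_cohort_sizes(self):
        spec = ScenarioSpec()
        assert spec.reference.n_subjects == 20
        assert all(sp.n_subjects == 5 for sp in spec.others)

    def test_cross_subject_sd_matches_configuration(self, src):
        template = self._template(src)
        sd = 0.05
        cohort = make_cohort(template, 20, NoiseSpec(sd, 0.0, 10.0), seed=2)
        stack = np.vstack([m.values for m in cohort])
        interior = (template.values > 0.15) & (template.values < 0.85)  # no clipping
        observed = stack[:, interior].std(axis=0, ddof=1).mean()
        assert abs(observed - sd) / sd < 0.2

    def test_n_subjects_validated(self, src):
        with pytest.raises(ArgumentError):
            make_cohort(self._template(src), 0, NoiseSpec(), seed=0)


class TestSyntheticTractography:
    def test_seeded_determinism(self, src):
        spec = TractSpec("t", patch_center=(0, 0, 1.0))
        grid = make_grid(src, voxel_size=5.0)
        t1, m1, w1 = make_synthetic_tractography(src, grid, spec, seed=5)
        t2, m2, w2 = make_synthetic_tractography(src, grid, spec, seed=5)
        assert np.array_equal(t1.values, t2.values)
        assert (m1.matrix != m2.matrix).nnz == 0
        assert w1 == w2

    def test_matrix_support_within_capture_radius(self, src):
        spec = TractSpec("t", patch_center=(0, 0, 1.0))
        grid = make_grid(src, voxel_size=5.0)
        rc = 7.0
        _, m, _ = make_synthetic_tractography(src, grid, spec, seed=5,
                                              capture_radius=rc)
        coo = m.matrix.tocoo()
        centers = grid.voxel_centers(coo.col)
        d = np.linalg.norm(src.vertices[coo.row] - centers, axis=1)
        assert d.max() <= rc

    def test_doubling_streamlines_preserves_normalized_map(self, src):
        spec = TractSpec("t", patch_center=(0, 0, 1.0))
        grid = make_grid(src, voxel_size=5.0)
        t1, _, w1 = make_synthetic_tractography(src, grid, spec, seed=5,
                                                n_streamlines=2000)
        t2, _, w2 = make_synthetic_tractography(src, grid, spec, seed=5,
                                                n_streamlines=4000)
        assert w2 == 2 * w1
        n1 = normalize_by_waytotal(t1)
        n2 = normalize_by_waytotal(t2)
        support = (n1.values > 0) | (n2.values > 0)
        # visitation frequencies converge at Monte-Carlo rate
        assert np.abs(n1.values - n2.values)[support].mean() < 0.01


class TestStudy:
    def test_structure_and_determinism(self):
        spec = ScenarioSpec(
            reference=SpeciesSpec("human", 3, 100.0, 3, 4.0),
            others=(SpeciesSpec("macaca", 2, 50.0, 2, 2.0),),
        )
        s1 = make_study(spec, seed=4)
        s2 = make_study(spec, seed=4)
        assert set(s1.others) == {"macaca"}
        assert len(s1.reference.cohorts["af_like"]) == 3
        assert len(s1.others["macaca"].cohorts["af_like"]) == 2
        for tract in s1.reference.cohorts:
            for a, b in zip(s1.reference.cohorts[tract], s2.reference.cohorts[tract]):
                assert np.array_equal(a.values, b.values)
        truth = s1.others["macaca"].truth
        assert truth.folded_faces().size == 0
        assert np.median(geodesic_errors(truth, truth)) == 0.0
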