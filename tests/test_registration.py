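"""Spherical registration: warp recovery, composition, distortion, QA maps."""

import numpy as np
import pytest

from tractshift.exceptions import ArgumentError, FoldingError
from tractshift.mesh import Mesh, SurfaceMap, build_icosphere, spherical_triangle_areas
from tractshift.registration import (
    Registration,
    RegistrationParams,
    apply_registration,
    compose,
    distortion_map,
    geodesic_errors,
    local_similarity_map,
    register_feature_maps,
    roi_initialize,
)
from tractshift.synth import (
    DEFAULT_LANDMARKS,
    ScenarioSpec,
    _unit,
    make_deformation,
    make_myelin_map,
)
from tractshift.compare import dice


def _rotation_matrix_z(deg):
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@pytest.fixture(scope="module")
def src():
    return build_icosphere(3, 50.0, name="src")


@pytest.fixture(scope="module")
def tgt():
    return build_icosphere(4, 100.0, name="tgt")


@pytest.fixture(scope="module")
def truth(src, tgt):
    return make_deformation(src, tgt, ScenarioSpec().hotspots)


@pytest.fixture(scope="module")
def linked_myelin(src, tgt, truth):
    """Myelin pair on a species pair linked by the ground-truth warp."""
    wu = truth.warped_positions / np.linalg.norm(
        truth.warped_positions, axis=1, keepdims=True
    )
    m_tgt, rois_tgt = make_myelin_map(tgt, noise_sd=0.02, seed=1)
    m_src, rois_src = make_myelin_map(src, noise_sd=0.02, seed=2, directions=wu)
    return m_src, m_tgt, rois_src, rois_tgt


class TestIdentityAndValidation:
    def test_identity_applies_as_noop(self, sphere2, rng):
        reg = Registration.identity(sphere2, sphere2)
        m = SurfaceMap(rng.random(sphere2.n_vertices), sphere2)
        out = apply_registration(reg, m)
        assert np.allclose(out.values, m.values, atol=1e-12)

    def test_constant_map_invariant_under_any_registration(self, src, tgt, truth):
        m = SurfaceMap(np.full(src.n_vertices, 0.42), src)
        out = apply_registration(truth, m)
        assert np.allclose(out.values, 0.42, atol=1e-12)

    def test_folded_warp_rejected(self, sphere2):
        warped = sphere2.vertices.copy()
        # swapping two adjacent vertices flips the orientation of their faces
        warped[[0, 1]] = warped[[1, 0]]
        reg = Registration(sphere2, sphere2, warped)
        with pytest.raises(FoldingError):
            reg.validate()


class TestApplyRegistration:
    def test_rotation_matches_analytic_field(self, tgt):
        # transporting f(v)=v_z through a rotation must equal the rotated field
        src_mesh = build_icosphere(3, 100.0, name="rot_src")
        R = _rotation_matrix_z(25.0)
        reg = Registration(src_mesh, tgt, src_mesh.vertices @ R.T)
        f = SurfaceMap(src_mesh.unit_vertices[:, 2], src_mesh)
        out = apply_registration(reg, f)
        expected = (tgt.unit_vertices @ R)[:, 2]  # R^-1 applied to targets
        assert np.abs(out.values - expected).max() < 5e-3


class TestCompose:
    def test_compose_with_identity(self, src, tgt, truth):
        ident_src = Registration.identity(src, src)
        left = compose(ident_src, truth)
        assert np.allclose(left.warped_positions, truth.warped_positions, atol=1e-9)
        ident_tgt = Registration.identity(tgt, tgt)
        right = compose(truth, ident_tgt)
        err = np.linalg.norm(right.warped_positions - truth.warped_positions, axis=1)
        assert err.max() < 2.0 * tgt.mean_edge_length  # interpolation tolerance

    def test_matches_sequential_application(self, rng):
        # applying compose(A, B) to a map equals applying A then B
        a_mesh = build_icosphere(3, 50.0)
        b_mesh = build_icosphere(3, 80.0)
        c_mesh = build_icosphere(3, 100.0)
        A = make_deformation(a_mesh, b_mesh, ScenarioSpec().hotspots[:1])
        B = make_deformation(b_mesh, c_mesh, ScenarioSpec().hotspots[1:])
        AB = compose(A, B)
        m = SurfaceMap(np.sin(1.5 * a_mesh.unit_vertices[:, 0]), a_mesh)
        direct = apply_registration(AB, m)
        stepwise = apply_registration(B, apply_registration(A, m))
        ok = direct.valid_mask & stepwise.valid_mask
        diff = np.abs(direct.values[ok] - stepwise.values[ok])
        # the two routes are algebraically equal up to barycentric
        # interpolation of the warp field and of the map; on a level-3 mesh
        # that is second-order in the ~8 degree edge length.  The bulk of the
        # sphere must agree to interpolation accuracy and no vertex may
        # deviate at the scale of the field's variation per edge (~0.2).
        assert np.quantile(diff, 0.95) < 1e-2
        assert diff.max() < 5e-2

    def test_mesh_mismatch_rejected(self, src, tgt, truth):
        with pytest.raises(ArgumentError):
            compose(truth, truth)


class TestDistortionMap:
    def test_identity_is_zero(self, sphere2):
        reg = Registration.identity(sphere2, sphere2)
        d = distortion_map(reg)
        assert np.abs(d.values).max() < 1e-9

    def test_area_doubling_warp(self):
        # polar warp with cos(theta') = 2 cos(theta) - 1 doubles the local
        # area exactly for theta < 60 deg; beyond, a linear ramp closes the
        # sphere.  Check log2 ratio = 1 near the pole.
        mesh = build_icosphere(4, 1.0)
        u = mesh.unit_vertices
        ct = np.clip(u[:, 2], -1, 1)
        theta = np.arccos(ct)
        lim = np.pi / 3
        theta_new = np.where(
            theta <= lim,
            np.arccos(np.clip(2 * np.cos(theta) - 1, -1, 1)),
            np.pi / 2 + (theta - lim) * (np.pi / 2) / (np.pi - lim),
        )
        phi = np.arctan2(u[:, 1], u[:, 0])
        warped = np.column_stack(
            [
                np.sin(theta_new) * np.cos(phi),
                np.sin(theta_new) * np.sin(phi),
                np.cos(theta_new),
            ]
        )
        reg = Registration(mesh, mesh, warped)
        d = distortion_map(reg)
        near_pole = theta < np.radians(50.0)
        vals = d.values[near_pole]
        assert np.abs(vals - 1.0).max() < 0.05

    def test_total_area_conserved(self, src, truth):
        # any fold-free sphere-to-sphere warp conserves total area, so the
        # area-weighted mean of 2^distortion is exactly 1 (equal radii after
        # rescaling the ratio by (R_src/R_tgt)^2)
        d = distortion_map(truth)
        a0 = spherical_triangle_areas(src.vertices, src.faces, src.radius)
        w = np.array([a0[src.vertex_faces[v]].sum() for v in range(src.n_vertices)])
        scale = (truth.target_mesh.radius / src.radius) ** 2
        mean_ratio = np.sum(w * 2 ** d.values) / np.sum(w) / scale
        assert abs(mean_ratio - 1.0) < 1e-6


class TestLocalSimilarity:
    def test_self_correlation_is_one(self, sphere2, rng):
        a = SurfaceMap(rng.random(sphere2.n_vertices), sphere2)
        out = local_similarity_map(a, a.copy(), window=40.0)
        ok = out.valid_mask
        assert ok.any()
        assert np.allclose(out.values[ok], 1.0, atol=1e-9)

    def test_negated_map_is_minus_one(self, sphere2, rng):
        a = SurfaceMap(rng.random(sphere2.n_vertices), sphere2)
        b = a.copy(values=-a.values)
        out = local_similarity_map(a, b, window=40.0)
        ok = out.valid_mask
        assert np.allclose(out.values[ok], -1.0, atol=1e-9)

    def test_matches_dense_pearson(self, sphere2, rng):
        a = SurfaceMap(rng.random(sphere2.n_vertices), sphere2)
        b = SurfaceMap(rng.random(sphere2.n_vertices), sphere2)
        out = local_similarity_map(a, b, window=40.0)
        units = sphere2.unit_vertices
        for v in (0, 50, 161):
            nbr = np.flatnonzero(units @ units[v] >= np.cos(np.radians(40.0)))
            expected = np.corrcoef(a.values[nbr], b.values[nbr])[0, 1]
            assert abs(out.values[v] - expected) < 1e-10

    def test_mesh_mismatch(self, sphere2, sphere3, rng):
        a = SurfaceMap(rng.random(sphere2.n_vertices), sphere2)
        b = SurfaceMap(rng.random(sphere3.n_vertices), sphere3)
        with pytest.raises(ArgumentError):
            local_similarity_map(a, b)


class TestFeatureRegistration:
    def test_same_features_stay_near_identity(self, rng):
        mesh = build_icosphere(3, 100.0)
        m, _ = make_myelin_map(mesh, noise_sd=0.0, seed=5)
        reg = register_feature_maps(mesh, mesh, m, m.copy())
        disp = reg.displacement_angles() * mesh.radius
        assert disp.mean() < 0.02 * mesh.radius
        assert reg.folded_faces().size == 0

    def test_constant_feature_rejected(self, sphere2):
        const = SurfaceMap(np.ones(sphere2.n_vertices), sphere2)
        with pytest.raises(ArgumentError):
            register_feature_maps(sphere2, sphere2, const, const.copy())

    def test_huge_regularization_freezes_warp(self, src, tgt, linked_myelin):
        m_src, m_tgt, _, _ = linked_myelin
        params = RegistrationParams(levels=1, regularization_weight=1e6)
        reg = register_feature_maps(src, tgt, m_src, m_tgt, None, params)
        # only the isometric rotation stage may act; control-point moves all
        # cost distortion and are vetoed by the regularizer
        ctrl_spacing_mm = np.radians(31.7) * tgt.radius
        disp = reg.displacement_angles() * tgt.radius
        assert disp.max() <= ctrl_spacing_mm + 1e-6

    def test_recovers_known_deformation(self, src, tgt, truth):
        # target features are exactly the source features pulled through the
        # ground-truth warp (no measurement noise in this construction)
        wu = truth.warped_positions / np.linalg.norm(
            truth.warped_positions, axis=1, keepdims=True
        )
        m_tgt, _ = make_myelin_map(tgt, noise_sd=0.0, seed=1)
        m_src, _ = make_myelin_map(src, noise_sd=0.0, seed=2, directions=wu)
        reg = register_feature_maps(src, tgt, m_src, m_tgt)
        err = geodesic_errors(reg, truth)
        id_err = geodesic_errors(Registration.identity(src, tgt), truth)
        assert reg.folded_faces().size == 0
        assert err.mean() < 0.4 * id_err.mean()  # id_err == true displacement
        assert np.median(err) < np.median(id_err)
        hist = reg.objective_history
        assert all(b >= a - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_noisy_features_still_beat_identity(self, src, tgt, truth, linked_myelin):
        m_src, m_tgt, _, _ = linked_myelin  # noise_sd = 0.02 per map
        reg = register_feature_maps(src, tgt, m_src, m_tgt)
        err = geodesic_errors(reg, truth)
        id_err = geodesic_errors(Registration.identity(src, tgt), truth)
        assert np.median(err) < np.median(id_err)
        assert err.mean() < id_err.mean()

    def test_deterministic(self, src, tgt, linked_myelin):
        m_src, m_tgt, _, _ = linked_myelin
        params = RegistrationParams(levels=1)
        r1 = register_feature_maps(src, tgt, m_src, m_tgt, None, params)
        r2 = register_feature_maps(src, tgt, m_src, m_tgt, None, params)
        assert np.array_equal(r1.warped_positions, r2.warped_positions)


class TestRoiInitialize:
    def test_recovers_bulk_rotation(self, src, tgt):
        R = _rotation_matrix_z(20.0)
        truth_rot = Registration(src, tgt, (src.unit_vertices @ R.T) * tgt.radius)
        _, rois_src = make_myelin_map(src, noise_sd=0.0, seed=3)
        rois_tgt = []
        for i, lm in enumerate([l for l in DEFAULT_LANDMARKS if l.roi]):
            c = R @ _unit(lm.center)
            th = np.degrees(np.arccos(np.clip(tgt.unit_vertices @ c, -1, 1)))
            rois_tgt.append(
                SurfaceMap((th <= lm.width).astype(float), tgt, name=f"roi{i}")
            )
        reg = roi_initialize(src, tgt, rois_src, rois_tgt)
        err = geodesic_errors(reg, truth_rot)
        displacement = np.radians(20.0) * tgt.radius  # upper bound of true disp
        assert np.median(err) < 0.25 * displacement
        for rs, rt in zip(rois_src, rois_tgt):
            warped = apply_registration(reg, rs)
            wbin = SurfaceMap(
                (np.nan_to_num(warped.values) >= 0.5).astype(float), tgt
            )
            assert dice(wbin, rt) >= 0.8

    def test_coincident_rois_near_identity(self, src, tgt):
        _, rois_src = make_myelin_map(src, noise_sd=0.0, seed=4)
        _, rois_tgt = make_myelin_map(tgt, noise_sd=0.0, seed=5)
        reg = roi_initialize(src, tgt, rois_src, rois_tgt)
        disp = reg.displacement_angles() * tgt.radius
        assert disp.mean() < tgt.mean_edge_length

    def test_empty_roi_rejected(self, src, tgt):
        empty = SurfaceMap(np.zeros(src.n_vertices), src)
        good_t = SurfaceMap(np.ones(tgt.n_vertices), tgt)
        with pytest.raises(ArgumentError):
            roi_initialize(src, tgt, [empty], [good_t])
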