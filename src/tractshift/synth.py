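"""Ground-truthed synthetic inputs for the cross-species pipeline.

The generator emulates the statistical structure the analysis assumes:

* "species" spheres of differing mesh resolution and radius;
* myelin-like feature maps built from high-intensity angular-Gaussian
  landmarks (a motor-strip-like band end, an MT+-like hotspot, an
  occipital-pole-like bump) plus smooth noise, with landmark ROI masks;
* smooth, fold-free expansion deformations linking the species (the
  ground-truth registration);
* tract termination maps under two scenarios: *relocation* (the target
  species map is exactly the source map transported through the true
  deformation) and *extension* (an additional disjoint termination patch
  appears in the target species);
* synthetic tractography volumes and vertex-voxel matrices;
* noisy subject cohorts (reference species n=20, others n=5 by default).

Everything is bit-deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .exceptions import ArgumentError, FoldingError
from .mesh import (
    Mesh,
    SurfaceMap,
    build_icosphere,
    smoothing_operator,
)
from .registration import Registration
from .tracts import (
    Tractogram,
    TractMap,
    VertexVoxelMatrix,
    VolumeGrid,
    postprocess,
)

DEFAULT_N_HUMAN = 20
DEFAULT_N_OTHER = 5

#: icospheres are deterministic given (level, radius); sharing one instance
#: across studies also shares its cached geodesic-distance tables, which is
#: what makes repeated seeded study generation cheap
_MESH_CACHE: dict[tuple[int, float, str], Mesh] = {}


def cached_icosphere(level: int, radius: float, name: str = "") -> Mesh:
    key = (level, float(radius), name)
    if key not in _MESH_CACHE:
        _MESH_CACHE[key] = build_icosphere(level, radius, name=name or None)
    return _MESH_CACHE[key]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class Hotspot:
    """One radial expansion field: vertices within ``extent`` degrees of
    ``center`` move away from it, peaking at ``magnitude`` degrees of
    displacement half-way out."""

    center: tuple[float, float, float]
    extent: float = 60.0
    magnitude: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.extent < 90:
            raise ArgumentError("hotspot extent must be in (0, 90) degrees")
        if self.magnitude < 0:
            raise ArgumentError("hotspot magnitude must be >= 0")
        # monotone radial profile requires peak displacement < extent / pi
        if np.radians(self.magnitude) >= np.radians(self.extent) / np.pi:
            raise ArgumentError(
                "hotspot magnitude too large for its extent (would fold); "
                f"need magnitude < extent/pi = {self.extent / np.pi:.2f} deg"
            )


@dataclass
class Landmark:
    """An angular-Gaussian myelin landmark.

    ``roi`` marks sharp landmarks that also emit a binary ROI mask for the
    coarse registration stage.
    """

    center: tuple[float, float, float]
    width: float = 18.0  # degrees (Gaussian sigma)
    amplitude: float = 1.0
    roi: bool = True


@dataclass
class TractSpec:
    """A tract's termination geometry and its evolutionary scenario."""

    name: str
    patch_center: tuple[float, float, float]
    patch_radius: float = 25.0  # degrees
    falloff: float = 22.0  # degrees; decay scale of the smoothed indicator
    scenario: str = "relocation"
    extension_center: tuple[float, float, float] | None = None
    extension_radius: float = 20.0
    extension_amplitude: float = 0.9

    def __post_init__(self) -> None:
        if self.scenario not in ("relocation", "extension"):
            raise ArgumentError("scenario must be 'relocation' or 'extension'")
        if self.scenario == "extension" and self.extension_center is None:
            raise ArgumentError("extension scenario needs an extension_center")


@dataclass
class NoiseSpec:
    """Per-subject map noise: smooth additive + multiplicative perturbation."""

    additive_sd: float = 0.05
    multiplicative_sd: float = 0.10
    smoothness: float = 10.0  # degrees; angular scale of the noise fields


def _texture_landmarks() -> tuple[Landmark, ...]:
    """Fixed pseudo-random field of medium- and fine-scale myelin bumps.

    Real myelin maps are informative everywhere, not only at the handful of
    sharp landmarks: association cortex carries broad gradients and
    fine-grained areal texture.  Without that texture a feature-driven
    registration is underdetermined away from the sharp landmarks.
    """
    rng = np.random.default_rng(20231108)
    out = []
    for n, wlo, whi, alo, ahi in ((8, 25.0, 40.0, 0.2, 0.45),
                                  (30, 8.0, 15.0, 0.12, 0.3)):
        pts = rng.standard_normal((n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        for p in pts:
            out.append(
                Landmark(
                    center=tuple(p),
                    width=float(rng.uniform(wlo, whi)),
                    amplitude=float(rng.uniform(alo, ahi)),
                    roi=False,
                )
            )
    return tuple(out)


#: default landmarks: a motor-strip-like band end, an MT+-like hotspot and an
#: occipital-pole-like bump (the three sharp, high-myelin features that also
#: define the ROIs of the coarse registration stage), plus a fixed field of
#: broad and fine texture bumps standing in for the myelin structure of
#: association cortex
DEFAULT_LANDMARKS = (
    Landmark(center=(0.0, 0.3, 1.0), width=20.0, amplitude=1.0),
    Landmark(center=(1.0, 0.4, -0.2), width=12.0, amplitude=0.9),
    Landmark(center=(-0.6, -1.0, -0.3), width=15.0, amplitude=0.8),
) + _texture_landmarks()


@dataclass
class SpeciesSpec:
    name: str
    mesh_level: int
    radius: float
    n_subjects: int
    smoothing_sigma: float  # mm, tract map smoothing kernel
    #: fraction of the reference extension territory this species' own tract
    #: already reaches (0 = none); differing values across species create a
    #: species-by-tract interaction in the extension ratios
    extension_presence: float = 0.0
    #: scale applied to the scenario's expansion hotspots for this species
    deformation_scale: float = 1.0


@dataclass
class ScenarioSpec:
    """Full synthetic study description (defaults mirror the study design:
    reference cohort of 20, other-species cohorts of 5, two tracts of which
    one extends in the reference species)."""

    reference: SpeciesSpec = field(
        default_factory=lambda: SpeciesSpec("human", 4, 100.0, DEFAULT_N_HUMAN, 4.0)
    )
    others: tuple[SpeciesSpec, ...] = field(
        default_factory=lambda: (
            SpeciesSpec("macaca", 3, 50.0, DEFAULT_N_OTHER, 2.0,
                        extension_presence=0.0, deformation_scale=1.0),
            SpeciesSpec("pan", 3, 80.0, DEFAULT_N_OTHER, 3.0,
                        extension_presence=0.6, deformation_scale=0.75),
        )
    )
    landmarks: tuple[Landmark, ...] = DEFAULT_LANDMARKS
    hotspots: tuple[Hotspot, ...] = (
        Hotspot(center=(0.8, 0.8, 0.4), extent=80.0, magnitude=16.0),
        Hotspot(center=(-0.5, 0.6, -0.8), extent=70.0, magnitude=12.0),
        Hotspot(center=(0.1, -0.9, 0.2), extent=75.0, magnitude=10.0),
    )
    tracts: tuple[TractSpec, ...] = (
        TractSpec("mdlf_like", patch_center=(0.9, 0.1, 0.6), scenario="relocation"),
        TractSpec(
            "af_like",
            patch_center=(0.2, -0.9, 0.5),
            scenario="extension",
            extension_center=(-0.9, 0.1, 0.35),
            extension_radius=20.0,
        ),
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0


# ---------------------------------------------------------------------------
# deformations
# ---------------------------------------------------------------------------


def _deform_directions(units: np.ndarray, hotspots: tuple[Hotspot, ...]) -> np.ndarray:
    """Apply the superposed radial expansion fields to unit directions."""
    out = units.copy()
    for h in hotspots:
        c = _unit(h.center)
        theta = np.arccos(np.clip(out @ c, -1.0, 1.0))
        extent = np.radians(h.extent)
        amp = np.radians(h.magnitude)
        inside = (theta > 1e-9) & (theta < extent)
        if not np.any(inside):
            continue
        delta = amp * np.sin(np.pi * theta[inside] / extent)
        u = out[inside]
        axes = np.cross(np.broadcast_to(c, u.shape), u)
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        cosd = np.cos(delta)[:, None]
        sind = np.sin(delta)[:, None]
        dots = np.einsum("ij,ij->i", axes, u)[:, None]
        out[inside] = u * cosd + np.cross(axes, u) * sind + axes * dots * (1 - cosd)
    return out


def make_deformation(source: Mesh, target: Mesh,
                     hotspots: tuple[Hotspot, ...]) -> Registration:
    """Ground-truth registration: smooth fold-free warp of the source sphere
    onto the target sphere, built from radial expansion hotspots.

    Each hotspot pushes directions away from its center with a sinusoidal
    radial profile that vanishes at the center and at the hotspot rim, so
    each field is a diffeomorphism of the sphere; folding of the
    superposition is checked explicitly.
    """
    warped_units = _deform_directions(source.unit_vertices, hotspots)
    reg = Registration(
        source, target, warped_units * target.radius,
        provenance=["ground-truth"],
    )
    if reg.folded_faces().size:
        raise FoldingError(
            "deformation folds the mesh; reduce hotspot magnitudes"
        )
    return reg


# ---------------------------------------------------------------------------
# myelin maps and ROIs
# ---------------------------------------------------------------------------


def _bumps(units: np.ndarray, landmarks: tuple[Landmark, ...]) -> np.ndarray:
    total = np.zeros(units.shape[0])
    for lm in landmarks:
        theta = np.degrees(np.arccos(np.clip(units @ _unit(lm.center), -1.0, 1.0)))
        total += lm.amplitude * np.exp(-0.5 * (theta / lm.width) ** 2)
    return total


def smooth_noise(mesh: Mesh, sd: float, smoothness_deg: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise on the sphere, rescaled to the requested sd."""
    if sd == 0:
        return np.zeros(mesh.n_vertices)
    white = rng.standard_normal(mesh.n_vertices)
    sigma_mm = mesh.radius * np.radians(smoothness_deg)
    op = smoothing_operator(mesh, sigma_mm)
    smooth = op @ white
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def make_myelin_map(mesh: Mesh, landmarks: tuple[Landmark, ...] = DEFAULT_LANDMARKS,
                    noise_sd: float = 0.0, noise_smoothness: float = 10.0,
                    seed: int = 0,
                    directions: np.ndarray | None = None) -> tuple[SurfaceMap, list[SurfaceMap]]:
    """Myelin-like map (sum of landmark bumps + smooth noise, rescaled to
    [0, 1]) plus one binary ROI mask per landmark (the 1-sigma disc).

    ``directions`` lets the analytic landmark field be evaluated at warped
    vertex directions: passing a ground-truth warp's unit positions yields
    the species whose cortex is the *pre-expansion* version of the canonical
    field, which is how linked species pairs are generated.
    """
    centers = [tuple(np.round(_unit(lm.center), 12)) for lm in landmarks]
    if len(set(centers)) != len(centers):
        raise ArgumentError("landmark centers must be distinct")
    units = mesh.unit_vertices if directions is None else np.asarray(directions)
    vals = _bumps(units, landmarks)
    rng = np.random.default_rng(seed)
    vals = vals + smooth_noise(mesh, noise_sd, noise_smoothness, rng)
    lo, hi = vals.min(), vals.max()
    vals = (vals - lo) / (hi - lo) if hi > lo else vals * 0.0
    myelin = SurfaceMap(vals, mesh, name="myelin")
    rois = []
    for i, lm in enumerate(landmarks):
        if not lm.roi:
            continue
        theta = np.degrees(np.arccos(np.clip(units @ _unit(lm.center), -1.0, 1.0)))
        rois.append(
            SurfaceMap((theta <= lm.width).astype(float), mesh, name=f"roi{i}")
        )
    return myelin, rois


def transported_rois(truth: Registration, source_rois: list[SurfaceMap]) -> list[SurfaceMap]:
    """Target-mesh ROI masks: the source indicators carried through the
    ground-truth warp and re-binarised at 0.5."""
    out = []
    for roi in source_rois:
        vals = truth.locator.sample(
            roi.values, truth.target_mesh.vertices, propagate_invalid=False
        )
        out.append(
            SurfaceMap((np.nan_to_num(vals) >= 0.5).astype(float),
                       truth.target_mesh, name=roi.name)
        )
    return out


# ---------------------------------------------------------------------------
# tract scenarios
# ---------------------------------------------------------------------------


def _soft_patch(units: np.ndarray, center, radius_deg: float,
                falloff_deg: float, amplitude: float = 1.0) -> np.ndarray:
    """Smoothed indicator of a geodesic cap: 1 inside, Gaussian tail outside."""
    theta = np.degrees(np.arccos(np.clip(units @ _unit(center), -1.0, 1.0)))
    out = np.where(
        theta <= radius_deg,
        1.0,
        np.exp(-0.5 * ((theta - radius_deg) / falloff_deg) ** 2),
    )
    return amplitude * out


def make_tract_scenario(source: Mesh, target: Mesh, truth: Registration,
                        spec: TractSpec, source_sigma: float,
                        target_sigma: float,
                        source_extension_presence: float = 0.0
                        ) -> tuple[TractMap, TractMap, dict]:
    """Template tract maps for both species under the spec's scenario.

    The termination patch is specified in target (reference) space.  The
    source-species map is the smoothed patch indicator seen through the
    ground-truth warp (its patch is the pre-image of the target patch), so
    under the relocation scenario the target map is exactly the source map
    transported through the true deformation.  In the extension scenario the
    target species additionally has a disjoint termination patch the source
    species lacks.  Both maps are postprocessed (smoothed + lognorm) to
    [0, 1].
    """
    warped_units = truth.warped_positions / np.linalg.norm(
        truth.warped_positions, axis=1, keepdims=True
    )
    src_raw = _soft_patch(
        warped_units, spec.patch_center, spec.patch_radius, spec.falloff
    )
    tgt_raw = _soft_patch(
        target.unit_vertices, spec.patch_center, spec.patch_radius, spec.falloff
    )
    labels = {"tract": spec.name, "scenario": spec.scenario}
    if spec.scenario == "extension":
        ext = _soft_patch(
            target.unit_vertices, spec.extension_center, spec.extension_radius,
            spec.falloff, spec.extension_amplitude,
        )
        # disjointness is required of the patches proper (the caps where the
        # smoothed indicators are saturated), not of their Gaussian tails
        relocated_support = tgt_raw >= 0.9
        ext_support = ext >= 0.9 * spec.extension_amplitude
        if np.any(relocated_support & ext_support):
            raise ArgumentError(
                "extension patch overlaps the relocated termination zone"
            )
        tgt_raw = np.maximum(tgt_raw, ext)
        labels["extension_vertices"] = int(ext_support.sum())
        if source_extension_presence > 0:
            ext_src = _soft_patch(
                warped_units, spec.extension_center, spec.extension_radius,
                spec.falloff,
                spec.extension_amplitude * source_extension_presence,
            )
            src_raw = np.maximum(src_raw, ext_src)
    src_map = postprocess(
        TractMap(SurfaceMap(src_raw, source, name=spec.name), spec.name), source_sigma
    )
    tgt_map = postprocess(
        TractMap(SurfaceMap(tgt_raw, target, name=spec.name), spec.name), target_sigma
    )
    labels["source_support"] = int((src_raw >= 0.5).sum())
    labels["target_support"] = int((tgt_raw >= 0.5).sum())
    return src_map, tgt_map, labels


def make_cohort(template: TractMap, n_subjects: int, noise: NoiseSpec,
                seed: int, id_prefix: str = "sub") -> list[TractMap]:
    """Per-subject maps: template with smooth multiplicative and additive
    noise, re-clipped to [0, 1].  Subject ids are stable across runs."""
    if n_subjects < 1:
        raise ArgumentError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    mesh = template.mesh
    out = []
    for i in range(n_subjects):
        mult = smooth_noise(mesh, noise.multiplicative_sd, noise.smoothness, rng)
        add = smooth_noise(mesh, noise.additive_sd, noise.smoothness, rng)
        vals = np.clip(template.values * (1.0 + mult) + add, 0.0, 1.0)
        out.append(
            TractMap(
                SurfaceMap(vals, mesh, name=template.tract_name),
                tract_name=template.tract_name,
                subject_id=f"{id_prefix}{i:02d}",
                postprocessed=template.postprocessed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# synthetic tractography
# ---------------------------------------------------------------------------


def make_grid(mesh: Mesh, voxel_size: float) -> VolumeGrid:
    """Axis-aligned grid enclosing the mesh with a small margin."""
    lo = mesh.vertices.min(axis=0) - 2 * voxel_size
    hi = mesh.vertices.max(axis=0) + 2 * voxel_size
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel_size)) for i in range(3))
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo + voxel_size / 2.0
    return VolumeGrid(shape=shape, affine=affine)


def make_synthetic_tractography(mesh: Mesh, grid: VolumeGrid, spec: TractSpec,
                                seed: int = 0, n_streamlines: int = 2000,
                                capture_radius: float | None = None
                                ) -> tuple[Tractogram, VertexVoxelMatrix, int]:
    """Streamline-visitation volume and vertex-voxel matrix for one tract.

    Streamline endpoints are drawn around the termination patch center (the
    angular spread matches the patch radius); each streamline runs on a
    straight segment from a deep core point to its endpoint, and voxel
    values count traversals.  The vertex-voxel matrix concentrates each
    vertex's connectivity on the voxels within ``capture_radius`` (default
    two voxel edges) of the vertex.
    """
    import logging

    logger = logging.getLogger(__name__)
    if grid.voxel_edge > 4.0 * mesh.mean_edge_length:
        logger.warning(
            "grid voxel edge %.2f mm is coarse relative to the mesh spacing",
            grid.voxel_edge,
        )
    rng = np.random.default_rng(seed)
    R = float(np.linalg.norm(mesh.vertices, axis=1).mean())

    def _endpoint_dirs(center, radius_deg, n):
        c = _unit(center)
        e1 = _unit(np.cross(c, [0.0, 0.0, 1.0]) if abs(c[2]) < 0.9
                   else np.cross(c, [1.0, 0.0, 0.0]))
        e2 = np.cross(c, e1)
        ang = np.abs(rng.normal(0.0, np.radians(radius_deg) / 1.5, n))
        phi = rng.uniform(0, 2 * np.pi, n)
        return (
            np.outer(np.cos(ang), c)
            + np.outer(np.sin(ang) * np.cos(phi), e1)
            + np.outer(np.sin(ang) * np.sin(phi), e2)
        )

    # endpoint directions: tangent-plane Gaussian around each termination
    # patch; extension-scenario tracts terminate in both territories
    if spec.scenario == "extension" and spec.extension_center is not None:
        n_ext = int(round(0.3 * n_streamlines))
        dirs = np.vstack(
            [
                _endpoint_dirs(spec.patch_center, spec.patch_radius,
                               n_streamlines - n_ext),
                _endpoint_dirs(spec.extension_center, spec.extension_radius, n_ext),
            ]
        )
    else:
        dirs = _endpoint_dirs(spec.patch_center, spec.patch_radius, n_streamlines)
    endpoints = dirs * R
    core = _unit(spec.patch_center) * 0.3 * R
    counts = np.zeros(grid.n_voxels)
    step = grid.voxel_edge / 2.0
    inv_aff = np.linalg.inv(grid.affine)
    for p in endpoints:
        seg = p - core
        length = np.linalg.norm(seg)
        ts = np.arange(0.0, 1.0 + step / length, step / length)
        pts = core[None, :] + ts[:, None] * seg[None, :]
        hom = np.column_stack([pts, np.ones(len(pts))])
        ijk = np.round((hom @ inv_aff.T)[:, :3]).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
        flat = np.unique(np.ravel_multi_index(ijk[ok].T, grid.shape))
        counts[flat] += 1
    tractogram = Tractogram(
        grid, counts.reshape(grid.shape), waytotal=float(n_streamlines)
    )
    # vertex-voxel matrix: Gaussian capture of voxel centers near each vertex
    rc = capture_radius if capture_radius is not None else 2.0 * grid.voxel_edge
    centers = grid.voxel_centers()
    tree = cKDTree(centers)
    rows, cols, data = [], [], []
    for v, pos in enumerate(mesh.vertices):
        near = tree.query_ball_point(pos, rc)
        if not near:
            continue
        d = np.linalg.norm(centers[near] - pos, axis=1)
        w = np.exp(-0.5 * (d / grid.voxel_edge) ** 2)
        rows.extend([v] * len(near))
        cols.extend(near)
        data.extend(w.tolist())
    matrix = VertexVoxelMatrix(
        sparse.csr_matrix(
            (data, (rows, cols)), shape=(mesh.n_vertices, grid.n_voxels)
        ),
        mesh, grid, weighted=False,
    )
    return tractogram, matrix, int(n_streamlines)


# ---------------------------------------------------------------------------
# whole-study bundle
# ---------------------------------------------------------------------------


@dataclass
class SpeciesData:
    spec: SpeciesSpec
    mesh: Mesh
    myelin: SurfaceMap
    rois: list[SurfaceMap]
    tract_templates: dict[str, TractMap]
    cohorts: dict[str, list[TractMap]]
    truth: Registration | None = None  # ground-truth warp onto the reference


@dataclass
class StudyData:
    spec: ScenarioSpec
    reference: SpeciesData
    others: dict[str, SpeciesData]


def make_study(spec: ScenarioSpec | None = None, seed: int | None = None) -> StudyData:
    """Generate the full synthetic study: reference species plus the other
    species linked to it by seeded ground-truth expansion deformations, with
    myelin maps, ROI masks, tract templates per scenario and noisy cohorts.
    """
    spec = spec or ScenarioSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    base = np.random.SeedSequence(spec.seed)
    ref_spec = spec.reference
    ref_mesh = cached_icosphere(ref_spec.mesh_level, ref_spec.radius, name=ref_spec.name)
    seeds = base.spawn(1 + len(spec.others))
    ref_ids = [int(x % 2**31) for x in seeds[0].generate_state(2 + len(spec.tracts))]

    # canonical fields (myelin landmarks, tract patches) live in reference
    # space; each other species sees them through its ground-truth warp
    ref_myelin, ref_rois = make_myelin_map(
        ref_mesh, spec.landmarks, noise_sd=0.02,
        noise_smoothness=spec.noise.smoothness, seed=ref_ids[0],
    )

    others: dict[str, SpeciesData] = {}
    ref_tracts: dict[str, TractMap] = {}
    ref_cohorts: dict[str, list[TractMap]] = {}
    for k, sp in enumerate(spec.others):
        s_ids = [int(x % 2**31) for x in seeds[1 + k].generate_state(8)]
        mesh = cached_icosphere(sp.mesh_level, sp.radius, name=sp.name)
        hotspots = tuple(
            replace(h, magnitude=h.magnitude * sp.deformation_scale)
            for h in spec.hotspots
        )
        truth = make_deformation(mesh, ref_mesh, hotspots)
        warped_units = truth.warped_positions / np.linalg.norm(
            truth.warped_positions, axis=1, keepdims=True
        )
        myelin, rois = make_myelin_map(
            mesh, spec.landmarks, noise_sd=0.02,
            noise_smoothness=spec.noise.smoothness, seed=s_ids[0],
            directions=warped_units,
        )
        templates = {}
        cohorts = {}
        for j, tr in enumerate(spec.tracts):
            src_map, tgt_map, _ = make_tract_scenario(
                mesh, ref_mesh, truth, tr, sp.smoothing_sigma,
                ref_spec.smoothing_sigma,
                source_extension_presence=sp.extension_presence,
            )
            templates[tr.name] = src_map
            cohorts[tr.name] = make_cohort(
                src_map, sp.n_subjects, spec.noise, s_ids[1 + j],
                id_prefix=f"{sp.name}_",
            )
            # identical for every species: the canonical reference-space map
            if tr.name not in ref_tracts:
                ref_tracts[tr.name] = tgt_map
        others[sp.name] = SpeciesData(
            spec=sp, mesh=mesh, myelin=myelin, rois=rois,
            tract_templates=templates, cohorts=cohorts, truth=truth,
        )

    for j, tr in enumerate(spec.tracts):
        ref_cohorts[tr.name] = make_cohort(
            ref_tracts[tr.name], ref_spec.n_subjects, spec.noise,
            ref_ids[2 + j], id_prefix=f"{ref_spec.name}_",
        )
    reference = SpeciesData(
        spec=ref_spec, mesh=ref_mesh, myelin=ref_myelin, rois=ref_rois,
        tract_templates=ref_tracts, cohorts=ref_cohorts, truth=None,
    )
    return StudyData(spec=spec, reference=reference, others=others)
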