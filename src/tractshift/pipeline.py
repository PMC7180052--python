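"""End-to-end orchestration: simulate -> register -> project -> compare -> stats.

Each hemisphere is an independent branch (its own seeded study) sharing one
configuration.  Every artifact the pipeline writes is recorded in a manifest
with its SHA-256 hash; identical (config, seed) reruns produce byte-identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import io as tio
from . import stats as tstats
from . import synth
from .exceptions import ArgumentError
from .registration import (
    RegistrationParams,
    Registration,
    apply_registration,
    distortion_map,
    local_similarity_map,
    register_feature_maps,
    roi_initialize,
)
from .tracts import (
    average_matrices,
    distance_weight,
    mask_regions,
    normalize_by_waytotal,
    postprocess,
    project_tractogram,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One-file configuration of the demo pipeline.

    The analysis defaults are the study conditions: 40% surface coverage for
    thresholding (sweep 20/30/50%), a 40 degree correlation window, 5000
    permutations, reference cohort n=20 and other-species cohorts n=5 (via
    the scenario spec).
    """

    out_dir: str = "results"
    seed: int = 0
    coverage_fraction: float = cmp.DEFAULT_COVERAGE
    coverage_sweep: tuple[float, ...] = cmp.COVERAGE_SWEEP
    correlation_window: float = cmp.DEFAULT_WINDOW
    n_perm: int = tstats.DEFAULT_N_PERM
    roi_stage: bool = True
    hemispheres: tuple[str, ...] = ("L", "R")
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    scenario: synth.ScenarioSpec = field(default_factory=synth.ScenarioSpec)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "registration" in kwargs:
            kwargs["registration"] = RegistrationParams(**kwargs["registration"])
        if "scenario" in kwargs:
            sc = dict(kwargs["scenario"])
            if "reference" in sc:
                sc["reference"] = synth.SpeciesSpec(**sc["reference"])
            if "others" in sc:
                sc["others"] = tuple(synth.SpeciesSpec(**o) for o in sc["others"])
            if "tracts" in sc:
                sc["tracts"] = tuple(synth.TractSpec(**t) for t in sc["tracts"])
            if "hotspots" in sc:
                sc["hotspots"] = tuple(synth.Hotspot(**h) for h in sc["hotspots"])
            if "landmarks" in sc:
                sc["landmarks"] = tuple(synth.Landmark(**l) for l in sc["landmarks"])
            if "noise" in sc:
                sc["noise"] = synth.NoiseSpec(**sc["noise"])
            kwargs["scenario"] = synth.ScenarioSpec(**sc)
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(kwargs) - known
        if unknown:
            raise ArgumentError(f"unknown config key(s): {sorted(unknown)}")
        return PipelineConfig(**kwargs)

    def to_dict(self) -> dict:
        """Config as plain data, without the output location (which does not
        affect any computed result and so is kept out of the config hash)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return json.loads(json.dumps(d, default=list))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.entries: dict[str, str] = {}
        self.config = config
        self.notes: dict[str, object] = {}

    def add(self, path: Path) -> None:
        self.entries[str(path.relative_to(self.out_dir))] = _sha256(path)

    def write(self) -> Path:
        payload = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "files": dict(sorted(self.entries.items())),
            "notes": self.notes,
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages for every hemisphere; returns the manifest path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    lock = out / "config.lock.yaml"
    lock.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest.add(lock)
    for k, hemi in enumerate(config.hemispheres):
        _run_hemisphere(config, hemi, int(config.seed) + k, out / hemi, manifest)
    path = manifest.write()
    logger.info("pipeline complete; manifest at %s", path)
    return path


def _run_hemisphere(config: PipelineConfig, hemi: str, seed: int, out: Path,
                    manifest: _Manifest) -> None:
    out.mkdir(parents=True, exist_ok=True)
    logger.info("[%s] simulate (seed %d)", hemi, seed)
    study = synth.make_study(config.scenario, seed=seed)
    ref = study.reference

    sim = out / "simdata"
    sim.mkdir(exist_ok=True)
    manifest.add(tio.write_surface(ref.mesh, sim / f"{ref.spec.name}.sphere.surf.gii"))
    manifest.add(tio.write_map(ref.myelin, sim / f"{ref.spec.name}.myelin.func.gii"))
    truth_info = {}
    for name, sp in study.others.items():
        manifest.add(tio.write_surface(sp.mesh, sim / f"{name}.sphere.surf.gii"))
        manifest.add(tio.write_map(sp.myelin, sim / f"{name}.myelin.func.gii"))
        manifest.add(
            tio.write_registration(sp.truth, sim / f"{name}.truth.sphere.reg.surf.gii")
        )
        truth_info[name] = {
            t: lbl for t, lbl in
            ((tr.name, tr.scenario) for tr in config.scenario.tracts)
        }
    gt = sim / "ground_truth.json"
    gt.write_text(json.dumps(truth_info, indent=1, sort_keys=True))
    manifest.add(gt)

    logger.info("[%s] register", hemi)
    reg_dir = out / "reg"
    reg_dir.mkdir(exist_ok=True)
    regs: dict[str, Registration] = {}
    for name, sp in study.others.items():
        init = None
        if config.roi_stage:
            init = roi_initialize(sp.mesh, ref.mesh, sp.rois, ref.rois,
                                  config.registration)
        reg = register_feature_maps(sp.mesh, ref.mesh, sp.myelin, ref.myelin,
                                    init, config.registration)
        regs[name] = reg
        manifest.add(
            tio.write_registration(reg, reg_dir / f"{name}-to-{ref.spec.name}.sphere.reg.surf.gii")
        )
        manifest.add(
            tio.write_map(distortion_map(reg), reg_dir / f"{name}.distortion.func.gii")
        )
        warped_myelin = apply_registration(reg, sp.myelin)
        qa = local_similarity_map(warped_myelin, ref.myelin, config.correlation_window)
        manifest.add(tio.write_map(qa, reg_dir / f"{name}.myelin.localcorr.func.gii"))

    logger.info("[%s] project (synthetic tractography demo)", hemi)
    proj_dir = out / "project"
    proj_dir.mkdir(exist_ok=True)
    _project_stage(config, study, seed, proj_dir, manifest)

    logger.info("[%s] compare", hemi)
    cmp_dir = out / "compare"
    cmp_dir.mkdir(exist_ok=True)
    fractions = tuple(
        dict.fromkeys((config.coverage_fraction,) + tuple(config.coverage_sweep))
    )
    records = cmp.run_comparison(
        human_maps=ref.cohorts,
        other_maps={n: sp.cohorts for n, sp in study.others.items()},
        registrations=regs,
        hemisphere=hemi,
        coverage_fractions=fractions,
        human_species=ref.spec.name,
    )
    rec_path = cmp_dir / "records.csv"
    records.to_csv(rec_path, index=False, float_format="%.12g")
    manifest.add(rec_path)
    summary = cmp.summarize_records(records)
    sum_path = cmp_dir / "summary.csv"
    summary.to_csv(sum_path, index=False, float_format="%.12g")
    manifest.add(sum_path)

    # group-level weighted correlation maps (pair-mean maps, for figures)
    from .tracts import group_average

    for name, sp in study.others.items():
        for tract, maps in sp.cohorts.items():
            pred = [cmp.predict_tract_map(regs[name], m) for m in maps]
            actual_mean = group_average(ref.cohorts[tract])
            pred_mean = group_average(pred)
            wc = cmp.weighted_correlation_map(
                actual_mean, pred_mean, config.correlation_window
            )
            manifest.add(
                tio.write_map(wc, cmp_dir / f"{name}.{tract}.wcorr.func.gii")
            )

    # connectivity fingerprints at two characteristic vertices: one inside
    # the extension territory (prediction should fail), one inside the main
    # termination patch (prediction should succeed)
    fp_rows = []
    tract_order = tuple(tr.name for tr in config.scenario.tracts)
    verts = _fingerprint_vertices(config, study)
    for label, v in verts.items():
        fp = cmp.fingerprint(ref.cohorts, v, cohort=ref.spec.name,
                             tract_order=tract_order)
        fp_rows.append(dict(vertex_label=label, vertex=v, cohort=fp.cohort,
                            **{t: m for t, m in zip(fp.tracts, fp.mean)}))
        for name, sp in study.others.items():
            pred = {t: [cmp.predict_tract_map(regs[name], m) for m in maps]
                    for t, maps in sp.cohorts.items()}
            fpp = cmp.fingerprint(pred, v, cohort=f"{name}-predicted",
                                  tract_order=tract_order)
            fp_rows.append(dict(vertex_label=label, vertex=v, cohort=fpp.cohort,
                                **{t: m for t, m in zip(fpp.tracts, fpp.mean)}))
    fp_path = cmp_dir / "fingerprints.csv"
    pd.DataFrame(fp_rows).to_csv(fp_path, index=False, float_format="%.12g")
    manifest.add(fp_path)

    logger.info("[%s] stats (n_perm=%d)", hemi, config.n_perm)
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    at_default = records[records["coverage_fraction"] == config.coverage_fraction]
    table = tstats.extension_table(at_default)
    results = tstats.two_factor_permutation(
        table, hemisphere=hemi, n_perm=config.n_perm, seed=seed
    )
    frame = tstats.results_frame(results)
    st_path = stats_dir / "permutation.csv"
    frame.to_csv(st_path, index=False, float_format="%.12g")
    manifest.add(st_path)
    js_path = stats_dir / "permutation.json"
    js_path.write_text(
        json.dumps([r.__dict__ for r in results], indent=1, sort_keys=True)
    )
    manifest.add(js_path)


def _project_stage(config: PipelineConfig, study: synth.StudyData, seed: int,
                   out: Path, manifest: _Manifest) -> None:
    """Demonstrate the tractogram-to-surface chain on the reference mesh.

    For each tract a synthetic tractogram and vertex-voxel matrix are built
    from the termination patch, pushed through normalization, distance
    weighting, projection, masking and postprocessing, and the result is
    compared (Dice at the default coverage) with the analytic template the
    cohorts are based on.
    """
    ref = study.reference
    mesh = ref.mesh
    grid = synth.make_grid(mesh, voxel_size=mesh.radius / 12.0)
    qa = {}
    for j, tr in enumerate(config.scenario.tracts):
        tractogram, matrix, _ = synth.make_synthetic_tractography(
            mesh, grid, tr, seed=seed + 101 + j
        )
        weighted = distance_weight(matrix)
        averaged = average_matrices([weighted])
        projected = project_tractogram(
            averaged, normalize_by_waytotal(tractogram), tract_name=tr.name
        )
        projected = mask_regions(projected, [])
        tract_map = postprocess(projected, config.scenario.reference.smoothing_sigma)
        manifest.add(
            tio.write_map(tract_map.surface_map, out / f"{tr.name}.projected.func.gii")
        )
        # QA: correlation with the analytic template the cohorts are based
        # on (the focal tractogram does not cover the template's full tail,
        # so a coverage-threshold Dice would be dominated by background ties)
        template = ref.tract_templates[tr.name]
        both = tract_map.valid_mask & template.valid_mask
        a = tract_map.values[both]
        b = template.values[both]
        qa[tr.name] = float(np.corrcoef(a, b)[0, 1])
    qa_path = out / "projection_qa.json"
    qa_path.write_text(json.dumps(qa, indent=1, sort_keys=True))
    manifest.add(qa_path)
    manifest.notes["projection_template_corr"] = qa


def _fingerprint_vertices(config: PipelineConfig, study: synth.StudyData) -> dict[str, int]:
    """Two representative vertices: the extension-patch center and the main
    termination-patch center of the first extension tract (falling back to
    the first tract's patch if no extension scenario is configured)."""
    ref_units = study.reference.mesh.unit_vertices
    ext = next(
        (t for t in config.scenario.tracts if t.scenario == "extension"), None
    )
    out = {}
    first = config.scenario.tracts[0]
    out["main_patch"] = int(np.argmax(ref_units @ synth._unit(first.patch_center)))
    if ext is not None:
        out["extension_patch"] = int(
            np.argmax(ref_units @ synth._unit(ext.extension_center))
        )
    return out
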