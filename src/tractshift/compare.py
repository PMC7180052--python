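"""Cross-species tract map comparison.

Predicted tract maps (another species' maps transported through the
spherical registration) are compared with actual reference-species maps by:

* a coverage-based threshold: the cutoff is picked per tract so that a fixed
  fraction (default 40%) of valid reference vertices is covered, and the
  *same absolute* threshold is applied to the predicted map;
* the Dice coefficient 2|A&B| / (|A|+|B|) of the two thresholded sets;
* the tract extension ratio |H| / |H&P|, which is 1 when the predicted map
  covers everything the reference map covers and grows above 1 when the
  reference tract occupies territory the registration cannot explain;
* a sliding-window weighted correlation map that localizes where the
  prediction succeeds;
* connectivity fingerprints: per-vertex intensity profiles across tracts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, UndefinedStatisticError
from .mesh import SurfaceMap
from .registration import Registration, apply_registration
from .tracts import TractMap

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE = 0.40
COVERAGE_SWEEP = (0.20, 0.30, 0.50)
DEFAULT_WINDOW = 40.0
FINGERPRINT_TRACTS = ("CST", "MDLF", "VOF", "IFO", "ILF", "SLF3", "AF")


@dataclass
class ComparisonRecord:
    tract_name: str
    species_pair: str
    human_id: str
    other_id: str
    hemisphere: str
    dice: float
    extension_ratio: float
    threshold_used: float
    coverage_fraction: float


@dataclass
class Fingerprint:
    vertex: int
    tracts: tuple[str, ...]
    cohort: str
    per_subject: np.ndarray  # (n_subjects, n_tracts)
    subject_ids: list[str] = field(default_factory=list)

    @property
    def mean(self) -> np.ndarray:
        return self.per_subject.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.per_subject.std(axis=0, ddof=0)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def predict_tract_map(reg: Registration, tract_map: TractMap) -> TractMap:
    """Transport a (postprocessed) tract map into the target species' space."""
    predicted = apply_registration(reg, tract_map.surface_map)
    vals = np.clip(predicted.values, 0.0, 1.0)
    return TractMap(
        SurfaceMap(vals, predicted.mesh, name=tract_map.tract_name),
        tract_name=tract_map.tract_name,
        subject_id=tract_map.subject_id,
        postprocessed=tract_map.postprocessed,
    )


def coverage_threshold(tract_map: TractMap | SurfaceMap, fraction: float = DEFAULT_COVERAGE) -> float:
    """Intensity threshold so that ``fraction`` of valid vertices is covered.

    Returns the k-th largest valid value with k = round(fraction * n_valid);
    ties at the threshold are all included when binarizing, so actual
    coverage can exceed the target by the tie count (logged).
    """
    if not 0 < fraction <= 1:
        raise ArgumentError("fraction must be in (0, 1]")
    sm = tract_map.surface_map if isinstance(tract_map, TractMap) else tract_map
    vals = sm.values[sm.valid_mask]
    if vals.size == 0:
        raise ArgumentError("map has no valid vertices")
    k = int(round(fraction * vals.size))
    k = max(k, 1)
    t = float(np.sort(vals)[::-1][k - 1])
    n_at = int((vals == t).sum())
    if n_at > 1:
        logger.debug("%d tied values at threshold %.6g", n_at, t)
    return t


def binarize(tract_map: TractMap | SurfaceMap, threshold: float) -> SurfaceMap:
    """Binary map of valid vertices with value >= threshold."""
    sm = tract_map.surface_map if isinstance(tract_map, TractMap) else tract_map
    vals = np.where(sm.valid_mask, (np.nan_to_num(sm.values) >= threshold) & sm.valid_mask, np.nan)
    return SurfaceMap(vals.astype(float), sm.mesh, name=f"{sm.name}_bin")


def _as_set(bin_map: SurfaceMap) -> np.ndarray:
    return bin_map.valid_mask & (np.nan_to_num(bin_map.values) > 0.5)


def dice(bin_a: SurfaceMap, bin_b: SurfaceMap) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|) over valid vertices."""
    if bin_a.mesh is not bin_b.mesh:
        raise ArgumentError("maps live on different meshes")
    a = _as_set(bin_a)
    b = _as_set(bin_b)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise UndefinedStatisticError("Dice is undefined for two empty sets")
    return 2.0 * int((a & b).sum()) / (na + nb)


def extension_ratio(human_bin: SurfaceMap, predicted_bin: SurfaceMap) -> float:
    """|H| / |H & P|: 1 means the prediction covers the whole reference
    tract; larger values quantify extension into unexplained territory."""
    if human_bin.mesh is not predicted_bin.mesh:
        raise ArgumentError("maps live on different meshes")
    h = _as_set(human_bin)
    p = _as_set(predicted_bin)
    nh = int(h.sum())
    if nh == 0:
        raise ArgumentError("reference set is empty")
    inter = int((h & p).sum())
    if inter == 0:
        logger.warning("no overlap between reference and predicted sets")
        return float("inf")
    return nh / inter


def weighted_correlation_map(actual: TractMap, predicted: TractMap,
                             window: float = DEFAULT_WINDOW,
                             weighting: str = "post") -> SurfaceMap:
    """Sliding-window correlation of actual vs predicted tract maps,
    up-weighted where both tracts terminate.

    Per vertex, the Pearson correlation of the two maps over the geodesic
    disc of ``window`` degrees is multiplied (``weighting='post'``) by the
    product of the two intensities rescaled to [0, 1].  ``weighting='none'``
    returns the plain correlation; ``'inside'`` uses the product as
    per-vertex weights inside a weighted correlation.
    """
    mesh = actual.mesh
    if predicted.mesh is not mesh:
        raise ArgumentError("maps live on different meshes")
    if window <= 0:
        raise ArgumentError("window must be positive")
    if weighting not in ("post", "inside", "none"):
        raise ArgumentError("weighting must be 'post', 'inside' or 'none'")
    both = actual.valid_mask & predicted.valid_mask
    a_all = actual.values
    b_all = predicted.values
    w_all = np.where(both, np.nan_to_num(a_all) * np.nan_to_num(b_all), np.nan)
    top = np.nanmax(w_all) if np.any(both) else 0.0
    w_scaled = w_all / top if top > 0 else np.where(both, 0.0, np.nan)

    cosr = np.cos(np.radians(window)) if window < 180 else -1.0
    units = mesh.unit_vertices
    out = np.zeros(mesh.n_vertices)
    valid_out = np.zeros(mesh.n_vertices, dtype=bool)
    for v in range(mesh.n_vertices):
        if not both[v]:
            continue
        nbr = np.flatnonzero((units @ units[v] >= cosr) & both)
        if nbr.size < 3:
            continue
        a = a_all[nbr]
        b = b_all[nbr]
        if weighting == "inside":
            w = np.nan_to_num(w_all[nbr])
            if w.sum() <= 0:
                valid_out[v] = True
                continue
            wm = w / w.sum()
            am, bm = np.sum(wm * a), np.sum(wm * b)
            cov = np.sum(wm * (a - am) * (b - bm))
            va, vb = np.sum(wm * (a - am) ** 2), np.sum(wm * (b - bm) ** 2)
        else:
            am, bm = a.mean(), b.mean()
            cov = np.mean((a - am) * (b - bm))
            va, vb = np.mean((a - am) ** 2), np.mean((b - bm) ** 2)
        if va < 1e-24 or vb < 1e-24:
            continue
        r = cov / np.sqrt(va * vb)
        if weighting == "post":
            r *= w_scaled[v]
        out[v] = r
        valid_out[v] = True
    out[~valid_out] = np.nan
    sm = SurfaceMap(out, mesh, name=f"wcorr_{actual.tract_name}")
    # vertices with too-sparse or constant windows carry value 0, flagged invalid
    sm.values[~valid_out] = np.nan
    return sm


def overlay(actual: TractMap, predicted_maps: list[TractMap],
            thresholds: list[float]) -> SurfaceMap:
    """Categorical membership map of thresholded actual + predicted sets.

    The label is a bitmask: bit 0 = actual above its threshold, bit i =
    predicted map i-1 above its threshold; intersections are the sums.
    """
    if len(predicted_maps) + 1 != len(thresholds):
        raise ArgumentError("need one threshold per map (actual first)")
    for t in thresholds:
        if not 0 <= t <= 1:
            raise ArgumentError("thresholds must lie in [0, 1]")
    mesh = actual.mesh
    label = np.zeros(mesh.n_vertices)
    sets = [_as_set(binarize(actual, thresholds[0]))]
    for pm, t in zip(predicted_maps, thresholds[1:]):
        if pm.mesh is not mesh:
            raise ArgumentError("predicted map lives on a different mesh")
        sets.append(_as_set(binarize(pm, t)))
    for bit, s in enumerate(sets):
        label[s] += 2**bit
    return SurfaceMap(label, mesh, name=f"overlay_{actual.tract_name}")


def fingerprint(tract_maps: dict[str, list[TractMap]], vertex: int,
                cohort: str = "cohort",
                tract_order: tuple[str, ...] = FINGERPRINT_TRACTS) -> Fingerprint:
    """Connectivity fingerprint at one vertex: per-subject intensity across a
    fixed, ordered tract set."""
    missing = [t for t in tract_order if t not in tract_maps]
    if missing:
        raise ArgumentError(f"missing tract map(s): {', '.join(missing)}")
    n_subjects = len(tract_maps[tract_order[0]])
    values = np.empty((n_subjects, len(tract_order)))
    subject_ids = [m.subject_id for m in tract_maps[tract_order[0]]]
    for j, tract in enumerate(tract_order):
        maps = tract_maps[tract]
        if len(maps) != n_subjects:
            raise ArgumentError(f"tract '{tract}' has a different subject count")
        for i, m in enumerate(maps):
            if not m.valid_mask[vertex]:
                raise ArgumentError(
                    f"vertex {vertex} is invalid in tract '{tract}' subject "
                    f"'{m.subject_id}'"
                )
            values[i, j] = m.values[vertex]
    return Fingerprint(
        vertex=vertex, tracts=tuple(tract_order), cohort=cohort,
        per_subject=values, subject_ids=subject_ids,
    )


# ---------------------------------------------------------------------------
# the pairwise comparison table
# ---------------------------------------------------------------------------


def compare_pair(human_map: TractMap, predicted_map: TractMap,
                 coverage_fraction: float = DEFAULT_COVERAGE) -> tuple[float, float, float]:
    """Threshold the reference map by coverage, binarize both maps with the
    same absolute threshold, and return (dice, extension_ratio, threshold)."""
    t = coverage_threshold(human_map, coverage_fraction)
    h = binarize(human_map, t)
    p = binarize(predicted_map, t)
    return dice(h, p), extension_ratio(h, p), t


def run_comparison(human_maps: dict[str, list[TractMap]],
                   other_maps: dict[str, dict[str, list[TractMap]]],
                   registrations: dict[str, Registration],
                   hemisphere: str = "L",
                   coverage_fractions: tuple[float, ...] = (DEFAULT_COVERAGE,),
                   human_species: str = "human") -> pd.DataFrame:
    """All-pairs comparison for one hemisphere.

    ``human_maps``: tract -> list of reference-subject maps (on the
    reference mesh).  ``other_maps``: species -> tract -> list of
    source-subject maps (on that species' mesh).  ``registrations``:
    species -> source-to-reference registration.  Every (reference subject,
    other subject) pair contributes one record per tract, species and
    coverage fraction.
    """
    records = []
    n_skipped = 0
    for species, tracts in other_maps.items():
        reg = registrations[species]
        for tract, source_subject_maps in tracts.items():
            if tract not in human_maps:
                logger.warning("no reference maps for tract %s; skipping", tract)
                n_skipped += 1
                continue
            predicted = [predict_tract_map(reg, m) for m in source_subject_maps]
            for hm, pm in itertools.product(human_maps[tract], predicted):
                for frac in coverage_fractions:
                    d, er, t = compare_pair(hm, pm, frac)
                    records.append(
                        ComparisonRecord(
                            tract_name=tract,
                            species_pair=f"{species}-to-{human_species}",
                            human_id=hm.subject_id,
                            other_id=pm.subject_id,
                            hemisphere=hemisphere,
                            dice=d,
                            extension_ratio=er,
                            threshold_used=t,
                            coverage_fraction=frac,
                        )
                    )
    if n_skipped:
        logger.warning("%d tract(s) skipped for missing reference maps", n_skipped)
    return pd.DataFrame([r.__dict__ for r in records])


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of dice and extension ratio per tract/species/coverage cell."""
    grouped = records.groupby(
        ["species_pair", "tract_name", "hemisphere", "coverage_fraction"]
    )
    return grouped.agg(
        dice_mean=("dice", "mean"),
        dice_sd=("dice", "std"),
        extension_mean=("extension_ratio", "mean"),
        extension_sd=("extension_ratio", "std"),
        n_pairs=("dice", "size"),
    ).reset_index()
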