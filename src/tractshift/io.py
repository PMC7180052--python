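"""File formats.

Surfaces and per-vertex maps use GIFTI (via nibabel), with plain-text
fallbacks (OBJ for surfaces, single-column CSV for maps).  Tractograms are
NIfTI volumes with the waytotal in a single-line text sidecar (the FSL
convention).  Vertex-voxel matrices are sparse COO triplet text plus a JSON
grid descriptor.  Registrations are stored as a GIFTI "warped sphere"
(warped positions as coordinates) plus a JSON sidecar with provenance.

All vertex and voxel indices on disk are 0-based; NaN in a map file means
"invalid vertex".
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import sparse

from .exceptions import FormatError
from .mesh import MIDTHICKNESS, SPHERE, Mesh, SurfaceMap
from .registration import Registration
from .tracts import Tractogram, VertexVoxelMatrix, VolumeGrid

# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def write_surface(mesh: Mesh, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".obj":
        lines = [f"# kind={mesh.kind} radius={mesh.radius if mesh.radius else 'none'}"]
        lines += [f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices]
        lines += [f"f {f[0]+1} {f[1]+1} {f[2]+1}" for f in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
        return path
    meta = nib.gifti.GiftiMetaData(
        kind=mesh.kind, radius=str(mesh.radius if mesh.radius is not None else ""),
        name=mesh.name,
    )
    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET",
        datatype="NIFTI_TYPE_FLOAT32",
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE",
        datatype="NIFTI_TYPE_INT32",
    )
    img = nib.gifti.GiftiImage(darrays=[coords, tris], meta=meta)
    nib.save(img, str(path))
    return path


def read_surface(path: str | Path) -> Mesh:
    path = Path(path)
    if path.suffix == ".obj":
        verts, faces, kind, radius = [], [], SPHERE, None
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                for token in line[1:].split():
                    k, _, v = token.partition("=")
                    if k == "kind":
                        kind = v
                    elif k == "radius" and v != "none":
                        radius = float(v)
            elif line.startswith("v "):
                verts.append([float(x) for x in line.split()[1:4]])
            elif line.startswith("f "):
                faces.append([int(x.split("/")[0]) - 1 for x in line.split()[1:4]])
        return Mesh(np.array(verts), np.array(faces), kind=kind, radius=radius,
                    name=path.stem)
    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0]
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0]
    meta = dict(img.meta)
    kind = meta.get("kind", SPHERE)
    radius_s = meta.get("radius", "")
    radius = float(radius_s) if radius_s else None
    if kind == MIDTHICKNESS:
        radius = None
    return Mesh(np.asarray(coords.data, float), np.asarray(tris.data, np.int64),
                kind=kind, radius=radius, name=meta.get("name", path.stem))


# ---------------------------------------------------------------------------
# per-vertex maps
# ---------------------------------------------------------------------------


def write_map(surface_map: SurfaceMap, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".csv":
        vals = [f"{v:.17g}" if np.isfinite(v) else "nan" for v in surface_map.values]
        path.write_text("value\n" + "\n".join(vals) + "\n")
        return path
    arr = nib.gifti.GiftiDataArray(
        surface_map.values.astype(np.float32), intent="NIFTI_INTENT_NONE",
        datatype="NIFTI_TYPE_FLOAT32",
    )
    img = nib.gifti.GiftiImage(
        darrays=[arr], meta=nib.gifti.GiftiMetaData(name=surface_map.name)
    )
    nib.save(img, str(path))
    return path


def read_map(path: str | Path, mesh: Mesh) -> SurfaceMap:
    path = Path(path)
    if path.suffix == ".csv":
        lines = path.read_text().strip().splitlines()
        vals = np.array([float(x) for x in lines[1:]])
    else:
        img = nib.load(str(path))
        vals = np.asarray(img.darrays[0].data, dtype=float)
    if vals.shape[0] != mesh.n_vertices:
        raise FormatError(
            f"map file {path.name} has {vals.shape[0]} values but the mesh "
            f"has {mesh.n_vertices} vertices"
        )
    return SurfaceMap(vals, mesh, name=path.stem.split(".")[0])


# ---------------------------------------------------------------------------
# tractograms
# ---------------------------------------------------------------------------


def write_tractogram(t: Tractogram, path: str | Path,
                     waytotal_path: str | Path | None = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(t.values.astype(np.float64), t.grid.affine)
    nib.save(img, str(path))
    wt = Path(waytotal_path) if waytotal_path else path.parent / "waytotal"
    wt.write_text(f"{t.waytotal:.17g}\n")
    return path


def read_tractogram(path: str | Path, waytotal_path: str | Path | None = None,
                    normalized: bool = False) -> Tractogram:
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    wt_path = Path(waytotal_path) if waytotal_path else path.parent / "waytotal"
    waytotal = float(wt_path.read_text().split()[0])
    grid = VolumeGrid(shape=values.shape, affine=np.asarray(img.affine))
    return Tractogram(grid, values, waytotal, normalized=normalized)


# ---------------------------------------------------------------------------
# vertex-voxel matrices
# ---------------------------------------------------------------------------


def write_matrix(m: VertexVoxelMatrix, path: str | Path,
                 grid_path: str | Path | None = None) -> Path:
    """COO triplet text (row, col, value per line) plus a JSON grid file."""
    path = Path(path)
    coo = m.matrix.tocoo()
    order = np.lexsort((coo.col, coo.row))
    lines = [f"# rows={m.matrix.shape[0]} cols={m.matrix.shape[1]} weighted={int(m.weighted)}"]
    lines += [
        f"{coo.row[i]} {coo.col[i]} {coo.data[i]:.17g}" for i in order
    ]
    path.write_text("\n".join(lines) + "\n")
    gp = Path(grid_path) if grid_path else path.with_suffix(".grid.json")
    gp.write_text(json.dumps(
        {"shape": list(m.grid.shape), "affine": m.grid.affine.tolist()},
        indent=0, sort_keys=True,
    ))
    return path


def read_matrix(path: str | Path, mesh: Mesh,
                grid_path: str | Path | None = None) -> VertexVoxelMatrix:
    path = Path(path)
    gp = Path(grid_path) if grid_path else path.with_suffix(".grid.json")
    gspec = json.loads(gp.read_text())
    grid = VolumeGrid(shape=tuple(gspec["shape"]), affine=np.array(gspec["affine"]))
    rows, cols, data, weighted = [], [], [], False
    shape = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            tokens = dict(t.partition("=")[::2] for t in line[1:].split())
            shape = (int(tokens["rows"]), int(tokens["cols"]))
            weighted = bool(int(tokens.get("weighted", "0")))
            continue
        r, c, v = line.split()
        rows.append(int(r)); cols.append(int(c)); data.append(float(v))
    if shape is None:
        shape = (mesh.n_vertices, grid.n_voxels)
    if shape != (mesh.n_vertices, grid.n_voxels):
        raise FormatError(
            f"matrix header {shape} does not match mesh x grid "
            f"({mesh.n_vertices}, {grid.n_voxels})"
        )
    mat = sparse.csr_matrix((data, (rows, cols)), shape=shape)
    return VertexVoxelMatrix(mat, mesh, grid, weighted=weighted)


# ---------------------------------------------------------------------------
# registrations
# ---------------------------------------------------------------------------


def write_registration(reg: Registration, sphere_path: str | Path,
                       sidecar_path: str | Path | None = None) -> Path:
    """MSM-style warped sphere: the source topology with warped coordinates."""
    sphere_path = Path(sphere_path)
    warped = Mesh(
        reg.warped_positions, reg.source_mesh.faces, kind=SPHERE,
        radius=reg.target_mesh.radius, name=f"{reg.source_mesh.name}.warped",
    )
    write_surface(warped, sphere_path)
    sp = Path(sidecar_path) if sidecar_path else sphere_path.with_suffix(".json")
    sp.write_text(json.dumps(
        {
            "source_mesh": reg.source_mesh.name,
            "target_mesh": reg.target_mesh.name,
            "target_radius": reg.target_mesh.radius,
            "provenance": reg.provenance,
            "objective_history": reg.objective_history,
        },
        indent=1, sort_keys=True,
    ))
    return sphere_path


def read_registration(sphere_path: str | Path, source: Mesh, target: Mesh,
                      sidecar_path: str | Path | None = None) -> Registration:
    sphere_path = Path(sphere_path)
    warped = read_surface(sphere_path)
    if warped.n_vertices != source.n_vertices:
        raise FormatError(
            f"warped sphere has {warped.n_vertices} vertices; source mesh has "
            f"{source.n_vertices}"
        )
    provenance: list[str] = []
    history: list[float] = []
    sp = Path(sidecar_path) if sidecar_path else sphere_path.with_suffix(".json")
    if sp.exists():
        sidecar = json.loads(sp.read_text())
        provenance = list(sidecar.get("provenance", []))
        history = list(sidecar.get("objective_history", []))
    return Registration(source, target, warped.vertices, provenance=provenance,
                        objective_history=history)
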