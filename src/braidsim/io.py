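"""File round-trips: VTK polyline meshes, STL surfaces, array containers.

Wire meshes and centerlines are exchanged as legacy-ASCII VTK polydata
(points + line cells with optional integer point data), surfaces as STL
through trimesh, and numeric artifacts (SDF grids, snapshot matrices,
metric tables) as npz / CSV.  Every writer has a matching reader and the
pair preserves counts exactly and coordinates to well below 1e-6 mm.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from braidsim.vessel import SignedDistanceGrid, TriSurface

__all__ = [
    "write_polydata_vtk",
    "read_polydata_vtk",
    "write_stl",
    "read_stl",
    "save_sdf",
    "load_sdf",
    "save_snapshot_matrix",
    "load_snapshot_matrix",
    "write_manifest",
    "write_read_roundtrip",
]


def write_polydata_vtk(
    path,
    points: np.ndarray,
    lines: np.ndarray | None = None,
    point_data: dict | None = None,
) -> None:
    """Write points + polyline cells as legacy-ASCII VTK polydata.

    ``lines`` is an (M, 2) array of point-index pairs (wire segments) or
    None for a bare point cloud/centerline; ``point_data`` maps names to
    integer per-point arrays (e.g. wire or ring ids).
    """
    points = np.asarray(points, dtype=float)
    out = ["# vtk DataFile Version 3.0", "braidsim polydata", "ASCII",
           "DATASET POLYDATA", f"POINTS {len(points)} double"]
    out += [" ".join(f"{c:.12g}" for c in p) for p in points]
    if lines is not None and len(lines):
        lines = np.asarray(lines, dtype=np.int64)
        out.append(f"LINES {len(lines)} {3 * len(lines)}")
        out += [f"2 {a} {b}" for a, b in lines]
    if point_data:
        out.append(f"POINT_DATA {len(points)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            out.append(f"SCALARS {name} int 1")
            out.append("LOOKUP_TABLE default")
            out += [str(int(v)) for v in arr]
    Path(path).write_text("\n".join(out) + "\n")


def read_polydata_vtk(path):
    """Read polydata written by :func:`write_polydata_vtk`.

    Returns ``(points, lines, point_data)``.

    Raises
    ------
    ValueError
        On malformed content, with the offending line number.
    """
    tokens = []
    text = Path(path).read_text().splitlines()
    points = None
    lines = np.empty((0, 2), dtype=np.int64)
    point_data: dict[str, np.ndarray] = {}
    i = 0
    try:
        while i < len(text):
            t = text[i].split()
            if not t:
                i += 1
                continue
            if t[0] == "POINTS":
                n = int(t[1])
                vals = []
                i += 1
                while len(vals) < 3 * n:
                    vals += [float(v) for v in text[i].split()]
                    i += 1
                points = np.array(vals).reshape(n, 3)
                continue
            if t[0] == "LINES":
                m = int(t[1])
                rows = []
                i += 1
                for _ in range(m):
                    parts = text[i].split()
                    if parts[0] != "2":
                        raise ValueError("only 2-point line cells supported")
                    rows.append((int(parts[1]), int(parts[2])))
                    i += 1
                lines = np.array(rows, dtype=np.int64)
                continue
            if t[0] == "SCALARS":
                name = t[1]
                i += 2  # skip LOOKUP_TABLE
                vals = []
                while len(vals) < len(points) and i < len(text):
                    vals += [int(v) for v in text[i].split()]
                    i += 1
                point_data[name] = np.array(vals, dtype=np.int64)
                continue
            i += 1
    except (IndexError, ValueError) as err:
        raise ValueError(f"parse error in {path} near line {i + 1}: {err}")
    if points is None:
        raise ValueError(f"parse error in {path}: no POINTS section")
    return points, lines, point_data


def write_stl(path, surface: TriSurface, binary: bool = True) -> None:
    """Export a surface as STL (binary or ASCII)."""
    mesh = surface.to_trimesh()
    path = str(path)
    if binary:
        mesh.export(path, file_type="stl")
    else:
        mesh.export(path, file_type="stl_ascii")


def read_stl(path) -> TriSurface:
    """Load an STL file into a TriSurface.

    Raises
    ------
    ValueError
        If the file cannot be parsed as STL.
    """
    import trimesh

    try:
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as err:
        raise ValueError(f"parse error reading STL {path}: {err}")
    return TriSurface.from_trimesh(mesh)


def save_sdf(path, grid: SignedDistanceGrid) -> None:
    np.savez_compressed(
        path, origin=grid.origin, spacing=grid.spacing, values=grid.values
    )


def load_sdf(path) -> SignedDistanceGrid:
    with np.load(path) as z:
        return SignedDistanceGrid(
            origin=z["origin"], spacing=float(z["spacing"]), values=z["values"]
        )


def save_snapshot_matrix(path, S: np.ndarray, parameters: np.ndarray) -> None:
    """Persist a snapshot matrix with its index-aligned parameter rows.

    Raises
    ------
    ValueError
        On an empty snapshot matrix.
    """
    S = np.asarray(S)
    if S.size == 0:
        raise ValueError("refusing to write an empty snapshot matrix")
    np.savez_compressed(path, S=S, parameters=np.asarray(parameters))


def load_snapshot_matrix(path):
    with np.load(path) as z:
        return z["S"], z["parameters"]


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, inputs: dict, seed: int, artifacts: list) -> dict:
    """Write a reproducibility manifest (inputs hash, seed, versions)."""
    import braidsim

    manifest = {
        "inputs_hash": _hash_obj(inputs),
        "inputs": inputs,
        "seed": int(seed),
        "versions": {
            "braidsim": braidsim.__version__,
            "numpy": np.__version__,
        },
        "artifacts": sorted(str(a) for a in artifacts),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_read_roundtrip(kind: str, obj, path) -> dict:
    """Write an artifact, read it back and report equality.

    ``kind`` is one of ``stent-vtk`` (StentMesh), ``surface-stl``
    (TriSurface), ``snapshot-npz`` ((S, parameters) tuple) or
    ``metrics-csv`` (DataFrame).  Counts must round-trip exactly and
    coordinates to 1e-6 mm.
    """
    import pandas as pd

    if kind == "stent-vtk":
        write_polydata_vtk(
            path, obj.nodes, obj.beams,
            {"wire_id": obj.wire_id, "ring_id": obj.ring_id},
        )
        pts, lines, pdata = read_polydata_vtk(path)
        return {
            "count_equal": len(pts) == len(obj.nodes)
            and len(lines) == len(obj.beams),
            "max_coord_err": float(np.abs(pts - obj.nodes).max()),
            "data_equal": bool(
                np.array_equal(pdata["wire_id"], obj.wire_id)
                and np.array_equal(pdata["ring_id"], obj.ring_id)
            ),
        }
    if kind == "surface-stl":
        write_stl(path, obj)
        back = read_stl(path)
        return {
            "count_equal": len(back.triangles) == len(obj.triangles),
            "max_coord_err": float(
                np.abs(np.sort(back.vertices, axis=0)
                       - np.sort(obj.vertices, axis=0)).max()
            ),
        }
    if kind == "snapshot-npz":
        S, params = obj
        save_snapshot_matrix(path, S, params)
        S2, p2 = load_snapshot_matrix(path)
        return {
            "count_equal": S2.shape == np.asarray(S).shape,
            "max_coord_err": float(np.abs(S2 - S).max()),
        }
    if kind == "metrics-csv":
        obj.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        return {
            "count_equal": back.shape == obj.shape,
            "max_coord_err": float(
                np.abs(back.to_numpy(float) - obj.to_numpy(float)).max()
            ),
        }
    raise ValueError(f"unknown artifact kind {kind!r}")
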