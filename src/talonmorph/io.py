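"""Readers and writers for landmarks, meshes, trees and species tables.

Fixed dialects:

* landmarks — TPS with ``LM3=`` blocks (one specimen per block, ``ID=`` as
  specimen id) or long-format CSV with header
  ``specimen,label,kind,curve,x,y,z``;
* surfaces — PLY / STL / OFF (via :mod:`trimesh`);
* volumes — TetGen ``.node`` / ``.ele`` pairs (1-based on disk, 0-based in
  memory);
* trees — Newick / NEXUS (via :mod:`dendropy`);
* species table — CSV with header ``species,diet,body_mass``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .geometry import TetMesh, TriMesh
from .landmarks import LandmarkSet

DIET_CATEGORIES = ("SM", "ML", "NP")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------- landmarks

def read_landmarks(path: str | os.PathLike, format: str | None = None) -> list[LandmarkSet]:
    """Read all specimens from a TPS or CSV landmark file.

    All specimens must share one point count; a mismatch raises
    :class:`FormatError` naming the offending specimen.
    """
    path = Path(path)
    fmt = format or ("tps" if path.suffix.lower() == ".tps" else "csv")
    if fmt == "tps":
        sets = _read_tps(path)
    elif fmt == "csv":
        sets = _read_landmark_csv(path)
    else:
        raise FormatError(f"unknown landmark format: {fmt!r}")
    if sets:
        n0 = sets[0].n_points
        for s in sets:
            if s.n_points != n0:
                raise FormatError(
                    f"inconsistent point count: specimen '{s.specimen_id}' "
                    f"has {s.n_points} points, expected {n0}")
    return sets


def _read_tps(path: Path) -> list[LandmarkSet]:
    sets: list[LandmarkSet] = []
    n_expected = 0
    coords: list[list[float]] = []
    spec_id = None
    block_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                if spec_id is not None or coords:
                    sets.append(_finish_tps_block(spec_id, coords, n_expected,
                                                  block_line, len(sets)))
                    coords, spec_id = [], None
                try:
                    n_expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad LM3 count") from exc
                block_line = lineno
            elif upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif upper.startswith(("IMAGE=", "SCALE=")):
                continue
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}")
                try:
                    coords.append([float(p) for p in parts])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
    if coords or spec_id is not None:
        sets.append(_finish_tps_block(spec_id, coords, n_expected, block_line, len(sets)))
    return sets


def _finish_tps_block(spec_id, coords, n_expected, lineno, index) -> LandmarkSet:
    if len(coords) != n_expected:
        raise FormatError(
            f"TPS block at line {lineno}: LM3={n_expected} but "
            f"{len(coords)} coordinate lines")
    sid = spec_id if spec_id is not None else f"specimen_{index}"
    labels = [f"P{i:03d}" for i in range(len(coords))]
    return LandmarkSet(sid, np.asarray(coords), labels)


def write_tps(sets: list[LandmarkSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write(f"LM3={s.n_points}\n")
            for x, y, z in s.points:
                fh.write(f"{x:.9f} {y:.9f} {z:.9f}\n")
            fh.write(f"ID={s.specimen_id}\n")


def _read_landmark_csv(path: Path) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    required = {"specimen", "label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: landmark CSV needs columns {sorted(required)}")
    sets = []
    for sid, grp in df.groupby("specimen", sort=False):
        kind = list(grp["kind"]) if "kind" in grp else []
        curve = [c if isinstance(c, str) else None for c in grp["curve"]] \
            if "curve" in grp else []
        sets.append(LandmarkSet(str(sid), grp[["x", "y", "z"]].to_numpy(float),
                                [str(lb) for lb in grp["label"]], kind, curve))
    return sets


def write_landmarks_csv(sets: list[LandmarkSet], path: str | os.PathLike) -> None:
    rows = []
    for s in sets:
        for (x, y, z), lb, k, c in zip(s.points, s.labels, s.kind, s.curve_id):
            rows.append({"specimen": s.specimen_id, "label": lb, "kind": k,
                         "curve": c if c else "", "x": x, "y": y, "z": z})
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------------- meshes

_SURFACE_EXTS = {".ply", ".stl", ".off"}


def read_mesh(path: str | os.PathLike) -> TriMesh | TetMesh:
    """Read a surface (.ply/.stl/.off) or a TetGen volume (.node/.ele).

    Pass either member of a .node/.ele pair for a volume mesh. Negative
    tet volumes are repaired by a vertex-order swap.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _SURFACE_EXTS:
        tm = _trimesh.load(str(path), process=False, force="mesh")
        return TriMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    if ext in {".node", ".ele"}:
        return _read_tetgen(path.with_suffix(".node"), path.with_suffix(".ele"))
    raise FormatError(f"unknown mesh extension: {ext!r}")


def write_mesh(mesh: TriMesh | TetMesh, path: str | os.PathLike) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if isinstance(mesh, TriMesh):
        if ext not in _SURFACE_EXTS:
            raise FormatError(f"surface mesh needs .ply/.stl/.off, got {ext!r}")
        if ext == ".ply":
            _write_ascii_ply(mesh, path)  # full double precision
        else:
            mesh.to_trimesh().export(str(path))
    elif isinstance(mesh, TetMesh):
        if ext not in {".node", ".ele"}:
            raise FormatError(f"volume mesh needs .node/.ele, got {ext!r}")
        _write_tetgen(mesh, path.with_suffix(".node"), path.with_suffix(".ele"))
    else:
        raise TypeError(f"cannot write {type(mesh).__name__}")


def _write_ascii_ply(mesh: TriMesh, path: Path) -> None:
    # trimesh's PLY export quantizes to float32; double-precision vertices
    # are required for lossless round-trips
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n"
                 f"element vertex {mesh.n_vertices}\n"
                 "property double x\nproperty double y\nproperty double z\n"
                 f"element face {mesh.n_faces}\n"
                 "property list uchar int vertex_indices\nend_header\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")


def _tetgen_rows(path: Path):
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                yield line.split()


def _read_tetgen(node_path: Path, ele_path: Path) -> TetMesh:
    rows = list(_tetgen_rows(node_path))
    n_nodes = int(rows[0][0])
    body = rows[1:1 + n_nodes]
    ids = np.array([int(r[0]) for r in body])
    offset = ids.min()  # TetGen convention is 1-based; accept 0-based too
    nodes = np.empty((n_nodes, 3))
    nodes[ids - offset] = [[float(r[1]), float(r[2]), float(r[3])] for r in body]

    rows = list(_tetgen_rows(ele_path))
    n_tets = int(rows[0][0])
    body = rows[1:1 + n_tets]
    tets = np.array([[int(v) - offset for v in r[1:5]] for r in body], np.int64)
    mesh = TetMesh(nodes, tets)
    n_repaired = mesh.fix_orientation()
    if n_repaired:
        import logging
        logging.getLogger(__name__).info(
            "repaired %d negative-volume tets by vertex-order swap", n_repaired)
    sets_path = node_path.with_suffix(".sets.json")
    if sets_path.exists():
        import json
        raw = json.loads(sets_path.read_text())
        mesh.node_sets = {k: np.asarray(v, np.int64) for k, v in raw.items()}
    return mesh


def _write_tetgen(mesh: TetMesh, node_path: Path, ele_path: Path) -> None:
    with open(node_path, "w") as fh:
        fh.write(f"{mesh.n_nodes} 3 0 0\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
    with open(ele_path, "w") as fh:
        fh.write(f"{mesh.n_tets} 4 0\n")
        for i, t in enumerate(mesh.tets + 1, start=1):
            fh.write(f"{i} {t[0]} {t[1]} {t[2]} {t[3]}\n")
    if mesh.node_sets:
        import json
        node_path.with_suffix(".sets.json").write_text(
            json.dumps({k: v.tolist() for k, v in mesh.node_sets.items()}))


# -------------------------------------------------------------------- trees

def read_tree(path: str | os.PathLike, schema: str | None = None):
    from .phylo import Phylo
    return Phylo.from_file(path, schema=schema)


def read_tree_set(path: str | os.PathLike, schema: str | None = None):
    from .phylo import TreeSample
    return TreeSample.from_file(path, schema=schema)


# ------------------------------------------------------------ species table

def read_species_table(path: str | os.PathLike) -> pd.DataFrame:
    """Species table CSV: ``species,diet,body_mass`` (mass in g)."""
    df = pd.read_csv(path)
    required = {"species", "diet", "body_mass"}
    if not required.issubset(df.columns):
        raise FormatError(f"species table needs columns {sorted(required)}")
    bad = set(df["diet"]) - set(DIET_CATEGORIES)
    if bad:
        raise FormatError(f"unknown diet categories: {sorted(bad)}")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise FormatError(f"duplicate species: {dup}")
    return df


def check_tree_matches_table(tree, table: pd.DataFrame) -> None:
    """Raise if tree tips and species-table rows are not the same set."""
    tips = set(tree.tip_labels)
    species = set(table["species"])
    if tips != species:
        raise FormatError(
            f"tree/table mismatch: only in tree {sorted(tips - species)}, "
            f"only in table {sorted(species - tips)}")
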