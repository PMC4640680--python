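"""Mesh file I/O: TetGen .node/.ele pairs and legacy ASCII VTK grids.

TetGen files are 1-based on disk; indices are converted to the internal
0-based convention on read and back on write.  Both readers validate the
mesh (positive volumes, conformity) before returning it.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

from .mesh import TetMesh


class MeshParseError(ValueError):
    """Malformed mesh file; the message names the offending file and line."""


def _tokens(path):
    """Yield (line_number, token_list) skipping blanks and # comments."""
    with open(path, "r") as fh:
        for i, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if body:
                yield i, body.split()


def read_tetgen(basename: str) -> TetMesh:
    """Read a TetGen ``basename.node`` / ``basename.ele`` pair."""
    base, ext = os.path.splitext(basename)
    if ext in (".node", ".ele"):
        basename = base
    node_path = basename + ".node"
    ele_path = basename + ".ele"

    rows = list(_tokens(node_path))
    if not rows:
        raise MeshParseError(f"{node_path}: empty file")
    ln, header = rows[0]
    try:
        n_nodes = int(header[0])
    except (ValueError, IndexError):
        raise MeshParseError(f"{node_path}:{ln}: bad node header")
    if len(rows) - 1 < n_nodes:
        raise MeshParseError(f"{node_path}: header promises {n_nodes} nodes")
    ids = np.empty(n_nodes, dtype=np.int64)
    coords = np.empty((n_nodes, 3))
    for k in range(n_nodes):
        ln, tok = rows[1 + k]
        try:
            ids[k] = int(tok[0])
            coords[k] = [float(tok[1]), float(tok[2]), float(tok[3])]
        except (ValueError, IndexError):
            raise MeshParseError(f"{node_path}:{ln}: bad node row")
    first = int(ids[0])  # TetGen allows 0- or 1-based numbering
    if first not in (0, 1):
        raise MeshParseError(f"{node_path}: node numbering must start at 0 or 1")

    rows = list(_tokens(ele_path))
    if not rows:
        raise MeshParseError(f"{ele_path}: empty file")
    ln, header = rows[0]
    try:
        n_ele = int(header[0])
    except (ValueError, IndexError):
        raise MeshParseError(f"{ele_path}:{ln}: bad element header")
    if len(rows) - 1 < n_ele:
        raise MeshParseError(f"{ele_path}: header promises {n_ele} elements")
    elements = np.empty((n_ele, 4), dtype=np.int64)
    for k in range(n_ele):
        ln, tok = rows[1 + k]
        try:
            elements[k] = [int(t) for t in tok[1:5]]
        except (ValueError, IndexError):
            raise MeshParseError(f"{ele_path}:{ln}: bad element row")
        if elements[k].min() < first or elements[k].max() - first >= n_nodes:
            raise MeshParseError(
                f"{ele_path}:{ln}: node index out of range (file has {n_nodes} nodes)"
            )
    mesh = TetMesh(coords, elements - first)
    mesh.validate()
    return mesh


def write_tetgen(mesh: TetMesh, basename: str) -> None:
    """Write ``basename.node`` / ``basename.ele`` with 1-based indices."""
    base, ext = os.path.splitext(basename)
    if ext in (".node", ".ele"):
        basename = base
    with open(basename + ".node", "w") as fh:
        fh.write(f"{mesh.node_count} 3 0 0\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {x:.12g} {y:.12g} {z:.12g}\n")
    with open(basename + ".ele", "w") as fh:
        fh.write(f"{mesh.element_count} 4 0\n")
        for i, row in enumerate(mesh.elements + 1, start=1):
            fh.write(f"{i} {row[0]} {row[1]} {row[2]} {row[3]}\n")


def read_vtk(path: str) -> TetMesh:
    """Read a legacy ASCII VTK unstructured grid of tetrahedra (cell type 10)."""
    with open(path, "r") as fh:
        lines = fh.readlines()
    i = 0
    n = len(lines)
    coords = None
    cells = None
    cell_types = None
    while i < n:
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0].upper()
        if key == "DATASET":
            if len(tok) < 2 or tok[1].upper() != "UNSTRUCTURED_GRID":
                raise MeshParseError(f"{path}:{i + 1}: expected UNSTRUCTURED_GRID")
            i += 1
        elif key == "POINTS":
            n_pts = int(tok[1])
            vals = []
            i += 1
            while len(vals) < 3 * n_pts and i < n:
                vals.extend(float(t) for t in lines[i].split())
                i += 1
            if len(vals) < 3 * n_pts:
                raise MeshParseError(f"{path}: truncated POINTS block")
            coords = np.array(vals[: 3 * n_pts]).reshape(n_pts, 3)
        elif key == "CELLS":
            n_cells = int(tok[1])
            total = int(tok[2])
            vals = []
            i += 1
            while len(vals) < total and i < n:
                vals.extend(int(t) for t in lines[i].split())
                i += 1
            cells = []
            k = 0
            for _ in range(n_cells):
                cnt = vals[k]
                cells.append(vals[k + 1 : k + 1 + cnt])
                k += 1 + cnt
        elif key == "CELL_TYPES":
            n_ct = int(tok[1])
            vals = []
            i += 1
            while len(vals) < n_ct and i < n:
                vals.extend(int(t) for t in lines[i].split())
                i += 1
            cell_types = vals
        else:
            i += 1
    if coords is None or cells is None or cell_types is None:
        raise MeshParseError(f"{path}: missing POINTS/CELLS/CELL_TYPES block")
    elements = []
    for c, t in zip(cells, cell_types):
        if t != 10:
            continue  # ignore non-tet cells (e.g. embedded surface triangles)
        if len(c) != 4:
            raise MeshParseError(f"{path}: tetra cell with {len(c)} nodes")
        elements.append(c)
    if not elements:
        raise MeshParseError(f"{path}: no tetrahedral (type 10) cells found")
    bad = [idx for row in elements for idx in row if idx < 0 or idx >= len(coords)]
    if bad:
        raise MeshParseError(f"{path}: cell references node index {bad[0]}")
    mesh = TetMesh(coords, np.array(elements, dtype=np.int64))
    mesh.validate()
    return mesh


def write_vtk(mesh: TetMesh, path: str, point_data: Optional[dict] = None) -> None:
    """Write a legacy ASCII VTK unstructured grid, optionally with nodal scalars."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tetrahedral mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.node_count} double\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
        m = mesh.element_count
        fh.write(f"CELLS {m} {5 * m}\n")
        for row in mesh.elements:
            fh.write(f"4 {row[0]} {row[1]} {row[2]} {row[3]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["10"] * m) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.node_count}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.12g}" for v in np.asarray(values)) + "\n")


def read_mesh(path: str, fmt: Optional[str] = None) -> TetMesh:
    """Read a mesh, inferring the format from the extension when not given."""
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "vtk" if ext == ".vtk" else "tetgen"
    if fmt == "tetgen":
        return read_tetgen(path)
    if fmt == "vtk":
        return read_vtk(path)
    raise ValueError(f"unknown mesh format: {fmt}")


def write_mesh(mesh: TetMesh, path: str, fmt: Optional[str] = None) -> None:
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "vtk" if ext == ".vtk" else "tetgen"
    if fmt == "tetgen":
        write_tetgen(mesh, path)
    elif fmt == "vtk":
        write_vtk(mesh, path)
    else:
        raise ValueError(f"unknown mesh format: {fmt}")
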