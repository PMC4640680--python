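"""Tetrahedral mesh container and geometry queries.

Everything downstream (photon transport, Jacobian assembly, adaptation,
field transfer) operates on :class:`TetMesh`: a flat array of node
coordinates in millimetres plus an array of 4-node connectivity rows.
Elements follow a fixed orientation convention: the signed volume
``det([v1-v0, v2-v0, v3-v0]) / 6`` must be strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

#: Sentinel returned by point location when no element contains the point.
OUTSIDE = -1


def tet_volume(coords: np.ndarray) -> float:
    """Unsigned volume (mm^3) of the tetrahedron spanned by four 3D points.

    Returns 0 for degenerate (coplanar) point sets.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (4, 3):
        raise ValueError("tet_volume expects four 3D points")
    e = coords[1:] - coords[0]
    return abs(np.linalg.det(e)) / 6.0


def signed_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed volumes of all elements under the orientation convention."""
    v = nodes[elements]
    e = v[:, 1:, :] - v[:, :1, :]
    return np.linalg.det(e) / 6.0


# local faces opposite each local vertex, ordered so that for a positively
# oriented tet the cross product of the first two edges points outward
_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]], dtype=np.int64)


@dataclass
class TetMesh:
    """Conforming tetrahedral mesh: node coordinates (mm) and connectivity.

    Parameters
    ----------
    nodes : (N, 3) float array
    elements : (M, 4) int array
        Each row indexes ``nodes``; positive signed volume required.
    """

    nodes: np.ndarray
    elements: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (M, 4)")

    # -- basic counts ----------------------------------------------------
    @property
    def node_count(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def element_count(self) -> int:
        return int(self.elements.shape[0])

    def copy(self) -> "TetMesh":
        return TetMesh(self.nodes.copy(), self.elements.copy())

    # -- cached geometry -------------------------------------------------
    def element_volumes(self) -> np.ndarray:
        if "volumes" not in self._cache:
            self._cache["volumes"] = signed_volumes(self.nodes, self.elements)
        return self._cache["volumes"]

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def node_volumes(self) -> np.ndarray:
        """Nodal volume share: 1/4 of the volume of each incident element."""
        if "node_volumes" not in self._cache:
            vols = self.element_volumes()
            nv = np.zeros(self.node_count)
            np.add.at(nv, self.elements.ravel(), np.repeat(vols / 4.0, 4))
            self._cache["node_volumes"] = nv
        return self._cache["node_volumes"]

    def faces(self) -> np.ndarray:
        """All (M, 4, 3) element faces with sorted node triples."""
        f = self.elements[:, _FACE_LOCAL]  # (M, 4, 3)
        return np.sort(f, axis=2)

    def boundary_faces(self) -> np.ndarray:
        """(F, 3) sorted node triples of faces on exactly one element."""
        if "boundary_faces" not in self._cache:
            f = self.faces().reshape(-1, 3)
            uniq, counts = np.unique(f, axis=0, return_counts=True)
            self._cache["boundary_faces"] = uniq[counts == 1]
        return self._cache["boundary_faces"]

    def boundary_node_mask(self) -> np.ndarray:
        if "boundary_mask" not in self._cache:
            mask = np.zeros(self.node_count, dtype=bool)
            bf = self.boundary_faces()
            if bf.size:
                mask[np.unique(bf.ravel())] = True
            self._cache["boundary_mask"] = mask
        return self._cache["boundary_mask"]

    def bbox_diagonal(self) -> float:
        lo = self.nodes.min(axis=0)
        hi = self.nodes.max(axis=0)
        return float(np.linalg.norm(hi - lo))

    def node_to_elements(self) -> List[np.ndarray]:
        if "node_to_elements" not in self._cache:
            order = np.argsort(self.elements.ravel(), kind="stable")
            elem_ids = np.repeat(np.arange(self.element_count), 4)[order]
            sorted_nodes = self.elements.ravel()[order]
            bounds = np.searchsorted(sorted_nodes, np.arange(self.node_count + 1))
            self._cache["node_to_elements"] = [
                elem_ids[bounds[i] : bounds[i + 1]] for i in range(self.node_count)
            ]
        return self._cache["node_to_elements"]

    def neighbors(self) -> np.ndarray:
        """(M, 4) neighbor element across each local face; -1 on boundary."""
        if "neighbors" not in self._cache:
            f = self.faces().reshape(-1, 3)
            elem_ids = np.repeat(np.arange(self.element_count), 4)
            local = np.tile(np.arange(4), self.element_count)
            # lexicographic sort of face triples; shared faces become adjacent
            order = np.lexsort((f[:, 2], f[:, 1], f[:, 0]))
            fs = f[order]
            es = elem_ids[order]
            ls = local[order]
            nb = np.full((self.element_count, 4), -1, dtype=np.int64)
            same = np.all(fs[:-1] == fs[1:], axis=1)
            idx = np.nonzero(same)[0]
            nb[es[idx], ls[idx]] = es[idx + 1]
            nb[es[idx + 1], ls[idx + 1]] = es[idx]
            self._cache["neighbors"] = nb
        return self._cache["neighbors"]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise ValueError on any broken mesh invariant."""
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= self.node_count
        ):
            raise ValueError("element references a node index out of range")
        row_sorted = np.sort(self.elements, axis=1)
        if np.any(row_sorted[:, :-1] == row_sorted[:, 1:]):
            raise ValueError("element with duplicate node indices")
        sv = signed_volumes(self.nodes, self.elements)
        if np.any(sv <= 0):
            bad = int(np.argmin(sv))
            raise ValueError(
                f"element {bad} has nonpositive signed volume ({sv[bad]:.3e} mm^3)"
            )
        f = self.faces().reshape(-1, 3)
        _, counts = np.unique(f, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise ValueError("non-conforming mesh: face shared by >2 elements")


def edge_set(mesh: TetMesh) -> Dict[Tuple[int, int], List[int]]:
    """Undirected edges of the mesh with their incident element lists.

    Returns a dict keyed by ``(i, j)`` with ``i < j``.
    """
    out: Dict[Tuple[int, int], List[int]] = {}
    combos = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    elems = mesh.elements
    for e in range(mesh.element_count):
        row = elems[e]
        for a, b in combos:
            i, j = int(row[a]), int(row[b])
            if i > j:
                i, j = j, i
            out.setdefault((i, j), []).append(e)
    return out


# -- element quality -----------------------------------------------------

def element_qualities(mesh: TetMesh) -> np.ndarray:
    """Scale-invariant radius-ratio quality 3*r_in/R per element.

    1 for the regular tetrahedron, -> 0 for slivers and degenerate tets.
    """
    v = mesh.nodes[mesh.elements]
    vols = np.abs(signed_volumes(mesh.nodes, mesh.elements))
    # inradius = 3V / (sum of face areas)
    areas = np.zeros(mesh.element_count)
    for f in range(4):
        tri = v[:, _FACE_LOCAL[f], :]
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        areas += 0.5 * np.linalg.norm(cr, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_in = np.where(areas > 0, 3.0 * vols / areas, 0.0)
    # circumradius from the linear system 2 (v_i - v_0) . c = |v_i|^2 - |v_0|^2
    a = 2.0 * (v[:, 1:, :] - v[:, :1, :])
    rhs = np.einsum("mij,mij->mi", v[:, 1:, :], v[:, 1:, :]) - np.einsum(
        "mj,mj->m", v[:, 0, :], v[:, 0, :]
    )[:, None]
    det = np.linalg.det(a)
    q = np.zeros(mesh.element_count)
    ok = np.abs(det) > 1e-300
    if np.any(ok):
        center = np.linalg.solve(a[ok], rhs[ok][..., None])[..., 0]
        r_circ = np.linalg.norm(center - v[ok, 0, :], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            q[ok] = np.where(r_circ > 0, 3.0 * r_in[ok] / r_circ, 0.0)
    return np.clip(q, 0.0, 1.0)


def min_quality(mesh: TetMesh) -> float:
    """Minimum element quality over the mesh (1 regular, -> 0 sliver)."""
    q = element_qualities(mesh)
    return float(q.min()) if q.size else 1.0


# -- point location ------------------------------------------------------

def _bary_setup(mesh: TetMesh):
    """Cache per-element inverse affine maps for barycentric evaluation."""
    if "bary" not in mesh._cache:
        v = mesh.nodes[mesh.elements]
        edges = np.transpose(v[:, 1:, :] - v[:, :1, :], (0, 2, 1))  # (M,3,3) columns
        tinv = np.linalg.inv(edges)
        mesh._cache["bary"] = (tinv, v[:, 0, :].copy())
    return mesh._cache["bary"]


def barycentric(mesh: TetMesh, elem: int, point: np.ndarray) -> np.ndarray:
    """Barycentric coordinates (4,) of a point w.r.t. one element."""
    tinv, v0 = _bary_setup(mesh)
    b = tinv[elem] @ (np.asarray(point, dtype=float) - v0[elem])
    return np.concatenate(([1.0 - b.sum()], b))


def locate_points(mesh: TetMesh, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Containing element per point (lowest element index on ties), or OUTSIDE.

    Brute-force barycentric test against every element, chunked over elements
    in ascending index order so shared-face ties resolve deterministically.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tinv, v0 = _bary_setup(mesh)
    n_pts = points.shape[0]
    result = np.full(n_pts, OUTSIDE, dtype=np.int64)
    unresolved = np.arange(n_pts)
    chunk = max(1, int(2e7 // max(n_pts, 1)))
    for start in range(0, mesh.element_count, chunk):
        if unresolved.size == 0:
            break
        stop = min(start + chunk, mesh.element_count)
        d = points[unresolved][:, None, :] - v0[None, start:stop, :]  # (p,c,3)
        b = np.einsum("cij,pcj->pci", tinv[start:stop], d)
        b0 = 1.0 - b.sum(axis=2)
        inside = (b >= -tol).all(axis=2) & (b0 >= -tol)
        hit_any = inside.any(axis=1)
        if np.any(hit_any):
            first = start + np.argmax(inside[hit_any], axis=1)
            result[unresolved[hit_any]] = first
            unresolved = unresolved[~hit_any]
    return result


def locate_point(mesh: TetMesh, point, tol: float = 1e-9) -> int:
    """Element containing ``point`` (all barycentrics >= -tol), or OUTSIDE.

    Walks from the element ring of the nearest node; falls back to the
    deterministic brute-force scan when the walk exits the mesh or the hit
    is not strictly interior (shared-face ties go to the lowest element
    index).
    """
    point = np.asarray(point, dtype=float)
    nearest = int(np.argmin(np.einsum("ij,ij->i", mesh.nodes - point, mesh.nodes - point)))
    ring = mesh.node_to_elements()[nearest]
    if ring.size:
        nb = mesh.neighbors()
        elem = int(ring[0])
        for _ in range(4 * mesh.element_count):
            b = barycentric(mesh, elem, point)
            worst = int(np.argmin(b))
            if b[worst] >= -tol:
                if b[worst] > tol:  # strictly interior: unambiguous
                    return elem
                break  # on a face: defer to deterministic scan
            nxt = nb[elem, worst]
            if nxt < 0:
                break
            elem = int(nxt)
    return int(locate_points(mesh, point[None, :], tol)[0])
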