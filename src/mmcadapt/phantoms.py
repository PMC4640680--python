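"""Synthetic phantoms: slab and extruded elliptical slice with optodes.

Desk-scale stand-ins for a mouse-torso cross section: a rectangular slab
and a 4 mm thick elliptical slice probed by 7 source / 7 detector pairs in
transmission geometry.  Generation is fully deterministic — same
parameters, same mesh, bit for bit.
"""

from __future__ import annotations

from typing import List

import numpy as np
from scipy.spatial import Delaunay

from .mesh import TetMesh, signed_volumes
from .optics import Optode, OpticalProperties


def default_properties() -> OpticalProperties:
    """Average NIR optical properties of mouse tissue.

    mu_a = 0.3 cm^-1, mu_s' = 15 cm^-1, g = 0.9, n = 1.37 (stored in mm^-1:
    0.03 and 1.5).
    """
    return OpticalProperties.from_cm(0.3, 15.0, 0.9, 1.37)


def _orient_positive(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    sv = signed_volumes(nodes, elements)
    flip = sv < 0
    if np.any(flip):
        elements = elements.copy()
        elements[flip, 2], elements[flip, 3] = (
            elements[flip, 3].copy(),
            elements[flip, 2].copy(),
        )
    return elements


# Kuhn subdivision of the unit cube into 6 tets along the main diagonal;
# identical in every cell, which makes the grid conforming.
_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def make_slab_mesh(lx: float, ly: float, lz: float, h: float) -> TetMesh:
    """Structured slab [0,lx]x[0,ly]x[0,lz]; each box split into 6 tets.

    Total volume is exactly lx*ly*lz.  ``h`` is the target box edge; the
    box counts are rounded to cover each side exactly.
    """
    if min(lx, ly, lz) <= 0 or h <= 0:
        raise ValueError("dimensions and h must be positive")
    if h > min(lx, ly, lz):
        raise ValueError("h must not exceed the smallest slab dimension")
    nx, ny, nz = (max(1, round(l / h)) for l in (lx, ly, lz))
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elements = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = np.array([i, j, k])
                for perm in _PERMS:
                    path = [corner.copy()]
                    cur = corner.copy()
                    for ax in perm:
                        cur = cur.copy()
                        cur[ax] += 1
                        path.append(cur)
                    elements.append([nid(*p) for p in path])
    elements = _orient_positive(nodes, np.array(elements, dtype=np.int64))
    return TetMesh(nodes, elements)


def _ellipse_points_2d(a: float, b: float, h: float) -> np.ndarray:
    """Boundary ring plus interior grid points of an ellipse, spacing ~h."""
    perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    n_ring = max(12, int(round(perimeter / h)))
    theta = 2 * np.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    xs = np.arange(-a, a + h / 2, h)
    ys = np.arange(-b, b + h / 2, h)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    rho = np.sqrt((pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2)
    # keep interior points clear of the ring to avoid sliver triangles
    margin = 0.45 * h / min(a, b)
    inner = pts[rho <= 1.0 - margin]
    return np.vstack([ring, inner])


def make_slice_phantom(
    a: float = 12.0, b: float = 8.0, thickness: float = 4.0, h: float = 1.0
) -> TetMesh:
    """Extruded elliptical slice (semi-axes a, b mm; given thickness).

    The 2D cross section is Delaunay-triangulated (the ellipse is convex,
    so the triangulation covers the inscribed polygon exactly) and each
    triangular prism layer is split into 3 tets with the diagonal rule
    keyed on global node ids, which keeps the mesh conforming.
    """
    if min(a, b, thickness, h) <= 0:
        raise ValueError("parameters must be positive")
    if h > thickness and round(thickness / h) < 1:
        raise ValueError("h too large for the slice thickness")
    pts2d = _ellipse_points_2d(a, b, h)
    tri = Delaunay(pts2d)
    simplices = np.sort(tri.simplices, axis=1)  # sorted ids drive the prism rule
    n2d = pts2d.shape[0]
    nz = max(1, round(thickness / h))
    zs = np.linspace(0, thickness, nz + 1)
    nodes = np.concatenate(
        [np.column_stack([pts2d, np.full(n2d, z)]) for z in zs], axis=0
    )
    elements = []
    for k in range(nz):
        lo = k * n2d
        hi = (k + 1) * n2d
        for s in simplices:
            b0, b1, b2 = lo + s[0], lo + s[1], lo + s[2]
            t0, t1, t2 = hi + s[0], hi + s[1], hi + s[2]
            elements.append([b0, b1, b2, t2])
            elements.append([b0, b1, t1, t2])
            elements.append([b0, t0, t1, t2])
    elements = _orient_positive(nodes, np.array(elements, dtype=np.int64))
    return TetMesh(nodes, elements)


def place_transmission_optodes(
    mesh: TetMesh, n_sources: int = 7, n_detectors: int = 7
) -> List[Optode]:
    """Sources fanned over one side of the boundary, detectors mirrored.

    Optodes snap to boundary-ring nodes of the layer nearest the mid-plane
    of the extrusion axis (z); directions point inward toward the ring
    centroid.  Sources span polar angles pi/4..3pi/4 (the +y side),
    detectors the mirrored -y side.
    """
    if n_sources < 1 or n_detectors < 1:
        raise ValueError("need at least one source and one detector")
    mask = mesh.boundary_node_mask()
    bnodes = np.nonzero(mask)[0]
    if bnodes.size == 0:
        raise ValueError("mesh has no boundary nodes")
    coords = mesh.nodes[bnodes]
    z_mid = 0.5 * (mesh.nodes[:, 2].min() + mesh.nodes[:, 2].max())
    dz = np.abs(coords[:, 2] - z_mid)
    layer = bnodes[dz <= dz.min() + 1e-9]
    lc = mesh.nodes[layer]
    center = lc.mean(axis=0)
    half = np.maximum(np.abs(lc - center).max(axis=0), 1e-12)

    def pick(angles: np.ndarray, kind: str) -> List[Optode]:
        out = []
        used: set = set()
        for th in angles:
            target = center + np.array(
                [half[0] * np.cos(th), half[1] * np.sin(th), 0.0]
            )
            d2 = np.einsum("ij,ij->i", lc - target, lc - target)
            order = np.argsort(d2, kind="stable")
            j = next((int(o) for o in order if int(layer[o]) not in used), int(order[0]))
            used.add(int(layer[j]))
            pos = mesh.nodes[layer[j]]
            direction = center + np.array([0.0, 0.0, 0.0]) - pos
            direction[2] = 0.0
            out.append(Optode(pos, direction, kind))
        return out

    src_angles = np.pi / 2 + np.linspace(-np.pi / 4, np.pi / 4, n_sources)
    det_angles = -src_angles
    return pick(src_angles, "source") + pick(det_angles, "detector")
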