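"""Inverse-distance transfer operator between meshes and Jacobian rescaling.

The transformation matrix T has one row per input-mesh node and one
column per output-mesh node.  Each output node falls into one of three
cases: (1) it coincides with an input node and the value is carried over
unchanged; (2) it lies inside an input element and gets the inverse-
distance-weighted combination of that element's 4 vertices; (3) it lies
outside the input mesh and gets the inverse-distance combination of the
4 nearest input nodes.  Weights w_i = 1/d(x, x_i) are normalized to sum
to one, so every column of T sums to exactly 1 and constant fields are
preserved.  A rescaled Jacobian is just W @ T per (pair, gate) slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .jacobian import Jacobian, mesh_hash
from .mesh import TetMesh, locate_points, OUTSIDE

CASE_CARRIED = 0
CASE_INTERIOR = 1
CASE_EXTERIOR = 2


@dataclass
class TransformationMatrix:
    """Sparse (input nodes x output nodes) operator with unit column sums."""

    matrix: sp.csc_matrix
    cases: np.ndarray  # per output node: CASE_CARRIED | CASE_INTERIOR | CASE_EXTERIOR

    @property
    def shape(self):
        return self.matrix.shape

    def compose(self, other: "TransformationMatrix") -> "TransformationMatrix":
        """Chain two transfers: self (A -> B) then other (B -> C)."""
        return TransformationMatrix(
            (self.matrix @ other.matrix).tocsc(), other.cases.copy()
        )


def build_transformation(
    old_mesh: TetMesh, new_mesh: TetMesh, tol: float | None = None
) -> TransformationMatrix:
    """Build the inverse-distance transfer operator old -> new.

    ``tol`` is the coincidence tolerance of the carried-over case; default
    1e-9 times the input-mesh bounding-box diagonal.  Zero distances in
    the weighted cases degenerate to the carried case.  Nearest-node ties
    resolve to the lowest node index (cKDTree with exact distances).
    """
    if old_mesh.node_count == 0:
        raise ValueError("input mesh has no nodes")
    if tol is None:
        tol = 1e-9 * old_mesh.bbox_diagonal()
    pts = new_mesh.nodes
    n_new = new_mesh.node_count
    tree = cKDTree(old_mesh.nodes)
    d_near, i_near = tree.query(pts)
    cases = np.empty(n_new, dtype=np.int8)
    rows = []
    cols = []
    vals = []

    carried = d_near <= tol
    cases[carried] = CASE_CARRIED
    rows.append(i_near[carried])
    cols.append(np.nonzero(carried)[0])
    vals.append(np.ones(int(carried.sum())))

    todo = np.nonzero(~carried)[0]
    if todo.size:
        elems = locate_points(old_mesh, pts[todo])
        inside = elems != OUTSIDE
        for subset, case in ((inside, CASE_INTERIOR), (~inside, CASE_EXTERIOR)):
            idx = todo[subset]
            if idx.size == 0:
                continue
            cases[idx] = case
            if case == CASE_INTERIOR:
                support = old_mesh.elements[elems[subset]]  # (k, 4)
            else:
                _, support = tree.query(pts[idx], k=4)
                support = np.atleast_2d(support)
            diff = old_mesh.nodes[support] - pts[idx][:, None, :]
            d = np.linalg.norm(diff, axis=2)  # (k, 4)
            w = 1.0 / np.maximum(d, 1e-300)
            # a vanishing distance degenerates to the carried case
            zero = d <= tol
            has_zero = zero.any(axis=1)
            w[has_zero] = zero[has_zero].astype(float)
            w /= w.sum(axis=1, keepdims=True)
            rows.append(support.ravel())
            cols.append(np.repeat(idx, 4))
            vals.append(w.ravel())

    t = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(old_mesh.node_count, n_new),
    )
    # exact unit column sums (duplicate-entry accumulation can perturb)
    colsum = np.asarray(t.sum(axis=0)).ravel()
    t = t @ sp.diags(1.0 / colsum)
    return TransformationMatrix(t.tocsc(), cases)


def rescale(w: Jacobian, t: TransformationMatrix, new_mesh: TetMesh | None = None) -> Jacobian:
    """Rescale a Jacobian onto the output mesh: each slice right-multiplied by T."""
    if w.n_nodes != t.shape[0]:
        raise ValueError(
            f"Jacobian node dimension {w.n_nodes} != transformation rows {t.shape[0]}"
        )
    flat = w.W.reshape(-1, w.n_nodes)
    out = (t.matrix.T @ flat.T).T
    return Jacobian(
        W=np.ascontiguousarray(out.reshape(w.n_pairs, w.n_gates, t.shape[1])),
        pairs=list(w.pairs),
        gating=w.gating,
        mesh_hash=mesh_hash(new_mesh) if new_mesh is not None else "",
    )


def barycentric_transformation(
    old_mesh: TetMesh, new_mesh: TetMesh, tol: float | None = None
) -> TransformationMatrix:
    """Opt-in comparison mode: linear-shape-function (barycentric) weights.

    Same structure as :func:`build_transformation` but interior columns use
    barycentric coordinates instead of inverse distances.  Not the primary
    path; provided for studying the interpolation model itself.
    """
    if tol is None:
        tol = 1e-9 * old_mesh.bbox_diagonal()
    base = build_transformation(old_mesh, new_mesh, tol)
    pts = new_mesh.nodes
    interior = np.nonzero(base.cases == CASE_INTERIOR)[0]
    if interior.size == 0:
        return base
    elems = locate_points(old_mesh, pts[interior])
    from .mesh import _bary_setup

    tinv, v0 = _bary_setup(old_mesh)
    b = np.einsum("kij,kj->ki", tinv[elems], pts[interior] - v0[elems])
    bary = np.column_stack([1.0 - b.sum(axis=1), b])
    bary = np.clip(bary, 0.0, None)
    bary /= bary.sum(axis=1, keepdims=True)
    t = base.matrix.tolil()
    for col, e, wts in zip(interior, elems, bary):
        t[:, col] = 0.0
        for node, wt in zip(old_mesh.elements[e], wts):
            t[node, col] = wt
    return TransformationMatrix(t.tocsc(), base.cases)
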