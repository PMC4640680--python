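"""Transformation-matrix construction and Jacobian rescaling."""

import numpy as np
import pytest
import scipy.sparse as sp

from mmcadapt.jacobian import Jacobian
from mmcadapt.mesh import OUTSIDE, TetMesh, locate_points
from mmcadapt.optics import Optode, TimeGating
from mmcadapt.phantoms import make_slab_mesh
from mmcadapt.transfer import (
    CASE_CARRIED,
    CASE_EXTERIOR,
    CASE_INTERIOR,
    build_transformation,
    rescale,
)


def idw_oracle_column(old_mesh, point, tol):
    """Independent 3-case inverse-distance weights for one output node."""
    d_all = np.linalg.norm(old_mesh.nodes - point, axis=1)
    nearest = int(np.argmin(d_all))
    col = np.zeros(old_mesh.node_count)
    if d_all[nearest] <= tol:
        col[nearest] = 1.0
        return col, CASE_CARRIED
    elem = locate_points(old_mesh, point[None, :])[0]
    if elem != OUTSIDE:
        support = old_mesh.elements[elem]
        case = CASE_INTERIOR
    else:
        support = np.argsort(d_all, kind="stable")[:4]
        case = CASE_EXTERIOR
    w = 1.0 / d_all[support]
    col[support] = w / w.sum()
    return col, case


@pytest.fixture()
def old_mesh():
    return make_slab_mesh(6.0, 6.0, 4.0, 2.0)


def _jac_on(mesh, n_pairs=2, n_gates=3, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.random((n_pairs, n_gates, mesh.node_count))
    src = Optode([0, 0, 0], [0, 0, 1], "source")
    det = Optode([0, 0, 1], [0, 0, -1], "detector")
    return Jacobian(w, [(src, det)] * n_pairs, TimeGating(1.0, n_gates))


class TestBuildTransformation:
    def test_identity_on_identical_meshes(self, old_mesh):
        t = build_transformation(old_mesh, old_mesh)
        assert np.all(t.cases == CASE_CARRIED)
        assert (t.matrix != sp.identity(old_mesh.node_count, format="csc")).nnz == 0

    def test_unit_column_sums(self, old_mesh):
        new = make_slab_mesh(6.0, 6.0, 4.0, 1.5)
        t = build_transformation(old_mesh, new)
        colsums = np.asarray(t.matrix.sum(axis=0)).ravel()
        assert np.max(np.abs(colsums - 1.0)) <= 1e-12

    def test_centroid_of_regular_tet_gets_quarter_weights(self):
        nodes = np.array(
            [[0, 0, 0], [1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=float
        )
        old = TetMesh(nodes, np.array([[0, 1, 2, 3]]))
        centroid = nodes.mean(axis=0)
        new = TetMesh(
            np.vstack([nodes + 10.0, centroid]),  # carried far away + 1 interior
            np.array([[0, 1, 2, 3]]),
        )
        t = build_transformation(old, new)
        col = t.matrix[:, 4].toarray().ravel()
        assert np.allclose(col, 0.25, atol=1e-12)

    def test_unit_right_tet_interior_weights(self):
        """Inverse-distance weights at (0.25, 0.25, 0.25): the corner at the
        origin (distance 0.4330) outweighs the three at distance 0.8292."""
        nodes = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        old = TetMesh(nodes, np.array([[0, 1, 2, 3]]))
        new = TetMesh(
            np.vstack([nodes + 10.0, [0.25, 0.25, 0.25]]),
            np.array([[0, 1, 2, 3]]),
        )
        t = build_transformation(old, new)
        col = t.matrix[:, 4].toarray().ravel()
        assert np.allclose(col, [0.390, 0.203, 0.203, 0.203], atol=5e-4)

    def test_matches_oracle_on_random_points(self, old_mesh):
        """100 random output nodes (inside and outside) against the
        independent per-node 3-case evaluation."""
        rng = np.random.default_rng(21)
        pts = np.vstack(
            [
                rng.uniform([0, 0, 0], [6, 6, 4], size=(60, 3)),    # interior
                rng.uniform([-3, -3, -2], [0, 0, 0], size=(20, 3)),  # exterior
                old_mesh.nodes[rng.integers(0, old_mesh.node_count, 20)],  # carried
            ]
        )
        # wrap the query points in a throwaway mesh (geometry-only columns)
        filler = np.array([[50, 0, 0], [51, 0, 0], [50, 1, 0], [50, 0, 1.0]])
        new = TetMesh(np.vstack([filler, pts]), np.array([[0, 1, 2, 3]]))
        tol = 1e-9 * old_mesh.bbox_diagonal()
        t = build_transformation(old_mesh, new)
        dense = t.matrix.toarray()
        for i, p in enumerate(pts):
            col, case = idw_oracle_column(old_mesh, p, tol)
            assert t.cases[4 + i] == case
            assert np.allclose(dense[:, 4 + i], col, atol=1e-12)


class TestRescale:
    def test_identity_keeps_jacobian(self, old_mesh):
        jac = _jac_on(old_mesh)
        t = build_transformation(old_mesh, old_mesh)
        out = rescale(jac, t)
        assert np.array_equal(out.W, jac.W)

    def test_constant_field_preserved(self, old_mesh):
        new = make_slab_mesh(6.0, 6.0, 4.0, 1.3)
        t = build_transformation(old_mesh, new)
        jac = _jac_on(old_mesh)
        jac.W[:] = 7.25
        out = rescale(jac, t)
        assert np.allclose(out.W, 7.25, rtol=1e-12)

    def test_values_match_per_node_oracle(self, old_mesh):
        new = make_slab_mesh(6.0, 6.0, 4.0, 1.5)
        t = build_transformation(old_mesh, new)
        jac = _jac_on(old_mesh, seed=5)
        out = rescale(jac, t, new)
        tol = 1e-9 * old_mesh.bbox_diagonal()
        for c in range(0, new.node_count, 7):
            col, _ = idw_oracle_column(old_mesh, new.nodes[c], tol)
            assert np.allclose(out.W[:, :, c], jac.W @ col, rtol=1e-10)

    def test_nonnegativity_and_range_preserved(self, old_mesh):
        new = make_slab_mesh(6.0, 6.0, 4.0, 1.1)
        t = build_transformation(old_mesh, new)
        jac = _jac_on(old_mesh, seed=6)
        out = rescale(jac, t)
        assert np.all(out.W >= 0)
        assert out.W.max() <= jac.W.max() + 1e-12
        assert out.W.min() >= jac.W.min() - 1e-12

    def test_composition_equals_chained(self, old_mesh):
        mid = make_slab_mesh(6.0, 6.0, 4.0, 1.5)
        fin = make_slab_mesh(6.0, 6.0, 4.0, 1.0)
        t1 = build_transformation(old_mesh, mid)
        t2 = build_transformation(mid, fin)
        jac = _jac_on(old_mesh, seed=7)
        chained = rescale(rescale(jac, t1), t2)
        composed = rescale(jac, t1.compose(t2))
        assert np.allclose(chained.W, composed.W, rtol=1e-12, atol=1e-14)

    def test_barycentric_mode_uses_shape_functions(self, old_mesh):
        """The opt-in comparison mode puts linear shape-function weights on
        interior columns while keeping unit column sums."""
        from mmcadapt.transfer import CASE_INTERIOR, barycentric_transformation

        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        old = TetMesh(nodes, np.array([[0, 1, 2, 3]]))
        p = np.array([0.1, 0.2, 0.3])
        new = TetMesh(np.vstack([nodes + 10.0, p]), np.array([[0, 1, 2, 3]]))
        t = barycentric_transformation(old, new)
        assert t.cases[4] == CASE_INTERIOR
        col = t.matrix[:, 4].toarray().ravel()
        assert np.allclose(col, [1 - p.sum(), *p], atol=1e-12)
        colsums = np.asarray(t.matrix.sum(axis=0)).ravel()
        assert np.max(np.abs(colsums - 1.0)) <= 1e-12

    def test_dimension_mismatch_rejected(self, old_mesh):
        new = make_slab_mesh(6.0, 6.0, 4.0, 1.5)
        t = build_transformation(old_mesh, new)
        with pytest.raises(ValueError):
            rescale(_jac_on(new), t)
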