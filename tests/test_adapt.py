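"""Edge split/collapse validity and the iterative adaptation loop."""

import numpy as np
import pytest

from mmcadapt.adapt import (
    AdaptConfig,
    Rejected,
    adapt_loop,
    adapt_once,
    collapse_edge,
    split_edge,
)
from mmcadapt.fields import SizeField, SizeFieldParams
from mmcadapt.mesh import TetMesh
from mmcadapt.phantoms import make_slab_mesh


@pytest.fixture()
def unit_tet():
    return TetMesh(
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float),
        np.array([[0, 1, 2, 3]]),
    )


@pytest.fixture()
def star_mesh():
    """Interior node M connected to all four corners of a big tet."""
    nodes = np.array(
        [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [1, 1, 1]], dtype=float
    )
    elements = np.array(
        [[4, 1, 2, 3], [0, 4, 2, 3], [0, 1, 4, 3], [0, 1, 2, 4]]
    )
    mesh = TetMesh(nodes, elements)
    mesh.validate()
    return mesh


class TestSplit:
    def test_unit_tet_bisection(self, unit_tet):
        out = split_edge(unit_tet, (0, 1))
        out.validate()
        assert out.node_count == 5
        assert out.element_count == 2
        assert np.allclose(np.sort(out.element_volumes()), [1 / 12, 1 / 12])

    def test_shared_edge_split_stays_conforming(self):
        nodes = np.array(
            [[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2], [2, 2, 2]], dtype=float
        )
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))
        mesh.validate()
        out = split_edge(mesh, (1, 2))  # edge on the shared face
        out.validate()
        assert out.element_count == 4
        assert out.node_count == 6

    def test_volume_conserved(self, slab_mesh):
        from mmcadapt.mesh import edge_set

        total = slab_mesh.total_volume()
        for edge in list(edge_set(slab_mesh))[::37]:
            out = split_edge(slab_mesh, edge)
            assert out.total_volume() == pytest.approx(total, rel=1e-12)

    def test_unknown_edge_rejected(self, unit_tet):
        with pytest.raises(ValueError):
            split_edge(unit_tet, (0, 7))


class TestCollapse:
    def test_interior_collapse_removes_node(self, star_mesh):
        out = collapse_edge(star_mesh, (0, 4), kept_node=0)
        assert not isinstance(out, Rejected)
        out.validate()
        assert out.node_count == 4
        assert out.element_count == 1
        assert out.total_volume() == pytest.approx(star_mesh.total_volume(), rel=1e-12)

    def test_boundary_into_interior_rejected(self, star_mesh):
        out = collapse_edge(star_mesh, (0, 4), kept_node=4)  # removes corner 0
        assert isinstance(out, Rejected)
        assert out.reason == "boundary"

    def test_inversion_guard_fires_somewhere(self):
        """On a structured grid, some collapses must invert an element."""
        mesh = make_slab_mesh(3.0, 3.0, 3.0, 1.0)
        from mmcadapt.mesh import edge_set

        boundary = mesh.boundary_node_mask()
        reasons = set()
        for (a, b) in edge_set(mesh):
            if boundary[a] or boundary[b]:
                continue
            for kept in (a, b):
                out = collapse_edge(mesh, (a, b), kept)
                if isinstance(out, Rejected):
                    reasons.add(out.reason)
                else:
                    out.validate()  # accepted collapses stay valid
        assert "inversion" in reasons

    def test_kept_node_must_be_endpoint(self, star_mesh):
        with pytest.raises(ValueError):
            collapse_edge(star_mesh, (0, 4), kept_node=2)


class TestAdaptOnce:
    def test_unit_size_field_is_fixed_point(self, slab_mesh):
        size = SizeField(np.ones(slab_mesh.node_count))
        out, rec = adapt_once(slab_mesh, size, AdaptConfig())
        assert out.node_count == slab_mesh.node_count
        assert out.element_count == slab_mesh.element_count
        assert rec.splits == 0 and rec.collapses == 0

    def test_coarsening_decreases_nodes(self):
        mesh = make_slab_mesh(10.0, 10.0, 4.0, 1.0)
        size = SizeField(np.full(mesh.node_count, 1.25))
        out, rec = adapt_once(mesh, size, AdaptConfig())
        out.validate()
        assert out.node_count < mesh.node_count
        assert rec.collapses > 0

    def test_refinement_increases_nodes(self):
        mesh = make_slab_mesh(8.0, 8.0, 8.0, 4.0)
        size = SizeField(np.full(mesh.node_count, 0.5))
        out, rec = adapt_once(mesh, size, AdaptConfig())
        out.validate()
        assert out.node_count > mesh.node_count
        assert rec.splits > 0
        assert out.total_volume() == pytest.approx(mesh.total_volume(), rel=1e-12)

    def test_deterministic(self):
        mesh = make_slab_mesh(10.0, 10.0, 4.0, 1.0)
        size = SizeField(np.full(mesh.node_count, 1.3))
        a, _ = adapt_once(mesh, size, AdaptConfig())
        b, _ = adapt_once(mesh, size, AdaptConfig())
        assert np.array_equal(a.elements, b.elements)
        assert np.array_equal(a.nodes, b.nodes)


class TestAdaptLoop:
    def test_geometry_recipe_on_converged_mesh(self, slab_mesh, slice_optodes):
        """A mesh already at target size converges in one iteration."""
        params = SizeFieldParams(1.0001, 1.0)
        res = adapt_loop(
            slab_mesh, "distance", params, AdaptConfig(), optodes=slice_optodes
        )
        assert res.report.status == "converged"
        assert res.report.records[0].nodes == slab_mesh.node_count

    def test_attenuation_monotone_coarsening(self, slice_mesh, slice_optodes, props):
        params = SizeFieldParams(1.25, 1.0)
        res = adapt_loop(
            slice_mesh, "attenuation", params, AdaptConfig(),
            optodes=slice_optodes, mu=props.mu_a + props.mu_s_prime,
        )
        counts = [r.nodes for r in res.report.records]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert res.report.status == "converged"
        res.mesh.validate()
        drift = abs(res.mesh.total_volume() - slice_mesh.total_volume())
        assert drift <= 0.02 * slice_mesh.total_volume()

    def test_volume_cutoff_stops_loop(self, slice_mesh, slice_optodes, props):
        cutoff = 0.25
        params = SizeFieldParams(1.25, 1.0)
        res = adapt_loop(
            slice_mesh, "attenuation", params,
            AdaptConfig(volume_cutoff=cutoff),
            optodes=slice_optodes, mu=props.mu_a + props.mu_s_prime,
        )
        assert res.report.status == "volume_cutoff"
        assert res.report.records[-1].max_elem_vol_mm3 >= cutoff
        for rec in res.report.records[:-1]:
            assert rec.max_elem_vol_mm3 < cutoff

    def test_jacobian_recipe_requires_jacobian(self, slice_mesh):
        with pytest.raises(ValueError, match="requires a Jacobian"):
            adapt_loop(slice_mesh, "sum_jacobian", SizeFieldParams(), AdaptConfig())
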