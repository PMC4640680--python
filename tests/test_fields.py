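"""Solution fields and the threshold/exponential size-factor map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmcadapt.fields import (
    SizeFieldParams,
    SolutionField,
    attenuation_field,
    curvature,
    distance_field,
    log_sum_jacobian,
    normalized_sum,
    sum_jacobian,
    to_size_field,
)
from mmcadapt.jacobian import Jacobian
from mmcadapt.optics import Optode, TimeGating


def _jac(w):
    gating = TimeGating(1.0, w.shape[1])
    src = Optode([0, 0, 0], [0, 0, 1], "source")
    det = Optode([0, 0, 1], [0, 0, -1], "detector")
    return Jacobian(w, [(src, det)] * w.shape[0], gating)


class TestJacobianFields:
    def test_sum_single_slice_is_identity(self):
        w = np.random.default_rng(0).random((1, 1, 6))
        assert np.allclose(sum_jacobian(_jac(w)).values, w[0, 0])

    def test_sum_matches_loop(self):
        rng = np.random.default_rng(1)
        w = rng.random((3, 4, 6))
        expected = np.array(
            [sum(w[p, g, r] for p in range(3) for g in range(4)) for r in range(6)]
        )
        assert np.allclose(sum_jacobian(_jac(w)).values, expected, rtol=1e-12)

    def test_log_sum(self):
        w = np.array([[[1.0, np.e, np.e**2]]])
        vals = log_sum_jacobian(_jac(w)).values
        assert np.allclose(vals, [0, 1, 2], atol=1e-5)

    def test_normalized_sum_unit_max_per_row(self):
        rng = np.random.default_rng(2)
        w = rng.random((1, 1, 8))
        assert normalized_sum(_jac(w)).values.max() == pytest.approx(1.0)
        w2 = np.concatenate([w, w], axis=1)  # two identical rows
        assert normalized_sum(_jac(w2)).values.max() == pytest.approx(2.0)

    def test_normalized_sum_matches_oracle(self):
        rng = np.random.default_rng(3)
        w = rng.random((2, 3, 7))
        flat = w.reshape(-1, 7)
        expected = sum(row / row.max() for row in flat)
        assert np.allclose(normalized_sum(_jac(w)).values, expected, rtol=1e-12)


class TestCurvature:
    def test_constant_annihilated(self):
        s = SolutionField(np.full(10, 3.7), "sum_jacobian")
        assert np.allclose(curvature(s).values, 0.0, atol=1e-12)

    def test_two_node_antisymmetry(self):
        s = SolutionField(np.array([1.0, 3.0]), "sum_jacobian")
        assert np.allclose(curvature(s).values, [-2.0, 2.0])

    def test_matches_dense_operator(self):
        rng = np.random.default_rng(5)
        v = rng.random(50)
        n = 50
        laplacian = np.full((n, n), -1.0 / (n - 1))
        np.fill_diagonal(laplacian, 1.0)
        assert np.allclose(curvature(SolutionField(v, "sum_jacobian")).values,
                           laplacian @ v, rtol=1e-12)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            curvature(SolutionField(np.array([1.0]), "sum_jacobian"))


class TestGeometryFields:
    def test_distance_at_optode_is_zero(self, slice_mesh, slice_optodes):
        f = distance_field(slice_mesh, slice_optodes)
        assert f.orientation == "coarsen_high"
        assert f.values.min() == pytest.approx(0.0, abs=1e-9)

    def test_distance_matches_brute_force(self, slice_mesh, slice_optodes):
        f = distance_field(slice_mesh, slice_optodes)
        pos = np.array([o.position for o in slice_optodes])
        for node in (0, 37, 512, slice_mesh.node_count - 1):
            expected = min(
                np.linalg.norm(slice_mesh.nodes[node] - p) for p in pos
            )
            assert f.values[node] == pytest.approx(expected, rel=1e-12)

    def test_attenuation_closed_forms(self, slice_mesh, slice_optodes):
        f0 = attenuation_field(slice_mesh, slice_optodes, 0.0)
        assert np.allclose(f0.values, 1.0)
        mu = 0.8
        f = attenuation_field(slice_mesh, slice_optodes, mu)
        d = distance_field(slice_mesh, slice_optodes).values
        assert np.allclose(f.values, np.exp(-mu * d), rtol=1e-12)
        near = int(np.argmin(np.abs(d - 1.0 / mu)))  # d ~ 1/mu -> e^-1
        assert f.values[near] == pytest.approx(np.exp(-mu * d[near]))

    def test_empty_optodes_rejected(self, slice_mesh):
        with pytest.raises(ValueError):
            distance_field(slice_mesh, [])


class TestSizeFieldMap:
    def test_threshold_endpoints(self):
        params = SizeFieldParams(1.25, 1.0)
        med = 10.0
        t_lo, t_hi = 0.2 * med, 1.6 * med
        vals = np.array([t_lo, t_hi, med, med, med])
        y = to_size_field(SolutionField(vals, "sum_jacobian"), params).factors
        assert y[0] == pytest.approx(1.25, rel=1e-12)
        assert y[1] == pytest.approx(1.0, rel=1e-12)

    def test_midpoint_sqrt(self):
        params = SizeFieldParams(1.25, 1.0)
        med = 1.0
        t_lo, t_hi = 0.2, 1.6
        vals = np.array([0.5 * (t_lo + t_hi), med, med])
        y = to_size_field(SolutionField(vals, "sum_jacobian"), params).factors
        assert y[0] == pytest.approx(np.sqrt(1.25), rel=1e-9)

    def test_orientation_mirroring(self):
        """For coarsen_high fields large values get the max size factor."""
        params = SizeFieldParams(1.25, 1.0)
        vals = np.linspace(0.1, 30, 11)
        y = to_size_field(
            SolutionField(vals, "distance", orientation="coarsen_high"), params
        ).factors
        assert y[-1] == pytest.approx(1.25)
        assert y[0] == pytest.approx(1.0)

    def test_nonpositive_median_raises_with_optional_shift(self):
        vals = np.array([-3.0, -2.0, -1.0, 0.5, 1.0])
        field = SolutionField(vals, "log_sum_jacobian")
        params = SizeFieldParams(1.25, 1.0)
        with pytest.raises(ValueError, match="nonpositive"):
            to_size_field(field, params)
        y = to_size_field(field, params, shift_to_positive=True).factors
        assert np.all((1.0 <= y) & (y <= 1.25))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1e4), min_size=4, max_size=40),
        st.floats(1.0, 3.0),
        st.floats(0.2, 1.0),
    )
    def test_bounds_and_monotonicity(self, vals, max_sf, min_frac):
        """Factors stay in [min, max] and never increase with the value."""
        min_sf = min_frac * max_sf
        params = SizeFieldParams(max_sf, min_sf)
        vals = np.array(vals)
        y = to_size_field(SolutionField(vals, "sum_jacobian"), params).factors
        assert np.all(y >= min_sf - 1e-12) and np.all(y <= max_sf + 1e-12)
        order = np.argsort(vals)
        assert np.all(np.diff(y[order]) <= 1e-12)
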