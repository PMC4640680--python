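"""Shared fixtures: phantoms, optics, and small Monte Carlo runs.

Everything is generated programmatically; expensive objects are session-
scoped so the suite reuses them.
"""

import numpy as np
import pytest

from mmcadapt.optics import Optode, TimeGating
from mmcadapt.phantoms import (
    default_properties,
    make_slab_mesh,
    make_slice_phantom,
    place_transmission_optodes,
)


@pytest.fixture(scope="session")
def props():
    return default_properties()


@pytest.fixture(scope="session")
def gating():
    return TimeGating(50.0, 40)


@pytest.fixture(scope="session")
def slab_mesh():
    return make_slab_mesh(10.0, 10.0, 4.0, 2.0)


@pytest.fixture(scope="session")
def fine_slab():
    return make_slab_mesh(6.0, 6.0, 6.0, 1.0)


@pytest.fixture(scope="session")
def slice_mesh():
    return make_slice_phantom()


@pytest.fixture(scope="session")
def slice_optodes(slice_mesh):
    return place_transmission_optodes(slice_mesh)


@pytest.fixture(scope="session")
def central_pair(slice_optodes):
    sources = [o for o in slice_optodes if o.kind == "source"]
    detectors = [o for o in slice_optodes if o.kind == "detector"]
    return sources[len(sources) // 2], detectors[len(detectors) // 2]


@pytest.fixture(scope="session")
def slab_source(slab_mesh):
    lx, ly, _ = slab_mesh.nodes.max(axis=0)
    return Optode([lx / 2, ly / 2, 0.0], [0.0, 0.0, 1.0], "source")


@pytest.fixture(scope="session")
def diffusion_run(props):
    """1e6-photon pencil-beam run on a thick slab for diffusion checks."""
    from mmcadapt.forward import propagate

    mesh = make_slab_mesh(40.0, 40.0, 20.0, 2.0)
    src = Optode([20.0, 20.0, 0.0], [0.0, 0.0, 1.0], "source")
    gf = propagate(mesh, props, src, 1_000_000, TimeGating(50.0, 40), seed=5)
    return mesh, src, gf


def diffusion_semi_infinite_cw(props, rho, z):
    """Extrapolated-boundary diffusion solution for a unit pencil beam."""
    mu_a, musp, n = props.mu_a, props.mu_s_prime, props.n_refr
    d_coef = 1.0 / (3.0 * (mu_a + musp))
    mu_eff = np.sqrt(3.0 * mu_a * (mu_a + musp))
    r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    z_b = 2.0 * (1 + r_eff) / (1 - r_eff) * d_coef
    z_0 = 1.0 / musp
    r1 = np.sqrt(rho**2 + (z - z_0) ** 2)
    r2 = np.sqrt(rho**2 + (z + z_0 + 2 * z_b) ** 2)
    return (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (
        4 * np.pi * d_coef
    )


@pytest.fixture(scope="session")
def small_green_pair(slice_mesh, slice_optodes, props, gating, central_pair):
    """Forward/adjoint Green's functions at a modest photon count."""
    from mmcadapt.forward import adjoint_green, propagate

    src, det = central_pair
    gx = propagate(slice_mesh, props, src, 50_000, gating, seed=101)
    gm = adjoint_green(slice_mesh, props, det, 50_000, gating, seed=102)
    return gx, gm
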