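"""Desk-scale mesh-based Monte Carlo forward model.

Produces time-gated Green's functions (photon fluence per launched photon,
per mm^3, per gate) for point sources and, via the adjoint formulation,
for detectors treated as sources.  The transport physics lives in the
jitted kernel (:mod:`mmcadapt._kernel`); this module prepares the mesh
acceleration structures, launches packets and normalizes deposition into
fluence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from . import _kernel
from .mesh import TetMesh, _FACE_LOCAL, locate_point, OUTSIDE
from .optics import Optode, OpticalProperties, TimeGating

#: Russian-roulette weight floor and survival probability (standard MCML values).
ROULETTE_FLOOR = 1e-4
ROULETTE_SURVIVE = 0.1


def sample_hg_cosine(g: float, xi) -> np.ndarray:
    """Henyey-Greenstein polar scattering cosine by inverse-CDF sampling.

    ``xi`` is a uniform variate (or array) in [0, 1); the g = 0 branch is
    isotropic (2*xi - 1).
    """
    if not (0.0 <= g < 1.0):
        raise ValueError("anisotropy g must be in [0, 1)")
    xi = np.asarray(xi, dtype=float)
    if g < 1e-12:
        return 2.0 * xi - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return np.clip((1.0 + g * g - f * f) / (2.0 * g), -1.0, 1.0)


@dataclass
class GreenFunction:
    """Per (node, gate) fluence from one optode, with full run metadata."""

    values: np.ndarray  # (n_nodes, n_gates), >= 0
    optode: Optode
    n_photons: int
    seed: int
    gating: TimeGating
    kind: str = "forward"  # "forward" | "adjoint"
    budget: Dict[str, float] = field(default_factory=dict)

    def time_integrated(self) -> np.ndarray:
        """CW fluence per node (mm^-2 per launched photon).

        Gate values are already integrated over each gate, so the CW
        fluence is the plain sum over gates.
        """
        return self.values.sum(axis=1)


def _transport_arrays(mesh: TetMesh):
    """Face normals/offsets, neighbors and barycentric maps for the kernel."""
    if "transport" not in mesh._cache:
        v = mesh.nodes[mesh.elements]  # (M,4,3)
        face_n = np.empty((mesh.element_count, 4, 3))
        face_off = np.empty((mesh.element_count, 4))
        for f in range(4):
            tri = v[:, _FACE_LOCAL[f], :]
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            # orient outward: away from the opposite vertex f
            inward = np.einsum("ij,ij->i", n, v[:, f, :] - tri[:, 0]) > 0
            n[inward] *= -1.0
            face_n[:, f, :] = n
            face_off[:, f] = np.einsum("ij,ij->i", n, tri[:, 0])
        edges = np.transpose(v[:, 1:, :] - v[:, :1, :], (0, 2, 1))
        tinv = np.linalg.inv(edges)
        mesh._cache["transport"] = (
            np.ascontiguousarray(face_n),
            np.ascontiguousarray(face_off),
            np.ascontiguousarray(mesh.neighbors()),
            np.ascontiguousarray(tinv),
            np.ascontiguousarray(v[:, 0, :]),
        )
    return mesh._cache["transport"]


def _launch_state(mesh: TetMesh, optode: Optode):
    """Nudge the launch point just inside the mesh and find its element."""
    diag = mesh.bbox_diagonal()
    for eps in (1e-6 * diag, 1e-4 * diag, 1e-3 * diag, 1e-2 * diag):
        p = optode.position + eps * optode.direction
        elem = locate_point(mesh, p)
        if elem != OUTSIDE:
            return p, elem
    raise ValueError(
        f"optode at {optode.position} (direction {optode.direction}) does not "
        "enter the mesh; is it on the boundary pointing inward?"
    )


def propagate(
    mesh: TetMesh,
    props: OpticalProperties,
    optode: Optode,
    n_photons: int,
    gating: TimeGating,
    seed: int,
    kind: str = "forward",
) -> GreenFunction:
    """Run the Monte Carlo transport from one optode.

    Returns the Green's function with ``values[node, gate]`` = fluence per
    launched photon per mm^3 per gate (absorption estimator: deposited
    weight / (mu_a * nodal volume * n_photons)).  Identical seeds give
    bit-identical results.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if props.mu_a <= 0:
        raise ValueError("absorption estimator requires mu_a > 0")
    mesh.validate()
    face_n, face_off, neighbors, tinv, v0 = _transport_arrays(mesh)
    p, elem = _launch_state(mesh, optode)
    d = optode.direction
    out = _kernel.run_photons(
        mesh.elements, face_n, face_off, neighbors, tinv, v0,
        mesh.node_count,
        props.mu_a, props.mu_s, props.g, props.n_refr,
        p[0], p[1], p[2], d[0], d[1], d[2], elem,
        int(n_photons), int(seed) & 0x7FFFFFFF,
        gating.gate_width, gating.n_gates, gating.t0,
        ROULETTE_FLOOR, ROULETTE_SURVIVE,
    )
    dep, w_dep, w_exit, w_kill, w_expire, w_lost, lx, ly, lz = out
    if w_lost > 1e-6 * n_photons:
        raise RuntimeError(
            f"photon escaped element connectivity near ({lx:.4g}, {ly:.4g}, "
            f"{lz:.4g}); lost weight {w_lost:.4g} of {n_photons}"
        )
    fluence = dep / (props.mu_a * mesh.node_volumes()[:, None] * n_photons)
    return GreenFunction(
        values=fluence,
        optode=optode,
        n_photons=int(n_photons),
        seed=int(seed),
        gating=gating,
        kind=kind,
        budget={
            "launched": float(n_photons),
            "deposited": w_dep,
            "exited": w_exit,
            "roulette_killed": w_kill,
            "expired": w_expire,
            "lost": w_lost,
        },
    )


def adjoint_green(
    mesh: TetMesh,
    props: OpticalProperties,
    detector: Optode,
    n_photons: int,
    gating: TimeGating,
    seed: int,
) -> GreenFunction:
    """Adjoint Green's function: transport launched from the detector."""
    return propagate(mesh, props, detector, n_photons, gating, seed, kind="adjoint")
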