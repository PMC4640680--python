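"""Time-resolved sensitivity (Jacobian) assembly and forward measurements.

The forward-adjoint Born form: the sensitivity of a detected fluorescence
time gate to the effective quantum yield at node r is the temporal double
convolution of the source Green's function, the adjoint (detector)
Green's function, and the fluorophore lifetime decay exp(-t/tau),
evaluated per node.  Measurements are volume integrals of W * eta
discretized with nodal volume shares.

Discretization: left-endpoint Riemann sums with dt equal to the gate
width, so the brute-force triple-loop oracle matches to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .forward import GreenFunction
from .mesh import TetMesh
from .optics import Optode, TimeGating


@dataclass(frozen=True)
class Fluorophore:
    """Fluorophore with lifetime tau (ps) and per-node yield eta (>= 0)."""

    tau: float
    eta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("lifetime tau must be > 0")


@dataclass
class Jacobian:
    """Sensitivity W per (source-detector pair, gate, node)."""

    W: np.ndarray  # (n_pairs, n_gates, n_nodes)
    pairs: List[Tuple[Optode, Optode]]
    gating: TimeGating
    mesh_hash: str = ""

    @property
    def n_pairs(self) -> int:
        return self.W.shape[0]

    @property
    def n_gates(self) -> int:
        return self.W.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.W.shape[2]


def mesh_hash(mesh: TetMesh) -> str:
    """Cheap provenance hash of coordinates + connectivity."""
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.nodes).tobytes())
    h.update(np.ascontiguousarray(mesh.elements).tobytes())
    return h.hexdigest()[:16]


def assemble_jacobian(
    gx: GreenFunction, gm: GreenFunction, tau: float, gating: TimeGating
) -> np.ndarray:
    """One (gate, node) Jacobian slice from forward and adjoint Greens.

    inner[r, k'] = sum_{k''<=k'} Gx[r, k'-k''] * Gm[r, k''] * dt
    W[k, r]      = sum_{k'<=k}  exp(-(k-k') dt / tau) * inner[r, k'] * dt
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if gx.values.shape != gm.values.shape:
        raise ValueError("forward/adjoint Green's functions differ in shape")
    if gx.gating != gating or gm.gating != gating:
        raise ValueError("Green's function gating does not match the request")
    dt = gating.gate_width
    n_gates = gating.n_gates
    a = gx.values  # (nodes, gates)
    b = gm.values
    n_nodes = a.shape[0]
    # linear (non-circular) convolution along the gate axis via FFT
    nfft = 2 * n_gates
    fa = np.fft.rfft(a, nfft, axis=1)
    fb = np.fft.rfft(b, nfft, axis=1)
    inner = np.fft.irfft(fa * fb, nfft, axis=1)[:, :n_gates] * dt
    decay = np.exp(-np.arange(n_gates) * dt / tau)
    fd = np.fft.rfft(decay, nfft)
    fi = np.fft.rfft(inner, nfft, axis=1)
    w = np.fft.irfft(fi * fd[None, :], nfft, axis=1)[:, :n_gates] * dt
    w = np.maximum(w, 0.0)  # FFT rounding can leave tiny negatives
    return np.ascontiguousarray(w.T)  # (gates, nodes)


def assemble_pairs(
    greens_src: List[GreenFunction],
    greens_det: List[GreenFunction],
    pairs: List[Tuple[int, int]],
    tau: float,
    gating: TimeGating,
    mesh: Optional[TetMesh] = None,
) -> Jacobian:
    """Assemble a multi-pair Jacobian from per-optode Green's functions."""
    slices = []
    opt_pairs = []
    for si, di in pairs:
        slices.append(assemble_jacobian(greens_src[si], greens_det[di], tau, gating))
        opt_pairs.append((greens_src[si].optode, greens_det[di].optode))
    return Jacobian(
        W=np.stack(slices, axis=0),
        pairs=opt_pairs,
        gating=gating,
        mesh_hash=mesh_hash(mesh) if mesh is not None else "",
    )


def forward_tpsf(w_slice: np.ndarray, eta: np.ndarray, mesh: TetMesh) -> np.ndarray:
    """Detected fluorescence per gate: U_F[k] = sum_r W[k,r] eta(r) V(r)."""
    eta = np.asarray(eta, dtype=float)
    if eta.ndim == 0:
        eta = np.full(mesh.node_count, float(eta))
    if np.any(eta < 0):
        raise ValueError("eta must be nonnegative")
    if w_slice.shape[1] != mesh.node_count or eta.shape[0] != mesh.node_count:
        raise ValueError("W slice / eta / mesh node counts disagree")
    return w_slice @ (eta * mesh.node_volumes())


def rising_gate(tpsf: np.ndarray, fraction: float = 0.25) -> int:
    """Smallest gate index where the TPSF reaches ``fraction`` of its max."""
    tpsf = np.asarray(tpsf, dtype=float)
    peak = tpsf.max()
    if peak <= 0:
        raise ValueError("TPSF has no positive maximum")
    return int(np.argmax(tpsf >= fraction * peak))
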