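"""Forward-model accuracy metrics: per-gate TPSF error and nodal e(r).

e(r) is the percent deviation of a Jacobian value at node r from a
high-photon-count reference at the same node; averaged over the central
nodes (midway between a source-detector pair) it tracks the stochastic
stability of the forward model, scaling roughly as N^(-1/2) in the
photon count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from .mesh import TetMesh
from .optics import Optode


def nodal_error(v: np.ndarray, v_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node percent error |(v - v_ref)/v_ref| * 100.

    Nodes with a zero reference are excluded (error set to NaN); returns
    ``(errors, excluded_mask)``.
    """
    v = np.asarray(v, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    if v.shape != v_ref.shape:
        raise ValueError("v and v_ref must have the same shape")
    if np.all(v_ref == 0):
        raise ValueError("reference is identically zero")
    excluded = v_ref == 0
    e = np.full(v.shape, np.nan)
    e[~excluded] = np.abs((v[~excluded] - v_ref[~excluded]) / v_ref[~excluded]) * 100.0
    return e, excluded


def mean_central_error(e: np.ndarray, node_set: np.ndarray) -> float:
    """Arithmetic mean of e(r) over a node set (NaN entries skipped)."""
    node_set = np.asarray(node_set, dtype=np.int64)
    if node_set.size == 0:
        raise ValueError("node set is empty")
    vals = np.asarray(e, dtype=float)[node_set]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("node set has no finite errors")
    return float(vals.mean())


def tpsf_error(tpsf_test: np.ndarray, tpsf_ref: np.ndarray) -> np.ndarray:
    """Per-gate percent error; gates with zero reference are NaN."""
    t = np.asarray(tpsf_test, dtype=float)
    r = np.asarray(tpsf_ref, dtype=float)
    if t.shape != r.shape:
        raise ValueError("TPSFs must share the gating")
    out = np.full(t.shape, np.nan)
    ok = r != 0
    out[ok] = np.abs((t[ok] - r[ok]) / r[ok]) * 100.0
    return out


def central_node_set(
    mesh: TetMesh,
    source: Optode,
    detector: Optode,
    radius: float | None = None,
) -> np.ndarray:
    """Nodes within ``radius`` of the source-detector midpoint.

    Default radius: 15% of the source-detector separation.  Always
    contains at least the nearest node.
    """
    mid = 0.5 * (source.position + detector.position)
    if radius is None:
        radius = 0.15 * float(np.linalg.norm(source.position - detector.position))
    d = np.linalg.norm(mesh.nodes - mid, axis=1)
    idx = np.nonzero(d <= radius)[0]
    if idx.size == 0:
        idx = np.array([int(np.argmin(d))])
    return idx


@dataclass
class ErrorReport:
    """Per-gate and per-node error tables with run metadata."""

    gate_errors_pct: np.ndarray
    node_errors_pct: np.ndarray
    mean_central_pct: float
    central_nodes: np.ndarray
    metadata: Dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "mean_central_error_pct": self.mean_central_pct,
            "gate_errors_pct": [
                None if not np.isfinite(v) else float(v) for v in self.gate_errors_pct
            ],
            "n_central_nodes": int(self.central_nodes.size),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, gate_path: str, node_path: str) -> None:
        pd.DataFrame(
            {"gate": np.arange(self.gate_errors_pct.size),
             "error_pct": self.gate_errors_pct}
        ).to_csv(gate_path, index=False)
        pd.DataFrame(
            {"node": np.arange(self.node_errors_pct.size),
             "error_pct": self.node_errors_pct}
        ).to_csv(node_path, index=False)
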