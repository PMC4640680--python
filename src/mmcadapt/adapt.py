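"""Size-field-driven mesh adaptation by edge collapse and edge split.

Each iteration snapshots a per-node target edge length — the mean length
of the node's incident edges times its size factor — and walks the edge
list twice: collapse candidates (edges much shorter than their target)
shortest-ratio first, then split candidates (much longer) longest first.
An operation freezes its neighborhood for the rest of the pass, which
keeps passes local and deterministic.  Collapses are guarded: no element
inversion, no sliver below the quality floor, boundary nodes may only
merge along a shared boundary face, new edges must not overshoot their
target, and cumulative boundary volume drift is budgeted.  Interior
collapses conserve volume exactly (the cavity is retiled with the same
outer surface).

The loop re-derives the solution field on every new mesh — Jacobian
recipes from the analytically rescaled Jacobian, geometry recipes from
the geometry — and stops at convergence (node and element counts both
unchanged), at a maximum-element-volume cutoff, or at the iteration cap.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .fields import (
    JACOBIAN_RECIPES,
    SizeField,
    SizeFieldParams,
    compute_field,
    to_size_field,
)
from .jacobian import Jacobian
from .mesh import TetMesh
from .optics import Optode
from .transfer import TransformationMatrix, build_transformation, rescale


@dataclass(frozen=True)
class AdaptConfig:
    """Knobs of the adaptation pass.

    collapse_ratio: an edge is a collapse candidate when the inverse of
        its mean endpoint size factor falls below this (factors > ~1.11
        at the default 0.9)
    split_ratio: split candidates mirror that (mean factor < ~0.71); also
        the overshoot guard — no operation may leave an edge longer than
        split_ratio times its target length
    quality_floor: minimum element quality any operation may leave behind
    drift_budget: cumulative |boundary volume change| cap, fraction of the
        initial mesh volume
    volume_cutoff: stop the loop once max element volume reaches this (mm^3)
    """

    max_iterations: int = 30
    volume_cutoff: Optional[float] = None
    collapse_ratio: float = 0.9
    split_ratio: float = float(np.sqrt(2.0))
    quality_floor: float = 0.02
    drift_budget: float = 0.018

    def __post_init__(self) -> None:
        if not (0 < self.collapse_ratio < 1 < self.split_ratio):
            raise ValueError("need 0 < collapse_ratio < 1 < split_ratio")
        if not (0 < self.quality_floor < 1):
            raise ValueError("quality_floor must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationRecord:
    iteration: int
    nodes: int
    elements: int
    max_elem_vol_mm3: float
    splits: int
    collapses: int


@dataclass
class AdaptReport:
    """Per-iteration log mirroring the columns of the adaptation tables."""

    records: List[IterationRecord] = dc_field(default_factory=list)
    status: str = "running"  # converged | volume_cutoff | max_iterations

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "nodes": r.nodes,
                    "elements": r.elements,
                    "max_elem_vol_mm3": r.max_elem_vol_mm3,
                    "splits": r.splits,
                    "collapses": r.collapses,
                }
                for r in self.records
            ]
        )

    def write_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class Rejected:
    """Outcome of an invalid collapse attempt."""

    reason: str  # inversion | quality | boundary | conformity | overshoot | drift


# -- geometric helpers ----------------------------------------------------

def _tet_signed_volume(c0, c1, c2, c3) -> float:
    # scalar arithmetic: called per candidate element in tight pass loops
    ax, ay, az = c1[0] - c0[0], c1[1] - c0[1], c1[2] - c0[2]
    bx, by, bz = c2[0] - c0[0], c2[1] - c0[1], c2[2] - c0[2]
    cx, cy, cz = c3[0] - c0[0], c3[1] - c0[1], c3[2] - c0[2]
    return (
        ax * (by * cz - bz * cy)
        - ay * (bx * cz - bz * cx)
        + az * (bx * cy - by * cx)
    ) / 6.0


def _cross_norm(p, q, r) -> float:
    ux, uy, uz = q[0] - p[0], q[1] - p[1], q[2] - p[2]
    vx, vy, vz = r[0] - p[0], r[1] - p[1], r[2] - p[2]
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    return math.sqrt(cx * cx + cy * cy + cz * cz)


def _tet_quality(c0, c1, c2, c3) -> float:
    """3 * inradius / circumradius; 1 for regular, 0 for degenerate."""
    vol = abs(_tet_signed_volume(c0, c1, c2, c3))
    if vol <= 0:
        return 0.0
    area = 0.5 * (
        _cross_norm(c1, c2, c3)
        + _cross_norm(c0, c3, c2)
        + _cross_norm(c0, c1, c3)
        + _cross_norm(c0, c2, c1)
    )
    r_in = 3.0 * vol / area
    # circumcenter from 2 (v_i - v_0) . c = |v_i|^2 - |v_0|^2 (Cramer's rule)
    a11, a12, a13 = 2.0 * (c1[0] - c0[0]), 2.0 * (c1[1] - c0[1]), 2.0 * (c1[2] - c0[2])
    a21, a22, a23 = 2.0 * (c2[0] - c0[0]), 2.0 * (c2[1] - c0[1]), 2.0 * (c2[2] - c0[2])
    a31, a32, a33 = 2.0 * (c3[0] - c0[0]), 2.0 * (c3[1] - c0[1]), 2.0 * (c3[2] - c0[2])
    n0 = c0[0] * c0[0] + c0[1] * c0[1] + c0[2] * c0[2]
    b1 = c1[0] * c1[0] + c1[1] * c1[1] + c1[2] * c1[2] - n0
    b2 = c2[0] * c2[0] + c2[1] * c2[1] + c2[2] * c2[2] - n0
    b3 = c3[0] * c3[0] + c3[1] * c3[1] + c3[2] * c3[2] - n0
    det = (
        a11 * (a22 * a33 - a23 * a32)
        - a12 * (a21 * a33 - a23 * a31)
        + a13 * (a21 * a32 - a22 * a31)
    )
    if abs(det) < 1e-300:
        return 0.0
    x = (
        b1 * (a22 * a33 - a23 * a32)
        - a12 * (b2 * a33 - a23 * b3)
        + a13 * (b2 * a32 - a22 * b3)
    ) / det
    y = (
        a11 * (b2 * a33 - a23 * b3)
        - b1 * (a21 * a33 - a23 * a31)
        + a13 * (a21 * b3 - b2 * a31)
    ) / det
    z = (
        a11 * (a22 * b3 - b2 * a32)
        - a12 * (a21 * b3 - b2 * a31)
        + b1 * (a21 * a32 - a22 * a31)
    ) / det
    dx, dy, dz = x - c0[0], y - c0[1], z - c0[2]
    r_circ = math.sqrt(dx * dx + dy * dy + dz * dz)
    if r_circ <= 0:
        return 0.0
    return min(1.0, 3.0 * r_in / r_circ)


class _EditMesh:
    """Mutable mesh with incremental face-count bookkeeping."""

    def __init__(self, mesh: TetMesh):
        self.coords: List[np.ndarray] = [mesh.nodes[i] for i in range(mesh.node_count)]
        self.elems: Dict[int, Tuple[int, int, int, int]] = {
            i: tuple(int(v) for v in mesh.elements[i]) for i in range(mesh.element_count)
        }
        self.next_eid = mesh.element_count
        self.node_elems: Dict[int, set] = {}
        for eid, row in self.elems.items():
            for v in row:
                self.node_elems.setdefault(v, set()).add(eid)
        self.face_count: Dict[Tuple[int, int, int], int] = {}
        for row in self.elems.values():
            for f in self._faces_of(row):
                self.face_count[f] = self.face_count.get(f, 0) + 1
        self.boundary: set = {
            v for f, c in self.face_count.items() if c == 1 for v in f
        }

    @staticmethod
    def _faces_of(row):
        a, b, c, d = row
        return (
            tuple(sorted((b, c, d))),
            tuple(sorted((a, c, d))),
            tuple(sorted((a, b, d))),
            tuple(sorted((a, b, c))),
        )

    def add_node(self, p: np.ndarray) -> int:
        self.coords.append(np.asarray(p, dtype=float))
        return len(self.coords) - 1

    def add_elem(self, row) -> int:
        eid = self.next_eid
        self.next_eid += 1
        self.elems[eid] = tuple(int(v) for v in row)
        for v in self.elems[eid]:
            self.node_elems.setdefault(v, set()).add(eid)
        for f in self._faces_of(self.elems[eid]):
            self.face_count[f] = self.face_count.get(f, 0) + 1
        return eid

    def remove_elem(self, eid: int) -> None:
        row = self.elems.pop(eid)
        for v in row:
            s = self.node_elems.get(v)
            if s is not None:
                s.discard(eid)
        for f in self._faces_of(row):
            c = self.face_count.get(f, 0) - 1
            if c <= 0:
                self.face_count.pop(f, None)
            else:
                self.face_count[f] = c

    def elem_coords(self, row):
        return tuple(self.coords[v] for v in row)

    def to_mesh(self) -> Tuple[TetMesh, np.ndarray]:
        """Compact into a TetMesh; returns (mesh, old-node-id per new node)."""
        used = sorted({v for row in self.elems.values() for v in row})
        remap = {old: new for new, old in enumerate(used)}
        nodes = np.array([self.coords[i] for i in used])
        elements = np.array(
            [[remap[v] for v in row] for _, row in sorted(self.elems.items())],
            dtype=np.int64,
        )
        return TetMesh(nodes, elements), np.array(used, dtype=np.int64)


def _edge_elems(em: _EditMesh, a: int, b: int) -> List[int]:
    return sorted(em.node_elems.get(a, set()) & em.node_elems.get(b, set()))


def _try_collapse(
    em: _EditMesh,
    a: int,
    b: int,
    kept: int,
    config: AdaptConfig,
    drift_state: Optional[dict] = None,
    edge_targets: Optional[Dict[int, float]] = None,
):
    """Attempt to merge the other endpoint into ``kept``.

    Returns the list of touched nodes on success, or Rejected.
    """
    removed = b if kept == a else a
    shared = _edge_elems(em, a, b)
    if not shared:
        raise ValueError(f"edge ({a}, {b}) does not exist")
    if removed in em.boundary:
        if kept not in em.boundary:
            return Rejected("boundary")
        lo, hi = (a, b) if a < b else (b, a)
        on_bface = any(
            em.face_count.get(f, 0) == 1
            for eid in shared
            for f in em._faces_of(em.elems[eid])
            if lo in f and hi in f
        )
        if not on_bface:
            return Rejected("boundary")

    remap_eids = sorted(em.node_elems.get(removed, set()) - set(shared))
    new_rows = []
    vol_before = 0.0
    vol_after = 0.0
    for eid in shared:
        c = em.elem_coords(em.elems[eid])
        vol_before += abs(_tet_signed_volume(*c))
    for eid in remap_eids:
        row = em.elems[eid]
        new_row = tuple(kept if v == removed else v for v in row)
        c_old = em.elem_coords(row)
        c_new = em.elem_coords(new_row)
        vol_before += abs(_tet_signed_volume(*c_old))
        sv = _tet_signed_volume(*c_new)
        if sv <= 0:
            return Rejected("inversion")
        if _tet_quality(*c_new) < config.quality_floor:
            return Rejected("quality")
        vol_after += sv
        new_rows.append((eid, new_row))
    if len({tuple(sorted(r)) for _, r in new_rows}) != len(new_rows):
        return Rejected("conformity")

    # overshoot guard: new edges at `kept` must not exceed their target
    if edge_targets is not None:
        pk = em.coords[kept]
        neighbor_nodes = {
            v for _, r in new_rows for v in r if v != kept
        }
        for v in neighbor_nodes:
            tgt = 0.5 * (edge_targets.get(kept, np.inf) + edge_targets.get(v, np.inf))
            if np.isfinite(tgt):
                if float(np.linalg.norm(em.coords[v] - pk)) > config.split_ratio * tgt:
                    return Rejected("overshoot")

    # volume drift budget (boundary collapses change the outer surface)
    drift = abs(vol_before - vol_after)
    if drift_state is not None:
        if drift_state["used"] + drift > drift_state["budget"]:
            return Rejected("drift")

    # conformity: simulate the face-count delta
    delta: Dict[Tuple[int, int, int], int] = {}
    for eid in shared:
        for f in em._faces_of(em.elems[eid]):
            delta[f] = delta.get(f, 0) - 1
    for eid, _ in new_rows:
        for f in em._faces_of(em.elems[eid]):
            delta[f] = delta.get(f, 0) - 1
    for _, r in new_rows:
        for f in em._faces_of(r):
            delta[f] = delta.get(f, 0) + 1
    for f, d in delta.items():
        if em.face_count.get(f, 0) + d > 2:
            return Rejected("conformity")

    # commit
    for eid in shared:
        em.remove_elem(eid)
    for eid, r in new_rows:
        em.remove_elem(eid)
        em.add_elem(r)
    if removed in em.boundary:
        em.boundary.discard(removed)
        em.boundary.add(kept)
    if drift_state is not None:
        drift_state["used"] += drift
    touched = {kept}
    for _, r in new_rows:
        touched.update(r)
    return sorted(touched)


def _do_split(em: _EditMesh, a: int, b: int) -> List[int]:
    """Split edge (a, b) at its midpoint; returns touched nodes."""
    shared = _edge_elems(em, a, b)
    if not shared:
        raise ValueError(f"edge ({a}, {b}) does not exist")
    m = em.add_node(0.5 * (em.coords[a] + em.coords[b]))
    was_boundary = a in em.boundary and b in em.boundary
    touched = {a, b, m}
    for eid in shared:
        row = em.elems[eid]
        touched.update(row)
        em.remove_elem(eid)
        em.add_elem(tuple(m if v == a else v for v in row))
        em.add_elem(tuple(m if v == b else v for v in row))
    if was_boundary:
        # midpoint of a boundary edge lies on the surface
        em.boundary.add(m)
    return sorted(touched)


# -- public single-operation API ------------------------------------------

def split_edge(mesh: TetMesh, edge: Tuple[int, int]) -> TetMesh:
    """Split one edge at its midpoint; conforming, volume-exact."""
    em = _EditMesh(mesh)
    _do_split(em, int(edge[0]), int(edge[1]))
    new_mesh, _ = em.to_mesh()
    return new_mesh

def collapse_edge(
    mesh: TetMesh,
    edge: Tuple[int, int],
    kept_node: int,
    config: Optional[AdaptConfig] = None,
):
    """Collapse one edge into ``kept_node``; returns a TetMesh or Rejected."""
    if kept_node not in (int(edge[0]), int(edge[1])):
        raise ValueError("kept_node must be an endpoint of the edge")
    em = _EditMesh(mesh)
    out = _try_collapse(
        em, int(edge[0]), int(edge[1]), int(kept_node), config or AdaptConfig()
    )
    if isinstance(out, Rejected):
        return out
    new_mesh, _ = em.to_mesh()
    return new_mesh


# -- one full pass ---------------------------------------------------------

def node_mean_edge_length(mesh: TetMesh) -> np.ndarray:
    """Mean incident-edge length per node — the local discretization scale."""
    rows = mesh.elements
    combos = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    pairs = np.concatenate([rows[:, [i, j]] for i, j in combos], axis=0)
    pairs.sort(axis=1)
    pairs = np.unique(pairs, axis=0)
    lengths = np.linalg.norm(mesh.nodes[pairs[:, 0]] - mesh.nodes[pairs[:, 1]], axis=1)
    h_sum = np.zeros(mesh.node_count)
    h_cnt = np.zeros(mesh.node_count)
    np.add.at(h_sum, pairs.ravel(), np.repeat(lengths, 2))
    np.add.at(h_cnt, pairs.ravel(), 1.0)
    return h_sum / np.maximum(h_cnt, 1.0)


def adapt_once(
    mesh: TetMesh,
    size_field: SizeField,
    config: Optional[AdaptConfig] = None,
    drift_state: Optional[dict] = None,
    ref_length: Optional[np.ndarray] = None,
) -> Tuple[TetMesh, IterationRecord]:
    """One collapse-then-split pass driven by the size field.

    The per-node target edge length is ``ref_length * size_factor``;
    ``ref_length`` defaults to the current mesh's local edge length (so a
    lone pass adapts relative to what it is given), while the iterative
    loop passes the initial mesh's local length carried across iterations,
    which anchors the converged element size to the original
    discretization.  Deterministic: candidates are ordered by
    (ratio, node pair) and an operation freezes its neighborhood for the
    remainder of the pass.
    """
    config = config or AdaptConfig()
    sf = np.asarray(size_field.factors, dtype=float)
    if sf.shape[0] != mesh.node_count:
        raise ValueError("size field length != mesh node count")
    if drift_state is None:
        drift_state = {"used": 0.0, "budget": config.drift_budget * mesh.total_volume()}

    em = _EditMesh(mesh)
    rows = mesh.elements
    combos = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    pairs = np.concatenate([rows[:, [i, j]] for i, j in combos], axis=0)
    pairs.sort(axis=1)
    pairs = np.unique(pairs, axis=0)
    lengths = np.linalg.norm(mesh.nodes[pairs[:, 0]] - mesh.nodes[pairs[:, 1]], axis=1)
    h_ref = (
        np.asarray(ref_length, dtype=float)
        if ref_length is not None
        else node_mean_edge_length(mesh)
    )
    if h_ref.shape[0] != mesh.node_count:
        raise ValueError("ref_length length != mesh node count")
    target_len = {i: h_ref[i] * sf[i] for i in range(mesh.node_count)}
    edge_target = 0.5 * (
        h_ref[pairs[:, 0]] * sf[pairs[:, 0]] + h_ref[pairs[:, 1]] * sf[pairs[:, 1]]
    )
    ratio = lengths / edge_target
    # candidacy follows the size factors alone (a unit size field is an
    # exact fixed point); the anchored targets order candidates and bound
    # growth through the overshoot guard
    mean_sf = 0.5 * (sf[pairs[:, 0]] + sf[pairs[:, 1]])
    collapse_cand = mean_sf > 1.0 / config.collapse_ratio
    split_cand = mean_sf < 1.0 / config.split_ratio

    frozen: set = set()
    n_collapses = 0
    n_splits = 0

    # --- collapse pass: shortest ratio first ---
    order = np.lexsort((pairs[:, 1], pairs[:, 0], ratio))
    for k in order:
        if not collapse_cand[k] or ratio[k] >= config.split_ratio:
            continue
        a, b = int(pairs[k, 0]), int(pairs[k, 1])
        if a in frozen or b in frozen:
            continue
        if not (em.node_elems.get(a) and em.node_elems.get(b)):
            continue
        if not _edge_elems(em, a, b):
            continue
        # keep a boundary endpoint when mixed; otherwise lower index first
        a_b, b_b = a in em.boundary, b in em.boundary
        if a_b != b_b:
            kept_options = [a if a_b else b]
        else:
            kept_options = [min(a, b), max(a, b)]
        done = None
        for kept in kept_options:
            out = _try_collapse(em, a, b, kept, config, drift_state, target_len)
            if not isinstance(out, Rejected):
                done = out
                break
        if done is not None:
            n_collapses += 1
            frozen.update(done)

    # --- split pass: longest ratio first ---
    order = np.lexsort((pairs[:, 1], pairs[:, 0], -ratio))
    for k in order:
        if not split_cand[k]:
            continue
        a, b = int(pairs[k, 0]), int(pairs[k, 1])
        if a in frozen or b in frozen:
            continue
        if not (em.node_elems.get(a) and em.node_elems.get(b)):
            continue
        if not _edge_elems(em, a, b):
            continue
        touched = _do_split(em, a, b)
        n_splits += 1
        frozen.update(touched)

    new_mesh, _ = em.to_mesh()
    record = IterationRecord(
        iteration=0,
        nodes=new_mesh.node_count,
        elements=new_mesh.element_count,
        max_elem_vol_mm3=float(new_mesh.element_volumes().max()),
        splits=n_splits,
        collapses=n_collapses,
    )
    return new_mesh, record


@dataclass
class AdaptResult:
    mesh: TetMesh
    report: AdaptReport
    transformation: Optional[TransformationMatrix]
    jacobian: Optional[Jacobian]


def adapt_loop(
    mesh: TetMesh,
    field_recipe: str,
    params: SizeFieldParams,
    config: Optional[AdaptConfig] = None,
    jacobian: Optional[Jacobian] = None,
    optodes: Optional[List[Optode]] = None,
    mu: Optional[float] = None,
    shift_to_positive: bool = False,
) -> AdaptResult:
    """Iterate adaptation to convergence, a volume cutoff, or the cap.

    Jacobian recipes rescale the Jacobian onto each new mesh and recompute
    the field from the rescaled values; geometry recipes recompute from
    geometry.  The returned transformation chains every iteration, mapping
    the initial mesh's nodal values onto the final mesh in one multiply.
    """
    config = config or AdaptConfig()
    if field_recipe in JACOBIAN_RECIPES and jacobian is None:
        raise ValueError(f"recipe '{field_recipe}' requires a Jacobian")
    report = AdaptReport()
    chain: Optional[TransformationMatrix] = None
    jac = jacobian
    current = mesh
    h_ref = node_mean_edge_length(mesh)  # anchor target sizes to the initial mesh
    drift_state = {"used": 0.0, "budget": config.drift_budget * mesh.total_volume()}
    for it in range(1, config.max_iterations + 1):
        field = compute_field(field_recipe, current, optodes=optodes, jac=jac, mu=mu)
        size = to_size_field(field, params, shift_to_positive=shift_to_positive)
        new_mesh, rec = adapt_once(current, size, config, drift_state, ref_length=h_ref)
        rec.iteration = it
        report.records.append(rec)
        t_iter = build_transformation(current, new_mesh)
        chain = t_iter if chain is None else chain.compose(t_iter)
        h_ref = t_iter.matrix.T.dot(h_ref)
        if jac is not None:
            jac = rescale(jac, t_iter, new_mesh)
        converged = (
            new_mesh.node_count == current.node_count
            and new_mesh.element_count == current.element_count
        )
        current = new_mesh
        if config.volume_cutoff is not None and (
            rec.max_elem_vol_mm3 >= config.volume_cutoff
        ):
            report.status = "volume_cutoff"
            break
        if converged:
            report.status = "converged"
            break
    else:
        report.status = "max_iterations"
    return AdaptResult(mesh=current, report=report, transformation=chain, jacobian=jac)
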