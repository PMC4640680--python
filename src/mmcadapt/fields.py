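"""Per-node solution fields and their conversion to size fields.

A solution field ranks nodes by how much they matter to the forward model
(sensitivity-derived fields) or by geometry (distance/attenuation to the
nearest optode).  The size-field map turns that ranking into a per-node
size factor: values below a lower threshold (20% of the median by
default) get the maximum size factor (coarsen hardest), values above the
upper threshold (8x the lower) get the minimum, and in between an
exponential y = p * a^x interpolates continuously between the two clamps.
Fields whose large values should be coarsened (plain distance) are
mirrored before the map is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .jacobian import Jacobian
from .mesh import TetMesh
from .optics import Optode

FIELD_KINDS = (
    "sum_jacobian",
    "log_sum_jacobian",
    "normalized_sum",
    "curvature",
    "log_curvature",
    "distance",
    "attenuation",
)

#: Field recipes that need a Jacobian (vs geometry-only recipes).
JACOBIAN_RECIPES = (
    "sum_jacobian",
    "log_sum_jacobian",
    "normalized_sum",
    "curvature",
    "log_curvature",
)


@dataclass
class SolutionField:
    """Per-node scalar field with its coarsening orientation.

    ``coarsen_low`` kinds coarsen where the value is small (low
    sensitivity, low attenuation-weighted visibility); the plain distance
    field coarsens where the value is large (``coarsen_high``).
    """

    values: np.ndarray
    kind: str
    orientation: str = "coarsen_low"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in FIELD_KINDS:
            raise ValueError(f"unknown field kind: {self.kind}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("solution field contains non-finite values")


@dataclass(frozen=True)
class SizeFieldParams:
    """Thresholds and bounds of the solution-to-size-field map."""

    max_size_factor: float = 1.25
    min_size_factor: float = 1.0
    lower_frac: float = 0.2
    upper_mult: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.min_size_factor <= self.max_size_factor):
            raise ValueError("need 0 < min_size_factor <= max_size_factor")
        if self.lower_frac <= 0:
            raise ValueError("lower_frac must be > 0")
        if self.upper_mult <= 1:
            raise ValueError("upper_mult must be > 1")


@dataclass
class SizeField:
    """Per-node size factors, bounded by [min, max] of the generating params."""

    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)


# -- sensitivity-derived fields ------------------------------------------

def sum_jacobian(w: Jacobian) -> SolutionField:
    """Sum of all (pair, gate) rows of the Jacobian per node."""
    return SolutionField(w.W.sum(axis=(0, 1)), "sum_jacobian")


def log_sum_jacobian(w: Jacobian) -> SolutionField:
    """Natural log of the row sum, guarding zeros with a tiny offset."""
    s = w.W.sum(axis=(0, 1))
    pos = s[s > 0]
    eps = (pos.min() * 1e-6) if pos.size else 1.0
    return SolutionField(np.log(s + eps), "log_sum_jacobian")


def normalized_sum(w: Jacobian) -> SolutionField:
    """Row sum after normalizing each (pair, gate) row to unit maximum."""
    flat = w.W.reshape(-1, w.n_nodes)
    maxes = flat.max(axis=1)
    keep = maxes > 0
    vals = (flat[keep] / maxes[keep, None]).sum(axis=0)
    return SolutionField(vals, "normalized_sum")


def curvature(s: SolutionField) -> SolutionField:
    """Laplacian-type contrast: u_i = S_i - mean of all other S_j.

    Annihilates constant fields; highlights nodes that deviate from the
    global mean.
    """
    v = s.values
    n = v.shape[0]
    if n < 2:
        raise ValueError("curvature needs at least 2 nodes")
    u = v - (v.sum() - v) / (n - 1)
    kind = "log_curvature" if s.kind.startswith("log") else "curvature"
    return SolutionField(u, kind)


def log_curvature(w: Jacobian) -> SolutionField:
    """log of the curvature magnitude of the Jacobian row sum."""
    u = curvature(sum_jacobian(w)).values
    mag = np.abs(u)
    pos = mag[mag > 0]
    eps = (pos.min() * 1e-6) if pos.size else 1.0
    return SolutionField(np.log(mag + eps), "log_curvature")


# -- geometry-derived fields ---------------------------------------------

def _min_optode_distance(mesh: TetMesh, optodes: List[Optode]) -> np.ndarray:
    if not optodes:
        raise ValueError("need at least one optode")
    pos = np.array([o.position for o in optodes])
    d = np.linalg.norm(mesh.nodes[:, None, :] - pos[None, :, :], axis=2)
    return d.min(axis=1)


def distance_field(mesh: TetMesh, optodes: List[Optode]) -> SolutionField:
    """Minimum Euclidean distance to any optode; far nodes coarsen most."""
    return SolutionField(
        _min_optode_distance(mesh, optodes), "distance", orientation="coarsen_high"
    )


def attenuation_field(
    mesh: TetMesh, optodes: List[Optode], mu: float
) -> SolutionField:
    """Beer-Lambert visibility exp(-mu * min optode distance).

    ``mu`` (mm^-1) is the total attenuation; the package default used by
    the recipes is mu_a + mu_s'.  Low values (deep, poorly sampled nodes)
    coarsen most.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return SolutionField(
        np.exp(-mu * _min_optode_distance(mesh, optodes)), "attenuation"
    )


# -- size-field map -------------------------------------------------------

def to_size_field(
    field: SolutionField,
    params: SizeFieldParams,
    shift_to_positive: bool = False,
) -> SizeField:
    """Map a solution field to size factors via thresholds on the median.

    T_lo = lower_frac * median, T_hi = upper_mult * T_lo.  Below T_lo the
    factor is the max (coarsen hardest); above T_hi the min; between them
    y(x) = max_sf * (min_sf/max_sf)**((x - T_lo)/(T_hi - T_lo)), the
    exponential form continuous at both clamps.  ``coarsen_high`` fields
    are mirrored (x <- T_lo + T_hi - x) first.

    Log-family fields can have a nonpositive median, which makes the
    thresholds meaningless (T_hi < T_lo); this raises unless
    ``shift_to_positive`` is set, which shifts the field to min > 0 first.
    """
    x = field.values.astype(float).copy()
    med = float(np.median(x))
    if med <= 0:
        if not shift_to_positive:
            raise ValueError(
                f"solution field median is nonpositive ({med:.4g}); thresholds "
                "are undefined — pass shift_to_positive=True to shift the field"
            )
        span = x.max() - x.min()
        x = x - x.min() + (1e-6 * span if span > 0 else 1.0)
        med = float(np.median(x))
    t_lo = params.lower_frac * med
    t_hi = params.upper_mult * t_lo
    if field.orientation == "coarsen_high":
        x = t_lo + t_hi - x
    lo, hi = params.min_size_factor, params.max_size_factor
    with np.errstate(over="ignore"):
        y = hi * (lo / hi) ** ((x - t_lo) / (t_hi - t_lo))
    y = np.where(x < t_lo, hi, np.where(x > t_hi, lo, y))
    return SizeField(np.clip(y, lo, hi))


def compute_field(
    recipe: str,
    mesh: TetMesh,
    optodes: List[Optode] | None = None,
    jac: Jacobian | None = None,
    mu: float | None = None,
) -> SolutionField:
    """Dispatch a named recipe to its field builder."""
    if recipe in JACOBIAN_RECIPES:
        if jac is None:
            raise ValueError(f"recipe '{recipe}' requires a Jacobian")
        if recipe == "sum_jacobian":
            return sum_jacobian(jac)
        if recipe == "log_sum_jacobian":
            return log_sum_jacobian(jac)
        if recipe == "normalized_sum":
            return normalized_sum(jac)
        if recipe == "curvature":
            return curvature(sum_jacobian(jac))
        return log_curvature(jac)
    if recipe == "distance":
        if optodes is None:
            raise ValueError("distance recipe requires optodes")
        return distance_field(mesh, optodes)
    if recipe == "attenuation":
        if optodes is None or mu is None:
            raise ValueError("attenuation recipe requires optodes and mu")
        return attenuation_field(mesh, optodes, mu)
    raise ValueError(f"unknown recipe: {recipe}")
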