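"""HDF5 persistence for Green's functions, Jacobians and transfer operators."""

from __future__ import annotations

from typing import List, Tuple

import h5py
import numpy as np
import scipy.sparse as sp

from .forward import GreenFunction
from .jacobian import Jacobian
from .optics import Optode, TimeGating
from .transfer import TransformationMatrix


def _write_gating(grp, gating: TimeGating) -> None:
    grp.attrs["gate_width"] = gating.gate_width
    grp.attrs["n_gates"] = gating.n_gates
    grp.attrs["t0"] = gating.t0


def _read_gating(grp) -> TimeGating:
    return TimeGating(
        float(grp.attrs["gate_width"]), int(grp.attrs["n_gates"]), float(grp.attrs["t0"])
    )


def _write_optode(grp, name: str, opt: Optode) -> None:
    g = grp.create_group(name)
    g.create_dataset("position", data=opt.position)
    g.create_dataset("direction", data=opt.direction)
    g.attrs["kind"] = opt.kind


def _read_optode(grp) -> Optode:
    return Optode(grp["position"][:], grp["direction"][:], str(grp.attrs["kind"]))


def save_green(path: str, gf: GreenFunction) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=gf.values, compression="gzip")
        meta = fh.create_group("meta")
        _write_optode(meta, "optode", gf.optode)
        meta.attrs["n_photons"] = gf.n_photons
        meta.attrs["seed"] = gf.seed
        meta.attrs["kind"] = gf.kind
        for k, v in gf.budget.items():
            meta.attrs[f"budget_{k}"] = v
        _write_gating(meta.create_group("gating"), gf.gating)


def load_green(path: str) -> GreenFunction:
    with h5py.File(path, "r") as fh:
        meta = fh["meta"]
        budget = {
            k[len("budget_"):]: float(v)
            for k, v in meta.attrs.items()
            if k.startswith("budget_")
        }
        return GreenFunction(
            values=fh["values"][:],
            optode=_read_optode(meta["optode"]),
            n_photons=int(meta.attrs["n_photons"]),
            seed=int(meta.attrs["seed"]),
            gating=_read_gating(meta["gating"]),
            kind=str(meta.attrs["kind"]),
            budget=budget,
        )


def save_jacobian(path: str, jac: Jacobian) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("W", data=jac.W, compression="gzip")
        fh.attrs["mesh_hash"] = jac.mesh_hash
        _write_gating(fh.create_group("gating"), jac.gating)
        pairs = fh.create_group("pairs")
        for i, (s, d) in enumerate(jac.pairs):
            g = pairs.create_group(str(i))
            _write_optode(g, "source", s)
            _write_optode(g, "detector", d)


def load_jacobian(path: str) -> Jacobian:
    with h5py.File(path, "r") as fh:
        pairs: List[Tuple[Optode, Optode]] = []
        grp = fh["pairs"]
        for i in range(len(grp)):
            g = grp[str(i)]
            pairs.append((_read_optode(g["source"]), _read_optode(g["detector"])))
        return Jacobian(
            W=fh["W"][:],
            pairs=pairs,
            gating=_read_gating(fh["gating"]),
            mesh_hash=str(fh.attrs["mesh_hash"]),
        )


def save_transformation(path: str, t: TransformationMatrix) -> None:
    coo = t.matrix.tocoo()
    with h5py.File(path, "w") as fh:
        fh.create_dataset("row", data=coo.row)
        fh.create_dataset("col", data=coo.col)
        fh.create_dataset("val", data=coo.data)
        fh.create_dataset("cases", data=t.cases)
        fh.attrs["shape"] = t.matrix.shape


def load_transformation(path: str) -> TransformationMatrix:
    with h5py.File(path, "r") as fh:
        shape = tuple(int(v) for v in fh.attrs["shape"])
        m = sp.coo_matrix(
            (fh["val"][:], (fh["row"][:], fh["col"][:])), shape=shape
        ).tocsc()
        return TransformationMatrix(m, fh["cases"][:])
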