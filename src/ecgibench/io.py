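"""Serialization of potential fields, maps, and transfer matrices.

Potential fields travel as HDF5 containers (``/values`` dataset with
``fs``/``t0`` attributes) or, for small fixtures, as CSV with a header
comment carrying the sampling rate. Transfer matrices use MatrixMarket
dense array format (with a sidecar flag comment) or the same HDF5 layout.
"""

from __future__ import annotations

import numpy as np
import h5py
from scipy.io import mmread, mmwrite

from .forward import TransferMatrix
from .phantom import PotentialField

__all__ = [
    "save_field",
    "load_field",
    "save_transfer_matrix",
    "load_transfer_matrix",
]


def save_field(field: PotentialField, path) -> None:
    p = str(path)
    if p.endswith((".h5", ".hdf5")):
        with h5py.File(p, "w") as fh:
            d = fh.create_dataset("values", data=field.values)
            d.attrs["fs"] = field.fs
            d.attrs["t0"] = field.t0
    elif p.endswith(".csv"):
        header = f"fs={field.fs} t0={field.t0}"
        np.savetxt(p, field.values, delimiter=",", header=header)
    else:
        raise ValueError(f"unsupported field extension: {p}")


def load_field(path) -> PotentialField:
    p = str(path)
    if p.endswith((".h5", ".hdf5")):
        with h5py.File(p, "r") as fh:
            d = fh["values"]
            return PotentialField(d[...], float(d.attrs["fs"]),
                                  float(d.attrs.get("t0", 0.0)))
    if p.endswith(".csv"):
        with open(p) as fh:
            first = fh.readline()
        meta = dict(tok.split("=") for tok in first.lstrip("# ").split())
        values = np.loadtxt(p, delimiter=",", ndmin=2)
        return PotentialField(values, float(meta["fs"]),
                              float(meta.get("t0", 0.0)))
    raise ValueError(f"unsupported field extension: {p}")


def save_transfer_matrix(A: TransferMatrix, path) -> None:
    p = str(path)
    if p.endswith(".mtx"):
        mmwrite(p, A.entries,
                comment=f"referenced={A.referenced}")
    elif p.endswith((".h5", ".hdf5")):
        with h5py.File(p, "w") as fh:
            d = fh.create_dataset("entries", data=A.entries)
            d.attrs["referenced"] = A.referenced
            if A.lead_positions is not None:
                fh.create_dataset("lead_positions", data=A.lead_positions)
    else:
        raise ValueError(f"unsupported transfer-matrix extension: {p}")


def load_transfer_matrix(path) -> TransferMatrix:
    p = str(path)
    if p.endswith(".mtx"):
        referenced = False
        with open(p) as fh:
            for line in fh:
                if line.startswith("%") and "referenced=True" in line:
                    referenced = True
                if not line.startswith("%"):
                    break
        entries = np.asarray(mmread(p))
        return TransferMatrix(entries, referenced=referenced)
    if p.endswith((".h5", ".hdf5")):
        with h5py.File(p, "r") as fh:
            d = fh["entries"]
            lead = (fh["lead_positions"][...]
                    if "lead_positions" in fh else None)
            return TransferMatrix(d[...], bool(d.attrs["referenced"]),
                                  lead_positions=lead)
    raise ValueError(f"unsupported transfer-matrix extension: {p}")
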