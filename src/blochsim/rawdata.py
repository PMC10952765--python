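"""Raw-data serialization.

A simplified ISMRMRD-compatible HDF5 profile: a ``/header`` group whose
attributes carry the field of view, matrix size, sequence name and a
snapshot of the simulation parameters, plus one ``/acq{i}`` group per
readout with ``data`` (complex samples), ``t`` (sample times, s) and an
optional ``traj`` (k-space positions, 1/m).  Field names are documented
here so a converter to the strict standard header is a thin adapter.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .core import RawData, Readout

__all__ = ["write_rawdata", "read_rawdata"]


def write_rawdata(raw: RawData, path) -> None:
    """Write raw data to the HDF5 profile described in the module docs."""
    with h5py.File(path, "w") as f:
        hdr = f.create_group("header")
        hdr.attrs["n_readouts"] = len(raw.readouts)
        for key, val in raw.header.items():
            if isinstance(val, (dict, list, tuple)):
                hdr.attrs[key] = json.dumps(val)
            elif val is not None:
                hdr.attrs[key] = val
        for i, ro in enumerate(raw.readouts):
            g = f.create_group(f"acq{i}")
            g.create_dataset("data", data=np.asarray(ro.samples, dtype=complex))
            g.create_dataset("t", data=np.asarray(ro.times, dtype=float))
            if ro.traj is not None:
                g.create_dataset("traj", data=np.asarray(ro.traj, dtype=float))


def read_rawdata(path) -> RawData:
    """Read a file produced by :func:`write_rawdata`."""
    with h5py.File(path, "r") as f:
        if "header" not in f:
            raise ValueError("malformed raw-data file: missing /header")
        hdr = {}
        for key, val in f["header"].attrs.items():
            if isinstance(val, bytes):
                val = val.decode()
            if isinstance(val, str) and val[:1] in "[{":
                try:
                    val = json.loads(val)
                except json.JSONDecodeError:
                    pass
            hdr[key] = val
        n = int(hdr.pop("n_readouts", 0))
        readouts = []
        for i in range(n):
            name = f"acq{i}"
            if name not in f:
                raise ValueError(f"malformed raw-data file: missing /{name}")
            g = f[name]
            if "data" not in g or "t" not in g:
                raise ValueError(
                    f"malformed raw-data file: /{name} lacks data or t"
                )
            traj = np.asarray(g["traj"]) if "traj" in g else None
            readouts.append(
                Readout(np.asarray(g["t"]), np.asarray(g["data"]), traj)
            )
    return RawData(readouts, hdr)
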