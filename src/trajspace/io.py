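"""HDF5 reading/writing of epoched recordings.

Layout
------
``/data``          float64, trials x sensors x samples
``/times``         float64 seconds
``/sensor_names``  UTF-8 strings
``/meta/<col>``    one dataset per metadata column
root attributes    ``fs``, ``band``

A CSV sidecar ``<stem>.meta.csv`` mirrors the metadata table.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .core import META_COLUMNS, EpochedRecording

__all__ = ["read_epochs", "write_epochs", "EpochsFormatError"]

_STRING_COLS = ("subject_id", "session_id", "orientation", "response")
_INT_COLS = ("seen", "correct")


class EpochsFormatError(ValueError):
    """Raised when an epochs file does not follow the documented layout."""


def write_epochs(rec: EpochedRecording, path, overwrite: bool = False) -> str:
    """Write a recording to the documented HDF5 layout (+ CSV metadata sidecar).

    Refuses to persist non-finite data and to overwrite an existing file
    unless ``overwrite=True``.
    """
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if rec.data.size and not np.all(np.isfinite(rec.data)):
        raise ValueError("refusing to persist non-finite (NaN/Inf) data")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.asarray(rec.data, dtype=np.float64))
        f.create_dataset("times", data=np.asarray(rec.times, dtype=np.float64))
        f.create_dataset(
            "sensor_names",
            data=np.array(rec.sensor_names, dtype=h5py.string_dtype("utf-8")),
        )
        f.attrs["fs"] = float(rec.fs)
        f.attrs["band"] = rec.band
        g = f.create_group("meta")
        for col in META_COLUMNS:
            vals = rec.meta[col].to_numpy()
            if col in _STRING_COLS:
                ds = g.create_dataset(
                    col, shape=(len(vals),), dtype=h5py.string_dtype("utf-8")
                )
                if len(vals):
                    ds[...] = [str(v) for v in vals]
            else:
                g.create_dataset(col, data=np.asarray(vals, dtype=np.int64))
    rec.meta.to_csv(_sidecar(path), index=False)
    return path


def read_epochs(path) -> EpochedRecording:
    """Read a recording written by :func:`write_epochs`.

    Round-trips bit-exactly on the data array. Raises
    :class:`EpochsFormatError` naming any missing dataset/attribute; shape
    mismatches surface as the container's invariant errors.
    """
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        for key in ("data", "times", "sensor_names", "meta"):
            if key not in f:
                raise EpochsFormatError(f"{path}: missing dataset {key!r}")
        for attr in ("fs", "band"):
            if attr not in f.attrs:
                raise EpochsFormatError(f"{path}: missing attribute {attr!r}")
        data = f["data"][...]
        times = f["times"][...]
        names = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sensor_names"][...]]
        cols = {}
        for col in META_COLUMNS:
            if col not in f["meta"]:
                raise EpochsFormatError(f"{path}: missing metadata column {col!r}")
            vals = f["meta"][col][...]
            if col in _STRING_COLS:
                vals = np.array(
                    [v.decode() if isinstance(v, bytes) else str(v) for v in vals]
                )
            cols[col] = vals
        meta = pd.DataFrame(cols, columns=META_COLUMNS)
        return EpochedRecording(
            data=data,
            fs=float(f.attrs["fs"]),
            times=times,
            sensor_names=names,
            meta=meta,
            band=str(f.attrs["band"]),
        )


def _sidecar(path: str) -> str:
    stem, _ = os.path.splitext(path)
    return stem + ".meta.csv"
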