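"""Small h5py helpers shared by writer, reader and validator."""

from __future__ import annotations

import hashlib

import h5py
import numpy as np

STR_DTYPE = h5py.string_dtype(encoding="utf-8")


def as_str(value) -> str:
    """Decode an attribute/dataset scalar that may be bytes or str."""
    if isinstance(value, bytes):
        return value.decode("utf-8")
    return str(value)


def str_list(values) -> list[str]:
    return [as_str(v) for v in np.asarray(values).ravel()]


def read_str_dataset(ds: h5py.Dataset) -> list[str]:
    return [as_str(v) for v in ds.asstr()[...]] if ds.size else []


def is_vlen_float(ds: h5py.Dataset) -> bool:
    base = h5py.check_vlen_dtype(ds.dtype)
    return base is not None and np.dtype(base).kind == "f"


def dim_scales(ds: h5py.Dataset, dim: int) -> dict[str, h5py.Dataset]:
    """Scales attached to dimension *dim*, keyed by their scale name."""
    try:
        return {as_str(name): scale for name, scale in ds.dims[dim].items()}
    except (KeyError, RuntimeError):
        return {}


def uid_hash(uid: str) -> str:
    """Short, stable hash used to derive deterministic per-source names."""
    return hashlib.sha1(uid.encode("utf-8")).hexdigest()[:8]


def sanitize_component(uid: str) -> str:
    """Last path component of a uid, usable as an HDF5 node name."""
    tail = uid.rstrip("/").rsplit("/", 1)[-1]
    return tail if tail else uid_hash(uid)
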