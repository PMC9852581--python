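"""Minimal MAT v7.3 (HDF5-based) container backend.

Writes and reads the subset of the MATLAB HDF5 schema the standardized
containers need: double arrays, char vectors, logicals, scalar structs and
1xN struct arrays (stored as object-reference datasets under ``/#refs#``).
The 512-byte userblock carries the MAT-file free-text header with version
word 0x0200.  Object time-tracking is disabled everywhere so that writing the
same tree twice yields byte-identical files.

The in-memory exchange format ("tree") is shared with the v7 backend:
dict = struct, str = char, list-of-dict = 1xN struct array, bool ndarray =
logical, any other ndarray/float = double.
"""

from __future__ import annotations

import struct as _struct

import h5py
import numpy as np

__all__ = ["save_mat73", "load_mat73"]

_HEADER_TEXT = (
    b"MATLAB 7.3 MAT-file, Platform: PCWIN64, Created by: wearstd "
    b"HDF5 schema 1.00 ."
)


def _write_userblock(path) -> None:
    header = _HEADER_TEXT.ljust(116, b" ")[:116]
    header += b"\x00" * 8  # subsystem data offset
    header += _struct.pack("<H", 0x0200)
    header += b"IM"  # endian indicator
    header = header.ljust(512, b"\x00")
    with open(path, "r+b") as fh:
        fh.write(header)


def _notime_plist(cls):
    plist = h5py.h5p.create(cls)
    plist.set_obj_track_times(False)
    return plist


def _create_file(path) -> h5py.File:
    fcpl = _notime_plist(h5py.h5p.FILE_CREATE)
    fcpl.set_userblock(512)
    fid = h5py.h5f.create(
        str(path).encode(), h5py.h5f.ACC_TRUNC, fcpl=fcpl
    )
    return h5py.File(fid)


def _make_group(parent: h5py.Group, name: str) -> h5py.Group:
    gid = h5py.h5g.create(
        parent.id, name.encode(), gcpl=_notime_plist(h5py.h5p.GROUP_CREATE)
    )
    return h5py.Group(gid)


def _set_class(obj, matlab_class: bytes, int_decode: int | None = None) -> None:
    obj.attrs.create("MATLAB_class", np.bytes_(matlab_class))
    if int_decode is not None:
        obj.attrs.create("MATLAB_int_decode", np.int32(int_decode))


class _RefCounter:
    def __init__(self) -> None:
        self.n = 0

    def next_name(self) -> str:
        self.n += 1
        return f"r{self.n}"


def _write_dataset(parent: h5py.Group, name: str, data: np.ndarray, **kw):
    return parent.create_dataset(name, data=data, track_times=False, **kw)


def _write_node(parent: h5py.Group, name: str, node, refs: h5py.Group, ctr) -> None:
    if isinstance(node, dict):
        grp = _make_group(parent, name)
        _set_class(grp, b"struct")
        for key, value in node.items():
            _write_node(grp, key, value, refs, ctr)
        return
    if isinstance(node, str):
        codes = np.array([ord(c) for c in node], dtype=np.uint16)
        if codes.size == 0:
            ds = _write_dataset(parent, name, np.zeros((2,), dtype=np.uint64))
            _set_class(ds, b"char", int_decode=2)
            ds.attrs.create("MATLAB_empty", np.int32(1))
            return
        # MATLAB char is 1 x L; file dims are reversed -> (L, 1)
        ds = _write_dataset(parent, name, codes.reshape(-1, 1))
        _set_class(ds, b"char", int_decode=2)
        return
    if isinstance(node, list):  # 1 x N struct array via object references
        _write_struct_array(parent, name, node, refs, ctr)
        return
    arr = np.asarray(node)
    if arr.dtype == bool or arr.dtype == np.uint8 and getattr(node, "_logical", False):
        data = arr.astype(np.uint8)
        mat_shape = _matlab_shape(data)
        if data.size == 0:
            ds = _write_dataset(
                parent, name, np.asarray(mat_shape, dtype=np.uint64)
            )
            _set_class(ds, b"logical", int_decode=1)
            ds.attrs.create("MATLAB_empty", np.int32(1))
            return
        ds = _write_dataset(parent, name, data.reshape(mat_shape).T)
        _set_class(ds, b"logical", int_decode=1)
        return
    data = arr.astype(np.float64)
    mat_shape = _matlab_shape(data)
    if data.size == 0:
        ds = _write_dataset(parent, name, np.asarray(mat_shape, dtype=np.uint64))
        _set_class(ds, b"double")
        ds.attrs.create("MATLAB_empty", np.int32(1))
        return
    ds = _write_dataset(parent, name, data.reshape(mat_shape).T)
    _set_class(ds, b"double")


def _matlab_shape(arr: np.ndarray) -> tuple[int, ...]:
    """MATLAB-side dims: scalars (1,1), 1-D vectors as columns (N,1)."""
    if arr.ndim == 0:
        return (1, 1)
    if arr.ndim == 1:
        return (arr.shape[0], 1)
    return arr.shape


def _write_struct_array(
    parent: h5py.Group, name: str, elements: list, refs: h5py.Group, ctr
) -> None:
    if not all(isinstance(e, dict) for e in elements):
        raise TypeError(f"struct array {name!r} must contain only dicts")
    grp = _make_group(parent, name)
    _set_class(grp, b"struct")
    if not elements:
        grp.attrs.create("MATLAB_empty", np.int32(1))
        return
    fields: list[str] = []
    for e in elements:
        for k in e:
            if k not in fields:
                fields.append(k)
    n = len(elements)
    for fld in fields:
        refs_arr = np.empty((n, 1), dtype=h5py.ref_dtype)
        for i, e in enumerate(elements):
            ref_name = ctr.next_name()
            _write_node(refs, ref_name, e.get(fld, np.zeros((0,))), refs, ctr)
            refs_arr[i, 0] = refs[ref_name].ref
        ds = _write_dataset(grp, fld, refs_arr)
        ds.attrs.create("MATLAB_class", np.bytes_(b"cell"))


def save_mat73(path, variables: dict) -> None:
    """Write ``variables`` (name -> tree node) as a MAT v7.3 container."""
    f = _create_file(path)
    try:
        refs = _make_group(f, "#refs#")
        ctr = _RefCounter()
        for name, node in variables.items():
            _write_node(f, name, node, refs, ctr)
    finally:
        f.close()
    _write_userblock(path)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_node(obj, f: h5py.File):
    if isinstance(obj, h5py.Group):
        children = list(obj.keys())
        is_ref_ds = [
            isinstance(obj[c], h5py.Dataset) and obj[c].dtype == h5py.ref_dtype
            for c in children
        ]
        if children and all(is_ref_ds):
            # 1 x N struct array: every field is a reference dataset
            n = obj[children[0]].shape[0] if obj[children[0]].ndim else 1
            out = []
            for i in range(int(np.prod(obj[children[0]].shape))):
                elem = {}
                for c in children:
                    ref = np.asarray(obj[c][()]).ravel()[i]
                    elem[c] = _read_node(f[ref], f)
                out.append(elem)
            return out
        return {c: _read_node(obj[c], f) for c in children}
    mat_class = obj.attrs.get("MATLAB_class", b"")
    if isinstance(mat_class, bytes):
        cls = mat_class.decode()
    else:
        cls = str(mat_class)
    if obj.attrs.get("MATLAB_empty", 0):
        if cls == "char":
            return ""
        if cls == "struct":
            return []
        dtype = bool if cls == "logical" else np.float64
        return np.zeros((0,), dtype=dtype)
    data = obj[()]
    if cls == "char":
        codes = np.asarray(data, dtype=np.uint16).ravel()
        return "".join(chr(c) for c in codes)
    if cls == "logical":
        arr = np.squeeze(np.asarray(data).T.astype(bool))
        return bool(arr) if arr.ndim == 0 else arr
    arr = np.squeeze(np.asarray(data, dtype=np.float64).T)
    return float(arr) if arr.ndim == 0 else arr


def load_mat73(path) -> dict:
    """Read a MAT v7.3 container into the shared tree representation."""
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            if name == "#refs#":
                continue
            out[name] = _read_node(f[name], f)
    return out
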