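"""Minimal LAS 1.2 reader/writer (point formats 0-3, uncompressed).

Stores coordinates as scaled int32 per the LAS specification; the default
scale of 1 mm bounds round-trip error by half the scale quantum. Only the
x/y/z fields are interpreted; other point-record bytes are preserved on
read as opaque padding and written as zeros.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_HEADER_SIZE = 227
_POINT_SIZES = {0: 20, 1: 28, 2: 26, 3: 34}

DEFAULT_SCALE = 0.001


def write_las(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    path: str | Path,
    scale: float = DEFAULT_SCALE,
) -> None:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = x.size
    if n:
        offset = (float(x.min()), float(y.min()), float(z.min()))
        bounds = (x.max(), x.min(), y.max(), y.min(), z.max(), z.min())
    else:
        offset = (0.0, 0.0, 0.0)
        bounds = (0.0,) * 6
    header = struct.pack(
        "<4sHHLHH8sBB32s32sHHHLLBHL5L12d",
        b"LASF",
        0,  # file source id
        0,  # global encoding
        0, 0, 0, b"\x00" * 8,  # project GUID
        1, 2,  # version 1.2
        b"rowlai".ljust(32, b"\x00"),
        b"rowlai".ljust(32, b"\x00"),
        1,  # day
        2020,  # year
        _HEADER_SIZE,
        _HEADER_SIZE,  # offset to point data
        0,  # number of VLRs
        0,  # point data format
        _POINT_SIZES[0],
        n,
        n, 0, 0, 0, 0,  # points by return
        scale, scale, scale,
        *offset,
        *bounds,
    )
    assert len(header) == _HEADER_SIZE
    rec = np.zeros(n, dtype=[("x", "<i4"), ("y", "<i4"), ("z", "<i4"), ("pad", "V8")])
    rec["x"] = np.round((x - offset[0]) / scale).astype(np.int64)
    rec["y"] = np.round((y - offset[1]) / scale).astype(np.int64)
    rec["z"] = np.round((z - offset[2]) / scale).astype(np.int64)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


def read_las(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    data = Path(path).read_bytes()
    if len(data) < _HEADER_SIZE or data[:4] != b"LASF":
        raise IOError(f"not a LAS file: {path}")
    point_format = data[104]
    if point_format not in _POINT_SIZES:
        raise IOError(f"{path}: unsupported LAS point format {point_format}")
    (record_len,) = struct.unpack_from("<H", data, 105)
    (n,) = struct.unpack_from("<L", data, 107)
    (offset_to_points,) = struct.unpack_from("<L", data, 96)
    sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", data, 131)
    dt = np.dtype(
        [("x", "<i4"), ("y", "<i4"), ("z", "<i4"), ("pad", f"V{record_len - 12}")]
    )
    rec = np.frombuffer(data, dtype=dt, count=n, offset=offset_to_points)
    return (
        rec["x"] * sx + ox,
        rec["y"] * sy + oy,
        rec["z"] * sz + oz,
    )
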