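"""Minimal reader/writer for the C3D motion-capture container.

Supports the common modern subset: Intel (little-endian) byte order and
floating-point 3D/analog data.  Integer-scaled data and DEC/MIPS byte orders
are rejected with a FormatError.  The writer exists mainly so synthetic
trials can be exported to (and round-tripped through) the standard format.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .core_io import FormatError

_BLOCK = 512
_INTEL = 84


@dataclass
class C3DData:
    point_labels: list[str]
    points: np.ndarray  # (frames, npoints, 3)
    point_rate: float
    point_units: str
    analog_labels: list[str]
    analog: np.ndarray  # (frames*apf, nchan)
    analog_rate: float


def _read_params(buf: bytes, start: int) -> dict[str, dict[str, object]]:
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    if len(buf) < start + 4:
        raise FormatError("truncated parameter section")
    proc = buf[start + 3]
    if proc != _INTEL:
        raise FormatError(f"unsupported processor type {proc} (only Intel supported)")
    pos = start + 4
    group_names: dict[int, str] = {}
    params: dict[int, dict[str, object]] = {}
    while pos < len(buf):
        nname = struct.unpack_from("b", buf, pos)[0]
        if nname == 0:
            break
        gid = struct.unpack_from("b", buf, pos + 1)[0]
        name = buf[pos + 2 : pos + 2 + abs(nname)].decode("ascii").strip()
        p = pos + 2 + abs(nname)
        offset = struct.unpack_from("<h", buf, p)[0]
        next_pos = p + offset if offset > 0 else len(buf)
        p += 2
        if gid < 0:  # group definition
            group_names[-gid] = name
        else:  # parameter
            dtype = struct.unpack_from("b", buf, p)[0]
            ndim = buf[p + 1]
            dims = list(buf[p + 2 : p + 2 + ndim])
            p += 2 + ndim
            count = int(np.prod(dims)) if dims else 1
            if dtype == -1:
                raw = buf[p : p + count]
                if ndim <= 1:
                    value: object = raw.decode("ascii").strip()
                else:
                    width = dims[0]
                    n = count // width
                    value = [
                        raw[i * width : (i + 1) * width].decode("ascii").strip()
                        for i in range(n)
                    ]
            elif dtype == 1:
                value = np.frombuffer(buf, np.int8, count, p)
            elif dtype == 2:
                value = np.frombuffer(buf, "<i2", count, p)
            elif dtype == 4:
                value = np.frombuffer(buf, "<f4", count, p)
            else:
                raise FormatError(f"unknown parameter type {dtype} for {name}")
            params.setdefault(gid, {})[name] = value
        if offset <= 0:
            break
        pos = next_pos
    out: dict[str, dict[str, object]] = {}
    for gid, ps in params.items():
        out[group_names.get(gid, f"GROUP{gid}")] = ps
    return out


def _scalar(v, cast=float):
    arr = np.asarray(v).ravel()
    return cast(arr[0])


def read_c3d_file(path) -> C3DData:
    """Read a float-format Intel C3D file."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < _BLOCK or buf[1] != 0x50:
        raise FormatError("not a C3D file (bad magic)")
    hdr = struct.unpack_from("<8h", buf, 0)
    first_param_block = buf[0]
    npoints = hdr[1]
    analog_per_frame_total = hdr[2]
    first_frame, last_frame = hdr[3], hdr[4]
    scale = struct.unpack_from("<f", buf, 12)[0]
    data_start_block = struct.unpack_from("<h", buf, 16)[0]
    apf = struct.unpack_from("<h", buf, 18)[0]  # analog samples/frame/channel
    point_rate = struct.unpack_from("<f", buf, 20)[0]
    if scale >= 0:
        raise FormatError("integer-scaled C3D data is not supported")
    groups = _read_params(buf, (first_param_block - 1) * _BLOCK)

    point = groups.get("POINT", {})
    analog = groups.get("ANALOG", {})
    if "USED" in point:
        npoints = _scalar(point["USED"], int)
    n_frames = last_frame - first_frame + 1
    if "FRAMES" in point:
        n_frames = _scalar(point["FRAMES"], int)
    if "RATE" in point:
        point_rate = _scalar(point["RATE"])
    units = str(point.get("UNITS", "m"))
    labels = list(point.get("LABELS", []))[:npoints]
    nchan = _scalar(analog["USED"], int) if "USED" in analog else 0
    if nchan and apf == 0 and nchan:
        apf = analog_per_frame_total // nchan

    pos = (data_start_block - 1) * _BLOCK
    words_per_frame = 4 * npoints + nchan * apf
    raw = np.frombuffer(buf, "<f4", n_frames * words_per_frame, pos)
    raw = raw.reshape(n_frames, words_per_frame)
    pts = raw[:, : 4 * npoints].reshape(n_frames, npoints, 4)[:, :, :3].astype(float)
    to_m = 0.001 if units.lower().startswith("mm") else 1.0
    pts = pts * to_m
    if nchan:
        asig = raw[:, 4 * npoints :].reshape(n_frames * apf, nchan).astype(float)
        gen = _scalar(analog.get("GEN_SCALE", 1.0))
        chan_scale = np.asarray(analog.get("SCALE", np.ones(nchan)), float).ravel()[:nchan]
        offs = np.asarray(analog.get("OFFSET", np.zeros(nchan)), float).ravel()[:nchan]
        asig = (asig - offs) * chan_scale * gen
        analog_labels = list(analog.get("LABELS", []))[:nchan]
    else:
        asig = np.zeros((0, 0))
        analog_labels = []
    return C3DData(
        point_labels=[str(l) for l in labels],
        points=pts,
        point_rate=float(point_rate),
        point_units="m",
        analog_labels=[str(l) for l in analog_labels],
        analog=asig,
        analog_rate=float(point_rate) * (apf or 1),
    )


# ---------------------------------------------------------------------------
# writer


def _char_param(name: str, values: list[str]) -> bytes:
    width = max((len(v) for v in values), default=1)
    data = b"".join(v.ljust(width).encode("ascii") for v in values)
    return _param(name, -1, [width, len(values)], data)


def _param(name: str, dtype: int, dims: list[int], data: bytes) -> bytes:
    body = struct.pack("bb", dtype, len(dims)) + bytes(dims) + data + b"\x00"
    head = struct.pack("bb", len(name), 0) + name.encode("ascii")
    # group id patched by caller; offset = len(body) + 2
    return head + struct.pack("<h", len(body) + 2) + body


def _patch_gid(rec: bytes, gid: int) -> bytes:
    return rec[:1] + struct.pack("b", gid) + rec[2:]


def write_c3d_file(
    path,
    point_labels: list[str],
    points: np.ndarray,
    point_rate: float,
    *,
    units: str = "m",
    analog_labels: list[str] | None = None,
    analog: np.ndarray | None = None,
    analog_per_frame: int = 1,
) -> None:
    """Write a float-format Intel C3D file (residuals set to zero)."""
    points = np.asarray(points, float)
    n_frames, npoints = points.shape[0], points.shape[1]
    analog_labels = analog_labels or []
    nchan = len(analog_labels)
    if nchan:
        analog = np.asarray(analog, float)
        if analog.shape != (n_frames * analog_per_frame, nchan):
            raise FormatError("analog must be (frames*analog_per_frame, nchan)")

    def group(gid: int, name: str) -> bytes:
        head = struct.pack("bb", -len(name), -gid) + name.encode("ascii")
        return head + struct.pack("<h", 3) + b"\x00"

    recs = [group(1, "POINT")]
    pp = [
        _param("USED", 2, [], struct.pack("<h", npoints)),
        _param("FRAMES", 2, [], struct.pack("<h", min(n_frames, 32767))),
        _param("SCALE", 4, [], struct.pack("<f", -1.0)),
        _param("RATE", 4, [], struct.pack("<f", point_rate)),
        _param("UNITS", -1, [len(units)], units.encode("ascii")),
        _char_param("LABELS", point_labels),
    ]
    recs += [_patch_gid(r, 1) for r in pp]
    if nchan:
        recs.append(group(2, "ANALOG"))
        ap = [
            _param("USED", 2, [], struct.pack("<h", nchan)),
            _param("GEN_SCALE", 4, [], struct.pack("<f", 1.0)),
            _param("SCALE", 4, [nchan], struct.pack(f"<{nchan}f", *([1.0] * nchan))),
            _param("OFFSET", 2, [nchan], struct.pack(f"<{nchan}h", *([0] * nchan))),
            _param("RATE", 4, [], struct.pack("<f", point_rate * analog_per_frame)),
            _char_param("LABELS", analog_labels),
        ]
        recs += [_patch_gid(r, 2) for r in ap]
    param_body = b"".join(recs) + b"\x00\x00"
    param_blocks = -(-(len(param_body) + 4) // _BLOCK)
    data_start = 2 + param_blocks

    header = bytearray(_BLOCK)
    struct.pack_into("<8h", header, 0, 0, npoints, nchan * analog_per_frame, 1, n_frames, 10, 0, 0)
    header[0] = 2  # first parameter block
    header[1] = 0x50
    struct.pack_into("<f", header, 12, -1.0)
    struct.pack_into("<h", header, 16, data_start)
    struct.pack_into("<h", header, 18, analog_per_frame if nchan else 0)
    struct.pack_into("<f", header, 20, point_rate)

    param_sec = bytearray(param_blocks * _BLOCK)
    param_sec[0] = 1
    param_sec[1] = 0x50
    param_sec[2] = param_blocks
    param_sec[3] = _INTEL
    param_sec[4 : 4 + len(param_body)] = param_body

    words_per_frame = 4 * npoints + nchan * analog_per_frame
    data = np.zeros((n_frames, words_per_frame), "<f4")
    pd4 = np.zeros((n_frames, npoints, 4), "<f4")
    scale_out = 1000.0 if units.lower().startswith("mm") else 1.0
    pd4[:, :, :3] = points * scale_out
    data[:, : 4 * npoints] = pd4.reshape(n_frames, 4 * npoints)
    if nchan:
        data[:, 4 * npoints :] = analog.reshape(n_frames, nchan * analog_per_frame)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(param_sec)
        payload = data.tobytes()
        fh.write(payload)
        pad = (-len(payload)) % _BLOCK
        fh.write(b"\x00" * pad)
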