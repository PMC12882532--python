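"""Minimal MRC2014 reader/writer for single 2D images.

Supports modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16), little-endian
only, with the pixel size stored in the cell dimensions (apix = xlen / mx) and
free-form key=value annotations in the 80-character header labels.
"""

from __future__ import annotations

import numpy as np

HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_MODES = {np.dtype(d): m for m, d in _MODE_DTYPES.items()}


class MrcError(IOError):
    """Raised when a file cannot be parsed as MRC2014."""


def write_mrc(path, data: np.ndarray, pixel_size: float = 1.0,
              labels: tuple[str, ...] = ()) -> None:
    """Write a 2D array as a single-section MRC2014 file.

    ``pixel_size`` is in Å/pixel; ``labels`` are up to ten 80-character
    strings stored verbatim in the header label block.
    """
    data = np.asarray(data)
    if data.ndim != 2:
        raise MrcError(f"only 2D images are supported, got ndim={data.ndim}")
    if data.dtype not in _DTYPE_MODES:
        raise MrcError(f"unsupported dtype {data.dtype}; use one of "
                       f"{sorted(str(d) for d in _DTYPE_MODES)}")
    if len(labels) > 10:
        raise MrcError("at most 10 header labels are allowed")
    ny, nx = data.shape
    mode = _DTYPE_MODES[data.dtype]

    hdr_i = np.zeros(256, dtype="<i4")
    hdr_f = hdr_i.view("<f4")
    hdr_i[0:3] = (nx, ny, 1)          # nx, ny, nz
    hdr_i[3] = mode
    hdr_i[7:10] = (nx, ny, 1)         # mx, my, mz
    hdr_f[10:13] = (nx * pixel_size, ny * pixel_size, pixel_size)  # cella
    hdr_f[13:16] = 90.0               # cell angles
    hdr_i[16:19] = (1, 2, 3)          # mapc, mapr, maps
    hdr_f[19] = float(data.min()) if data.size else 0.0
    hdr_f[20] = float(data.max()) if data.size else 0.0
    hdr_f[21] = float(data.mean()) if data.size else 0.0
    hdr_i[22] = 0                     # ispg: image stack
    hdr_i[27] = 20140                 # nversion
    hdr_i[52] = int.from_bytes(b"MAP ", "little")
    hdr_i[53] = int.from_bytes(bytes((0x44, 0x44, 0, 0)), "little")  # machst LE
    hdr_f[54] = float(data.std()) if data.size else 0.0
    hdr_i[55] = len(labels)
    header = bytearray(hdr_i.tobytes())
    for k, lab in enumerate(labels):
        enc = lab.encode("ascii", "replace")[:80].ljust(80)
        header[224 + 80 * k: 224 + 80 * (k + 1)] = enc

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data).tobytes())


def read_mrc(path) -> tuple[np.ndarray, float, list[str]]:
    """Read a 2D (or single-section 3D) MRC2014 file.

    Returns ``(data, pixel_size, labels)`` with data shaped (rows, cols).
    """
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise MrcError(f"{path}: truncated header")
        hdr_i = np.frombuffer(header, dtype="<i4", count=256)
        hdr_f = hdr_i.view("<f4")
        if header[208:212] != b"MAP ":
            raise MrcError(f"{path}: missing MAP identifier; not MRC2014")
        nx, ny, nz, mode = int(hdr_i[0]), int(hdr_i[1]), int(hdr_i[2]), int(hdr_i[3])
        if mode not in _MODE_DTYPES:
            raise MrcError(f"{path}: unsupported MRC mode {mode}")
        if nz != 1:
            raise MrcError(f"{path}: expected a single 2D section, got nz={nz}")
        nsymbt = int(hdr_i[23])
        if nsymbt:
            fh.seek(nsymbt, 1)
        dtype = np.dtype(_MODE_DTYPES[mode])
        n_expect = nx * ny
        data = np.fromfile(fh, dtype=dtype, count=n_expect)
        if data.size != n_expect:
            raise MrcError(f"{path}: truncated data block "
                           f"({data.size} of {n_expect} values)")
    mx = int(hdr_i[7]) or nx
    xlen = float(hdr_f[10])
    pixel_size = xlen / mx if xlen > 0 else 0.0
    nlabl = int(hdr_i[55])
    labels = []
    for k in range(max(0, min(nlabl, 10))):
        raw = header[224 + 80 * k: 224 + 80 * (k + 1)]
        labels.append(raw.decode("ascii", "replace").rstrip())
    return data.reshape(ny, nx), pixel_size, labels
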