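"""MRC2014 stack I/O, gain/dark correction, file-size model, and the
ground-truth JSON sidecar.

The writer emits the standard MRC2014 layout: a 1024-byte header (no
extended header), little-endian with machine stamp, frame data stored as
z-slices. Supported data modes: 0 (int8), 1 (int16), 2 (float32, the movie
default), 6 (uint16). The reader honours the machine stamp for endianness
and tolerates (skips) an extended header.
"""

from __future__ import annotations

import json
import os
import struct
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, InvalidParameterError
from .motion import MotionGroundTruth
from .phantom import FrameStack

__all__ = [
    "MrcStackInfo",
    "write_mrc",
    "read_mrc",
    "expected_file_size",
    "apply_gain_dark",
    "write_ground_truth",
    "read_ground_truth",
]

HEADER_BYTES = 1024

_MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    6: np.dtype(np.uint16),
}


@dataclass(frozen=True)
class MrcStackInfo:
    """Parsed MRC header essentials."""

    nx: int
    ny: int
    nz: int
    mode: int
    pixel_size: float
    header_bytes: int = HEADER_BYTES

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise FormatError("nx/ny/nz must be >= 1")
        if self.mode not in _MODE_DTYPES:
            raise FormatError(f"unsupported MRC mode {self.mode}")


def bytes_per_pixel(mode: int) -> int:
    if mode not in _MODE_DTYPES:
        raise InvalidParameterError(f"unsupported MRC mode {mode}")
    return _MODE_DTYPES[mode].itemsize


def expected_file_size(nx: int, ny: int, nz: int, mode: int = 2) -> int:
    """Predicted on-disk size in bytes: 1024-byte header + raw voxel data."""
    if min(nx, ny, nz) < 1:
        raise InvalidParameterError("dims must be >= 1")
    return HEADER_BYTES + nx * ny * nz * bytes_per_pixel(mode)


def _build_header(
    nx: int, ny: int, nz: int, mode: int, pixel_size: float, data: np.ndarray
) -> bytes:
    header = bytearray(HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # NX NY NZ
    struct.pack_into("<i", header, 12, mode)                # MODE
    struct.pack_into("<3i", header, 16, 0, 0, 0)            # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)         # MX MY MZ
    struct.pack_into(                                       # CELLA (Å)
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # MAPC MAPR MAPS
    struct.pack_into(                                       # DMIN DMAX DMEAN
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 0)                   # ISPG (image stack)
    struct.pack_into("<i", header, 92, 0)                   # NSYMBT
    header[208:212] = b"MAP "                               # MAP id
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])       # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))  # RMS
    struct.pack_into("<i", header, 220, 0)                  # NLABL
    return bytes(header)


def write_mrc(
    stack: "FrameStack | np.ndarray",
    path: str | os.PathLike,
    mode: int = 2,
    pixel_size: float | None = None,
) -> None:
    """Write a frame stack or single image as an MRC2014 file.

    Integer modes reject values outside the dtype's representable range
    rather than silently wrapping.
    """
    if isinstance(stack, FrameStack):
        data = stack.frames
        pixel_size = stack.pixel_size if pixel_size is None else pixel_size
    else:
        data = np.asarray(stack)
        pixel_size = 1.0 if pixel_size is None else pixel_size
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise InvalidParameterError("expected 2-D image or 3-D stack")
    dtype = _MODE_DTYPES.get(mode)
    if dtype is None:
        raise InvalidParameterError(f"unsupported MRC mode {mode}")
    if dtype.kind in "iu":
        info = np.iinfo(dtype)
        if data.min() < info.min or data.max() > info.max:
            raise InvalidParameterError(
                f"values outside mode-{mode} range [{info.min}, {info.max}]"
            )
    out = np.ascontiguousarray(data, dtype=dtype.newbyteorder("<"))
    nz, ny, nx = out.shape
    header = _build_header(nx, ny, nz, mode, pixel_size, data)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(out.tobytes())


def read_mrc(path: str | os.PathLike) -> tuple[FrameStack, MrcStackInfo]:
    """Read an MRC file; integer modes are promoted losslessly to float."""
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise FormatError("header: file shorter than 1024 bytes")
        stamp = header[212:214]
        if stamp == b"\x44\x44" or stamp == b"\x44\x41":
            endian = "<"
        elif stamp == b"\x11\x11":
            endian = ">"
        else:
            # pre-2014 writers often leave the stamp empty; assume little
            endian = "<"
        nx, ny, nz = struct.unpack_from(f"{endian}3i", header, 0)
        (mode,) = struct.unpack_from(f"{endian}i", header, 12)
        if min(nx, ny, nz) < 1:
            raise FormatError(f"nx/ny/nz: non-positive dimensions ({nx},{ny},{nz})")
        if mode not in _MODE_DTYPES:
            raise FormatError(f"mode: unsupported value {mode}")
        mx = struct.unpack_from(f"{endian}i", header, 28)[0]
        cella_x = struct.unpack_from(f"{endian}f", header, 40)[0]
        pixel_size = cella_x / mx if mx > 0 and cella_x > 0 else 1.0
        (nsymbt,) = struct.unpack_from(f"{endian}i", header, 92)
        if nsymbt < 0:
            raise FormatError(f"nsymbt: negative extended header length {nsymbt}")
        if nsymbt:
            fh.seek(nsymbt, os.SEEK_CUR)
        dtype = _MODE_DTYPES[mode].newbyteorder(endian)
        count = nx * ny * nz
        raw = fh.read(count * dtype.itemsize)
        if len(raw) < count * dtype.itemsize:
            raise FormatError("data: file truncated before end of voxel data")
        data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx)
    info = MrcStackInfo(
        nx=nx, ny=ny, nz=nz, mode=mode, pixel_size=pixel_size,
        header_bytes=HEADER_BYTES + nsymbt,
    )
    frames = data.astype(np.float64)
    return FrameStack(frames=frames, pixel_size=pixel_size), info


def apply_gain_dark(
    frames: np.ndarray, gain: np.ndarray, dark: np.ndarray
) -> np.ndarray:
    """Detector correction: ``corrected = (raw - dark) * gain`` per pixel.

    ``frames`` may be a single image or a stack; gain/dark must match the
    frame dims.
    """
    frames = np.asarray(frames, dtype=np.float64)
    gain = np.asarray(gain, dtype=np.float64)
    dark = np.asarray(dark, dtype=np.float64)
    frame_shape = frames.shape[-2:]
    if gain.shape != frame_shape or dark.shape != frame_shape:
        raise InvalidParameterError(
            f"gain/dark dims {gain.shape}/{dark.shape} != frame dims {frame_shape}"
        )
    return (frames - dark) * gain


_GT_FIELDS = ("frame_index", "shift_x_px", "shift_y_px", "k1", "k2")


def write_ground_truth(truth: MotionGroundTruth, path: str | os.PathLike) -> None:
    """Persist the exact motion as a JSON sidecar, one record per frame."""
    records = [
        {
            "frame_index": t,
            "shift_x_px": float(truth.shifts[t, 0]),
            "shift_y_px": float(truth.shifts[t, 1]),
            "k1": float(truth.k_coeffs[t, 0]),
            "k2": float(truth.k_coeffs[t, 1]),
        }
        for t in range(truth.n_frames)
    ]
    payload = {
        "dims": list(truth.dims),
        "normalization": truth.normalization,
        "frames": records,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path: str | os.PathLike) -> MotionGroundTruth:
    """Load a ground-truth sidecar; errors name the missing field."""
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("dims", "normalization", "frames"):
        if key not in payload:
            raise FormatError(f"ground-truth sidecar: missing field {key!r}")
    shifts, ks = [], []
    for i, rec in enumerate(payload["frames"]):
        for key in _GT_FIELDS:
            if key not in rec:
                raise FormatError(
                    f"ground-truth sidecar: frame {i} missing field {key!r}"
                )
        shifts.append((rec["shift_x_px"], rec["shift_y_px"]))
        ks.append((rec["k1"], rec["k2"]))
    return MotionGroundTruth(
        shifts=np.array(shifts),
        k_coeffs=np.array(ks),
        dims=tuple(payload["dims"]),
        normalization=payload["normalization"],
    )
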