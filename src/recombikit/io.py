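"""Shared format readers/writers: TIFF, PNG, MRC, CSV.

Conventions: CSV is comma-separated, header row, UTF-8, '.' decimal, with
units embedded in column names (``length_nm``). Rasters round-trip
losslessly as 32-bit float TIFF. Coordinates are 0-based and intervals
half-open throughout the package.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "read_mrc",
    "SchemaError",
]


class SchemaError(ValueError):
    """A table is missing a required column."""


_MRC_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_mrc(path) -> tuple[np.ndarray, float | None]:
    """Read a 2-D (or first-section 3-D) MRC2014 map.

    Returns ``(data, pixel_size_A)``; the pixel size is taken from the
    header cell dimensions when present (cella.x / nx), else None.
    Supported modes: 0 (int8), 1 (int16), 2 (float32), 6 (uint16).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise ValueError("corrupt MRC header: file shorter than 1024 bytes")
    nx, ny, nz, mode = struct.unpack("<4i", raw[0:16])
    if mode not in _MRC_MODE_DTYPES:
        raise ValueError(f"unsupported MRC mode {mode}")
    cella = struct.unpack("<3f", raw[40:52])
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    machst = raw[212:216]
    if machst[:2] not in (b"\x44\x44", b"\x44\x41", b"\x00\x00"):
        raise ValueError("unsupported MRC byte order (big-endian)")
    dtype = _MRC_MODE_DTYPES[mode]
    count = nx * ny * max(nz, 1)
    offset = 1024 + nsymbt
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    data = data.reshape((max(nz, 1), ny, nx)).astype(np.float32)
    pixel_size = cella[0] / nx if cella[0] > 0 and nx > 0 else None
    return (data[0] if data.shape[0] == 1 else data), pixel_size


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a raster; returns ``(array, metadata)``.

    Recognized extensions: .tif/.tiff (multi-page stacks come back as a
    3-D array), .png, .mrc/.map (mode-2 float supported; ``pixel_size_A``
    in the metadata when the header carries cell dimensions), .csv (plain
    numeric matrix, no header).
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(p)), {}
    if suffix == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(p)), {}
    if suffix in (".mrc", ".map"):
        data, px = read_mrc(p)
        meta = {"pixel_size_A": px} if px else {}
        return data, meta
    if suffix == ".csv":
        return np.loadtxt(p, delimiter=","), {}
    raise ValueError(f"unrecognized image extension: {suffix!r}")


def write_image(path, data: np.ndarray) -> None:
    """Write a raster (float32 TIFF, uint8 PNG, or headerless CSV matrix)."""
    p = Path(path)
    suffix = p.suffix.lower()
    data = np.asarray(data)
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(p, data.astype(np.float32))
        return
    if suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(p, data.astype(np.uint8))
        return
    if suffix == ".csv":
        np.savetxt(p, np.atleast_2d(data), delimiter=",")
        return
    raise ValueError(f"unrecognized image extension: {suffix!r}")


def read_table(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally validating its schema.

    Raises :class:`SchemaError` naming the first missing required column.
    """
    df = pd.read_csv(path)
    for col in required_columns or []:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
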