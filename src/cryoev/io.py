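"""File formats: MRC and TIFF micrographs, mask images, particle-record
CSV, distribution/metrics JSON, YAML configs.

nm is the single physical unit across all in-memory interfaces; the MRC
header stores Angstrom and the conversion happens only here at the file
boundary. The MRC support is a minimal MRC2014 implementation (2-D
single-section images, modes 0/1/2/6 read, mode 2 float32 write, pixel
size from the cell dimensions).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import Micrograph, ParticleRecord

__all__ = [
    "read_micrograph",
    "write_mrc",
    "write_tiff",
    "write_mask_png",
    "read_mask",
    "records_to_dataframe",
    "write_records_csv",
    "read_records_csv",
    "write_json",
    "read_json",
    "write_yaml",
    "read_yaml",
]

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}

RECORD_COLUMNS = [
    "image_id", "class_name", "y", "x", "radius_px", "diameter_nm",
    "score", "source", "border_truncated", "excluded", "exclusion_reason",
]


# ---------------------------------------------------------------------------
# MRC


def write_mrc(m: Micrograph, path) -> None:
    """Write a 2-D micrograph as MRC2014 mode 2 (float32) with the pixel
    size recorded in the cell dimensions (Angstrom)."""
    data = np.asarray(m.pixels, dtype="<f4")
    ny, nx = data.shape
    apix = m.pixel_size * 10.0  # nm -> Angstrom
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, 1)  # nx ny nz
    struct.pack_into("<i", header, 12, 2)  # mode 2
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx my mz
    struct.pack_into("<3f", header, 40, nx * apix, ny * apix, apix)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc mapr maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def _read_mrc(path):
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode = struct.unpack_from("<i", header, 12)[0]
        mx = struct.unpack_from("<i", header, 28)[0]
        xlen = struct.unpack_from("<f", header, 40)[0]
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        if mode not in _MRC_MODES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        if nz != 1:
            raise ValueError(f"{path}: expected a single 2-D section, got nz={nz}")
        fh.seek(1024 + nsymbt)
        dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
        data = np.frombuffer(fh.read(nx * ny * dtype.itemsize), dtype=dtype)
        if data.size != nx * ny:
            raise ValueError(f"{path}: truncated MRC data")
        data = data.reshape(ny, nx).astype(np.float64)
    apix = (xlen / mx) if (mx > 0 and xlen > 0) else None
    pixel_size_nm = apix / 10.0 if apix else None
    return data, pixel_size_nm


def read_micrograph(path, pixel_size_override: float = None) -> Micrograph:
    """Read an MRC or TIFF micrograph.

    MRC pixel size comes from the header (Angstrom -> nm), overridable;
    TIFF carries no trusted physical size here, so an explicit
    ``pixel_size_override`` (nm) is required.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mrc":
        data, pixel_size = _read_mrc(path)
        if pixel_size_override is not None:
            pixel_size = pixel_size_override
        if pixel_size is None or pixel_size <= 0:
            raise ValueError(f"{path}: MRC header has no usable pixel size; "
                             f"pass pixel_size_override")
        return Micrograph(pixels=data, pixel_size=pixel_size)
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a 2-D TIFF")
        if pixel_size_override is None:
            raise ValueError(f"{path}: TIFF requires an explicit pixel size (nm)")
        return Micrograph(pixels=np.asarray(data, dtype=np.float64),
                          pixel_size=pixel_size_override)
    raise ValueError(f"{path}: unsupported micrograph format {suffix!r}")


# ---------------------------------------------------------------------------
# TIFF / masks


def write_tiff(m: Micrograph, path, dtype: str = "uint16") -> None:
    """Write as 8- or 16-bit TIFF, linearly scaled to the dtype range."""
    px = np.asarray(m.pixels, dtype=np.float64)
    lo, hi = px.min(), px.max()
    span = hi - lo if hi > lo else 1.0
    if dtype == "uint8":
        out = ((px - lo) / span * 255).astype(np.uint8)
    elif dtype == "uint16":
        out = ((px - lo) / span * 65535).astype(np.uint16)
    elif dtype == "float32":
        out = px.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, out)


def write_mask_png(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask).astype(bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    import imageio.v3 as iio

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) > 0


# ---------------------------------------------------------------------------
# particle records


def records_to_dataframe(records: list, image_id: str = "") -> pd.DataFrame:
    rows = [{
        "image_id": image_id, "class_name": r.class_name, "y": r.y, "x": r.x,
        "radius_px": r.radius_px, "diameter_nm": r.diameter_nm, "score": r.score,
        "source": r.source, "border_truncated": r.border_truncated,
        "excluded": r.excluded, "exclusion_reason": r.exclusion_reason,
    } for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records_csv(records, path, image_id: str = "") -> None:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_dataframe(records, image_id=image_id)
    df.to_csv(path, index=False)


def read_records_csv(path) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(ParticleRecord(
            class_name=row["class_name"], y=float(row["y"]), x=float(row["x"]),
            radius_px=float(row["radius_px"]), diameter_nm=float(row["diameter_nm"]),
            score=float(row["score"]), source=row["source"],
            border_truncated=bool(row["border_truncated"]),
            excluded=bool(row["excluded"]),
            exclusion_reason=str(row["exclusion_reason"]),
        ))
    return records


# ---------------------------------------------------------------------------
# JSON / YAML


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
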