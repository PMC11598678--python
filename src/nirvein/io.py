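"""Image and disparity-map I/O.

Grayscale rasters move through the toolkit as float64 arrays in [0, 1]
(row-major, 0-based ``(row, col)`` indexing); files on disk are 8- or
16-bit PNG/TIFF/PGM.  Ground-truth and estimated disparity maps use the
Middlebury PFM dialect: a ``Pf`` header, a scale line whose sign encodes
endianness (negative = little-endian), and rows stored bottom-up.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_image",
    "read_pfm",
    "write_pfm",
    "to_uint8",
    "to_float",
]

# ITU-R BT.601 luma weights, used when an RGB file is handed to a
# grayscale pipeline.
_LUMA = np.array([0.299, 0.587, 0.114])


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a float image in [0, 1] to 8-bit."""
    img = np.asarray(img, dtype=np.float64)
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def to_float(img: np.ndarray) -> np.ndarray:
    """Normalize an integer image to float64 in [0, 1]."""
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float64) / 65535.0
    return img.astype(np.float64)


def read_image(path: str | Path, as_float: bool = True) -> np.ndarray:
    """Read a grayscale image; RGB inputs are collapsed with BT.601 weights."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        log.info("%s: RGB input collapsed to grayscale with BT.601 weights", path)
        arr = (arr.astype(np.float64) @ _LUMA)
        if not as_float:
            return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        return arr / 255.0
    return to_float(arr) if as_float else arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a grayscale image; float inputs are quantized to 8-bit."""
    img = np.asarray(img)
    if img.dtype == bool:
        img = img.astype(np.uint8) * 255
    elif img.dtype not in (np.uint8, np.uint16):
        img = to_uint8(img)
    iio.imwrite(Path(path), img)


def read_pfm(path: str | Path) -> np.ndarray:
    """Read a single-channel PFM file into a float32 array (row 0 on top)."""
    data = Path(path).read_bytes()
    m = re.match(rb"(P[fF])\s+(\d+)\s+(\d+)\s+([-+0-9.eE]+)\s", data)
    if m is None:
        raise ValueError(f"{path}: malformed PFM header near offset 0")
    if m.group(1) != b"Pf":
        raise ValueError(f"{path}: only single-channel 'Pf' files are supported")
    width, height = int(m.group(2)), int(m.group(3))
    scale = float(m.group(4))
    if scale == 0:
        raise ValueError(f"{path}: PFM scale must be nonzero (offset {m.start(4)})")
    offset = m.end()
    count = width * height
    raw = data[offset : offset + 4 * count]
    if len(raw) < 4 * count:
        raise ValueError(f"{path}: truncated PFM payload at offset {offset + len(raw)}")
    endian = "<" if scale < 0 else ">"
    arr = np.frombuffer(raw, dtype=endian + "f4").reshape(height, width)
    return arr[::-1].astype(np.float32)  # PFM stores rows bottom-up


def write_pfm(path: str | Path, arr: np.ndarray, scale: float = 1.0) -> None:
    """Write a float map as little-endian PFM (negative scale line)."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError("PFM writer expects a 2-D array")
    if scale <= 0:
        raise ValueError("scale must be positive; endianness sets the sign")
    h, w = arr.shape
    header = f"Pf\n{w} {h}\n{-scale}\n".encode("ascii")
    payload = arr[::-1].astype("<f4").tobytes()
    Path(path).write_bytes(header + payload)
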