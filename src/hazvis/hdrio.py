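"""Reading and writing luminance images, masks, and their metadata.

Luminance maps travel as HDR images — PFM or 32-bit float TIFF — with a
small YAML sidecar carrying the semantically required metadata: pixels per
degree and the cd/m² scale factor.  A missing ``ppd`` is an error, never a
guess.  Binary masks (edges, ROIs) round-trip through PNG.

The PFM codec is implemented here directly (the format is a three-line
ASCII header followed by raw float32 scanlines, bottom-up); TIFF goes
through :mod:`tifffile` and PNG through :mod:`imageio`.
"""

from __future__ import annotations

import pathlib

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .exceptions import InvalidInputError
from .filtering import LuminanceImage


def write_pfm(path, values: np.ndarray, scale: float = -1.0) -> None:
    """Write a 2-D float array as a grayscale PFM (little-endian)."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2:
        raise InvalidInputError("PFM writer expects a 2-D grayscale array")
    path = pathlib.Path(path)
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{values.shape[1]} {values.shape[0]}\n".encode())
        fh.write(f"{-abs(scale)}\n".encode())  # negative scale = little-endian
        fh.write(np.flipud(values).astype("<f4").tobytes())


def read_pfm(path) -> np.ndarray:
    """Read a grayscale PFM into a float64 array (top-down row order)."""
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header not in (b"Pf", b"PF"):
            raise InvalidInputError(f"{path}: not a PFM file")
        if header == b"PF":
            raise InvalidInputError(f"{path}: color PFM not supported; luminance only")
        dims = fh.readline().split()
        width, height = int(dims[0]), int(dims[1])
        scale = float(fh.readline())
        dtype = "<f4" if scale < 0 else ">f4"
        data = np.frombuffer(fh.read(width * height * 4), dtype=dtype)
    values = data.reshape(height, width).astype(float)
    if abs(scale) not in (0.0, 1.0):
        values = values * abs(scale)
    return np.flipud(values).copy()


def _sidecar_path(path: pathlib.Path) -> pathlib.Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_luminance(path, img: LuminanceImage) -> None:
    """Write a luminance image (PFM or float TIFF by extension) + sidecar."""
    path = pathlib.Path(path)
    if path.suffix.lower() == ".pfm":
        write_pfm(path, img.values)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.values.astype(np.float32))
    else:
        raise InvalidInputError(f"unsupported luminance format {path.suffix!r}; use .pfm or .tif")
    meta = {"ppd": float(img.ppd), "units": "cd/m^2", "scale": 1.0}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def load_luminance(path, ppd: float | None = None) -> LuminanceImage:
    """Read a luminance image; ``ppd`` comes from the sidecar unless given.

    Raises an explicit error when no angular resolution is available — the
    whole model is expressed in cycles/degree and cannot proceed without it.
    """
    path = pathlib.Path(path)
    if path.suffix.lower() == ".pfm":
        values = read_pfm(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path).astype(float)
    else:
        raise InvalidInputError(f"unsupported luminance format {path.suffix!r}")
    scale = 1.0
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        scale = float(meta.get("scale", 1.0))
        if ppd is None:
            ppd = meta.get("ppd")
    if ppd is None:
        raise InvalidInputError(
            f"{path}: pixels-per-degree metadata missing; provide a sidecar "
            "with a 'ppd' key or pass ppd explicitly"
        )
    return LuminanceImage(values * scale, float(ppd), "loaded")


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    iio.imwrite(pathlib.Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    """Read a PNG mask back to boolean (any nonzero pixel is True)."""
    arr = iio.imread(pathlib.Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0
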