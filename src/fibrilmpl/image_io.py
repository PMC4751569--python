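"""Grayscale micrograph I/O.

Images are held as 2-D float64 arrays in native intensity units: an 8-bit
pixel storing 131 loads as 131.0 and is never rescaled.  The measurement
pipeline is a pure intensity ratio, so units cancel, but mixing differently
scaled images in one measurement set is not meaningful and the API takes a
single image per run.

Coordinate convention (package-wide): ``x`` is the column index, ``y`` the
row index, origin at the top-left, 0-based, with pixel centers at integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import tifffile
import imageio.v3 as iio

from .errors import ImageFormatError

#: Allowed values for :attr:`Image.source_bit_depth` / ``save_image`` depth.
BIT_DEPTHS = (8, 16, "float")

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}


@dataclass
class Image:
    """A single-channel raster with intensity values in native units.

    Parameters
    ----------
    pixels
        2-D array of finite intensity values; cast to float64 on construction.
    source_bit_depth
        ``8``, ``16`` or ``"float"`` — metadata recording the storage type the
        pixel values originated from.
    """

    pixels: np.ndarray
    source_bit_depth: Union[int, str] = "float"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ImageFormatError(f"expected a 2-D array, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ImageFormatError("zero-size image")
        if not np.all(np.isfinite(arr)):
            raise ImageFormatError("image contains non-finite intensity values")
        if self.source_bit_depth not in BIT_DEPTHS:
            raise ImageFormatError(
                f"source_bit_depth must be one of {BIT_DEPTHS}, got {self.source_bit_depth!r}"
            )
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _collapse_channels(arr: np.ndarray, path: Path) -> np.ndarray:
    """Reduce an H×W×C array to H×W, requiring identical color channels."""
    if arr.ndim != 3 or arr.shape[2] not in (2, 3, 4):
        raise ImageFormatError(f"{path}: unsupported image shape {arr.shape}")
    color = arr[..., :3] if arr.shape[2] >= 3 else arr[..., :1]
    first = color[..., 0]
    for c in range(1, color.shape[2]):
        if not np.array_equal(color[..., c], first):
            raise ImageFormatError(f"{path}: not grayscale (channels differ)")
    return first


def _depth_from_dtype(dtype: np.dtype, path: Path) -> Union[int, str]:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    if np.issubdtype(dtype, np.floating):
        return "float"
    raise ImageFormatError(f"{path}: unsupported pixel type {dtype}")


def load_image(path) -> Image:
    """Read a single-channel TIFF or PNG into an :class:`Image`.

    Values are cast to float with no rescaling.  RGB(A) files whose color
    channels are all identical are accepted and collapsed to one channel.

    Raises
    ------
    OSError
        If the file does not exist or cannot be decoded.
    ImageFormatError
        For multi-channel images with unequal channels, zero-size images, or
        unsupported pixel types.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if not path.is_file():
        raise OSError(f"cannot read image file: {path}")
    try:
        if suffix in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        elif suffix in _PNG_SUFFIXES:
            arr = iio.imread(path)
        else:
            raise ImageFormatError(f"{path}: unsupported format {suffix!r} (use TIFF or PNG)")
    except (ImageFormatError, OSError):
        raise
    except Exception as exc:  # decoder-specific failure
        raise OSError(f"cannot read image file: {path}: {exc}") from exc
    arr = np.asarray(arr)
    depth = _depth_from_dtype(arr.dtype, path)
    if arr.ndim == 3:
        arr = _collapse_channels(arr, path)
    if arr.ndim != 2 or arr.size == 0:
        raise ImageFormatError(f"{path}: zero-size or non-2-D image")
    return Image(pixels=arr.astype(np.float64), source_bit_depth=depth)


def _round_half_away(values: np.ndarray) -> np.ndarray:
    # round-half-away-from-zero, the documented export rule (99.5 -> 100, -0.5 -> -1)
    return np.copysign(np.floor(np.abs(values) + 0.5), values)


def save_image(img: Image, path, bit_depth: Union[int, str] = "float") -> None:
    """Write ``img`` to ``path`` at the requested bit depth.

    Integer depths round half away from zero and clip to the representable
    range ([0, 255] or [0, 65535]); clipping at a black background truncates
    the noise floor and is a known bias source, so synthetic work defaults to
    float TIFF.  ``"float"`` writes 32-bit float TIFF, exact for values
    representable in float32.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if bit_depth == 8:
        out = np.clip(_round_half_away(img.pixels), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.clip(_round_half_away(img.pixels), 0, 65535).astype(np.uint16)
    elif bit_depth == "float":
        if suffix in _PNG_SUFFIXES:
            raise ImageFormatError("PNG cannot store float pixels; use TIFF")
        out = img.pixels.astype(np.float32)
    else:
        raise ImageFormatError(f"bit_depth must be one of {BIT_DEPTHS}, got {bit_depth!r}")
    try:
        if suffix in _TIFF_SUFFIXES:
            tifffile.imwrite(path, out)
        elif suffix in _PNG_SUFFIXES:
            iio.imwrite(path, out)
        else:
            raise ImageFormatError(f"{path}: unsupported format {suffix!r} (use TIFF or PNG)")
    except ImageFormatError:
        raise
    except Exception as exc:
        raise OSError(f"cannot write image file: {path}: {exc}") from exc
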