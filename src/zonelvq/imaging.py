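"""Grayscale conversion and global-threshold binarization.

Images are plain ``numpy`` arrays: a grayscale image is a 2-D ``uint8``
array with intensities in [0, 255]; a binary image is a 2-D ``uint8``
array over {0, 1} where 1 means white.  The screening pipeline converts
an axial CT slice (or any raster) to grayscale by channel averaging,
then thresholds it so that hyperdense structures — the skull ring and
any bright lesion — come out white.

Two threshold policies are supported:

* ``fixed`` — a constant intensity, default 128, the operating point
  used for the CT screening task;
* ``midpoint`` — the per-image midpoint ``T = (f_max + f_min) / 2``
  between the darkest and brightest pixel.

A pixel is white iff its intensity is *strictly greater* than T; a
pixel exactly at the threshold is black.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import UnsupportedFormatError

__all__ = [
    "ThresholdSpec",
    "to_grayscale",
    "compute_threshold",
    "binarize",
    "read_image",
    "read_dicom",
    "write_binary_png",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Threshold policy: ``mode='fixed'`` with ``value``, or ``mode='midpoint'``.

    The default is the fixed intensity 128 used for CT screening; the
    midpoint rule adapts T to each image's dynamic range.
    """

    mode: str = "fixed"
    value: float = 128.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "midpoint"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed" and not (0 <= self.value <= 255):
            raise ValueError(f"fixed threshold {self.value} outside [0, 255]")

    def resolve(self, img: np.ndarray) -> float:
        """Return the effective threshold for ``img`` as a real number."""
        if self.mode == "fixed":
            return float(self.value)
        return compute_threshold(img)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert a raster to a 2-D uint8 grayscale array.

    3-channel input is reduced to the arithmetic mean of the channels,
    rounded half-up to the nearest integer.  Already-grayscale input
    (2-D, or a single-channel third axis) passes through unchanged.

    Raises
    ------
    UnsupportedFormatError
        If the array is neither 2-D nor (H, W, 1) nor (H, W, 3).
    """
    arr = np.asarray(img)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0].astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] == 3:
        mean = arr.astype(np.float64).mean(axis=2)
        # round half-up: floor(x + 0.5), so 0.5 fractions go to the larger integer
        return np.floor(mean + 0.5).astype(np.uint8)
    raise UnsupportedFormatError(
        f"expected a 2-D grayscale or (H, W, 3) RGB array, got shape {arr.shape}"
    )


def compute_threshold(img: np.ndarray) -> float:
    """Midpoint threshold ``(f_max + f_min) / 2`` of a grayscale image.

    Returned as a real number without rounding; always lies within
    ``[img.min(), img.max()]``.
    """
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("cannot compute a threshold on an empty image")
    return (float(arr.max()) + float(arr.min())) / 2.0


def binarize(img: np.ndarray, spec: ThresholdSpec | None = None) -> np.ndarray:
    """Threshold a grayscale image to a {0, 1} binary image.

    A pixel is white (1) iff its intensity exceeds the threshold
    strictly; pixels equal to the threshold are black.  Shape is
    preserved.
    """
    if spec is None:
        spec = ThresholdSpec()
    arr = np.asarray(img)
    t = spec.resolve(arr)
    return (arr.astype(np.float64) > t).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a raster file (PNG etc.) and return it as grayscale uint8."""
    with Image.open(path) as im:
        mode = im.mode
        if mode in ("L", "I;16", "I"):
            arr = np.asarray(im.convert("L"))
            return arr.astype(np.uint8)
        arr = np.asarray(im.convert("RGB"))
    return to_grayscale(arr)


def read_dicom(path: str | Path) -> np.ndarray:
    """Read a single-frame DICOM file, min-max rescaled to 0-255.

    Convenience reader only: stored values are linearly mapped so the
    darkest pixel becomes 0 and the brightest 255 (no Hounsfield
    windowing).  Requires ``pydicom``.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.floor((arr - lo) / (hi - lo) * 255.0 + 0.5).astype(np.uint8)


def write_binary_png(binary: np.ndarray, path: str | Path) -> None:
    """Write a {0, 1} binary image as an 8-bit PNG (1 -> 255)."""
    arr = (np.asarray(binary, dtype=np.uint8) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))
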