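"""Zoning feature extraction and lesion localization.

The binarized slice is partitioned into an R x C grid of equal
rectangular zones (default 8 x 8, so a 512 x 512 image yields 64 zones
of 64 x 64 pixels).  Each zone is summarized by its white-pixel count
Z_n; the feature vector divides every count by the largest one,

    feature_n = Z_n / Z_highest,

so features lie in [0, 1] with at least one exact 1 whenever the image
has any white pixel at all.  Zones are indexed row-major and 1-based:
zone n = (row - 1) * cols + col.

Localization assigns a suspected slice to the left or right half of the
image by the dominant *interior* zone — the border ring of zones is
excluded because the bright skull ring concentrates there and would
otherwise mask the lesion.  Left/right follows the image-side
convention (column index, not patient side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateImageError, DimensionMismatchError

__all__ = [
    "ZoneGridSpec",
    "Localization",
    "partition_and_count",
    "extract_features",
    "zone_argmax",
    "locate_tumor",
    "features_to_frame",
]


@dataclass(frozen=True)
class ZoneGridSpec:
    """Zone grid geometry: ``rows`` x ``cols`` equal rectangular zones."""

    rows: int = 8
    cols: int = 8

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"zone grid must be at least 1x1, got {self.rows}x{self.cols}")

    @property
    def n_zones(self) -> int:
        return self.rows * self.cols

    def zone_index(self, row: int, col: int) -> int:
        """1-based row-major zone index of 1-based (row, col)."""
        return (row - 1) * self.cols + col

    def zone_coords(self, index: int) -> tuple[int, int]:
        """1-based (row, col) of a 1-based zone index."""
        if not 1 <= index <= self.n_zones:
            raise ValueError(f"zone index {index} outside 1..{self.n_zones}")
        return (index - 1) // self.cols + 1, (index - 1) % self.cols + 1


@dataclass(frozen=True)
class Localization:
    """Dominant-zone localization of a suspected slice.

    ``side`` is 'left', 'right', or 'none'; zone fields are ``None``
    when the slice is classified normal.
    """

    zone_index: int | None
    row: int | None
    col: int | None
    side: str


def partition_and_count(binary: np.ndarray, spec: ZoneGridSpec | None = None) -> np.ndarray:
    """White-pixel count per zone, as a ``rows x cols`` integer array.

    The image dimensions must be divisible by the grid so every zone is
    the same size; ``counts[r, c]`` (0-based here) covers the half-open
    pixel block ``[r*h/rows, (r+1)*h/rows) x [c*w/cols, (c+1)*w/cols)``.

    Raises
    ------
    DimensionMismatchError
        If the image shape is not divisible by the grid.
    """
    if spec is None:
        spec = ZoneGridSpec()
    arr = np.asarray(binary)
    h, w = arr.shape
    if h % spec.rows or w % spec.cols:
        raise DimensionMismatchError(
            f"image shape {h}x{w} is not divisible by zone grid {spec.rows}x{spec.cols}"
        )
    zh, zw = h // spec.rows, w // spec.cols
    blocks = arr.reshape(spec.rows, zh, spec.cols, zw)
    return blocks.sum(axis=(1, 3)).astype(np.int64)


def extract_features(counts: np.ndarray) -> np.ndarray:
    """Max-normalized zone features in row-major zone order.

    Divides every zone count by the highest count Z_highest, giving a
    flat vector of ``rows*cols`` values in [0, 1] whose maximum is
    exactly 1.

    Raises
    ------
    DegenerateImageError
        If every count is zero (all-black binarized image).
    """
    c = np.asarray(counts, dtype=np.float64)
    z_highest = c.max()
    if z_highest <= 0:
        raise DegenerateImageError(
            "all zone counts are zero; features are undefined for an all-black image"
        )
    return (c / z_highest).ravel()


def zone_argmax(counts: np.ndarray) -> int:
    """1-based row-major index of the zone with the most white pixels.

    Ties break to the lowest zone index.
    """
    c = np.asarray(counts)
    if c.max() <= 0:
        raise DegenerateImageError("all zone counts are zero; no dominant zone exists")
    return int(c.argmax()) + 1


def locate_tumor(
    counts: np.ndarray,
    predicted_class: str,
    spec: ZoneGridSpec | None = None,
    *,
    normal_label: str = "normal",
    interior_margin: int = 1,
) -> Localization:
    """Locate the dominant lesion zone and its image side.

    For a slice predicted ``normal_label`` the result is
    ``side='none'`` with no zone.  Otherwise the argmax is taken over
    interior zones only — rows and columns more than ``interior_margin``
    zones away from the border — to suppress the skull ring, and the
    side is 'left' if the winning zone's column is in the left half of
    the grid (column <= cols/2), else 'right'.  Left/right is the image
    side as displayed, not the radiological patient side.
    """
    if spec is None:
        spec = ZoneGridSpec()
    c = np.asarray(counts)
    if predicted_class == normal_label:
        return Localization(zone_index=None, row=None, col=None, side="none")
    m = interior_margin
    if spec.rows <= 2 * m or spec.cols <= 2 * m:
        interior = c
        m = 0
    else:
        interior = c[m : spec.rows - m, m : spec.cols - m]
    if interior.max() <= 0:
        raise DegenerateImageError("no white pixels in the interior zones; cannot localize")
    flat = int(interior.argmax())
    row = flat // interior.shape[1] + m + 1
    col = flat % interior.shape[1] + m + 1
    side = "left" if col <= spec.cols / 2 else "right"
    return Localization(zone_index=spec.zone_index(row, col), row=row, col=col, side=side)


def features_to_frame(
    features: list[np.ndarray],
    filenames: list[str],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate feature vectors: one row per image, columns z1..zN.

    ``labels`` may be omitted for unlabeled (prediction-time) data.
    """
    if len(features) != len(filenames):
        raise ValueError("features and filenames differ in length")
    n = len(features[0]) if features else 0
    data = {"filename": filenames}
    if labels is not None:
        if len(labels) != len(filenames):
            raise ValueError("labels and filenames differ in length")
        data["label"] = labels
    mat = np.vstack(features) if features else np.empty((0, n))
    frame = pd.DataFrame(data)
    for j in range(mat.shape[1]):
        frame[f"z{j + 1}"] = mat[:, j]
    return frame
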