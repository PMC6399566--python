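"""Core raster containers shared by every pipeline stage.

Images follow the usual raster convention: row 0 at the top, column 0 at
the left, 0-based indices.  Intensities are kept as floats in [0, 255]
regardless of the on-disk bit depth.  Slopes, when reported, use a y-up
Cartesian frame (x = column, y = -row) so that a line rising toward the
right has positive slope, matching how endplate tilts are drawn on a
radiograph viewed the normal way up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np

__all__ = ["SpineImage", "ProjectionProfile", "ROIBox", "read_image", "write_image"]

MAX_GRAY = 255.0


@dataclass
class SpineImage:
    """A 2-D grayscale radiograph (or phantom) with provenance metadata."""

    pixels: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("SpineImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ProjectionProfile:
    """Per-row or per-column intensity sums of an image.

    ``axis`` names the index dimension of ``values``: a ``"column"``
    profile has one entry per image column (intensities summed down each
    column), a ``"row"`` profile one entry per image row.
    """

    values: np.ndarray
    axis: str  # "column" | "row"

    def __post_init__(self) -> None:
        if self.axis not in ("column", "row"):
            raise ValueError("axis must be 'column' or 'row'")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("profile values must be 1-D")
        if np.any(v < 0):
            raise ValueError("projection sums cannot be negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ROIBox:
    """Half-open crop box [top, bottom) x [left, right) in image indices."""

    top: int
    bottom: int
    left: int
    right: int

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValueError(f"degenerate ROI box {self!r}")
        if min(self.top, self.left) < 0:
            raise ValueError(f"ROI box out of bounds {self!r}")

    def crop(self, image: SpineImage) -> SpineImage:
        if self.bottom > image.height or self.right > image.width:
            raise ValueError(f"ROI box {self!r} exceeds image {image.pixels.shape}")
        sub = image.pixels[self.top : self.bottom, self.left : self.right].copy()
        meta = dict(image.meta)
        meta["roi_box"] = (self.top, self.bottom, self.left, self.right)
        return SpineImage(sub, meta)

    def as_dict(self) -> dict[str, int]:
        return {"top": self.top, "bottom": self.bottom, "left": self.left, "right": self.right}


def read_image(path: str | Path) -> SpineImage:
    """Read a PNG/TIFF grayscale image, collapsing RGB to luma if needed."""
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # RGB(A) -> gray
        arr = arr[..., :3].mean(axis=-1)
    return SpineImage(arr, {"source": str(path)})


def write_image(path: str | Path, image: SpineImage | np.ndarray) -> None:
    px = image.pixels if isinstance(image, SpineImage) else np.asarray(image, dtype=float)
    iio.imwrite(Path(path), np.clip(px, 0, MAX_GRAY).astype(np.uint8))
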