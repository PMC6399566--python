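"""Spine region-of-interest isolation from a full AP radiograph.

The spine occupies a bright vertical band: columns summed down the image
peak over the spinal column, while row sums dip in the gap between the
skull and T1 and jump at the pelvis.  The stage therefore (1) downscales
the image to a quarter of its linear size, (2) takes vertical and
horizontal projection profiles, (3) picks the column band around the
profile maximum that stays above mean + c*sd, and (4) picks the top row
at the lowest local minimum of the upper half of the row profile and the
bottom row at the largest discontinuity of its lower half.  All boxes
are expressed in quarter-scale coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import argrelmin
from skimage.filters import threshold_otsu
from skimage.transform import rotate as _rotate

from .image import ProjectionProfile, ROIBox, SpineImage

__all__ = [
    "downscale_quarter",
    "project",
    "select_column_band",
    "select_row_band",
    "align_principal_axis",
    "isolate_spine_roi",
]


def downscale_quarter(image: SpineImage) -> SpineImage:
    """Quarter-size reduction by 4x4 block averaging.

    Output is floor(height/4) x floor(width/4); block averaging keeps the
    projection profiles smooth (nearest-neighbour would alias the thin
    intervertebral gaps away).
    """
    h, w = image.height, image.width
    if h < 4 or w < 4:
        raise ValueError(f"image {h}x{w} too small to quarter (need >= 4x4)")
    hq, wq = h // 4, w // 4
    px = image.pixels[: hq * 4, : wq * 4]
    out = px.reshape(hq, 4, wq, 4).mean(axis=(1, 3))
    meta = dict(image.meta)
    meta["downscale"] = 4
    return SpineImage(out, meta)


def project(image: SpineImage, axis: str) -> ProjectionProfile:
    """Intensity projection profile: one sum per column or per row."""
    if axis == "column":
        return ProjectionProfile(image.pixels.sum(axis=0), "column")
    if axis == "row":
        return ProjectionProfile(image.pixels.sum(axis=1), "row")
    raise ValueError("axis must be 'column' or 'row'")


def select_column_band(profile: ProjectionProfile, c: float = 1.0) -> tuple[int, int]:
    """Left/right ROI bounds from the vertical projection.

    Anchored at the profile maximum (the spinal column), expanded
    outward while values stay >= mean + c*sd of the profile.  Returns a
    half-open [left, right) interval.  A flat profile degenerates to the
    full width with a warning.
    """
    if profile.axis != "column":
        raise ValueError("select_column_band expects a column profile")
    v = profile.values
    n = len(v)
    if n < 3:
        raise ValueError("profile too short")
    sd = float(v.std())
    if sd == 0.0:
        warnings.warn("flat column profile; returning full width")
        return 0, n
    thr = float(v.mean()) + c * sd
    peak = int(np.argmax(v))
    left = peak
    while left > 0 and v[left - 1] >= thr:
        left -= 1
    right = peak + 1
    while right < n and v[right] >= thr:
        right += 1
    return left, right


def select_row_band(profile: ProjectionProfile) -> tuple[int, int]:
    """Top/bottom ROI bounds from the horizontal projection.

    Top: the lowest extremum (global minimum among local minima) in the
    upper half of the profile — the dark gap below the skull.  Bottom:
    the largest jump |v[y+1] - v[y]| in the lower half — the pelvis
    discontinuity.  Returns half-open [top, bottom).
    """
    if profile.axis != "row":
        raise ValueError("select_row_band expects a row profile")
    v = profile.values
    n = len(v)
    if n < 5:
        raise ValueError("profile too short")
    mid = n // 2
    minima = argrelmin(v[:mid])[0]
    if len(minima) == 0:
        warnings.warn("no local minimum in the upper half; top falls back to row 0")
        top = 0
    else:
        top = int(minima[np.argmin(v[minima])])
    jumps = np.abs(np.diff(v[mid:]))
    bottom = mid + int(np.argmax(jumps)) + 1
    if top >= bottom:  # pathological profile; keep ordering contract
        warnings.warn("degenerate row band; returning full height")
        return 0, n
    return top, bottom


def align_principal_axis(image: SpineImage) -> SpineImage:
    """Rotate so the principal axis of the bright foreground is vertical.

    Optional pre-step for images acquired with the patient off-axis.
    Foreground is the Otsu-bright region; the rotation brings its second
    -moment principal axis to vertical.  Off by default in the pipeline
    (phantoms and properly acquired EOS films are upright).
    """
    px = image.pixels
    thr = threshold_otsu(px)
    fg = px > thr
    rows, cols = np.nonzero(fg)
    if rows.size < 2:
        return image
    y = rows - rows.mean()
    x = cols - cols.mean()
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]  # (x, y) of the long axis
    angle = np.degrees(np.arctan2(major[0], major[1]))  # from vertical
    if abs(angle) < 0.5:
        return image
    out = _rotate(px, -angle, preserve_range=True, mode="constant",
                  cval=float(np.median(px)))
    meta = dict(image.meta)
    meta["alignment_rotation_deg"] = -float(angle)
    return SpineImage(out, meta)


def isolate_spine_roi(
    image: SpineImage,
    c: float = 1.0,
    align: bool = False,
    col_pad: int = 15,
) -> tuple[ROIBox, SpineImage]:
    """Quarter-downscale, project, and crop the T1-L5 spine band.

    Returns the box (quarter-scale indices) and the cropped quarter-scale
    image.  The column band is padded by ``col_pad`` quarter-scale pixels
    on each side: the projection band hugs the spine, and the downstream
    sibling-window boundary search needs room outside the spine edge.
    On structure-free input the band selectors degrade to the full frame
    with warnings rather than failing.
    """
    if align:
        image = align_principal_axis(image)
    small = downscale_quarter(image)
    left, right = select_column_band(project(small, "column"), c=c)
    top, bottom = select_row_band(project(small, "row"))
    left = max(0, left - col_pad)
    right = min(small.width, right + col_pad)
    box = ROIBox(top=top, bottom=bottom, left=left, right=right)
    return box, box.crop(small)
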