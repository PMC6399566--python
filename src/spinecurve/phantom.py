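"""Synthetic AP-view spine radiograph phantoms with known geometry.

A phantom emulates the gross intensity structure the measurement
pipeline exploits on a real AP radiograph: a bright column of 17 stacked
vertebra-like quadrilaterals (12 thoracic + 5 lumbar) separated by
darker intervertebral gaps, a linear intensity ramp making the lumbar
region brighter than the thoracic, a soft-tissue background, optional
bright head/hip blobs bracketing the spine, and additive Gaussian noise.
Every sample carries its generative ground truth: per-vertebra masks,
oriented corner quadrilaterals, endplate slopes, and the exact Cobb
angle implied by those slopes.

The geometry is deliberately schematic (tilted rectangles, no texture):
the pipeline only uses intensity contrast and endplate orientation, so
that is what the phantom controls analytically.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.draw import ellipse as _ellipse
from skimage.draw import polygon as _polygon
from skimage.transform import resize as _resize

from .cobb import CobbResult, cobb_angle
from .image import MAX_GRAY, SpineImage, write_image

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "true_cobb",
           "scoliotic_spec", "make_dataset", "extract_chips", "CHIP_SHAPE"]

#: Per-vertebra crop size (rows, cols) fed to the segmentation networks.
CHIP_SHAPE = (256, 128)


@dataclass
class PhantomSpec:
    """Generative parameters of one phantom radiograph.

    Defaults approximate a full-spine AP exposure at roughly the scale of
    clinical files (a few thousand pixels tall) so that the detection
    window defaults (51x13 windows on the quarter-size image) see
    vertebrae of realistic apparent size (~50 px tall after downscale).
    """

    image_height: int = 4800
    image_width: int = 2800
    n_vertebrae: int = 17  # 12 thoracic + 5 lumbar
    centerline_coeffs: Sequence[float] = (1400.0,)  # col = polyval(coeffs, row)
    vertebra_height: int = 180
    gap_height: int = 60
    vertebra_width: int = 280
    tilt_angles: Sequence[float] | None = None  # degrees per vertebra; None = all 0
    spine_top: int = 300  # row of the first (T1) upper endplate
    intensity_spine: float = 230.0
    intensity_gradient: tuple[float, float] = (0.95, 1.10)  # thoracic -> lumbar
    gap_contrast: float = 0.10  # disc intensity fraction between soft tissue and bone
    soft_tissue_level: float = 60.0  # torso band; the air background is darker
    background_level: float = 30.0
    noise_sd: float = 4.0
    include_head_hips: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 3:
            raise ValueError("need at least 3 vertebrae")
        if self.vertebra_height <= 0 or self.vertebra_width <= 0:
            raise ValueError("vertebra dimensions must be positive")
        if self.gap_height < 1:
            raise ValueError("gap_height must be >= 1")
        for name in ("intensity_spine", "background_level"):
            v = getattr(self, name)
            if not 0 <= v <= MAX_GRAY:
                raise ValueError(f"{name}={v} outside [0, {MAX_GRAY}]")
        if self.tilt_angles is not None:
            t = np.asarray(self.tilt_angles, dtype=float)
            if len(t) != self.n_vertebrae:
                raise ValueError("tilt_angles length must equal n_vertebrae")
            if not np.all(np.isfinite(t)):
                raise ValueError("tilt_angles must be finite")

    @property
    def stack_height(self) -> int:
        return self.n_vertebrae * self.vertebra_height + (self.n_vertebrae - 1) * self.gap_height


@dataclass
class PhantomSample:
    """A rendered phantom plus its generative ground truth."""

    image: SpineImage
    vertebra_masks: list[np.ndarray]  # full-image binary grids, one per vertebra
    vertebra_corners: list[np.ndarray]  # (4, 2) (row, col) quadrilateral corners
    upper_slopes: np.ndarray  # y-up rise/run per vertebra
    lower_slopes: np.ndarray
    true_cobb_deg: float  # signed; same convention as cobb.cobb_angle
    true_end_vertebrae: tuple[int, int]  # 0-based (upper, lower)
    spec: PhantomSpec = None

    @property
    def centroids(self) -> np.ndarray:
        return np.array([np.argwhere(m).mean(axis=0) for m in self.vertebra_masks])


def true_cobb(upper_slopes: Sequence[float], lower_slopes: Sequence[float]) -> CobbResult:
    """Ground-truth Cobb angle of a slope configuration.

    Shares the pair-search implementation with :func:`spinecurve.cobb.
    cobb_angle`, so phantom truth and pipeline output use one definition.
    """
    return cobb_angle(upper_slopes, lower_slopes)


def _vertebra_corners(center_rc: tuple[float, float], h: float, w: float,
                      tilt_deg: float) -> np.ndarray:
    """Corners of a tilted rectangle, ordered; top edge slope = tan(tilt)."""
    th = math.radians(tilt_deg)
    c, s = math.cos(th), math.sin(th)
    half = np.array(
        [[-w / 2, h / 2], [w / 2, h / 2], [w / 2, -h / 2], [-w / 2, -h / 2]]
    )  # (x, y) y-up, order: top-left, top-right, bottom-right, bottom-left
    rot = half @ np.array([[c, s], [-s, c]])  # rotate by +tilt (counter-clockwise)
    rows = center_rc[0] - rot[:, 1]
    cols = center_rc[1] + rot[:, 0]
    return np.column_stack([rows, cols])


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom. Deterministic for a fixed ``spec.seed``."""
    H, W = spec.image_height, spec.image_width
    bottom_row = spec.spine_top + spec.stack_height
    if bottom_row > int(0.92 * H):
        raise ValueError(
            f"vertebra stack ends at row {bottom_row}, beyond the usable frame "
            f"(row {int(0.92 * H)}) of a {H}-row image"
        )
    tilts = (np.zeros(spec.n_vertebrae) if spec.tilt_angles is None
             else np.asarray(spec.tilt_angles, dtype=float))
    img = np.full((H, W), spec.background_level, dtype=float)

    def centerline(row):
        return np.polyval(spec.centerline_coeffs, row)

    # intensity ramp over the spine extent (thoracic dim, lumbar bright)
    g0, g1 = spec.intensity_gradient
    def bone_level(row):
        frac = np.clip((row - spec.spine_top) / max(spec.stack_height, 1), 0, 1)
        return spec.intensity_spine * (g0 + (g1 - g0) * frac)

    # soft-tissue torso band: a wide, mildly bright column region against
    # the dark air margins.  The column-projection ROI rule depends on the
    # torso being broadly brighter than the film edges, as on real AP films.
    torso_top = int(0.03 * H)
    t_half = int(0.26 * W)
    t_c = int(np.clip(centerline(H // 2), t_half, W - t_half)) if W >= 2 * t_half else W // 2
    img[torso_top:, max(0, t_c - t_half): t_c + t_half] = spec.soft_tissue_level

    # spine column band at intervertebral (disc) intensity
    rows_band = np.arange(spec.spine_top, bottom_row)
    ccols = centerline(rows_band)
    lo = np.clip(np.round(ccols - spec.vertebra_width / 2).astype(int), 0, W - 1)
    hi = np.clip(np.round(ccols + spec.vertebra_width / 2).astype(int), 0, W)
    disc = spec.soft_tissue_level + spec.gap_contrast * (bone_level(rows_band) - spec.soft_tissue_level)
    for r, a, b, d in zip(rows_band, lo, hi, disc):
        img[r, a:b] = d

    masks: list[np.ndarray] = []
    corners_list: list[np.ndarray] = []
    for k in range(spec.n_vertebrae):
        top = spec.spine_top + k * (spec.vertebra_height + spec.gap_height)
        crow = top + spec.vertebra_height / 2
        ccol = float(centerline(crow))
        corners = _vertebra_corners((crow, ccol), spec.vertebra_height,
                                    spec.vertebra_width, tilts[k])
        if corners[:, 0].min() < 0 or corners[:, 0].max() >= H:
            raise ValueError(f"vertebra {k} overflows the image at row "
                             f"{corners[:, 0].min():.0f}..{corners[:, 0].max():.0f}")
        rr, cc = _polygon(corners[:, 0], corners[:, 1], shape=(H, W))
        mask = np.zeros((H, W), dtype=bool)
        mask[rr, cc] = True
        # transverse dome: the projected path through the vertebral body
        # and spinous process peaks at the midline, so an AP film is
        # brightest along the spine axis; a 0.55 floor keeps the lateral
        # cortical edge sharp against the soft tissue
        u = corners[1] - corners[0]
        u = u / np.hypot(*u)
        lat = (rr - crow) * u[0] + (cc - ccol) * u[1]
        dome = np.sqrt(np.clip(1.0 - (2.0 * lat / spec.vertebra_width) ** 2, 0.0, 1.0))
        img[rr, cc] = bone_level(crow) * (0.55 + 0.45 * dome)
        masks.append(mask)
        corners_list.append(corners)
    # vertebrae never overlap by construction, but tilted neighbours could
    # collide if tilts are extreme; keep masks disjoint by priority order.
    for k in range(1, len(masks)):
        masks[k] &= ~masks[k - 1]

    if spec.include_head_hips:
        # skull: clipped at the frame top; the dark neck gap above T1 is
        # what the row-profile "lowest extremum" rule detects.  Tilted end
        # vertebrae can poke ~w/2*sin(tilt) rows above spine_top, so the
        # skull stays well clear of it.
        head_lvl = 0.85 * spec.intensity_spine
        rr, cc = _ellipse(int(0.010 * H), int(centerline(0)),
                          int(0.030 * H), int(0.14 * W), shape=(H, W))
        img[rr, cc] = head_lvl
        # pelvis: a wide bright band below L5 with a sharp superior edge,
        # the "largest discontinuity" that bounds the ROI from below
        hip_top = min(int(bottom_row + 0.02 * H), H - 1)
        hip_c = int(centerline(bottom_row))
        half_w = int(0.42 * W)
        img[hip_top:, max(0, hip_c - half_w): hip_c + half_w] = spec.intensity_spine
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(img.shape, dtype=np.float32) * spec.noise_sd
    img = np.clip(img + noise, 0, MAX_GRAY)

    upper = np.tan(np.radians(tilts))
    lower = upper.copy()  # rectangle endplates are parallel
    truth = true_cobb(upper, lower)
    return PhantomSample(
        image=SpineImage(img, {"phantom_seed": spec.seed}),
        vertebra_masks=masks,
        vertebra_corners=corners_list,
        upper_slopes=upper,
        lower_slopes=lower,
        true_cobb_deg=truth.phi,
        true_end_vertebrae=(truth.upper_index, truth.lower_index),
        spec=spec,
    )


def scoliotic_spec(cobb_deg: float, seed: int = 0, direction: int = 1,
                   **overrides) -> PhantomSpec:
    """Build a spec whose curve produces approximately the requested Cobb angle.

    The centerline is a quadratic bow (apex at mid-spine); vertebra tilts
    follow the local tangent, as they do anatomically.  The exact ground
    truth is recomputed from the resulting tilt list, so ``cobb_deg`` is
    a target, not a promise; the realised value is within a fraction of
    a degree for moderate curves.  ``direction=+1`` bows toward +columns.
    """
    base = PhantomSpec(seed=seed, **overrides)
    stack = base.stack_height
    amp = direction * stack * math.tan(math.radians(abs(cobb_deg)) / 2.0) / 4.0
    mid = base.spine_top + stack / 2.0
    halfspan = stack / 2.0
    # col = center + amp * (1 - ((row - mid)/halfspan)^2)
    a2 = -amp / halfspan**2
    coeffs = (a2, -2 * a2 * mid, a2 * mid**2 + amp + base.image_width / 2.0)
    tilts = []
    for k in range(base.n_vertebrae):
        crow = base.spine_top + k * (base.vertebra_height + base.gap_height) \
            + base.vertebra_height / 2.0
        dcol_drow = 2 * a2 * crow + coeffs[1]
        tilts.append(math.degrees(math.atan(dcol_drow)))
    return replace(base, centerline_coeffs=coeffs, tilt_angles=tuple(tilts))


def extract_chips(sample: PhantomSample, chip_shape: tuple[int, int] = CHIP_SHAPE,
                  margin: float = 0.15) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-vertebra (chip, mask) crops rescaled to ``chip_shape``.

    Crops the full-resolution image around each vertebra's mask bounding
    box, padded by ``margin`` of the box size, and rescales.  Masks are
    rescaled with the same transform and re-binarised.
    """
    out = []
    px = sample.image.pixels
    H, W = px.shape
    for mask in sample.vertebra_masks:
        rows, cols = np.nonzero(mask)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        mr = int(margin * (r1 - r0))
        mc = int(margin * (c1 - c0))
        r0, r1 = max(0, r0 - mr), min(H, r1 + mr)
        c0, c1 = max(0, c0 - mc), min(W, c1 + mc)
        chip = _resize(px[r0:r1, c0:c1], chip_shape, order=1,
                       preserve_range=True, anti_aliasing=True)
        mchip = _resize(mask[r0:r1, c0:c1].astype(float), chip_shape, order=0,
                        preserve_range=True, anti_aliasing=False) > 0.5
        out.append((chip.astype(np.float32), mchip))
    return out


def make_dataset(n_images: int, spec_ranges: dict | None = None, seed: int = 0,
                 chip_shape: tuple[int, int] = CHIP_SHAPE,
                 keep_samples: bool = True):
    """Phantom training/evaluation collection.

    ``spec_ranges`` maps PhantomSpec field names (plus ``cobb_deg``) to
    (low, high) sampling ranges; defaults cover mild-to-severe curves.
    Returns ``(samples, chips)`` where ``chips`` is a flat list of
    (chip, mask) pairs, ``n_images * n_vertebrae`` of them.  With
    ``keep_samples=False`` the full-frame samples are discarded after
    chip extraction (a rendered sample with its masks is ~200 MB), and
    the first list comes back empty.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if spec_ranges is None:
        ranges = {"cobb_deg": (5.0, 45.0)}
    elif len(spec_ranges) == 0:
        raise ValueError("spec_ranges is empty; provide ranges or pass None for defaults")
    else:
        ranges = dict(spec_ranges)
    if "cobb_deg" not in ranges:
        raise ValueError("spec_ranges must include a 'cobb_deg' range")
    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    chips: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n_images):
        kw = {}
        for name, (lo, hi) in ranges.items():
            if name == "cobb_deg":
                continue
            val = rng.uniform(lo, hi)
            kw[name] = int(round(val)) if isinstance(lo, int) else val
        cobb = rng.uniform(*ranges["cobb_deg"])
        direction = 1 if rng.random() < 0.5 else -1
        spec = scoliotic_spec(cobb, seed=int(rng.integers(0, 2**31 - 1)),
                              direction=direction, **kw)
        sample = generate_phantom(spec)
        if keep_samples:
            samples.append(sample)
        chips.extend(extract_chips(sample, chip_shape=chip_shape))
    return samples, chips


def save_sample(sample: PhantomSample, out_dir: str | Path, stem: str) -> None:
    """Write image, masks and a ground-truth row for CLI use."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / f"{stem}.png", sample.image)
    mask_all = np.zeros(sample.image.pixels.shape, dtype=np.uint8)
    for k, m in enumerate(sample.vertebra_masks, start=1):
        mask_all[m] = k * (255 // len(sample.vertebra_masks))
    write_image(out / f"{stem}_masks.png", mask_all.astype(float))


def write_manifest(samples: Sequence[PhantomSample], path: str | Path,
                   stems: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stem", "true_cobb_deg", "upper_end", "lower_end",
                    "n_vertebrae", "seed", "upper_slopes", "lower_slopes"])
        for s, stem in zip(samples, stems):
            w.writerow([
                stem, f"{s.true_cobb_deg:.3f}", s.true_end_vertebrae[0],
                s.true_end_vertebrae[1], len(s.vertebra_masks), s.spec.seed,
                ";".join(f"{v:.5f}" for v in s.upper_slopes),
                ";".join(f"{v:.5f}" for v in s.lower_slopes),
            ])
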