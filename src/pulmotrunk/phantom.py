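"""Synthetic anterior-posterior chest scout-view phantoms.

The clinical cohorts behind the pulmonary-trunk localization task are not
public, so training and evaluation run on stylized scout-view phantoms:
a body silhouette, two darker lung fields, a brighter mediastinal column,
and a horizontal band of raised contrast inside the mediastinum that
marks the ground-truth pulmonary-trunk region. The band's vertical
position is tied to the lung fields (the visible landmark a reader would
use), every case carries an exact row-interval annotation, and the
reference-standard row is the band centre.

This is deliberately a geometric phantom, not a CT simulator: it
exercises the learning and evaluation machinery, not clinical
transferability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    AnnotationSource,
    Region,
    RegionAnnotation,
    ScoutImage,
    region_center,
)

__all__ = [
    "PhantomParams",
    "PhantomCase",
    "PhantomConfigError",
    "generate_phantom",
    "generate_cohort",
    "augment_shift",
    "derive_case_seed",
]


class PhantomConfigError(ValueError):
    """Parameters cannot place the band inside the body silhouette."""


@dataclass(frozen=True)
class PhantomParams:
    """Study conditions for the phantom cohort.

    ``band_height_rows`` defaults to 15-35 rows at 1.0 mm spacing,
    i.e. 3-7 axial CT slices of 5 mm — the bulk of the clinical band
    lengths (median 5 slices). ``band_center_fraction`` places the band
    centre in the mid-chest. Intensities are on a [0, 1] grayscale.
    """

    image_rows: int = 128
    image_cols: int = 64
    row_spacing_mm: float = 1.0
    band_height_rows: tuple[int, int] = (15, 35)
    band_center_fraction: tuple[float, float] = (0.35, 0.55)
    lung_darkness: tuple[float, float] = (0.18, 0.30)
    body_brightness: tuple[float, float] = (0.50, 0.62)
    band_contrast: float = 0.14
    background: float = 0.05
    noise_sd: float = 0.05
    shift_jitter_rows: int = 3

    def __post_init__(self) -> None:
        for name in ("band_height_rows", "band_center_fraction", "lung_darkness", "body_brightness"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise PhantomConfigError(f"{name} range is empty: ({lo}, {hi})")
        if self.band_height_rows[0] < 3:
            raise PhantomConfigError("band_height_rows minimum must be >= 3")
        if self.image_rows < 8 or self.image_cols < 8:
            raise PhantomConfigError("image must be at least 8 x 8")
        if self.row_spacing_mm <= 0:
            raise PhantomConfigError("row_spacing_mm must be positive")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be non-negative")


@dataclass
class PhantomCase:
    image: ScoutImage
    annotation: RegionAnnotation
    params_used: dict = field(default_factory=dict)


def derive_case_seed(seed: int, index: int) -> int:
    """SplitMix64-style hash of (seed, index) -> independent per-case seed."""
    z = (seed * 0x9E3779B97F4A7C15 + index + 1) & 0xFFFFFFFFFFFFFFFF
    z = (z ^ (z >> 30)) * 0xBF58476D1CE4E5B9 & 0xFFFFFFFFFFFFFFFF
    z = (z ^ (z >> 27)) * 0x94D049BB133111EB & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0x7FFFFFFF


def _ellipse(rows: int, cols: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    y, x = np.ogrid[:rows, :cols]
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def generate_phantom(params: PhantomParams, seed: int, case_id: str | None = None) -> PhantomCase:
    """Render one phantom scout view with its exact band annotation.

    Deterministic for a fixed ``(params, seed)``. Pixels are quantized to
    a 16-bit grayscale grid so lossless raster round-trips are exact.
    """
    rng = np.random.default_rng(seed)
    H, W = params.image_rows, params.image_cols

    band_h = int(rng.integers(params.band_height_rows[0], params.band_height_rows[1] + 1))
    frac = rng.uniform(*params.band_center_fraction)
    jitter = int(rng.integers(-params.shift_jitter_rows, params.shift_jitter_rows + 1))
    center = int(round(frac * H)) + jitter
    start = center - band_h // 2
    end = start + band_h
    if start < 0 or end > H:
        raise PhantomConfigError(
            f"band [{start}, {end}) does not fit in {H} rows; "
            "narrow band_center_fraction or band_height_rows"
        )

    body = rng.uniform(*params.body_brightness)
    lung = rng.uniform(*params.lung_darkness)
    cx = W / 2 + rng.uniform(-0.02, 0.02) * W

    img = np.full((H, W), params.background, dtype=np.float64)

    # torso: tall ellipse filling most of the frame
    body_ry = 0.52 * H * rng.uniform(0.95, 1.05)
    body_rx = 0.42 * W * rng.uniform(0.92, 1.05)
    body_mask = _ellipse(H, W, 0.5 * H, cx, body_ry, body_rx)
    img[body_mask] = body
    if not (body_mask[start:end, int(cx)].all()):
        raise PhantomConfigError("band does not fit inside the body silhouette")

    # lung fields: two dark ellipses whose vertical position tracks the band
    lung_cy = center - 0.04 * H + rng.uniform(-1.5, 1.5)
    lung_ry = 0.21 * H * rng.uniform(0.9, 1.1)
    lung_rx = 0.14 * W * rng.uniform(0.9, 1.1)
    lung_dx = 0.22 * W
    for sgn in (-1.0, 1.0):
        img[_ellipse(H, W, lung_cy, cx + sgn * lung_dx, lung_ry, lung_rx)] = lung

    # mediastinal column between the lungs, slightly brighter than the torso
    medi_half_w = 0.09 * W
    x = np.arange(W)
    medi_cols = np.abs(x - cx) <= medi_half_w
    medi_rows = np.zeros(H, dtype=bool)
    row_lo = max(0, int(lung_cy - lung_ry))
    row_hi = min(H, int(lung_cy + lung_ry) + 1)
    medi_rows[row_lo:row_hi] = True
    img[np.outer(medi_rows, medi_cols) & body_mask] += 0.05

    # the pulmonary-trunk band: raised contrast across the mediastinum
    band_cols = np.abs(x - cx) <= 0.11 * W
    band_rows = np.zeros(H, dtype=bool)
    band_rows[start:end] = True
    img[np.outer(band_rows, band_cols) & body_mask] += params.band_contrast

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    img = np.round(img * 65535.0) / 65535.0  # 16-bit grayscale grid

    region = Region(start, end)
    annotation = RegionAnnotation(region, region_center(region), AnnotationSource.GROUND_TRUTH)
    image = ScoutImage(
        img.astype(np.float32),
        row_spacing_mm=params.row_spacing_mm,
        case_id=case_id or f"phantom-{seed:08x}",
    )
    params_used = {
        "seed": seed,
        "band_height_rows": band_h,
        "band_center_row": center,
        "body_brightness": body,
        "lung_darkness": lung,
        "background": params.background,
        "noise_sd": params.noise_sd,
    }
    return PhantomCase(image, annotation, params_used)


def generate_cohort(params: PhantomParams, n: int, seed: int) -> list[PhantomCase]:
    """Generate ``n`` cases with per-case seeds hashed from ``(seed, index)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        generate_phantom(params, derive_case_seed(seed, i), case_id=f"case{i:04d}")
        for i in range(n)
    ]


def augment_shift(case: PhantomCase, dy: int, dx: int) -> PhantomCase:
    """Translate a case by (dy rows, dx cols), shifting the annotation with it.

    The band and reference row must stay fully inside the image; shifts
    that would clip them are rejected rather than silently truncated.
    Exposed margins are padded with the background intensity.
    """
    img = case.image.pixels
    H, W = img.shape
    region = case.annotation.region
    new_start, new_end = region.start_row + dy, region.end_row + dy
    if new_start < 0 or new_end > H:
        raise ValueError(
            f"shift dy={dy} moves band [{region.start_row}, {region.end_row}) "
            f"outside {H} rows"
        )
    if abs(dx) >= W:
        raise ValueError(f"shift dx={dx} moves the whole image out of frame")

    pad = float(case.params_used.get("background", float(np.min(img))))
    out = np.full_like(img, pad)
    ys_src = slice(max(0, -dy), min(H, H - dy))
    ys_dst = slice(max(0, dy), min(H, H + dy))
    xs_src = slice(max(0, -dx), min(W, W - dx))
    xs_dst = slice(max(0, dx), min(W, W + dx))
    out[ys_dst, xs_dst] = img[ys_src, xs_src]

    annotation = RegionAnnotation(
        Region(new_start, new_end),
        case.annotation.reference_row + dy,
        case.annotation.source,
    )
    image = ScoutImage(out, case.image.row_spacing_mm, case.image.case_id)
    return PhantomCase(image, annotation, dict(case.params_used))
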