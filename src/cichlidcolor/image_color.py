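"""Photo-based color quantification.

White-standard calibration, CIELab belly sampling, Lab-chromaticity (LC),
HSB threshold segmentation of the colored ornament, connected-component
area filtering, lateral projection area (LPA), relative colored area (RCA),
and a Fulton-type body condition index.

Conventions
-----------
Images are 8-bit sRGB (or floats in [0, 1]); CIELab conversion assumes the
sRGB primaries with D65 reference white, approximating photographs
white-balanced to 6500 K. HSB thresholds live on a 0-255 scale for all
three channels, mirroring 8-bit editor sliders: a hue range "0-64"
therefore spans roughly 0-90 degrees, red through yellow. Hue wraparound
(lo > hi) is supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import color as skcolor
from skimage import measure

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """White-standard calibration cannot proceed (e.g. a dead channel)."""


# ---------------------------------------------------------------------------
# Pixel scale helpers
# ---------------------------------------------------------------------------

def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    """Return image as float RGB in [0, 1] (accepts uint8 or float)."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    img = img.astype(float)
    if img.max() > 1.0 + 1e-9:
        raise ValueError("float images must be scaled to [0, 1]")
    return img


def srgb_to_linear(rgb: np.ndarray) -> np.ndarray:
    """Invert the sRGB transfer curve (gamma expansion)."""
    rgb = np.asarray(rgb, dtype=float)
    return np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(lin: np.ndarray) -> np.ndarray:
    lin = np.asarray(lin, dtype=float)
    return np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)


# ---------------------------------------------------------------------------
# White-standard calibration
# ---------------------------------------------------------------------------

def calibrate_white(
    image: np.ndarray,
    white_patch_region: tuple[int, int, int, int],
    reference_rgb=(243, 243, 243),
) -> np.ndarray:
    """Scale each channel so the white-standard patch hits its reference.

    The gain is applied in linear-RGB space (gamma removed first): a change
    in illumination is multiplicative in light, not in gamma-encoded pixel
    values. ``white_patch_region`` is ``(row0, row1, col0, col1)``,
    half-open. Gains that push pixels past the channel maximum are clipped,
    with a logged warning. Returns a float image in [0, 1].
    """
    img = _as_float_rgb(image)
    r0, r1, c0, c1 = white_patch_region
    patch = img[r0:r1, c0:c1]
    if patch.size == 0:
        raise CalibrationError("white patch region is empty")
    ref = np.asarray(reference_rgb, dtype=float)
    if ref.max() > 1.0:
        ref = ref / 255.0
    obs = srgb_to_linear(patch).reshape(-1, 3).mean(axis=0)
    if np.any(obs <= 0):
        raise CalibrationError("white patch has a zero-valued channel; cannot derive gain")
    gain = srgb_to_linear(ref) / obs
    lin = srgb_to_linear(img) * gain
    n_clip = int(np.sum(lin > 1.0))
    if n_clip:
        logger.warning("calibration clipped %d channel values at maximum", n_clip)
        lin = np.clip(lin, 0.0, 1.0)
    return linear_to_srgb(lin)


# ---------------------------------------------------------------------------
# CIELab sampling
# ---------------------------------------------------------------------------

def lab_chromaticity(a, b):
    """Lab-chromaticity LC = sqrt(a^2 + b^2), the distance from the
    achromatic axis; independent of lightness L. Vectorized."""
    return np.hypot(a, b)


@dataclass(frozen=True)
class LabSample:
    L: float
    a: float
    b: float

    @property
    def LC(self) -> float:
        return float(lab_chromaticity(self.a, self.b))


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """sRGB (floats in [0,1] or uint8) to CIE 1976 L*a*b*, D65 white."""
    arr = np.asarray(rgb)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    return skcolor.rgb2lab(arr)


def sample_belly(
    image: np.ndarray,
    belly_mask: np.ndarray,
    n_samples: int = 16,
    sample_radius: int = 2,
) -> tuple[list[LabSample], float]:
    """Take ``n_samples`` Lab color samples evenly spread over the belly.

    Sample points are placed on a deterministic rectangular grid over the
    mask's bounding box (grid shape follows the box aspect ratio); points
    falling outside the mask snap to the nearest mask pixel. Each sample
    averages the sRGB values in a disk of ``sample_radius`` pixels
    (intersected with the mask) before converting to Lab — mimicking an
    averaging eyedropper.

    Returns the per-sample Lab values and the mean LC across samples.
    """
    img = _as_float_rgb(image)
    mask = np.asarray(belly_mask, dtype=bool)
    n_mask = int(mask.sum())
    if n_mask < n_samples:
        raise ValueError(
            f"belly mask has {n_mask} pixels; at least {n_samples} are required"
        )
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    h = max(r1 - r0, 1)
    w = max(c1 - c0, 1)
    # grid dims: close to the box aspect, enough cells for n_samples
    gr = max(1, int(round(np.sqrt(n_samples * h / w))))
    gc = int(np.ceil(n_samples / gr))
    while gr * gc < n_samples:
        gc += 1
    rr = np.linspace(r0, r1, gr + 2)[1:-1] if gr > 1 else np.array([(r0 + r1) / 2])
    cc = np.linspace(c0, c1, gc + 2)[1:-1] if gc > 1 else np.array([(c0 + c1) / 2])
    pts = np.array([(r, c) for r in rr for c in cc])[:n_samples]

    tree = cKDTree(np.column_stack([rows, cols]))
    _, idx = tree.query(pts)
    snapped = np.column_stack([rows[idx], cols[idx]])

    samples: list[LabSample] = []
    for r, c in snapped:
        rlo, rhi = max(0, r - sample_radius), min(mask.shape[0], r + sample_radius + 1)
        clo, chi = max(0, c - sample_radius), min(mask.shape[1], c + sample_radius + 1)
        sub = np.zeros_like(mask)
        sub[rlo:rhi, clo:chi] = True
        sel = sub & mask
        mean_rgb = img[sel].mean(axis=0)
        L, a, b = rgb_to_lab(mean_rgb.reshape(1, 1, 3))[0, 0]
        samples.append(LabSample(float(L), float(a), float(b)))
    mean_lc = float(np.mean([s.LC for s in samples]))
    return samples, mean_lc


# ---------------------------------------------------------------------------
# HSB threshold segmentation and areas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColorThresholds:
    """Inclusive hue/saturation/brightness ranges on a 0-255 scale."""

    hue_lo: int
    hue_hi: int
    sat_lo: int
    sat_hi: int
    bright_lo: int
    bright_hi: int

    def __post_init__(self) -> None:
        for name in ("hue_lo", "hue_hi", "sat_lo", "sat_hi", "bright_lo", "bright_hi"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.sat_lo > self.sat_hi or self.bright_lo > self.bright_hi:
            raise ValueError("saturation/brightness ranges must have lo <= hi")
        # hue_lo > hue_hi is legal: wraparound range


#: Yellow male ornament selection (hue 0-64, i.e. red through yellow).
MALE_THRESHOLDS = ColorThresholds(0, 64, 100, 255, 66, 255)
#: Purple female nuptial coloration selection.
FEMALE_THRESHOLDS = ColorThresholds(154, 255, 5, 255, 66, 255)


def hsb_mask(image: np.ndarray, thresholds: ColorThresholds) -> np.ndarray:
    """Binary mask of pixels whose H, S and B all fall in their ranges."""
    img = _as_float_rgb(image)
    hsv = skcolor.rgb2hsv(img) * 255.0
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    t = thresholds
    if t.hue_lo <= t.hue_hi:
        h_ok = (h >= t.hue_lo) & (h <= t.hue_hi)
    else:  # wraparound, e.g. magenta-red straddling 255/0
        h_ok = (h >= t.hue_lo) | (h <= t.hue_hi)
    return (
        h_ok
        & (s >= t.sat_lo) & (s <= t.sat_hi)
        & (v >= t.bright_lo) & (v <= t.bright_hi)
    )


@dataclass(frozen=True)
class AreaMeasurement:
    LPA_cm2: float
    colored_cm2: float
    RCA: float
    n_components_kept: int
    px_per_cm: float


def colored_area(
    mask: np.ndarray,
    px_per_cm: float,
    min_component_cm2: float = 0.05,
    largest_only: bool = False,
) -> tuple[float, int]:
    """Total area (cm^2) of 8-connected mask components above the size cutoff.

    Components must exceed ``min_component_cm2`` strictly (the 0.05 cm^2
    rule); by default all qualifying components are summed, or only the
    largest with ``largest_only``. Returns ``(area_cm2, n_components_kept)``.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return 0.0, 0
    counts = np.bincount(labels.ravel())[1:]
    areas_cm2 = counts / px_per_cm**2
    kept = areas_cm2[areas_cm2 > min_component_cm2]
    if kept.size == 0:
        return 0.0, 0
    if largest_only:
        return float(kept.max()), 1
    return float(kept.sum()), int(kept.size)


def relative_colored_area(
    colored_cm2: float, body_mask: np.ndarray, px_per_cm: float
) -> tuple[float, float]:
    """LPA (cm^2) from the body mask and RCA = colored area / LPA."""
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    body_px = int(np.asarray(body_mask, dtype=bool).sum())
    if body_px == 0:
        raise ValueError("body mask is empty: LPA undefined")
    lpa = body_px / px_per_cm**2
    return lpa, colored_cm2 / lpa


def measure_photo(
    image: np.ndarray,
    body_mask: np.ndarray,
    belly_mask: np.ndarray,
    px_per_cm: float,
    white_patch_region: tuple[int, int, int, int] | None = None,
    thresholds: ColorThresholds = MALE_THRESHOLDS,
    reference_rgb=(243, 243, 243),
    min_component_cm2: float = 0.05,
    n_samples: int = 16,
) -> dict:
    """Full photo chain: calibrate, sample belly Lab/LC, segment, RCA."""
    img = _as_float_rgb(image)
    if white_patch_region is not None:
        img = calibrate_white(img, white_patch_region, reference_rgb)
    samples, mean_lc = sample_belly(img, belly_mask, n_samples=n_samples)
    mask = hsb_mask(img, thresholds) & np.asarray(body_mask, dtype=bool)
    area_cm2, n_kept = colored_area(mask, px_per_cm, min_component_cm2)
    lpa, rca = relative_colored_area(area_cm2, body_mask, px_per_cm)
    return {
        "L_mean": float(np.mean([s.L for s in samples])),
        "a_mean": float(np.mean([s.a for s in samples])),
        "b_mean": float(np.mean([s.b for s in samples])),
        "LC": mean_lc,
        "LPA_cm2": lpa,
        "colored_cm2": area_cm2,
        "RCA": rca,
        "n_components": n_kept,
        "samples": samples,
    }


def condition_index(mass_g: float, sl_cm: float) -> float:
    """Fulton-type body condition index, 100 * mass / SL^3 (g/cm^3)."""
    mass_g = np.asarray(mass_g, dtype=float)
    sl_cm = np.asarray(sl_cm, dtype=float)
    if np.any(mass_g <= 0) or np.any(sl_cm <= 0):
        raise ValueError("mass and standard length must be positive")
    out = 100.0 * mass_g / sl_cm**3
    return float(out) if out.ndim == 0 else out
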