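"""Synthetic inputs with known ground truth for every pipeline stage.

The study design being emulated: lateral photographs of cichlids with a
white standard and a size indicator; replicate reflectance spectra of the
yellow ventral ornament; repeated color measurements per individual; and
dyadic contests in which dominance depends on display behavior and the
display-color relationship differs between dominant and subordinate males.

Every generator is a pure function of its arguments including the seed:
the same configuration yields byte-identical output. Structural choices
(elliptical body, logistic reflectance step, lamp curve shape) are invented
stand-ins — the real photographs and spectra are not available — but the
quantities the downstream analyses estimate (patch area fraction, patch
Lab, variance components, model slopes) are exact, recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as skcolor

from .image_color import linear_to_srgb, srgb_to_linear

#: sRGB value (0-255) the rendered white standard is drawn at; also the
#: default calibration reference. Roughly a 90% diffuse reflector.
WHITE_STANDARD_SRGB = 243


class GamutError(ValueError):
    """Requested patch Lab color is not representable in sRGB."""


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageGroundTruth:
    """Parameters and bookkeeping for one synthetic fish photograph."""

    patch_area_fraction: float = 0.10
    patch_lab: tuple[float, float, float] = (70.0, 10.0, 55.0)
    body_area_cm2: float = 15.0
    px_per_cm: float = 40.0
    noise_sd: float = 0.8  # sensor noise, sRGB 8-bit units
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.patch_area_fraction <= 1.0:
            raise ValueError("patch_area_fraction must lie in [0, 1]")
        if self.body_area_cm2 <= 0 or self.px_per_cm <= 0:
            raise ValueError("body area and pixel scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for the tabular generators.

    Defaults mirror the scale of the study system: 46 males in 23 dyads,
    two measurement timepoints, Lab-chromaticity around 30 with a standard
    deviation near 10, displays lasting tens of seconds.
    """

    n_individuals: int = 46
    n_replicates: int = 2
    sigma2_between: float = 50.0
    sigma2_within: float = 50.0
    n_pairs: int = 23
    n_families: int | None = None
    beta_display: float = 0.15        # log-odds of dominance per second of display difference
    slope_dominant: float = 0.2       # LC units per second of display
    slope_subordinate: float = -0.2
    family_sd: float = 0.5            # SD of family random effect (log-odds / LC scale)
    color_noise_sd: float = 5.0       # residual SD of LC around the display line
    mean_value: float = 30.0          # grand mean for repeated measures (LC scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_individuals < 1 or self.n_replicates < 1 or self.n_pairs < 1:
            raise ValueError("counts must be at least 1")
        if self.family_sd < 0 or self.color_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def true_repeatability(self) -> float:
        tot = self.sigma2_between + self.sigma2_within
        if tot == 0:
            raise ValueError("both variance components are zero")
        return self.sigma2_between / tot

    def resolved_families(self) -> int:
        return self.n_families if self.n_families is not None else max(2, self.n_pairs // 2 + 1)


# ---------------------------------------------------------------------------
# Fish photograph
# ---------------------------------------------------------------------------

@dataclass
class FishImage:
    """A rendered photograph plus its exact segmentation ground truth."""

    image: np.ndarray                      # (H, W, 3) uint8 sRGB
    body_mask: np.ndarray                  # bool
    belly_mask: np.ndarray                 # bool; the region sampled for Lab
    patch_mask: np.ndarray                 # bool; exactly the colored pixels
    white_patch_region: tuple[int, int, int, int]
    ground_truth: ImageGroundTruth
    body_px: int = 0
    patch_px: int = 0

    @property
    def true_rca(self) -> float:
        """Exact relative colored area: patch pixels / body pixels."""
        return self.patch_px / self.body_px


def _lab_to_srgb_checked(lab: tuple[float, float, float]) -> np.ndarray:
    """Convert a Lab triplet to sRGB in [0,1]; raise GamutError if outside."""
    arr = np.asarray(lab, dtype=float).reshape(1, 1, 3)
    rgb = skcolor.lab2rgb(arr)[0, 0]  # skimage clips out-of-gamut results
    # detect clipping by round-tripping: an in-gamut color survives intact
    back = skcolor.rgb2lab(rgb.reshape(1, 1, 3))[0, 0]
    if np.max(np.abs(back - np.asarray(lab))) > 1.0:
        raise GamutError(f"Lab {tuple(lab)} is outside the sRGB gamut")
    return rgb


def gen_fish_image(ground_truth: ImageGroundTruth) -> FishImage:
    """Render a standardized lateral photograph with exact masks.

    Layout: grey background; an elliptical fish body (aspect ~2.4:1) in a
    neutral desaturated color; a ventral patch of exactly
    ``round(fraction * body_px)`` pixels rendered at ``patch_lab``; a white
    standard rectangle (outside the body); and a 1 cm black scale bar of
    ``px_per_cm`` pixels. The patch fills the bottom rows of the body, the
    last row partially, so the pixel count is exact.
    """
    gt = ground_truth
    patch_rgb = _lab_to_srgb_checked(gt.patch_lab)

    body_px_target = gt.body_area_cm2 * gt.px_per_cm**2
    semi_b = np.sqrt(body_px_target / (np.pi * 2.4))
    semi_a = 2.4 * semi_b
    margin = 12
    bar_len = int(round(gt.px_per_cm))
    height = int(2 * semi_b + 2 * margin + 40)  # room for white patch + scale bar
    width = max(int(2 * semi_a + 2 * margin), bar_len + 2 * margin)

    cy = 30 + margin + semi_b
    cx = width / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    body = ((xx - cx) / semi_a) ** 2 + ((yy - cy) / semi_b) ** 2 <= 1.0

    body_px = int(body.sum())
    k = int(round(gt.patch_area_fraction * body_px))
    patch = np.zeros_like(body)
    if k > 0:
        rows, cols = np.nonzero(body)
        # bottom rows first; within a row, left to right
        order = np.lexsort((cols, -rows))
        sel = order[:k]
        patch[rows[sel], cols[sel]] = True
    patch_px = int(patch.sum())

    # belly region: the patch itself when present, else the bottom third of the body
    if patch_px > 0:
        belly = patch.copy()
    else:
        belly = body & (yy > cy + semi_b / 3)

    rng = np.random.default_rng(gt.seed)
    img = np.full((height, width, 3), 186, dtype=float)          # grey background
    img[body] = (120, 125, 135)                                  # desaturated body
    img[patch] = np.round(patch_rgb * 255.0)

    white_region = (8, 28, 8, 48)  # (row0, row1, col0, col1), clear of the body
    r0, r1, c0, c1 = white_region
    img[r0:r1, c0:c1] = WHITE_STANDARD_SRGB
    # 1 cm scale bar, bottom left
    img[height - 14 : height - 8, margin : margin + bar_len] = 0

    if gt.noise_sd > 0:
        img = img + rng.normal(0.0, gt.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return FishImage(
        image=img, body_mask=body, belly_mask=belly, patch_mask=patch,
        white_patch_region=white_region, ground_truth=gt,
        body_px=body_px, patch_px=patch_px,
    )


def dim_image(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale image intensity in linear-RGB space, emulating reduced light."""
    if not 0 < factor <= 1:
        raise ValueError("dimming factor must be in (0, 1]")
    img = np.asarray(image)
    scale = 255.0 if img.dtype == np.uint8 else 1.0
    lin = srgb_to_linear(img.astype(float) / scale) * factor
    out = linear_to_srgb(lin) * scale
    return np.round(out).astype(np.uint8) if img.dtype == np.uint8 else out


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _grid() -> np.ndarray:
    return np.arange(300.0, 701.0)


def reflectance_curve(
    grid: np.ndarray, step_wavelength: float, max_reflectance: float, steepness_nm: float = 15.0
) -> np.ndarray:
    """Noise-free sigmoidal long-pass reflectance (a yellow step spectrum)."""
    return max_reflectance / (1.0 + np.exp(-(grid - step_wavelength) / steepness_nm))


def gen_reflectance_set(
    n_replicates: int,
    step_wavelength: float = 500.0,
    max_reflectance: float = 0.6,
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """Replicate reflectance spectra of a yellow long-pass ornament.

    Low reflectance below the step wavelength rising sigmoidally to
    ``max_reflectance`` above it, on a 1 nm grid from 300 to 700 nm, with
    i.i.d. Gaussian noise per replicate, clamped to [0, 1].
    """
    from .visual_model import Spectrum

    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if not 300.0 <= step_wavelength <= 700.0:
        raise ValueError("step_wavelength must lie in [300, 700] nm")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    grid = _grid()
    base = reflectance_curve(grid, step_wavelength, max_reflectance)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        vals = np.clip(base + rng.normal(0.0, noise_sd, grid.size), 0.0, 1.0)
        out.append(Spectrum(grid, vals))
    return out


def gen_illumination(kind: str, cutoff_nm: float = 400.0):
    """Either the tank downwelling irradiance or the ocular lens transmission.

    ``irradiance``: zero below the cutoff (a UV-blocking cover), a smooth
    two-peaked lamp-like curve above (arbitrary photon-flux units).
    ``lens``: logistic transmission rising from ~0 below the cutoff to ~1
    above it.
    """
    from .visual_model import Spectrum

    if not 300.0 <= cutoff_nm <= 700.0:
        raise ValueError("cutoff_nm must lie in [300, 700] nm")
    grid = _grid()
    if kind == "irradiance":
        lamp = np.exp(-(((grid - 450.0) / 18.0) ** 2)) + 0.85 * np.exp(
            -(((grid - 560.0) / 70.0) ** 2)
        )
        vals = np.where(grid >= cutoff_nm, lamp, 0.0)
    elif kind == "lens":
        vals = 1.0 / (1.0 + np.exp(-(grid - cutoff_nm) / 6.0))
    else:
        raise ValueError(f"unknown illumination kind {kind!r}")
    return Spectrum(grid, vals)


# ---------------------------------------------------------------------------
# Repeated measures
# ---------------------------------------------------------------------------

def gen_repeated_measures(config: SimulationConfig) -> pd.DataFrame:
    """Grouped Gaussian data: value = mu + u_individual + e_replicate.

    u ~ N(0, sigma2_between), e ~ N(0, sigma2_within). The true
    repeatability R = sigma2_b / (sigma2_b + sigma2_w) is stored in
    ``df.attrs['true_R']``.
    """
    if config.n_individuals < 2 or config.n_replicates < 2:
        raise ValueError("need at least 2 individuals and 2 replicates")
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_replicates
    u = rng.normal(0.0, np.sqrt(config.sigma2_between), n)
    e = rng.normal(0.0, np.sqrt(config.sigma2_within), (n, m))
    values = config.mean_value + u[:, None] + e
    df = pd.DataFrame(
        {
            "individual": np.repeat(np.arange(n), m),
            "replicate": np.tile(np.arange(m), n),
            "value": values.ravel(),
        }
    )
    df.attrs["true_R"] = config.true_repeatability
    df.attrs["sigma2_between"] = config.sigma2_between
    df.attrs["sigma2_within"] = config.sigma2_within
    return df


# ---------------------------------------------------------------------------
# Dyadic contests
# ---------------------------------------------------------------------------

def gen_dyad_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Paired contest data with known dominance and color effects.

    Per dyad: two males from different families with standard length (cm),
    mass (g), condition index, display duration (s, truncated normal,
    mean 30, SD 10) and
    attack counts. Dominance of male 1 is Bernoulli with log-odds
    ``beta_display * (display_1 - display_2)`` plus the difference of
    family random effects. Conditional on dominance status, the color
    variables follow

        LC  = 25   + slope * (display - 30) + N(0, color_noise_sd)
        RCA = 0.10 + 0.002 * [slope * (display - 30) + N(0, color_noise_sd)]

    with ``slope`` = ``slope_dominant`` or ``slope_subordinate`` and 30 s
    the expected display duration: the two status-specific regression
    lines cross at the mean display, so dominant and subordinate males
    have the same expected color overall while the display-color slope
    flips sign with status. All ground-truth parameters are echoed in
    ``df.attrs``.
    """
    if config.n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    n_fam = config.resolved_families()
    if n_fam < 2:
        raise ValueError("need at least 2 families")
    rng = np.random.default_rng(config.seed)
    u_fam = rng.normal(0.0, config.family_sd, n_fam)

    rows = []
    for pair in range(config.n_pairs):
        f1, f2 = rng.choice(n_fam, size=2, replace=False)
        fams = (int(f1), int(f2))
        sl = rng.normal(6.2, 0.38, 2).clip(4.0)
        ci = rng.normal(2.39, 0.21, 2).clip(1.5)
        mass = ci * sl**3 / 100.0
        display = rng.normal(30.0, 10.0, 2).clip(1.0)
        attacks = rng.poisson(10.0, 2)
        logit = config.beta_display * (display[0] - display[1]) + u_fam[f1] - u_fam[f2]
        p1 = 1.0 / (1.0 + np.exp(-logit))
        male1_dominant = rng.random() < p1
        for j in range(2):
            dominant = male1_dominant if j == 0 else not male1_dominant
            slope = config.slope_dominant if dominant else config.slope_subordinate
            centered = display[j] - 30.0
            lc = 25.0 + slope * centered + rng.normal(0.0, config.color_noise_sd)
            rca = 0.10 + 0.002 * (
                slope * centered + rng.normal(0.0, config.color_noise_sd)
            )
            rows.append(
                {
                    "individual": 2 * pair + j,
                    "trial": pair,
                    "family": fams[j],
                    "SL": sl[j],
                    "mass": mass[j],
                    "CI": ci[j],
                    "display": display[j],
                    "attacks": int(attacks[j]),
                    "dominant": int(dominant),
                    "LC_before": lc,
                    "RCA_before": rca,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs.update(
        beta_display=config.beta_display,
        slope_dominant=config.slope_dominant,
        slope_subordinate=config.slope_subordinate,
        family_sd=config.family_sd,
        seed=config.seed,
    )
    return df
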