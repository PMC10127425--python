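"""Trichromatic visual modeling of reflectance spectra.

Implements the spectrometry side of the coloration pipeline: averaging of
replicate reflectance spectra, restriction to the 300–700 nm visual range,
multiplication by ocular lens transmission, photoreceptor quantum catches
under a measured irradiance, projection of the three relative catches onto
the Maxwell triangle, and achieved chroma ``r_A`` — chromatic distance from
the achromatic center normalized by the maximum attainable distance in the
same hue direction.

The receptor set defaults to the three cone opsins of *Pelvicachromis
taeniatus* (SWS2A, RH2Abeta, LWS; lambda_max = 455, 518, 560 nm), with
sensitivity curves generated from the Govardovskii A1 alpha+beta visual
pigment template.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

VISUAL_RANGE_NM = (300.0, 700.0)

#: Default opsin peak sensitivities (nm): SWS2A, RH2Abeta, LWS.
DEFAULT_LAMBDA_MAX = (455.0, 518.0, 560.0)


class GridMismatchError(ValueError):
    """Two spectra do not share a common wavelength grid."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength (reflectance, irradiance, ...).

    Wavelengths must be strictly ascending. Negative values are clamped to
    zero on construction, with the clamp count logged — measured reflectance
    near zero routinely dips below zero from instrument noise.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        n_neg = int(np.sum(vals < 0))
        if n_neg:
            logger.warning("clamped %d negative spectrum values to 0", n_neg)
            vals = np.clip(vals, 0.0, None)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    def restrict(self, lo: float = VISUAL_RANGE_NM[0], hi: float = VISUAL_RANGE_NM[1]) -> "Spectrum":
        """Return the spectrum restricted to ``[lo, hi]`` nm (inclusive)."""
        keep = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not np.any(keep):
            raise ValueError(f"no samples in [{lo}, {hi}] nm")
        return Spectrum(self.wavelengths[keep], self.values[keep])

    def resample(self, grid: np.ndarray) -> "Spectrum":
        """Linearly interpolate onto ``grid`` (explicit, never implicit)."""
        grid = np.asarray(grid, dtype=float)
        return Spectrum(grid, np.interp(grid, self.wavelengths, self.values))

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.array_equal(
            self.wavelengths, other.wavelengths
        )


def _require_common_grid(*spectra: Spectrum) -> None:
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise GridMismatchError(
                "spectra are on different wavelength grids; resample explicitly first"
            )


def mean_spectrum(replicates: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra on a common grid."""
    if len(replicates) < 1:
        raise ValueError("need at least one replicate")
    _require_common_grid(*replicates)
    stack = np.vstack([r.values for r in replicates])
    return Spectrum(replicates[0].wavelengths, stack.mean(axis=0))


def apply_lens(reflectance: Spectrum, lens_transmission: Spectrum) -> Spectrum:
    """Multiply a reflectance spectrum by the lens transmission curve."""
    _require_common_grid(reflectance, lens_transmission)
    return Spectrum(reflectance.wavelengths, reflectance.values * lens_transmission.values)


# ---------------------------------------------------------------------------
# Visual pigment template
# ---------------------------------------------------------------------------

def pigment_template(lambda_max: float, grid: np.ndarray) -> Spectrum:
    """Govardovskii et al. (2000) A1 visual pigment absorbance template.

    Alpha band: S(x) = 1 / (exp(A(a - x)) + exp(B(b - x)) + exp(C(c - x)) + D)
    with x = lambda_max / lambda, A = 69.7, B = 28, C = -14.9, D = 0.674,
    b = 0.922, c = 1.104 and
    a = 0.8795 + 0.0459 * exp(-(lambda_max - 300)^2 / 11940).

    Beta band: a Gaussian A_beta * exp(-((lambda - lambda_m_beta)/d)^2) with
    A_beta = 0.26, lambda_m_beta = 189 + 0.315 * lambda_max and
    d = -40.5 + 0.195 * lambda_max.

    The sum of both bands is renormalized so the curve peaks at exactly 1.
    """
    if not 330.0 <= lambda_max <= 700.0:
        raise ValueError(f"lambda_max {lambda_max} outside template validity [330, 700] nm")
    lam = np.asarray(grid, dtype=float)
    x = lambda_max / lam

    a = 0.8795 + 0.0459 * math.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    b = 0.922
    c = 1.104
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    alpha = 1.0 / (
        np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D
    )

    A_beta = 0.26
    lam_beta = 189.0 + 0.315 * lambda_max
    d = -40.5 + 0.195 * lambda_max
    beta = A_beta * np.exp(-(((lam - lam_beta) / d) ** 2))

    sens = alpha + beta
    return Spectrum(lam, sens / sens.max())


@dataclass(frozen=True)
class ReceptorSet:
    """Three peak-normalized cone sensitivity spectra for a trichromat."""

    sensitivities: tuple[Spectrum, Spectrum, Spectrum]
    labels: tuple[str, str, str] = ("SWS2A", "RH2Abeta", "LWS")
    lambda_max: tuple[float, float, float] = DEFAULT_LAMBDA_MAX

    @classmethod
    def from_lambda_max(
        cls,
        lambda_max: tuple[float, float, float] = DEFAULT_LAMBDA_MAX,
        grid: np.ndarray | None = None,
        labels: tuple[str, str, str] = ("SWS2A", "RH2Abeta", "LWS"),
    ) -> "ReceptorSet":
        if grid is None:
            grid = np.arange(VISUAL_RANGE_NM[0], VISUAL_RANGE_NM[1] + 1.0)
        curves = tuple(pigment_template(lm, grid) for lm in lambda_max)
        return cls(curves, labels, tuple(float(v) for v in lambda_max))


# ---------------------------------------------------------------------------
# Quantum catches and the Maxwell triangle
# ---------------------------------------------------------------------------

def quantum_catch(
    effective_reflectance: Spectrum, irradiance: Spectrum, sensitivity: Spectrum
) -> float:
    """Trapezoidal integral of reflectance x irradiance x sensitivity."""
    _require_common_grid(effective_reflectance, irradiance, sensitivity)
    if len(effective_reflectance) < 2:
        raise ValueError("need at least two wavelength samples to integrate")
    if not np.any(irradiance.values > 0):
        raise ValueError("irradiance is identically zero: stimulus undefined")
    integrand = effective_reflectance.values * irradiance.values * sensitivity.values
    return float(np.trapezoid(integrand, effective_reflectance.wavelengths))


# Maxwell-triangle vertices at angles 90, 210, 330 degrees; centroid-to-vertex
# distance 1 (r_A is scale-invariant, so the choice is cosmetic).
_VERTEX_ANGLES = np.deg2rad([90.0, 210.0, 330.0])
TRIANGLE_VERTICES = np.column_stack([np.cos(_VERTEX_ANGLES), np.sin(_VERTEX_ANGLES)])
# Outward unit normals of the three edges; every edge lies at distance 1/2
# (the inradius) from the centroid.
_EDGE_NORMAL_ANGLES = np.deg2rad([270.0, 30.0, 150.0])
_EDGE_NORMALS = np.column_stack([np.cos(_EDGE_NORMAL_ANGLES), np.sin(_EDGE_NORMAL_ANGLES)])
_INRADIUS = 0.5


def max_chroma_radius(hue_angle: float) -> float:
    """Distance from the achromatic center to the triangle edge along ``hue_angle``."""
    d = np.array([math.cos(hue_angle), math.sin(hue_angle)])
    proj = _EDGE_NORMALS @ d
    with np.errstate(divide="ignore"):
        t = np.where(proj > 0, _INRADIUS / proj, np.inf)
    return float(t.min())


@dataclass(frozen=True)
class ChromaticPoint:
    """Position of a stimulus in the trichromatic Maxwell triangle."""

    q: tuple[float, float, float]
    xy: tuple[float, float]
    r: float
    hue_angle: float
    r_achieved: float
    catches: tuple[float, float, float] = field(default=(np.nan,) * 3)


def to_chromatic_point(catches) -> ChromaticPoint:
    """Map three non-negative quantum catches to a Maxwell-triangle point.

    Relative catches q = Q / sum(Q) are barycentric coordinates on an
    equilateral triangle centered at the origin. ``r`` is the Euclidean
    distance from the achromatic center, ``hue_angle`` the direction, and
    ``r_achieved`` = r / r_max(hue_angle) in [0, 1], reaching 1 exactly when
    one relative catch is zero (the point sits on the triangle boundary).
    """
    Q = np.asarray(catches, dtype=float)
    if Q.shape != (3,):
        raise ValueError("expected exactly three catches")
    if np.any(Q < 0):
        raise ValueError("catches must be non-negative")
    total = Q.sum()
    if total == 0:
        raise ValueError("all catches are zero: chromatic point undefined")
    q = Q / total
    xy = q @ TRIANGLE_VERTICES
    r = float(np.hypot(*xy))
    hue = float(math.atan2(xy[1], xy[0]))
    if r == 0.0:
        r_a = 0.0
    else:
        r_a = r / max_chroma_radius(hue)
        r_a = min(r_a, 1.0)  # guard against roundoff a hair above 1
    return ChromaticPoint(
        q=tuple(q), xy=(float(xy[0]), float(xy[1])), r=r, hue_angle=hue,
        r_achieved=r_a, catches=tuple(Q),
    )


def spectra_pipeline(
    replicates: list[Spectrum],
    lens: Spectrum,
    irradiance: Spectrum,
    receptor_set: ReceptorSet | None = None,
) -> ChromaticPoint:
    """Full spectrometry chain for one individual.

    mean of replicates -> restrict to 300-700 nm -> multiply by lens
    transmission -> quantum catch per receptor under the irradiance ->
    chromatic point with achieved chroma.

    All spectra are resampled onto the mean spectrum's restricted grid
    (linear interpolation, explicit).
    """
    if receptor_set is None:
        receptor_set = ReceptorSet.from_lambda_max()
    mean = mean_spectrum(replicates).restrict()
    grid = mean.wavelengths
    effective = apply_lens(mean, lens.resample(grid))
    irr = irradiance.resample(grid)
    catches = [
        quantum_catch(effective, irr, sens.resample(grid))
        for sens in receptor_set.sensitivities
    ]
    return to_chromatic_point(catches)
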