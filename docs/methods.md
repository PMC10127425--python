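# Methods

This note documents the models implemented in `cichlidcolor`, the choices
made where the underlying procedures are underspecified in common practice,
and what the synthetic-data generator does and does not emulate.

## Photo-based color quantification

Images are interpreted as 8-bit sRGB and converted to CIE 1976 L\*a\*b\*
with the D65 reference white. This matches photographs white-balanced to a
6500 K illuminant; no RAW demosaicing or camera-specific color profiling
is attempted (masks and pixel scale are inputs, never inferred from image
content).

**White-standard calibration.** "Adjusting brightness to the white
standard" is implemented as a per-channel linear gain applied in
linear-RGB space (the sRGB transfer curve is removed first), because a
change of illumination is multiplicative in light, not in gamma-encoded
values. The gain is `reference / observed mean` over the standard's
region. Gains that push channels past the maximum are clipped and the
clip count logged. Dimming an image by a known factor and recalibrating
restores belly Lab within ΔE < 0.5 in practice (the acceptance run
reports the measured value); the quantization floor of 8-bit storage is
the limiting factor.

**Belly sampling.** Sixteen samples "evenly spread over the belly" are
placed on a deterministic rectangular grid over the belly mask's bounding
box (grid aspect follows the box), snapped to the nearest mask pixel where
the grid point falls outside. Each sample averages sRGB over a 2 px-radius
neighborhood intersected with the mask — an averaging eyedropper. Manual
placement in the original workflow is not reproducible; a deterministic
grid is the testable surrogate.

**HSB segmentation.** Thresholds are inclusive ranges on a 0–255 scale
for hue, saturation and brightness alike (8-bit editor sliders). The male
yellow range hue 0–64 therefore spans roughly 0–90°, covering red through
yellow; hue wraparound (lo > hi) is supported. Thresholding is strict
per-pixel set membership; no fuzziness or anti-aliasing semantics are
modeled. Components are labeled 8-connected, and components whose area
exceeds 0.05 cm² strictly are summed (a flag restricts to the largest
component only). Area conversion uses px / px_per_cm².

**Condition index.** CI = 100 · mass(g) / SL(cm)³, the Fulton-type index;
the factor 100 puts typical adult males near 2.4 g/cm³.

## Visual model

Spectra are sampled functions on a 1 nm grid; all resampling is explicit
linear interpolation (never silent), and operations on mismatched grids
raise. Values are restricted to 300–700 nm, the assumed visual range; the
300–400 nm band is retained in the data structures but contributes
nothing under the default tank irradiance, which is zero below 400 nm
(UV-blocking cover).

**Receptor sensitivities.** The Govardovskii et al. (2000) A1 α+β
template generates each cone's absorbance curve from its λmax alone
(α band: 1/(e^{A(a−x)}+e^{B(b−x)}+e^{C(c−x)}+D) with x = λmax/λ, A = 69.7,
B = 28, C = −14.9, D = 0.674, b = 0.922, c = 1.104,
a = 0.8795 + 0.0459·e^{−(λmax−300)²/11940}; β band: a Gaussian at
189 + 0.315·λmax with width −40.5 + 0.195·λmax and amplitude 0.26), then
peak-normalizes. Defaults are the three cichlid cone opsins SWS2A (455),
RH2Aβ (518) and LWS (560 nm).

**Quantum catches and chromaticity.** Qᵢ is the trapezoidal integral of
reflectance × irradiance × sensitivity on the native 1 nm grid. Relative
catches q = Q/ΣQ are linear ("relative excitations"); a log-transform
switch exists at the call level but is not the default, and no von Kries
chromatic adaptation is applied (no adapting background is defined).
The q vector is embedded barycentrically in an equilateral triangle with
vertices at 90°, 210°, 330° and centroid–vertex distance 1 (the scale is
cosmetic: r_A is scale-invariant). Achieved chroma divides the distance
from the achromatic center by the distance to the triangle boundary along
the same hue direction, computed from the three edge normals (inradius
1/2); r_A ∈ [0, 1] with equality at 1 exactly when a relative catch is 0.

Replicate outlier handling is deliberately absent: the mean spectrum uses
all replicates as given.

## Repeatability

The model is the Gaussian random-intercept model; R is the intraclass
correlation. The one-way structure allows the REML criterion to be
profiled down to the single variance ratio θ = σ²_b/σ²_w, which is
optimized on the log scale (bounded scalar minimization, compared against
the θ = 0 boundary; negative between-group estimates are thereby clamped
at zero). For balanced data this reproduces the closed-form ANOVA
estimator to ≈1e−8. The profiled fit makes a bootstrap refit cost well
under a millisecond, so parametric-bootstrap CIs (simulate from the fitted
model on the observed group structure, refit, take the 2.5/97.5
percentiles) are cheap at 500–1000 draws.

The p-value for R = 0 is a likelihood-ratio test of the random-intercept
model against the iid model, both fit by ML, referred to the boundary
mixture ½χ²₀ + ½χ²₁ — the standard Gaussian default. A permutation test
(shuffling values across individuals) is provided as a cross-check; which
procedure produced a given published p-value is generally not knowable, so
both are exposed and LRT is the default.

## Dominance and display statistics

**Model reduction.** "Stepwise model reduction" is implemented as
single-term deletion: every term of the full model is tested by a
likelihood-ratio test against the model with that term removed, so degrees
of freedom always differ by one; dropped terms are not re-entered. The
display × dominance interaction is tested between models that both contain
the main effects. All tests are two-sided; all model fits for LRTs use ML
(never REML).

**Mixed-model engine.** Fitting is done by a small internal engine sized
for these designs. Gaussian models profile the fixed effects and residual
variance and optimize only the variance ratios through dense Cholesky
factorizations of the n × n marginal correlation matrix; on test data it
reproduces reference logliks to ~1e−6. Binomial models use the Laplace
approximation with the random-effect modes and fixed effects found jointly
by penalized Newton iterations and the log-determinant correction taken
over the random-effect block; this is the "profiled" Laplace flavor, which
agrees with the fully profiled reference implementation to a few percent
on likelihood-ratio statistics — adequate for the calibration and pattern
questions asked here, and two orders of magnitude faster than shelling out
per fit. Runaway coefficients (|β| > 15 on the logit scale) flag probable
complete separation on the affected term results rather than raising.

Subset models (dominant-only, subordinate-only) use family as the sole
random factor; full-data models use family and trial. A random factor
with fewer than two levels is dropped with a warning and the model
degrades toward a fixed-intercept fit.

**Correlation matrix.** Each variable is screened with the Lilliefors
test at α = 0.05; a pair uses Pearson if both pass and Spearman otherwise,
with the method recorded per cell. Constant columns give undefined cells.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study inputs — not fish.
Bodies are ellipses, the ornament is a ventral block of exactly
`round(fraction × body pixels)` pixels (the last row partial, so the
ground-truth RCA is exact), the lamp curve and lens are smooth invented
shapes, and reflectance is a logistic long-pass step with Gaussian
replicate noise clamped to [0, 1]. Passing tests therefore demonstrate
that the measurement chain is correct and well calibrated, not that it is
robust to fins covering the ornament, specular highlights, or real
segmentation error.

Tabular defaults follow the study system's scale: 46 males in 23 dyads,
two timepoints, chromaticity ≈ 25–30 with residual SD 5–10, displays as
durations (seconds; a truncated normal, mean 30 s, SD 10 — the duration
reading of "display" is the default, a count works identically), attack
counts Poisson, and a family random effect of SD 0.5 on the logit scale.
Dominance of a pair member follows a Bernoulli with log-odds
β_display · Δdisplay plus the difference of family effects (β = 0.15 by
default, chosen so the display term's χ² at the study's sample size lands
in the low twenties). Conditional on status, color follows
intercept + slope · (display − 30) + noise with slopes ±0.2: the two
status lines *cross at the mean display*, so status-specific slopes have
opposite signs while dominant and subordinate males have equal expected
color overall — the configuration in which an ornament signals motivation
rather than fixed quality, and the one consistent with display being the
dominant predictor of contest outcome while prior color is not.

## Problem sizes used in automated runs

Statistical checks run at sizes chosen to give informative Monte-Carlo
precision at interactive cost: repeatability recovery uses 1000
simulations per true R (100 × 2 observations); bootstrap coverage 500
simulations × 500 draws (script: 200 × 300); mixed-model null calibration
600 datasets of 60 pairs with the dominance model reduced to display +
standard length (script: 200); the boundary-LRT null 2000 datasets; and
pattern recovery 100 datasets of 100 pairs (script: 30). At these sizes
binomial Monte-Carlo error is ~1% on a 5% rejection rate and ~1–3% on
coverage/recovery percentages.

## Known limitations

- The binomial Laplace likelihood is an approximation; reported GLMM χ²
  values can differ by a few percent from adaptive-quadrature fits.
- With exactly one dominant per trial, the trial-level variance in the
  dominance model is weakly identified and is routinely estimated at its
  zero boundary; it is retained because the design calls for it.
- Bootstrap CIs are percentile-based; slight undercoverage (~1–2 points)
  at n = 40 groups is inherent to the percentile method at this size.
- The image pipeline assumes provided body/belly masks; there is no
  automatic fish or fin segmentation.
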