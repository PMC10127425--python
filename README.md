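# cichlidcolor

Quantification of **dynamic body coloration** in fish, built around the
yellow ventral ornament of the cichlid *Pelvicachromis taeniatus* and its
role in male dominance contests. The package implements the full analysis
chain a behavioral ecologist needs to go from standardized photographs,
reflectance spectra and contest records to the statistics that describe a
dynamic color signal — and it ships a synthetic-data generator with exact
ground truth so every stage is testable end to end without any raw data.

## What it computes

**Photo variables** (`cichlidcolor.image_color`)

- White-standard calibration: per-channel linear gain in linear-RGB space
  so the photographed white standard hits its reference value.
- Lab-chromaticity of the belly, sampled at 16 points evenly spread over
  the belly region and converted to CIE 1976 L\*a\*b\* (sRGB, D65):

  LC = √(a² + b²)

- Colored ornament area by HSB threshold segmentation (inclusive ranges on
  a 0–255 scale per channel; males: hue 0–64, saturation 100–255,
  brightness 66–255), 8-connected components, and a 0.05 cm² minimum
  component size; the **relative colored area** RCA = colored area / LPA,
  where LPA is the lateral projection area of the body excluding fins.
- Fulton-type condition index CI = 100 · mass / SL³ (g/cm³).

**Visual model** (`cichlidcolor.visual_model`)

- Mean of replicate reflectance spectra, restricted to 300–700 nm, times
  the ocular lens transmission.
- Quantum catches Qᵢ = ∫ R(λ) I(λ) Sᵢ(λ) dλ for the three cone opsins
  SWS2A, RH2Aβ and LWS (λmax = 455, 518, 560 nm), with sensitivity curves
  from the Govardovskii A1 α+β pigment template.
- The relative catches q = Q / ΣQ plotted in the Maxwell triangle, and
  **achieved chroma** r_A = r / r_max(hue): chromatic distance from the
  achromatic center scaled by the maximum attainable in that hue direction.

**Statistics** (`cichlidcolor.repeatability`, `cichlidcolor.behavior_stats`)

- Repeatability R = σ²_between / (σ²_between + σ²_within) from a REML
  random-intercept fit, with parametric-bootstrap SE and 95% CI and a
  ½χ²₀ + ½χ²₁ boundary likelihood-ratio p-value (permutation optional).
- The dominance analysis: a binomial GLMM for contest outcome (random
  intercepts for family and trial; single-term-deletion likelihood-ratio
  tests, df = 1), linear mixed models for the color variables with a
  display × dominance interaction, and status-specific subset models.
- Supporting tests: Lilliefors-corrected Kolmogorov–Smirnov normality
  screening, Box–Cox transformation, Welch t, exact Wilcoxon rank sum,
  paired t, and a correlation matrix that uses Pearson where both
  variables pass the normality screen and Spearman otherwise.

**Synthetic data** (`cichlidcolor.synthetic_data`) renders lateral fish
photographs with an exactly bookkept colored patch, white standard and
1 cm scale bar; long-pass "yellow" reflectance spectra with replicate
noise; tank irradiance (UV-blocked below 400 nm) and lens transmission
curves; grouped repeated measures with chosen variance components; and
dyadic-contest tables in which dominance depends on display and the
display–color slope flips sign with status.

## Worked example

```python
import cichlidcolor as cc

# render a fish with a ventral patch covering 10% of the body
gt = cc.ImageGroundTruth(patch_area_fraction=0.10, seed=3)
fish = cc.gen_fish_image(gt)

m = cc.measure_photo(fish.image, fish.body_mask, fish.belly_mask,
                     gt.px_per_cm, white_patch_region=fish.white_patch_region)
print(round(m["LC"], 2), round(m["LPA_cm2"], 2), round(m["RCA"], 3))
# 55.73 14.99 0.1

# visual model of the yellow ornament under tank light
reps = cc.gen_reflectance_set(12, seed=1)
pt = cc.spectra_pipeline(reps, cc.gen_illumination("lens"),
                         cc.gen_illumination("irradiance"))
print([round(q, 3) for q in pt.q], round(pt.r_achieved, 3))
# [0.054, 0.375, 0.57] 0.837

# repeatability of repeated color measurements
df = cc.gen_repeated_measures(cc.SimulationConfig(n_individuals=100, seed=2))
res = cc.repeatability_analysis(df["value"], df["individual"],
                                n_boot=200, seed=1)
print(round(res.R, 3), [round(c, 3) for c in res.CI], f"p={res.p:.2g}")
# 0.407 [0.247, 0.546] p=1.3e-05
```

The photo chain recovers the generator's exact patch fraction (RCA 0.100);
the long-pass ornament excites the long-wavelength cone most (q_LWS 0.57)
and sits near the triangle edge (r_A 0.84); the repeated measures were
generated at true R = 0.5 and the fitted CI covers it.

A CLI mirrors the library: `cichlidcolor simulate | photo | spectra | rpt |
stats | run`, each stage reading and writing CSV/PNG plus a JSON manifest.

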