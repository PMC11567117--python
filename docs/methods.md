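# Methods and numerics

This note records the modeling assumptions, numerical choices and design
decisions behind the package, and what the synthetic study does and does
not establish about real data.

## Two-layer skin model

Murine skin is modeled as a thin epidermis (default thickness
d_e = 0.06 mm, fit range 0.01–0.15 mm) over a dermis treated as
semi-infinite (d_d = 20 mm, giving diffuse transmittance below 10⁻⁴
across the band). Epidermal absorption is melanin over a bloodless
baseline; dermal absorption adds oxy/deoxyhemoglobin (volume fractions
of whole blood at 150 g/L), bilirubin and reduced/oxidized cytochrome-c
oxidase (molar concentrations). Both layers share the reduced-scattering
law with amplitude a (1/mm at 500 nm), Mie power b and Rayleigh fraction
f_Ray. Anisotropy and refractive index are not model parameters: they
are fixed at g = 0.9 (Henyey–Greenstein) and n = 1.4 (ambient 1.0), the
standard skin-optics convention; since the model is parameterized by
μₛ′, reflectance is insensitive to the particular g.

The packaged chromophore tables are synthetic reconstructions — smooth
log-space interpolants through anchor values that reproduce the band
structure of published compilations (Soret band, oxyhemoglobin α/β
bands, isosbestic crossings between 500 and 600 nm, melanin power law
μₐ = 66.7·(λ/500)⁻³·³³ mm⁻¹, baseline exponential). They are labelled
`synthetic_*` and live in `data/chromophores/` as two-column text
tables. The study is internally consistent (generation and inversion
share the library), so conclusions about pipeline behavior do not hinge
on absolute literature fidelity; conclusions about any *real* cube
would.

## Adding–doubling solver

The solver works in a flux (per-channel power) convention: R and T are
matrices over direction-cosine quadrature channels, layer composition is
plain matrix algebra, and energy conservation is a column sum. Choices:

* **Quadrature.** 16 nodes by default (minimum 4). With refractive
  mismatch the range [0, 1] splits at the critical cosine
  μ_c = √(1 − 1/n²); the lower interval takes Gauss–Legendre nodes, the
  upper a Radau rule with μ = 1 as an explicit node so the collimated
  normal beam is a channel of the discretization.
* **Phase function.** Henyey–Greenstein, expanded in Legendre
  polynomials to the quadrature order with δ-M scaling (f = g^N), then
  symmetrically renormalized (a few balancing iterations) so that
  discrete scattering conserves energy exactly; a conservative slab
  returns R + T = 1 to ~10⁻¹¹ at any order.
* **Doubling.** A homogeneous slab starts at optical thickness
  τ/2^K ≤ 10⁻⁵ with a single-scatter initialization that is exactly
  flux-conserving at unit albedo, and doubles K times. The two layer
  stacks are joined with the adding equations; Fresnel boundary
  "layers" (diagonal reflectance/transmission with total internal
  reflection below μ_c) wrap the stack. Specular reflectance of the
  incident beam is excluded from the reported total diffuse reflectance,
  matching a crossed-polarizer instrument.
* **Validation.** Against the Monte-Carlo oracle on a 3×3×2 grid of
  (μₐ, μₛ′, g) spanning physiologic skin values, agreement is ≤ 0.2 %
  absolute reflectance (test threshold 1 %).

The Monte-Carlo reference is a numba-compiled weighted-packet simulation
in the classic multilayer style (implicit capture, Russian roulette at
weight 10⁻⁴, Henyey–Greenstein sampling, Fresnel boundaries), seeded and
batch-wise, reporting standard errors from 10 photon batches.

## Reflectance table and per-pixel fitting

For fixed g, n and layer thicknesses, reflectance depends on wavelength
only through three scalars: μₐ,ₑ, μₐ,d and μₛ′. The lookup table
(`ReflectanceLUT`) therefore tabulates R on a 3-D grid — log-spaced
absorption axes (40 × 64 points over 0.002–12 and 0.002–18 mm⁻¹) and a
linear μₛ′ axis (96 points over 0.15–8.5 mm⁻¹) — built once per session
in a few seconds by batched adding–doubling, and interpolates
trilinearly. Worst-case interpolation error against the exact solver is
≈ 0.2 % absolute reflectance over the fit bounds (checked in tests).
This accelerated forward path is what makes per-pixel fitting of whole
cohorts tractable on one CPU; the exact solver remains available
everywhere via `forward="exact"`.

Fitting choices:

* **Objective.** Residuals are scaled by 1/reflectance by default
  ("relative" weighting) — the maximum-likelihood objective under the
  multiplicative noise of the renderer, and empirically far less biased
  than plain differences (recovered THB bias ≈ 0 vs ≈ −0.5 points at
  1 % noise). The *reported* residual is always the plain sum of squared
  reflectance differences, recomputed once from the fitted parameters so
  re-simulation reproduces it bitwise.
* **Bounds.** Physiologic ranges (melanin ≤ 0.1, each hemoglobin
  fraction ≤ 0.15, bilirubin ≤ 50 µM, cytochrome ≤ 100 µM, a ∈ [0.5, 5]
  mm⁻¹, b ∈ [0, 3], f_Ray ∈ [0, 1]); a parameter with equal bounds is
  held fixed. Optimization is bound-constrained (trust-region reflective
  for single spectra), not post-hoc clipping.
* **Per-pixel strategy.** `fit_cube(strategy="lut")` runs a vectorized
  bound-projected Levenberg–Marquardt over all masked pixels at once
  (forward-difference Jacobians, per-pixel damping, active-set freezing
  of converged pixels) against the interpolated forward. The default
  per-pixel free set is {f_m, f_Hb, f_HbO₂, a, b}: the parameters that
  dominate visible-band reflectance; minor chromophores, f_Ray and the
  thicknesses stay at their defaults. `strategy="exact"` fits every
  pixel with the full model (for phantoms). Single-start LM; the
  possibility of local minima is real but not observed to matter within
  the bounded, smooth forward used here.

## Preprocessing conventions

* Normalization (I_raw − I_dark)/(I_white − I_dark) with a degenerate-
  reference guard; results clipped to [0, 1].
* Spectral reduction averages native bands within ±2.5 nm of each
  450:5:750 center; spatial reduction is 2×2 mean binning (not
  decimation). Scenes are flat: curvature/height corrections are out of
  scope, so the generator renders flat geometry.
* **Spectral-angle segmentation.** The spectral-angle-mapper angle between
  raw positive reflectance spectra is compressed far below the
  78.46° default threshold for any plausible background, because all-positive
  vectors correlate strongly. `remove_background` therefore mean-centers
  each spectrum before taking the angle (configurable), making the
  measure shape-sensitive: a flat, nearly dark background scatters
  around 90° while tissue stays tens of degrees below threshold. The
  reference is the mean spectrum of the brightest-quartile pixels
  (tissue); a pixel is tissue iff its angle is ≤ threshold; the largest
  connected component is kept. In the pipeline the tissue mask is
  additionally eroded by one pixel: after binning, boundary pixels are
  tissue/background mixtures and measurably bias fitted hemoglobin.
* Erythema index: mean reflectance over 610–700 nm divided by mean over
  510–580 nm (window choices exposed in config); display preparation is
  a 3×3 median filter followed by adaptive histogram equalization.

## Features

Ten parameters (f_m, f_Hb, f_HbO₂, THB, StO₂, f_brub, f_CO, f_COO₂, a,
b) × eight statistics, in the fixed column layout 1–10 mean, 11–20 SD,
21–30 skewness, 31–40 kurtosis, 41–50 entropy, 51–60 contrast, 61–70
energy, 71–80 homogeneity (so column 41 is melanin entropy, 74 THB
homogeneity, etc.). Region minima/maxima are excluded — the fit bounds
predetermine them. Conventions: sample SD (ddof 1), Fisher–Pearson
skewness, Pearson (non-excess) kurtosis, constant region → skewness =
kurtosis = 0; entropy (bits) and energy come from a 32-level histogram
over the region min–max (energy as histogram uniformity Σp², keeping it
in [1/N_g, 1] — the per-pixel summation variant differs only by a known
reweighting). GLCM: 32 levels, offset distance 1 in the infinity norm,
angles {0°, 45°, 90°, 135°} computed per angle from pairs fully inside
the region, symmetrized, normalized, then averaged. scikit-image's GLCM
cannot restrict to an irregular mask, so pair counting is done directly.
Gaussian smoothing of maps is mask-normalized (no leakage from invalid
pixels), with σ = 0 defined as a bitwise identity.

## Selection and classification

Mutual information uses quantile discretization (4 bins by default,
suited to 84 training rows) and the plug-in estimate; MRMR uses the
difference criterion Φ = D − R with greedy forward selection, ties
broken to the lowest column index, and constant columns excluded (their
Φ = 0 would otherwise outrank informative but partly redundant
candidates). The greedy path is verified in tests against exhaustive
re-evaluation on small instances.

The classifier roster is config data
(`data/classifier_registry.yaml`): 30 scikit-learn estimators spanning
linear models, SVM variants, trees and ensembles, naive Bayes,
discriminant analysis, neighbors, Gaussian process, a neural network, a
label-spreading model and a majority-class dummy — default
hyperparameters, seeds fixed per run. AUC is computed by the
Mann–Whitney rank formulation (tested against brute-force pair counting
and trapezoidal ROC); scores come from predicted probabilities where the
model defines them, else the decision margin, else hard predictions.
Cross-validation is leave-one-subject-out over the four training mice;
contamination (a subject on both sides of any split) raises before any
training. Tumor is the positive class.

## Synthetic cohort

The generator emulates the study design: 6 mice, imaging days
{0, 1–3, 6–10, 13–14}, two mice held out for validation; 66 cubes, 126
labeled regions (66 healthy + 60 tumor; 84 train/test + 42 validation).
Scenes are 48×64 post-binning (rendered at 2× and binned; full-size
rendering is a parameter, not a different code path). Per-day targets:
healthy THB 2.7 % (SD 1.4 in total), healthy StO₂ 38 %, tumor THB
ramping 3 → 6 % over days 1–14, tumor StO₂ interpolating 28.2 % (day 1)
→ 52.9 % (day 9) → 45 % (day 14), tumor radius growing ≈ 0.85 px/day
from 3 px. Design choices worth flagging:

* **Dispersion allocation.** The reported ± spreads are realized mostly
  as intra-region pixel heterogeneity (e.g. tumor StO₂ pixel SD 8.7 →
  13.8 across the study) with a smaller between-subject jitter (1.5–2
  points). This keeps cohort-level means stable study conditions rather
  than a per-seed lottery, while single-region statistics still show the
  stated spread.
* **Region-centered fields.** Heterogeneity fields are Gaussian random
  fields (correlation length 5 px healthy, 2 px tumor) standardized
  *over the region they fill*; without this, a small tumor inside a
  correlated field inherits an O(pixel-SD) random offset and the per-day
  targets are not realized.
* **Melanin marginals.** Healthy melanin is a probit-flattened field
  (near-uniform marginal over 0.012–0.028), tumor melanin tightly peaked
  (0.020 ± 0.0018): the tumor's melanin histogram is more ordered, which
  reproduces the qualitative finding that melanin entropy separates the
  classes. This is a modeling choice, not a measured fact. Tumor
  scattering differs modestly (a 2.35 vs 2.0, b 0.95 vs 1.2) so
  scattering features are informative.
* **Background** pixels carry a flat, nearly dark spectrum (reflectance
  0.006) so spectral-angle segmentation is non-trivially testable.
* **Noise**: 1 % multiplicative plus an additive floor of 0.002 at native
  resolution, applied to reflectance before conversion to raw counts
  against smooth synthetic white/dark reference frames, so reference
  normalization is exercised end to end.
* **Rendering** uses the interpolated forward by default (the dense
  table doubles as the renderer); `forward="exact"` renders through
  adding–doubling per pixel and is used in tests that compare the two.
* Day 0 contributes one image per mouse, which reproduces the study's
  session counts.

What passing tests show — and do not. The synthetic cohort shares the
real study's design, trajectories, noise scale and class structure, so
end-to-end tests establish that the *pipeline* is correct and
well-conditioned: normalization, segmentation, inversion (recovered
healthy THB within ~0.1 of the generating 2.7 %; day-9 tumor StO₂ within
~1 of 52.9 %), feature bookkeeping, leakage-free evaluation. They do not
establish that real CT26 tumors are separable with AUC 1 — the synthetic
class differences are planted, whereas the real ones are an empirical
finding; nor do they span hair, curvature, misalignment or depilation
artifacts, which the generator deliberately omits.

## Robustness protocols

The smoothing sweep (σ = 0…10 step 0.5, 21 conditions) and
leave-one-day-out (10 conditions, day 0 never omitted, validation mice
untouched) re-run selection, training and validation per condition with
shared seeds; σ = 0 reproduces the baseline bitwise. The day-wise test is
Welch's two-sample t-test (small n, unequal variances), Mann–Whitney by
flag, no multiple-testing correction — flags mirror a per-day significance annotation. The "smoothing does not hurt under noise" property is
checked on a purpose-built high-noise cohort in which blood trajectories
are equalized between classes and heavy pixel noise is added to the
maps, so the class signal rides on spatial structure that denoising
recovers; with strong mean separations (the default cohort), smoothing
has nothing to repair and the property is uninformative. The averaged
"all models" curves include the dummy baseline.

## Problem sizes and determinism

Default test and acceptance runs use the 48×64 scene, 16-node
quadrature, the session-cached reflectance table, 4·10⁴-photon
Monte-Carlo checks (10⁵–10⁶ for tighter oracle studies), and
60-iteration per-pixel LM; these sizes were chosen so a full cohort
study completes in minutes on a single core while every tolerance in the
test suite retains a comfortable margin. All randomness flows from
explicit seeds (numpy `SeedSequence` spawning per image; fixed
`random_state` per classifier), so every pipeline product — spectra,
cohorts, reports, sweeps — is bitwise reproducible at a given seed.

## Known limitations

* The chromophore tables are qualitative reconstructions; absolute
  parameter values from real cubes would carry their error.
* The per-pixel fit holds minor chromophores fixed by default; bilirubin
  or cytochrome dynamics would alias into the fitted parameters.
* Single-start LM can in principle settle in local minima; multistart is
  not implemented.
* The classifier roster beyond the families named in the study design is
  a reasonable completion, not a reconstruction of an unpublished list.
* Flat scenes only: no curvature, hair or registration artifacts.
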