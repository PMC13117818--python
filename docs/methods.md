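# Methods

## The measurement problem

Fluorescent tracers (e.g. Glo Germ™, melamine-copolymer beads in lotion)
are used to visualize contamination in hand-hygiene training: hands are
photographed under near-UV illumination before and after washing, and the
question is how much fluorescent material was removed.  A camera pixel under
these conditions does not record fluorescence alone — it mixes fluorescent
emission with UV light reflected off the skin and with any residual
broadband room light.  Single-channel proxies (luminance, the blue channel)
conflate those sources.  This package implements a physically grounded
alternative: model each pixel as a linear mixture of known spectral
signatures and estimate the fluorophore contribution per pixel.

## Mixture model

Radiance leaving the surface is modelled as

    I(λ) = α_s s(λ) + α_f f(λ),

where `s` and `f` are *spectral power density functions* (SPDFs): spectra
normalized to integrate to 1 over the visible range V = [390, 830] nm, so
they carry chromaticity only, and `α_s`, `α_f` are the visible radiant
powers of the skin-reflectance and fluorescence components.  Because any
linear filter L (here: projection through the XYZ color-matching functions)
preserves the mixture,

    L(I) = α_s L(s) + α_f L(f),

estimation reduces to linear regression in tristimulus space.  The working
model adds a broadband white-light column and a residual:

    c(x, y) = β_w L(w) + β_s L(ŝ) + β_f L(f̂) + ε,   β ≥ 0,

with `L(w) = (1,1,1)` by definition.  `β` is estimated per pixel by
non-negative least squares (NNLS); `β_f` is the fluorescence density map,
and its sum over analyzed pixels is the scalar used in paired comparisons.
The residual ε absorbs light outside the 3-column subspace plus sensor
noise, assumed approximately Gaussian (large photon counts).

The shipped default design matrix is

    [L(w), L(ŝ), L(f̂)] = [[1.0000, 0.0914, 0.2149],
                           [1.0000, 0.0702, 0.1614],
                           [1.0000, 0.3381, 1.1198]]

with columns derived from measured spectra of the UV-illuminated-skin
population standard and the tracer emission.  The matched-filter baseline is
`g(c) = L(f̂)·c = 0.2149 X + 0.1614 Y + 1.1198 Z`; a power-normalized
variant divides by ‖L(f̂)‖² so that a pure-fluorescence pixel returns
exactly α_f, which makes the two estimators directly comparable and makes
the matched filter's overestimation attributable to background confusion
rather than scale convention.

## Numerical choices

- **Quadrature**: composite trapezoid on a fixed 1 nm grid over
  V = [390, 830] nm (441 samples).  All spectra are linearly interpolated
  onto this grid (zero-filled outside their support) before any integral;
  SPDF unit-integral invariants hold to 1e-9.
- **Color-matching functions**: the package evaluates and ships a 1 nm
  tabulation of the Wyman–Sloan–Shirley piecewise-Gaussian analytic model
  of the CIE 2° XYZ CMFs (`data/cmf_xyz_2deg_1nm.csv`).  Tiny negative
  values of the x̄ correction lobe are clipped to zero.  Any CMF-dependent
  comparison against published coordinates is tolerance-based; the default
  design matrix and camera matrix are shipped as constants and do not
  depend on the CMF tabulation.
- **White column**: defined as exactly (1, 1, 1) rather than recomputed
  from an equal-energy SPDF, which under any specific tabulation would give
  only approximately equal coordinates.
- **NNLS**: the per-pixel problem is a fixed 3-column system solved with
  the Lawson–Hanson active-set algorithm (scipy).  The batch path first
  computes the unconstrained 3×3 solution for all pixels at once and
  accepts rows that are already entrywise non-negative (NNLS coincides with
  ordinary least squares there); only boundary cases go through the
  active-set solver.  Tests verify exact agreement with an exhaustive
  8-support-set enumeration oracle to 1e-8, including KKT conditions.
- **Negative XYZ values** (possible because the camera matrix has negative
  entries) are passed through to the estimators, never clamped:
  non-negativity lives in coefficient space and clamping would bias β_w.
- **Saturation**: pixels with any raw channel at ≥ 0.99 of full scale are
  flagged; they appear in maps but are excluded from scalar integration by
  default (switchable), because clipping violates the linear radiometric
  model and drives the decomposition toward the white column.
- **RMS contrast** is standard deviation over mean (coefficient of
  variation) of masked map values.  The published reference values
  (1.184/1.685 for NNLS, 0.975/1.312 for the matched filter) exceed any
  possible standard deviation of [0,1]-scaled data, so a mean-relative
  definition is the only standard one consistent with them.

## Monte-Carlo estimator comparison

`simulate.run_mse_study` draws `c = α_s L(ŝ) + α_f L(f̂) + η` with
`η ~ N(0, σ²I₃)` (σ in CMF-projection units, iid across channels) and
scores both estimators by squared error in α_f, under two scenarios:
`fixed_skin` (α_s = 1, α_f ∈ [0, 10]) and `fixed_total` (α_s + α_f = 10).
Default grids: α_f in steps of 0.5 (21 points), σ ∈ {0, 0.25, 0.5, 1, 2,
4}, 10⁴ replications per cell.  A single standard-normal block is scaled by
σ (common random numbers across cells, σ levels and methods), which makes
monotone trends visible at modest replication counts; the automated checks
use 2 000 replications per cell for the surface-shape properties and 10⁵
draws for the matched-filter moment checks, sizes at which every asserted
effect is many standard errors wide.

Closed forms used as oracles: the matched-filter error is Gaussian with
mean `α_s (L(f̂)·L(ŝ))/‖L(f̂)‖²` (≈ 0.3088 α_s for the default basis) and
variance `σ²/‖L(f̂)‖²`; at σ = 0 NNLS recovers (α_s, α_f) exactly because
the noiseless sample lies in the span of an invertible 3×3 system with a
non-negative solution.  Estimation always uses all three basis columns,
matching the image pipeline.

## Synthetic data

The generator module emulates the study conditions so every stage is
testable without measured data:

- **Illuminant**: Gaussian line at 400 nm, sd 3 nm — essentially all power
  within the physical lamp's 395–405 nm band.
- **Fluorophore emission**: dominant Gaussian at 450 nm (sd 25 nm) plus a
  15%-amplitude peak at 398 nm (sd 4 nm) representing reflected excitation
  light; its XYZ projection reproduces the Z > X > Y ordering of the
  shipped fluorescence column.
- **Skin reflectances**: smooth curves rising toward the red end, with
  per-subject overall scale in [0.3, 0.9] and a few-percent smooth shape
  perturbation.  Under the narrowband illuminant the per-subject SPDFs
  collapse onto one curve (max pointwise CV < 0.05), which is the mechanism
  that justifies a single population skin column.
- **Test strips**: swatches with geometric dilution 15/65 (~23.07% per
  step; 12 swatches by default, since the step count is a free parameter),
  fluorescent power proportional to concentration above a 1% floor, an
  exposure scale, optional Gaussian tristimulus noise, and per-channel
  clipping with ground-truth clip bookkeeping.
- **Hand scenes**: a white-lit card strip, a skin region, and Gaussian
  fluorescence blobs with retained coefficient maps; rendering is the exact
  forward model `c = basis·β (+ noise, clip)`, so noiseless unclipped
  decomposition must return the truth to machine precision.

Fixtures are small (≤ 256×256) so the suite runs in seconds.  What passing
synthetic tests do **not** show: the generator has no felt texture, no
optical-brightener contamination, no spatially varying illumination, no
demosaicing artifacts, and Gaussian rather than Poisson noise — so
agreement on fixtures demonstrates correctness of the estimation machinery,
not photographic realism.

## Interfaces and conventions

Images are linear (black-level-corrected, gamma-free) RGB, rescaled to
[0, 1] by full-scale division; the shipped 3×3 RGB→XYZ matrix comes from
the reference camera's DNG calibration metadata and can be overridden by a
row-major CSV.  Quantitative maps are written as 32-bit float TIFF with a
per-image-rescaled 16-bit PNG alongside for display only.  Paired
comparisons enforce identical basis/matrix/threshold configuration on both
images and report both integrated fluorescence scalars, their after/before
ratio (flagged undefined if the "before" integral is zero), RMS contrasts,
pixel/saturation counts, and full provenance.  Cohort-level statistics
across subjects are left to the user.

## Known limitations

- Real CMF tabulations differ from the analytic model in the 3rd decimal;
  rebuilding a design matrix from measured spectra will differ accordingly.
- The decomposition is only as good as the linearity of the input: RAW
  development that applies gamma or local tone mapping silently breaks it.
- No automatic skin segmentation; masks are the caller's responsibility.
- The three-column basis cannot represent colored room light; such light
  lands partly in the residual and partly on the nearest basis column.
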