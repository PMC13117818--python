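# glowsplit

Quantitative fluorescence maps from color photographs of fluorescent-tracer
experiments.

Hand-hygiene training and contamination studies use UV-excited fluorescent
tracers (e.g. Glo Germ™): hands are photographed under a near-UV lamp
before and after washing, and the question is how much tracer was removed.
The light a camera pixel records under these conditions is a *mixture* —
fluorescent emission plus UV light reflected off skin plus residual
broadband room light — so single-channel proxies (luminance, the blue
channel) systematically conflate fluorescence with background.  glowsplit
separates the sources.

## Model

Each XYZ pixel is modelled as a non-negative linear mixture of three
spectral signatures projected through the CIE color-matching functions:

    c(x, y) = β_w L(w) + β_s L(ŝ) + β_f L(f̂) + ε,   β ≥ 0,

where `L(w) = (1,1,1)` is broadband white light, `L(ŝ)` the tristimulus
column of UV-illuminated skin, and `L(f̂)` that of the tracer emission
(SPDFs — spectra normalized to unit integral over 390–830 nm — so columns
encode chromaticity only).  Per-pixel non-negative least squares gives the
fluorescence coefficient map `β_f(x, y)`; its sum over analyzed pixels is a
scalar proportional to total tracer, and the ratio of that scalar between
paired before/after images measures the intervention.  The shipped default
design matrix is

    [L(w), L(ŝ), L(f̂)] = [[1.0000, 0.0914, 0.2149],
                           [1.0000, 0.0702, 0.1614],
                           [1.0000, 0.3381, 1.1198]]

The classical matched filter `g(c) = 0.2149·X + 0.1614·Y + 1.1198·Z` is
provided as the baseline: SNR-optimal under Gaussian noise, but unable to
distinguish fluorescence from correlated backgrounds.  A Monte-Carlo module
compares both estimators' ability to recover the true fluorescent power.

## Worked example

Decompose a synthetic before/after pair in which washing removed 75% of
the tracer:

```python
from glowsplit.synthkit import synth_scene, render_scene, SceneTruth
from glowsplit.report import compare_pair

before_truth = synth_scene((96, 96), seed=7)          # card + skin + blobs
after_truth = SceneTruth(before_truth.beta_w_map.copy(),
                         before_truth.beta_s_map.copy(),
                         0.25 * before_truth.beta_f_map)
before = render_scene(before_truth, seed=7)
after = render_scene(after_truth, seed=8)

report = compare_pair(before, after)
print(f"integrated fluorescence before: {report.integrated_fluorescence_before:.2f}")
print(f"integrated fluorescence after:  {report.integrated_fluorescence_after:.2f}")
print(f"after/before ratio:             {report.ratio_after_over_before:.3f}")
print(f"RMS contrast (before, NNLS map):           {report.rms_contrast['before_beta_f']:.3f}")
print(f"RMS contrast (before, matched-filter map): {report.rms_contrast['before_matched_filter']:.3f}")
```

prints

```
integrated fluorescence before: 406.86
integrated fluorescence after:  101.72
after/before ratio:             0.250
RMS contrast (before, NNLS map):           4.052
RMS contrast (before, matched-filter map): 0.471
```

The ratio recovers the ground-truth 0.25 exactly in this noiseless render,
and the NNLS map is far higher-contrast than the matched-filter map because
it zeroes the skin and card backgrounds instead of projecting them onto the
fluorescence axis.  On real photographs the scalar is only proportional to
tracer quantity, so the ratio — not the absolute number — is the
reportable result, and both images must be taken under identical
illumination, camera settings, and analysis configuration (enforced by
`compare_pair`).

## Command line

```sh
glowsplit decompose IMG.tif --mask MASK.png --out out/      # coefficient maps + summary.json
glowsplit compare BEFORE.tif AFTER.tif --out cmp/           # paired ComparisonReport
glowsplit teststrip STRIP.tif --boxes boxes.csv --concentrations conc.csv
glowsplit simulate-mse --scenario fixed_total --seed 1 --reps 10000 --out mse/
glowsplit synth strip --seed 1 --out fixtures/              # synthetic fixtures
```

Inputs are linear (gamma-free) 8/16-bit TIFF or PNG; a 3×3 CSV can override
the shipped camera RGB→XYZ matrix or projection basis.  Saturated pixels
(any raw channel ≥ 0.99 full scale) are flagged and excluded from scalar
integration by default, because clipping breaks the linear model and makes
the decomposition misread fluorescence as white light.

See `docs/methods.md` for the full model description, numerical choices,
and what the synthetic generators do and do not emulate.

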