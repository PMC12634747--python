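# Methods

`maskscope` implements a desk-scale analysis of mammographic
lesion-masking risk: how well a score combining model-observer
detectability, density-map texture and age separates screening
examinations with screen-detected cancers (assumed low masking risk) from
negative examinations preceding interval cancers (assumed high masking
risk), and how that compares to volumetric breast density (VBD) alone.
Because the screening data such analyses run on are not public, the
package ships a calibrated synthetic-cohort generator and validates the
full pipeline on it.

## Synthetic cohort generator

The generator emulates a Dutch biennial screening sample restricted to
ages 50–75. Each examination carries a group label (screen-detected vs
interval cancer), age, a ground-truth VBD, a retrospective visible-mass
flag, cancer laterality, and screening-timing fields; four views (left
and right, CC and MLO) can be rendered per exam.

**Age** is drawn from a normal distribution truncated to [50, 75] years
with σ = IQR/1.349. An asymmetric truncation window shifts the median
away from the location parameter (for the interval group, a location of
58 would yield a truncated median near 59.7), so the location is solved
numerically so that the *truncated* distribution's median equals the
group median: 64 y (IQR 59–70) for screen-detected, 58 y (53–65) for
interval exams.

**VBD** is log-normal with the group median and IQR matched in closed
form (IQR = 2·median·sinh(z₇₅σ), z₇₅ = Φ⁻¹(0.75)): medians 5.9%
(4.3–8.8) and 8.3% (5.7–14.2). Values are clipped to [0.5, 70]%, which
affects only the far upper tail and leaves the median untouched.

**Visible-mass rates** default to 0.82 (screen-detected) and 0.55
(interval). Among interval exams, the flag separates intermediate
(visible in retrospect) from high (not visible) masking categories;
intermediate-category lesions are inserted at half the dense-equivalent
amplitude of screen-detected lesions (2 vs 4 mm) — present but harder to
see. Interval cancers are diagnosed after a truncated-normal delay with
median 13 months (IQR 7–19) on [0, 24].

**Phantoms and rendering.** The breast is a semi-ellipse with uniform
compressed thickness T = 50 mm. Background texture is an isotropic
power-law random field (spectrum ∝ f^−β, β = 3, synthesized by Fourier
filtering of white noise with the DC bin zeroed). The dense-thickness map
is a clamped affine map of the texture, t_d = clip(c + g·texture, 0, T);
the offset c is solved by bisection so the phantom's true VBD hits the
drawn target, and the gain g = 0.1·T·√(VBD/10) ties texture amplitude to
density so dense breasts also carry stronger, more masking texture. Raw
images follow a two-compartment attenuation law,
I = I₀·exp(−μ_fat(T−t_d) − μ_gland·t_d), with μ_fat = 0.05/mm,
μ_gland = 0.09/mm, open-beam signal I₀ = 5000, saturation 16383, and
additive Gaussian noise of 0.001·I₀. The noise default is deliberately
low: the density inversion clamps negative thickness estimates to zero,
and stronger per-pixel noise would bias VBD upward through that clamp
(the shipped default keeps the estimator bias below 0.1 percentage
points); texture, not detector noise, is the masking mechanism of
interest. Lesions are Gaussian bumps of dense-equivalent thickness
(σ = 2 mm) added to the ipsilateral views.

The default raster is 512×512 at 0.1 mm pitch; a `small` preset
(128×128 at 0.4 mm) keeps the same breast geometry in millimetres and is
used throughout the test suite and repeated-cohort experiments.

What the generator does **not** emulate: anthropomorphic anatomy,
peripheral breast thinning, scatter and beam hardening, vendor
post-processing, reader behaviour, and any correlation between age and
density beyond the group marginals. Passing tests therefore demonstrate
the internal consistency and statistical calibration of the pipeline,
not clinical performance on real mammograms.

## Density mapping

The open-beam signal is self-calibrated as the median of unsaturated
background pixels, requiring at least 1% of the image area; saturated or
absent backgrounds are reported as calibration failures and propagate to
exam-level exclusions, mirroring how real pipelines drop images with a
missing open-beam reference. The breast is segmented as the largest
connected attenuated region (midpoint threshold, holes filled). Dense
thickness per pixel inverts the attenuation law,
t_d = (ln(I₀/I) − μ_fat·T)/(μ_gland − μ_fat), clamped to [0, T];
VBD = 100·Σt_d/ΣT over the mask. A uniform T per image is a documented
simplification (no peripheral-thinning correction). BI-RADS-like density
categories use fixed VBD cut points 3.5/7.5/15.5%, boundaries rounding
up.

## Detectability maps

The detectability index is the detection SNR of a prewhitening ideal
observer for a known Gaussian lesion against the local background:
d′² = Σ_{f≠0} |S(f)|²/NPS(f), with S the unitary DFT of the lesion
profile and the NPS estimated from mean-subtracted, Hann-windowed ROIs
normalized so the mean non-DC power equals the windowed sample variance.
A non-prewhitening observer is available behind a switch.

The raw windowed periodogram has χ²₂ fluctuations per frequency bin,
which makes the prewhitened statistic very noisy in the few
low-frequency bins where a Gaussian lesion concentrates its energy
(coefficient of variation ≈ 0.75 across white-noise ROIs). The default
map therefore conditions each local NPS by an isotropic power-law
regression: the radially averaged profile is fitted by weighted least
squares in log–log space and broadcast back to the grid. This matches
the power-law texture family of the generator, reduces the white-noise
CoV to ≈ 0.12 at a 64-px ROI, and preserves the monotone response of d′
to texture amplitude and slope. The raw mode remains available
(`nps_mode="raw"`).

Maps are evaluated on the dense-thickness raster (so d′ reflects
anatomic texture rather than detector signal scale) at stride-spaced
ROIs fully inside the breast; defaults are ROI = image/4 (at least
8 lesion σ), stride = ROI/2, lesion σ = 2 mm, and a signal amplitude
normalized to give d′ = 3 against unit-variance white noise. All of
these are configuration, since the upstream method publishes none of
them.

## Features and model

Per view, the pipeline extracts the sample standard deviation of the
detectability map and the Haralick correlation of the gray-level
co-occurrence matrix (GLCM) of the density map (32 linear levels over
the in-mask range; offsets (0,1), (1,0), (1,1), (1,−1) averaged;
symmetric, normalized, pairs restricted to the breast mask). Features
and VBD are averaged over the available views; age joins them as the
third predictor. An examination with no calibratable view raises an
exam-level failure and is excluded.

The masking score is a logistic model on z-standardized features,
fitted by maximum likelihood (Newton, tolerance 1e−10, 100 iterations;
complete separation flagged and refitted with a tiny ridge).
Bidirectional stepwise selection on AIC = 2k − 2logL from the
intercept-only model is provided; the shipped default model instead fits
the fixed three-feature set {detectability-map SD, GLCM correlation,
age}, refit on the default synthetic cohort (n = 400/group, small
preset, seed 20250926) with the seed and standardization constants
recorded in the serialized JSON. The per-exam score is the mean of the
per-view scores; for model fitting, view-averaged features are used.
Both conventions are deliberate and documented because the upstream
method does not state which it uses.

## Reference standard and analyses

Inclusion: screen-detected = positive screen, diagnosis within
12 months, negative prior screen under 30 months before; interval =
negative screen, diagnosis within 24 months. Exclusions: in situ,
micro-invasive, metachronous, bilateral, missing prior, first round,
implant. Month boundaries are inclusive; month arithmetic is
⌊days/30.44⌋. Four categories follow from retrospective mass
visibility: (1) screen-detected visible → low risk, (2) screen-detected
not visible → unknown, (3) interval visible → intermediate, (4) interval
not visible → high. Analysis 1 contrasts {1,2} vs {3,4}; analysis 2 is
the cumulative (ordinal) contrast 1 < 3 < 4 with category 2 dropped. A
supplement mode restricts interval exams to diagnoses within 12 months.

AUCs use the Mann–Whitney pair-count estimator with 0.5 tie credit
(identical to the trapezoidal area under the empirical ROC). Confidence
intervals are percentile bootstrap over whole-case resampling
(B = 1000, α = 0.05, degenerate resamples redrawn and counted). The
paired model-vs-VBD comparison uses leave-one-case-out jackknife
pseudo-values of each AUC; the variance of the per-case pseudo-value
differences carries the covariance of the two predictors on shared
cases (a single-reader multi-case design collapsed to one reader).
Comparison with a published AUC uses an independent two-sample Z-test
with SEs recovered from printed 95% CIs as width/3.92. Proportions are
compared with Pearson's chi-square without continuity correction
(Fisher's exact on zero margins).

## Problem sizes and numerical choices

The repeated-cohort experiments (directional replication of
"model beats VBD", 20 seeds) run at n = 200 exams/group on the small
raster preset; the group marginals are scale-free, so the expected
effect direction is unchanged while the full-resolution cohort is left
to explicit configuration. Bisection tolerances: phantom VBD calibration
to ~1e−12·T; logistic convergence 1e−10 relative; d′ floor
ε = 1e−8·max(NPS); GLCM quantization falls back to level 0 on constant
rasters; Haralick correlation returns 0 when a marginal variance
vanishes; degenerate bootstrap resamples are redrawn.

## Known limitations

Stepwise AIC admits a pure-noise candidate whenever its
likelihood-ratio improvement exceeds 2, i.e. with probability ≈ 0.157
under the null at any sample size; users wanting stricter parsimony
should use the fixed three-feature fit or a BIC-style penalty. The
jackknife/bootstrap machinery assumes independent examinations (one
exam per woman). The VBD estimator shares its forward model with the
renderer, so density-estimation accuracy on synthetic data is by
construction better than any real-world density algorithm; it is a
stand-in that preserves monotonicity and calibration logic, not a
replication of commercial software.
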