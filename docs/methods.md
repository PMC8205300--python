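# Methods

## Scope and model

The package reproduces, end to end, the procedure for optimizing low-field
MRI acquisition for non-destructive prediction of loin quality traits:
texture features extracted from a rectangular region of interest feed a
linear predictive model per trait, the model's cross-validated correlation
coefficient is the response of a designed experiment over the acquisition
parameters (echo time TE, repetition time TR), and a quadratic response
surface fitted to that design locates the best acquisition settings.

## Synthetic phantoms and cohorts

Real low-field images of loin are not redistributable, so every stage is
exercised on synthetic phantoms: an elliptical tissue region (default
204×256 image, emulating a 256×204 spin-echo matrix) whose interior is
`base_gray` plus a spatially correlated Gaussian field plus bright streaks
plus i.i.d. noise, clipped to 8-bit range; the background is exactly 0,
which keeps segmentation trivial and the ROI stage deterministic.

- The correlated field is white noise smoothed with a Gaussian kernel
  (sigma = `texture_corr_length`, default 3 px) and rescaled so its
  in-ellipse standard deviation equals `texture_sd` exactly. This is the
  simplest stationary correlated field; it does not emulate MR physics
  (no T1/T2 relaxation, no coil shading, no Rician noise).
- Fat-like streaks are straight line segments between random in-ellipse
  points set to `streak_gray`; real intramuscular fat is curvilinear and
  partial-volume blurred.
- Cohort traits are *linear functions of the latent generator parameters*
  (`texture_sd`, `n_streaks`, `base_gray`) plus Gaussian noise — not of
  extracted features — so the texture extractors can be validated against
  an independent ground truth and regression/selection can be tested as a
  parameter-recovery problem. Default couplings center the traits on
  typical fresh (a_W 0.97, pH 5.54, moisture 72 %, lipids 6 %, L* 48.4)
  and dry-cured (a_W 0.88, pH 5.85, moisture 42 %, lipids 6.1 %, L* 37.4,
  salt 2.9 %) values; the fresh/dry-cured distinction is only a shift of
  trait means, with salt defined for dry-cured samples only. Out-of-range
  trait values are clipped and counted.
- Triplicate measurements are Gaussian draws around each trait value,
  re-centred so the replicate mean equals the trait exactly; the sample
  standard deviation is unaffected by re-centring, so the mean per-sample
  replicate SD (TSTD) estimates `c4(3)·sigma ≈ 0.886·sigma` of the
  within-sample SD, as for any SD of three normal draws.

Passing tests on these phantoms demonstrate the correctness of the
algorithms and the recoverability of linear structure; they do not
demonstrate predictive performance on real loin images, whose texture–trait
relationship is unknown here.

All generators take explicit integer seeds and are bit-reproducible; there
is no global random state.

## ROI selection

The tissue contour is obtained by thresholding (Otsu by default; the
original acquisition chain presupposes a closed contour without stating how
it was derived), keeping the largest connected component and filling holes.
"Largest inscribed rectangle" is interpreted as *axis-aligned* — the
downstream row/column tiling requires axis alignment — and found exactly in
O(H·W) by the histogram-stack method; ties in area resolve to the smallest
(row0, col0) for determinism. Tiling into 32×32 mini-ROIs anchors at the
rectangle's top-left corner and discards remainder pixels (the fractal
estimator's fixed tile contract). Coordinates are 0-based and half-open.

## GLCM features

Gray levels (0–255) are linearly binned into G = 32 levels by default; the
level count is configurable and 32 stabilizes counts on small regions. One
co-occurrence matrix accumulates ordered pairs at distance 1 along 0°, 45°,
90°, 135° and their opposites (symmetric accumulation), computed with
scikit-image and summed over directions. Feature formulas are the standard
Haralick/Conners definitions with entropy in bits; contrast and inertia are
both Σ(i−j)²p — the source feature list names both without formulas, so
they are kept as documented aliases in distinct schema columns. Likewise
correlation and Haralick's correlation are algebraically identical for any
normalized matrix; both are reported. For a constant region (zero marginal
variance) the correlation statistics are returned as their limit 1 with a
degeneracy flag. The GLCM is computed on the whole ROI rectangle; tiling is
used only by the fractal path.

## OPFTA features

The one-point ("one-scale") fractal value of a 32×32 tile is differential
box counting at the single box size s = 8: the tile splits into (32/8)² =
16 boxes, the gray column height is h = ceil(256·s/32) = 64 units, each box
contributes `ceil((max+1)/h) − ceil((min+1)/h) + 1`, and
`D = log(ΣN)/log(32/s)`. A flat tile scores exactly 2. Under this formula
the value is invariant to gray shifts by multiples of h (and to *any* shift
only when boxes stay within layer boundaries); it increases with within-box
range. Per-tile values are assembled in tile position, the observed value
range is linearly binned into Q = 8 levels (small matrices need few
levels; a constant matrix maps to level 0), and the seven second-order
statistics are computed from the same symmetric distance-1 co-occurrence
construction as the gray-level path. Efficiency (EFI) has no published
closed form; it is defined here as entropy normalized by log₂ of the number
of occupied levels, 1 when a single level is occupied, and saturated at 1
(the joint-pair entropy can exceed log₂(levels) for strongly alternating
matrices, and a bounded [0, 1] statistic is retained by saturation).

## Regression, selection and validation

The model is least squares with penalty `ridge·Σβ_j²` (default 1e-4) on
z-scored predictors; the intercept is unpenalized, standardization uses the
training split only, and coefficients are reported on the original scale.
M5-style elimination drops the attribute with the smallest |standardized
coefficient| and accepts the reduction while the Akaike-corrected training
error `MAE·(n+p)/(n−p)` does not worsen (p = retained predictors); the
accepted steps form a monotone audit trail. Elimination of a chance-
correlated pure-noise attribute is probabilistic — a noise column whose
sample correlation with the residual exceeds ≈ sqrt(2/n) survives the
correction factor's slack — which is why the deterministic unit test
orthogonalizes its noise columns and the cohort-level test fixes the seed.
Cross validation uses a seeded uniform shuffle into 10 folds (no
stratification; regression targets), repeats selection per training split,
and pools out-of-fold predictions for the metrics. The headline metric
`r = sqrt(Σ(f−ȳ)²/Σ(y−ȳ)²)` is reported as the non-negative root exactly as
defined (it equals |Pearson r| for in-sample least-squares fits); the
signed Pearson correlation is kept as a separate diagnostic. RMSEP and WAPE
are reported on the 0–100 scale. A two-group one-way ANOVA helper
(scipy `f_oneway`, F = t²) is included as a convenience for comparing
feature populations.

## Response-surface methodology

The design is a two-factor face-centered CCD (alpha = 1): center
(22, 770) ms, deltas (4, 140) ms, 4 factorial + 4 axial + 5 center runs.
The quadratic model is fitted by OLS on the coded regressors
(1, A, B, AB, A², B²), df_residual = 13 − 6 = 7. ANOVA uses partial
(Type III) sums of squares — on this design the linear and interaction
terms are orthogonal contrasts, which cross-validates the partial-SS path —
with pure error pooled over replicated design points (df 4 from the five
center runs), lack of fit = residual − pure error (df 3), F tests against
the residual mean square (lack of fit against pure error), p-values from
the F survival function, and significance remarks at 0.05. Diagnostics:
adjusted R² = 1 − (SS_res/7)/(SS_tot/12); predicted R² = 1 − PRESS/SS_tot
with leave-one-out PRESS from the hat matrix; adequate precision =
(max ŷ − min ŷ)/sqrt(p·MS_res/n) with p = 6 terms, n = 13. Both the
PRESS-based predicted R² and the plain R² are always reported because
published CCD diagnostics are not consistently labeled across software.

Multi-response optimization evaluates each fitted surface on a grid over
the rectangular design region (0.1 ms × 1 ms resolution by default) and
maximizes the unweighted mean of the predicted responses; a weighted
aggregate is available, but no desirability configuration is assumed.
Ties resolve to the smallest (TE, TR). On the packaged fresh-loin design
the optimum lands at the low-TR boundary (TR = 630 ms) with mean predicted
r ≈ 0.98.

## Problem sizes and numerical choices

Tests run on reduced phantoms (≈ 80×100 to 140×170) and cohorts of
10–500 samples; the packaged design analysis is exact and instantaneous.
Exhaustive oracles (O(n⁴) rectangle search, brute-force pair enumeration)
are restricted to ≤ 20×20 inputs. Feature formula oracles assert agreement
to 1e-12; design-matrix identities to 1e-10. Degenerate inputs (constant
regions, empty masks, single-pixel regions, rank-deficient unpenalized
fits, designs without replicates, leverage-1 runs) raise typed errors
rather than returning NaNs.

## Known limitations

- Phantom realism is a stand-in; no claim is made that passing tests imply
  field performance on loin MRI.
- The exact published fractal estimator and the efficiency statistic are
  defined in earlier sources not reproduced here; the single-scale
  differential box-counting reading and normalized entropy are documented
  package choices.
- The multi-response optimum depends on the aggregation rule; only the
  unweighted mean is implemented as default and the low-TR location, not an
  exact (TE, TR) pair, is the stable conclusion.
- Contrast/inertia (and correlation/Haralick-correlation) are aliases by
  construction, retained as separate columns for schema fidelity.
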