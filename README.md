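# loinmri

Texture-based prediction of pork-loin quality traits from low-field MRI,
and response-surface optimization of the acquisition parameters.

Low-field (0.15–0.5 T) MRI scanners are cheap enough for routine food
inspection but produce noisy images, so both the acquisition settings and
the image-analysis chain must be tuned before the images can predict
physicochemical traits (water activity a\_W, pH, moisture %, lipid %,
instrumental color L\*, salt %) non-destructively. `loinmri` implements that
full optimization pipeline as a tested Python library:

- **Synthetic phantoms** — elliptical tissue cross-sections on a dark
  background with spatially correlated gray texture and bright fat-like
  streaks, plus cohorts whose traits are linear functions of the latent
  texture parameters (ground truth for validating every downstream stage),
  and triplicate laboratory-style measurements.
- **ROI selection** — Otsu/fixed thresholding, the largest axis-aligned
  rectangle inscribed in the tissue contour (O(H·W) histogram-stack
  algorithm), and tiling into 32×32 mini-ROIs.
- **Texture features** — a single gray-level co-occurrence matrix (GLCM)
  accumulated over the four directions at distance 1 with ten statistics
  (energy, entropy, correlation, Haralick's correlation, inverse difference
  moment, inertia, cluster shade/prominence, contrast, dissimilarity), and
  the one-point fractal texture algorithm (OPFTA): a differential
  box-counting value per mini-ROI at the single box size 8,
  `D = log(Σ_boxes n_box) / log(32/8)`, assembled into a matrix from which
  seven second-order statistics are taken.
- **Predictive modeling** — multiple linear regression with a ridge value
  of 1×10⁻⁴ on z-scored predictors, M5-style backward elimination of the
  smallest standardized coefficient under the Akaike-corrected error
  `MAE·(n+p)/(n−p)`, 10-fold cross validation, and the five validation
  metrics

  ```
  r     = sqrt( Σ(f_i − ȳ)² / Σ(y_i − ȳ)² )
  RMSEP = 100·sqrt( (1/n) Σ(f_i − y_i)² )
  MAE   = (1/n) Σ|f_i − y_i|
  TSTD  = (1/N) Σ_i sqrt( (1/(M−1)) Σ_j (d_ij − d̄_i)² )
  WAPE  = 100·Σ|f_i − y_i| / Σf_i
  ```

- **Response-surface optimization** — a two-factor face-centered central
  composite design (α = 1, 13 runs: 4 factorial + 4 axial + 5 center
  replicates) over echo time TE ∈ [18, 26] ms and repetition time
  TR ∈ [630, 910] ms, quadratic fits
  `y = b₀ + b₁A + b₂B + b₁₂AB + b₁₁A² + b₂₂B²` on the coded factors, the
  full ANOVA (Type III partial SS, lack of fit vs pure error from the
  center replicates), fit diagnostics (R², adjusted R², PRESS-based
  predicted R², adequate precision) and in-range grid-search optimization
  of the aggregated predicted surfaces. The published 13-run fresh-loin
  design with its five observed responses ships as a packaged fixture.

The estimators (`M5RidgeRegressor`, `GLCMFeaturizer`, `OPFTAFeaturizer`,
`ResponseSurface`) follow scikit-learn conventions and compose with its
pipelines and model selection.

## Worked example

```python
from loinmri import (PhantomSpec, generate_phantom, extract_roi,
                     tile_mini_rois, build_fractal_matrix, opfta_features,
                     load_fresh_loin_ccd, fit_quadratic, optimize_in_range)

img = generate_phantom(PhantomSpec(seed=1))
rect, region = extract_roi(img)
print("ROI:", rect)

grid = tile_mini_rois(img, rect, tile=32)
features = opfta_features(build_fractal_matrix(grid, box=8))
print(f"OPFTA: UNI={features.UNI:.3f} ENT={features.ENT:.3f} "
      f"HOM={features.HOM:.3f} EFI={features.EFI:.3f}")

design, responses = load_fresh_loin_ccd()
fit = fit_quadratic(design, responses["moisture"])
print(fit.anova_.round(4)[["SS", "df", "F", "p", "remark"]])
d = fit.diagnostics_
print(f"adjusted R2 = {d.adj_r_squared:.3f}, "
      f"adequate precision = {d.adequate_precision:.3f}")

fits = {c: fit_quadratic(design, responses[c]) for c in responses.columns}
best = optimize_in_range(fits, design, aggregation="mean")
print(f"optimum: TE = {best.te:.1f} ms, TR = {best.tr:.0f} ms, "
      f"mean predicted r = {best.aggregate:.3f}")
```

prints

```
ROI: Rectangle(row0=53, col0=57, height=99, width=143)
OPFTA: UNI=0.052 ENT=4.409 HOM=0.458 EFI=1.000
                 SS  df        F       p remark
term
model        0.0068   5  11.8171  0.0026      S
TE           0.0005   1   3.8933  0.0891     NS
TR           0.0008   1   7.2582  0.0309      S
TE x TR      0.0023   1  19.4917  0.0031      S
TE^2         0.0029   1  24.9621  0.0016      S
TR^2         0.0000   1   0.0318  0.8634     NS
lack of fit  0.0007   3   7.5806  0.0398      S
pure error   0.0001   4      NaN     NaN
residual     0.0008   7      NaN     NaN
total        0.0076  12      NaN     NaN
adjusted R2 = 0.818, adequate precision = 12.098
optimum: TE = 23.3 ms, TR = 630 ms, mean predicted r = 0.981
```

The moisture surface is significant (model F ≈ 11.8, p ≈ 0.003) with a
strong TE×TR interaction and TE² curvature; aggregating the five fitted
surfaces places the optimum at the low end of the repetition-time range
with predicted correlation coefficients around 0.98.

A thin CLI mirrors the library (`loinmri synth|roi|features|model|rsm`),
e.g. `loinmri rsm fit --response moisture` or
`loinmri synth cohort --n 50 --out cohort/`.

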