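# Methods

This note describes, in the package's own terms, what each stage of the
pipeline computes, why it is set up the way it is, and where its limits are.

## Thermal time

Growing degree days for one day are

```
gdd = max(0, (min(tmax, 33.9) + tmin) / 2 - 15.6)
```

with temperatures in °C. The cap at 33.9 °C reflects the plateau of cotton
development at high temperature; the base of 15.6 °C is the conventional
cotton threshold. Accumulated GDD from planting to a date is the inclusive
sum of the daily values over that span; any missing day in the span is an
error, not an interpolation. Cumulative GDD indexes crop stage and enters the
regression models as a covariate alongside the vegetation index.

## Canopy segmentation

Each plot raster carries five reflectance bands (blue, green, red, red edge,
NIR). The classification index is the product of

* NDVI = (NIR − R) / (NIR + R), which separates vegetation from soil in the
  red/NIR plane, and
* excess greenness ExG = 2G − R − B, which separates green canopy from
  bright, spectrally flat residue,

and a pixel is canopy when NDVI × ExG > 0.02 (strict). Per-plot reflectance
is the mean over canopy pixels whose centers (column + 0.5, row + 0.5) fall
strictly inside the plot's ROI polygon. If a ROI contains canopy pixels only
outside the mask, an optional fallback averages all in-ROI pixels instead
(off by default; enabling it is logged). Restricting to canopy pixels makes
the index means largely insensitive to the soil background, which is what
allows a single index–response model to transfer across dates as cover
changes.

## Vegetation indices

Twenty indices are computed from the segmented band means, plus the five raw
band means, for 25 candidate predictors per observation. Indices with zero
denominators at a given observation evaluate to NaN and that observation is
dropped for that candidate only. Two indices are kept in two published
algebraic forms (`EVI`/`EVI_classic`, `RGBVI`/`RGBVI_classic`) because both
forms circulate in the literature; the sweep treats them as separate
candidates.

## Radiation budget

Incident PAR is taken as 0.45 × daily shortwave solar radiation. The
intercepted fraction measured in the field is

```
ipar_f = (par_above - par_below) / par_above
```

clamped to [1e−6, 1 − 1e−6] so it stays inside the open support of the beta
distribution. Cumulative intercepted PAR multiplies the per-date fraction by
the cumulative incident PAR between samplings. RUE at sampling n is the
difference quotient

```
rue_n = (biomass_n - biomass_1) / (cum_ipar_n - cum_ipar_1)
```

(undefined at the first sampling), i.e. an average conversion efficiency over
the season so far rather than an instantaneous one. Measured harvest index
is lint yield (kg ha⁻¹) over 10 × the season-maximum biomass (g m⁻²); the
factor 10 converts g m⁻² to kg ha⁻¹.

## Regression models

Each response is modeled with the GLM family matching its support:

| response | family | link |
|---|---|---|
| IPAR_f (fraction in (0,1)) | beta | logit |
| biomass (positive) | gamma | log |
| RUE (real) | gaussian | identity |

The linear predictor is always

```
eta = b0 + b1·VI + b2·GDD + b3·VI·GDD
```

For IPAR_f and biomass, VI and GDD are the per-date values. For RUE, the
model uses the intercept plus the vegetation index averaged over the period
from the first sampling to the current one, matching the period-average
nature of the RUE response.

Fitting details:

* **Beta**: maximum likelihood via `statsmodels` `BetaModel`. The design is
  standardized internally (centered/scaled columns) for conditioning; fitted
  coefficients are mapped back exactly to the raw scale through the linear
  back-transform, so reported coefficients refer to the unstandardized
  predictors.
* **Gamma**: the mean coefficients come from iteratively reweighted least
  squares with a log link; the shape parameter is then profiled out by
  maximum likelihood, solving the profile score equation with a bracketed
  root finder. This gives a true ML shape rather than the moment or Pearson
  estimate.
* **Gaussian**: ordinary least squares; the dispersion is σ² = RSS / n (the
  ML estimate, consistent with likelihood-based model scores).

Responses outside the family's support (IPAR_f not strictly in (0,1),
non-positive biomass) raise errors rather than being silently clamped at this
stage.

### Scoring and ranking

* Generalized R² is Nagelkerke's correction of the Cox–Snell statistic.
  The Nagelkerke denominator `1 − exp(2·ll_null / n)` is only used when it
  lies in (0, 1]; for continuous likelihoods the null log-likelihood can be
  positive and push the denominator out of range, in which case the
  uncorrected Cox–Snell value is reported.
* AICc and BIC count `k = (number of mean coefficients) + 1` parameters, the
  +1 being the dispersion/precision parameter of every family (including the
  gaussian σ²).
* Outliers are removed before splitting: observations with a response outside
  1.5 × IQR of the pooled response distribution are dropped and counted.
* The split is stratified by sampling date: within each date,
  `round(0.6 · n_date)` observations go to training (seeded, deterministic);
  a date with a single observation goes to training. Stratifying by date
  prevents the validation set from being dominated by one growth stage.
* Cross-validated R² and RMSE are computed on the held-out 40%. Candidates
  are ranked by ascending RMSEcv, ties broken by descending R²cv, then
  ascending AICc; candidates whose fit failed or whose scores are NaN rank
  last.

### Mechanistic RUE

Beyond regressing RUE directly, the pipeline reconstructs it from the other
fitted models: predicted IPAR_f drives cumulative intercepted PAR, and the
numerator is either modeled biomass or the measured biomass. The
measured-biomass variant isolates the quality of the IPAR_f model, because
biomass measurement noise appears identically in the reconstruction and in
any measured reference quotient and cancels.

## Cotton fiber index and lint yield

Open bolls are bright, near-achromatic blobs. The enhancement chain is fixed:

1. grayscale = mean of R, G, B;
2. edge-preserving bilateral smoothing (σ_spatial = 3, σ_range = 30 intensity
   units);
3. additive 5×5 Laplacian sharpening (all −1, center +24), clipped to
   [0, 255];
4. 3×3 arithmetic-mean filter;

all with reflect padding, so a constant image is a fixed point of the chain.
CFI is the fraction of ROI pixels strictly above intensity 150, and lint
yield is regressed linearly on CFI over all plots (no split; harvest plot
counts are small).

**Known limitation — small-blob erosion.** The additive Laplacian drives a
ring just outside each bright blob to 0 (clipping), and the subsequent 3×3
mean then pulls boundary blob pixels below threshold: a boundary pixel with
five bright and four zeroed neighbors averages to about (5·255)/9 ≈ 142 <
150. The chain therefore removes roughly half of the one-pixel perimeter
ring of each blob. For blobs of radius 7+ pixels this is a few percent of
area; for radius 3–4 (typical rendered boll size) it is a 12–18% per-blob
area loss, and about 20% at image level. The CFI remains a nearly linear,
strongly correlated proxy for the true white-area fraction — the slope of
the yield regression absorbs the attenuation — but CFI should not be read as
an unbiased area estimate when bolls are only a few pixels across.

## Harvest index

Predicted HI is predicted lint yield over 10 × the maximum of the predicted
per-date biomass series. Predicted vs measured HI is compared per season and
pooled (squared Pearson correlation and RMSE); groups with fewer than 3
plots are skipped. HI is a ratio of two model outputs, so its precision is
limited by the weaker of the two — in the synthetic study, the yield model.

## Synthetic study generator

`generate_study(SimConfig(seed=...))` emits a complete, self-consistent
trial: 5 nitrogen rates × 5 blocks = 25 plots, observed on 5 sampling dates.
All randomness descends from a single `SeedSequence(seed)` split into
independent substreams (weather, canopy, observation noise, harvest
imagery), so studies are reproducible bit-for-bit and substreams do not
interact.

* **Weather**: seasonal sinusoid plus noise for tmax/tmin/solar, with
  tmin ≤ tmax and solar floored at 2 MJ m⁻² enforced.
* **Canopy cover** follows a logistic curve in cumulative GDD whose asymptote
  increases with nitrogen rate; plot rasters are rendered as two-endmember
  scenes (nitrogen-dependent canopy endmember over a fixed soil endmember)
  with painted cover matching the logistic cover, plus optional per-band
  noise.
* **IPAR_f** is drawn from a beta distribution whose mean follows a logit
  model in true NDVI and GDD with coefficients (−3, 2.5, 0.002, 0.0005) and
  precision 60; field PAR readings are emitted as `par_above = 2000`,
  `par_below = (1 − ipar_f) · par_above`, so the fraction round-trips
  exactly.
* **Biomass** is gamma-distributed around a log-linear mean in the same
  covariates with coefficients (0.8, 2.4, 0.0011, 0.0009) and shape 25.
  These values were chosen so that biomass spans roughly 30–600 g m⁻² over
  the season with a realistic ~20% coefficient of variation, and so that the
  implied RUE stays in the agronomically plausible 1.5–3.5 g MJ⁻¹ band.
* **Yield and harvest imagery**: true HI is drawn per plot (clipped to a
  plausible band), lint yield = HI × 10 × max true biomass, and the harvest
  RGB image paints `Poisson(0.05 × yield)` bright disks (radius 2–4 px,
  intensity ~N(235, 8)) over a soil/defoliated-vegetation background
  (~N(100, 10) and ~N(130, 10)). The painted-disk mask is recorded, so the
  true white-area fraction (`true_cfi`) is known exactly. The default
  harvest image is 240×80 px, large enough that disk overlap is negligible
  at realistic yields.
* A `noiseless()` variant of the config turns all noise off (and sends the
  beta/gamma dispersions to effectively infinite precision), which is what
  the exactness tests run against.

The generator records every latent quantity it uses (true NDVI, IPAR_f,
biomass, cumulative intercepted PAR, HI, yield, true CFI), so each pipeline
stage can be validated against ground truth rather than only against other
pipeline outputs.

### What the generator does and does not emulate

It emulates the statistical structure the pipeline assumes: beta/gamma/
gaussian noise with the declared links, two-endmember plot scenes, and
boll-like harvest imagery. It does **not** emulate illumination or
atmospheric variation between flights, canopy shadows or row geometry,
georeferencing error, mixed pixels at canopy edges, defoliation gradients,
or multi-season weather regimes. Conclusions about the pipeline's ranking
behavior on synthetic data therefore say "the machinery is correct", not
"these indices will win in the field".

## Other limitations

* A statistical bound, not a code defect: with n = 250, beta precision 60 and
  an interaction coefficient of 5×10⁻⁴, the Fisher information of even a
  D-optimal design over the plausible covariate region caps interaction
  recovery at about 10–12% median relative error, and the ML estimator sits
  at that bound. Small interaction effects in this regime need larger n or
  wider covariate spread, not a different estimator.
* The CFI → yield regression is fit without a holdout; with 25 plots its R²
  is an in-sample quantity and will be optimistic for new plots.
* Beta and gamma likelihood-based scores (AICc/BIC, generalized R²) are
  comparable within a response but not across responses or families.
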