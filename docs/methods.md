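# Methods

This note documents the models, the synthetic study design, the numerical
choices, and what the test suite does and does not demonstrate.

## The modeling problem

A monitoring network observes hourly pollutant concentrations at n ≈ 35
fixed sites. Annual-mean concentrations are regressed on p geographic
covariates (land-use regression, LUR) and the fitted model predicts
concentrations at the centers of a 1-km grid covering the urban area.
Because LUR residuals at monitoring sites are typically spatially
correlated, each LUR family can be hybridized with ordinary kriging (OK)
of its residuals: the hybrid prediction at location s is

    ŷ(s) = LUR(x(s)) + OK(residuals)(s).

Model skill is estimated by leave-one-site-out cross-validation (LOOCV)
and the downstream consequence of model choice is measured as the share of
the population assigned to different exposure quartiles by two models.

## Temporal averaging

Hourly → daily → ISO-weekly → annual → long-term mean (LTM), with
completeness screening at every level:

| level  | rule                                                      |
|--------|-----------------------------------------------------------|
| daily  | ≥ 12 of 24 hours present (50%)                             |
| weekly | ≥ 3 of 7 daily values available                            |
| annual | ≥ ceil(0.25 × weeks in the ISO year) weekly values (13/52, 14/53) |
| LTM    | mean of the available annual values; ≥ 1 required          |

Values failing a rule are *missing*, never imputed. Weeks are ISO-8601
(a week belongs to the ISO year of its Thursday) because the week
convention is otherwise ambiguous; days are delimited in local standard
time with a configurable UTC offset (default +8). Sites missing a year's
annual value are simply dropped from that year's cross-validation. An
optional per-season minimum is deliberately not enforced by default: the
25% annual rule alone is the reproducible reading of the screening
criteria.

## Model families

* **PLS** (scikit-learn `PLSRegression`) on centered-and-scaled
  covariates, 3 scores by default. The first-score sign is fixed so that
  it correlates non-negatively with the response, which stabilizes the
  score–covariate correlation diagnostic (the sign is otherwise
  arbitrary). Zero-variance columns are dropped with a warning.
* **RF** (scikit-learn `RandomForestRegressor`): mtry = 50 features per
  split, 500 trees, minimum leaf size 5. mtry is clamped to p with a
  warning when p < 50 so the reference setting works at any scale.
  Importance is "IncMSE-style": for each tree, the increase in out-of-bag
  MSE after permuting one covariate among that tree's OOB samples,
  averaged over trees. OOB indices are reconstructed by replaying the
  bootstrap draw from each tree's seed; the reconstruction is verified
  against `oob_prediction_` in the tests. The exact normalization used by
  other implementations varies, so ranks rather than raw values are the
  meaningful output.
* **SLR** — supervised forward stepwise regression. Round 0 picks the
  single predictor with the highest R² whose coefficient matches its
  expected sign ('+', '−', or unconstrained '0'); each later round adds
  the predictor with the largest R² gain among candidates that keep
  *every* selected coefficient sign-plausible (strict re-checking each
  round is the reproducible choice); selection stops when the best gain
  falls below 0.1. The 0.1 default is unusually large — ESCAPE-style
  procedures commonly use 0.01 — and is exposed as `r2_gain_threshold`.
  Collinearity is then removed iteratively: while any variance inflation
  factor exceeds 3, drop the worst variable and refit (a single pass can
  leave violating combinations behind).

All families share a column-name-based predict contract: storage order of
covariate columns never matters.

## Variograms and ordinary kriging

The empirical semivariogram is the Matheron estimator
γ̂(h) = Σ(zᵢ−zⱼ)²/(2N(h)), binned into 12 equal-width lag bins up to half
the maximum inter-site distance (both configurable). Parametric models
(exponential by default; spherical and gaussian selectable — the family is
a free design choice, and exponential is the common default for
air-pollution residuals) are fit by weighted least squares with weights
N(h)/h², nonnegativity box constraints, and a small multistart from
method-of-moments initial values. A flat empirical variogram degenerates
to a pure-nugget model with a warning.

OK solves the standard system with an unbiasedness constraint; the
semivariance of a point with itself is 0, so the nugget acts between
distinct locations and a zero-nugget model interpolates exactly.
Degenerate inputs fail loudly: duplicate support coordinates with zero
nugget name the offending rows. Kriging variances are clipped at 0 within
numerical noise. Hybrid concentration predictions are floored at 0 (counts
logged) because concentrations are physical quantities.

In LOOCV the variogram and the kriging support are refit inside each fold;
the held-out site contributes nothing to its own prediction — not via the
LUR, not via the residual field, not via PLS scaling constants. Any other
choice leaks information and inflates skill.

## Synthetic study design

The generator produces the conditions the analysis assumes, so every
stage is testable without proprietary monitoring or GIS data:

* **Network**: 35 sites — 1 background, 7 traffic, 14 urban, 13 suburban.
  Urban sites cluster within ~15 km of the center, traffic sites sit on
  the central road web, suburban sites ring the periphery, and the single
  background site lies farther out than every other site.
* **Covariates**: smooth random fields (random-Fourier-feature
  approximations of Gaussian random fields, length scale 20 km, ≈ unit
  variance) named after the variable groups real studies extract
  (population, roads, POI, NDVI, land use, topography), plus two scaled
  coordinate variables. They are abstract fields with the same statistical
  role, not GIS extractions. A stated subset carries nonzero true
  coefficients; each variable's expected sign equals the sign of its beta.
* **Concentrations**: hourly value = 40 + Xβ + S + seasonal + ε, floored
  at 0, with S a zero-mean Gaussian field with exponential covariance
  (sill 9 (µg/m³)², range 15 km, nugget 0.25) simulated by Cholesky
  factorization at site locations, a 1-year sinusoid of amplitude
  10 µg/m³ standing in for seasonality, and iid hourly noise of SD
  8 µg/m³. Missingness (default 15%) is half random hours, half
  contiguous week/month outages, so the completeness rules see both
  passing and failing cases.
* **Population grid**: 3301 1-km cells (a 58×57 lattice trimmed of its 5
  outermost corners), center-peaked density (12-km exponential decay with
  lognormal texture) clipped to [211, 32097] persons/km² and iteratively
  rescaled to a 15.94-million total.

Coordinates are an abstract planar projection in meters; no geodesy.
What the generator does **not** emulate: meteorology and chemistry
(seasonality is a fixed sinusoid), instrument drift or calibration error,
covariate measurement error, anisotropy, and non-stationary residual
structure. Passing tests therefore demonstrate the correctness of the
algorithms and the qualitative behavior of the workflow (e.g. that kriging
residuals helps when residuals are spatial), not the performance numbers
to be expected on any real network.

## Exposure comparison

Quartile cutpoints are **person-level**: each person carries their cell's
exposure and the 25/50/75% quantiles are taken over the population (a
grid-count mode exists for sensitivity analyses). A cutpoint is the
smallest exposure whose cumulative population share reaches the target
quantile; ties go to the lower quartile. This matches an explicit
one-row-per-person expansion exactly for integer populations, which the
tests exploit as a brute-force oracle. Cutpoints are computed per model,
not pooled. The misclassification report is a 4×4 population-share matrix
with totals split into over-/under-estimation and a non-adjacent (≥2
quartiles apart) share. The cross-model coefficient of variation uses the
sample (n−1) standard deviation across models — three models are a
sample — and is undefined (flagged) at zero-mean cells.

## Problem sizes and defaults

The demo configuration (`configs/demo.yaml`) uses 35 sites, two simulated
years plus their LTM, 12 covariates (4 carrying signal) and the 3301-cell
grid — sizes chosen so a full pipeline run finishes in about a minute on a
single CPU while still exercising every stage at the reference network
scale. Grid-scale covariates are evaluated directly from the closed-form
fields, which sidesteps the cost of factorizing a 3301×3301 covariance
(the Cholesky route is used where it matters, at site scale).

## Known limitations

* PLS with k scores equals OLS only when k reaches the covariate rank;
  with the default 3 scores on many covariates it is a genuinely different
  (biased, lower-variance) estimator — intended, but worth remembering
  when comparing coefficients.
* The SLR sign rule can reject every starting variable when the expected
  signs contradict the data; this raises with a diagnostic rather than
  silently relaxing the constraint.
* OK assumes second-order stationarity and isotropy of the residual field;
  no universal kriging, co-kriging or anisotropy.
* With fewer than ~10 sites the variogram cannot be estimated; the hybrid
  then falls back to a pure-nugget model, making it equivalent to the
  plain LUR plus the mean residual.
* LOOCV metrics on 35 sites are noisy; seed-to-seed variation of a few
  hundredths in R²_mse is normal and the tests assert majorities over
  seeds, not single-run values.
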