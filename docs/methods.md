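# Methods

This note documents the models, the numerical choices, and the synthetic
data that make the pipeline testable; it is the reference for every default
the code ships with.

## Trajectory processing

Tracks are regularized onto a strict hourly grid between each individual's
first and last successful fix; hours missing from the input are failed
fixes. Failed fixes are filled by linear interpolation of latitude and
longitude (independently, in degrees) between the temporally nearest
successful fixes. Interpolation in raw degrees rather than along the great
circle is an approximation, adequate because hourly elephant steps are
short (≪ 0.1° of arc); slots before the first or after the last successful
fix have no flanking pair and stay missing.

Hourly net displacement `S^N(t)` is the haversine distance between fixes
`t` and `t+1` on a sphere of radius 6371 km (haversine rather than the
spherical law of cosines for numerical stability at small separations).
A day is the block of 24 hours starting at local midnight; the local offset
defaults to UTC+3 (East Africa) and is configurable, since the choice of
day boundary is a convention. The displacement of hour `t` belongs to the
day containing `t`'s start, so each complete day owns exactly 24
displacements and its last one reaches into the next day's first fix.
Diel displacement DD is their sum. Days with fewer than 20 of 24 successful
fixes are kept in the record table with `valid = False` and excluded from
modeling; interpolated hours inside a valid day count toward DD.

Model rows are built from triplets of three consecutive valid calendar
days, so each row carries the responses of days `i−1` and `i−2` as lagged
covariates.

## Movement predictability

`S^N` is min–max rescaled to [0, 1] within each day (a constant day maps to
zero), which removes day-to-day variance changes and leaves the shape of
the diel activity profile. The whole multi-day normalized series per
individual is then transformed with a continuous Morlet wavelet
(center frequency ω₀ = 6, the standard choice in movement chronobiology;
Fourier period ≈ 1.033 × scale). The transform is computed in the
frequency domain with zero padding to the next power of two at least twice
the series length and is normalized so the expected power of white noise
equals its variance at every scale — verified in tests against the
closed-form exponential null (95% quantile = −ln 0.05 × variance) and
against a direct time-domain convolution oracle at relative error 1e−6.

Significance thresholds per scale are the pointwise (1−α) quantiles of
wavelet power over 1000 white-noise surrogate series with variance matched
to the analyzed series, pooling time points outside the cone of influence
(e-folding distance √2·scale from either end). Because wavelet power is
exactly linear in input variance, thresholds are computed once at unit
variance for a given length and rescaled — this identity is also what lets
one bootstrap serve all individuals with equal-length series. α = 0.05
pointwise per scale, with no multiplicity correction across the three diel
scales: classification is deliberately a union ("any of 1, 2 or 3
cycles/day"), so the white-noise hourly false-positive rate lies between α
and 1−(1−α)³ ≈ 0.14 (measured ≈ 0.12 end-to-end). An hour is classified
periodic if power at the grid scale nearest 24, 12 or 8 h exceeds its
threshold; MP(day) is the fraction of its 24 hours classified periodic.
A zero-variance (constant) series yields MP = 0. The full scale grid for
spectrum output spans 2–48 h at 12 voices per octave.

Edge days (within the 24-h cone of influence of the series ends) are
retained — their power is biased low by padding, which is conservative —
and daily MP is only reported for complete 24-h days.

The companion Fourier view uses a Tukey (cosine-bell) taper with fraction
0.1 and a modified Daniell smoother with spans (3, 3) (half-weight
endpoints, convolved), normalized by the white-noise expectation so a
random walk's increments sit at power 1.

## Forage categories

Each movement day receives the NDVI value for its date (linear
interpolation in time if the series is coarser than daily; days outside
the series span are dropped with a warning). The LFA/MFA/HFA bins are
three equal-width intervals of the NDVI range observed over *valid*
movement days pooled across individuals, half-open with a closed top
interval so the partition is exhaustive.

## Mixed models

Both models share the fixed-effect structure NDVI + rank + NDVI:rank +
lag1 + lag2 with a Gaussian random intercept per individual and rank coded
against the reference level "low"; no random slopes (random slopes and
intercepts are near-collinear in data of this shape). Everything is plain
maximum likelihood — no REML — so likelihood-ratio tests on nested
fixed-effect structures are valid. NDVI enters unstandardized on its
native ~[0, 1] scale.

* **DD**: linear mixed model (statsmodels MixedLM). If the variance
  estimate hits the boundary the model degenerates to ordinary least
  squares, which is then the exact ML solution and is used directly.
* **MP**: MP·24 is treated as a binomial count of 24 trials with a logit
  link. A proportion that lives mostly at 0 and 1 needs a genuine
  likelihood rather than a Gaussian approximation, and the binomial count
  interpretation is the natural one for "significant hours out of 24".
  The marginal likelihood integrates the random intercept by adaptive
  Gauss–Hermite quadrature: per group, a Newton search finds the
  conditional mode, and 15 nodes re-centered at the mode with the local
  curvature evaluate the integral. The fit matches lme4's `glmer`
  (nAGQ = 15) to ~1e−3 on coefficients in tests. Lag covariates enter as
  raw proportions on the linear predictor, keeping the recursion
  interpretable on the MP scale. Fixed-effect standard errors condition on
  the variance estimate, as lme4 does.

The likelihood-ratio ladder mirrors the analysis design: full model vs an
intercept-plus-random-effect null (df 9), interaction vs main effects only
(df 3), first lag vs no lags (df 1), second lag vs first only (df 1).
Rank-specific NDVI slopes are `β_ndvi` plus the rank's interaction
coefficient, and the high-vs-low contrast is reported as a percent change
rounded to the nearest percent. Predictions are population-level (random
intercept at zero) over an NDVI grid with the lag covariates pinned at
their across-individual median (DD) or mean (MP).

## Descriptive summaries

The mean trend of DD against NDVI is a loess (local linear, tricube
weights) fit with span 0.75; the CV trend computes SD/mean of DD within
the span-nearest NDVI neighbors of each observation and smooths those
pointwise CVs with the same loess. The windowed CV estimator is a
documented choice — any local second-moment estimator would do. Category
tables use the median of DD (robust to occasional migration-scale days)
and the mean of MP, per individual × category; pooled values are
unweighted averages across individuals so long-tracked animals do not
dominate.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with exported ground truth:

* **NDVI**: mean 0.45 plus a saturating seasonal wave
  0.34·tanh(3·cos(2π(doy−121)/182.625)) — two greening peaks per year near
  May 1 and Oct 31 — plus AR(1) noise (lag-1 correlation 0.9, marginal SD
  0.12), clipped to [0.05, 0.9]. The saturating shape makes the ecosystem
  alternate between extended dry and green phases so daily NDVI spreads
  widely (marginal SD ≈ 0.29) across its range, as in strongly bimodal
  semi-arid rainfall systems; this spread is also what identifies the NDVI
  slopes in the recovery experiments.
* **Population**: nine individuals — 3 high, 2 medium, 3 low, 1 variable
  rank — tracked 900 days by default.
* **Daily responses**: DD follows the identity-link recursion with its
  random intercept (SD 0.15), two lags and Gaussian residuals; the default
  residual SD is 0.6 km, chosen for coherence with the reference
  coefficient vector's reported standard errors (back-solving SE ≈ 0.07 on
  the NDVI slope at the reference sample sizes implies a residual SD well
  under 1 km). DD stays on the model's real-valued scale here; the
  physical non-negativity clamp (0.1 km) is applied only when rendering
  tracks, because clamping inside the response model would censor the very
  distribution the recovery experiments refit. MP is realized as
  binomial(24)/24 around the inverse-logit of its predictor (random
  intercept SD 0.2), with realized proportions feeding the lags. Both
  recursions start at their stationary means.
* **Tracks**: each day draws 24 step lengths — from a fixed diurnal
  template mixing 1, 2 and 3 cycles/day harmonics (with lognormal jitter)
  when the day is "periodic" (drawn with probability equal to the day's
  MP), otherwise exchangeable exponential steps — rescaled so their sum
  equals the day's DD. Headings are uniform per hour (no directional
  persistence; the simplest model consistent with step-sum = DD), steps
  convert to degrees around 0.55° N, 37.5° E, and fixes fail independently
  at rate 0.10, which makes ≈ 91.5% of days pass the 20-fix rule
  (binomial closed form).

What the generator does *not* emulate: home-range geometry, directional
persistence, landscape or river attraction, spatially varying NDVI, and
burst-correlated fix failures. Passing tests therefore demonstrate that
the estimators recover the generating structure under the stated noise
model, not that real elephant data would satisfy the same effect sizes.

## Recovery experiments and problem sizes

The headline experiments (`dielmove.recovery`, driven by
`scripts/acceptance.py`) simulate daily responses for 9 × 900 days from the
reference coefficient vectors and refit each model over a ten-seed grid,
reporting seed-averaged low- and high-rank NDVI slopes. The DD experiment
deliberately uses a residual SD of 3 km — five times the coherent default —
as a stress condition; with only three individuals per reference rank the
per-seed slope SE is then ≈ 0.2, so the ten-seed average still carries an
SE near 0.065 and individual runs can land a few hundredths from the
generating values. The MP experiment is far better conditioned (binomial
precision), recovering slopes to within a few hundredths. The full
pipeline round trip (simulate → tracks → DD → MP → refit, ten seeds at the
default configuration) checks sign agreement of the NDVI main effects and
high-rank interactions; measured MP is an attenuated version of the
generating MP (classification is a noisy measurement), so magnitudes are
not expected to round-trip there.

Test-suite problem sizes were chosen to exercise the full-scale spectral
machinery once (21,600 hours, 1000 surrogates — the multi-year scale) while
keeping unit tests on series of a few hundred to a few thousand hours.

## Known limitations

* Interpolated fixes shorten paths slightly, so DD under fix failure is
  biased low by a fraction of a percent per interpolated hour.
* Wavelet time-localization leaks across day boundaries: an isolated noise
  day inside a periodic stretch inherits elevated MP (and vice versa).
  Block designs in the tests quantify this.
* The white-noise null is the analysis's definition of "unpredictable";
  red-noise nulls would be stricter at the 24-h scale and are out of scope.
* With nine individuals the random-intercept variance is weakly estimated;
  it is a nuisance parameter here, retained to avoid pseudo-replication.
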