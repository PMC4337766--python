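# dielmove

Movement-ecology analysis of hourly GPS tracks: how daily travel distance
and the circadian regularity of movement respond to forage availability and
social rank in a free-ranging herbivore population.

## What it computes

Given hourly GPS fixes for a set of individuals, a daily NDVI (Normalized
Difference Vegetation Index) series for the ecosystem, and each
individual's social-rank category, the package derives two daily movement
descriptors and models both against the environment:

* **Diel displacement (DD)** — the sum over one day of the hourly net
  displacements `S^N` (great-circle distance between consecutive fixes on a
  6371-km sphere). A proxy for daily energy expenditure. Failed fixes are
  filled by linear interpolation between the nearest successful fixes, and
  days with fewer than 20 successful fixes are excluded from modeling.

* **Movement predictability (MP)** — the proportion of a day's 24 hours
  whose Morlet wavelet power at 1, 2 or 3 cycles/day significantly exceeds
  a white-noise null (1000 bootstrap surrogates with variance matched to
  the analyzed series, pointwise α = 0.05). `S^N` is min–max normalized
  within each day first, so MP tracks changes in periodicity rather than
  changes in variance. MP measures circadian regularity — *when* an animal
  moves, complementing DD's *how much*.

Each response `n_{i,j}` (day `i`, individual `j`) is then fit with a
random-intercept mixed model

```
g(E[n_{i,j}]) = β₀ + β₁·NDVIᵢ + rankⱼ + NDVIᵢ:rankⱼ + γ₁·n_{i-1,j} + γ₂·n_{i-2,j} + b_j
```

with `g` the identity link for DD (Gaussian residuals) and the logit link
for MP (MP·24 treated as a binomial count of 24 trials), `b_j ~ N(0, σ_b²)`,
and rank coded against the reference level "low". Two lagged-response terms
absorb the strong endogenous autocorrelation at ~2-day scales. Models are
fit by maximum likelihood (the binomial model by adaptive Gauss–Hermite
quadrature), so nested fixed-effect structures are compared by
likelihood-ratio χ² tests. The headline quantity is the NDVI slope per rank
(`β₁` plus the rank's interaction coefficient) and the percent change of
the high-rank slope relative to low rank.

Days are assigned to low / medium / high forage availability (LFA / MFA /
HFA) by three equal-width bins of the NDVI range observed over all valid
movement days; descriptive layers (loess trends of mean and CV of DD
against NDVI, per-individual category tables) mirror the exploratory side
of the analysis.

Because multi-year elephant tracking data are not public, the package
includes a first-class synthetic generator (`dielmove.synthetic`) that
simulates NDVI, daily DD/MP from known coefficient vectors, and hourly
tracks whose step structure reproduces the daily targets — so the whole
pipeline is testable end-to-end with exported ground truth.

## Worked example

```python
from dielmove import io, pipeline
from dielmove.glmm import slope_percent_change
from dielmove.synthetic import SimulationConfig, simulate_dataset

config = SimulationConfig(seed=11, n_days=365)
tracks_df, ndvi, ranks, truth = simulate_dataset(config)
tracks = io.tracks_from_frame(tracks_df)
result = pipeline.run_pipeline(tracks, ndvi, ranks, n_surrogates=200, seed=11)

records = result["records"]
print(f"{int(records['valid'].sum())} valid days of {len(records)}")
for resp in ("dd", "mp"):
    suite = result["models"][resp]
    slopes = suite["slopes"]
    test = suite["tests"]["interaction"]
    print(
        f"{resp}: NDVI slopes by rank "
        + ", ".join(f"{k}={v:.2f}" for k, v in slopes.items())
        + f" | high vs low {slope_percent_change(slopes):+.0f}%"
        + f" | interaction LRT chi2={test.chi2:.1f} df={test.df} p={test.p_value:.3g}"
    )
```

prints

```
3007 valid days of 3284
dd: NDVI slopes by rank low=0.45, medium=0.32, variable=0.49, high=0.46 | high vs low +2% | interaction LRT chi2=2.8 df=3 p=0.418
mp: NDVI slopes by rank low=1.96, medium=1.20, variable=2.02, high=1.60 | high vs low -18% | interaction LRT chi2=87.1 df=3 p=9.24e-19
```

Both NDVI main effects are positive: animals travel farther (DD) and move
more rhythmically (MP) when forage is abundant. With only one simulated
year the rank × NDVI interaction is already unambiguous for MP (the
high-rank slope is damped relative to low rank, here −18%) while for the
much noisier DD response it is not yet separable from zero (p = 0.42) —
recovering the DD interaction reliably takes the multi-year records the
full-scale experiments use.

The same chain is available from the shell:

```
dielmove simulate --seed 11 --n-days 365 --out-dir data/
dielmove compute-dd --tracks data/tracks.csv --ndvi data/ndvi.csv --ranks data/ranks.csv --out data/diel.csv
dielmove compute-mp --tracks data/tracks.csv --diel data/diel.csv --seed 11 --out data/diel.csv
dielmove fit --diel data/diel.csv --response mp --out data/fit_mp.json
dielmove report --diel data/diel.csv --out data/report/
```

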