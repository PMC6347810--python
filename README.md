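# volesoc

Sociality of cyclic vole populations from live-trapping data: spatially
explicit capture-recapture (SECR), a residual home-range-overlap index,
and mixed-model selection — with a synthetic-data generator for testing
and demonstration.

## The problem

Multiannual population cycles of boreal voles have long been linked to
changes in social behaviour: the hypothesis is that adult breeding females
tolerate more home-range overlap (are more social) during the increase
phase of a cycle than during the crash, and that sociality tracks
population growth. Testing this from monthly live trapping on a set of
small grids requires (i) estimating density `D` and the spatial scale of
detection `σ` per grid and season, (ii) turning `σ` into an overlap index
that controls for density, and (iii) comparing phase/season models of
that index and of seasonal growth.

`volesoc` implements this chain for anyone analysing multi-catch
live-trapping data on small-mammal grids, or simulating such studies.

## The model in brief

Detection is half-normal, `g(d) = g0·exp(−d²/2σ²)`, around a latent
activity centre; multi-catch traps compete for animals through hazards
`h_k = −ln(1−g(d_k))`. Densities come from the full (Poisson-N) SECR
likelihood over a 50 m habitat mask. Under constant home-range overlap,
`k = σ√D` is constant, so `ln σ = ln k − ½ ln D`: the inverse-variance
weighted regression of `ln σ̂` on `ln D̂` across grid-seasons has slope
−1/2, and its residuals index sociality (positive = more overlap than
expected at that density). Phase/season effects are compared with linear
mixed models (grid random intercept, ML) ranked by
`AICc = −2logL + 2df + 2df(df+1)/(n−df−1)` and Akaike weights.

See `docs/methods.md` for assumptions, parameter defaults and numerical
details.

## Worked example

Run the packaged demo scenario — 24 grids (16-trap crosses at 15 m
spacing, every fifth grid a 9–12-trap line), monthly sessions June 2013 –
August 2015 with September 2014 untrapped, an increase phase with overlap
parameter k = 0.6 and a crash phase with k = 0.3:

```
$ volesoc run --seed 4 --mask-spacing 10 --out demo_out
216 grid-seasons analysed
overlap regression slope -0.439 (SE 0.053)
best overlap model: Phase + season
best growth model:  Season
outputs in demo_out
```

The slope sits near the constant-overlap value −1/2, flattened slightly
because `k` differs between phases. `demo_out/selection_overlap.csv`
holds the overlap model ranking (rounded):

```
variables       aicc    delta_aicc  weight  df  loglik
Phase + season  -51.40  0.00        0.83    7   33.30
Season          -48.23  3.17        0.17    6   30.56
Phase           -38.77  12.64       0.00    4   23.59
Null            -35.96  15.45       0.00    3   21.10
```

Phase-containing models carry most of the weight: the generator really
did halve `k` at the crash, and crash-phase grid-seasons average residual
overlap −0.20 versus +0.08 in the increase phase in this run (`panel.csv`
has the per-session values; `mnka.csv` tracks the
minimum-number-known-alive trajectory that motivates the phase split).
The same commands accept real trap/capture/covariate CSVs (see
`volesoc fit --help` and the dialect notes in `volesoc/pipeline.py`).

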