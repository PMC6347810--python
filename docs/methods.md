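# Methods

`volesoc` implements an analysis chain for asking whether small-rodent
sociality — measured as home-range overlap among adult females — changes
with the phase of a multiannual population cycle, and whether it tracks
population growth. The chain is: spatially explicit capture-recapture
(SECR) estimation per trapping grid and season, a residual overlap index
built on the `k = σ√D` parameterisation, simple demography (MNKA, seasonal
growth rates), and AICc-based selection among linear mixed models.

## The SECR model

Each animal is assumed to have a latent activity centre `X`; activity
centres form a homogeneous Poisson process with intensity `D` (animals per
hectare). Detection by a trap at distance `d` from the centre follows the
half-normal form

    g(d) = g0 · exp(−d² / (2σ²)),

with `g0` the per-occasion capture probability at distance zero and `σ`
(metres) the spatial scale of detection — an increasing proxy for
home-range size. Traps are multi-catch (several animals can share a trap),
so animals are the competing units: with per-trap hazards
`h_k = −ln(1 − g(d_k))` and `H = Σ h_k`, an animal enters trap `k` on one
occasion with probability `(h_k/H)(1 − e^(−H))` and escapes capture with
probability `e^(−H)`; these sum to one exactly.

The activity-centre integral is approximated by a habitat mask: a square
lattice (default pitch 5 m) clipped to a 50 m buffer around the traps.
The full (Poisson-N) log-likelihood for one session of `S` occasions is

    Σ_i ln( D_m Σ_m P(ω_i | X_m) c ) − D_m a(θ),

where `D_m` is density per m², `c` the mask cell area,
`P(ω_i | X_m)` the probability of animal `i`'s capture history given a
centre at mask point `X_m`, and
`a(θ) = Σ_m (1 − e^(−S·H(X_m))) c` the effective sampling area — the
`−ln n!` constant is dropped. With `g0, σ` fixed, the density that
maximises this likelihood is `n / a(θ)` in closed form, which the tests
exploit as an oracle.

Fitting maximises the likelihood over `(ln D, logit g0, ln σ)`
(Nelder–Mead followed by BFGS polish, gradient tolerance 1e-8). Standard
errors come from the inverse observed information (central finite
differences, step 1e-4 on the transformed scale), delta-method
back-transformed. A fit is `converged` only if the optimiser succeeded
*and* the Hessian is positive definite. Sessions with no captures, or one
animal seen at a single trap (the likelihood then has no interior maximum
in `σ`), are flagged inestimable and propagate as missing rows — never
dropped — mirroring field seasons with too few captures.

Numerical choices worth knowing:

- **Buffer 50 m.** At σ ≈ 15 m this is ≈ 3.3σ; the half-normal tail beyond
  it contributes O(1e-3) to the log-likelihood and < 1% to D-hat. When an
  analysis produces σ-hat approaching the buffer (low densities under
  constant `k`), density estimates are no longer buffer-insensitive; such
  sessions in the demo scenario are typically inestimable anyway.
- **Mask pitch.** 5 m by default; 10 m (≈ 200-point masks for the standard
  cross grid) changes the log-likelihood by ≪ 0.5 and is used in the
  large replicated checks for speed.
- **Start values.** `ln σ₀ = ln(½ · mean recapture displacement + pitch)`,
  `g0₀ = 0.1`, `D₀ = n / mask area` — strictly interior and scale-free.

## The overlap index

If overlap between circular bivariate-normal home ranges is constant
across populations, `σ = k/√D` with `k = σ√D` dimensionless (density
converted to animals per m²), so `ln σ = ln k − ½ ln D`. The package
regresses `ln σ̂` on `ln D̂` across grid-seasons, weighting observations by
`1/SE_σ̂²` (natural scale; a delta-method `(σ/SE_σ)²` variant is available
behind a switch). The regressor is `ln D`, so the constant-overlap slope is
exactly −1/2. Residuals are the sociality index: positive means more
overlap than expected at that density. By default the index uses
adult-female fits only (the territorial part of the population), with the
whole-population variant available for diagnostics. Missing sessions keep
their rows with missing residuals.

Because the regressor is an *estimate*, the slope is mildly attenuated
toward zero (regression dilution): with ~10–40 animals per session the
sampling variance of `ln D̂` is roughly `1/n`, and across simulated
24-session panels the expected fitted slope under constant `k` is ≈ −0.43
rather than −0.50 (panel-to-panel SD ≈ 0.04–0.07). The effect is a
property of the design, not of the implementation — it is insensitive to
the density range, to `k`, and to the weight variant — and it biases the
*slope*, not the residual ranks that form the overlap index.

## Demography

Seasons are summer = Jun–Aug, fall = Sep–Nov, winter = Dec–Feb (labelled
by the December year), spring = Mar–May. The cycle phase is `increase` up
to and including a configurable peak month (default August 2014) and
`crash` after. MNKA for month `t` counts animals caught in `t` plus those
caught both before and after `t`; bridging sees through untrapped months,
but an untrapped month has no per-trap value. Seasonal growth is
`r_t = D_t / D_{t−1}` on whole-population density; it is missing when
either season is inestimable or the denominator is zero.

## Mixed models and selection

Candidate models are Gaussian linear mixed models with a grid-level random
intercept: overlap ~ {1, phase, season, phase+season} and growth ~ all
eight subsets of {phase, season, overlap index}. Fits use maximum
likelihood (REML log-likelihoods are not comparable across fixed-effect
structures). With a single grouping factor the ML problem reduces to a 1-D
profile over the variance ratio `λ = σ_b²/σ_e²`: given λ, the GLS
coefficients and residual variance are closed-form, so the search is a
bounded scalar optimisation with the λ = 0 boundary (no grid variance)
evaluated exactly and flagged. This is why the package does not call a
general mixed-model optimiser for the fit itself; the test suite
cross-checks the fits against `statsmodels` MixedLM.

Model degrees of freedom count fixed-effect coefficients (treatment
coding, alphabetical reference level) plus the two variance components;
`AICc = −2logL + 2df + 2df(df+1)/(n−df−1)`. Akaike weights are
`exp(−Δ/2)` normalised over the candidate set; all candidates are fitted
on the listwise-complete rows of the union of their variables so AICc is
comparable. The overlap–growth association is summarised by the Spearman
mid-rank correlation of seasonal means.

## The synthetic-data generator

The generator realises exactly the model the estimator assumes —
activity centres uniform on the trap box extended by `max(4σ, 50 m)`,
half-normal multi-catch detection, closed populations — so parameter
recovery tests isolate estimator error from model misspecification.
Multi-grid scenarios draw one population per grid-season (closure within
a season, turnover between seasons) and emit monthly capture histories of
6 occasions that pool into season-level sessions with genuine across-month
recaptures. Per-month σ follows `σ = k/√D` from a phase-level overlap
parameter `k`, capped at a home-range ceiling (`sigma_max`, default 30 m):
space use cannot expand without bound as density collapses, and without
the cap near-extinction sessions would imply σ far beyond both biological
plausibility and the 50 m estimation buffer. Grid heterogeneity
multiplies density (log-normal, sd 0.25) and `k` (sd 0.1).

The packaged demo scenario mimics a two-and-a-quarter-year study on 24
grids (every fifth one a 9–12-trap line, the rest 16-trap crosses):
monthly trapping June 2013 – August 2015 with September 2014 untrapped,
an increase phase through August 2014 (k = 0.6) and a crash phase after
(k = 0.3). Densities (per ha) are seasonal — increase
summer/fall/winter/spring = 25/18/10/14; crash fall/winter/spring/summer =
16/4/0.6/0.3 — so the crash starts at high density and collapses to
effective extinction, leaving late-crash sessions inestimable. The k
levels put σ in the 8–30 m range, comfortably inside the 50 m buffer at
the densities where sessions are estimable. These levels are illustrative
package defaults shaped like a boreal vole cycle, not estimates of any
real population.

Sessions are fitted only when at least 5 animals were captured
(`PipelineConfig.min_animals`); SECR fits on fewer individuals routinely
"converge" to meaningless estimates, and the corresponding field seasons
were inestimable in practice. Below-threshold sessions keep their panel
rows with missing estimates.

What the generator does **not** emulate: behavioural responses to traps
(trap-happiness/shyness), individual heterogeneity in `g0` or `σ`,
within-season movement or turnover, kin structure, and covariate effects
on detection. Passing tests therefore demonstrate correctness of the
estimation machinery under its own assumptions, not robustness of the
scientific conclusions to these real-data complications.

## Problem sizes used in the checks

The replicated checks run 24 single-season fits for the slope recovery,
50 replicates for parameter recovery and standard-error calibration, and
20 seeds of the 8-grid demo pipeline for the selection-structure check,
all on ≈ 200-point masks; these sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping the default suite quick.

## Known limitations

- Density is assumed homogeneous within a grid's mask; no density
  surfaces or habitat covariates.
- The SE of `σ̂` used as regression weight is itself estimated; at very
  small female counts weights are noisy and the residual index with them.
- Closure over a 3-month season is an approximation (inherited from the
  study design); demographic turnover within a season would bias `D̂`
  upward.
- The profile-likelihood mixed-model fitter handles exactly one random
  intercept; no random slopes or temporal autocorrelation.
- The Spearman correlation of seasonal mean overlap with seasonal mean
  growth is computed over only ~6 seasonal points on the demo calendar and
  is accordingly noisy and sign-unstable across seeds; on the demo
  scenario the pooled ln σ ~ ln D line partially absorbs the phase
  contrast at the low-density end (a structural feature of the residual
  index whenever k and density co-vary), which further weakens it. The
  mixed-model selection, not this correlation, is the stable phase signal.
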