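# Methods

This note records the modelling assumptions behind `cropdyn`, the defaults
that matter and why they were chosen, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## The model family

The quantity modelled is the rate of yield increase
`R_t = Y_t − Y_{t−1}`, the first difference of *detrended natural-log* yield
between successive harvests of the same crop in its rotation (one time step =
one harvest ≈ 3 calendar years). The base map is the Ricker/Royama
exponential form

    R_t = r_max − exp(a·Y_{t−d} + c),

a first-order negative feedback whose rate is bounded above by `r_max` (no
crop produces unbounded yield gains). The parameters have biological
readings: `r_max` the maximum rate of yield increase, `c` a measure of the
supply/demand ratio of limiting resources, `a` the shape of the nonlinear
feedback. An external factor `Z` (weed-diversity index, growing-season
climate summary, or a ratio of two such variables) may perturb exactly one of
them through `b·g(Z)` with `g = ln` by default:

* **lateral (L)** — `c + b·g(Z)` inside the exponent: translates the
  production curve sideways; the equilibrium moves, the local slope
  (`r_max·a`) does not.
* **vertical (V)** — `+ b·g(Z)` outside the exponent: an additive shift of
  the maximum rate; moves the curve vertically.
* **nonlinear (N)** — `(a + b·g(Z))·Y` in the exponent: reshapes the
  feedback; both the equilibrium and its stability change.

Interaction covariates are ratios `Z1/Z2` formed **before** the transform.
Since ratios of variables that cross zero (a freezing-season minimum
temperature, say) are outside the log's domain, the log transform refuses
non-positive values loudly; the identity transform must be requested
explicitly. No silent offsets are ever added.

### Equilibrium and stability

The yield potential `K` solves `R = 0`; closed forms are

| form | K | slope magnitude at K |
|------|---|----------------------|
| P | (ln r_max − c)/a | a·r_max |
| L | (ln r_max − c − b·g(Z))/a | a·r_max |
| V | (ln(r_max + b·g(Z)) − c)/a | a·(r_max + b·g(Z)) |
| N | (ln r_max − c)/(a + b·g(Z)) | (a + b·g(Z))·r_max |

Because the yield map is `Y_t = Y_{t−1} + R_t`, its eigenvalue at `K` is
`λ = 1 − slope`: slope in (0,1) gives monotonic damping, (1,2) oscillatory
damping, above 2 instability. The boundary values themselves (slope exactly 1
or 2) are measure-zero; the classifier assigns them to the upper regime.
Every closed form is pinned against numerical oracles (bisection roots,
central differences) in the test suite.

The vertical form's slope depends on `Z`, so a *reported* slope needs an
evaluation point; the pipeline evaluates at the sample mean of the covariate
and records it in `stability.csv` (`Z_eval`). This choice is deliberate and
flagged: published per-model slope summaries for vertical fits are sensitive
to (and often silent about) the evaluation point.

### r_max is not estimated

`r_max` is fixed at the maximum observed `R_t` for the crop. This follows the
convention that the maximum realised rate bounds the model, keeps the
candidate fits comparable (identical `r_max` across all forms for a crop),
and removes a poorly identified parameter from the optimization. The
consequence — explored in the simulation studies — is that when the observed
series has little variance, max-observed `R_t` can sit far below the
generative `r_max`, which misspecifies *every* candidate; validation studies
that target the estimation machinery itself therefore fix `r_max` at its
generating value.

## Feedback-order diagnosis (PRCF)

The partial rate correlation function is `PRCF(1) = corr(R_t, Y_{t−1})` and,
for lag i > 1, the partial correlation of `R_t` with `Y_{t−i}` given the
intervening lags, computed by correlating the residuals of the two OLS
regressions on the conditioning set. Pairs are pooled across replicate blocks
but never straddle a block boundary. The significance band is the usual
approximation ±2/√n with n the usable pairs at that lag.

## Fitting and model comparison

Free parameters (`a`, `c` and, for perturbed forms, `b`) are estimated by
nonlinear least squares (`scipy.optimize.least_squares`, tolerances 1e-10,
at most 200 function evaluations per start) with analytic Jacobians. The
exponential surface is initialization-sensitive, so fitting is multi-start:
a ∈ {0.1, 0.5, 1, 2}; c solving the pure-form equilibrium at the sample mean
of `Y_lag`; b ∈ {−0.5, 0, 0.5}; plus one warm start from the log-linear
regression `ln(r_max − R) ~ Y (+ g(Z))` where the margin is positive. The
best converged residual sum of squares wins; a fit that converges from no
start is returned as a flagged failure record and excluded from selection
with a warning, never raised mid-pipeline. Exponent arguments are clipped at
50 to keep wild starts finite; the optimum is far inside the clip for any
data on the rate scale.

Standard errors come from the Jacobian-based covariance
`σ̂²(JᵀJ)⁻¹` with `σ̂² = RSS/(n − p)`; p-values from asymptotic t statistics.
Model comparison uses the Gaussian small-sample criterion

    AICc = n·ln(RSS/n) + 2p′ + 2p′(p′+1)/(n − p′ − 1),   p′ = p_free + 1,

counting the error variance as a parameter. Only ΔAICc, Akaike weights
`w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)` and the 99% confidence set (smallest
weight-sorted prefix reaching the level) are treated as comparable across
software; absolute AICc magnitudes depend on likelihood constants and
parameter-counting conventions that differ between implementations. Ties in
AICc break toward fewer parameters, then lexicographic model id. The reported
pseudo-R² is `1 − RSS/TSS` about the mean rate — the Gaussian-deviance case
of the deviance-residual definition.

## Preprocessing

Log yields are detrended by an OLS quadratic in calendar year, pooled per
crop across treatments and blocks (per-treatment trends are a config option),
and recentred at the grand mean of log yield so that `c` and `K` keep
interpretable log(kg/ha) scales. Trend coefficients are reported in the raw
calendar-year basis. Detrending a finite stationary series still removes a
(small) fitted quadratic; rates computed after detrending therefore differ
from generative rates at order 1/√n even when no trend was injected. This is
a property of detrending, not a bug; the test suite checks exact recovery
where it is exact (noise-free fixed-point series) and the linear consistency
`Δ(detrended) = Δ(log yield) − Δ(fitted trend)` everywhere.

Growing-season climate summaries use daily mean `(tmin + tmax)/2` over a
planting→harvest window per crop (maize: May 1 – Sep 30; soybean: May 25 –
Oct 5); missing days are an error listing the dates, not an imputation.

## Community analysis

Diversity indices (richness S; Shannon H in nats; Simpson D; inverse Simpson;
Pielou J = H/ln S, defined 0 at S = 1; E-evenness = exp(H)/S) are computed
from biomass shares. The Hellinger transform is `sqrt(cell/row_sum)`.
Rare-species filtering is by occupancy: species with positive biomass in at
most the threshold fraction (default 5%) of samples are dropped — the
boundary is inclusive, so a species in exactly 5% of samples is removed.
The alternative reading (share of a sample's biomass) is not a dataset-level
criterion and was rejected. Index–species screening reports Pearson r for
every index × Hellinger-species pair with |r| strictly above the threshold
(default 0.4), sorted by |r|; no p-values are attached because the indices
are functions of the same species data. Indices enter the yield models
block-specific by default; per-year averaging across blocks is an option.

## The synthetic-data generator

`synthio` iterates `Y_t = Y_{t−1} + R(Y_{t−1}, Z_{t−d′}) + ε_t` with
`ε_t ~ N(0, noise_sd²)` — Gaussian and additive on the rate scale, matching
the least-squares error assumption — then exponentiates, optionally adding a
quadratic calendar-year trend so the detrending stage has real work. Default
internal dynamics are maize-like (`r_max = 1.2, a = 0.93, c = −7.91`,
equilibrium ≈ 8.7 log(kg/ha) ≈ 6 t/ha); default rate noise sd is 0.05.
Covariate generators: log-normal (diversity-like; default log-sd 0.5, the
spread implied by long-term weed-survey index statistics, whose coefficients
of variation run ≈ 0.45–0.65), Gaussian (temperature-like, may be negative),
a community-driven mode in which `Z` *is* a named diversity index computed
from the generated weed table, and a climate-driven mode using the generated
daily weather. Weed communities use geometric (log-series-like) rank
abundances with a controllable richness mean and evenness-decay ratio; daily
weather is a sinusoidal annual temperature cycle with Gaussian perturbation
and intermittent gamma rainfall, Michigan-like in level. All randomness flows
from one integer seed through independent named streams, so identical
configs produce bitwise-identical datasets.

What the generator does **not** emulate: spatial correlation among blocks,
treatment-by-year management effects, weather autocorrelation beyond the
seasonal cycle, measurement error in yields, and crop rotation interactions.
Passing tests on synthetic data therefore demonstrate correctness of the
estimation machinery under the stated model, not robustness to the full
structure of field data.

## Simulation studies

**Parameter recovery** (`experiments.parameter_recovery`): one block of 500
rates from the study parameters (`a = 0.9, c = −7.9, b = 0.3`), refit with
`r_max` fixed at its generating value. The series starts one log-unit below
equilibrium: a noise-free pure-form series started *at* equilibrium is
constant and carries no parameter information (any `a·K + c = ln r_max`
fits exactly), so the transient supplies identification. Noise-free runs
recover parameters to ≈ machine precision; at noise sd 0.05 the errors are a
few percent.

**Model identification** (`experiments.model_identification_study`): 100
replicate datasets (6 blocks × 60 cycles, noise sd 0.05) per generating form;
all four candidate forms are fitted and AICc ranks them. Design choices and
their reasons:

* Perturbation strengths are set so each form's one-step rate shock has
  standard deviation near `r_max/2`: (b, lnZ-sd) = L: (1.0, 0.5),
  V: (1.2, 0.5), N: (0.3, 0.2). The N form's covariate multiplies the yield
  level (≈ 9 log-units), so equal log-spread perturbs its equilibrium roughly
  K-fold harder than L or V; spreads beyond this margin drive the simulated
  system non-stationary (crashing trajectories), which no field series the
  model is meant for exhibits. Near-equilibrium series with much weaker
  perturbations leave L and N nearly observationally equivalent
  (`b·lnZ·Y ≈ (b·K)·lnZ` when `Y ≈ K`) and form selection degenerates toward
  a coin flip — an identifiability fact about the family, not a software
  property.
* The study fixes `r_max` at the generating value and runs without
  detrending (no trend is injected), isolating form selection from
  maximum-rate and trend-estimation error, each of which is validated
  separately.

Problem sizes throughout (500-cycle recovery series, 100 replicates × 3 forms
for identification, 1000 random draws for the oracle-equivalence checks) were
chosen to keep the full suite fast on a single CPU while leaving the
statistical conclusions unambiguous.

## Known limitations

* Second-order (delayed) feedback models and bifurcation analyses are out of
  scope; `d` ∈ {1, 2} only, and the stability analysis is local.
* Absolute AICc values are convention-dependent (see above); compare only
  differences and weights across implementations.
* Reported vertical-form slopes depend on the covariate evaluation point.
* The rare-species occupancy boundary is inclusive at the threshold.
* Fitting assumes homoscedastic Gaussian rate errors; block structure enters
  only through lag alignment, not as random effects.
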