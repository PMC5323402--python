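# cropdyn

Population-dynamics analysis of crop-yield time series.

Annual grain yields from long-term cropping experiments fluctuate around a
slowly drifting trend. `cropdyn` treats the detrended log-yield series the
way population ecologists treat abundance series: the **rate of yield
increase** between successive harvests of the same crop,
*R*<sub>t</sub> = *Y*<sub>t</sub> − *Y*<sub>t−1</sub> (with *Y* the detrended
natural-log yield), is modelled by a Royama/Ricker-type *R*-function with an
external perturbation *Z* — a weed-community diversity index, a
growing-season climate summary, or a ratio of two such variables — entering
one of the three interpretable parameters:

| form | model | the perturbation changes |
|------|-------|--------------------------|
| P (pure)      | *R* = *r*<sub>max</sub> − exp(*aY* + *c*) | nothing (internal feedback only) |
| L (lateral)   | *R* = *r*<sub>max</sub> − exp(*aY* + *c* + *b* ln *Z*) | *c*, the supply/demand measure |
| V (vertical)  | *R* = *r*<sub>max</sub> − exp(*aY* + *c*) + *b* ln *Z* | *r*<sub>max</sub>, the maximum rate (additive) |
| N (nonlinear) | *R* = *r*<sub>max</sub> − exp((*a* + *b* ln *Z*)*Y* + *c*) | *a*, the feedback shape |

*r*<sub>max</sub> is fixed at the maximum observed *R*<sub>t</sub>; the free
parameters (*a*, *c*, *b*) are estimated by nonlinear least squares.
Candidate models are ranked by small-sample AIC (AICc), compared through
Akaike weights and 99% confidence sets, and each fitted model yields an
equilibrium ("yield potential") *K* solving *R* = 0 and a stability slope
|d*R*/d*Y*| at *K* (≈ *r*<sub>max</sub>·*a*) that classifies the dynamics as
monotonically damped, oscillatory damped, or unstable. The feedback order is
diagnosed beforehand with the partial rate correlation function (PRCF).
Weed-community structure is summarised with the standard diversity indices
(richness, Shannon, Simpson, inverse Simpson, *J*- and *E*-evenness),
Hellinger-transformed abundances, rare-species filtering, and an
index-species correlation screen.

A synthetic-data generator emulates the schema of a block-replicated
maize–soybean rotation experiment (annual yields in kg/ha, weed dry biomass
by species in g/m², daily weather), with known ground truth embedded so every
stage of the analysis is testable end to end without field data.

## Worked example

```python
import cropdyn as cd

# simulate a vertical-perturbation crop system with known parameters
cfg = cd.SyntheticConfig(
    form="V", r_max=1.2, a=0.9, c=-7.9, b=0.3, noise_sd=0.05,
    covariate=cd.CovariateSpec(name="Z", kind="lognormal", params=(0.0, 0.5)),
    n_blocks=6, n_cycles=60, y0=4.7, seed=9,
)
run = cd.RunConfig(crop="maize", out_dir="out", seed=9, synthetic=cfg,
                   covariates=["Z"], detrend_degree=None)
res = cd.run_pipeline(run)
print(res["selection"][["fit", "a", "c", "b", "dAICc", "w", "R2"]].head(3))
```

```
  fit         a         c         b       dAICc             w        R2
0   V  0.914106 -8.022302  0.298214    0.000000  1.000000e+00  0.976376
1   L  0.918984 -8.074897 -0.247026  131.887222  2.296432e-29  0.965710
2   N  0.917714 -8.063463 -0.027400  144.999214  3.264531e-32  0.964416
```

The generating vertical form wins decisively (Akaike weight ≈ 1), and the
estimates recover the generating parameters (*a* = 0.9, *c* = −7.9,
*b* = 0.3) to within about 2%:

```python
top = res["best_fit"]
print(top.summary())           # estimates, standard errors, p-values
print(top.stability(Z=1.0))    # K, slope, eigenvalue, regime
```

```
R-function model results
========================================================
form: V    covariate: Z  (d'=0, log)
nobs: 354   r_max (fixed): 1.206   converged: True
RSS: 0.886422   AICc: -2112.296   pseudo-R2: 0.976
--------------------------------------------------------
 param     estimate    std err    p-value
     a       0.9141     0.0124 4.182e-215 **
     c      -8.0223     0.1120 1.615e-211 **
     b       0.2982     0.0052 8.801e-180 **
========================================================
StabilityReport(K=8.9811..., slope_magnitude=1.1025..., eigenvalue=-0.1025...,
                regime='oscillatory damped')
```

At the reference covariate level the fitted map has its yield potential near
*K* ≈ 8.98 log(kg/ha) and slope ≈ 1.10, an oscillatory damped approach to
equilibrium.

The same stages are exposed on the command line:

```bash
cropdyn simulate --config cfg.yml --out data/
cropdyn prcf --data data/ --crop maize --out prcf.csv
cropdyn run --config run.yml --out results/
```

## Layout

- `cropdyn.synthio` — synthetic dataset generation and CSV/JSON I/O
- `cropdyn.prep` — quadratic detrending, rates, climate summaries, frame assembly
- `cropdyn.community` — diversity indices, Hellinger transform, screens
- `cropdyn.dynamics` — R-function forms, equilibria, stability, PRCF
- `cropdyn.inference` — `RFunctionModel`/`RFunctionResults`, AICc selection
- `cropdyn.pipeline` / `cropdyn.cli` — orchestration and the `cropdyn` command
- `docs/methods.md` — modelling assumptions, defaults and limitations
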