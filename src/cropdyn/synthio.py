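"""Synthetic agroecosystem datasets with known generating parameters.

Emulates the schema of a long-term cropping-system experiment: block-replicated
annual grain yields (kg/ha) for a crop grown every third calendar year in a
rotation, daily weather (precipitation, min/max air temperature) with seasonal
structure, and weed-community dry-biomass tables with controllable richness and
evenness.  Yields are produced by iterating a chosen R-function form on the
natural-log scale,

    Y_t = Y_{t-1} + R(Y_{t-1}, Z_{t-d'}) + eps_t,    eps_t ~ N(0, noise_sd^2),

then exponentiated, optionally with an injected quadratic calendar-year trend
so the detrending stage of the analysis pipeline has work to do.  The ground
truth (form, parameters, covariate values, seed) is embedded in the dataset so
every downstream stage can be tested for recovery without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ModelSpec, Params, equilibrium, predict_rate

__all__ = [
    "CovariateSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_rate_series",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

# default species pool: codes observed at the study site plus common ruderals
SPECIES_POOL = (
    "TRIPR", "BARVU", "CAPBU", "DIGSA", "SETFA", "TAROF",
    "CHEAL", "ABUTH", "AMARE", "POLPE", "ERICA", "PANDI",
)

@dataclass(frozen=True)
class CovariateSpec:
    """How the external perturbation Z is generated.

    kind:
      * ``lognormal`` — positive, diversity-index-like draws;
        params: mu, sigma on the log scale (defaults 0.0, 0.5).
      * ``gaussian``  — temperature-like draws, may be negative;
        params: mean, sd (defaults 15.0, 2.0).
      * ``community`` — Z is the named diversity index computed from the
        generated weed communities (lag d' must be 0).
      * ``climate``   — Z is the named growing-season climate summary
        computed from the generated daily weather (lag d' must be 0).
    """

    name: str = "Z"
    kind: str = "lognormal"
    lag: int = 0
    params: tuple = ()

    def __post_init__(self):
        if self.kind not in ("lognormal", "gaussian", "community", "climate"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.lag not in (0, 1):
            raise ValueError("covariate lag d' must be 0 or 1")
        if self.kind in ("community", "climate") and self.lag != 0:
            raise ValueError(f"{self.kind} covariates support lag 0 only")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for one synthetic crop series."""

    crop: str = "maize"
    form: str = "P"
    r_max: float = 1.20
    a: float = 0.93
    c: float = -7.91
    b: float = 0.0
    noise_sd: float = 0.05
    covariate: CovariateSpec | None = None
    transform: str = "log"
    n_blocks: int = 6
    n_cycles: int = 6
    y0: float | None = None  # default: pure-form equilibrium
    seed: int = 0
    trend: tuple[float, float] = (0.0, 0.0)  # quadratic trend in (year - start)
    start_year: int = 1996
    treatment: str = "T1"
    # community generator knobs (weeds table is always produced)
    richness_mean: float = 6.0
    evenness_decay: float = 0.6  # geometric abundance ratio, 1.0 = even
    biomass_scale: float = 20.0  # g/m^2 of the dominant species

    def __post_init__(self):
        if self.form not in ("P", "L", "V", "N"):
            raise ValueError(f"unknown form {self.form!r}")
        if not self.r_max > 0:
            raise ValueError("r_max must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be >= 3")
        if self.a <= 0:
            raise ValueError("a must be > 0 for stationary simulations")
        if self.form != "P" and self.covariate is None:
            raise ValueError(f"form {self.form} requires a covariate spec")

    @property
    def params(self) -> Params:
        b = None if self.form == "P" else self.b
        return Params(r_max=self.r_max, a=self.a, c=self.c, b=b)

    @property
    def spec(self) -> ModelSpec:
        cov = None if self.form == "P" else (self.covariate.name if self.covariate else "Z")
        lag = self.covariate.lag if (self.covariate and self.form != "P") else 0
        return ModelSpec(
            form=self.form, covariate=cov, transform=self.transform, lag_covariate=lag
        )


@dataclass
class SyntheticDataset:
    """Generated tables plus the embedded ground truth."""

    yields: pd.DataFrame
    climate: pd.DataFrame
    community: pd.DataFrame
    truth: dict


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def simulate_rate_series(config: SyntheticConfig, covariate_series=None) -> np.ndarray:
    """Iterate the configured R-function; return log-yield array (n_blocks, n_cycles).

    ``covariate_series`` holds the value driving each step: element ``t``
    (0-based) enters the rate at cycle ``t`` (i.e. the caller supplies the
    already-lagged series Z_{t-d'}).  A 1-D series is shared across blocks; a
    2-D array gives one series per block.  Noise is an additive Gaussian draw
    on the rate scale, deterministic given the config seed.
    """
    spec, params = config.spec, config.params
    nb, nc = config.n_blocks, config.n_cycles
    if spec.form != "P":
        if covariate_series is None:
            raise ValueError(f"form {spec.form} requires a covariate series")
        Z = np.asarray(covariate_series, dtype=float)
        if Z.ndim == 1:
            Z = np.broadcast_to(Z, (nb, Z.shape[0]))
        if Z.shape[1] < nc:
            raise ValueError(
                f"covariate series length {Z.shape[1]} < n_cycles {nc}"
            )
        if spec.transform == "log":
            bad = np.argwhere(Z[:, :nc] <= 0)
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"log transform requested but covariate is non-positive at "
                    f"block {i}, cycle {j} (value {Z[i, j]})"
                )
    else:
        Z = None

    y0 = config.y0
    if y0 is None:
        y0 = equilibrium(ModelSpec(form="P"), Params(config.r_max, config.a, config.c))
    eps = _rng(config.seed, 0).normal(0.0, config.noise_sd, size=(nb, nc))

    Y = np.empty((nb, nc))
    prev = np.full(nb, float(y0))
    for t in range(nc):
        z_t = Z[:, t] if Z is not None else None
        R = predict_rate(spec, params, prev, z_t)
        prev = prev + np.asarray(R) + eps[:, t]
        Y[:, t] = prev
    return Y


# ---------------------------------------------------------------------------
# covariate, climate and community generators
# ---------------------------------------------------------------------------


def _draw_covariate(config: SyntheticConfig, n_extra: int) -> np.ndarray:
    """Draw (n_blocks, n_cycles + n_extra) values for distribution kinds."""
    cov = config.covariate
    rng = _rng(config.seed, 1)
    shape = (config.n_blocks, config.n_cycles + n_extra)
    if cov.kind == "lognormal":
        mu, sigma = cov.params if cov.params else (0.0, 0.5)
        return rng.lognormal(mu, sigma, size=shape)
    if cov.kind == "gaussian":
        mean, sd = cov.params if cov.params else (15.0, 2.0)
        return rng.normal(mean, sd, size=shape)
    raise AssertionError(cov.kind)


def _daily_climate(years, seed: int) -> pd.DataFrame:
    """Daily weather with a sinusoidal annual temperature cycle (Michigan-like)
    and intermittent gamma-distributed rainfall."""
    rng = _rng(seed, 2)
    frames = []
    for year in years:
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        doy = dates.dayofyear.to_numpy()
        tmean = 9.0 - 14.0 * np.cos(2 * np.pi * (doy - 15) / 365.25)
        tmean = tmean + rng.normal(0, 2.5, size=len(doy))
        half_range = np.clip(rng.normal(5.5, 1.2, size=len(doy)), 1.0, None)
        wet = rng.random(len(doy)) < 0.35
        precip = np.where(wet, rng.gamma(0.8, 8.0, size=len(doy)), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "date": dates.strftime("%Y-%m-%d"),
                    "precip_mm": np.round(precip, 2),
                    "tmin_c": np.round(tmean - half_range, 2),
                    "tmax_c": np.round(tmean + half_range, 2),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _communities(config: SyntheticConfig, years) -> pd.DataFrame:
    """Weed dry-biomass table: geometric (log-series-like) abundances.

    Per sample, richness S is drawn around ``richness_mean`` (min 2) and the
    i-th ranked species receives biomass ``scale * decay**i`` times a
    lognormal deviate, so ``evenness_decay`` close to 1 gives even
    communities and small values strongly dominated ones.
    """
    rng = _rng(config.seed, 3)
    pool = list(SPECIES_POOL)
    rows = []
    for rep in range(1, config.n_blocks + 1):
        for year in years:
            S = int(np.clip(2 + rng.poisson(max(config.richness_mean - 2, 0.0)),
                            2, len(pool)))
            species = rng.choice(pool, size=S, replace=False)
            ranks = np.arange(S)
            biomass = (
                config.biomass_scale
                * config.evenness_decay ** ranks
                * rng.lognormal(0.0, 0.25, size=S)
            )
            for sp, bm in zip(species, biomass):
                rows.append(
                    {
                        "year": year,
                        "crop": config.crop,
                        "treatment": config.treatment,
                        "replicate": rep,
                        "species_code": sp,
                        "biomass_g_m2": round(float(bm), 6),
                    }
                )
    return pd.DataFrame(rows)


def _index_from_community(
    weeds: pd.DataFrame, name: str, years, treatment: str, n_blocks: int
) -> np.ndarray:
    from .community import community_matrix, diversity_table

    idx = diversity_table(community_matrix(weeds))
    out = np.empty((n_blocks, len(years)))
    for j, year in enumerate(years):
        for i in range(n_blocks):
            out[i, j] = idx.loc[(year, treatment, i + 1), name]
    return out


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset (yields, daily climate, weed communities, truth)."""
    years = [config.start_year + 3 * t for t in range(config.n_cycles)]
    climate = _daily_climate(years, config.seed)
    weeds = _communities(config, years)

    cov = config.covariate
    cov_obs = None  # observed covariate per (block, cycle)
    driving = None  # value entering the rate at each cycle (already lagged)
    if config.form != "P":
        if cov.kind in ("lognormal", "gaussian"):
            draws = _draw_covariate(config, n_extra=cov.lag)
            # draws[:, s] is the covariate observed at cycle s - lag
            driving = draws[:, : config.n_cycles]
            cov_obs = draws[:, cov.lag:]
        elif cov.kind == "community":
            cov_obs = _index_from_community(
                weeds, cov.name, years, config.treatment, config.n_blocks
            )
            driving = cov_obs
        else:  # climate
            from .prep import growing_season_summary

            summ = growing_season_summary(climate, crop=config.crop, years=years)
            vals = summ[cov.name].to_numpy(float)
            cov_obs = np.broadcast_to(vals, (config.n_blocks, config.n_cycles)).copy()
            driving = cov_obs

    Y = simulate_rate_series(config, driving)

    t1, t2 = config.trend
    x = np.asarray(years, dtype=float) - config.start_year
    trend = t1 * x + t2 * x**2
    rows = []
    for rep in range(1, config.n_blocks + 1):
        for j, year in enumerate(years):
            rows.append(
                {
                    "year": year,
                    "crop": config.crop,
                    "treatment": config.treatment,
                    "replicate": rep,
                    "yield_kg_ha": float(np.exp(Y[rep - 1, j] + trend[j])),
                }
            )
    yields = pd.DataFrame(rows)

    truth = {
        "form": config.form,
        "r_max": config.r_max,
        "a": config.a,
        "c": config.c,
        "b": None if config.form == "P" else config.b,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "crop": config.crop,
        "treatment": config.treatment,
        "transform": config.transform,
        "n_blocks": config.n_blocks,
        "n_cycles": config.n_cycles,
        "y0": config.y0,
        "trend": list(config.trend),
        "start_year": config.start_year,
        "years": years,
        "log_yield": Y.tolist(),
        "covariate": None
        if cov is None or config.form == "P"
        else {
            "name": cov.name,
            "kind": cov.kind,
            "lag": cov.lag,
            "observed": cov_obs.tolist(),
            "driving": driving.tolist(),
        },
    }
    return SyntheticDataset(yields=yields, climate=climate, community=weeds, truth=truth)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED = {
    "yields.csv": ["year", "crop", "treatment", "replicate", "yield_kg_ha"],
    "weeds.csv": ["year", "crop", "treatment", "replicate", "species_code", "biomass_g_m2"],
    "climate.csv": ["date", "precip_mm", "tmin_c", "tmax_c"],
}


def write_dataset(dataset: SyntheticDataset, directory) -> dict[str, Path]:
    """Write yields.csv, weeds.csv, climate.csv and truth.json to `directory`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for fname, df in (
        ("yields.csv", dataset.yields),
        ("weeds.csv", dataset.community),
        ("climate.csv", dataset.climate),
    ):
        p = directory / fname
        df.to_csv(p, index=False, float_format="%.17g")
        paths[fname] = p
    p = directory / "truth.json"
    p.write_text(json.dumps(dataset.truth, indent=1))
    paths["truth.json"] = p
    return paths


def _validate(df: pd.DataFrame, fname: str) -> pd.DataFrame:
    missing = [c for c in _REQUIRED[fname] if c not in df.columns]
    if missing:
        raise ValueError(f"{fname}: missing required column(s) {missing}")
    if fname == "yields.csv":
        bad = df.index[df["yield_kg_ha"] <= 0]
        if len(bad):
            raise ValueError(f"{fname}: non-positive yield at row {bad[0]}")
        keys = df[["year", "crop", "treatment", "replicate"]]
        if keys.duplicated().any():
            raise ValueError(f"{fname}: conflicting duplicate keys at row "
                             f"{keys.index[keys.duplicated()][0]}")
    if fname == "weeds.csv":
        bad = df.index[df["biomass_g_m2"] < 0]
        if len(bad):
            raise ValueError(f"{fname}: negative biomass at row {bad[0]}")
    return df


def read_dataset(directory) -> SyntheticDataset:
    """Read a dataset directory written by :func:`write_dataset` (truth optional)."""
    directory = Path(directory)
    frames = {}
    for fname in _REQUIRED:
        p = directory / fname
        if not p.exists():
            raise FileNotFoundError(p)
        frames[fname] = _validate(pd.read_csv(p), fname)
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticDataset(
        yields=frames["yields.csv"],
        climate=frames["climate.csv"],
        community=frames["weeds.csv"],
        truth=truth,
    )
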