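"""End-to-end orchestration: simulate/load -> preprocess -> diversity ->
PRCF -> fit -> select -> report.

Every stage delegates to the corresponding module, so pipeline outputs equal
the standalone-module outputs on identical inputs; the pipeline only wires
tables together, resolves covariate names and writes the CSV report bundle.
"""

from __future__ import annotations

import json
import traceback
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    INDEX_NAMES,
    community_matrix,
    correlation_screen,
    diversity_table,
    filter_rare,
    hellinger,
)
from .dynamics import prcf
from .inference import enumerate_candidates, fit_candidates, selection_table
from .prep import assemble_frame, detrend_quadratic, growing_season_summary, rate_of_increase
from .synthio import SyntheticConfig, generate_dataset, read_dataset, write_dataset

__all__ = ["RunConfig", "run_pipeline"]

CLIMATE_NAMES = ("tM", "tmax", "tmin", "tMax", "tMin", "precM", "precMax")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    crop: str = "maize"
    out_dir: str = "cropdyn_out"
    seed: int = 0
    input_dir: str | None = None          # read an existing dataset directory
    synthetic: SyntheticConfig | None = None  # or generate one
    covariates: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    forms: tuple[str, ...] = ("L", "V", "N")
    include_pure: bool = True
    transform: str = "log"
    covariate_lags: tuple[int, ...] = (0,)
    feedback_lag: int = 1
    level: float = 0.99
    rare_threshold: float = 0.05
    corr_threshold: float = 0.4
    detrend_degree: int | None = 2
    per_treatment_trend: bool = False
    block_specific_indices: bool = True
    max_prcf_lag: int = 4

    def __post_init__(self):
        if not 0 < self.level <= 1:
            raise ValueError("selection level must be in (0, 1]")
        if not 0 < self.rare_threshold < 1:
            raise ValueError("rare-species threshold must be in (0, 1)")
        if not 0 < self.corr_threshold < 1:
            raise ValueError("correlation threshold must be in (0, 1)")
        if not self.covariates and not self.include_pure:
            raise ValueError("need at least one covariate or pure-only mode")
        if self.input_dir is None and self.synthetic is None:
            raise ValueError("provide input_dir or a synthetic config")


def _year_to_cycle(years) -> dict:
    return {int(y): t for t, y in enumerate(sorted(set(int(y) for y in years)))}


def _covariate_series(name, config, dataset, levels, div, climate_summ, y2t):
    """Resolve a covariate name to a series indexed by t or (block, t)."""
    if name in INDEX_NAMES:
        if div is None:
            raise ValueError(f"covariate {name!r}: no community data available")
        ser = div[name].copy()
        # index (year, treatment, replicate) -> (block, t)
        idx = []
        for year, treatment, rep in ser.index:
            idx.append((f"{config.crop}|{treatment}|R{rep}", y2t.get(int(year))))
        ser.index = pd.MultiIndex.from_tuples(idx)
        ser = ser[[t is not None for _, t in ser.index]]
        if not config.block_specific_indices:
            ser = ser.groupby(level=1).mean()
        return ser
    if name in CLIMATE_NAMES:
        ser = climate_summ[name].copy()
        ser.index = [y2t[int(y)] for y in ser.index]
        return ser
    truth_cov = (dataset.truth or {}).get("covariate")
    if truth_cov and truth_cov.get("name") == name:
        obs = np.asarray(truth_cov["observed"], dtype=float)
        treatment = dataset.truth.get("treatment", "T1")
        idx, vals = [], []
        for b in range(obs.shape[0]):
            for t in range(obs.shape[1]):
                idx.append((f"{config.crop}|{treatment}|R{b + 1}", t))
                vals.append(obs[b, t])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx))
    raise ValueError(f"unknown covariate {name!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict of in-memory results (tables and fit objects).  On a stage
    failure, partial outputs remain on disk next to ``errors.json`` (a
    machine-readable manifest naming the failed stage) and the exception is
    re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "init"
    try:
        stage = "data"
        if config.input_dir is not None:
            dataset = read_dataset(config.input_dir)
        else:
            dataset = generate_dataset(config.synthetic)
            write_dataset(dataset, out / "inputs")
        results["dataset"] = dataset

        stage = "prep"
        yields = dataset.yields[dataset.yields["crop"] == config.crop]
        if yields.empty:
            raise ValueError(f"no yield rows for crop {config.crop!r}")
        levels, trends = detrend_quadratic(
            yields, per_treatment=config.per_treatment_trend,
            degree=config.detrend_degree,
        )
        rates = rate_of_increase(levels)
        y2t = _year_to_cycle(levels["year"])
        results["levels"], results["rates"], results["trends"] = levels, rates, trends

        stage = "community"
        div = None
        weeds = dataset.community
        if weeds is not None and len(weeds):
            weeds = weeds[weeds["crop"] == config.crop] if "crop" in weeds.columns else weeds
        if weeds is not None and len(weeds):
            mat = community_matrix(weeds)
            div = diversity_table(mat)
            reduced, removed = filter_rare(mat, config.rare_threshold)
            screen = pd.DataFrame(columns=["index", "species", "r"])
            if reduced.shape[1]:
                hel = hellinger(reduced)
                screen = correlation_screen(div, hel, config.corr_threshold)
            div_out = div.reset_index()
            div_out.to_csv(out / "diversity.csv", index=False)
            screen.to_csv(out / "screen.csv", index=False)
            results["diversity"], results["screen"] = div, screen
            results["removed_species"] = removed

        stage = "climate"
        climate_summ = None
        if dataset.climate is not None and len(dataset.climate):
            climate_summ = growing_season_summary(
                dataset.climate, crop=config.crop, years=sorted(y2t)
            )
            climate_summ.to_csv(out / "climate_summary.csv")
            results["climate_summary"] = climate_summ

        stage = "prcf"
        prcf_tab = prcf(levels, max_lag=config.max_prcf_lag)
        prcf_tab.to_csv(out / "prcf.csv", index=False)
        results["prcf"] = prcf_tab

        stage = "frame"
        frames = {}
        base_names = list(config.covariates)
        for name in {z for pair in config.interactions for z in pair}:
            if name not in base_names:
                base_names.append(name)
        for lag in config.covariate_lags:
            cov_series = {
                name: _covariate_series(
                    name, config, dataset, levels, div, climate_summ, y2t
                )
                for name in base_names
            }
            frames[lag] = assemble_frame(
                rates, levels, cov_series, d=config.feedback_lag, d_prime=lag,
                transform=config.transform, interactions=config.interactions,
            )
        results["frames"] = frames
        if frames:
            frames[config.covariate_lags[0]].to_csv(out / "frame.csv", index=False)

        stage = "fit"
        r_max = float(rates["R"].max())
        fits = []
        for lag, frame in frames.items():
            specs = enumerate_candidates(
                config.covariates, forms=config.forms, lags=(lag,),
                interactions=config.interactions,
                include_pure=config.include_pure and lag == config.covariate_lags[0],
                transform=config.transform,
            )
            fits.extend(fit_candidates(specs, frame, r_max=r_max))
        results["fits"] = fits

        stage = "selection"
        table = selection_table(fits, level=config.level, crop=config.crop)
        table.to_csv(out / "selection.csv", index=False)
        results["selection"] = table
        best_id = table.iloc[0]["model_id"]
        results["best_fit"] = next(
            f for f in fits if f.converged and f.spec.model_id == best_id
        )

        fit_detail = []
        for f in fits:
            fit_detail.append(
                {
                    "model_id": f.spec.model_id,
                    "converged": bool(f.converged),
                    "r_max": f.model.r_max,
                    "params": dict(zip(f.param_names, map(float, f.theta))),
                    "bse": dict(zip(f.param_names, map(float, f.bse))),
                    "pvalues": dict(zip(f.param_names, map(float, f.pvalues))),
                    "rss": float(f.rss),
                    "n": int(f.nobs),
                    "aicc": float(f.aicc) if f.converged else None,
                    "pseudo_r2": float(f.pseudo_r2) if f.converged else None,
                }
            )
        (out / "fits.json").write_text(json.dumps(fit_detail, indent=1))

        stage = "stability"
        frame0 = frames[config.covariate_lags[0]] if frames else None
        stab_rows = []
        for f in fits:
            if not f.converged:
                continue
            if f.spec.form == "P":
                z = None
            else:
                lag = f.spec.lag_covariate
                z = float(frames[lag][f.spec.covariate].mean())
            try:
                rep = f.stability(z)
            except ValueError as exc:
                warnings.warn(f"{f.spec.model_id}: no stability report ({exc})")
                continue
            stab_rows.append(
                {"model_id": f.spec.model_id, "Z_eval": z if z is not None else np.nan,
                 "K": rep.K, "slope": rep.slope_magnitude,
                 "eigenvalue": rep.eigenvalue, "regime": rep.regime}
            )
        stability = pd.DataFrame(
            stab_rows, columns=["model_id", "Z_eval", "K", "slope", "eigenvalue", "regime"]
        )
        stability.to_csv(out / "stability.csv", index=False)
        results["stability"] = stability

        stage = "log"
        (out / "run.json").write_text(
            json.dumps(
                {
                    "version": __version__,
                    "seed": config.seed,
                    "crop": config.crop,
                    "n_rates": int(len(rates)),
                    "n_candidates": int(len(fits)),
                    "r_max": r_max,
                    "config": {
                        k: v
                        for k, v in asdict(config).items()
                        if k not in ("synthetic",)
                    },
                },
                indent=1,
                default=str,
            )
        )
    except Exception as exc:
        (out / "errors.json").write_text(
            json.dumps(
                {"stage": stage, "error": str(exc),
                 "type": type(exc).__name__,
                 "traceback": traceback.format_exc()},
                indent=1,
            )
        )
        raise
    return results
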