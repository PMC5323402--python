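"""Transform raw tables into the modelling frame.

Stages: (1) quadratic detrending of log yields per crop (removing slow
non-climatic drift from management and genetics while preserving the log-yield
scale), (2) rates of increase R_t = Y_t - Y_{t-1} within blocks, (3)
growing-season climate summaries, (4) lag-aligned assembly of the frame
consumed by the R-function models.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

__all__ = [
    "GROWING_SEASON",
    "detrend_quadratic",
    "rate_of_increase",
    "growing_season_summary",
    "assemble_frame",
]

GROWING_SEASON = {  # planting -> harvest (month, day)
    "maize": ((5, 1), (9, 30)),
    "soybean": ((5, 25), (10, 5)),
}

BLOCK_KEY = ["crop", "treatment", "replicate"]


def _block_id(df: pd.DataFrame) -> pd.Series:
    return (
        df["crop"].astype(str)
        + "|" + df["treatment"].astype(str)
        + "|R" + df["replicate"].astype(str)
    )


def detrend_quadratic(
    yields: pd.DataFrame, per_treatment: bool = False, degree: int | None = 2
):
    """Detrend log yields by an OLS quadratic in calendar year, pooled per crop.

    The detrended level is ``Y_t = residual + grand mean of log yield`` so the
    log(kg/ha) scale — and hence the interpretation of the supply/demand
    parameter c and the yield potential K — is preserved.  Set
    ``per_treatment=True`` to fit one trend per (crop, treatment) instead of
    pooling; ``degree=None`` skips detrending (Y_t = log yield).

    Returns
    -------
    levels : DataFrame with columns crop, treatment, replicate, block, year,
        t (cycle index within block), Y.
    trends : dict mapping group key -> ndarray of polynomial coefficients in
        the raw calendar-year basis, ascending order (c0, c1, c2).
    """
    for col in ("year", "crop", "yield_kg_ha"):
        if col not in yields.columns:
            raise ValueError(f"yields table: missing required column {col!r}")
    if (yields["yield_kg_ha"] <= 0).any():
        row = yields.index[yields["yield_kg_ha"] <= 0][0]
        raise ValueError(f"non-positive yield at row {row}")

    group_cols = ["crop", "treatment"] if per_treatment else ["crop"]
    out, trends = [], {}
    for key, g in yields.groupby(group_cols, sort=True):
        key = key if per_treatment else key[0]
        years = g["year"].to_numpy(float)
        if degree is not None and len(np.unique(years)) < 4:
            raise ValueError(
                f"group {key!r}: need >= 4 distinct calendar years to fit a quadratic trend"
            )
        logy = np.log(g["yield_kg_ha"].to_numpy(float))
        if degree is None:
            fitted = np.zeros_like(logy)
            trends[key] = np.zeros(3)
            Y = logy
        else:
            poly = Polynomial.fit(years, logy, degree)
            trends[key] = poly.convert().coef
            fitted = poly(years)
            Y = (logy - fitted) + logy.mean()
        gg = g[[c for c in ("year", "crop", "treatment", "replicate") if c in g.columns]].copy()
        gg["Y"] = Y
        out.append(gg)
    levels = pd.concat(out, ignore_index=True)
    if "treatment" not in levels.columns:
        levels["treatment"] = "NA"
    if "replicate" not in levels.columns:
        levels["replicate"] = 1
    levels["block"] = _block_id(levels)
    levels = levels.sort_values(["block", "year"]).reset_index(drop=True)
    levels["t"] = levels.groupby("block").cumcount()
    return levels, trends


def rate_of_increase(levels: pd.DataFrame) -> pd.DataFrame:
    """Rates R_t = Y_t - Y_{t-1} within each block (never across blocks).

    Single-cycle blocks are dropped with a warning.  Returns a DataFrame with
    columns block, crop, t, R where t is the cycle index of the later harvest.
    """
    rows = []
    for block, g in levels.groupby("block", sort=True):
        g = g.sort_values("t")
        if len(g) < 2:
            warnings.warn(f"block {block!r} has a single cycle; dropped from rates")
            continue
        y = g["Y"].to_numpy(float)
        t = g["t"].to_numpy()
        for i in range(1, len(g)):
            rows.append(
                {"block": block, "crop": g["crop"].iloc[0], "t": int(t[i]),
                 "R": float(y[i] - y[i - 1])}
            )
    return pd.DataFrame(rows, columns=["block", "crop", "t", "R"])


def growing_season_summary(
    climate: pd.DataFrame,
    crop: str | None = None,
    years=None,
    window: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Growing-season climate summaries per crop-year.

    Daily mean temperature is (tmin + tmax)/2.  For each year the summary
    holds the seasonal averages tM (of daily means), tmax (of daily maxima),
    tmin (of daily minima), the extremes tMax and tMin, the average daily
    precipitation precM and its maximum precMax.

    The window is planting->harvest as (month, day) pairs; defaults come from
    ``GROWING_SEASON[crop]``.  Missing days inside a window raise an error
    listing the dates.
    """
    for col in ("date", "precip_mm", "tmin_c", "tmax_c"):
        if col not in climate.columns:
            raise ValueError(f"climate table: missing required column {col!r}")
    if window is None:
        if crop is None or crop not in GROWING_SEASON:
            raise ValueError(f"unknown crop {crop!r}: pass an explicit window")
        window = GROWING_SEASON[crop]
    dates = pd.to_datetime(climate["date"])
    if years is None:
        years = sorted(dates.dt.year.unique())
    (pm, pd_), (hm, hd) = window
    rows = []
    for year in years:
        start = pd.Timestamp(year=int(year), month=pm, day=pd_)
        end = pd.Timestamp(year=int(year), month=hm, day=hd)
        mask = (dates >= start) & (dates <= end)
        g = climate.loc[mask]
        expected = pd.date_range(start, end, freq="D")
        present = set(dates[mask])
        missing = [d.strftime("%Y-%m-%d") for d in expected if d not in present]
        if missing:
            raise ValueError(
                f"climate window {year}: missing {len(missing)} day(s): "
                + ", ".join(missing[:10])
            )
        tmin = g["tmin_c"].to_numpy(float)
        tmax = g["tmax_c"].to_numpy(float)
        prec = g["precip_mm"].to_numpy(float)
        daily_mean = (tmin + tmax) / 2.0
        rows.append(
            {
                "year": int(year),
                "tM": daily_mean.mean(),
                "tmax": tmax.mean(),
                "tmin": tmin.mean(),
                "tMax": tmax.max(),
                "tMin": tmin.min(),
                "precM": prec.mean(),
                "precMax": prec.max(),
            }
        )
    return pd.DataFrame(rows).set_index("year")


def _lookup(series: pd.Series, block: str, t: int):
    """Covariate lookup: series indexed by t (shared) or by (block, t)."""
    if isinstance(series.index, pd.MultiIndex):
        key = (block, t)
    else:
        key = t
    try:
        return float(series.loc[key])
    except KeyError:
        return None


def assemble_frame(
    rates: pd.DataFrame,
    levels: pd.DataFrame,
    covariates: dict[str, pd.Series] | None = None,
    d: int = 1,
    d_prime: int = 0,
    transform: str = "log",
    interactions: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Assemble the modelling frame: rows (block, t, R_t, Y_{t-d}, Z_{t-d'}).

    Covariate series are indexed by cycle t (shared across blocks) or by
    (block, t).  An interaction pair (z1, z2) produces the ratio covariate
    ``z1/z2`` computed *before* any transform.  Covariate columns hold the raw
    (untransformed) lagged values; the requested transform is validated here
    (log demands strictly positive values) and recorded in ``frame.attrs``.
    Rows with any unavailable lag are dropped and counted in
    ``frame.attrs["n_dropped"]``.
    """
    if d not in (1, 2):
        raise ValueError("feedback lag d must be 1 or 2")
    if d_prime not in (0, 1):
        raise ValueError("covariate lag d' must be 0 or 1")
    if transform not in ("log", "identity"):
        raise ValueError(f"unknown transform {transform!r}")
    covariates = dict(covariates or {})
    for z1, z2 in interactions or []:
        if z1 not in covariates or z2 not in covariates:
            raise ValueError(f"interaction ({z1}, {z2}): unknown covariate")

    lvl = levels.set_index(["block", "t"])["Y"]
    rows, n_dropped = [], 0
    inter = list(interactions or [])
    for _, rrow in rates.iterrows():
        block, t = rrow["block"], int(rrow["t"])
        try:
            y_lag = float(lvl.loc[(block, t - d)])
        except KeyError:
            n_dropped += 1
            continue
        rec = {"block": block, "crop": rrow["crop"], "t": t,
               "R": float(rrow["R"]), "Y_lag": y_lag}
        ok = True
        zvals = {}
        for name, series in covariates.items():
            v = _lookup(series, block, t - d_prime)
            if v is None:
                ok = False
                break
            zvals[name] = v
        if ok:
            for z1, z2 in inter:
                if zvals[z2] == 0:
                    raise ZeroDivisionError(
                        f"interaction {z1}/{z2}: zero denominator at ({block}, t={t - d_prime})"
                    )
                zvals[f"{z1}/{z2}"] = zvals[z1] / zvals[z2]
            for name, v in zvals.items():
                if transform == "log" and v <= 0:
                    raise ValueError(
                        f"log transform of covariate {name!r}: non-positive value "
                        f"{v} at ({block}, t={t - d_prime}); "
                        "request the identity transform explicitly instead"
                    )
                rec[name] = v
            rows.append(rec)
        else:
            n_dropped += 1
    cov_cols = list(covariates) + [f"{a}/{b}" for a, b in inter]
    frame = pd.DataFrame(rows, columns=["block", "crop", "t", "R", "Y_lag"] + cov_cols)
    frame.attrs.update({"d": d, "d_prime": d_prime, "transform": transform,
                        "n_dropped": n_dropped})
    return frame
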