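"""Royama R-function model family for crop-yield dynamics.

The rate of yield increase ``R_t = Y_t - Y_{t-1}`` (first difference of
detrended log yield between successive harvests of the same crop) is modelled
as an exponential (Ricker-type) function of the previous yield level, with an
external perturbation ``Z`` (a weed-diversity index, a growing-season climate
summary, or a ratio of two such variables) entering one of the three
biologically interpretable parameters:

====  =========================================  =================================
form  R(Y, Z)                                    perturbation enters
====  =========================================  =================================
P     r_max - exp(a*Y + c)                       none (pure internal feedback)
L     r_max - exp(a*Y + c + b*g(Z))              c   ("lateral": shifts the curve)
V     r_max - exp(a*Y + c) + b*g(Z)              r_max ("vertical": additive)
N     r_max - exp((a + b*g(Z))*Y + c)            a   ("nonlinear": reshapes)
====  =========================================  =================================

with ``g`` the covariate transform (natural log by default; identity offered
for covariates such as temperature ratios that may be non-positive).

``r_max`` is the maximum rate of yield increase and is *not* a free
parameter: it is fixed at the maximum R_t observed in the data.  ``c``
measures the supply/demand ratio of limiting resources and ``a`` is the shape
parameter of the nonlinear feedback.

The nontrivial root ``K`` of ``R = 0`` is the equilibrium log yield ("yield
potential"); the local slope ``|dR/dY|`` at ``K`` determines the stability of
the first-order map ``Y_t = Y_{t-1} + R(Y_{t-1})``, whose eigenvalue is
``1 - |dR/dY|``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FORMS",
    "ModelSpec",
    "Params",
    "StabilityReport",
    "predict_rate",
    "equilibrium",
    "stability_slope",
    "partial_slope_z",
    "prcf",
]

FORMS = ("P", "L", "V", "N")
_TRANSFORMS = ("log", "identity")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate R-function: form, covariate descriptor and lags.

    Parameters
    ----------
    form : {"P", "L", "V", "N"}
        Pure, lateral, vertical or nonlinear perturbation form.
    covariate : str or None
        Covariate column name; a ratio covariate is written ``"z1/z2"``.
        Must be None for form P.
    transform : {"log", "identity"}
        Transform g applied to the covariate inside the model.
    lag_feedback : int
        Feedback lag d (in harvest cycles of the focal crop); d >= 1.
    lag_covariate : int
        Covariate lag d' in {0, 1}.
    """

    form: str
    covariate: str | None = None
    transform: str = "log"
    lag_feedback: int = 1
    lag_covariate: int = 0

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.form == "P" and self.covariate is not None:
            raise ValueError("form P admits no covariate")
        if self.form != "P" and self.covariate is None:
            raise ValueError(f"form {self.form} requires a covariate")
        if self.lag_feedback < 1:
            raise ValueError("feedback lag d must be >= 1")
        if self.lag_covariate not in (0, 1):
            raise ValueError("covariate lag d' must be 0 or 1")

    @property
    def n_free(self) -> int:
        """Number of free parameters (a, c and, for L/V/N, b)."""
        return 2 if self.form == "P" else 3

    @property
    def model_id(self) -> str:
        if self.form == "P":
            return "P"
        return f"{self.form}:{self.covariate}:d'={self.lag_covariate}:{self.transform}"


@dataclass(frozen=True)
class Params:
    """R-function parameters.  ``b`` is absent (None) for form P."""

    r_max: float
    a: float
    c: float
    b: float | None = None

    def __post_init__(self) -> None:
        if not self.r_max > 0:
            raise ValueError("r_max must be positive")


@dataclass(frozen=True)
class StabilityReport:
    """Equilibrium and local-stability diagnosis of the fitted map."""

    K: float
    slope_magnitude: float
    eigenvalue: float
    regime: str


def _transform(z, transform: str):
    z = np.asarray(z, dtype=float)
    if transform == "log":
        if np.any(z <= 0):
            bad = int(np.argmax(np.asarray(z <= 0)))
            raise ValueError(
                f"log transform requested but covariate value at index {bad} "
                f"is non-positive ({np.atleast_1d(z)[bad] if z.ndim else z})"
            )
        return np.log(z)
    return z


def predict_rate(spec: ModelSpec, params: Params, Y, Z=None):
    """Evaluate the R-function at log-yield ``Y`` and covariate ``Z``.

    Vectorized over ``Y`` (and ``Z``).  Returns a scalar for scalar input.
    """
    Y = np.asarray(Y, dtype=float)
    r_max, a, c = params.r_max, params.a, params.c
    if spec.form == "P":
        if Z is not None:
            raise ValueError("form P takes no covariate")
        out = r_max - np.exp(a * Y + c)
        return out if out.ndim else float(out)
    if Z is None:
        raise ValueError(f"form {spec.form} requires a covariate value")
    if params.b is None:
        raise ValueError(f"form {spec.form} requires parameter b")
    u = _transform(Z, spec.transform)
    b = params.b
    if spec.form == "L":
        out = r_max - np.exp(a * Y + c + b * u)
    elif spec.form == "V":
        out = (r_max - np.exp(a * Y + c)) + b * u
    else:  # N
        out = r_max - np.exp((a + b * u) * Y + c)
    return out if out.ndim else float(out)


def equilibrium(spec: ModelSpec, params: Params, Z=None) -> float:
    """Closed-form nontrivial root K of ``R = 0`` (the yield potential).

    P: (ln r_max - c)/a;  L: (ln r_max - c - b*g(Z))/a;
    V: (ln(r_max + b*g(Z)) - c)/a;  N: (ln r_max - c)/(a + b*g(Z)).
    """
    r_max, a, c = params.r_max, params.a, params.c
    if spec.form == "P":
        return (math.log(r_max) - c) / a
    u = float(_transform(Z, spec.transform))
    b = params.b
    if spec.form == "L":
        return (math.log(r_max) - c - b * u) / a
    if spec.form == "V":
        top = r_max + b * u
        if top <= 0:
            raise ValueError(
                f"no positive equilibrium: r_max + b*g(Z) = {top:.4g} <= 0"
            )
        return (math.log(top) - c) / a
    a_eff = a + b * u
    if a_eff == 0:
        raise ValueError("degenerate nonlinear form: a + b*g(Z) = 0")
    return (math.log(r_max) - c) / a_eff


def _classify(slope: float) -> str:
    if slope < 1.0:
        return "monotonic damped"
    if slope < 2.0:
        return "oscillatory damped"
    return "unstable"


def stability_slope(spec: ModelSpec, params: Params, Z=None) -> StabilityReport:
    """Slope magnitude ``|dR/dY|`` at the equilibrium K and its regime.

    Closed forms: P, L: a*r_max (Z-invariant for L); V: a*(r_max + b*g(Z));
    N: (a + b*g(Z))*r_max.  The eigenvalue of the map is 1 - slope; the
    steeper the slope, the less stable the equilibrium.
    """
    K = equilibrium(spec, params, Z)
    r_max, a = params.r_max, params.a
    if spec.form in ("P", "L"):
        slope = a * r_max
    elif spec.form == "V":
        u = float(_transform(Z, spec.transform))
        slope = a * (r_max + params.b * u)
    else:
        u = float(_transform(Z, spec.transform))
        slope = (a + params.b * u) * r_max
    slope = abs(slope)
    return StabilityReport(
        K=K, slope_magnitude=slope, eigenvalue=1.0 - slope, regime=_classify(slope)
    )


def partial_slope_z(spec: ModelSpec, params: Params, Y, Z):
    """Partial derivative dR/dZ of the fitted surface at (Y, Z).

    With the log transform: V: b/Z (independent of Y);
    L: -(b/Z)*exp(a*Y + c + b*ln Z);  N: -(b/Z)*Y*exp((a + b*ln Z)*Y + c).
    With the identity transform the 1/Z chain factor is replaced by 1.
    """
    if spec.form == "P":
        raise ValueError("form P has no covariate; dR/dZ undefined")
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    u = _transform(Z, spec.transform)
    dudz = 1.0 / Z if spec.transform == "log" else np.ones_like(Z)
    r_max, a, c, b = params.r_max, params.a, params.c, params.b
    if spec.form == "V":
        out = b * dudz
        out = np.broadcast_to(out, np.broadcast_shapes(Y.shape, Z.shape)).copy()
    elif spec.form == "L":
        out = -b * dudz * np.exp(a * Y + c + b * u)
    else:  # N
        out = -b * dudz * Y * np.exp((a + b * u) * Y + c)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Partial rate correlation function
# ---------------------------------------------------------------------------


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of OLS of y on X (with intercept)."""
    X1 = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    return y - X1 @ beta


def prcf(levels, rates=None, max_lag: int = 4, block: str | None = "block") -> pd.DataFrame:
    """Partial rate correlation function PRCF(1..max_lag).

    PRCF(i) is the partial correlation between R_t and the lagged level
    Y_{t-i}, conditioning on the intermediate lags Y_{t-1}..Y_{t-i+1};
    PRCF(1) is the plain Pearson correlation of (R_t, Y_{t-1}).  Pairs are
    pooled across blocks but lags never cross a block boundary.  The
    approximate 95% significance band is +/- 2/sqrt(n).

    Parameters
    ----------
    levels : pandas.DataFrame or array-like
        Either a long DataFrame with columns ``Y`` and cycle order within
        blocks (column named by `block`; omitted or None => single series),
        or a 1-D array of Y values for a single block.
    rates : ignored unless None
        If None, rates are computed as first differences of ``Y`` within
        blocks (the standard construction).
    max_lag : int
        Largest lag to evaluate.

    Returns
    -------
    pandas.DataFrame with columns lag, prcf, n, band.
    """
    if isinstance(levels, pd.DataFrame):
        if block is not None and block in levels.columns:
            groups = [g["Y"].to_numpy(float) for _, g in levels.groupby(block, sort=True)]
        else:
            groups = [levels["Y"].to_numpy(float)]
    else:
        arr = np.asarray(levels, dtype=float)
        groups = [arr] if arr.ndim == 1 else [row for row in arr]

    rows = []
    for lag in range(1, max_lag + 1):
        resp, lagged, cond = [], [], []
        for y in groups:
            r = np.diff(y)  # R_t for t = 1..len-1, aligned with y[1:]
            # R at index t (1-based within block) pairs with y[t - i]
            for t in range(lag, len(y)):
                resp.append(r[t - 1])
                lagged.append(y[t - lag])
                cond.append([y[t - j] for j in range(1, lag)])
        n = len(resp)
        if n < lag + 2:
            rows.append({"lag": lag, "prcf": np.nan, "n": n, "band": np.nan})
            warnings.warn(f"PRCF lag {lag}: only {n} usable pairs; reported as missing")
            continue
        resp = np.asarray(resp)
        lagged = np.asarray(lagged)
        C = np.asarray(cond, dtype=float).reshape(n, lag - 1)
        if lag == 1:
            coef = np.corrcoef(resp, lagged)[0, 1]
        else:
            e1 = _residualize(resp, C)
            e2 = _residualize(lagged, C)
            coef = np.corrcoef(e1, e2)[0, 1]
        rows.append({"lag": lag, "prcf": float(coef), "n": n, "band": 2.0 / math.sqrt(n)})
    return pd.DataFrame(rows)
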