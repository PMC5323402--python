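"""Nonlinear least-squares fitting of R-function models and AICc multi-model
inference.

The central objects follow the statsmodels idiom: :class:`RFunctionModel` is
built from a model frame (rows of R_t, Y_{t-d} and lagged covariates) and a
:class:`~cropdyn.dynamics.ModelSpec`; its :meth:`~RFunctionModel.fit` returns
an :class:`RFunctionResults` carrying estimates, Jacobian-based standard
errors, asymptotic t-test p-values, AICc, pseudo-R² and a ``summary()`` table.

The maximum rate r_max is not estimated: it is fixed at the largest observed
R_t (per crop), so the free parameters are (a, c) for the pure form and
(a, c, b) otherwise.  Because the exponential response surface makes the
least-squares problem initialization-sensitive, fitting uses a multi-start
grid (a in {0.1, 0.5, 1, 2}; c solving the pure-form equilibrium at the mean
observed level; b in {-0.5, 0, 0.5}) plus a log-linear warm start, keeping
the best converged solution by residual sum of squares.

Model comparison uses the small-sample Akaike criterion for Gaussian errors,

    AICc = n ln(RSS/n) + 2p' + 2p'(p'+1)/(n - p' - 1),   p' = p_free + 1,

(the +1 counts the error variance), Akaike weights
w_i = exp(-Δ_i/2)/Σ_j exp(-Δ_j/2), and the 99% confidence set — the smallest
prefix of weight-sorted candidates whose weights sum to the level.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dynamics import ModelSpec, Params, stability_slope

__all__ = [
    "RFunctionModel",
    "RFunctionResults",
    "enumerate_candidates",
    "fit_model",
    "fit_candidates",
    "aicc",
    "akaike_weights",
    "confidence_set",
    "pseudo_r2",
    "selection_table",
]

_EXP_CLIP = 50.0  # rate-scale residuals are O(1); caps overflow from wild starts


def enumerate_candidates(
    covariates,
    forms=("L", "V", "N"),
    lags=(0, 1),
    interactions=None,
    include_pure: bool = True,
    transform: str = "log",
    known: set | None = None,
) -> list[ModelSpec]:
    """Cartesian product of covariates x forms x covariate lags, de-duplicated.

    Interaction pairs (z1, z2) contribute ratio covariates named ``"z1/z2"``.
    ``known``, when given, is the set of admissible covariate names; an
    unknown name raises.
    """
    covariates = list(covariates)
    if covariates and not forms:
        raise ValueError("no forms given for a non-empty covariate list")
    names = list(covariates)
    for z1, z2 in interactions or []:
        names.append(f"{z1}/{z2}")
        for z in (z1, z2):
            if known is not None and z not in known:
                raise ValueError(f"unknown covariate {z!r}")
    if known is not None:
        for name in covariates:
            if name not in known:
                raise ValueError(f"unknown covariate {name!r}")
    specs, seen = [], set()
    for name, form, lag in itertools.product(names, forms, lags):
        spec = ModelSpec(form=form, covariate=name, transform=transform,
                         lag_covariate=lag)
        if spec.model_id not in seen:
            seen.add(spec.model_id)
            specs.append(spec)
    if include_pure:
        specs.append(ModelSpec(form="P"))
    return specs


def aicc(rss: float, n: int, p_free: int) -> float:
    """Small-sample AIC for a Gaussian NLS fit (error variance counted)."""
    p = p_free + 1
    if n <= p + 2:
        raise ValueError(f"AICc needs n > p_free + 2 (n={n}, p_free={p_free})")
    if rss <= 0:
        warnings.warn("RSS = 0: AICc is -inf (saturated fit)")
        return -math.inf
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-Δ_i/2) / Σ exp(-Δ_j/2) over the candidate set."""
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("need at least one finite AICc value")
    delta = a - a[finite].min()
    w = np.where(finite, np.exp(-np.where(finite, delta, 0.0) / 2.0), 0.0)
    # -inf AICc (saturated) dominates everything
    if np.any(a == -math.inf):
        w = (a == -math.inf).astype(float)
    return w / w.sum()


def confidence_set(weights, level: float = 0.99) -> np.ndarray:
    """Boolean membership flags of the smallest weight-sorted prefix whose
    cumulative weight reaches `level`."""
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    order = np.argsort(-w, kind="stable")
    cum = np.cumsum(w[order])
    k = int(np.searchsorted(cum, level - 1e-12)) + 1
    k = min(k, len(w))
    member = np.zeros(len(w), dtype=bool)
    member[order[:k]] = True
    return member


def pseudo_r2(rss: float, r_values) -> float:
    """1 - RSS/TSS with TSS about the mean rate (Gaussian deviance form)."""
    r = np.asarray(r_values, dtype=float)
    tss = float(((r - r.mean()) ** 2).sum())
    if tss == 0:
        return math.nan
    return 1.0 - rss / tss


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class RFunctionModel:
    """R-function regression model bound to data.

    Parameters
    ----------
    endog : array-like
        Observed rates R_t.
    level_lag : array-like
        Lagged detrended log-yield levels Y_{t-d}.
    covariate : array-like or None
        Raw (untransformed) lagged covariate values Z_{t-d'}; required for
        forms L/V/N.
    spec : ModelSpec
        Which form / covariate / transform to fit.
    r_max : float or None
        Fixed maximum rate; defaults to ``max(endog)``.
    """

    def __init__(self, endog, level_lag, covariate=None, *,
                 spec: ModelSpec, r_max: float | None = None):
        self.spec = spec
        self.endog = np.asarray(endog, dtype=float)
        self.level_lag = np.asarray(level_lag, dtype=float)
        n = self.endog.size
        if self.level_lag.size != n:
            raise ValueError("endog and level_lag lengths differ")
        if spec.form == "P":
            self.u = None
        else:
            if covariate is None:
                raise ValueError(f"form {spec.form} requires a covariate column")
            Z = np.asarray(covariate, dtype=float)
            if Z.size != n:
                raise ValueError("covariate length differs from endog")
            if spec.transform == "log":
                if np.any(Z <= 0):
                    raise ValueError(
                        f"log transform of covariate {spec.covariate!r}: "
                        "non-positive values present"
                    )
                self.u = np.log(Z)
            else:
                self.u = Z
        self.r_max = float(np.max(self.endog)) if r_max is None else float(r_max)
        if n < spec.n_free + 2:
            raise ValueError(
                f"need at least {spec.n_free + 2} rows to fit {spec.n_free} "
                f"parameters (got {n})"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, spec: ModelSpec,
                   r_max: float | None = None) -> "RFunctionModel":
        """Build from a prep.assemble_frame output (columns R, Y_lag, covariates)."""
        cov = None if spec.form == "P" else frame[spec.covariate].to_numpy(float)
        return cls(frame["R"].to_numpy(float), frame["Y_lag"].to_numpy(float),
                   cov, spec=spec, r_max=r_max)

    # -- model surface ------------------------------------------------------

    def _unpack(self, theta):
        if self.spec.form == "P":
            a, c = theta
            return a, c, None
        a, c, b = theta
        return a, c, b

    def predict(self, theta):
        a, c, b = self._unpack(theta)
        Y, u = self.level_lag, self.u
        if self.spec.form == "P":
            ex = np.clip(a * Y + c, None, _EXP_CLIP)
            return self.r_max - np.exp(ex)
        if self.spec.form == "L":
            ex = np.clip(a * Y + c + b * u, None, _EXP_CLIP)
            return self.r_max - np.exp(ex)
        if self.spec.form == "V":
            ex = np.clip(a * Y + c, None, _EXP_CLIP)
            return self.r_max - np.exp(ex) + b * u
        ex = np.clip((a + b * u) * Y + c, None, _EXP_CLIP)
        return self.r_max - np.exp(ex)

    def _residual(self, theta):
        return self.endog - self.predict(theta)

    def _jacobian(self, theta):
        """d(residual)/d(theta); residual = R - model."""
        a, c, b = self._unpack(theta)
        Y, u = self.level_lag, self.u
        form = self.spec.form
        if form == "P":
            E = np.exp(np.clip(a * Y + c, None, _EXP_CLIP))
            return np.column_stack([E * Y, E])
        if form == "L":
            E = np.exp(np.clip(a * Y + c + b * u, None, _EXP_CLIP))
            return np.column_stack([E * Y, E, E * u])
        if form == "V":
            E = np.exp(np.clip(a * Y + c, None, _EXP_CLIP))
            return np.column_stack([E * Y, E, -u])
        E = np.exp(np.clip((a + b * u) * Y + c, None, _EXP_CLIP))
        return np.column_stack([E * Y, E, E * Y * u])

    # -- starts -------------------------------------------------------------

    def _starts(self):
        ybar = float(self.level_lag.mean())
        a_grid = (0.1, 0.5, 1.0, 2.0)
        b_grid = (0.0,) if self.spec.form == "P" else (-0.5, 0.0, 0.5)
        starts = []
        for a0 in a_grid:
            c0 = math.log(self.r_max) - a0 * ybar  # pure-form equilibrium at Ȳ
            for b0 in b_grid:
                starts.append([a0, c0] if self.spec.form == "P" else [a0, c0, b0])
        # log-linear warm start: ln(r_max - R) ≈ a Y + c (+ b u) where defined
        margin = self.r_max - self.endog
        mask = margin > 1e-8
        if mask.sum() >= self.spec.n_free + 1:
            lhs = np.log(margin[mask])
            cols = [self.level_lag[mask], np.ones(mask.sum())]
            if self.spec.form in ("L",):
                cols.append(self.u[mask])
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, lhs, rcond=None)
            if np.all(np.isfinite(beta)):
                if self.spec.form == "P":
                    starts.append([beta[0], beta[1]])
                elif self.spec.form == "L":
                    starts.append([beta[0], beta[1], beta[2]])
                else:
                    starts.append([beta[0], beta[1], 0.0])
        return starts

    def fit(self, tol: float = 1e-10, max_nfev: int = 200) -> "RFunctionResults":
        """Minimize Σ(R_t - model)² over every start; best RSS wins.

        A fit that converges from no start is returned with
        ``converged=False`` (a flagged failure record, not an exception).
        """
        best = None
        for x0 in self._starts():
            r0 = self._residual(np.asarray(x0, dtype=float))
            if not np.all(np.isfinite(r0)):
                continue
            try:
                res = optimize.least_squares(
                    self._residual, x0, jac=self._jacobian,
                    xtol=tol, ftol=tol, gtol=tol, max_nfev=max_nfev,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            rss = float(2 * res.cost)
            if res.success and (best is None or rss < best[0]):
                best = (rss, res)
        if best is None:
            return RFunctionResults(model=self, theta=np.full(self.spec.n_free, np.nan),
                                    rss=math.inf, converged=False)
        rss, res = best
        return RFunctionResults(model=self, theta=res.x, rss=rss, converged=True)


@dataclass
class RFunctionResults:
    """Fit results: estimates, uncertainties, diagnostics and summary()."""

    model: RFunctionModel
    theta: np.ndarray
    rss: float
    converged: bool
    bse: np.ndarray = field(init=False)
    pvalues: np.ndarray = field(init=False)

    def __post_init__(self):
        n, p = self.nobs, self.model.spec.n_free
        if not self.converged:
            self.bse = np.full(p, np.nan)
            self.pvalues = np.full(p, np.nan)
            return
        J = self.model._jacobian(self.theta)
        sigma2 = self.rss / max(n - p, 1)
        try:
            cov = sigma2 * np.linalg.pinv(J.T @ J)
            self.bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            self.bse = np.full(p, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = self.theta / self.bse
        self.pvalues = 2 * stats.t.sf(np.abs(tstat), df=max(n - p, 1))

    # -- accessors ----------------------------------------------------------

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def nobs(self) -> int:
        return self.model.endog.size

    @property
    def param_names(self) -> list[str]:
        return ["a", "c"] if self.spec.form == "P" else ["a", "c", "b"]

    @property
    def params(self) -> Params:
        a, c, b = self.model._unpack(self.theta)
        return Params(r_max=self.model.r_max, a=float(a), c=float(c),
                      b=None if b is None else float(b))

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.nobs, self.spec.n_free)

    @property
    def pseudo_r2(self) -> float:
        return pseudo_r2(self.rss, self.model.endog)

    def stability(self, Z=None):
        """Equilibrium/stability report at covariate value Z (raw scale)."""
        return stability_slope(self.spec, self.params, Z)

    def summary(self) -> str:
        lines = [
            "R-function model results",
            "=" * 56,
            f"form: {self.spec.form:<4} covariate: {self.spec.covariate or '-'}"
            f"  (d'={self.spec.lag_covariate}, {self.spec.transform})",
            f"nobs: {self.nobs}   r_max (fixed): {self.model.r_max:.4g}   "
            f"converged: {self.converged}",
            f"RSS: {self.rss:.6g}   AICc: {self.aicc:.3f}   "
            f"pseudo-R2: {self.pseudo_r2:.3f}",
            "-" * 56,
            f"{'param':>6} {'estimate':>12} {'std err':>10} {'p-value':>10}",
        ]
        for name, est, se, p in zip(self.param_names, self.theta, self.bse, self.pvalues):
            mark = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            lines.append(f"{name:>6} {est:>12.4f} {se:>10.4f} {p:>10.4g} {mark}")
        lines.append("=" * 56)
        return "\n".join(lines)


def fit_model(spec: ModelSpec, frame: pd.DataFrame,
              r_max: float | None = None) -> RFunctionResults:
    """Convenience wrapper: build an RFunctionModel from a frame and fit it."""
    return RFunctionModel.from_frame(frame, spec, r_max=r_max).fit()


def fit_candidates(specs, frame: pd.DataFrame,
                   r_max: float | None = None) -> list[RFunctionResults]:
    """Fit every candidate; failures are flagged records, not exceptions."""
    if r_max is None:
        r_max = float(frame["R"].max())
    out = []
    for spec in specs:
        try:
            out.append(fit_model(spec, frame, r_max=r_max))
        except (ValueError, KeyError) as exc:
            warnings.warn(f"candidate {spec.model_id}: not fit ({exc})")
    return out


def selection_table(fits, level: float = 0.99, crop: str | None = None) -> pd.DataFrame:
    """Ranked candidate-model table (AICc ascending) with ΔAICc, Akaike
    weights and confidence-set membership.

    Ties in AICc are broken by fewer free parameters, then model id.
    Non-converged fits are excluded with a warning.
    """
    ok = [f for f in fits if f.converged]
    for f in fits:
        if not f.converged:
            warnings.warn(f"model {f.spec.model_id} failed to converge; excluded")
    if not ok:
        raise ValueError("no successfully fitted models")
    ok = sorted(ok, key=lambda f: (f.aicc, f.spec.n_free, f.spec.model_id))
    a = np.array([f.aicc for f in ok])
    w = akaike_weights(a)
    member = confidence_set(w, level=level)
    rows = []
    for f, ai, wi, m in zip(ok, a, w, member):
        p = f.params
        sig = {
            name: ("**" if pv < 0.01 else "*" if pv < 0.05 else "")
            for name, pv in zip(f.param_names, f.pvalues)
        }
        rows.append(
            {
                "crop": crop if crop is not None else "",
                "model_id": f.spec.model_id,
                "fit": f.spec.form,
                "variable": f.spec.covariate or "",
                "lag": f.spec.lag_covariate,
                "r_max": f.model.r_max,
                "a": p.a, "a_sig": sig["a"],
                "c": p.c, "c_sig": sig["c"],
                "b": p.b if p.b is not None else np.nan,
                "b_sig": sig.get("b", ""),
                "n": f.nobs,
                "RSS": f.rss,
                "AICc": ai,
                "dAICc": ai - a.min(),
                "w": wi,
                "in_conf_set": bool(m),
                "R2": f.pseudo_r2,
            }
        )
    return pd.DataFrame(rows)
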