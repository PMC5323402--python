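"""R-function evaluation, equilibria, stability and PRCF diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from cropdyn.dynamics import (
    ModelSpec,
    Params,
    equilibrium,
    partial_slope_z,
    prcf,
    predict_rate,
    stability_slope,
)
from cropdyn.synthio import SyntheticConfig, simulate_rate_series

MAIZE_P = Params(r_max=1.20, a=0.93, c=-7.91)


def _random_params(rng, form):
    r_max = rng.uniform(0.5, 2.5)
    a = rng.uniform(0.2, 2.0)
    c = rng.uniform(-12.0, -2.0)
    b = rng.uniform(-0.4, 0.4) if form != "P" else None
    return Params(r_max=r_max, a=a, c=c, b=b)


def _numeric_root(spec, params, Z):
    return brentq(lambda y: predict_rate(spec, params, y, Z), -50.0, 60.0, xtol=1e-13)


class TestPredictRate:
    def test_lateral_with_zero_b_reduces_to_pure(self):
        pL = Params(1.2, 0.9, -7.9, b=0.0)
        pP = Params(1.2, 0.9, -7.9)
        Y = np.linspace(5, 11, 13)
        out_L = predict_rate(ModelSpec("L", covariate="Z"), pL, Y, 3.7)
        out_P = predict_rate(ModelSpec("P"), pP, Y)
        np.testing.assert_array_equal(out_L, out_P)

    def test_vertical_at_z_e_differs_from_pure_by_b(self):
        b = 0.31
        pV = Params(0.97, 0.63, -4.09, b=b)
        pP = Params(0.97, 0.63, -4.09)
        Y = 6.5
        rV = predict_rate(ModelSpec("V", covariate="Z"), pV, Y, np.e)
        rP = predict_rate(ModelSpec("P"), pP, Y)
        assert rV - rP == pytest.approx(b, abs=1e-12)

    def test_pure_rate_vanishes_at_equilibrium(self):
        spec = ModelSpec("P")
        K = _numeric_root(spec, MAIZE_P, None)
        assert predict_rate(spec, MAIZE_P, K) == pytest.approx(0.0, abs=1e-10)

    def test_form_covariate_mismatch_errors(self):
        with pytest.raises(ValueError):
            predict_rate(ModelSpec("P"), MAIZE_P, 8.0, 2.0)
        with pytest.raises(ValueError):
            predict_rate(ModelSpec("V", covariate="Z"), Params(1.2, 0.9, -7.9, 0.3), 8.0)

    def test_log_transform_rejects_nonpositive_covariate(self):
        with pytest.raises(ValueError, match="non-positive"):
            predict_rate(ModelSpec("L", covariate="Z"),
                         Params(1.2, 0.9, -7.9, 0.3), 8.0, -1.0)


class TestEquilibrium:
    def test_lateral_at_unit_covariate_equals_pure(self):
        pL = Params(1.2, 0.93, -7.91, b=5.0)
        kL = equilibrium(ModelSpec("L", covariate="Z"), pL, 1.0)
        kP = equilibrium(ModelSpec("P"), MAIZE_P)
        assert kL == pytest.approx(kP, abs=1e-12)

    def test_maize_pure_equilibrium_near_8_7(self):
        k = equilibrium(ModelSpec("P"), MAIZE_P)
        assert k == pytest.approx(_numeric_root(ModelSpec("P"), MAIZE_P, None), abs=1e-9)
        assert k == pytest.approx(8.70, abs=0.005)

    @pytest.mark.parametrize("form", ["P", "L", "V", "N"])
    def test_rate_vanishes_at_closed_form_root(self, form, rng):
        spec = ModelSpec(form, covariate=None if form == "P" else "Z")
        for _ in range(50):
            params = _random_params(rng, form)
            Z = None if form == "P" else rng.uniform(0.3, 4.0)
            try:
                K = equilibrium(spec, params, Z)
            except ValueError:
                continue  # no positive equilibrium for this draw
            assert predict_rate(spec, params, K, Z) == pytest.approx(0.0, abs=1e-10)

    def test_vertical_no_positive_equilibrium_errors(self):
        p = Params(0.5, 0.9, -7.9, b=2.0)
        with pytest.raises(ValueError, match="no positive equilibrium"):
            equilibrium(ModelSpec("V", covariate="Z"), p, np.exp(-1.0))

    def test_nonlinear_degenerate_errors(self):
        p = Params(1.2, 0.9, -7.9, b=0.45)
        with pytest.raises(ValueError, match="degenerate"):
            equilibrium(ModelSpec("N", covariate="Z"), p, np.exp(-2.0))


class TestStability:
    def test_vertical_with_zero_b_matches_pure_slope(self):
        sV = stability_slope(ModelSpec("V", covariate="Z"),
                             Params(1.2, 0.93, -7.91, b=0.0), 2.5)
        sP = stability_slope(ModelSpec("P"), MAIZE_P)
        assert sV.slope_magnitude == pytest.approx(sP.slope_magnitude, abs=1e-12)

    def test_lateral_slope_invariant_to_covariate(self):
        p = Params(1.2, 0.37, -5.49, b=12.58)
        slopes = [
            stability_slope(ModelSpec("L", covariate="Z"), p, z).slope_magnitude
            for z in (0.2, 1.0, 5.0)
        ]
        assert np.ptp(slopes) < 1e-12
        assert slopes[0] == pytest.approx(1.2 * 0.37, abs=1e-12)

    @pytest.mark.parametrize("form", ["P", "L", "V", "N"])
    def test_closed_form_slope_matches_central_difference(self, form, rng):
        spec = ModelSpec(form, covariate=None if form == "P" else "Z")
        h = 1e-6
        for _ in range(40):
            params = _random_params(rng, form)
            Z = None if form == "P" else rng.uniform(0.3, 4.0)
            try:
                rep = stability_slope(spec, params, Z)
            except ValueError:
                continue
            num = (predict_rate(spec, params, rep.K + h, Z)
                   - predict_rate(spec, params, rep.K - h, Z)) / (2 * h)
            assert abs(num) == pytest.approx(rep.slope_magnitude, abs=1e-6)
            assert rep.eigenvalue == pytest.approx(1 - rep.slope_magnitude, abs=1e-12)

    def test_regime_classification_boundaries(self):
        mk = lambda s: stability_slope(
            ModelSpec("P"), Params(r_max=1.0, a=s, c=-7.0)
        ).regime
        assert mk(0.5) == "monotonic damped"
        assert mk(1.5) == "oscillatory damped"
        assert mk(2.5) == "unstable"

    @pytest.mark.parametrize("a,expected", [(0.7, "monotonic"), (1.5, "oscillatory")])
    def test_noise_free_trajectories_match_regime(self, a, expected):
        """Slope in (0,1): monotone approach to K; in (1,2): alternating signs."""
        cfg = SyntheticConfig(form="P", r_max=1.0, a=a, c=-7.0, noise_sd=0.0,
                              n_blocks=1, n_cycles=25, y0=None, seed=0)
        K = equilibrium(ModelSpec("P"), Params(1.0, a, -7.0))
        cfg = SyntheticConfig(form="P", r_max=1.0, a=a, c=-7.0, noise_sd=0.0,
                              n_blocks=1, n_cycles=25, y0=K - 0.8, seed=0)
        dev = simulate_rate_series(cfg)[0] - K
        assert abs(dev[-1]) < abs(dev[0])
        signs = np.sign(dev[np.abs(dev) > 1e-9])
        if expected == "monotonic":
            assert np.all(signs == signs[0])
        else:
            assert np.all(signs[1:] != signs[:-1])


class TestPartialSlope:
    def test_vertical_is_b_over_z(self):
        p = Params(0.97, 0.63, -4.09, b=0.31)
        got = partial_slope_z(ModelSpec("V", covariate="Z"), p, 6.0, 0.5)
        assert got == pytest.approx(0.31 / 0.5, abs=1e-12)

    def test_vertical_slope_decelerates_with_diversity(self):
        p = Params(0.97, 0.63, -4.09, b=0.31)
        z = np.linspace(0.2, 3.0, 40)
        s = partial_slope_z(ModelSpec("V", covariate="Z"), p, 6.0, z)
        assert np.all(np.diff(s) < 0) and np.all(s > 0)

    @pytest.mark.parametrize("form", ["L", "V", "N"])
    def test_matches_central_difference(self, form, rng):
        spec = ModelSpec(form, covariate="Z")
        h = 1e-7
        for _ in range(20):
            Y, Z = rng.uniform(5, 10), rng.uniform(0.5, 3.0)
            draw = _random_params(rng, form)
            # keep the exponential term O(1) so the central-difference oracle
            # is not dominated by cancellation error
            params = Params(draw.r_max, draw.a,
                            np.log(draw.r_max) - draw.a * Y + rng.uniform(-1, 1),
                            draw.b)
            num = (predict_rate(spec, params, Y, Z + h)
                   - predict_rate(spec, params, Y, Z - h)) / (2 * h)
            assert partial_slope_z(spec, params, Y, Z) == pytest.approx(
                num, rel=5e-6, abs=1e-8
            )

    def test_pure_form_errors(self):
        with pytest.raises(ValueError):
            partial_slope_z(ModelSpec("P"), MAIZE_P, 8.0, 1.0)


class TestPRCF:
    @staticmethod
    def _series(n=120, seed=5):
        cfg = SyntheticConfig(form="P", r_max=1.2, a=0.9, c=-7.9,
                              noise_sd=0.05, n_blocks=1, n_cycles=n, seed=seed)
        return simulate_rate_series(cfg)[0]

    def test_lag1_equals_plain_correlation(self):
        y = self._series()
        tab = prcf(y, max_lag=3)
        r = np.diff(y)
        expect = np.corrcoef(r, y[:-1])[0, 1]
        assert tab.loc[0, "prcf"] == pytest.approx(expect, abs=1e-12)
        assert tab.loc[0, "band"] == pytest.approx(2 / np.sqrt(len(r)), abs=1e-12)

    def test_noise_free_ricker_shows_first_order_negative_feedback(self):
        K = equilibrium(ModelSpec("P"), Params(1.2, 0.9, -7.9))
        cfg = SyntheticConfig(form="P", r_max=1.2, a=0.9, c=-7.9, noise_sd=0.0,
                              n_blocks=1, n_cycles=500, y0=K - 1.0, seed=0)
        y = simulate_rate_series(cfg)[0]
        tab = prcf(y, max_lag=1)
        assert tab.loc[0, "prcf"] < -tab.loc[0, "band"]

    def test_lag3_matches_brute_force_partial_correlation(self):
        y = self._series(n=200, seed=8)
        tab = prcf(y, max_lag=3)
        # brute force: residualize R_t and Y_{t-3} on (Y_{t-1}, Y_{t-2})
        r = np.diff(y)
        resp, lag3, c1, c2 = [], [], [], []
        for t in range(3, len(y)):
            resp.append(r[t - 1]); lag3.append(y[t - 3])
            c1.append(y[t - 1]); c2.append(y[t - 2])
        X = np.column_stack([np.ones(len(resp)), c1, c2])

        def resid(v):
            beta, *_ = np.linalg.lstsq(X, np.asarray(v), rcond=None)
            return np.asarray(v) - X @ beta

        expect = np.corrcoef(resid(resp), resid(lag3))[0, 1]
        assert tab.loc[2, "prcf"] == pytest.approx(expect, abs=1e-10)

    def test_lag2_matches_pingouin_partial_correlation(self):
        pingouin = pytest.importorskip("pingouin")
        y = self._series(n=150, seed=3)
        r = np.diff(y)
        df = pd.DataFrame({"R": r[1:], "Ylag2": y[:-2], "Ylag1": y[1:-1]})
        expect = pingouin.partial_corr(df, x="R", y="Ylag2", covar="Ylag1")["r"].iloc[0]
        tab = prcf(y, max_lag=2)
        assert tab.loc[1, "prcf"] == pytest.approx(expect, abs=1e-10)

    def test_lags_do_not_cross_block_boundaries(self):
        levels = pd.DataFrame({
            "block": ["a"] * 6 + ["b"] * 6,
            "Y": np.concatenate([self._series(6, 1), self._series(6, 2)]),
        })
        tab = prcf(levels, max_lag=2)
        # per block of length 6: 5 lag-1 pairs, 4 lag-2 pairs
        assert tab.loc[0, "n"] == 10
        assert tab.loc[1, "n"] == 8

    def test_insufficient_pairs_reported_missing(self):
        with pytest.warns(UserWarning, match="usable pairs"):
            tab = prcf(np.array([8.0, 8.1, 8.05, 8.02]), max_lag=3)
        assert np.isnan(tab.loc[2, "prcf"])
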