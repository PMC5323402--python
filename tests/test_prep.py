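"""Detrending, rate construction, climate summaries and frame assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cropdyn.prep import (
    assemble_frame,
    detrend_quadratic,
    growing_season_summary,
    rate_of_increase,
)
from cropdyn.synthio import SyntheticConfig, generate_dataset


def _yields(years, logy, crop="maize", treatment="T1", replicate=1):
    return pd.DataFrame({
        "year": years, "crop": crop, "treatment": treatment,
        "replicate": replicate, "yield_kg_ha": np.exp(logy),
    })


class TestDetrend:
    def test_exact_quadratic_collapses_to_grand_mean(self):
        years = np.arange(1996, 2026, 3)
        t = years - 1996
        logy = 7 + 0.1 * t + 0.01 * t**2
        levels, _ = detrend_quadratic(_yields(years, logy))
        np.testing.assert_allclose(levels["Y"], logy.mean(), atol=1e-9)

    def test_residuals_orthogonal_to_trend_basis(self, rng):
        years = np.arange(1996, 2026, 3)
        logy = 8 + rng.normal(0, 0.3, size=len(years))
        levels, _ = detrend_quadratic(_yields(years, logy))
        resid = levels["Y"] - levels["Y"].mean()
        for basis in (years.astype(float), years.astype(float) ** 2):
            r = np.corrcoef(resid, basis - basis.mean())[0, 1]
            assert abs(r) < 1e-10

    def test_recovers_injected_trend_coefficients(self):
        # noise-free series held at its fixed point: log yield = K + trend,
        # so the fitted quadratic must equal the injected trend exactly
        t1, t2 = 0.04, -0.002
        cfg = SyntheticConfig(form="P", r_max=1.2, a=0.9, c=-7.9, noise_sd=0.0,
                              n_blocks=4, n_cycles=7, seed=0, trend=(t1, t2),
                              start_year=1996)
        ds = generate_dataset(cfg)
        levels, trends = detrend_quadratic(ds.yields)
        c0, c1, c2 = trends["maize"]
        # injected poly in (year - 1996); expand to raw calendar-year basis
        assert c2 == pytest.approx(t2, abs=1e-8)
        assert c1 == pytest.approx(t1 - 2 * t2 * 1996, rel=1e-6)
        # and the detrended series is flat at the grand mean
        assert np.ptp(levels["Y"].to_numpy()) < 1e-8

    def test_detrended_rates_recover_simulated_rates_noise_free(self):
        cfg = SyntheticConfig(form="P", r_max=1.2, a=0.9, c=-7.9, noise_sd=0.0,
                              n_blocks=2, n_cycles=6, seed=0, trend=(0.05, -0.001))
        ds = generate_dataset(cfg)
        truth_Y = np.asarray(ds.truth["log_yield"])
        levels, _ = detrend_quadratic(ds.yields)
        rates = rate_of_increase(levels)
        for b in range(2):
            got = rates.loc[rates["block"] == f"maize|T1|R{b+1}", "R"].to_numpy()
            np.testing.assert_allclose(got, np.diff(truth_Y[b]), atol=1e-10)

    def test_too_few_years_rejected(self):
        years = [1996, 1999, 2002]
        with pytest.raises(ValueError, match="4 distinct"):
            detrend_quadratic(_yields(np.array(years), np.array([7.0, 7.1, 7.2])))

    def test_nonpositive_yield_rejected(self):
        df = _yields(np.arange(1996, 2011, 3), np.full(5, 7.0))
        df.loc[2, "yield_kg_ha"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            detrend_quadratic(df)


class TestRates:
    def test_direct_differences(self):
        levels = pd.DataFrame({"block": "x", "crop": "maize",
                               "t": [0, 1, 2], "Y": [7.0, 7.5, 7.2]})
        r = rate_of_increase(levels)
        np.testing.assert_allclose(r["R"], [0.5, -0.3], atol=1e-15)

    def test_constant_series_gives_zero_rates(self):
        levels = pd.DataFrame({"block": "x", "crop": "maize",
                               "t": range(6), "Y": [8.0] * 6})
        r = rate_of_increase(levels)
        assert len(r) == 5 and (r["R"] == 0).all()

    def test_single_cycle_block_dropped_with_warning(self):
        levels = pd.DataFrame({"block": ["a", "b", "b"], "crop": "maize",
                               "t": [0, 0, 1], "Y": [8.0, 8.0, 8.2]})
        with pytest.warns(UserWarning, match="single cycle"):
            r = rate_of_increase(levels)
        assert list(r["block"]) == ["b"]

    def test_detrend_then_difference_equals_difference_of_detrended(self, rng):
        """Differencing is linear: R_t from detrended levels equals the raw
        log-yield difference minus the fitted-trend difference."""
        years = np.arange(1996, 2026, 3)
        logy = 8 + 0.02 * (years - 1996) + rng.normal(0, 0.2, len(years))
        levels, trends = detrend_quadratic(_yields(years, logy))
        rates = rate_of_increase(levels)
        c0, c1, c2 = trends["maize"]
        trend_vals = c0 + c1 * years + c2 * years.astype(float) ** 2
        expect = np.diff(logy) - np.diff(trend_vals)
        np.testing.assert_allclose(rates["R"], expect, atol=1e-12)


class TestClimateSummary:
    @staticmethod
    def _daily(dates, tmin, tmax, prec):
        return pd.DataFrame({"date": dates, "precip_mm": prec,
                             "tmin_c": tmin, "tmax_c": tmax})

    def test_constant_days(self):
        dates = pd.date_range("2000-06-01", "2000-06-10").strftime("%Y-%m-%d")
        cl = self._daily(dates, 10.0, 20.0, 0.0)
        s = growing_season_summary(cl, window=((6, 1), (6, 10))).loc[2000]
        assert (s["tM"], s["tMin"], s["tMax"]) == (15.0, 10.0, 20.0)

    def test_three_day_toy_values(self):
        dates = ["2000-06-01", "2000-06-02", "2000-06-03"]
        cl = self._daily(dates, [10, 12, 8], [20, 30, 25], [0, 5, 1])
        s = growing_season_summary(cl, window=((6, 1), (6, 3))).loc[2000]
        assert s["tM"] == pytest.approx(17.5)
        assert s["tmax"] == pytest.approx(25.0)
        assert s["tmin"] == pytest.approx(10.0)
        assert s["tMax"] == 30 and s["tMin"] == 8
        assert s["precM"] == pytest.approx(2.0) and s["precMax"] == 5.0

    def test_single_day_window(self):
        cl = self._daily(["2000-07-04"], [12.0], [28.0], [3.0])
        s = growing_season_summary(cl, window=((7, 4), (7, 4))).loc[2000]
        assert s["tM"] == 20.0 and s["precM"] == 3.0 and s["precMax"] == 3.0

    def test_missing_days_listed(self):
        dates = ["2000-06-01", "2000-06-03"]
        cl = self._daily(dates, [10, 8], [20, 25], [0, 1])
        with pytest.raises(ValueError, match="2000-06-02"):
            growing_season_summary(cl, window=((6, 1), (6, 3)))

    def test_ordering_invariant_on_random_days(self, rng):
        dates = pd.date_range("2001-05-01", "2001-09-30").strftime("%Y-%m-%d")
        n = len(dates)
        tmin = rng.normal(12, 4, n)
        tmax = tmin + rng.uniform(0.5, 14, n)
        cl = self._daily(dates, tmin, tmax, rng.gamma(0.8, 6, n))
        s = growing_season_summary(cl, crop="maize").loc[2001]
        assert s["tMin"] <= s["tmin"] <= s["tM"] <= s["tmax"] <= s["tMax"]
        assert s["precMax"] >= s["precM"] >= 0


class TestAssembleFrame:
    @staticmethod
    def _block(n=6, block="maize|T1|R1"):
        levels = pd.DataFrame({"block": block, "crop": "maize",
                               "t": range(n), "Y": 8 + 0.1 * np.arange(n)})
        return levels, rate_of_increase(levels)

    def test_six_cycles_give_five_rows(self):
        levels, rates = self._block(6)
        z = pd.Series(np.linspace(1, 2, 6), index=range(6))
        frame = assemble_frame(rates, levels, {"z": z}, d=1, d_prime=0)
        assert len(frame) == 5
        np.testing.assert_allclose(frame["Y_lag"], levels["Y"][:5])

    def test_feedback_lag_two_drops_one_more_row(self):
        levels, rates = self._block(6)
        frame = assemble_frame(rates, levels, d=2)
        assert len(frame) == 4
        assert frame.attrs["n_dropped"] == 1

    def test_identical_interaction_pair_is_log_zero(self):
        levels, rates = self._block(5)
        z = pd.Series(np.linspace(1, 2, 5), index=range(5))
        frame = assemble_frame(rates, levels, {"z1": z, "z2": z},
                               interactions=[("z1", "z2")])
        np.testing.assert_allclose(np.log(frame["z1/z2"]), 0.0, atol=1e-15)

    def test_zero_covariate_with_log_transform_errors(self):
        levels, rates = self._block(5)
        z = pd.Series([1.0, 0.0, 1.0, 1.0, 1.0], index=range(5))
        with pytest.raises(ValueError, match="'z'"):
            assemble_frame(rates, levels, {"z": z}, transform="log")
        # identity transform must be an explicit escape hatch
        frame = assemble_frame(rates, levels, {"z": z}, transform="identity")
        assert len(frame) == 4

    def test_covariate_lag_one_uses_previous_cycle(self):
        levels, rates = self._block(4)
        z = pd.Series([10.0, 20.0, 30.0, 40.0], index=range(4))
        frame = assemble_frame(rates, levels, {"z": z}, d_prime=1)
        np.testing.assert_allclose(frame["z"], [10.0, 20.0, 30.0])

    @given(lengths=st.lists(st.integers(min_value=2, max_value=9),
                            min_size=1, max_size=4),
           d=st.sampled_from([1, 2]), dp=st.sampled_from([0, 1]))
    def test_row_count_is_exact_function_of_lags(self, lengths, d, dp):
        levels = pd.concat([
            pd.DataFrame({"block": f"b{i}", "crop": "c", "t": range(n),
                          "Y": 8 + 0.01 * np.arange(n)})
            for i, n in enumerate(lengths)
        ], ignore_index=True)
        rates = rate_of_increase(levels)
        z = {f"b{i}": pd.Series(np.ones(n), index=range(n))
             for i, n in enumerate(lengths)}
        zser = pd.concat(z, names=["block"])
        frame = assemble_frame(rates, levels, {"z": zser}, d=d, d_prime=dp)
        expect = sum(max(0, n - max(d, dp)) for n in lengths)
        assert len(frame) == expect
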