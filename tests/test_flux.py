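"""Flux mini-model: light-use-efficiency algebra, water-balance closure,
modifier ranges, fast/tape path agreement and the differentiability contract."""

import numpy as np
import pandas as pd
import pytest

from pinneco import autodiff as ad
from pinneco import flux


def _day(T=15.0, D=0.8, phi=30.0, R=0.0, fappfd=0.8, co2=390.0):
    return {"T": T, "D": D, "phi": phi, "R": R, "fappfd": fappfd, "co2": co2}


class TestGppStep:
    def test_zero_absorption_kills_productivity(self):
        params = flux.PMParams.defaults()
        mods = flux.ModifierSet(f_temp=0.9, f_vpd=0.8, f_wp=1.0, f_we=1.0)
        assert flux.gpp_step(_day(fappfd=0.0), mods, params) == 0.0

    def test_identity_modifiers_reduce_to_beta_phi_fappfd(self):
        params = flux.PMParams.defaults(beta=1.0)
        mods = flux.ModifierSet(f_temp=1.0, f_vpd=1.0, f_wp=1.0, f_we=1.0)
        assert flux.gpp_step(_day(phi=10.0, fappfd=0.5), mods, params) == pytest.approx(5.0)

    def test_full_year_matches_spreadsheet_style_reevaluation(self, climate_year):
        """Re-derive P on sampled days by substituting into the closed forms,
        carrying the temperature EMA and soil pool along independently."""
        params = flux.PMParams.defaults()
        series = flux.run_pm(climate_year, params)
        p = {n: flux.PARAM_TABLE[n][0] for n in flux.PARAM_NAMES}
        T = climate_year["T"].to_numpy()
        soil_prev = 0.7 * p["capacity"]
        ts = T[0]
        sampled = {}
        for k in range(len(climate_year)):
            if k > 0:
                ts += (T[k] - ts) / p["tau_temp"]
            row = climate_year.iloc[k]
            f_t = 1.0 / (1.0 + np.exp(-p["k_temp"] * (ts - p["t_opt"])))
            f_d = np.exp(-p["kappa_vpd"] * row["D"])
            w = soil_prev / p["capacity"]
            f_w = min(1.0, max(0.0, (w - p["wp_lo"]) / (p["wp_hi"] - p["wp_lo"])))
            sampled[k] = p["beta"] * row["phi"] * row["fappfd"] * f_t * f_d * f_w
            soil_prev = np.asarray(series.theta_soil)[k]
        check_days = list(range(0, 365, 36))
        for k in check_days:
            np.testing.assert_allclose(np.asarray(series.P)[k], sampled[k], rtol=1e-10)


class TestWaterBalance:
    def test_no_fluxes_leave_pools_unchanged(self):
        params = flux.PMParams.defaults()
        state = flux.FluxState(theta_soil=100.0, theta_snow=0.0)
        new, runoff = flux.water_balance_step(state, _day(T=10.0, R=0.0), params, gpp=0.0, f_we=0.5)
        assert new.theta_soil == 100.0 and new.theta_snow == 0.0 and runoff == 0.0

    def test_cold_precipitation_routes_to_snow(self):
        params = flux.PMParams.defaults()
        state = flux.FluxState(theta_soil=100.0, theta_snow=2.0)
        new, runoff = flux.water_balance_step(state, _day(T=-10.0, R=5.0), params, gpp=0.0, f_we=0.5)
        assert new.theta_snow == pytest.approx(7.0)
        assert new.theta_soil == pytest.approx(100.0)
        assert runoff == 0.0

    def test_daily_balance_closes_over_a_year(self, climate_year):
        params = flux.PMParams.defaults()
        series = flux.run_pm(climate_year, params)
        theta = np.asarray(series.theta)
        prev = np.concatenate([[0.7 * flux.PARAM_TABLE["capacity"][0]], theta[:-1]])
        closure = theta - prev - (
            climate_year["R"].to_numpy() - np.asarray(series.E) - np.asarray(series.runoff)
        )
        assert np.max(np.abs(closure)) < 1e-9

    def test_non_finite_covariates_rejected(self):
        params = flux.PMParams.defaults()
        state = flux.FluxState(theta_soil=100.0)
        with pytest.raises(ValueError, match="non-finite"):
            flux.water_balance_step(state, _day(T=np.nan), params, gpp=0.0, f_we=0.5)


class TestRunPm:
    def test_zero_rain_high_vpd_soil_never_increases(self, climate_year):
        cov = climate_year.copy()
        cov["R"] = 0.0
        cov["T"] = np.abs(cov["T"]) + 5.0  # no snow branch
        series = flux.run_pm(cov, flux.PMParams.defaults())
        soil = np.asarray(series.theta_soil)
        assert np.all(np.diff(soil) <= 1e-12)

    def test_doubling_beta_doubles_gpp_everywhere(self, climate_year):
        base = flux.run_pm(climate_year, flux.PMParams.defaults(beta=0.5))
        double = flux.run_pm(climate_year, flux.PMParams.defaults(beta=1.0))
        # soil feedback through E changes the water pools, so compare day 1 on
        # and re-run with modifiers pinned by identical water: day 0 is exact
        np.testing.assert_allclose(np.asarray(double.P)[0], 2 * np.asarray(base.P)[0], rtol=1e-12)

    def test_modifiers_stay_in_unit_interval(self, climate_year):
        params = flux.PMParams.defaults()
        series = flux.run_pm(climate_year, params)
        # implied joint modifier product: P / (beta phi fappfd) must be in [0, 1]
        denom = params["beta"] * climate_year["phi"].to_numpy() * climate_year["fappfd"].to_numpy()
        ok = denom > 0
        ratio = np.asarray(series.P)[ok] / denom[ok]
        assert np.all(ratio >= 0.0) and np.all(ratio <= 1.0 + 1e-12)

    def test_monotone_in_radiation_and_absorption_per_day(self, climate_year):
        """Raising one day's radiation (or absorbed fraction) never lowers
        that day's productivity; days with untouched inputs and state are
        unchanged.  (A global increase is not pointwise monotone: extra
        productivity dries the soil and can reduce later days.)"""
        params = flux.PMParams.defaults()
        base = np.asarray(flux.run_pm(climate_year, params).P)
        for col in ("phi", "fappfd"):
            for day in (30, 180, 300):
                mod = climate_year.copy()
                scale = 1.3 if col == "phi" else 0.99 / max(mod.loc[day, col], 1e-9)
                mod.loc[day, col] = mod.loc[day, col] * max(scale, 1.0)
                p_mod = np.asarray(flux.run_pm(mod, params).P)
                assert p_mod[day] >= base[day] - 1e-12
                np.testing.assert_allclose(p_mod[:day], base[:day])

    def test_forward_run_is_deterministic(self, climate_year):
        params = flux.PMParams.defaults()
        a = flux.run_pm(climate_year, params)
        b = flux.run_pm(climate_year, params)
        np.testing.assert_array_equal(np.asarray(a.P), np.asarray(b.P))

    def test_fast_and_generic_paths_agree(self, climate_year):
        params = flux.PMParams.defaults()
        fast = flux.run_pm(climate_year, params, backend="fast")
        generic = flux.run_pm(climate_year, params, backend="generic")
        for field in ("P", "E", "theta_soil", "theta_snow", "runoff"):
            np.testing.assert_allclose(
                np.asarray(getattr(fast, field)),
                np.asarray(ad.value_of(getattr(generic, field))),
                rtol=1e-10,
                atol=1e-12,
            )

    def test_batched_parameters_match_individual_runs(self, climate_year):
        betas = np.array([0.4, 0.7, 1.0])
        batched = flux.run_pm(climate_year, flux.PMParams.defaults(beta=betas))
        assert np.asarray(batched.P).shape == (3, len(climate_year))
        for i, b in enumerate(betas):
            single = flux.run_pm(climate_year, flux.PMParams.defaults(beta=float(b)))
            np.testing.assert_allclose(np.asarray(batched.P)[i], np.asarray(single.P))

    def test_gap_in_daily_series_rejected(self, climate_year):
        broken = pd.concat([climate_year.iloc[:100], climate_year.iloc[150:]])
        with pytest.raises(ValueError, match="gaps"):
            flux.run_pm(broken, flux.PMParams.defaults())

    def test_gradients_of_mean_p_match_finite_differences(self, climate_year):
        vals = {n: flux.PARAM_TABLE[n][0] for n in flux.PARAM_NAMES}
        tens = {n: ad.Tensor(v, requires_grad=True) for n, v in vals.items()}
        out = flux.run_pm(climate_year, flux.PMParams(dict(tens))).P.mean()
        out.backward()
        for name in flux.PARAM_NAMES:
            h = max(1e-6 * abs(vals[name]), 1e-7)
            up, dn = dict(vals), dict(vals)
            up[name] += h
            dn[name] -= h
            fp = np.asarray(flux.run_pm(climate_year, flux.PMParams(up)).P).mean()
            fm = np.asarray(flux.run_pm(climate_year, flux.PMParams(dn)).P).mean()
            fd = (fp - fm) / (2 * h)
            assert abs(float(tens[name].grad) - fd) <= 1e-4 * max(abs(fd), 1e-8), name


def test_params_config_roundtrip(tmp_path):
    params = flux.PMParams.defaults(beta=0.9, capacity=150.0)
    path = tmp_path / "pm.csv"
    params.to_config(path)
    back = flux.PMParams.from_config(path)
    assert back["beta"] == pytest.approx(0.9)
    assert back["capacity"] == pytest.approx(150.0)


def test_params_outside_bounds_rejected():
    with pytest.raises(ValueError, match="bounds"):
        flux.PMParams.defaults(beta=5.0)
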