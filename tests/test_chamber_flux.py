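"""Static-chamber flux estimation: regression, ideal-gas conversion,
interpolation and cumulation."""

import dataclasses
import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from agroflux.chambers import (
    ChamberError,
    ChamberGeometry,
    ConcentrationSeries,
    cumulate_emissions,
    estimate_flux,
    fit_concentration_slope,
    interpolate_daily_flux,
    slope_to_mass_flux,
)
from agroflux.synth import mass_flux_to_slope


def make_series(ppm, t=None, gas="CO2", temp_k=298.15, p_pa=101_325.0):
    if t is None:
        t = np.arange(len(ppm)) * 20.0
    return ConcentrationSeries(
        plot_id="P1", chamber_id="c1", date=dt.date(2021, 6, 1), gas=gas,
        elapsed_s=np.asarray(t, float), ppm=np.asarray(ppm, float),
        air_temp_k=temp_k, pressure_pa=p_pa,
    )


class TestSlopeFit:
    def test_exact_line(self):
        t = np.arange(0, 301, 20.0)
        slope, r2 = fit_concentration_slope(make_series(400 + 0.1 * t, t))
        assert slope == pytest.approx(0.1, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_series_zero_slope(self):
        slope, _ = fit_concentration_slope(make_series([400.0] * 16))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_matches_closed_form_least_squares(self):
        """OLS slope equals the covariance/variance ratio computed from
        first principles on the same draw."""
        rng = np.random.default_rng(42)
        t = np.arange(0, 301, 20.0)
        c = 400 + 0.1 * t + rng.normal(0, 1.0, t.size)
        slope, r2 = fit_concentration_slope(make_series(c, t))
        tbar, cbar = t.mean(), c.mean()
        expected = float(np.sum((t - tbar) * (c - cbar)) / np.sum((t - tbar) ** 2))
        assert slope == pytest.approx(expected, rel=1e-12)
        sse = np.sum((c - (cbar + expected * (t - tbar))) ** 2)
        assert r2 == pytest.approx(1 - sse / np.sum((c - cbar) ** 2), rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ChamberError, match=">= 3"):
            make_series([400.0, 401.0])


class TestIdealGasConversion:
    # frozen independent hand evaluation: slope 0.1 ppm/s CO2,
    # V = 0.005 m3, A = pi*(0.1015)^2, T = 298.15 K, P = 101325 Pa
    AREA = 0.03236547
    HEADSPACE_MOL = 0.20437022
    MOLAR = 6.31445192e-07      # mol m-2 s-1
    MASS_CO2C = 0.65528250      # g C m-2 day-1

    def test_basal_area_from_diameter(self):
        geom = ChamberGeometry()
        assert geom.area == pytest.approx(math.pi * (0.203 / 2) ** 2, rel=1e-12)
        assert geom.area == pytest.approx(self.AREA, abs=1e-7)

    def test_hand_oracle(self):
        geom = ChamberGeometry()
        molar, mass = slope_to_mass_flux(0.1, geom, 298.15, 101_325.0, "CO2")
        assert molar == pytest.approx(self.MOLAR, rel=1e-6)
        assert mass == pytest.approx(self.MASS_CO2C, rel=1e-6)

    def test_zero_slope_zero_flux(self):
        molar, mass = slope_to_mass_flux(0.0, ChamberGeometry(), 298.15, 101_325.0, "N2O")
        assert molar == 0.0 and mass == 0.0

    def test_linear_in_slope(self):
        geom = ChamberGeometry()
        _, m1 = slope_to_mass_flux(0.05, geom, 298.15, 101_325.0, "CO2")
        _, m2 = slope_to_mass_flux(0.10, geom, 298.15, 101_325.0, "CO2")
        assert m2 == pytest.approx(2 * m1, rel=1e-12)

    def test_n2o_counts_two_nitrogens(self):
        _, m_n2o = slope_to_mass_flux(0.1, ChamberGeometry(), 298.15, 101_325.0, "N2O")
        _, m_co2 = slope_to_mass_flux(0.1, ChamberGeometry(), 298.15, 101_325.0, "CO2")
        assert m_n2o / m_co2 == pytest.approx(28.014 / 12.011, rel=1e-9)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ChamberError):
            slope_to_mass_flux(0.1, ChamberGeometry(), -1.0, 101_325.0, "CO2")

    def test_negative_slope_gives_negative_flux(self):
        """Uptake is retained, not truncated."""
        molar, mass = slope_to_mass_flux(-0.01, ChamberGeometry(), 298.15, 101_325.0, "N2O")
        assert molar < 0 and mass < 0


class TestRoundTripRecovery:
    def test_zero_noise_recovers_generating_flux(self):
        """Forward ramp from a known flux, then the estimation chain,
        returns that flux to floating tolerance."""
        geom = ChamberGeometry()
        true_flux = 3.7  # g CO2-C m-2 day-1
        slope = mass_flux_to_slope(true_flux, geom, "CO2", 298.15, 101_325.0)
        t = np.arange(16) * 20.0
        est = estimate_flux(make_series(420 + slope * t, t), geom)
        assert est.mass_flux == pytest.approx(true_flux, rel=1e-10)
        assert est.qc_flags == ()

    def test_noisy_ensemble_unbiased(self):
        """200 chambers at one true flux with 1-ppm noise: ensemble mean
        within 2 standard errors of truth."""
        geom = ChamberGeometry()
        rng = np.random.default_rng(7)
        true_flux = 3.7
        slope = mass_flux_to_slope(true_flux, geom, "CO2", 298.15, 101_325.0)
        t = np.arange(16) * 20.0
        est = []
        for _ in range(200):
            c = 420 + slope * t + rng.normal(0, 1.0, 16)
            est.append(estimate_flux(make_series(c, t), geom).mass_flux)
        est = np.asarray(est)
        se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - true_flux) < 2 * se

    def test_flat_noisy_trace_not_flagged(self):
        """Near-zero flux legitimately has low r2; it is not flagged."""
        rng = np.random.default_rng(3)
        c = 420 + rng.normal(0, 1.0, 16)
        est = estimate_flux(make_series(c), ChamberGeometry())
        assert est.qc_flags == ()

    def test_steep_scattered_trace_flagged_but_retained(self):
        rng = np.random.default_rng(5)
        t = np.arange(16) * 20.0
        c = 420 + 0.05 * t + rng.normal(0, 15.0, 16)
        est = estimate_flux(make_series(c, t), ChamberGeometry())
        assert "low-r2" in est.qc_flags
        assert math.isfinite(est.mass_flux)


class TestDailyInterpolation:
    def obs(self, rows):
        return pd.DataFrame(rows, columns=["plot_id", "gas", "date", "mass_flux_g_m2_d"])

    def test_constant_endpoints(self):
        daily = interpolate_daily_flux(
            self.obs([("P1", "CO2", dt.date(2021, 6, 1), 2.0),
                      ("P1", "CO2", dt.date(2021, 6, 5), 2.0)])
        )
        assert len(daily) == 5
        assert np.allclose(daily["mass_flux_g_m2_d"], 2.0)

    def test_linear_ramp(self):
        daily = interpolate_daily_flux(
            self.obs([("P1", "CO2", dt.date(2021, 6, 1), 1.0),
                      ("P1", "CO2", dt.date(2021, 6, 5), 3.0)])
        )
        assert np.allclose(daily["mass_flux_g_m2_d"], [1.0, 1.5, 2.0, 2.5, 3.0])

    def test_single_observation(self):
        daily = interpolate_daily_flux(self.obs([("P1", "N2O", dt.date(2021, 6, 1), 0.4)]))
        assert len(daily) == 1
        assert daily["mass_flux_g_m2_d"].iloc[0] == pytest.approx(0.4)

    def test_same_day_replicates_averaged(self):
        daily = interpolate_daily_flux(
            self.obs([("P1", "CO2", dt.date(2021, 6, 1), 1.0),
                      ("P1", "CO2", dt.date(2021, 6, 1), 3.0)])
        )
        assert daily["mass_flux_g_m2_d"].iloc[0] == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ChamberError):
            interpolate_daily_flux(self.obs([]))


class TestCumulation:
    def daily(self, vals, start=dt.date(2021, 6, 1)):
        days = pd.date_range(start, periods=len(vals), freq="D")
        return pd.DataFrame(
            {"plot_id": "P1", "gas": "CO2", "date": days, "mass_flux_g_m2_d": vals}
        )

    def test_constant_series_unit_conversion(self):
        out = cumulate_emissions(self.daily([1.0] * 10), dt.date(2021, 6, 1), dt.date(2021, 6, 10))
        assert out[0].cumulative_kg_ha == pytest.approx(100.0)

    def test_ramp_total(self):
        out = cumulate_emissions(
            self.daily([1.0, 1.5, 2.0, 2.5, 3.0]), dt.date(2021, 6, 1), dt.date(2021, 6, 5)
        )
        assert out[0].cumulative_kg_ha == pytest.approx(100.0)  # 10 g/m2

    def test_all_zero(self):
        out = cumulate_emissions(self.daily([0.0] * 5), dt.date(2021, 6, 1), dt.date(2021, 6, 5))
        assert out[0].cumulative_kg_ha == 0.0

    def test_window_clipped_and_reported(self):
        out = cumulate_emissions(self.daily([1.0] * 5), dt.date(2021, 5, 1), dt.date(2021, 10, 1))
        assert out[0].clipped
        assert out[0].start == dt.date(2021, 6, 1)

    def test_disjoint_window_additivity(self):
        daily = self.daily([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        whole = cumulate_emissions(daily, dt.date(2021, 6, 1), dt.date(2021, 6, 6))
        a = cumulate_emissions(daily, dt.date(2021, 6, 1), dt.date(2021, 6, 3))
        b = cumulate_emissions(daily, dt.date(2021, 6, 4), dt.date(2021, 6, 6))
        assert whole[0].cumulative_kg_ha == pytest.approx(
            a[0].cumulative_kg_ha + b[0].cumulative_kg_ha
        )

    def test_empty_intersection_rejected(self):
        with pytest.raises(ChamberError, match="does not"):
            cumulate_emissions(self.daily([1.0] * 5), dt.date(2022, 1, 1), dt.date(2022, 2, 1))
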