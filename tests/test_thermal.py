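"""Thermal response: mass classes, Arrhenius fits, Q10, anomalies."""

import math

import numpy as np
import pandas as pd
import pytest

from thermoscale import (
    assign_mass_classes,
    compute_q10,
    compute_temperature_anomaly,
    fit_arrhenius,
    inverse_thermal_energy,
    q10_table,
    slope_heterogeneity_test,
)
from thermoscale.constants import BOLTZMANN_EV_PER_K, KELVIN_OFFSET

PRINTED_K = 8.167e-5  # transposed-digit variant of the Boltzmann constant


def arrhenius_records(e_ev, temps, masses, c=1.0, site="S", b=1.0,
                      k=BOLTZMANN_EV_PER_K, offset=0.0):
    """Noise-free records following ln(SMR/M) = const - E/kT, reusing the
    same masses at every temperature so mass and temperature are orthogonal."""
    rows = []
    j = 0
    for t in temps:
        inv = 1.0 / (k * (t + KELVIN_OFFSET))
        for m in masses:
            ms = c * math.exp(offset - e_ev * inv) * m ** (b - 1.0)
            rows.append(
                {"individual_id": f"i{j}", "site": site, "temp_level_c": t,
                 "dry_mass_mg": m, "mass_specific_smr": ms,
                 "smr_j_per_day": ms * m}
            )
            j += 1
    return pd.DataFrame(rows)


class TestMassClasses:
    def test_nine_mass_example(self):
        rec = pd.DataFrame(
            {"individual_id": [f"i{j}" for j in range(9)],
             "dry_mass_mg": np.arange(1.0, 10.0)}
        )
        out, assignment = assign_mass_classes(rec)
        got = out.set_index("dry_mass_mg")["mass_class"].to_dict()
        assert [got[m] for m in (1.0, 2.0, 3.0)] == ["small"] * 3
        assert [got[m] for m in (4.0, 5.0, 6.0)] == ["medium"] * 3
        assert [got[m] for m in (7.0, 8.0, 9.0)] == ["large"] * 3
        # 9 exceeds the 0.99 quantile of 1..9 but stays in 'large' with a flag
        assert assignment.n_above_upper == 1
        assert out.loc[out["dry_mass_mg"] == 9.0, "above_upper_quantile"].all()

    def test_degenerate_masses_error(self):
        rec = pd.DataFrame({"individual_id": ["a", "b", "c"], "dry_mass_mg": [2.0] * 3})
        with pytest.raises(ValueError, match="degenerate"):
            assign_mass_classes(rec)

    def test_classes_partition_and_stats(self, records_default):
        out, assignment = assign_mass_classes(records_default)
        assert set(out["mass_class"]) == {"small", "medium", "large"}
        q1, q2 = assignment.class_bounds_mg
        assert q1 < q2 < assignment.upper_cut_mg
        assert (out.loc[out["mass_class"] == "small", "dry_mass_mg"] <= q1).all()
        assert assignment.class_stats.loc["small", "mean"] < assignment.class_stats.loc["large", "mean"]


class TestInverseThermalEnergy:
    def test_reference_values(self):
        # 1/(k * 291.15 K) with k = 8.617333e-5 eV/K
        assert inverse_thermal_energy(18.0) == pytest.approx(39.8575, abs=5e-4)
        assert inverse_thermal_energy(26.2) == pytest.approx(38.7656, abs=5e-4)

    def test_strictly_decreasing(self):
        t = np.linspace(-2, 40, 50)
        assert np.all(np.diff(inverse_thermal_energy(t)) < 0)

    def test_nonphysical_temperature(self):
        with pytest.raises(ValueError):
            inverse_thermal_energy(-300.0)


class TestArrhenius:
    def test_noiseless_recovery_exact(self):
        rec = arrhenius_records(0.65, [11, 15, 20, 24, 28], [1.0, 3.0, 9.0])
        f = fit_arrhenius(rec)
        assert f.activation_energy_ev == pytest.approx(0.65, abs=1e-10)
        assert f.r2 == pytest.approx(1.0)

    def test_pooled_slopes_with_site_offsets(self):
        """Same E at both sites, +0.3 ln-unit offset: pooled E and offset back."""
        rng = np.random.default_rng(5)
        frames = []
        for site, off in (("A", 0.0), ("B", 0.3)):
            r = arrhenius_records(0.5, [10, 18, 26], np.exp(rng.uniform(0, 1, 30)),
                                  site=site, offset=off)
            r["mass_specific_smr"] *= np.exp(rng.normal(0, 0.1, len(r)))
            frames.append(r)
        rec = pd.concat(frames, ignore_index=True)
        f = fit_arrhenius(rec)
        assert f.pooled
        assert f.activation_energy_ev == pytest.approx(0.5, abs=0.05)
        assert f.site_intercepts_ln["B"] == pytest.approx(0.3, abs=0.1)

    def test_site_specific_slopes_reported_when_heterogeneous(self):
        rng = np.random.default_rng(6)
        frames = []
        for site, e in (("A", 0.3), ("B", 0.9)):
            r = arrhenius_records(e, [10, 18, 26], np.exp(rng.uniform(0, 1, 40)), site=site)
            r["mass_specific_smr"] *= np.exp(rng.normal(0, 0.1, len(r)))
            frames.append(r)
        f = fit_arrhenius(pd.concat(frames, ignore_index=True))
        assert not f.pooled
        assert f.per_site_e["A"] == pytest.approx(0.3, abs=0.1)
        assert f.per_site_e["B"] == pytest.approx(0.9, abs=0.1)

    def test_requires_two_levels(self):
        rec = arrhenius_records(0.5, [18], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="levels"):
            fit_arrhenius(rec)

    def test_current_forecast_range_selection(self, records_default, sites):
        classed, _ = assign_mass_classes(records_default)
        cur = fit_arrhenius(classed, "small", "current", site_presets=sites)
        fc = fit_arrhenius(classed, "small", "forecast", site_presets=sites)
        assert cur.n > 0 and fc.n > 0
        # forecast sits above each site's current maximum except the anchor level
        assert cur.temp_range == "current" and fc.temp_range == "forecast"

    def test_e_invariant_to_rate_rescaling(self):
        rec = arrhenius_records(0.65, [11, 18, 25], [1.0, 2.0, 4.0])
        f1 = fit_arrhenius(rec)
        rec2 = rec.copy()
        rec2["mass_specific_smr"] *= 7.3
        f2 = fit_arrhenius(rec2)
        assert f2.activation_energy_ev == pytest.approx(f1.activation_energy_ev, rel=1e-12)

    def test_printed_boltzmann_constant_rescales_e_only(self):
        rng = np.random.default_rng(11)
        rec = arrhenius_records(0.65, [11, 18, 25], np.exp(rng.uniform(0, 1, 20)))
        rec["mass_specific_smr"] *= np.exp(rng.normal(0, 0.1, len(rec)))
        f_phys = fit_arrhenius(rec, boltzmann_k=BOLTZMANN_EV_PER_K)
        f_printed = fit_arrhenius(rec, boltzmann_k=PRINTED_K)
        # 1/(k'T) = (k/k') * 1/(kT): slopes, hence E, rescale by k'/k
        assert f_printed.activation_energy_ev == pytest.approx(
            f_phys.activation_energy_ev * PRINTED_K / BOLTZMANN_EV_PER_K, rel=1e-9
        )
        assert f_printed.p_e == pytest.approx(f_phys.p_e, rel=1e-9)


class TestSlopeHeterogeneity:
    def _classed(self, e_by_class, n, sigma, seed):
        rng = np.random.default_rng(seed)
        frames = []
        for cls, e in e_by_class.items():
            r = arrhenius_records(e, [10, 18, 26], np.exp(rng.uniform(0, 1, n // 3 + 1))[: n // 3])
            r = r.iloc[:n].copy()
            r["mass_class"] = cls
            r["mass_specific_smr"] *= np.exp(rng.normal(0, sigma, len(r)))
            frames.append(r)
        return pd.concat(frames, ignore_index=True)

    def test_df_bookkeeping(self):
        rec = self._classed({"small": 0.5, "medium": 0.5, "large": 0.5}, 60, 0.15, 1)
        f, (df1, df2), p = slope_heterogeneity_test(rec)
        n = len(rec)
        assert df1 == 2  # classes - 1
        assert df2 == n - 6  # n - (intercept + slope) * 3 classes

    def test_power_for_class_differences(self):
        det = 0
        reps = 100
        for r in range(reps):
            rec = self._classed({"small": 0.6, "large": 0.4}, 240, 0.15, 100 + r)
            _, _, p = slope_heterogeneity_test(rec)
            if p < 0.05:
                det += 1
        assert det / reps > 0.8

    def test_single_class_errors(self):
        rec = self._classed({"small": 0.5}, 30, 0.1, 2)
        with pytest.raises(ValueError, match="single level"):
            slope_heterogeneity_test(rec)


class TestQ10:
    def test_equal_rates_give_one(self):
        assert compute_q10(2.0, 10.0, 2.0, 20.0).q10 == pytest.approx(1.0)

    def test_doubling_over_ten_degrees(self):
        assert compute_q10(1.0, 10.0, 2.0, 20.0).q10 == pytest.approx(2.0)

    def test_fractional_interval(self):
        assert compute_q10(1.0, 15.0, 1.5, 20.0).q10 == pytest.approx(2.25)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_q10(1.0, 15.0, 1.5, 15.0)
        with pytest.raises(ValueError):
            compute_q10(-1.0, 15.0, 1.5, 20.0)

    def test_consistency_with_arrhenius(self):
        """Noiseless Arrhenius rates give Q10 = exp(10E/(k T1 T2))."""
        e = 0.65
        t1c, t2c = 12.0, 25.0
        rec = arrhenius_records(e, [t1c, t2c], [1.0])
        r1, r2 = rec["mass_specific_smr"].to_numpy()
        q10 = compute_q10(r1, t1c, r2, t2c).q10
        t1, t2 = t1c + KELVIN_OFFSET, t2c + KELVIN_OFFSET
        expected = math.exp(10.0 * e / (BOLTZMANN_EV_PER_K * t1 * t2))
        assert q10 == pytest.approx(expected, rel=5e-3)

    def test_q10_table_structure(self, records_default):
        classed, _ = assign_mass_classes(records_default)
        tab = q10_table(classed)
        assert {"site", "mass_class", "temp_c", "ref_temp_c", "q10"} <= set(tab.columns)
        assert (tab["q10"] > 0).all()
        # reference is each site's minimum level
        for site, g in tab.groupby("site"):
            assert g["ref_temp_c"].nunique() == 1
            assert (g["temp_c"] > g["ref_temp_c"]).all()


class TestTemperatureAnomaly:
    def test_constant_series_gives_zero(self):
        idx = pd.date_range("2015-01-01", "2016-12-31", freq="D")
        s = pd.Series(17.0, index=idx)
        a = compute_temperature_anomaly(s)
        assert np.allclose(a.to_numpy(), 0.0)

    def test_constant_shift_recovered(self):
        idx = pd.date_range("2015-01-01", "2016-12-31", freq="D")
        clim = pd.Series(np.sin(np.arange(idx.size) / 58.0) * 5 + 15, index=idx)
        # use a one-year series equal to climatology + 1 over the same days
        year = clim.loc["2015"]
        shifted = year + 1.0
        clim_two_years = pd.concat([year, year.rename(lambda d: d.replace(year=2016))])
        a = compute_temperature_anomaly(shifted, climatology=clim_two_years)
        assert np.allclose(a.to_numpy(), 1.0)

    def test_leap_day_uses_neighbours(self):
        idx = pd.date_range("2019-01-01", "2020-12-31", freq="D")
        vals = pd.Series(np.arange(idx.size, dtype=float), index=idx)
        a = compute_temperature_anomaly(vals)
        feb29 = pd.Timestamp("2020-02-29")
        clim_feb28 = vals[[pd.Timestamp("2019-02-28"), pd.Timestamp("2020-02-28")]].mean()
        clim_mar1 = vals[[pd.Timestamp("2019-03-01"), pd.Timestamp("2020-03-01")]].mean()
        expected = vals[feb29] - (clim_feb28 + clim_mar1) / 2.0
        assert a[feb29] == pytest.approx(expected)

    def test_empty_climatology_errors(self):
        s = pd.Series([1.0], index=pd.to_datetime(["2020-01-01"]))
        with pytest.raises(ValueError):
            compute_temperature_anomaly(s, climatology=pd.Series(dtype=float))
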