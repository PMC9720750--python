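"""Scaling models: log-log fits, per-site ANCOVA, global model, stepwise."""

import math

import numpy as np
import pandas as pd
import pytest

from thermoscale import (
    GenerativeParams,
    compare_across_temperatures,
    fit_global_ancova,
    fit_mass_scaling,
    generate_records,
    stepwise_simplify,
)
from thermoscale._lm import term_parents


def power_law_records(masses, b=0.75, c=1.0, site="S", level=18.0):
    masses = np.asarray(masses, dtype=float)
    return pd.DataFrame(
        {
            "individual_id": [f"i{j}" for j in range(masses.size)],
            "site": site,
            "temp_level_c": level,
            "dry_mass_mg": masses,
            "smr_j_per_day": c * masses**b,
        }
    )


class TestMassScaling:
    def test_noiseless_power_law_recovered_exactly(self, rng):
        rec = power_law_records(np.exp(rng.uniform(-1, 2.6, 50)), b=0.75, c=2.0)
        f = fit_mass_scaling(rec)
        assert f.exponent_b == pytest.approx(0.75, abs=1e-12)
        assert f.intercept_ln == pytest.approx(math.log(2.0), abs=1e-12)
        assert f.r2 == pytest.approx(1.0)

    def test_collinear_isometric_points(self):
        rec = power_law_records([1.0, 10.0, 100.0], b=1.0, c=1.0)
        f = fit_mass_scaling(rec)
        assert f.exponent_b == pytest.approx(1.0, abs=1e-12)
        assert f.intercept_ln == pytest.approx(0.0, abs=1e-12)

    def test_preconditions(self):
        rec = power_law_records([1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            fit_mass_scaling(rec)
        rec = power_law_records([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            fit_mass_scaling(rec)

    def test_slope_invariant_to_log_base(self, rng):
        rec = power_law_records(np.exp(rng.uniform(-1, 2.6, 40)), b=0.8)
        rec["smr_j_per_day"] *= np.exp(rng.normal(0, 0.2, 40))
        f = fit_mass_scaling(rec)
        # base-10 fit by hand
        slope10 = np.polyfit(
            np.log10(rec["dry_mass_mg"]), np.log10(rec["smr_j_per_day"]), 1
        )[0]
        assert f.exponent_b == pytest.approx(slope10, rel=1e-10)
        assert f.intercept_log10 == pytest.approx(f.intercept_ln / math.log(10))

    def test_confidence_interval_coverage(self):
        """95% CI of b covers the truth in about 95% of 500 replicates."""
        b0, sigma, n = 0.75, 0.15, 40
        cover = 0
        reps = 500
        rng = np.random.default_rng(2024)
        for _ in range(reps):
            m = np.exp(rng.uniform(math.log(0.4), math.log(13.57), n))
            smr = m**b0 * np.exp(rng.normal(0, sigma, n))
            rec = power_law_records(m, b=1.0, c=1.0)
            rec["smr_j_per_day"] = smr
            f = fit_mass_scaling(rec)
            half = 1.96 * f.se_b
            if f.exponent_b - half <= b0 <= f.exponent_b + half:
                cover += 1
        assert 0.925 <= cover / reps <= 0.975


def multi_level_records(rng, slopes, n=40, sigma=0.15, site="S"):
    frames = []
    for lev, b in slopes.items():
        m = np.exp(rng.uniform(math.log(0.4), math.log(13.57), n))
        smr = m**b * np.exp(rng.normal(0, sigma, n))
        f = power_law_records(m, b=1.0, site=site, level=lev)
        f["smr_j_per_day"] = smr
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["individual_id"] = [f"i{j}" for j in range(len(out))]
    return out


class TestAncovaContrasts:
    def test_contrasts_match_separate_fits(self, rng):
        rec = multi_level_records(rng, {12.0: 0.9, 18.0: 0.75, 25.0: 0.6})
        contrasts = {c.temp_level_c: c for c in compare_across_temperatures(rec, "S")}
        fits = {
            lev: fit_mass_scaling(rec, site="S", temp_level=lev)
            for lev in (12.0, 18.0, 25.0)
        }
        for lev in (18.0, 25.0):
            assert contrasts[lev].d_slope == pytest.approx(
                fits[lev].exponent_b - fits[12.0].exponent_b, rel=1e-9
            )
            assert contrasts[lev].d_intercept == pytest.approx(
                fits[lev].intercept_ln - fits[12.0].intercept_ln, rel=1e-9
            )

    def test_baseline_contrast_is_zero(self, rng):
        rec = multi_level_records(rng, {12.0: 0.75, 25.0: 0.75})
        base = compare_across_temperatures(rec, "S")[0]
        assert base.temp_level_c == base.baseline_level_c == 12.0
        assert base.d_slope == 0.0 and base.d_intercept == 0.0

    def test_requires_two_levels(self, rng):
        rec = multi_level_records(rng, {12.0: 0.75})
        with pytest.raises(ValueError, match="level"):
            compare_across_temperatures(rec, "S")

    def test_type_i_error_of_slope_contrast(self):
        """Equal true slopes: the top-level slope contrast rejects ~5%."""
        rng = np.random.default_rng(77)
        reps, rej = 400, 0
        for _ in range(reps):
            rec = multi_level_records(rng, {12.0: 0.75, 18.0: 0.75, 25.0: 0.75})
            c = compare_across_temperatures(rec, "S")[-1]
            if c.p_slope < 0.05:
                rej += 1
        assert 0.025 <= rej / reps <= 0.08

    def test_power_to_detect_slope_drop(self):
        """Slope lower by 0.3 at the hottest level is detected in >80% of reps."""
        rng = np.random.default_rng(88)
        reps, det = 200, 0
        for _ in range(reps):
            rec = multi_level_records(rng, {12.0: 0.75, 18.0: 0.75, 25.0: 0.45})
            c = compare_across_temperatures(rec, "S")[-1]
            if c.p_slope < 0.05 and c.d_slope < 0:
                det += 1
        assert det / reps > 0.8


class TestGlobalAncova:
    def test_single_site_additive_reduction(self, rng):
        """With one site, the additive model equals a plain two-predictor OLS."""
        rec = multi_level_records(rng, {12.0: 0.75, 18.0: 0.75, 25.0: 0.75})
        fit = fit_global_ancova(rec)
        assert set(fit.terms) == {"lnM", "T", "lnM:T"}
        simplified = stepwise_simplify(fit)
        import statsmodels.api as sm

        y = np.log(rec["smr_j_per_day"])
        X = sm.add_constant(
            np.column_stack([np.log(rec["dry_mass_mg"]), rec["temp_level_c"]])
        )
        ols = sm.OLS(y, X).fit()
        additive = [t for t in simplified.terms if t in ("lnM", "T")]
        if set(simplified.terms) == {"lnM", "T"}:
            assert simplified.params.iloc[1] == pytest.approx(ols.params[1], rel=1e-9)
            assert simplified.r2_total == pytest.approx(ols.rsquared, rel=1e-9)
        else:  # interaction kept by chance: refit explicitly additive
            helper = fit._model.fit(["lnM", "T"])
            assert helper.rsquared == pytest.approx(ols.rsquared, rel=1e-9)

    def test_rank_deficiency_reported(self, rng):
        rec = multi_level_records(rng, {18.0: 0.75})  # constant temperature
        with pytest.raises(ValueError, match="aliased"):
            fit_global_ancova(rec)

    def test_random_intercept_path_runs(self, records_default):
        fit = fit_global_ancova(records_default, random_group="run_id")
        assert fit.random_variance is not None and fit.random_variance >= 0
        assert "coef" in fit.coef_table


class TestStepwise:
    def test_threeway_dropped_when_absent(self, sites):
        """Without a generated 3-way interaction the 3-way term is dropped >=90%."""
        p = GenerativeParams()  # lnM:T real; lnM:T:site absent
        dropped = 0
        reps = 100
        for r in range(reps):
            rec = generate_records(p, sites, seed=90_000 + r)
            fit = stepwise_simplify(fit_global_ancova(rec))
            if "lnM:T:site" not in fit.terms:
                dropped += 1
        assert dropped / reps >= 0.9

    def test_strong_interaction_retained(self, sites):
        p = GenerativeParams()
        kept = 0
        reps = 50
        for r in range(reps):
            rec = generate_records(p, sites, seed=91_000 + r)
            fit = stepwise_simplify(fit_global_ancova(rec))
            if "lnM:T" in fit.terms:
                kept += 1
        assert kept / reps >= 0.95

    def test_minimal_model_unchanged(self, rng):
        # strong slopes everywhere: nothing removable is non-significant
        rec = multi_level_records(
            rng, {12.0: 1.2, 25.0: 0.3}, n=200, sigma=0.05
        )
        fit = stepwise_simplify(fit_global_ancova(rec))
        again = stepwise_simplify(fit)
        assert again.terms == fit.terms

    def test_marginality_never_violated(self, sites):
        p = GenerativeParams()
        for r in range(10):
            rec = generate_records(p, sites, seed=92_000 + r)
            fit = stepwise_simplify(fit_global_ancova(rec))
            retained = set(fit.terms)
            for t in retained:
                assert term_parents(t) <= retained | set()  # parents of kept terms kept
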