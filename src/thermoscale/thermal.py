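"""Thermal sensitivity of mass-specific SMR: Arrhenius fits, Q10, anomalies.

Individuals are binned into small/medium/large body-mass classes by mass
quantiles (0.33, 0.66, 0.99). Within a class, the natural log of mass-specific
SMR (J day^-1 mg^-1) is regressed on inverse thermal energy 1/kT (eV^-1, with
k Boltzmann's constant and T in Kelvin) together with collection-site
intercepts; the negated slope is the activation energy E in electron-volts.
The site x 1/kT interaction is tested and, when non-significant, removed so a
single pooled E is reported with per-site intercept contrasts.

Fits are run separately over the *current* annual temperature range (local
minimum, reference, local maximum) and the *forecast* range (local maximum,
+0.6, +1.2 degC), the current maximum anchoring both. Temperature
coefficients Q10 = (R2/R1)^(10/(T2-T1)) are computed for each level against
the site minimum, and daily temperature anomalies against a multi-year
same-calendar-day climatology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lm import TermModel, nested_f_test
from .constants import BOLTZMANN_EV_PER_K, KELVIN_OFFSET
from .synth import SitePreset

__all__ = [
    "MassClassAssignment",
    "ArrheniusFit",
    "Q10Result",
    "ArrheniusModel",
    "assign_mass_classes",
    "inverse_thermal_energy",
    "fit_arrhenius",
    "slope_heterogeneity_test",
    "compute_q10",
    "q10_table",
    "compute_temperature_anomaly",
]

MASS_CLASSES = ("small", "medium", "large")


@dataclass(frozen=True)
class MassClassAssignment:
    """Quantile-based mass classes for a record set."""

    classes: pd.Series  # individual_id -> class label
    class_bounds_mg: tuple[float, float]
    upper_cut_mg: float
    quantiles_used: tuple[float, float, float]
    n_above_upper: int
    class_stats: pd.DataFrame


def assign_mass_classes(
    records: pd.DataFrame,
    quantiles: tuple[float, float, float] = (0.33, 0.66, 0.99),
    interpolation: str = "linear",
    include_above_upper: bool = True,
) -> tuple[pd.DataFrame, MassClassAssignment]:
    """Partition individuals into small/medium/large by mass quantiles.

    small: M <= q1; medium: q1 < M <= q2; large: q2 < M <= q3. Individuals
    above the upper quantile are included in ``large`` with a QC note by
    default (set ``include_above_upper=False`` to drop them). Type-7 (linear
    interpolation) quantiles by default.

    Returns the records with a ``mass_class`` column plus the assignment
    metadata (bounds and per-class mass summaries).
    """
    m = records["dry_mass_mg"].to_numpy(dtype=float)
    if np.unique(m).size < 3:
        raise ValueError("degenerate mass distribution: need >= 3 distinct masses")
    q1, q2, q3 = np.quantile(m, quantiles, method=interpolation)
    labels = np.where(m <= q1, "small", np.where(m <= q2, "medium", "large"))
    above = m > q3
    out = records.copy()
    out["mass_class"] = labels
    out["above_upper_quantile"] = above
    if not include_above_upper:
        out = out[~above].reset_index(drop=True)
    stats = (
        out.groupby("mass_class")["dry_mass_mg"]
        .agg(["count", "mean", "std"])
        .reindex(list(MASS_CLASSES))
    )
    assignment = MassClassAssignment(
        classes=out.set_index("individual_id")["mass_class"],
        class_bounds_mg=(float(q1), float(q2)),
        upper_cut_mg=float(q3),
        quantiles_used=tuple(quantiles),
        n_above_upper=int(above.sum()),
        class_stats=stats,
    )
    return out, assignment


def inverse_thermal_energy(temp_c, boltzmann_k: float = BOLTZMANN_EV_PER_K):
    """1/kT in eV^-1 for a temperature in degC (vectorised)."""
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= -KELVIN_OFFSET):
        raise ValueError("temperature at or below absolute zero")
    out = 1.0 / (boltzmann_k * (t + KELVIN_OFFSET))
    return float(out) if np.isscalar(temp_c) else out


@dataclass(frozen=True)
class ArrheniusFit:
    """Boltzmann-Arrhenius regression of ln mass-specific SMR on 1/kT."""

    mass_class: str | None
    temp_range: str
    activation_energy_ev: float
    se_e: float
    p_e: float
    site_intercepts_ln: dict[str, float]
    site_slope_test: tuple[float, int, int, float] | None  # (F, df_num, df_den, p)
    pooled: bool
    per_site_e: dict[str, float] | None
    n: int
    r2: float
    boltzmann_k_ev_per_k: float = BOLTZMANN_EV_PER_K

    def summary(self) -> str:
        lines = [
            f"Arrhenius fit ({self.mass_class or 'all'} class, {self.temp_range} range)",
            f"E = {self.activation_energy_ev:.3f} +/- {self.se_e:.3f} eV "
            f"(p={self.p_e:.3g}, n={self.n}, R2={self.r2:.3f}, "
            f"k={self.boltzmann_k_ev_per_k:.6g} eV/K)",
        ]
        if self.site_slope_test is not None:
            f, dfn, dfd, p = self.site_slope_test
            lines.append(
                f"site x 1/kT: F_{dfn},{dfd} = {f:.2f}, p = {p:.3g} -> "
                + ("pooled E" if self.pooled else "site-specific E")
            )
        for s, v in self.site_intercepts_ln.items():
            lines.append(f"  intercept contrast {s}: {v:+.3f} ln units")
        if self.per_site_e:
            for s, v in self.per_site_e.items():
                lines.append(f"  E[{s}] = {v:.3f} eV")
        return "\n".join(lines)


def _select_range(
    records: pd.DataFrame,
    temp_range: str,
    site_presets: dict[str, SitePreset] | None,
) -> pd.DataFrame:
    """Filter records to the requested temperature range per site.

    With presets the current range is (t_min, t_ref, t_max) and the forecast
    range (t_max, +0.6, +1.2). Without presets, sites exposing five levels are
    split 3/3 around the shared middle (current-maximum) level; otherwise all
    levels are used as-is.
    """
    if temp_range == "all":
        return records
    keep = []
    for site, g in records.groupby("site"):
        levels = np.sort(g["temp_level_c"].unique())
        if site_presets is not None and site in site_presets:
            preset = site_presets[site]
            wanted = preset.current_levels if temp_range == "current" else preset.forecast_levels
        elif levels.size == 5:
            wanted = levels[:3] if temp_range == "current" else levels[2:]
        else:
            wanted = levels
        sel = g[np.isclose(g["temp_level_c"].to_numpy()[:, None], np.asarray(wanted)).any(axis=1)]
        keep.append(sel)
    return pd.concat(keep, ignore_index=True)


class ArrheniusModel:
    """Arrhenius regression model for one mass class and temperature range."""

    def __init__(
        self,
        records: pd.DataFrame,
        mass_class: str | None = None,
        temp_range: str = "all",
        sites: list[str] | None = None,
        site_presets: dict[str, SitePreset] | None = None,
        boltzmann_k: float = BOLTZMANN_EV_PER_K,
        alpha: float = 0.05,
    ):
        df = records
        if mass_class is not None:
            if "mass_class" not in df.columns:
                raise ValueError("records lack a mass_class column; run assign_mass_classes")
            df = df[df["mass_class"] == mass_class]
        if sites is not None:
            df = df[df["site"].isin(sites)]
        df = _select_range(df, temp_range, site_presets)
        df = df[df["mass_specific_smr"] > 0].copy()
        levels_per_site = df.groupby("site")["temp_level_c"].nunique()
        if (levels_per_site < 2).any():
            bad = levels_per_site[levels_per_site < 2].index.tolist()
            raise ValueError(f"fewer than 2 temperature levels in range for site(s) {bad}")
        df["x"] = inverse_thermal_energy(df["temp_level_c"].to_numpy(), boltzmann_k)
        df["y"] = np.log(df["mass_specific_smr"].to_numpy(dtype=float))
        self.df = df
        self.site_levels = sorted(df["site"].unique())
        self.mass_class = mass_class
        self.temp_range = temp_range
        self.boltzmann_k = boltzmann_k
        self.alpha = alpha

    def fit(self) -> ArrheniusFit:
        multi_site = len(self.site_levels) > 1
        terms = ["x", "site", "x:site"] if multi_site else ["x"]
        model = TermModel.from_frame(
            self.df, response="y", terms=terms,
            categorical={"site": self.site_levels} if multi_site else None,
        )
        site_slope_test = None
        pooled = True
        per_site_e = None
        if multi_site:
            f, dfn, dfd, p = nested_f_test(model, terms, "x:site")
            site_slope_test = (f, dfn, dfd, p)
            pooled = p >= self.alpha
        report_terms = ["x", "site"] if multi_site else ["x"]
        if multi_site and not pooled:
            full = model.fit(terms)
            names = full.model.exog_names
            base_slope = float(full.params[names.index("x")])
            per_site_e = {self.site_levels[0]: -base_slope}
            for s in self.site_levels[1:]:
                per_site_e[s] = -(base_slope + float(full.params[names.index(f"x:site[{s}]")]))
        res = model.fit(report_terms)
        names = res.model.exog_names
        i_x = names.index("x")
        intercepts = {}
        if multi_site:
            for s in self.site_levels[1:]:
                intercepts[s] = float(res.params[names.index(f"site[{s}]")])
        return ArrheniusFit(
            mass_class=self.mass_class,
            temp_range=self.temp_range,
            activation_energy_ev=-float(res.params[i_x]),
            se_e=float(res.bse[i_x]),
            p_e=float(res.pvalues[i_x]),
            site_intercepts_ln=intercepts,
            site_slope_test=site_slope_test,
            pooled=pooled,
            per_site_e=per_site_e,
            n=int(res.nobs),
            r2=float(res.rsquared),
            boltzmann_k_ev_per_k=self.boltzmann_k,
        )


def fit_arrhenius(
    records: pd.DataFrame,
    mass_class: str | None = None,
    temp_range: str = "all",
    sites: list[str] | None = None,
    site_presets: dict[str, SitePreset] | None = None,
    boltzmann_k: float = BOLTZMANN_EV_PER_K,
    alpha: float = 0.05,
) -> ArrheniusFit:
    """Activation energy of mass-specific SMR for one class and range.

    Regresses ln(mass-specific SMR) on 1/kT with site intercept dummies; the
    site x 1/kT interaction is tested and dropped when p >= alpha, in which
    case a single pooled E (= -slope) is reported. E is reported signed: a
    non-significant decline stays negative-signed rather than being clamped.
    """
    return ArrheniusModel(
        records, mass_class, temp_range, sites, site_presets, boltzmann_k, alpha
    ).fit()


def slope_heterogeneity_test(
    records: pd.DataFrame,
    factor: str = "mass_class",
    boltzmann_k: float = BOLTZMANN_EV_PER_K,
) -> tuple[float, tuple[int, int], float]:
    """ANCOVA F-test of factor x (1/kT) slope heterogeneity.

    Tests whether the thermal sensitivity (activation energy) of mass-specific
    SMR differs among the levels of ``factor`` (body-mass classes by default)
    in a joint model ``ln(SMR/M) ~ 1/kT * factor``. Returns (F, (df1, df2), p).
    """
    df = records[records["mass_specific_smr"] > 0].copy()
    levels = sorted(df[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    df["x"] = inverse_thermal_energy(df["temp_level_c"].to_numpy(), boltzmann_k)
    df["y"] = np.log(df["mass_specific_smr"].to_numpy(dtype=float))
    df_cat = df.assign(fac=df[factor])
    model = TermModel.from_frame(
        df_cat, response="y", terms=["x", "fac", "x:fac"], categorical={"fac": levels}
    )
    f, dfn, dfd, p = nested_f_test(model, ["x", "fac", "x:fac"], "x:fac")
    return f, (dfn, dfd), p


@dataclass(frozen=True)
class Q10Result:
    """Temperature coefficient of a rate between two temperatures."""

    q10: float
    temp_c: float
    ref_temp_c: float
    site: str | None = None
    mass_class: str | None = None


def compute_q10(
    rate_ref: float, temp_ref_c: float, rate: float, temp_c: float,
    site: str | None = None, mass_class: str | None = None,
) -> Q10Result:
    """Q10 = (rate/rate_ref)^(10/(T - T_ref)); equal rates give 1."""
    if rate_ref <= 0 or rate <= 0:
        raise ValueError("rates must be positive")
    if temp_c == temp_ref_c:
        raise ValueError("temperatures must differ")
    q10 = (rate / rate_ref) ** (10.0 / (temp_c - temp_ref_c))
    return Q10Result(q10=float(q10), temp_c=temp_c, ref_temp_c=temp_ref_c,
                     site=site, mass_class=mass_class)


def q10_table(records: pd.DataFrame) -> pd.DataFrame:
    """Q10 of mean mass-specific SMR per site x mass class, vs the site minimum."""
    if "mass_class" not in records.columns:
        raise ValueError("records lack a mass_class column; run assign_mass_classes")
    rows = []
    for (site, cls), g in records.groupby(["site", "mass_class"]):
        means = g.groupby("temp_level_c")["mass_specific_smr"].mean().sort_index()
        t_ref = means.index[0]
        for t in means.index[1:]:
            r = compute_q10(means.loc[t_ref], t_ref, means.loc[t], t, site, cls)
            rows.append(
                {"site": site, "mass_class": cls, "temp_c": t,
                 "ref_temp_c": t_ref, "q10": r.q10}
            )
    return pd.DataFrame(rows)


def compute_temperature_anomaly(
    daily_series: pd.Series, climatology: pd.Series | None = None
) -> pd.Series:
    """Daily temperature anomalies against a same-calendar-day climatology.

    ``daily_series`` must be indexed by dates. The climatology defaults to the
    series itself (e.g. a 10-year window): for each calendar day the mean over
    all years is subtracted. Feb 29, which has few climatology samples, uses
    the mean of the Feb 28 and Mar 1 climatology values.
    """
    s = daily_series.copy()
    if not isinstance(s.index, pd.DatetimeIndex):
        s.index = pd.to_datetime(s.index)
    clim_src = climatology if climatology is not None else s
    if not isinstance(clim_src.index, pd.DatetimeIndex):
        clim_src = clim_src.copy()
        clim_src.index = pd.to_datetime(clim_src.index)
    if len(clim_src) == 0:
        raise ValueError("empty climatology")
    clim = clim_src.groupby([clim_src.index.month, clim_src.index.day]).mean()
    if (2, 28) in clim.index and (3, 1) in clim.index:
        clim.loc[(2, 29)] = (clim.loc[(2, 28)] + clim.loc[(3, 1)]) / 2.0
    lookup = pd.MultiIndex.from_arrays([s.index.month, s.index.day])
    baseline = clim.reindex(lookup).to_numpy(dtype=float)
    if np.isnan(baseline).any():
        missing = sorted(set(lookup[np.isnan(baseline)]))
        raise ValueError(f"climatology lacks calendar days: {missing[:5]}")
    return pd.Series(s.to_numpy(dtype=float) - baseline, index=s.index, name="anomaly")
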