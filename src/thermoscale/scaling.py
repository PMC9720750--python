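"""Mass-scaling of SMR across temperatures and sites.

SMR is modelled as a power law in dry body mass, ``SMR = a * M^b``, fitted by
OLS on the natural-log scale (the exponent ``b`` is invariant to the log base;
intercepts are reported in ln units with a log10 convenience conversion).
Three estimators live here:

* :func:`fit_mass_scaling` — per (site, temperature-level) log-log OLS.
* :func:`compare_across_temperatures` — one ANCOVA per site contrasting the
  slope and intercept of every temperature level against the site's lowest
  temperature.
* :func:`fit_global_ancova` / :func:`stepwise_simplify` — the global
  ln M x temperature x site ANCOVA with full interactions, optionally with a
  random intercept group, simplified by marginality-respecting backward
  elimination on nested F-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._lm import TermModel, stepwise_eliminate

__all__ = [
    "ScalingFit",
    "AncovaContrast",
    "GlobalModelFit",
    "MassScalingModel",
    "GlobalAncova",
    "fit_mass_scaling",
    "compare_across_temperatures",
    "fit_global_ancova",
    "stepwise_simplify",
]

LN10 = math.log(10.0)


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if (df["smr_j_per_day"] <= 0).any():
        df = df[df["smr_j_per_day"] > 0].copy()
    df["lnM"] = np.log(df["dry_mass_mg"].to_numpy(dtype=float))
    df["lnSMR"] = np.log(df["smr_j_per_day"].to_numpy(dtype=float))
    df["T"] = df["temp_level_c"].astype(float)
    return df


@dataclass(frozen=True)
class ScalingFit:
    """Log-log OLS of SMR on mass for one site x temperature cell."""

    site: str | None
    temp_level_c: float | None
    exponent_b: float
    intercept_ln: float
    se_b: float
    se_intercept: float
    n: int
    r2: float

    @property
    def intercept_log10(self) -> float:
        """Intercept re-expressed for a base-10 fit (slope is base-invariant)."""
        return self.intercept_ln / LN10

    def equation(self) -> str:
        """Human-readable power-law equation, Table-4 style."""
        return (
            f"ln SMR = {self.intercept_ln:.3f} + {self.exponent_b:.3f} ln M"
            f"  (n={self.n}, R2={self.r2:.3f})"
        )


class MassScalingModel:
    """Power-law scaling model ``ln SMR ~ ln M`` for a records subset."""

    def __init__(
        self,
        records: pd.DataFrame,
        site: str | None = None,
        temp_level: float | None = None,
    ):
        df = records
        if site is not None:
            df = df[df["site"] == site]
        if temp_level is not None:
            df = df[np.isclose(df["temp_level_c"].astype(float), temp_level)]
        df = _prepare(df)
        if len(df) < 3:
            raise ValueError(
                f"need >= 3 records for site={site!r} level={temp_level!r}; got {len(df)}"
            )
        if np.ptp(df["lnM"].to_numpy()) == 0:
            raise ValueError("zero variance in mass; scaling exponent unidentified")
        self.df = df
        self.site = site
        self.temp_level = temp_level

    def fit(self) -> ScalingFit:
        X = sm.add_constant(self.df["lnM"].to_numpy())
        res = sm.OLS(self.df["lnSMR"].to_numpy(), X).fit()
        return ScalingFit(
            site=self.site,
            temp_level_c=self.temp_level,
            exponent_b=float(res.params[1]),
            intercept_ln=float(res.params[0]),
            se_b=float(res.bse[1]),
            se_intercept=float(res.bse[0]),
            n=int(res.nobs),
            r2=float(res.rsquared),
        )


def fit_mass_scaling(
    records: pd.DataFrame, site: str | None = None, temp_level: float | None = None
) -> ScalingFit:
    """OLS of ln SMR on ln M; returns exponent, intercept, SEs, n, R2."""
    return MassScalingModel(records, site=site, temp_level=temp_level).fit()


@dataclass(frozen=True)
class AncovaContrast:
    """Slope/intercept contrast of one temperature level vs the site baseline."""

    site: str
    temp_level_c: float
    baseline_level_c: float
    d_slope: float
    d_intercept: float
    t_slope: float
    t_intercept: float
    df: int
    p_slope: float
    p_intercept: float


def compare_across_temperatures(records: pd.DataFrame, site: str) -> list[AncovaContrast]:
    """Per-site ANCOVA of log-log SMR-mass scaling across temperature levels.

    Fits a single dummy-coded model ``lnSMR ~ level * lnM`` with the site's
    minimum temperature as the reference level, and returns, for every level,
    the slope and intercept differences from the baseline with their t-tests.
    The baseline's own contrast is identically zero.
    """
    df = _prepare(records[records["site"] == site])
    levels = sorted(df["temp_level_c"].unique())
    if len(levels) < 2:
        raise ValueError(f"site {site!r} has {len(levels)} temperature level(s); need >= 2")
    baseline = levels[0]
    df = df.assign(level=df["temp_level_c"])
    model = TermModel.from_frame(
        df,
        response="lnSMR",
        terms=["level", "lnM", "level:lnM"],
        categorical={"level": levels},
    )
    res = model.fit(["level", "lnM", "level:lnM"])
    names = res.model.exog_names
    out = [
        AncovaContrast(
            site=site,
            temp_level_c=float(baseline),
            baseline_level_c=float(baseline),
            d_slope=0.0,
            d_intercept=0.0,
            t_slope=0.0,
            t_intercept=0.0,
            df=int(res.df_resid),
            p_slope=1.0,
            p_intercept=1.0,
        )
    ]
    for lev in levels[1:]:
        i_int = names.index(f"level[{lev}]")
        i_slope = names.index(f"level[{lev}]:lnM")
        out.append(
            AncovaContrast(
                site=site,
                temp_level_c=float(lev),
                baseline_level_c=float(baseline),
                d_slope=float(res.params[i_slope]),
                d_intercept=float(res.params[i_int]),
                t_slope=float(res.tvalues[i_slope]),
                t_intercept=float(res.tvalues[i_int]),
                df=int(res.df_resid),
                p_slope=float(res.pvalues[i_slope]),
                p_intercept=float(res.pvalues[i_int]),
            )
        )
    return out


FULL_TERMS = ["lnM", "T", "site", "lnM:T", "lnM:site", "T:site", "lnM:T:site"]


@dataclass
class GlobalModelFit:
    """Fitted (possibly simplified) global ANCOVA of ln SMR.

    Carries the retained terms, the coefficient table, total R2, the stepwise
    elimination trace, and — when a random group was supplied — the random
    intercept variance of the mixed refit.
    """

    terms: list[str]
    coef_table: pd.DataFrame
    r2_total: float
    elimination_trace: list[dict] = field(default_factory=list)
    random_group: str | None = None
    random_variance: float | None = None
    alpha: float = 0.05
    _model: TermModel | None = field(default=None, repr=False)
    _df: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return self.coef_table["coef"]

    @property
    def pvalues(self) -> pd.Series:
        return self.coef_table["p"]

    def summary(self) -> str:
        lines = [
            "Global ANCOVA of ln SMR on ln M, temperature (degC) and site",
            f"retained terms: {' + '.join(self.terms)}",
            f"total R2 = {self.r2_total:.4f}",
        ]
        if self.random_group:
            lines.append(
                f"random intercept: {self.random_group} "
                f"(variance {self.random_variance:.4g})"
            )
        lines.append(self.coef_table.to_string(float_format=lambda v: f"{v: .4f}"))
        if self.elimination_trace:
            lines.append("eliminated: " + ", ".join(
                f"{e['term']} (p={e['p']:.3f})" for e in self.elimination_trace
            ))
        return "\n".join(lines)


class GlobalAncova:
    """Global ANCOVA model: ln SMR ~ ln M * temperature * site (+ random group).

    Temperature enters as continuous degC; site as a dummy-coded factor. With
    ``random_group`` set, the selected fixed structure is refitted as a linear
    mixed model with a random intercept for that grouping.
    """

    def __init__(self, records: pd.DataFrame, random_group: str | None = None):
        df = _prepare(records)
        self.sites = sorted(df["site"].unique())
        terms = FULL_TERMS if len(self.sites) > 1 else ["lnM", "T", "lnM:T"]
        self.terms = list(terms)
        self.df = df
        self.random_group = random_group
        self.model = TermModel.from_frame(
            df, response="lnSMR", terms=self.terms, categorical={"site": self.sites}
        )
        self.model.check_full_rank(self.terms)

    def _results(self, terms: list[str], trace: list[dict]) -> GlobalModelFit:
        res = self.model.fit(terms)
        table = pd.DataFrame(
            {
                "coef": res.params,
                "se": res.bse,
                "t": res.tvalues,
                "p": res.pvalues,
            },
            index=res.model.exog_names,
        )
        random_variance = None
        if self.random_group is not None:
            X, names = self.model.design(terms)
            md = sm.MixedLM(
                self.model.y, X, groups=self.df[self.random_group].to_numpy()
            )
            mres = md.fit(reml=True)
            table = pd.DataFrame(
                {
                    "coef": mres.fe_params,
                    "se": mres.bse_fe,
                    "t": mres.tvalues[: len(mres.fe_params)],
                    "p": mres.pvalues[: len(mres.fe_params)],
                },
                index=names,
            )
            random_variance = float(np.asarray(mres.cov_re)[0, 0])
        return GlobalModelFit(
            terms=list(terms),
            coef_table=table,
            r2_total=float(res.rsquared),
            elimination_trace=trace,
            random_group=self.random_group,
            random_variance=random_variance,
            _model=self.model,
            _df=self.df,
        )

    def fit(self) -> GlobalModelFit:
        return self._results(self.terms, trace=[])


def fit_global_ancova(
    records: pd.DataFrame, random_group: str | None = None
) -> GlobalModelFit:
    """Fit the full-interaction global ANCOVA (ln M x temperature x site)."""
    return GlobalAncova(records, random_group=random_group).fit()


def stepwise_simplify(fit: GlobalModelFit, alpha: float = 0.05) -> GlobalModelFit:
    """Backward-eliminate non-significant terms from a global ANCOVA fit.

    Highest-order removable terms are tested first with nested-model F-tests;
    a term is never removed while an interaction containing it is retained.
    """
    if fit._model is None:
        raise ValueError("fit does not carry its design; refit with GlobalAncova")
    retained, trace = stepwise_eliminate(fit._model, fit.terms, alpha=alpha)
    # rebuild a results object on the simplified structure
    helper = GlobalAncova.__new__(GlobalAncova)
    helper.model = fit._model
    helper.df = fit._df
    helper.random_group = fit.random_group
    out = GlobalAncova._results(helper, retained, trace=fit.elimination_trace + trace)
    out.alpha = alpha
    return out
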