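"""Synthetic populations, latent SMR values, and raw respirometry traces.

The generator emulates a three-site, five-temperature-level experiment on a
lagoon amphipod: per site the levels are the local annual minimum, a common
18 degC reference, the local annual maximum, and two forecast increments of
+0.6 and +1.2 degC above that maximum. Latent standard metabolic rate follows
a mass-and-temperature model on the natural-log scale,

    ln SMR = ln_smr0 + site_offset + b0 * ln M
             - E(M) * (1/kT - 1/kT_ref),
    E(M)   = e0 + e_mass_slope * ln(M / M_geo),

i.e. a power law in dry mass M (mg) with a Boltzmann-Arrhenius temperature
response whose activation energy declines with ln-mass when ``e_mass_slope``
is negative (small/young individuals are more thermally sensitive). Lognormal
noise of standard deviation ``sigma_ln`` conflates biological scatter and
measurement error. An optional plateau caps ln SMR of heavy individuals at
its current-maximum value for selected (low-latitude) sites, mimicking
metabolic homeostasis above the locally experienced temperature range.

Raw flow-through traces are generated as the inverse of the respirometry
calculation: blank PO2 at air saturation for the working (T, S), specimen
steady state depressed by VO2/(S_O2 * F), plus an exponential equilibration
transient and AR(1) electrode noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import BOLTZMANN_EV_PER_K, HOURS_PER_DAY, KELVIN_OFFSET, OXYJOULE_J_PER_UMOL
from .respirometry import RespirometryTrace, compute_solubility, po2_saturation_torr

__all__ = [
    "SitePreset",
    "PlateauConfig",
    "GenerativeParams",
    "ChamberConfig",
    "default_sites",
    "generate_population",
    "generate_true_smr",
    "expected_ln_smr",
    "generate_records",
    "generate_trace",
    "generate_traces_for_records",
    "load_scenario",
    "scenario_to_dict",
]


@dataclass(frozen=True)
class SitePreset:
    """One collection site: location, salinity and its five temperature levels.

    ``temp_levels_c`` is ordered (t_min, t_ref, t_max, t_max+0.6, t_max+1.2).
    """

    name: str
    latitude_deg: float
    salinity_psu: float
    temp_levels_c: tuple[float, float, float, float, float]
    metabolic_level_offset: float = 0.0

    def __post_init__(self) -> None:
        lv = tuple(float(t) for t in self.temp_levels_c)
        if len(lv) != 5:
            raise ValueError(f"site {self.name}: exactly 5 temperature levels required")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError(f"site {self.name}: temperature levels must be strictly increasing")
        if not (math.isclose(lv[3], lv[2] + 0.6) and math.isclose(lv[4], lv[2] + 1.2)):
            raise ValueError(
                f"site {self.name}: forecast levels must be t_max+0.6 and t_max+1.2"
            )
        object.__setattr__(self, "temp_levels_c", lv)

    @property
    def t_min(self) -> float:
        return self.temp_levels_c[0]

    @property
    def t_ref(self) -> float:
        return self.temp_levels_c[1]

    @property
    def t_max(self) -> float:
        return self.temp_levels_c[2]

    @property
    def current_levels(self) -> tuple[float, float, float]:
        """Annual-range levels: minimum, reference, maximum."""
        return self.temp_levels_c[:3]

    @property
    def forecast_levels(self) -> tuple[float, float, float]:
        """Current maximum plus the +0.6 and +1.2 degC increments."""
        return self.temp_levels_c[2:]


def default_sites() -> dict[str, SitePreset]:
    """Default three-site scenario along a latitudinal gradient.

    Reference temperature 18 degC everywhere; Quarantia (high latitude)
    maximum 25.0 degC, Lesina maximum 28.0 degC, Acquatina minimum 12.0 degC;
    salinities 20/22/21 PSU. The remaining cells (Quarantia minimum 8.0,
    Lesina minimum 11.0, Acquatina maximum 27.0 degC) are synthetic-scenario
    values chosen to complete a plausible Adriatic lagoon gradient and are
    freely overridable.
    """
    return {
        "Quarantia": SitePreset(
            "Quarantia", 45.763, 20.0, (8.0, 18.0, 25.0, 25.6, 26.2), 0.3
        ),
        "Lesina": SitePreset(
            "Lesina", 41.871, 22.0, (11.0, 18.0, 28.0, 28.6, 29.2), 0.0
        ),
        "Acquatina": SitePreset(
            "Acquatina", 40.444, 21.0, (12.0, 18.0, 27.0, 27.6, 28.2), 0.0
        ),
    }


@dataclass(frozen=True)
class PlateauConfig:
    """High-temperature metabolic plateau for heavy individuals.

    For individuals with mass above ``mass_threshold_mg`` at the listed sites,
    latent ln SMR at temperatures above the site's current maximum is capped
    at its value at the maximum (metabolic homeostasis beyond the locally
    experienced range).
    """

    sites: tuple[str, ...]
    mass_threshold_mg: float = 5.0


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the latent SMR model and the sampling design.

    Defaults encode the study conditions: canonical 3/4-power mass scaling,
    a mean activation energy of 0.44 eV declining by 0.13 eV per unit ln-mass
    (so small individuals sit near 0.48 eV and large near 0.27-0.29 eV within
    the annual range), lognormal scatter of 0.15, and 25 individuals per
    site x temperature cell (375 in total for 3 sites x 5 levels).
    """

    b0: float = 0.75
    e0: float = 0.44
    e_mass_slope: float = -0.13
    ln_smr0: float = math.log(0.5)
    t_ref_c: float = 18.0
    sigma_ln: float = 0.15
    mass_range_mg: tuple[float, float] = (0.4, 13.57)
    n_per_cell: int = 25
    boltzmann_k: float = BOLTZMANN_EV_PER_K
    mass_distribution: str = "log-uniform"
    plateau: PlateauConfig | None = None

    def __post_init__(self) -> None:
        lo, hi = self.mass_range_mg
        if not (0 < lo < hi):
            raise ValueError("mass_range_mg must be positive and ordered")
        if self.sigma_ln < 0:
            raise ValueError("sigma_ln must be >= 0")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")

    @property
    def mass_geo_mean_mg(self) -> float:
        lo, hi = self.mass_range_mg
        return math.sqrt(lo * hi)


@dataclass(frozen=True)
class ChamberConfig:
    """Respirometer chamber and electrode-noise settings for trace synthesis."""

    flow_l_per_h: float = 0.006
    volume_ml: float = 6.0
    phase_duration_s: float = 900.0
    dt_s: float = 5.0
    noise_sd_torr: float = 0.0
    ar1_rho: float = 0.9
    transient_torr: float = 0.0
    transient_tau_s: float = 120.0


def _draw_masses(params: GenerativeParams, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.mass_range_mg
    if params.mass_distribution == "log-uniform":
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    if params.mass_distribution == "uniform":
        return rng.uniform(lo, hi, size=n)
    raise ValueError(f"unknown mass_distribution {params.mass_distribution!r}")


def generate_population(
    params: GenerativeParams,
    sites: dict[str, SitePreset] | None = None,
    seed: int | np.random.Generator = 0,
    levels: str = "all",
) -> pd.DataFrame:
    """Draw individuals for every site x temperature cell.

    Masses are drawn independently per cell from the same distribution
    (log-uniform on ``mass_range_mg`` by default), so the mass distribution is
    homogeneous across temperature levels up to sampling noise. Body length is
    derived from mass by an isometric cube-root relation with small scatter.
    Chamber/run bookkeeping assigns six chambers per run.

    ``levels`` selects ``"all"`` (5 levels), ``"current"`` (min, ref, max) or
    ``"forecast"`` (max, +0.6, +1.2).
    """
    sites = sites if sites is not None else default_sites()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    run_counter = 0
    idx = 0
    for site in sites.values():
        if levels == "all":
            lv = site.temp_levels_c
        elif levels == "current":
            lv = site.current_levels
        elif levels == "forecast":
            lv = site.forecast_levels
        else:
            raise ValueError(f"unknown levels selector {levels!r}")
        for t in lv:
            masses = _draw_masses(params, params.n_per_cell, rng)
            lengths = 10.25 * (masses / 4.27) ** (1 / 3) * np.exp(rng.normal(0, 0.03, masses.size))
            for j, (m, ln_mm) in enumerate(zip(masses, lengths)):
                chamber = f"ch{j % 6 + 1}"
                if j % 6 == 0:
                    run_counter += 1
                rows.append(
                    {
                        "individual_id": f"{site.name[:3].lower()}_{t:g}C_{idx:04d}",
                        "site": site.name,
                        "chamber_id": chamber,
                        "run_id": f"run{run_counter:04d}",
                        "temp_level_c": float(t),
                        "dry_mass_mg": float(m),
                        "length_mm": float(ln_mm),
                    }
                )
                idx += 1
    return pd.DataFrame(rows)


def expected_ln_smr(
    mass_mg, temp_c, site: SitePreset, params: GenerativeParams
):
    """Deterministic part of the latent ln SMR (J day^-1) for one site.

    Vectorised over ``mass_mg`` and ``temp_c``. Applies the optional
    high-temperature plateau for heavy individuals at configured sites.
    """
    m = np.asarray(mass_mg, dtype=float)
    t = np.asarray(temp_c, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    k = params.boltzmann_k
    inv_kt = 1.0 / (k * (t + KELVIN_OFFSET))
    inv_ref = 1.0 / (k * (params.t_ref_c + KELVIN_OFFSET))
    ln_m = np.log(m)
    e_of_m = params.e0 + params.e_mass_slope * (ln_m - math.log(params.mass_geo_mean_mg))
    ln_smr = (
        params.ln_smr0
        + site.metabolic_level_offset
        + params.b0 * ln_m
        - e_of_m * (inv_kt - inv_ref)
    )
    if params.plateau is not None and site.name in params.plateau.sites:
        inv_kt_max = 1.0 / (k * (site.t_max + KELVIN_OFFSET))
        capped = (
            params.ln_smr0
            + site.metabolic_level_offset
            + params.b0 * ln_m
            - e_of_m * (inv_kt_max - inv_ref)
        )
        hot = t > site.t_max
        heavy = m > params.plateau.mass_threshold_mg
        ln_smr = np.where(hot & heavy, capped, ln_smr)
    return ln_smr


def generate_true_smr(
    mass_mg,
    temp_c,
    site: SitePreset,
    params: GenerativeParams,
    rng: np.random.Generator | None = None,
):
    """Latent SMR (J day^-1), with lognormal noise when ``sigma_ln > 0``."""
    ln_smr = expected_ln_smr(mass_mg, temp_c, site, params)
    if params.sigma_ln > 0:
        if rng is None:
            raise ValueError("rng required when sigma_ln > 0")
        ln_smr = ln_smr + rng.normal(0.0, params.sigma_ln, size=np.shape(ln_smr))
    return np.exp(ln_smr)


def generate_records(
    params: GenerativeParams,
    sites: dict[str, SitePreset] | None = None,
    seed: int = 0,
    levels: str = "all",
) -> pd.DataFrame:
    """Individuals plus latent SMR: the analysis-ready table, no trace layer.

    Columns match the output of the respirometry stage (``smr_j_per_day``,
    ``mass_specific_smr``, ``vo2_umol_per_h``), so the statistical modules can
    be exercised directly on generator output.
    """
    sites = sites if sites is not None else default_sites()
    ss = np.random.SeedSequence(seed)
    rng_pop, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    individuals = generate_population(params, sites, rng_pop, levels=levels)
    smr = np.empty(len(individuals))
    for name, site in sites.items():
        sel = individuals["site"] == name
        if not sel.any():
            continue
        smr[sel.to_numpy()] = generate_true_smr(
            individuals.loc[sel, "dry_mass_mg"].to_numpy(),
            individuals.loc[sel, "temp_level_c"].to_numpy(),
            site,
            params,
            rng_noise,
        )
    out = individuals.copy()
    out["smr_j_per_day"] = smr
    out["vo2_umol_per_h"] = smr / (OXYJOULE_J_PER_UMOL * HOURS_PER_DAY)
    out["mass_specific_smr"] = smr / out["dry_mass_mg"]
    return out


def generate_trace(
    latent_smr: float,
    chamber_cfg: ChamberConfig,
    temp_c: float,
    salinity_psu: float,
    seed: int | np.random.Generator = 0,
    chamber_id: str = "ch1",
    run_id: str = "run0",
) -> tuple[RespirometryTrace, RespirometryTrace]:
    """Synthesize a (specimen, blank) trace pair for one latent SMR.

    Blank PO2 sits at air saturation for (T, S); the specimen steady state is
    depressed by VO2/(S_O2 * F). Both phases carry an optional exponential
    equilibration transient and AR(1) electrode noise. Raises when the implied
    steady-state PO2 would be negative (flow too low for that SMR).
    """
    if latent_smr < 0:
        raise ValueError("latent SMR must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    so2 = compute_solubility(temp_c, salinity_psu).so2
    po2_blank = po2_saturation_torr(temp_c, salinity_psu)
    vo2 = latent_smr / (OXYJOULE_J_PER_UMOL * HOURS_PER_DAY)
    depletion = vo2 / (so2 * chamber_cfg.flow_l_per_h)
    po2_specimen = po2_blank - depletion
    if po2_specimen < 0:
        raise ValueError(
            f"chamber flow {chamber_cfg.flow_l_per_h} L/h too low: steady-state "
            f"PO2 would be {po2_specimen:.1f} torr for SMR {latent_smr:.3g} J/day"
        )
    t = np.arange(0.0, chamber_cfg.phase_duration_s, chamber_cfg.dt_s)

    def _phase(level: float, phase: str) -> RespirometryTrace:
        po2 = level + chamber_cfg.transient_torr * np.exp(-t / chamber_cfg.transient_tau_s)
        if chamber_cfg.noise_sd_torr > 0:
            eps = np.empty(t.size)
            innov_sd = chamber_cfg.noise_sd_torr * math.sqrt(1 - chamber_cfg.ar1_rho**2)
            eps[0] = rng.normal(0, chamber_cfg.noise_sd_torr)
            for i in range(1, t.size):
                eps[i] = chamber_cfg.ar1_rho * eps[i - 1] + rng.normal(0, innov_sd)
            po2 = po2 + eps
        po2 = np.clip(po2, 0.0, None)
        return RespirometryTrace(
            chamber_id=chamber_id,
            phase=phase,
            time_s=t,
            po2_torr=po2,
            flow_l_per_h=chamber_cfg.flow_l_per_h,
            temp_c=temp_c,
            salinity_psu=salinity_psu,
            run_id=run_id,
        )

    return _phase(po2_specimen, "specimen"), _phase(po2_blank, "blank")


def generate_traces_for_records(
    records: pd.DataFrame,
    sites: dict[str, SitePreset] | None = None,
    chamber_cfg: ChamberConfig | None = None,
    seed: int = 0,
) -> list[RespirometryTrace]:
    """Trace pairs for every row of a latent-SMR record table."""
    sites = sites if sites is not None else default_sites()
    cfg = chamber_cfg or ChamberConfig()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(records))
    traces: list[RespirometryTrace] = []
    for (_, row), s in zip(records.iterrows(), child_seeds):
        site = sites[row["site"]]
        spec, blank = generate_trace(
            float(row["smr_j_per_day"]),
            cfg,
            float(row["temp_level_c"]),
            site.salinity_psu,
            np.random.default_rng(s),
            chamber_id=str(row["chamber_id"]),
            run_id=str(row["run_id"]),
        )
        traces.extend([spec, blank])
    return traces


def scenario_to_dict(params: GenerativeParams, sites: dict[str, SitePreset]) -> dict:
    """Serialisable scenario description (inverse of :func:`load_scenario`)."""
    return {
        "params": {
            "b0": params.b0,
            "e0": params.e0,
            "e_mass_slope": params.e_mass_slope,
            "ln_smr0": params.ln_smr0,
            "t_ref_c": params.t_ref_c,
            "sigma_ln": params.sigma_ln,
            "mass_range_mg": list(params.mass_range_mg),
            "n_per_cell": params.n_per_cell,
            "boltzmann_k": params.boltzmann_k,
            "mass_distribution": params.mass_distribution,
            "plateau": (
                {
                    "sites": list(params.plateau.sites),
                    "mass_threshold_mg": params.plateau.mass_threshold_mg,
                }
                if params.plateau
                else None
            ),
        },
        "sites": {
            name: {
                "latitude_deg": s.latitude_deg,
                "salinity_psu": s.salinity_psu,
                "temp_levels_c": list(s.temp_levels_c),
                "metabolic_level_offset": s.metabolic_level_offset,
            }
            for name, s in sites.items()
        },
    }


def load_scenario(source) -> tuple[GenerativeParams, dict[str, SitePreset]]:
    """Load a scenario from a YAML path or an already-parsed mapping."""
    import yaml

    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    pdoc = dict(doc.get("params", {}))
    plateau_doc = pdoc.pop("plateau", None)
    plateau = (
        PlateauConfig(
            sites=tuple(plateau_doc["sites"]),
            mass_threshold_mg=float(plateau_doc.get("mass_threshold_mg", 5.0)),
        )
        if plateau_doc
        else None
    )
    if "mass_range_mg" in pdoc:
        pdoc["mass_range_mg"] = tuple(pdoc["mass_range_mg"])
    params = GenerativeParams(**pdoc, plateau=plateau)
    sites = {
        name: SitePreset(
            name=name,
            latitude_deg=float(sd.get("latitude_deg", 0.0)),
            salinity_psu=float(sd["salinity_psu"]),
            temp_levels_c=tuple(sd["temp_levels_c"]),
            metabolic_level_offset=float(sd.get("metabolic_level_offset", 0.0)),
        )
        for name, sd in doc.get("sites", {}).items()
    } or default_sites()
    return params, sites
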