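"""Flow-through respirometry: from raw oxygen traces to individual SMR.

A flow-through (open-flow) respirometer passes water at a constant flow rate
``F`` through a small chamber holding one animal. At steady state the oxygen
consumption rate follows from the drop in oxygen partial pressure between the
blank (animal-free) outflow and the specimen outflow:

    VO2 = (PO2_out - PO2_in) * S_O2 * F          [umol O2 h^-1]

where ``S_O2`` is the solubility coefficient of dissolved oxygen
(umol L^-1 torr^-1) at the working temperature and salinity, ``PO2_out`` the
blank partial pressure and ``PO2_in`` the specimen partial pressure, both in
torr. VO2 converts to standard metabolic rate (SMR, J day^-1) through the
oxyjoule equivalent (0.45 J per umol O2) and the 24 h day.

The module reads long-format trace tables, averages the steady-state window of
each 15-minute trace with a drift check, computes the oxygen solubility from a
Garcia & Gordon (1992) style saturation fit (Benson & Krause data) with a
vapor-pressure correction, and assembles analysis-ready metabolic records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import (
    ATM_TORR,
    HOURS_PER_DAY,
    KELVIN_OFFSET,
    O2_MOLAR_VOLUME_L,
    O2_MOLE_FRACTION,
    OXYJOULE_J_PER_UMOL,
)

__all__ = [
    "RespirometryTrace",
    "SolubilityCoefficient",
    "WindowConfig",
    "SteadyState",
    "MetabolicRecord",
    "average_steady_state",
    "compute_solubility",
    "o2_saturation_umol_per_l",
    "po2_saturation_torr",
    "water_vapor_pressure_torr",
    "compute_vo2",
    "vo2_to_smr",
    "build_metabolic_table",
    "read_traces_csv",
    "traces_to_frame",
]


class RespirometryError(ValueError):
    """Raised on malformed traces or impossible respirometry inputs."""


@dataclass
class RespirometryTrace:
    """One chamber/phase oxygen time series with its water properties.

    Parameters
    ----------
    chamber_id : str
        Chamber identifier; specimen and blank phases of the same chamber and
        run are paired during table construction.
    phase : {"specimen", "blank"}
    time_s : array-like
        Seconds from the start of the measurement window; strictly increasing.
    po2_torr : array-like
        Dissolved oxygen partial pressure (torr), non-negative.
    flow_l_per_h : float
        Water flow F through the chamber (L h^-1), positive.
    temp_c, salinity_psu : float
        Water temperature (deg C) and salinity (PSU).
    run_id : str
        Measurement run/batch; pairs specimen with its temporally adjacent
        blank.
    """

    chamber_id: str
    phase: str
    time_s: np.ndarray
    po2_torr: np.ndarray
    flow_l_per_h: float
    temp_c: float
    salinity_psu: float
    run_id: str = "run0"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.po2_torr = np.asarray(self.po2_torr, dtype=float)
        if self.phase not in ("specimen", "blank"):
            raise RespirometryError(f"unknown phase {self.phase!r}")
        if self.time_s.shape != self.po2_torr.shape:
            raise RespirometryError("time and PO2 arrays differ in length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise RespirometryError(
                f"trace {self.chamber_id}/{self.phase}: time not strictly increasing"
            )
        if np.any(self.po2_torr < 0):
            raise RespirometryError(
                f"trace {self.chamber_id}/{self.phase}: negative PO2"
            )
        if not self.flow_l_per_h > 0:
            raise RespirometryError("flow must be positive")


@dataclass(frozen=True)
class SolubilityCoefficient:
    """Dissolved-O2 solubility S_O2 (umol L^-1 torr^-1) at (T, S)."""

    so2: float
    temp_c: float
    salinity_psu: float


@dataclass(frozen=True)
class WindowConfig:
    """Steady-state averaging rule for a trace window.

    ``window_frac`` selects the trailing fraction of the trace to average
    (1.0 = the whole nominal 15-min window); ``drift_slope_torr_per_min``
    is the |OLS slope| above which the window is flagged as not at steady
    state. ``smoothing_s`` optionally applies a centred moving average of
    that width before averaging (default: no smoothing).
    """

    window_frac: float = 1.0
    min_points: int = 10
    drift_slope_torr_per_min: float = 0.05
    smoothing_s: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.window_frac <= 1:
            raise ValueError("window_frac must be in (0, 1]")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


@dataclass(frozen=True)
class SteadyState:
    """Result of averaging a trace window."""

    mean_po2_torr: float
    drift_slope_torr_per_min: float
    drift_flag: bool
    n_points: int


@dataclass
class MetabolicRecord:
    """Analysis-ready row: one individual's mass, site, temperature and SMR."""

    individual_id: str
    site: str
    temp_level_c: float
    dry_mass_mg: float
    vo2_umol_per_h: float
    smr_j_per_day: float
    mass_specific_smr: float
    length_mm: float | None = None
    qc_flags: list[str] = field(default_factory=list)


def average_steady_state(trace: RespirometryTrace, window_cfg: WindowConfig | None = None) -> SteadyState:
    """Average the steady-state portion of a trace.

    Takes the arithmetic mean of PO2 over the trailing ``window_frac`` of the
    trace and flags the window when the within-window linear drift exceeds the
    configured slope threshold.
    """
    cfg = window_cfg or WindowConfig()
    t, p = trace.time_s, trace.po2_torr
    if t.size < cfg.min_points:
        raise RespirometryError(
            f"trace {trace.chamber_id}/{trace.phase}: {t.size} samples < "
            f"min_points={cfg.min_points}"
        )
    if cfg.smoothing_s:
        dt = np.median(np.diff(t))
        k = max(1, int(round(cfg.smoothing_s / dt)))
        kernel = np.ones(k) / k
        p = np.convolve(p, kernel, mode="same")
    t_start = t[-1] - cfg.window_frac * (t[-1] - t[0])
    sel = t >= t_start
    if sel.sum() < cfg.min_points:
        raise RespirometryError(
            f"trace {trace.chamber_id}/{trace.phase}: window holds "
            f"{int(sel.sum())} samples < min_points={cfg.min_points}"
        )
    tw, pw = t[sel], p[sel]
    slope_per_s = np.polyfit(tw, pw, 1)[0]
    slope_per_min = slope_per_s * 60.0
    return SteadyState(
        mean_po2_torr=float(pw.mean()),
        drift_slope_torr_per_min=float(slope_per_min),
        drift_flag=bool(abs(slope_per_min) > cfg.drift_slope_torr_per_min),
        n_points=int(sel.sum()),
    )


# Garcia & Gordon (1992) combined fit to the Benson & Krause O2 saturation
# data, coefficients for concentration in mL(STP) per L.  Valid for
# -2 <= T <= 40 degC, 0 <= S <= 42 PSU.
_GG_A = (2.00856, 3.22400, 3.99063, 4.80299, 9.78188e-1, 1.71069)
_GG_B = (-6.24097e-3, -6.93498e-3, -6.90358e-3, -4.29155e-3)
_GG_C0 = -3.11680e-7


def o2_saturation_umol_per_l(temp_c: float, salinity_psu: float) -> float:
    """Air-saturated dissolved O2 concentration (umol L^-1).

    Garcia & Gordon (1992) combined fit (Benson & Krause data), evaluated in
    mL L^-1 and converted with the O2 molar volume at STP.
    """
    ts = math.log((298.15 - temp_c) / (KELVIN_OFFSET + temp_c))
    lnc = sum(a * ts**i for i, a in enumerate(_GG_A))
    lnc += salinity_psu * sum(b * ts**i for i, b in enumerate(_GG_B))
    lnc += _GG_C0 * salinity_psu**2
    ml_per_l = math.exp(lnc)
    return ml_per_l / O2_MOLAR_VOLUME_L  # mL/L -> umol/L


def water_vapor_pressure_torr(temp_c: float, salinity_psu: float) -> float:
    """Saturation water vapor pressure over seawater (torr).

    Green & Carritt (1967) fit with a linear salinity depression.
    """
    tk = temp_c + KELVIN_OFFSET
    ln_p_atm = (
        24.4543
        - 67.4509 * (100.0 / tk)
        - 4.8489 * math.log(tk / 100.0)
        - 0.000544 * salinity_psu
    )
    return math.exp(ln_p_atm) * ATM_TORR


def po2_saturation_torr(
    temp_c: float, salinity_psu: float, atm_pressure_torr: float = ATM_TORR
) -> float:
    """Partial pressure of O2 in water equilibrated with moist air (torr)."""
    return O2_MOLE_FRACTION * (
        atm_pressure_torr - water_vapor_pressure_torr(temp_c, salinity_psu)
    )


def compute_solubility(
    temp_c: float, salinity_psu: float, atm_pressure_torr: float = ATM_TORR
) -> SolubilityCoefficient:
    """Dissolved-O2 solubility coefficient S_O2 (umol L^-1 torr^-1).

    Ratio of the air-saturated O2 concentration to the saturation O2 partial
    pressure at the same temperature and salinity. Strictly decreasing in both
    temperature and salinity over the valid domain.
    """
    if not -2.0 <= temp_c <= 40.0:
        raise RespirometryError(f"temperature {temp_c} degC outside [-2, 40]")
    if not 0.0 <= salinity_psu <= 40.0:
        raise RespirometryError(f"salinity {salinity_psu} PSU outside [0, 40]")
    c_sat = o2_saturation_umol_per_l(temp_c, salinity_psu)
    p_sat = po2_saturation_torr(temp_c, salinity_psu, atm_pressure_torr)
    return SolubilityCoefficient(
        so2=c_sat / p_sat, temp_c=temp_c, salinity_psu=salinity_psu
    )


def compute_vo2(
    po2_blank_torr: float,
    po2_specimen_torr: float,
    so2: float | SolubilityCoefficient,
    flow_l_per_h: float,
) -> float:
    """Oxygen consumption rate (umol O2 h^-1) from the blank/specimen drop.

    VO2 = (PO2_blank - PO2_specimen) * S_O2 * F. A negative value (specimen
    apparently releasing oxygen) is returned as-is; callers flag it.
    """
    s = so2.so2 if isinstance(so2, SolubilityCoefficient) else float(so2)
    if not s > 0:
        raise RespirometryError("solubility coefficient must be positive")
    if not flow_l_per_h > 0:
        raise RespirometryError("flow must be positive")
    for v in (po2_blank_torr, po2_specimen_torr):
        if not math.isfinite(v):
            raise RespirometryError("non-finite PO2")
    return (po2_blank_torr - po2_specimen_torr) * s * flow_l_per_h


def vo2_to_smr(vo2_umol_per_h: float) -> float:
    """Convert VO2 (umol O2 h^-1) to SMR (J day^-1): x 0.45 J/umol x 24 h."""
    if not math.isfinite(vo2_umol_per_h):
        raise RespirometryError("non-finite VO2")
    return vo2_umol_per_h * OXYJOULE_J_PER_UMOL * HOURS_PER_DAY


def build_metabolic_table(
    traces: Iterable[RespirometryTrace],
    individuals: pd.DataFrame,
    window_cfg: WindowConfig | None = None,
    drop_negative: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Join traces with individuals and compute VO2 / SMR / mass-specific SMR.

    Parameters
    ----------
    traces
        Specimen and blank traces; each specimen must have a blank with the
        same ``(run_id, chamber_id)``.
    individuals
        One row per individual with columns ``individual_id, site, chamber_id,
        run_id, temp_level_c, dry_mass_mg`` and optionally ``length_mm`` and a
        user-supplied ``so2`` column that bypasses the solubility fit.
    drop_negative
        When True, records whose VO2 is negative are excluded from the output
        table (they always appear in the QC log).

    Returns
    -------
    (records, qc) : analysis-ready DataFrame and a QC summary dict.
    """
    cfg = window_cfg or WindowConfig()
    by_key: dict[tuple[str, str, str], RespirometryTrace] = {}
    for tr in traces:
        by_key[(str(tr.run_id), str(tr.chamber_id), tr.phase)] = tr

    required = {"individual_id", "site", "chamber_id", "run_id", "temp_level_c", "dry_mass_mg"}
    missing_cols = required - set(individuals.columns)
    if missing_cols:
        raise RespirometryError(f"individuals table missing columns: {sorted(missing_cols)}")
    if individuals["dry_mass_mg"].isna().any() or (individuals["dry_mass_mg"] <= 0).any():
        bad = individuals.loc[
            individuals["dry_mass_mg"].isna() | (individuals["dry_mass_mg"] <= 0),
            "individual_id",
        ].tolist()
        raise RespirometryError(f"non-positive or missing dry mass for: {bad}")

    unmatched = []
    for _, row in individuals.iterrows():
        key = (str(row["run_id"]), str(row["chamber_id"]))
        if (*key, "specimen") not in by_key or (*key, "blank") not in by_key:
            unmatched.append(f"run={key[0]} chamber={key[1]}")
    if unmatched:
        raise RespirometryError(
            "specimen/blank pairing incomplete for: " + ", ".join(unmatched)
        )

    rows = []
    qc_events: list[dict] = []
    for _, row in individuals.iterrows():
        key = (str(row["run_id"]), str(row["chamber_id"]))
        spec = by_key[(*key, "specimen")]
        blank = by_key[(*key, "blank")]
        ss_spec = average_steady_state(spec, cfg)
        ss_blank = average_steady_state(blank, cfg)
        if "so2" in individuals.columns and pd.notna(row.get("so2")):
            so2 = float(row["so2"])
        else:
            so2 = compute_solubility(spec.temp_c, spec.salinity_psu).so2
        vo2 = compute_vo2(ss_blank.mean_po2_torr, ss_spec.mean_po2_torr, so2, spec.flow_l_per_h)
        smr = vo2_to_smr(vo2)
        mass = float(row["dry_mass_mg"])
        flags = []
        if vo2 < 0:
            flags.append("negative_vo2")
        if ss_spec.drift_flag:
            flags.append("specimen_drift")
        if ss_blank.drift_flag:
            flags.append("blank_drift")
        if flags:
            qc_events.append(
                {"individual_id": row["individual_id"], "flags": flags, "vo2": vo2}
            )
        rows.append(
            {
                "individual_id": row["individual_id"],
                "site": row["site"],
                "temp_level_c": float(row["temp_level_c"]),
                "dry_mass_mg": mass,
                "length_mm": float(row["length_mm"]) if "length_mm" in individuals.columns and pd.notna(row.get("length_mm")) else np.nan,
                "vo2_umol_per_h": vo2,
                "smr_j_per_day": smr,
                "mass_specific_smr": smr / mass,
                "so2_umol_per_l_torr": so2,
                "qc_flags": ";".join(flags),
            }
        )
    records = pd.DataFrame(rows)
    n_negative = int((records["vo2_umol_per_h"] < 0).sum())
    if drop_negative:
        records = records[records["vo2_umol_per_h"] >= 0].reset_index(drop=True)
    qc = {
        "n_individuals": int(len(individuals)),
        "n_records": int(len(records)),
        "n_negative_vo2": n_negative,
        "n_drift_flagged": int(sum("drift" in ";".join(e["flags"]) for e in qc_events)),
        "dropped_negative": bool(drop_negative),
        "events": qc_events,
    }
    return records, qc


def traces_to_frame(traces: Sequence[RespirometryTrace]) -> pd.DataFrame:
    """Flatten traces to the long-format ``traces.csv`` schema."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "chamber_id": tr.chamber_id,
                    "phase": tr.phase,
                    "time_s": tr.time_s,
                    "po2_torr": tr.po2_torr,
                    "flow_l_per_h": tr.flow_l_per_h,
                    "temp_c": tr.temp_c,
                    "salinity_psu": tr.salinity_psu,
                    "run_id": tr.run_id,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def read_traces_csv(path) -> list[RespirometryTrace]:
    """Read a long-format trace table and group it into trace objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {
        "chamber_id", "phase", "time_s", "po2_torr",
        "flow_l_per_h", "temp_c", "salinity_psu",
    }
    missing = required - set(df.columns)
    if missing:
        raise RespirometryError(f"traces table missing columns: {sorted(missing)}")
    if "run_id" not in df.columns:
        df["run_id"] = "run0"
    traces = []
    for (run, chamber, phase), g in df.groupby(["run_id", "chamber_id", "phase"], sort=True):
        g = g.sort_values("time_s")
        traces.append(
            RespirometryTrace(
                chamber_id=str(chamber),
                phase=str(phase),
                time_s=g["time_s"].to_numpy(),
                po2_torr=g["po2_torr"].to_numpy(),
                flow_l_per_h=float(g["flow_l_per_h"].iloc[0]),
                temp_c=float(g["temp_c"].iloc[0]),
                salinity_psu=float(g["salinity_psu"].iloc[0]),
                run_id=str(run),
            )
        )
    return traces
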