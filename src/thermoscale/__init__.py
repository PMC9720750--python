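"""thermoscale: mass- and temperature-dependence of standard metabolic rate.

A pipeline from raw flow-through respirometry oxygen traces to individual
standard metabolic rates (SMR), mass-scaling exponents across temperatures
and collection sites, Boltzmann-Arrhenius activation energies by body-mass
class for current and forecast temperature ranges, Q10 coefficients, and an
LMG decomposition of explained SMR variance — with a synthetic-data generator
that reproduces the statistical structure the analysis assumes.
"""

__version__ = "0.1.0"

from .constants import BOLTZMANN_EV_PER_K, OXYJOULE_J_PER_UMOL
from .respirometry import (
    MetabolicRecord,
    RespirometryTrace,
    SolubilityCoefficient,
    WindowConfig,
    average_steady_state,
    build_metabolic_table,
    compute_solubility,
    compute_vo2,
    vo2_to_smr,
)
from .scaling import (
    GlobalAncova,
    MassScalingModel,
    compare_across_temperatures,
    fit_global_ancova,
    fit_mass_scaling,
    stepwise_simplify,
)
from .synth import (
    ChamberConfig,
    GenerativeParams,
    PlateauConfig,
    SitePreset,
    default_sites,
    generate_population,
    generate_records,
    generate_trace,
    generate_traces_for_records,
    generate_true_smr,
)
from .thermal import (
    ArrheniusModel,
    assign_mass_classes,
    compute_q10,
    compute_temperature_anomaly,
    fit_arrhenius,
    inverse_thermal_energy,
    q10_table,
    slope_heterogeneity_test,
)
from .varpart import anova_oneway, lmg_shares
from .pipeline import PipelineConfig, run_pipeline
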