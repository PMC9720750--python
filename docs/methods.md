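# Methods

This note documents the models implemented in `thermoscale`, the choices
made where the underlying protocol left the design open, and what the
synthetic-data generator does and does not emulate.

## Respirometry inversion

Flow-through respirometry measures the steady-state oxygen drop between the
blank outflow (`P_O₂,out`, animal-free) and the specimen outflow
(`P_O₂,in`), alternated in 15-minute windows on the same chamber and run:

    V̇O₂ = (P_O₂,out − P_O₂,in) · S_O₂ · F

* **Steady-state rule.** A trace window is summarised by the arithmetic mean
  of PO₂ over its trailing `window_frac` (default 1.0, i.e. the whole
  nominal 15-minute window), with an OLS drift check: |slope| above
  0.05 torr min⁻¹ (configurable) flags the window as not settled. The rule
  is deliberately simple — robust, reproducible, tunable — because field
  protocols rarely state an explicit averaging convention. Optional moving-
  average smoothing is exposed (`smoothing_s`) and off by default.
* **Solubility.** `S_O₂ = C_sat(T,S) / pO₂_sat(T,S)`, with the air-saturated
  O₂ concentration from the Garcia & Gordon (1992) combined fit to the
  Benson & Krause data (mL L⁻¹ coefficients, converted with the 22.391 L/mol
  molar volume) and `pO₂_sat = 0.20946·(P_atm − p_vapor)`, vapor pressure
  from the Green & Carritt (1967) seawater fit. Practitioners often read
  S_O₂ off a web converter; those tools are not bit-reproducible, so the
  implementation accepts a user-supplied `so2` column that bypasses the fit
  entirely. The implemented fit matches the Benson–Krause tabulated
  freshwater saturation at 20 °C to <0.1%.
* **Blank pairing** uses the temporally paired blank of the same
  chamber/run, matching the alternating 15 + 15 min protocol.
* **Negative V̇O₂** (blank below specimen) is retained and QC-flagged, never
  silently clipped; `drop_negative` excludes such records from model fits on
  request. Dropping data silently is worse than modelling a known artefact.
* **Energy conversion.** SMR (J day⁻¹) = V̇O₂ × 0.45 J (µmol O₂)⁻¹ × 24; the
  oxyjoule equivalent assumes a mixed catabolic substrate appropriate for a
  detritivorous amphipod.

## Statistical models

* **Log base.** All fits use natural logarithms. Scaling exponents are
  base-invariant; intercepts are reported in ln units with a log10
  conversion column for comparison with base-10 conventions.
* **Per-site ANCOVA** codes temperature level as a categorical factor with
  the site's minimum temperature as reference, so each level's slope and
  intercept contrast is read directly off the dummy × lnM coefficients. The
  contrasts are algebraically identical to differences of the separate
  per-level fits (tested).
* **Global model.** Temperature enters the global ANCOVA as continuous °C
  (a single coefficient), not as levels. The full model is
  lnM × T × site; backward elimination drops the least-significant
  removable term (highest order first) by nested-model F-tests at α = 0.05,
  and never removes a main effect while an interaction containing it is
  retained. The "mixed" variant of this model in the motivating study never
  names its random term; the default here is fixed-effects OLS, with an
  optional random intercept (`random_group`, e.g. `run_id`) refitted by
  REML on the selected fixed structure. Model selection itself runs on the
  OLS likelihood — selecting fixed effects under REML across different
  fixed structures is not valid.
* **Mass classes** are quantile bins (0.33, 0.66, 0.99) of the pooled mass
  distribution, type-7 (linear interpolation) quantiles by default and
  configurable, since the binning convention is rarely stated. Individuals
  above the 0.99 quantile are kept in the large class with a QC note
  (default) rather than dropped.
* **Arrhenius fits** regress ln(SMR/M) on the continuous 1/kT of the
  assigned temperature level (matching an inverse-temperature axis), with
  site intercept dummies. The site × 1/kT interaction is F-tested: p ≥ α
  pools the slope into a single E; otherwise per-site E values are reported
  alongside. E is always reported signed with its p-value — a
  non-significant decline stays a negative estimate, never clamped to zero.
  The **forecast range** includes the current-maximum level as an anchor
  (3 levels: max, +0.6, +1.2): with only the two increment levels a fit
  with site terms would have no residual degrees of freedom.
* **Boltzmann constant.** The default is the physical
  k = 8.617333×10⁻⁵ eV K⁻¹. A `boltzmann_k` override exists everywhere
  because a transposed-digit variant (8.167×10⁻⁵) circulates in print;
  switching k rescales E by exactly k'/k and leaves every p-value unchanged
  (tested).
* **Q10** uses the standard definition (R₂/R₁)^(10/(T₂−T₁)) against each
  site's minimum temperature. For rates generated from an Arrhenius law,
  Q10 = exp(10E/(kT₁T₂)) — used as a cross-module consistency oracle.
* **Temperature anomalies** subtract a same-calendar-day climatology;
  Feb 29, underrepresented in any window, uses the mean of the Feb 28 and
  Mar 1 climatology values.
* **LMG.** Interactions are their own predictor groups, but orderings in
  which an interaction enters before a parent main effect are excluded
  (marginality restriction): an interaction's "share" is only meaningful
  conditional on its main effects. Shares are reported both as % of total
  response variance (summing to the full-model R²) and as % of explained
  variance (summing to 100), since published tables use either convention.
  Exact ordering enumeration is used up to 6 groups; beyond that a
  subset-weighted route counts admissible orderings by dynamic programming
  over down-sets of the marginality order. Both routes agree to 10⁻¹⁰
  (property-tested).

## Synthetic-data generator

The generator encodes the study conditions as its defaults and is the
package's substitute for undeposited field data:

    ln SMR = ln_smr0 + site_offset + b0·ln M − E(M)·(1/kT − 1/kT_ref)
    E(M)   = e0 + e_mass_slope·ln(M / M_geo)

* masses log-uniform on 0.4–13.57 mg, identically distributed across
  site × temperature cells; 25 individuals per cell (375 total);
* b0 = 0.75 (canonical ¾-power scaling); e0 = 0.44 eV and
  e_mass_slope = −0.13 eV per ln-mass, chosen so the class-level activation
  energies at the class mean masses span ≈0.48 eV (small) down to
  ≈0.27–0.29 eV (medium/large) within the annual range;
* site ln-offsets (Quarantia +0.3, Lesina 0, Acquatina 0) encode the higher
  metabolic level of the high-latitude population;
* lognormal scatter sigma_ln = 0.15 conflates biological and measurement
  variability — the protocol gives no way to separate them;
* centring at t_ref = 18 °C decorrelates intercepts and slopes without
  changing E;
* an optional plateau (`PlateauConfig`) caps ln SMR of individuals above a
  mass threshold at its current-maximum value for selected (low-latitude)
  sites, emulating metabolic homeostasis beyond the locally experienced
  range. It is off by default: thermal sensitivity is generated as a
  *continuous* function of ln-mass, and mass classes must emerge from the
  estimator, not be baked into the generative law.
* Site presets: reference 18 °C everywhere, Quarantia maximum 25.0 °C
  (forecast 25.6/26.2), Lesina maximum 28.0 °C (28.6/29.2), Acquatina
  minimum 12.0 °C; salinities 20/22/21 PSU. Three remaining cells have no
  published value and are filled with synthetic-scenario choices
  (Quarantia minimum 8.0 °C, Lesina minimum 11.0 °C, Acquatina maximum
  27.0 °C) completing a plausible Adriatic lagoon gradient; all preset
  values are overridable through the scenario YAML.

Raw traces are synthesised as the exact inverse of the respirometry
equation: blank PO₂ at air saturation for (T, S), specimen steady state
depressed by V̇O₂/(S_O₂·F), plus an exponential equilibration transient and
AR(1) electrode noise. With the default 6 mL h⁻¹ flow and the default
intercept (0.5 J day⁻¹ at 1 mg, 18 °C), the hottest, largest cells deplete
well below the ≈155 torr blank without reaching zero; a configuration whose
implied steady state would be negative raises immediately.

**What the generator does not emulate:** activity bouts and spontaneous
movement, electrode drift and calibration error, within-individual repeated
measurement structure, mortality/selection during acclimation, and any
ecological dynamics. Passing recovery tests therefore demonstrates that the
estimators invert the assumed generative law at realistic noise — not that
field data satisfy that law.

## Numerical choices and problem sizes

* Regressions are OLS via statsmodels; design matrices are assembled per
  named term (dummy coding against the first level) so nested F-tests,
  stepwise elimination and grouped LMG all share one structure. Rank
  deficiency is detected up front and reported with the aliased terms.
* Quantiles: type-7. Ties in stepwise p-values break toward the
  higher-order term, then the larger p.
* Monte-Carlo checks in the test suite and acceptance script use 100–1000
  replicates per property (200 for parameter-recovery means, 1000 for the
  type-I error of the slope-heterogeneity ANCOVA, 500 for CI coverage);
  these sizes put the Monte-Carlo standard error comfortably inside each
  asserted band while keeping the default run quick on a laptop.
* All randomness descends from a single root seed through named
  `SeedSequence` substreams; identical configs give byte-identical outputs.

## Known limitations

* The generator's scatter (sigma_ln = 0.15) yields a tighter global R²
  (≈0.96) than is typical of field respirometry of amphipods (≈0.5–0.6);
  recovery results at this noise level say nothing about heavier-tailed
  field error.
* The ANCOVA family assumes lognormal, homoscedastic errors on the ln
  scale; no robust/quantile variants are provided.
* Closed-chamber (intermittent) respirometry, electrode-drift calibration
  modelling and activity correction are out of scope.
* The LMG subset route is exponential in the number of groups (fine for the
  ≤8 groups these models produce); PMVD and dominance analysis are not
  implemented.
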