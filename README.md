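# thermoscale

Mass- and temperature-dependence of standard metabolic rate (SMR) in aquatic
ectotherms, from raw flow-through respirometry traces to activation energies,
scaling exponents, Q10 tables and variance partitioning.

The package is aimed at metabolic ecologists and ecophysiologists working
with flow-through (open-flow) respirometry of small aquatic invertebrates —
the motivating system is a lagoon amphipod measured at three collection sites
along a latitudinal gradient, at five temperature levels per site: the local
annual minimum, a common 18 °C reference, the local annual maximum, and two
forecast increments (+0.6 and +1.2 °C above the maximum, the conservative
IPCC RCP2.6 warming by 2040 and 2100).

## The models

**Respirometry.** At steady state the oxygen consumption of an individual in
a flow-through chamber is

    V̇O₂ = (P_O₂,out − P_O₂,in) · S_O₂ · F        [µmol O₂ h⁻¹]

with blank/specimen partial pressures in torr, flow `F` in L h⁻¹, and the
solubility coefficient `S_O₂` (µmol L⁻¹ torr⁻¹) computed from a
Garcia–Gordon (Benson–Krause) saturation fit with vapor-pressure correction.
SMR (J day⁻¹) = V̇O₂ × 0.45 J (µmol O₂)⁻¹ × 24 h.

**Mass scaling.** SMR = a·M^b, fitted as ln SMR = ln a + b ln M per
site × temperature, compared across temperatures by ANCOVA against each
site's lowest temperature, and jointly in a global ln M × T × site ANCOVA
with full interactions simplified by marginality-respecting backward
elimination (nested F-tests at α = 0.05).

**Thermal sensitivity.** Individuals are binned into small/medium/large
classes at mass quantiles (0.33, 0.66, 0.99). Within a class,
ln(SMR/M) = c − E·(1/kT) with k = 8.617333×10⁻⁵ eV K⁻¹ gives the activation
energy E (eV); site intercepts are included and the site × 1/kT interaction
is pooled away when non-significant. Q10 = (R₂/R₁)^(10/(T₂−T₁)).

**Relative importance.** The explained SMR variance is decomposed over
predictor groups with the LMG metric (sequential R² averaged over orderings),
restricted to orderings in which an interaction never precedes its main
effects.

A synthetic-data generator (`thermoscale.synth`) produces populations, latent
SMR values (power law × Boltzmann–Arrhenius with mass-dependent activation
energy and site offsets), and raw trace pairs (saturation blank, depressed
specimen steady state, equilibration transient, AR(1) electrode noise), so
the whole pipeline is testable without any field data.

## Worked example

```python
import thermoscale as ts

params = ts.GenerativeParams()          # 3 sites x 5 levels x 25 individuals
sites = ts.default_sites()
records = ts.generate_records(params, sites, seed=42)

fit = ts.stepwise_simplify(ts.fit_global_ancova(records))
print(fit.summary())
```

```
Global ANCOVA of ln SMR on ln M, temperature (degC) and site
retained terms: lnM + T + site + lnM:T
total R2 = 0.9641
                   coef      se        t       p
Intercept       -2.0611  0.0390 -52.8763  0.0000
lnM              1.0793  0.0269  40.1382  0.0000
T                0.0753  0.0016  46.7949  0.0000
site[Lesina]    -0.0135  0.0204  -0.6632  0.5076
site[Quarantia]  0.2959  0.0206  14.3914  0.0000
lnM:T           -0.0179  0.0012 -15.4489  0.0000
eliminated: lnM:T:site (p=0.553), T:site (p=0.594), lnM:site (p=0.131)
```

The stepwise procedure keeps mass, temperature, site and the negative
mass × temperature interaction: the SMR response to temperature weakens with
increasing body mass, and the high-latitude site (Quarantia) carries a
higher metabolic level (+0.30 ln units). The marginal coefficients are
centered at the data, so the lnM coefficient is not itself the scaling
exponent at 18 °C (b = 1.0793 − 0.0179·T at temperature T).

```python
classed, _ = ts.assign_mass_classes(records)
print(ts.fit_arrhenius(classed, mass_class="small", temp_range="current",
                       site_presets=sites).summary())
```

```
Arrhenius fit (small class, current range)
E = 0.579 +/- 0.022 eV (p=6.61e-39, n=75, R2=0.911, k=8.61733e-05 eV/K)
site x 1/kT: F_2,69 = 0.90, p = 0.41 -> pooled E
  intercept contrast Lesina: -0.044 ln units
  intercept contrast Quarantia: +0.289 ln units
```

Small individuals' mass-specific SMR rises with temperature at ≈0.58 eV in
this draw; the thermal slope does not differ among sites (pooled E), while
the high-latitude site again sits ≈0.29 ln units higher.

The full pipeline (synthetic traces → respirometry inversion → all report
tables) runs from the shell:

```sh
thermoscale all --outdir out --seed 42
```

writing `metabolic_records.csv`, the global-model / contrast / equation /
Arrhenius tables, `q10_table.csv`, `variance_partition.csv` and a
`run_manifest.json` that records the seed, constants and elimination traces.

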