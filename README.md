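# limnogas

Dissolved-gas biogeochemistry for stratified (meromictic) soda lakes.

Tropical soda lakes can hold extraordinary dissolved CH₄ concentrations in
their oxic surface waters while simultaneously acting as CO₂ sinks, because
their high pH keeps CO₂(aq) vanishingly small relative to HCO₃⁻/CO₃²⁻.
Quantifying what that means for greenhouse-gas exchange requires a chain of
standard but fiddly computations that this package implements as a tested
library (with a thin CLI) for limnologists and biogeochemists:

- **Headspace partitioning** (`limnogas.headspace`): flask headspace mole
  fractions → dissolved/headspace/total moles via Henry's law and the
  ideal-gas law.
- **Carbonate-system carbon isotopes** (`limnogas.carbonate_isotope`):
  δ¹³C of dissolved CO₂ from measured δ¹³C-TDIC by equilibrium mass
  balance,
  δ¹³C-CO₂ = δ¹³C-TDIC − (HCO₃/TDIC)·ε₁ − (CO₃/TDIC)·(ε₂ + ε₁), with
  ε₁ = ε_HCO₃−CO₂ = 9866/T − 24.12 ‰ and ε₂ = ε_CO₃−HCO₃ = 1.85 − 666/T ‰;
  plus closed-form carbonate speciation at a given pH.
- **Water–air fluxes** (`limnogas.gas_exchange`): thin-boundary-layer model
  Φ = β·k·(C_w − C_eq) with a registry of k600 wind-speed relations
  (Crusius–Wanninkhof, Cole–Caraco, Nightingale), Schmidt-number
  polynomials, Weiss / Wiesenburg–Guinasso solubilities, barometric station
  pressure, O₂ saturation, and the Hoover–Berkshire chemical-enhancement
  factor β for CO₂ invasion at high pH.
- **Profile diagnostics** (`limnogas.profile_core`): chemocline/oxycline
  location from conductivity and O₂ profiles, gas depletion-depth
  extrapolation, chlorophyll-a from extract absorbance.
- **DOM–CH₄ screen** (`limnogas.dom_screen`): van Krevelen classification
  (H/C, O/C, modified aromaticity index) of FT-ICR-MS molecular formulas
  and Spearman rank correlation of per-depth abundances against the CH₄
  profile, with exact permutation p-values for small depth counts.
- **Synthetic lake** (`limnogas.synthetic_data`): a seeded two-layer
  meromictic scenario generator with known ground truth for every stage.

See `docs/methods.md` for the models, assumptions, defaults and
limitations.

## Worked example

CH₄ efflux and CO₂ influx for a soda-lake surface (151 µmol CH₄ L⁻¹ and
1 µmol CO₂ L⁻¹ at 0.5 m), 21 °C, wind U₁₀ = 2 m s⁻¹, site elevation
1884 m:

```bash
limnogas flux --gas CH4 --cw 151 --gas CO2 --cw 1 \
    --temp-c 21 --u10 2 --model all --elevation-m 1884
```

```
gas,model,k600_cm_h,Sc,k_cm_h,beta,Ceq_umol_L,flux_mgC_m2_d
CH4,cole_caraco,2.769,654.26,2.613,1.0,0.00226,1137.16
CO2,cole_caraco,2.769,635.86,2.663,1.0,12.44,-87.84
CH4,crusius_wanninkhof,1.44,654.26,1.359,1.0,0.00226,591.47
CO2,crusius_wanninkhof,1.44,635.86,1.385,1.0,12.44,-45.69
CH4,nightingale,1.12,654.26,1.057,1.0,0.00226,460.03
CO2,nightingale,1.12,635.86,1.077,1.0,12.44,-35.54
```

(numeric columns abbreviated here; the command prints full precision).
Each row is one k600 wind relation: `k600_cm_h` its prediction at
U₁₀ = 2 m s⁻¹, `Sc` the gas's Schmidt number at 21 °C, `k_cm_h` the
velocity rescaled by (Sc/600)^(−0.67), `Ceq_umol_L` the atmospheric
equilibrium concentration at 0.80 atm station pressure (410 ppm CO₂,
1.87 ppm CH₄). Positive fluxes are efflux: the lake loses ~460–1140 mg
CH₄-C m⁻² d⁻¹ to the atmosphere while drawing down ~36–88 mg CO₂-C m⁻²
d⁻¹, because surface water is ~12 µmol L⁻¹ undersaturated in CO₂.
Passing `--ph 9.5` switches CO₂ to the chemically enhanced pathway
(β ≈ 4.6 at these conditions) instead of β = 1.

Bottom-water δ¹³C of dissolved CO₂ from titration and isotope data:

```bash
limnogas isotope d13c-co2 --hco3 9523 --co3 2196 \
    --co2-umol 126 --d13c-tdic 10.7 --temp-c 21
```

```
d13C-CO2: 1.36 permil vs V-PDB
  TDIC: 192.79 mmol/L (f_HCO3 0.810, f_CO3 0.190)
  eps_HCO3-CO2: 9.42  eps_CO3-HCO3: -0.41 permil
```

The CO₂ pool is ¹³C-depleted by ~9.3 ‰ relative to TDIC because nearly
all carbon sits in the isotopically heavier bicarbonate/carbonate pools.

Synthetic data with known truth:

```bash
limnogas simulate profile --seed 7 --out profile.csv
limnogas simulate formulas --seed 7 --out formulas.csv
limnogas dom screen --profile profile.csv --formulas formulas.csv --out screen.csv
```

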