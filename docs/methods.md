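# Methods

`limnogas` implements the dissolved-gas biogeochemistry of a stratified
(meromictic) soda lake: converting flask headspace measurements into
dissolved gas amounts, recovering the carbon-isotope composition of
dissolved CO₂ from total dissolved inorganic carbon (TDIC), estimating
water–air CO₂ and CH₄ diffusive fluxes with the thin-boundary-layer (TBL)
model including chemical enhancement at high pH, locating the lake's
chemocline and oxycline from sonde profiles, and screening molecular-formula
(FT-ICR-MS) abundance tables for covariation with the CH₄ depth profile.
A synthetic-lake generator provides inputs with known ground truth so every
stage is testable without field data.

## Depth profiles and stratification diagnostics

Depths are stored positive-downward in metres on a strictly increasing grid
(renderers may negate for display). Operations never interpolate across
missing cells: a diagnostic uses only the depths where its required
variables are present, and reports which depths it used.

**Chemocline.** The estimator is the midpoint of the depth interval with
the maximum absolute finite-difference conductivity gradient
|Δκ/Δz|, ties broken toward the shallowest interval. This is a deliberate
design choice — the boundary in a meromictic lake is conventionally read
off the conductivity step, but no standard point estimator exists; the
interval midpoint is unbiased for a symmetric logistic transition sampled
on a grid that brackets it symmetrically. It is exactly invariant under
adding a constant to conductivity and shifts one-for-one with a depth-axis
translation.

**Oxycline.** The shallowest interval midpoint where dissolved O₂ crosses
from ≥ threshold to < threshold. The anoxia threshold defaults to
0.5 mg L⁻¹ (configurable); anoxic layers in these systems typically read
~0.1 mg L⁻¹, so 0.5 separates them cleanly from oxygenated surface water
(several mg L⁻¹) while tolerating sonde noise. A profile already anoxic at
its shallowest depth places the oxycline there; a profile that never
becomes anoxic raises an error rather than fabricating a boundary. If the
estimated oxycline falls below the chemocline (possible only on data
inconsistent with the two-layer conceptual model), it is clamped to the
chemocline and flagged, preserving the OSW → ASW → BW ordering of layer
labels.

**Gas depletion depth.** An ordinary least-squares line of concentration
against depth over a caller-chosen window, extrapolated to zero
concentration. With depth positive downward, upward depletion corresponds
to a positive fitted slope dC/dz; a non-positive slope is flagged
"no depletion" and no crossing is reported. A crossing above the water
surface (negative depth) is returned as-is with a flag — it indicates the
fitted decrease would not exhaust the gas within the water column. The
window is deliberately a caller decision: the extrapolated depth is highly
sensitive to which limb of the profile is fitted, so the package does not
fix a default beyond the conventional 2–4.5 m lower limb.

**Chlorophyll-a.** Extract concentration from Beer–Lambert,
c = A / (a*·l), scaled by extract-to-filtered volume. The specific
absorption coefficient is interpreted as 84.1 L g⁻¹ cm⁻¹ — the standard
magnitude for Chl-a in 90% acetone. (The literal unit string
"ml µg⁻¹ cm⁻¹" sometimes attached to this number is dimensionally
inconsistent with Chl-a optics by three orders of magnitude; the
gram-based reading is the one that reproduces standard spectrophotometric
practice.) The coefficient is a parameter.

## Flask headspace partitioning

A pre-evacuated flask of volume V_f partially filled with sample water
(V_w) equilibrates; gas chromatography measures headspace mole fractions
x_i. Assuming Henry's-law equilibrium at the analysis temperature:

- headspace moles  n_g = x_i·P·(V_f − V_w) / (R·T), with
  R = 0.0820574 L atm mol⁻¹ K⁻¹ and T in kelvin;
- aqueous concentration  c = K_H·x_i·P  (mol L⁻¹), K_H the molar
  solubility in mol L⁻¹ atm⁻¹;
- dissolved moles  n_l = c·V_w;  total  n_t = n_l + n_g  exactly.

The reported partial pressure re-expands n_t over the full flask volume
(the "total gas-accessible volume" convention), making values comparable
across fill fractions. Headspace pressure defaults to 1 atm at analysis
time and is configurable, as are the Henry constants (shipped defaults are
freshwater values near 25 °C from the Sander compilation, source-tagged;
a CSV can replace them). When the constant's stated temperature differs
from the sample temperature by more than a tolerance (default 5 °C) a
warning is recorded in the result provenance rather than raised — the
temperature dependence of K_H over a few degrees is smaller than typical
GC error, but the analyst should see it. No non-ideal-gas or salting-out
corrections are applied in this module.

## Carbonate system and δ¹³C of dissolved CO₂

At pH ≥ 9.5 nearly all dissolved inorganic carbon is HCO₃⁻/CO₃²⁻, so
δ¹³C-CO₂ must be computed, not measured. Assuming chemical and isotopic
equilibrium among the species:

    δ¹³C-CO₂ = δ¹³C-TDIC − (HCO₃/TDIC)·ε_HCO3−CO2
                          − (CO₃/TDIC)·(ε_CO3−HCO3 + ε_HCO3−CO2)

with enrichment factors (‰, T in K):

    ε_HCO3−CO2 = 9866/T − 24.12
    ε_CO3−HCO3 = 1.85 − 666/T

Concentrations are mmol L⁻¹; titrated mg L⁻¹ values convert with molar
masses 61.017 (HCO₃⁻) and 60.009 (CO₃²⁻) g mol⁻¹. The result object
carries the species fractions and both ε values for provenance. The
relation is linear in δ¹³C-TDIC with unit slope, and collapses to
δ¹³C-CO₂ = δ¹³C-TDIC when the carbonate species vanish.

**Speciation.** Closed-form fractions from a_H = 10^(−pH) (hydrogen-ion
activity) and apparent constants K′₁, K′₂: the three fractions are
a_H², K′₁a_H, K′₁K′₂ over their sum. One known quantity fixes the scale:
TDIC, the titrated (HCO₃, CO₃) pair (CO₂ then follows as HCO₃·a_H/K′₁),
or carbonate alkalinity (HCO₃ + 2CO₃ + OH − H; infeasible combinations of
alkalinity and pH raise an error). Default constants are the classical
freshwater fits (Harned & Davis 1943 for K₁, Harned & Scholes 1941 for K₂,
Harned & Owen for K_w), giving pK₁ ≈ 6.38, pK₂ ≈ 10.37, pK_w ≈ 14.13 at
21 °C; they are replaceable via `EquilibriumConstants`.

**Known limitation — ionic strength.** No activity/ionic-strength
correction is applied by default. A hypersaline soda-lake monimolimnion
has apparent constants that differ appreciably from the freshwater values
(pK′₂ lower by up to a few tenths), so pH values inferred from species
ratios there are upper-bound estimates; full brine speciation with ion
pairing is out of scope. The δ¹³C mass balance itself takes measured
concentrations and is unaffected by this choice.

## Thin-boundary-layer fluxes

    Φ_i = β·k_i·(C_i,w − C_i,eq)

reported in mg C m⁻² d⁻¹ (cm h⁻¹ → m d⁻¹ via ×0.24; µmol L⁻¹ ≡ mmol m⁻³;
12.011 mg C mmol⁻¹), positive from water to air.

- **Schmidt numbers** from the fourth-order freshwater polynomial fits for
  CO₂ and CH₄ (valid 0–40 °C; out-of-range raises by default).
- **k600 registry**: 0.72·U₁₀ (Crusius–Wanninkhof), 0.215·U₁₀^1.7 + 2.07
  (Cole–Caraco), 0.23·U₁₀² + 0.1·U₁₀ (Nightingale), all cm h⁻¹ with U₁₀ in
  m s⁻¹. The Schmidt exponent is −0.67 for U₁₀ < 3 m s⁻¹ (smooth surface)
  and −0.5 otherwise; exactly 3 m s⁻¹ takes −0.5, for continuity with the
  rough-surface regime.
- **Equilibrium concentrations** C_eq = K₀(T,S)·x_atm·p_station with the
  Weiss (1974) CO₂ solubility and the Wiesenburg–Guinasso (1979) CH₄
  Bunsen coefficient (divided by 22.414 L mol⁻¹). Defaults: dry-air
  410 ppm CO₂ and 1.87 ppm CH₄ (configurable), salinity 0 for the
  mixolimnion, and station pressure from the isothermal barometric formula
  p = exp(−z/8400 m) at the site elevation (0.799 atm at 1884 m). At these
  conditions C_eq(CO₂) ≈ 12.4 µmol L⁻¹ and C_eq(CH₄) ≈ 0.0023 µmol L⁻¹ —
  negligible against ≥151 µmol L⁻¹ lake water.
- **Chemical enhancement** (CO₂ only — supplying β ≠ 1 for another gas is
  an error). Hoover–Berkshire stagnant-film model: CO₂ reacts while
  diffusing through the boundary layer with combined pseudo-first-order
  rate r = r₁ + r₂·K_w/a_H (hydration r₁ from the Johnson 1982 fit,
  ~0.026 s⁻¹ at 21 °C; hydroxylation r₂ from the Pinsent fit,
  ~6.2×10³ L mol⁻¹ s⁻¹ at 21 °C; both overridable). With
  τ = 1 + a_H²/(K′₁K′₂ + K′₁a_H), CO₂ diffusivity
  D = 14.6836×10⁻⁵·(T_K/217.2056 − 1)^1.997 cm² s⁻¹, and
  Q = √(rτ/D)·D/k (k in cm s⁻¹):

      β = τ / ((τ − 1) + tanh(Q)/Q)

  β ≥ 1 always, is non-increasing in k, and → 1 as k → ∞. At the default
  site conditions (21 °C, pH 9.5, k ≈ 1.4 cm h⁻¹) β ≈ 4.6.
- **Two reporting pathways.** `flux_table` computes fluxes with β = 1
  (`enhancement="unit"`, the default) or with Hoover–Berkshire β for CO₂
  (`"hoover_berkshire"`). The β = 1 pathway is the benchmarked one: the
  published flux set this package reproduces scales linearly with k600
  across the three wind models for CO₂ as well as CH₄, which is the β ≈ 1
  signature (in a strongly enhanced regime βk ≈ √(rτD), nearly independent
  of k). The enhanced pathway is validated against an independent
  re-evaluation of the closed-form expression on a parameter grid rather
  than against published flux values, and both are exposed so the user can
  report either.
- **O₂ saturation** from the García–Gordon (Benson–Krause) fit, µmol kg⁻¹
  converted at 1 kg L⁻¹ and scaled linearly by station pressure — adequate
  for judging sonde readings against saturation; not a high-precision
  density-corrected value.

## DOM–CH₄ covariation screen

Molecular formulas (C,H,N,O,S counts with per-depth relative abundances)
are placed on the van Krevelen plane and classified with the modified
aromaticity index AImod = (1 + C − O/2 − S − H/2)/(C − O/2 − S − N),
taking AImod = 0 when the denominator is non-positive:
aromatic-like when AImod > 0.5; aliphatic-like when H/C ≥ 1.5 and
AImod ≤ 0.5; "other" for the remainder. These are the standard FT-ICR-MS
conventions; the thresholds are a configurable rule set, since different
laboratories draw the aliphatic boundary differently.

Formulas present (abundance > 0) at **every** depth are screened by
Spearman rank correlation against the CH₄ profile; the number excluded by
this filter is reported. With n ≤ 8 depths the two-sided p-value comes
from the exact permutation distribution of ρ — all n! pairings of the
(average-tie) rank vectors, cached per tie structure — and from the usual
t approximation for larger n. A formula with constant abundance (all
ranks tied) has undefined ρ and is flagged non-significant. Raw p-values
are binned at 0.005 and 0.01 by the sign of ρ
(pos_strong/pos_weak/neg_strong/neg_weak/ns); no multiple-testing
correction is applied, mirroring the raw-p convention of van Krevelen
significance maps — an FDR column can be added downstream if desired.
`class_fraction_summary` reports, per class, the percentage with
significant (p < 0.01) positive and negative correlation, with counts;
an empty class reports NaN (undefined), not 0.

## Synthetic lake generator

The generator's defaults are the emulated study system's conditions:
the seven-depth grid 0–4.5 m; oxycline 1.5 m and chemocline 3.5 m;
temperature 22.4 → 20.5 °C and O₂ 3.6 → 0.1 mg L⁻¹ across the oxycline;
pH 9.61 → 9.47, conductivity, CH₄ 153 → 615 µmol L⁻¹, CO₂ 1 → 120 µmol L⁻¹,
DOC 97.3 → 593 mg L⁻¹, HCO₃⁻ → 9523 and CO₃²⁻ → 2196 mg L⁻¹, δ¹³C-CH₄
−16 → −78 ‰ and δ¹³C-TDIC 2.91 → 10.7 ‰ across the chemocline. Transitions
are logistic with steepness 8 m⁻¹ — steep enough that, on the default grid,
the maximum conductivity-gradient interval is (3, 4) m and the O₂ crossing
interval is (1, 2) m, so zero-noise recovery of the boundaries is exact.
Gaussian relative noise (default sd 2%, a typical sonde/GC reproducibility
figure) applies to conductivity, O₂, gases, DOC and carbonate species;
temperature, pH and isotope ratios stay clean. Noise draws are truncated
at zero and truncation events counted.

**DOM table.** Formulas are rejection-sampled per class (proposal H/C and
O/C ranges, accepted only if the classifier agrees, so truth labels are
guaranteed). Within the aliphatic-like class a planted fraction (default
0.275) receives abundances that are a *rank-uniform monotone transform* of
the realized CH₄ profile — base·(1 + amplitude·(rank−1)/(n−1)) — with
multiplicative Gaussian noise (default sd 5%); a planted fraction of
aromatic-like formulas (default 0.34) gets the reversed ordering; all
remaining formulas get independent lognormal abundances (null). The rank
transform is used rather than a linear map of concentrations because the
CH₄ profile is nearly flat above the chemocline: a linear map would let
measurement-scale noise scramble the ranks of the four surface depths and
make the planted covariation undetectable by construction, whereas rank
spacing makes the planted signal strength a single interpretable parameter
(noise sd relative to the uniform rank step). With the defaults the
per-formula detection probability at p < 0.01 is high and the recovered
class fractions land within the binomial 95% interval of the planted
fractions.

**Flask rows** are generated as the exact inverse of the partitioning
equation (mole fraction = c/(K_H·P)), so the round trip is exact to
floating point — a pure contract check for the headspace module.

All generators are pure functions of (scenario, seed); a single integer
seed feeds one named substream per generator (profile / formulas / flask),
so adding a generator never perturbs existing fixtures.

**What passing on synthetic data does not show.** The generator draws
independent Gaussian/lognormal noise on parametric logistic shapes. Real
profiles have correlated sensor drift, internal waves, and non-logistic
fine structure; real FT-ICR-MS tables have intensity-dependent missingness,
correlated formula families, and instrument normalization artifacts. Tests
on synthetic data demonstrate the estimators' correctness and calibration
under the stated noise model, not their field performance.

## Numerical choices and problem sizes

- Exact permutation null distributions are cached by rank tie-structure;
  n = 7 costs one 5040-row enumeration per structure.
- Chemocline gradient ties break toward the surface (first argmax).
- β evaluation switches tanh(Q)/Q to its limit 1 below Q = 10⁻⁸.
- Acceptance and test computations run at the study's own scale (single
  profiles of 7 depths, 400-formula tables); nothing is down-sampled.

## Out of desk scope (documented limitation)

Quantities in the emulated study that depend on field or instrument data
are out of scope and are not asserted by any test: the field DOM fractions
(27.5% aliphatic-like covarying / 34% aromatic-like anti-covarying — the
synthetic generator plants these fractions as defaults, and the screen
recovers the planted values, but the field values themselves cannot be
recomputed without the FT-ICR-MS dataset), community-ordination statistics
(PERMANOVA/PCoA), the cross-lake CH₄ literature regression, and all
sequencing, qPCR and flow-cytometry numbers. Ebullition fluxes were not
measured in the study and are not modelled. The 1.2 m CH₄
depletion-depth figure is window-dependent (the fitting window is a caller
choice) and is likewise not asserted.
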