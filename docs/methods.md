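# Methods

This note records the models, the defaults that matter, the calibrations,
and the limits of what the package's tests demonstrate.

## Feedstock characterization

Compositions are stored as unitless fractions; table readers convert from
the conventional %TS layout. The carbohydrate pool is everything volatile
that is neither protein nor lipid (NfE + R_F = VS − R_P − R_L); the
detergent-fiber series (NDF ≥ ADF ≥ ADL) splits it into starch,
hemicellulose, cellulose and lignin.

**ThOD.** Theoretical oxygen demand is computed from combustion
stoichiometry with nitrogen leaving as ammonia, using *nominal integer
atomic masses* (C = 12, H = 1, O = 16, N = 14). Published substrate-fraction
ThOD tables are built on these masses; IUPAC masses move the second decimal
(protein 1.41 vs 1.42 g O₂/g). The mass table is an argument for callers who
want exact masses.

**Degradation coefficient.** d = (NDF − VS(1 − D_VS)) / (NDF − ADL)
attributes the substrate's observed overall degradability D_VS first to the
fully degradable pools (protein, lipid, starch) and lets d absorb the
remainder as cellulose/hemicellulose degradability. Values outside [0, 1]
are clamped with a warning — they indicate an inconsistent D_VS for the
composition, not a numerical issue. With the packaged characterizations,
d = 0.151 (manure) and 0.165 (prairie biomass).

**f-factors.** f_Ch = (R_F+NfE − NDF + (NDF−ADL)d)/VS, f_P = R_P/VS,
f_L = R_L/VS, f_I = (ADL + (NDF−ADL)(1−d))/VS. Substituting the pool
identity shows Σf = 1 algebraically; the property suite verifies closure to
1e-9 on 10⁴ randomized compositions. A negative starch term (NDF exceeding
the carbohydrate pool, common for washed forages) is clamped to zero with a
warning and the deficit moved into the inert factor so closure survives.

**Manure solubles.** Ruminant manure arrives partially disintegrated; fixed
shares of composite COD (10.8% monosaccharide, 2.7% amino acid, 0.8% LCFA,
5.7% soluble inert — 20.0% total) are moved to the soluble pools and
subtracted from the corresponding particulate factors. Acetate solubility
is zero and is not modelled.

**Blending.** The default strategy characterizes each feedstock separately
(its own X_c, d, f-factors, solubles) and sums COD loads at the wet-mass
flows that deliver the prescribed VS split; the influent carries COD-weighted
f-factors. A `blend-composition` option mass-averages the compositions first
and characterizes the mixture once — kept to probe how the blending rule
changes the effective degradability, which linear blending leaves between
the mono values.

**Influent nitrogen.** Total feed nitrogen is taken as 16% of protein mass
(the standard Kjeldahl 6.25 factor, configurable). The part already carried
organically by ADM1's protein/amino-acid pools (N_aa × protein COD ≈ 13.9%
of protein mass) stays organic; only the remainder enters as influent
inorganic nitrogen. This avoids double-counting protein nitrogen while
keeping the feed's total N at the Kjeldahl value.

## ADM1

The digester is the standard ADM1 in the BSM2 parameterization: 26 liquid
states, 3 gas states, 19 biochemical processes. Specific choices:

- **DAE-as-ODE.** Ion speciation (ionized VFAs, bicarbonate, ammonia,
  hydroxide, H⁺ — the eight algebraic variables) is solved from the charge
  balance at every right-hand-side evaluation by a warm-started Newton
  iteration with a log-space bisection fallback; the returned root's
  residual is below 1e-12 kmol/m³ (verified by independent substitution in
  the tests).
- **Closed stoichiometry.** The inorganic carbon and nitrogen columns of the
  Petersen matrix are computed per process from the C/N contents of every
  other state, so the biochemical stoichiometry conserves COD, C and N at
  machine precision *by construction*; the composite pool's contents derive
  from its (feedstock-specific) f-factors. Decayed biomass returns to the
  composite pool and is re-partitioned with the same f-factors.
- **Inhibition.** Lower-pH-only Hill functions per trophic group,
  non-competitive hydrogen inhibition of acetogens, free-ammonia inhibition
  of acetoclastic methanogens (K_I = 0.0018 kmol N/m³), and a nitrogen
  limitation term. For the manure feed the ammonia term is the binding one
  (≈0.43 at steady state) — the expected behaviour for nitrogen-rich
  manure digestion.
- **Gas phase.** Dynamic headspace at 10% of liquid volume (config); gas
  outflow follows an overpressure law whose conductance scales with liquid
  volume, which makes the steady state intensive: scaling the influent flow
  at fixed concentrations and HRT leaves it unchanged (tested to 1e-8).
  Reported gas volumes are at 0 °C and 1 atm by default (`reference="25C"`
  available), since reporting conventions differ between studies.
- **Temperature.** Mesophilic is fixed at 35 °C; equilibrium and Henry
  constants are van 't Hoff-corrected from 25 °C.
- **Startup.** Integrating a high-strength feed (≈115 kgCOD/m³ here) at
  full load from a small inoculum collapses pH in the model exactly as in
  practice — the acidified washout state is a genuine stable steady state of
  ADM1. The default run therefore mimics an operator: settle at 10% organic
  load (stiff BDF integration in one-HRT windows), then step the load to
  100% in Newton-continuation increments, and finish with a Newton polish of
  the full right-hand side. The polish makes the reported steady state
  independent of the start to solver precision; converged roots are rejected
  if they are unphysical or have clearly jumped to the washout basin
  (collapsed acetoclasts, pH outside 4.5–9.5). Explicitly supplied initial
  states integrate directly, preserving the model's real multistability for
  studies that want it.
- **Calibration.** Per-feedstock kinetic overrides (hydrolysis,
  disintegration, uptake constants) merge key-by-key over the BSM2 defaults
  via config; the package ships no fitted values, so predicted yields are
  compared to literature bands and orderings, not to any single study's
  numbers. One parameter set serves all blend ratios. At the packaged
  defaults the model predicts 192 mL CH₄/gVS for manure mono-digestion
  (literature band 181–270) and 137 mL/gVS for prairie biomass (band
  104–309), with co-digestion intermediate — the model contains no synergy
  mechanism, so blends interpolate rather than exceed the mono endpoints.

## Plant balance

All flows are hourly steady-state means. The digester feed is diluted to
10% TS with recycled water; 5% of raw biogas (both species) is combusted
for site utilities; the scrubber captures 98% of the remaining CO₂ with MEA
makeup proportional to capture (45 kg/t CO₂, a calibration anchored to the
amine-makeup cost share typical of this plant class, ≈$1.0–1.3/GJ); the CH₄
leak is 2% of the upgraded product's volumetric flow, speciated as pure
CH₄. Residual digestate CH₄ (57 m³/dry tonne all-biomass to 139 all-manure,
linear in VS share) is captured into the RNG product by default
(`capture_residual_ch4=False` treats it as emitted). Biochar is undegraded
solids (characterization-level: dry feed − VS × D_VS) times a thermal-yield
factor fitted once to the two observed mono-digestion production rates
(557 and 436 kg/dry tonne) and interpolated on VS share — a calibration,
not a pyrolysis model. Utility demand uses per-m³-of-feed coefficients
(40 MJ heat, 1 kWh power) chosen so the 5% combustion split covers most of
the duty and the natural-gas purchase stays small and positive. The H₂S
removal step is a cost placeholder: base ADM1 carries no sulfur.

## Techno-economics

Capital = $13.31M × (raw biogas / 5,690 m³ d⁻¹)^0.6; the anchor flow is the
all-biomass scenario's throughput, so capital spans ≈$13.3–16.5M over the
sweep and peaks with the gassiest (manure-rich) scenarios. Financial
defaults: 7% required return, 20-year life, 90% capacity factor, 21% tax,
10-year straight-line depreciation, fixed O&M at 6% of capital per year,
feedstocks priced on wet mass as received ($41/t manure, $120/t biomass),
biochar sold at $150/t with a 0.91 marketable-recovery factor. Taxable
losses are offset at the margin (loss carryforward), which keeps the NPV
affine in price and every cost line; the MFSP is found by bracketed root
search (|NPV| < $1, verified independently) and the $/GJ breakdown —
feedstock, MEA, natural gas, fixed O&M, capital recovery grossed up for tax
net of the depreciation shield, biochar credit — sums to the MFSP exactly.

## Life-cycle assessment

Functional unit: 1 GJ RNG, well-to-gate. Six inventory streams (biomass,
manure, displaced N fertilizer, MEA, natural gas, CH₄ leak) carry packaged
TRACI characterization factors per kg; manure and displaced fertilizer rows
are credit-signed (manure is an avoided waste). Biochar's nitrogen (1.78%
dry wt herbaceous, 1.71% manure-derived, VS-share weighted) displaces
synthetic N fertilizer 1:1 by N mass — the displaced-product factor is
applied per kg of that nitrogen; if the factor is instead per kg of a
fertilizer product, the offset scales by that product's N fraction, a
recognized ambiguity left to config. Impacts are linear in flows and
invariant under joint scaling of flows and RNG rate. Transport of purchased
chemicals is an optional additional per-kg factor defaulting to zero, since
the factor table has no separate transport stream. Allocation
(mass/energy/economic; 22 MJ/kg biochar, 52.5 MJ/kg RNG, economic at the
solved MFSP) applies to the *un-expanded* totals — system expansion and
allocation are alternative co-product treatments and are never combined.

## Sensitivity

One-at-a-time ±20% perturbations around a baseline scenario (default
B1:M9), applied downstream of the digester: the ADM1 steady state is
computed once and the perturbed quantity (a price, a rate, a flow, a
factor) is re-propagated. Outputs are the MFSP and the net GWP; results are
ranked by output span. At defaults the RNG yield is the top MFSP driver and
the manure flow/factor pair dominates the GWP.

## Synthetic fixtures

`fixture_generator` draws valid compositions constructively: detergent
ordering, pool feasibility and a degradation coefficient in [0, 1] hold for
every sample; ~10% of draws have NDF above the carbohydrate pool to
exercise the starch clamp, and every 25th sits at the starch boundary. The
generator emulates the *structure* of characterization tables, not the
covariances of real forage assays — property tests on these fixtures
demonstrate algebraic closure and robustness, not agreement with any real
substrate.

## Problem sizes and numerical settings

Steady states use BDF integration (rtol 1e-6, species-scaled atol down to
1e-12 for dissolved hydrogen) in one-HRT windows with a 1e-6
relative-change-per-HRT steady criterion, then Newton polish. The standard
sweep is eleven ratios; property suites use 10⁴ random compositions, 10³
random states for conservation checks, and a few hundred draws elsewhere —
sizes chosen so the whole suite runs in well under a minute of simulation
time while leaving the asserted tolerances (1e-9 closures, 1e-12 residuals)
far from their failure points.

## Known limitations

- No co-digestion synergy: blends interpolate the mono-digestion kinetics,
  so the observed phenomenon of blends out-yielding *both* mono cases
  appears only weakly (via the manure-supplied nitrogen), if at all.
- No sulfur chemistry, phosphorus, or ammonia-inhibition refinements beyond
  standard ADM1; no parameter estimation from gas curves.
- The biochar and capital models are calibrated interpolations, valid near
  the packaged feedstocks and plant scale only.
- Biogas CH₄ fraction (~57%) sits at the low end of field experience, a
  known trait of COD-balanced ADM1 feeds rich in carbohydrate.
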