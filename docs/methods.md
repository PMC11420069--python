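# Methods

This note documents the model as implemented: its assumptions, parameter
choices, the synthetic-data design, numerical conventions, and the places
where the design was genuinely open and a choice had to be made.

## Scope and overall structure

The package is a desk-scale counterpart of a global recursive-dynamic
land-use assessment. It keeps the mechanisms — saturating sequestration
with vintage accounting, calibrated quadratic adoption costs, a biochar
feedstock market, a light-use-efficiency stand simulator, and the ex-post
tax/subsidy ledger — and deliberately drops everything that requires a full
partial-equilibrium world model: bilateral trade, endogenous land-cover
transitions, forestry responses, and energy-system coupling. Price and
quantity responses of commodities to the non-CO₂ tax are therefore a
reduced form (constant-elasticity supply contraction, elasticity 0.3, with
50 % cost pass-through to prices) whose only job is to give the economics
ledger non-trivial turnover entries; their magnitudes carry no claims.

Sequestration options are modelled as policy instruments: they deploy only
in scenarios that price agricultural CO₂ (`agCO2*`). In `baseline` and
`default*` scenarios adoption is identically zero, including the yield
co-benefit channel — without a removal subsidy there is no programme to
enrol in. This matches the scenario matrix, where the `default*` rows
exclude agricultural CO₂ options by construction.

## Synthetic world generator

The generator emulates the statistical structure the analysis needs, not
geography:

- **Regions** (default 10; the real-world counterpart uses 37) belong to
  five macro groups (AFR, LAM, ASIA, NORTH, OTHER_SOUTH) that govern yield
  co-benefits, GDP-based residue cost scaling, and the climate archetype.
- **Land areas** are a Dirichlet split (concentration 3.0) of configured
  global totals, so the totals are conserved exactly. The default totals —
  cropland 1,698 Mha, pasture 1,833 Mha — are back-derived from published
  adoption shares (900 Mha = 53 % of cropland, 1,100 Mha = 60 % of managed
  grassland) and are illustrative, not census figures.
- **Climate** follows three latitude-band archetypes (tropical,
  subtropical, temperate) with sinusoidal seasonality and additive noise;
  frost days are derived from monthly minimum temperature. Only plausible
  seasonal structure matters: the growth module consumes these records, and
  its outputs are used as relative coefficients, not biome predictions.
- **Sequestration coefficients** for SOC (cropland 0.45–0.80, pasture
  0.35–0.70 tCO₂e ha⁻¹ yr⁻¹) and biochar (1.60–2.10) are uniform draws
  within ranges bracketing published per-hectare magnitudes (SOC ≈ 0.5–0.6,
  biochar ≈ 2.1). Silvo-pasture coefficients are simulated, not drawn.
- **Exogenous bioenergy demand** on the shared feedstock pools is 444 Mtdm
  yr⁻¹ at baseline (≈ 50 % of 16 EJ yr⁻¹ of other solid biomass at
  18 GJ tdm⁻¹) and 2,222 Mtdm yr⁻¹ at the 1.5 °C level (≈ 40 EJ yr⁻¹ of
  solid-biomass feedstock pull in deep-mitigation scenarios). The 1.5 °C
  level is what makes feedstock competition bind, reproducing the
  qualitative result that enhanced bioenergy demand substantially reduces
  the economic biochar potential.

What the generator does **not** emulate: spatial autocorrelation, real
commodity heterogeneity (one crop and one livestock aggregate per region),
inter-annual climate variability, or any real-world country mapping.
Passing tests therefore demonstrate internal consistency and mechanism
fidelity, not geographic realism.

Serialization uses CSV tables with 17-significant-digit floats and reads
them back with round-trip float parsing, so `read(write(w)) == w` holds
exactly and re-serialization is byte-identical.

## Silvo-pasture growth simulator

A reduced 3-PG-family model on a monthly step, for the 25 % tree strip of a
silvo-pasture hectare:

- GPP = α · APAR · Π fᵢ, NPP = y · GPP with y = 0.47. α is the canopy
  quantum efficiency of the archetype (eucalypt 0.9, poplar 0.8 gC per MJ
  absorbed PAR, i.e. 9.0e-7 / 8.0e-7 tC MJ⁻¹); the values were chosen once
  so that simulated stands reach realistic plantation stocks (about 45–115
  tC ha⁻¹ of tree strip after 30 years, harvests of 24–65 tdm ha⁻¹ after
  10), which places annualized full-hectare rates at 0.7–3.5 tCO₂e ha⁻¹
  yr⁻¹, bracketing the ≈ 0.9 reported for silvo-pastures.
- Modifier forms: temperature — the standard asymmetric 3-PG response
  (1 at t_opt, 0 at/outside [t_min, t_max]); VPD — exp(−k_d·VPD), k_d =
  0.5–0.6 kPa⁻¹; soil water — sigmoid in the moisture ratio of a monthly
  bucket (rain in, radiation-driven PET of 0.15 mm per MJ m⁻² d⁻¹ per day
  out); frost — frost-free-day fraction; fertility — 1 (tree strips are
  assumed fertilized, hence unlimited by nutrients); age —
  1/(1+(age/0.95·max_age)⁴); CO₂ — 1 under historical climate. The
  soil-water sigmoid (rather than the raw ratio) is the one functional-form
  deviation taken for robustness: with a raw ratio, a single dry season
  multiplies growth by ≈ 0 and stands never establish in monsoonal
  archetypes.
- Allocation: root share rises linearly from 0.25 to 0.60 as the product of
  modifiers falls (harsh conditions push carbon below ground); the shoot
  remainder is split 30/70 foliage/stem. Fractions sum to 1 exactly, and
  Δpools + turnover = NPP holds to 1e-9 relative every step (tested).
- Turnover: fixed monthly fractions (foliage 0.02, root 0.015, stem 0);
  mortality is ignored because rotations are short and stands managed. The
  turnover/mortality treatment of plantation strips is not specified in the
  source assessment; these are documented knobs, not estimates.
- Species selection: eucalypt at mean annual temperature ≥ 11 °C, poplar
  below; below −2 °C no archetype matches and selection fails loudly.
  Stocking densities are drawn within the stated ranges (1,250–2,500
  stems ha⁻¹ for the 10-year system, 400–600 for the 30-year system),
  denser for poplar.
- Credited carbon: the 10-year bioenergy system reaches a "new equilibrium"
  after 10 years — implemented as the time-average standing stock over the
  rotation (the long-run average of staggered plantings); stem and foliage
  are harvested, roots remain. The 30-year carbon system credits the final
  standing stock. Both convert to full-hectare annualized rates with the
  0.25 strip fraction, 44/12, and the option's saturation horizon.
- Nutrient demand: nitrogen = compartment increments × tissue N
  concentrations, net of a constant soil mineralization supply (1 % of the
  soil N stock per year — a reduced stand-in for a full soil decomposition
  coupling); phosphorus is a fixed fraction of nitrogen.

## Options, vintages, saturation

Five variants per region: `soc_crop`, `soc_pasture`, `silvo_bioenergy`,
`silvo_carbon`, `biochar`. Saturation horizons 20/20/10/30/30 years.
Combinability: SOC+biochar on cropland and SOC+silvo on pasture may share a
hectare with additive fluxes; the two silvo systems are mutually exclusive
and share one 50 % cap. Dis-adoption is not modelled: the policy is assumed
to keep carbon in place, so vintage areas never shrink. Biochar carries no
area cap — its 28 %-of-cropland scale emerges from feedstock limits, not a
constraint. The `SequestrationOption` validator accepts any positive
integer horizon (not only the three defaults) because the sensitivity suite
shifts horizons by ±10 years and the price-dynamics demonstration uses a
5-year horizon.

## Adoption market and calibration

Marginal cost c₁ + s·a against marginal revenue p·q + v. For SOC options
c₁ = 0 — the stated calibration (90 %/60 % at 100 USD₂₀₀₀) then determines
s exactly and the round-trip is machine-precision. For the silvo systems
c₁ is positive: 150 USD₂₀₀₀ ha⁻¹ yr⁻¹ for the 10-year system
(establishment, maintenance, harvest) and 8 % of that for the 30-year
system, following the reported cost decomposition. Because the stated
calibration pins down only the SOC curves, silvo and biochar slopes are
anchored so that adoption reaches the cap at the top endpoint price
(200 USD₂₀₀₀) when the option is profitable at all; unprofitable options
(net margin ≤ 0) simply stay at zero.

The yield co-benefit is valued as v = (yield_k · q / 100) × crop revenue
per hectare and enters both the adoption condition and the SOC calibration.
Adoption is myopic (no foresight), consistent with recursive-dynamic
convention; together with saturation this generates the early-uptake
effect: high prices trigger adoption early, and those vintages can saturate
before 2050, so the 2050 annual flux can be lower at a higher price
endpoint even though cumulative mitigation is higher. With the default
20–30-year horizons this non-monotonicity appears only at the top
endpoints; with a 5-year horizon it is pronounced (both are exercised in
the tests).

Biochar adoption is bounded each period by the feedstock the merit-order
market allocates to it after livestock feed (15 % of sustainable residues)
and exogenous bioenergy demand are served. The 50 % pyrolysis byproduct
offsets exogenous bioenergy demand before fresh feedstock is drawn; the
resulting fixed point is solved by damped iteration (the map is a
contraction with factor 0.5). The allocation's shadow price is the unit
cost of the marginal pool. Infeasible total demand yields a reported
shortfall, never an exception.

## Economics ledger

All identities are exact by construction and property-tested on random
tables: net_producer = Δturnover − tax + subsidy, net_government = tax −
subsidy, and their sum equals the turnover change (transfer neutrality).
Turnover change is the revenue difference p_scn·q_scn − p_base·q_base, not
Δp·Δq — only this reading reproduces the signs of published aggregates.
The packaged `reference_global_components.csv` carries published global
component values for three pricing scenarios and is used to validate the
identities against their published net positions. Price labels floor the
1.63-converted value to the nearest multiple of 5 (163 → 160, 326 → 325);
currency aggregates are displayed to the nearest 5 billion, full precision
internally.

## Scenario runner and sensitivity suite

The five-row scenario matrix runs end to end against a baseline
counterfactual on the identical world draw; every run records a manifest
(config hash invariant to key order, seed, output list), and re-running
reproduces all outputs bit-identically. Perturbations are pure config
transforms: saturation ±10 years, doubled cost parameters, a 30 % livestock
demand cut in NORTH regions (the magnitude is a free parameter; no source
value exists), the 1.5 °C bioenergy level, tree-strip fractions of 0.20 and
0.15 (silvo rates scale linearly with the strip fraction), and caps × 0.75
or × 0.50. Two perturbations are structurally inert for in-horizon
mitigation and intentionally so: extending saturation by 10 years changes
nothing before 2050 because no vintage adopted after the 2030 price start
is older than 20 years by then, and the livestock demand cut moves only the
economics ledger, since land supply is not endogenous here.

## Numerical conventions and problem sizes

Default world: 10 regions, 5-year steps, 2020–2050 (extensible beyond 2050
by linear price continuation). A full scenario-matrix run takes a few
seconds; the test suite (169 tests, including 8 full MACC horizon runs on a
3-region world and 1,000-draw ledger property checks) completes in well
under a minute. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; ties between options with equal net margins
break lexicographically by option id. Floats serialize at 17 significant
digits; CSV re-parsing uses round-trip precision.

## Known limitations

- No land-market feedback: areas are fixed, so mitigation does not shift
  production across regions; the reduced-form supply response captures only
  the own-price effect of the non-CO₂ tax.
- The growth simulator omits mixed-stand light competition, bark/branch
  pools, water-use outputs, and parameter databases; two archetypes stand
  in for a species portfolio.
- Feedstock competition is a single global merit-order market without
  transport costs or regional segmentation.
- The world-average yield co-benefit (≈ 0.9 % per tCO₂ ha⁻¹ yr⁻¹) is an
  emergent aggregate here, not a constraint; whether the published average
  is area- or production-weighted is unknown.
- Climate impacts on sequestration are excluded by design (historical
  climate throughout).
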