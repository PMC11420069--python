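# agrocarbon

Desk-scale economic assessment of CO₂ sequestration options on agricultural
land. The package models three mitigation technologies — enhanced soil
organic carbon (SOC) management on cropland and pastures, silvo-pasture
systems (tree alleys on 25 % of the pasture hectare, in a 10-year bioenergy
rotation or a 30-year carbon rotation), and biochar application to cropland
— and asks how much carbon they sequester, at what cost, and who pays, when
a greenhouse-gas price ramps up linearly from 2030 to 2050.

It is written for researchers and students in land-use and climate-policy
modelling who want a transparent, fully synthetic, reproducible sandbox for
the mechanisms that large partial-equilibrium land-use models implement at
global scale: saturating carbon dynamics with vintage (cohort) accounting,
calibrated quadratic adoption-cost curves, feedstock competition between
biochar and bioenergy, marginal abatement cost curves (MACCs), and the
ex-post incidence of carbon taxes and subsidies on farmers and governments.
Everything runs from a synthetic world generator — no external data.

## The model

**Carbon dynamics.** Each option sequesters at a constant annualized rate
*q* (tCO₂e ha⁻¹ yr⁻¹) from adoption until a saturation horizon *T*
(20 yr for SOC, 30 yr for biochar and the 30-year silvo-pasture system,
10 yr for the 10-year system's biomass equilibrium). Adoption is
irreversible and tracked by vintages: a cohort of area *aᵥ* adopted in year
*tᵥ* contributes

    F(t) = Σᵥ aᵥ · q · 1[ 0 ≤ t − tᵥ < T ]

so the cumulative stock telescopes to Σᵥ aᵥ q min(t − tᵥ, T).

**Adoption.** Moving a share *a* of a land type into an option costs
C(a) = c₁a + (s/2)a², so marginal cost is c₁ + s·a. Each 5-year period,
each region adopts myopically up to

    a* = clip( (p·q + v − c₁) / s , 0, a_max )

where *p* is the current GHG price and *v* the value of yield co-benefits
(1.5 / 1.2 / 0.7 % yield per tCO₂ ha⁻¹ yr⁻¹ in the Africa / Latin America /
Asia groups). The SOC slopes *s* are calibrated so that a price of
100 USD₂₀₀₀ tCO₂e⁻¹ yields exactly 90 % adoption on cropland and 60 % on
pasture. Caps: 90 % (cropland SOC), 60 % (pasture SOC), 50 % combined for
the two mutually exclusive silvo-pasture systems; biochar is
feedstock-limited rather than area-capped.

**Silvo-pasture growth.** A monthly light-use-efficiency simulator: GPP =
α · APAR · Π fᵢ with Beer–Lambert light interception and multiplicative
modifiers fᵢ ∈ [0,1] for temperature, vapour-pressure deficit, soil water,
frost, fertility, stand age and CO₂; NPP = y · GPP is allocated to roots,
foliage and stem with root allocation prioritized under harsh conditions.
Rotation results feed per-hectare sequestration coefficients and harvested
bioenergy biomass back into the option catalog.

**Biochar chain.** Feedstock carbon content 0.45 tC tdm⁻¹ × 50 % retention
× 79.6 % 100-year storage = 0.1791 tCe tdm⁻¹ (displayed 0.18); chain cost
35 USD₂₀₀₀ tCO₂e⁻¹; 50 % of feedstock mass returns as a bioenergy
byproduct. Feedstock (crop residues at 50 % sustainable removal, silvo
harvest, other wood) clears a merit-order market against livestock feed and
exogenous bioenergy demand (baseline vs 1.5 °C level).

**Economics.** Ex post, per region and sector:
net_producer = Δturnover − tax + subsidy, net_government = tax − subsidy,
with tax = emissions × p and subsidy = removals × p; transfers cancel
exactly. Non-CO₂ gases convert with AR4 GWPs (298 N₂O, 25 CH₄); money
converts from USD₂₀₀₀ to USD₂₀₂₂ at 1.63.

## Worked example

```python
from agrocarbon.runner import run_scenario

run = run_scenario({"world": {"n_regions": 10}}, "agCO2_bio",
                   endpoint=100.0, seed=1)
for k, v in run.summary.items():
    print(f"{k}: {v:.1f}")
```

prints

```
annual_flux_2050: 4206.9
cumulative_mitigation: 37478.9
tax: 473.6
subsidy: 685.7
net_producer: 316.1
net_government: -212.1
macc_area_cost: 337.1
```

Read: under the `agCO2_bio` scenario (non-CO₂ emissions taxed, agricultural
CO₂ removals subsidized, 1.5 °C bioenergy demand) with a price ramp ending
at 100 USD₂₀₀₀ (163 USD₂₀₂₂) in 2050, the ten synthetic regions sequester
about 4.2 GtCO₂e yr⁻¹ in 2050 and 37.5 GtCO₂e cumulatively over 2020–2050.
Producers pay 474 billion USD₂₀₂₂ of GHG tax but receive 686 billion of
carbon subsidies, ending up 316 billion ahead of the baseline; the
government position is the mirror image of the net transfer. The economic
cost of adoption (area under the marginal cost curves) is 337 billion.

The same run is available from the shell:

```bash
agrocarbon run-scenario --scenario agCO2_bio --endpoint 100 --seed 1 --out out/
agrocarbon build-macc --seed 1 --out macc.csv
```

`build-macc` traces the cumulative MACC over the eight standard price
endpoints (25–200 USD₂₀₀₀, i.e. about 40–325 USD₂₀₂₂) with a by-option
decomposition; cumulative mitigation rises monotonically with the price
endpoint while the 2050 *annual* flux can decline at the top endpoints as
early-adopted vintages saturate before 2050.

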