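"""Physical, economic and policy constants shared across the model.

Units follow the conventions used throughout the package: areas in Mha,
masses in Mt (dry matter unless stated), carbon in tC or MtC, fluxes in
tCO2e ha-1 yr-1 or MtCO2e yr-1, money in constant USD2000 internally with
an ex-post conversion to USD2022 for reporting.
"""

from __future__ import annotations

# Stoichiometry
CO2_PER_C = 44.0 / 12.0

# 100-year global warming potentials (AR4 values)
GWP_N2O = 298.0
GWP_CH4 = 25.0

# Ex-post currency deflator, USD2000 -> USD2022 (US GDP deflator, global uniform)
USD2000_TO_USD2022 = 1.63

# Adoption-cost calibration: price at which the quadratic cost curve is fitted
CALIBRATION_PRICE_USD2000 = 100.0
CALIBRATION_SHARE_CROPLAND = 0.90
CALIBRATION_SHARE_PASTURE = 0.60

# Maximum adoption potentials (fraction of the relevant land type)
MAX_SHARE_SOC_CROPLAND = 0.90
MAX_SHARE_SOC_PASTURE = 0.60
MAX_SHARE_SILVO_COMBINED = 0.50

# Saturation horizons, years after adoption during which the flux persists
SATURATION_SOC = 20
SATURATION_BIOCHAR = 30
SATURATION_SILVO_BIOENERGY = 10
SATURATION_SILVO_CARBON = 30

# Silvo-pasture geometry: fraction of the hectare planted as tree alleys,
# and the matching loss of grazing biomass supply
TREE_STRIP_FRACTION = 0.25

# Species selection: mean annual temperature threshold below which the
# temperate archetype (poplar) replaces eucalypts
POPLAR_MAT_THRESHOLD_C = 11.0

# Stocking density ranges, stems per hectare of tree strip
DENSITY_RANGE_10YR = (1250.0, 2500.0)
DENSITY_RANGE_30YR = (400.0, 600.0)

# Wood density used for Mm3 <-> Mtdm conversions where a source reports volume
WOOD_DENSITY_TDM_M3 = 0.5

# Energy content used to convert exogenous bioenergy demand stated in EJ
BIOMASS_ENERGY_GJ_PER_TDM = 18.0

# GHG price trajectory convention
PRICE_START_YEAR = 2030
PRICE_END_YEAR = 2050
PRICE_ENDPOINTS_USD2000 = (25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 175.0, 200.0)
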