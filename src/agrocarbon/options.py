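"""Technology catalog and vintage-tracked carbon-flux dynamics.

Five option variants are modelled per region: enhanced soil organic carbon
(SOC) management on cropland and on pastures, two silvo-pasture systems
(a 10-year bioenergy rotation and a 30-year carbon rotation), and biochar
application to cropland. Each option sequesters at a constant per-hectare
rate from adoption until its saturation horizon, after which the flux of
that adoption cohort (vintage) drops to zero while the accumulated stock
remains. Adoption is capped per land type; SOC can be combined with biochar
on cropland and with silvo-pasture on pastures, but the two silvo-pasture
systems are mutually exclusive on the same hectare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants
from .growth import RotationResult
from .world import Region

OPTION_IDS = ("biochar", "silvo_bioenergy", "silvo_carbon", "soc_crop", "soc_pasture")

LAND_TYPE = {
    "soc_crop": "cropland",
    "biochar": "cropland",
    "soc_pasture": "pasture",
    "silvo_bioenergy": "pasture",
    "silvo_carbon": "pasture",
}

SATURATION_YEARS = {
    "soc_crop": constants.SATURATION_SOC,
    "soc_pasture": constants.SATURATION_SOC,
    "biochar": constants.SATURATION_BIOCHAR,
    "silvo_bioenergy": constants.SATURATION_SILVO_BIOENERGY,
    "silvo_carbon": constants.SATURATION_SILVO_CARBON,
}

# Options that may occupy the same hectare of their land type. The two
# silvo-pasture systems are mutually exclusive and share one combined cap.
COMBINABLE_PAIRS = frozenset(
    {frozenset({"soc_crop", "biochar"}), frozenset({"soc_pasture", "silvo_bioenergy"}),
     frozenset({"soc_pasture", "silvo_carbon"})}
)

#: Yield co-benefit slopes: annual % yield increase per tCO2 ha-1 yr-1
#: sequestered, for cropland soil-carbon practices on degraded land.
YIELD_K = {"AFR": 1.5, "LAM": 1.2, "ASIA": 0.7, "NORTH": 0.0, "OTHER_SOUTH": 0.0}

# Default silvo-pasture cost levels, USD2000 per tree-planted pasture ha per
# yr (establishment, maintenance, harvest). The 30-yr carbon system carries
# only 8% of the 10-yr system's total cost (no harvest, sparse planting).
SILVO_BIOENERGY_BASE_COST = 150.0
SILVO_CARBON_COST_FRACTION = 0.08


@dataclass
class SequestrationOption:
    """One technology variant in one region.

    seq_coeff in tCO2e ha-1 yr-1 (annualized 2020-2050); base_cost c1 in
    USD2000 ha-1 yr-1 and slope s in USD2000 ha-1 per unit adoption share
    define the quadratic adoption cost C(a) = c1*a + (s/2)*a**2.
    """

    id: str
    land_type: str
    seq_coeff: float
    saturation_years: int
    max_share: float
    base_cost: float = 0.0
    slope: float = 0.0
    yield_k: float = 0.0

    def __post_init__(self):
        if self.id not in OPTION_IDS:
            raise ValueError(f"unknown option id {self.id!r}")
        if self.seq_coeff < 0:
            raise ValueError("seq_coeff must be non-negative")
        if not (isinstance(self.saturation_years, (int, np.integer)) and self.saturation_years > 0):
            raise ValueError("saturation_years must be a positive integer")
        if not 0 < self.max_share <= 1:
            raise ValueError("max_share must lie in (0, 1]")
        if self.slope < 0 or self.base_cost < 0:
            raise ValueError("cost parameters must be non-negative")


def combinable(a: str, b: str) -> bool:
    """Whether options ``a`` and ``b`` may share a hectare."""
    if a == b:
        return False
    return frozenset({a, b}) in COMBINABLE_PAIRS


def build_catalog(
    region: Region,
    rotation_results: dict[str, RotationResult],
    silvo_bioenergy_cost: float = SILVO_BIOENERGY_BASE_COST,
) -> list[SequestrationOption]:
    """Build the five option variants for a region.

    SOC and biochar coefficients come from the region's coefficient table;
    silvo-pasture coefficients from the growth simulator's rotation results
    (keys ``bioenergy_10yr`` and ``carbon_30yr``). Cost slopes are left at
    zero: they are set by calibration (see :mod:`agrocarbon.market`).
    """
    missing = {"bioenergy_10yr", "carbon_30yr"} - set(rotation_results)
    if missing:
        raise ValueError(f"missing silvo-pasture rotation results: {sorted(missing)}")
    yield_k = YIELD_K[region.group]
    catalog = [
        SequestrationOption(
            id="soc_crop",
            land_type="cropland",
            seq_coeff=region.coefficients["soc_crop"],
            saturation_years=constants.SATURATION_SOC,
            max_share=constants.MAX_SHARE_SOC_CROPLAND,
            yield_k=yield_k,
        ),
        SequestrationOption(
            id="soc_pasture",
            land_type="pasture",
            seq_coeff=region.coefficients["soc_pasture"],
            saturation_years=constants.SATURATION_SOC,
            max_share=constants.MAX_SHARE_SOC_PASTURE,
        ),
        SequestrationOption(
            id="silvo_bioenergy",
            land_type="pasture",
            seq_coeff=rotation_results["bioenergy_10yr"].annualized_seq,
            saturation_years=constants.SATURATION_SILVO_BIOENERGY,
            max_share=constants.MAX_SHARE_SILVO_COMBINED,
            base_cost=silvo_bioenergy_cost,
        ),
        SequestrationOption(
            id="silvo_carbon",
            land_type="pasture",
            seq_coeff=rotation_results["carbon_30yr"].annualized_seq,
            saturation_years=constants.SATURATION_SILVO_CARBON,
            max_share=constants.MAX_SHARE_SILVO_COMBINED,
            base_cost=SILVO_CARBON_COST_FRACTION * silvo_bioenergy_cost,
        ),
        SequestrationOption(
            id="biochar",
            land_type="cropland",
            seq_coeff=region.coefficients["biochar"],
            saturation_years=constants.SATURATION_BIOCHAR,
            # feedstock-limited, not area-capped
            max_share=1.0,
            yield_k=yield_k,
        ),
    ]
    return sorted(catalog, key=lambda o: o.id)


@dataclass
class AdoptionLedger:
    """Vintage (cohort) bookkeeping of adopted areas per region and option.

    Each vintage is an (adoption_year, area in Mha) pair; areas only ever
    grow (dis-adoption is not modelled). The annual flux of a vintage is
    area * seq_coeff while year - adoption_year < saturation_years, zero
    afterwards, so the accumulated stock telescopes to
    area * seq_coeff * min(elapsed, saturation_years).
    """

    vintages: dict[tuple[str, str], list[tuple[int, float]]] = field(default_factory=dict)

    def add_vintage(self, region_id: str, option_id: str, year: int, area: float) -> None:
        if area < 0:
            raise ValueError("vintage area must be non-negative")
        if area == 0:
            return
        self.vintages.setdefault((region_id, option_id), []).append((year, area))

    def adopted_area(self, region_id: str, option_id: str) -> float:
        return sum(a for _, a in self.vintages.get((region_id, option_id), []))

    def option_flux(self, region_id: str, option: SequestrationOption, year: int) -> float:
        """Annual flux (MtCO2e yr-1) of one region-option in ``year``."""
        return annual_flux(self, region_id, option, year)

    def total_flux(self, catalogs: dict[str, list[SequestrationOption]], year: int) -> float:
        return sum(
            annual_flux(self, rid, opt, year)
            for rid, catalog in catalogs.items()
            for opt in catalog
        )

    def cumulative_stock(self, region_id: str, option: SequestrationOption,
                         year: int) -> float:
        """Accumulated sequestered stock (MtCO2e) through ``year`` inclusive."""
        total = 0.0
        for t0, area in self.vintages.get((region_id, option.id), []):
            elapsed = max(0, year - t0 + 1)
            total += area * option.seq_coeff * min(elapsed, option.saturation_years)
        return total


def annual_flux(ledger: AdoptionLedger, region_id: str,
                option: SequestrationOption, year: int) -> float:
    """Annual sequestration flux (MtCO2e yr-1) summed over vintages.

    A vintage adopted in year t0 sequesters at its full rate for
    saturation_years years (offsets 0 .. saturation_years-1) and nothing
    from offset saturation_years on.
    """
    flux = 0.0
    for t0, area in ledger.vintages.get((region_id, option.id), []):
        if 0 <= year - t0 < option.saturation_years:
            flux += area * option.seq_coeff
    return flux


def yield_co_benefit(group: str, seq_rate: float) -> float:
    """Annual % yield increase from sequestering ``seq_rate`` tCO2 ha-1 yr-1
    on cropland, by region group (Africa 1.5, Latin America 1.2, Asia 0.7 %
    per unit rate; zero elsewhere)."""
    if seq_rate < 0:
        raise ValueError("seq_rate must be non-negative")
    return YIELD_K[group] * seq_rate


def grazing_penalty(silvo_area: float, grazing_yield: float) -> float:
    """Grazing biomass supply lost (Mt dm yr-1) when ``silvo_area`` Mha of
    pasture converts to silvo-pasture: trees occupy 25% of each hectare and
    no compensating pasture productivity gain is assumed."""
    if silvo_area < 0:
        raise ValueError("silvo_area must be non-negative")
    return constants.TREE_STRIP_FRACTION * grazing_yield * silvo_area
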