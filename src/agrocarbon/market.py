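"""Price-driven adoption of sequestration options and MACC extraction.

A GHG price ramps linearly from zero in 2030 to its endpoint in 2050.
Each period, each region adopts each option up to the share where the
marginal adoption cost (from a quadratic cost curve) equals the marginal
revenue (GHG price times sequestration rate plus valued co-benefits) —
myopic, recursive-dynamic behaviour without foresight. Cost-curve slopes
are calibrated so that stated adoption shares obtain at a stated
calibration price (90% cropland SOC and 60% pasture SOC at 100 USD2000).
Adoption is irreversible: new area enters a vintage ledger whose fluxes
saturate per option. Running the full horizon at several price endpoints
traces out a marginal abatement cost curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants
from .biochar import (
    BiocharChainParams,
    FeedstockPool,
    allocate_feedstock,
    conversion_efficiency,
    residue_cost,
    residue_potential,
)
from .growth import RotationResult, simulate_rotation
from .options import AdoptionLedger, SequestrationOption, build_catalog
from .world import Region, World


class CalibrationError(ValueError):
    """Cost-curve calibration infeasible at the stated price."""


class ConstraintError(RuntimeError):
    """Adoption caps violated after combinability accounting."""


@dataclass(frozen=True)
class PriceTrajectory:
    """Linear GHG price ramp, USD2000 per tCO2e.

    Zero before ``start_year``, linear from zero at ``start_year`` to
    ``endpoint`` at ``end_year``, linear continuation at the same slope
    afterwards (used only when the horizon is extended).
    """

    endpoint: float
    start_year: int = constants.PRICE_START_YEAR
    end_year: int = constants.PRICE_END_YEAR

    def price(self, year: int | float) -> float:
        if year <= self.start_year:
            return 0.0
        slope = self.endpoint / (self.end_year - self.start_year)
        return slope * (year - self.start_year)


@dataclass(frozen=True)
class ScenarioConfig:
    """One row of the scenario matrix.

    ``default*`` scenarios price agricultural non-CO2 emissions only;
    ``agCO2*`` additionally subsidize CO2 removals on agricultural land;
    ``_bio`` variants impose the 1.5 C-compatible bioenergy demand level.
    A FOLU pricing flag is accepted for matrix completeness but inert
    (forestry responses are outside this model's scope).
    """

    name: str
    nonco2_priced: bool
    co2_priced: bool
    bioenergy_level: str = "baseline"
    folu_priced: bool = False
    endpoint: float = 100.0
    start_year: int = 2020
    end_year: int = 2050
    step: int = 5

    @property
    def trajectory(self) -> PriceTrajectory:
        return PriceTrajectory(endpoint=self.endpoint)

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1, self.step))


SCENARIO_MATRIX: dict[str, dict] = {
    "baseline": dict(nonco2_priced=False, co2_priced=False, bioenergy_level="baseline"),
    "default": dict(nonco2_priced=True, co2_priced=False, bioenergy_level="baseline",
                    folu_priced=True),
    "agCO2": dict(nonco2_priced=True, co2_priced=True, bioenergy_level="baseline",
                  folu_priced=True),
    "default_bio": dict(nonco2_priced=True, co2_priced=False, bioenergy_level="1p5C",
                        folu_priced=True),
    "agCO2_bio": dict(nonco2_priced=True, co2_priced=True, bioenergy_level="1p5C",
                      folu_priced=True),
}


def make_scenario(name: str, endpoint: float = 100.0, **overrides) -> ScenarioConfig:
    if name not in SCENARIO_MATRIX:
        raise ValueError(
            f"unknown scenario {name!r}; valid ids: {sorted(SCENARIO_MATRIX)}"
        )
    kwargs = {**SCENARIO_MATRIX[name], **overrides}
    return ScenarioConfig(name=name, endpoint=endpoint, **kwargs)


@dataclass
class MACCPoint:
    """One point of the marginal abatement cost curve (prices reported in
    USD2022 per tCO2e after the ex-post currency conversion)."""

    price: float
    mitigation: float  # cumulative 2020-2050, MtCO2e
    annual_2050: float  # MtCO2e yr-1 in 2050
    by_option: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.mitigation < 0:
            raise ValueError("mitigation must be non-negative")


# ---------------------------------------------------------------------------
# Quadratic adoption cost


def adoption_cost(option: SequestrationOption, a: float) -> float:
    """Adoption cost C(a) = c1*a + (s/2)*a**2, USD2000 per land-type
    hectare equivalent, for adoption share ``a``."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"adoption share {a} outside [0, 1]")
    if a > option.max_share + 1e-12:
        raise ValueError(f"adoption share {a} exceeds cap {option.max_share}")
    return option.base_cost * a + 0.5 * option.slope * a * a


def marginal_cost(option: SequestrationOption, a: float) -> float:
    return option.base_cost + option.slope * a


def optimal_adoption(option: SequestrationOption, ghg_price: float,
                     co_benefit_value: float = 0.0) -> float:
    """Profit-maximizing adoption share at a GHG price.

    Marginal revenue per land-type hectare is price * seq_coeff plus the
    valued co-benefit; the interior optimum solves MC(a) = MR, clipped to
    [0, max_share]. A zero slope with positive net marginal revenue puts
    the solution at the cap (corner), not at a division error.
    """
    if ghg_price < 0:
        raise ValueError("GHG price must be non-negative")
    net = ghg_price * option.seq_coeff + co_benefit_value - option.base_cost
    if net <= 0:
        return 0.0
    if option.slope == 0:
        return option.max_share
    return float(np.clip(net / option.slope, 0.0, option.max_share))


def calibrate_slope(
    option: SequestrationOption,
    target_share: float,
    calib_price: float = constants.CALIBRATION_PRICE_USD2000,
    co_benefit_value: float = 0.0,
) -> float:
    """Fit the cost-curve slope so that ``optimal_adoption`` at the
    calibration price returns ``target_share`` (closed form when interior).
    """
    if not 0 < target_share <= option.max_share:
        raise CalibrationError(
            f"target share {target_share} outside (0, {option.max_share}]"
        )
    if calib_price <= 0:
        raise CalibrationError("calibration price must be positive")
    net = calib_price * option.seq_coeff + co_benefit_value - option.base_cost
    if net <= 0:
        raise CalibrationError(
            f"net marginal revenue {net:.3f} <= 0 at the calibration price; "
            f"option {option.id} cannot be calibrated"
        )
    return net / target_share


def co_benefit_value(region: Region, option: SequestrationOption) -> float:
    """USD2000 per cropland ha per yr of the yield co-benefit.

    The annual % yield increase (yield_k * seq_coeff) is applied to the
    region's crop revenue per hectare. Pasture options carry no valued
    co-benefit.
    """
    if option.land_type != "cropland" or option.yield_k == 0.0:
        return 0.0
    if region.cropland_area == 0:
        return 0.0
    crop_yield = region.crop_production / region.cropland_area  # t per ha
    return option.yield_k * option.seq_coeff / 100.0 * crop_yield * region.crop_price


# ---------------------------------------------------------------------------
# Model state and the recursive-dynamic period step


@dataclass
class ModelState:
    """World plus everything the period loop threads through."""

    world: World
    catalogs: dict[str, list[SequestrationOption]]
    rotations: dict[str, dict[str, RotationResult]]
    ledger: AdoptionLedger = field(default_factory=AdoptionLedger)
    chain: BiocharChainParams = field(default_factory=BiocharChainParams)


def _calibrated_catalog(region: Region, rotations: dict[str, RotationResult],
                        cost_multiplier: float = 1.0,
                        cap_multiplier: float = 1.0,
                        saturation_shift: int = 0,
                        saturation_override: dict[str, int] | None = None,
                        ) -> list[SequestrationOption]:
    catalog = build_catalog(region, rotations)
    out = []
    for opt in catalog:
        v = co_benefit_value(region, opt)
        if opt.id in ("soc_crop", "soc_pasture"):
            # the stated calibration: 90% / 60% adoption at 100 USD2000
            target = {
                "soc_crop": constants.CALIBRATION_SHARE_CROPLAND,
                "soc_pasture": constants.CALIBRATION_SHARE_PASTURE,
            }[opt.id]
            slope = calibrate_slope(opt, target, co_benefit_value=v)
        else:
            # silvo / biochar slopes are not pinned by the SOC calibration;
            # anchor them so adoption reaches the cap at the top endpoint
            # price when profitable at all (net <= 0 leaves adoption at zero)
            anchor = max(constants.PRICE_ENDPOINTS_USD2000)
            net = anchor * opt.seq_coeff + v - opt.base_cost
            slope = net / opt.max_share if net > 0 else 1.0
        sat = opt.saturation_years
        if saturation_override and opt.id in saturation_override:
            sat = saturation_override[opt.id]
        elif saturation_shift:
            sat = max(1, sat + saturation_shift)
        out.append(
            replace(
                opt,
                slope=slope * cost_multiplier,
                base_cost=opt.base_cost * cost_multiplier,
                max_share=opt.max_share * cap_multiplier,
                saturation_years=sat,
            )
        )
    return out


def initialize_state(
    world: World,
    seed: int = 0,
    cost_multiplier: float = 1.0,
    cap_multiplier: float = 1.0,
    saturation_shift: int = 0,
    saturation_override: dict[str, int] | None = None,
    tree_fraction: float = constants.TREE_STRIP_FRACTION,
) -> ModelState:
    """Simulate rotations, build and calibrate the option catalog per region.

    ``cost_multiplier``, ``cap_multiplier``, ``saturation_shift`` and
    ``tree_fraction`` implement the sensitivity perturbations as pure
    config transforms; silvo sequestration rates scale linearly with the
    tree-strip fraction relative to the default 25%.
    """
    rotations = {}
    catalogs = {}
    tree_scale = tree_fraction / constants.TREE_STRIP_FRACTION
    for i, region in enumerate(world.regions):
        rot = {
            "bioenergy_10yr": simulate_rotation(region, "bioenergy_10yr", seed=seed + 2 * i),
            "carbon_30yr": simulate_rotation(region, "carbon_30yr", seed=seed + 2 * i + 1),
        }
        if tree_scale != 1.0:
            rot = {
                k: replace(
                    r,
                    annualized_seq=r.annualized_seq * tree_scale,
                    harvested_biomass=r.harvested_biomass,
                )
                for k, r in rot.items()
            }
        rotations[region.id] = rot
        catalogs[region.id] = _calibrated_catalog(
            region, rot, cost_multiplier=cost_multiplier,
            cap_multiplier=cap_multiplier, saturation_shift=saturation_shift,
            saturation_override=saturation_override,
        )
    return ModelState(world=world, catalogs=catalogs, rotations=rotations)


def _feedstock_pools(state: ModelState) -> list[FeedstockPool]:
    """Global feedstock pools available this period."""
    world = state.world
    cfg = world.config
    pools = []
    for region in world.regions:
        pot = residue_potential(
            region.crop_production, region.residue_product_ratio, state.chain
        )
        cost = residue_cost(cfg.residue_base_cost, region.gdp_per_capita, cfg.reference_gdp)
        pools.append(
            FeedstockPool(
                source=f"crop_residues_{region.id}",
                available=pot["sustainable"],
                unit_cost=cost,
            )
        )
        # harvested silvo biomass, annualized over the 10-yr rotation
        area = state.ledger.adopted_area(region.id, "silvo_bioenergy")
        if area > 0:
            rot = state.rotations[region.id]["bioenergy_10yr"]
            supply = (
                area * constants.TREE_STRIP_FRACTION
                * rot.harvested_biomass / rot.rotation_years
            )
            pools.append(
                FeedstockPool(
                    source=f"silvo_biomass_{region.id}",
                    available=supply,
                    unit_cost=1.25 * cost,
                )
            )
    pools.append(
        FeedstockPool(
            source="other_wood",
            available=cfg.other_wood_available,
            unit_cost=cfg.other_wood_cost,
        )
    )
    return pools


def _biochar_feedstock_per_mha(option: SequestrationOption,
                               chain: BiocharChainParams) -> float:
    """Mtdm of feedstock needed per Mha of biochar-treated cropland per yr."""
    return option.seq_coeff / (conversion_efficiency(chain) * constants.CO2_PER_C)


def run_period(state: ModelState, scenario: ScenarioConfig, year: int) -> pd.DataFrame:
    """Advance the model one period: solve adoption in every region, append
    new vintages (irreversible), and return the period report.

    Removal options respond to the GHG price only when the scenario prices
    agricultural CO2. Silvo-pasture variants share the combined 50% pasture
    cap, mutually exclusive per hectare; the better net-margin variant is
    served first (ties broken lexicographically by option id). Biochar
    adoption is bounded by the feedstock the merit-order market allocates
    to it after livestock and exogenous bioenergy claims.
    """
    if year not in scenario.years:
        raise ValueError(f"year {year} not on the scenario grid {scenario.years}")
    price = scenario.trajectory.price(year)
    co2_price = price if scenario.co2_priced else 0.0
    # sequestration options exist as policy instruments: scenarios that do
    # not price agricultural CO2 do not deploy them, co-benefits included
    policy_active = scenario.co2_priced and co2_price > 0.0

    # --- global feedstock market for biochar ----------------------------
    pools = _feedstock_pools(state)
    # desired biochar areas at this price, before feedstock limits
    desired: dict[str, float] = {}
    per_mha: dict[str, float] = {}
    for region in state.world.regions:
        opt = next(o for o in state.catalogs[region.id] if o.id == "biochar")
        v = co_benefit_value(region, opt)
        a_star = optimal_adoption(opt, co2_price, v) if policy_active else 0.0
        desired[region.id] = a_star * region.cropland_area
        per_mha[region.id] = _biochar_feedstock_per_mha(opt, state.chain)
    livestock_demand = sum(
        state.world.config.livestock_feed_residue_fraction
        * residue_potential(r.crop_production, r.residue_product_ratio, state.chain)["sustainable"]
        for r in state.world.regions
    )
    biochar_demand = sum(desired[rid] * per_mha[rid] for rid in desired)
    allocation = allocate_feedstock(
        pools,
        {
            "livestock": livestock_demand,
            "bioenergy": state.world.bioenergy_demand,
            "biochar": biochar_demand,
        },
        state.chain,
    )
    served = allocation.total("biochar")
    feed_ratio = served / biochar_demand if biochar_demand > 0 else 0.0

    rows = []
    for region in state.world.regions:
        catalog = state.catalogs[region.id]
        land = {"cropland": region.cropland_area, "pasture": region.pasture_area}

        # net unit margin orders the mutually exclusive silvo variants
        def net_margin(o: SequestrationOption) -> float:
            return co2_price * o.seq_coeff + co_benefit_value(region, o) - o.base_cost

        silvo = sorted(
            [o for o in catalog if o.id.startswith("silvo_")],
            key=lambda o: (-net_margin(o), o.id),
        )
        # silvo options share one combined cap equal to their (common) max_share
        silvo_cap = silvo[0].max_share if silvo else 0.0
        silvo_used = sum(
            state.ledger.adopted_area(region.id, o.id) / land["pasture"]
            if land["pasture"] > 0 else 0.0
            for o in silvo
        )

        for opt in catalog:
            area_land = land[opt.land_type]
            if area_land <= 0:
                continue
            current_share = state.ledger.adopted_area(region.id, opt.id) / area_land
            v = co_benefit_value(region, opt)
            target = optimal_adoption(opt, co2_price, v) if policy_active else 0.0
            if opt.id == "biochar":
                target *= feed_ratio
            if opt.id.startswith("silvo_"):
                headroom = max(0.0, silvo_cap - silvo_used)
                target = min(target, current_share + headroom)
            new_share = max(0.0, target - current_share)
            if opt.id.startswith("silvo_"):
                silvo_used += new_share
                if silvo_used > silvo_cap + 1e-9:
                    raise ConstraintError(
                        f"silvo cap exceeded in {region.id}: {silvo_used:.4f} > {silvo_cap}"
                    )
            new_area = new_share * area_land
            state.ledger.add_vintage(region.id, opt.id, year, new_area)
            share = current_share + new_share
            flux = state.ledger.option_flux(region.id, opt, year)
            rows.append(
                {
                    "year": year,
                    "region": region.id,
                    "option": opt.id,
                    "price_usd2000": price,
                    "co2_price_usd2000": co2_price,
                    "share": share,
                    "adopted_area": share * area_land,
                    "new_area": new_area,
                    "flux": flux,
                    "adoption_cost": adoption_cost(opt, min(share, opt.max_share))
                    * area_land,
                    "feedstock_shadow_price": allocation.shadow_price
                    if opt.id == "biochar" else np.nan,
                }
            )

    return pd.DataFrame(rows)


def nonco2_table(state: ModelState, scenario: ScenarioConfig, year: int) -> pd.DataFrame:
    """Reduced-form commodity response block for one period."""
    tax_rate = scenario.trajectory.price(year) if scenario.nonco2_priced else 0.0
    return pd.DataFrame(
        [_nonco2_response(region, tax_rate) for region in state.world.regions]
    ).assign(year=year)


#: Constant supply elasticity of the reduced-form non-CO2 tax response.
NONCO2_SUPPLY_ELASTICITY = 0.3
#: Share of the unit tax passed through to the producer price.
TAX_PASS_THROUGH = 0.5


def _nonco2_response(region: Region, ghg_price: float) -> dict:
    """Reduced-form commodity response to a non-CO2 emission tax: constant-
    elasticity supply contraction and partial cost pass-through to prices.
    Magnitudes feed the economics ledger only."""
    out = {"region": region.id}
    for sector, qty, price0, intensity_co2e in (
        ("crop", region.crop_production, region.crop_price,
         region.n2o_intensity * constants.GWP_N2O),
        ("livestock", region.livestock_output, region.livestock_price,
         region.ch4_intensity * constants.GWP_CH4),
    ):
        unit_tax = ghg_price * intensity_co2e
        q = qty * (1.0 + unit_tax / price0) ** (-NONCO2_SUPPLY_ELASTICITY)
        p = price0 + TAX_PASS_THROUGH * unit_tax
        out[f"{sector}_qty"] = q
        out[f"{sector}_price"] = p
        out[f"{sector}_emissions"] = q * intensity_co2e  # MtCO2e
        out[f"{sector}_tax"] = q * intensity_co2e * ghg_price  # million USD2000
    return out


def run_horizon(state: ModelState, scenario: ScenarioConfig) -> pd.DataFrame:
    """Run every period of the scenario; returns the concatenated report
    with the non-CO2 commodity block attached as ``.attrs['nonco2']``."""
    frames, nonco2 = [], []
    for year in scenario.years:
        frames.append(run_period(state, scenario, year))
        nonco2.append(nonco2_table(state, scenario, year))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["nonco2"] = pd.concat(nonco2, ignore_index=True)
    return out


def cumulative_mitigation(state: ModelState, scenario: ScenarioConfig) -> dict[str, float]:
    """Cumulative 2020-2050 sequestration (MtCO2e) per option, integrating
    the vintage fluxes year by year over the horizon."""
    totals = dict.fromkeys((o.id for c in state.catalogs.values() for o in c), 0.0)
    for year in range(scenario.start_year, scenario.end_year + 1):
        for rid, catalog in state.catalogs.items():
            for opt in catalog:
                totals[opt.id] += state.ledger.option_flux(rid, opt, year)
    return totals


def annual_flux_total(state: ModelState, year: int) -> float:
    return state.ledger.total_flux(state.catalogs, year)


def build_macc(
    world: World,
    endpoints: list[float],
    scenario_name: str = "agCO2",
    seed: int = 0,
    saturation_override: dict[str, int] | None = None,
) -> list[MACCPoint]:
    """Trace the MACC: one full horizon run per price endpoint.

    Returns one point per endpoint with the cumulative 2020-2050 mitigation
    (non-decreasing in the endpoint), the 2050 annual flux (which may be
    non-monotone: high prices trigger early adoption whose vintages saturate
    before 2050), and a by-option decomposition. Prices are reported in
    USD2022.
    """
    if len(endpoints) < 2:
        raise ValueError("need at least two price endpoints for a MACC")
    points = []
    for endpoint in endpoints:
        scenario = make_scenario(scenario_name, endpoint=endpoint)
        state = initialize_state(world, seed=seed, saturation_override=saturation_override)
        run_horizon(state, scenario)
        by_option = cumulative_mitigation(state, scenario)
        points.append(
            MACCPoint(
                price=constants.USD2000_TO_USD2022 * endpoint,
                mitigation=sum(by_option.values()),
                annual_2050=annual_flux_total(state, scenario.end_year),
                by_option=by_option,
            )
        )
    return points


def macc_area_cost(state: ModelState) -> float:
    """Economic cost of realized adoption: the area under each option's
    marginal adoption cost curve up to the realized share, summed over
    regions (million USD2000 per yr). For the quadratic curve this integral
    is exactly C(a) = c1*a + (s/2)*a**2 per land-type hectare."""
    total = 0.0
    for region in state.world.regions:
        land = {"cropland": region.cropland_area, "pasture": region.pasture_area}
        for opt in state.catalogs[region.id]:
            area_land = land[opt.land_type]
            if area_land <= 0:
                continue
            share = min(
                state.ledger.adopted_area(region.id, opt.id) / area_land, opt.max_share
            )
            total += adoption_cost(opt, share) * area_land
    return total
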