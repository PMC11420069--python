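"""Synthetic world generation and serialization.

The analysis operates on a configurable set of world regions, each carrying
land areas, a monthly climate record, soil attributes, per-option carbon
sequestration coefficients and a handful of economic attributes. The
generator replaces gridded soil/climate databases and published coefficient
tables with draws that have the same structure and magnitudes, so every
downstream stage (growth simulation, option catalog, adoption market,
economics) is testable without external data.

Regions are grouped into five macro groups (AFR, LAM, ASIA, NORTH,
OTHER_SOUTH); the group governs yield co-benefits of soil-carbon practices,
GDP-based cost scaling and the climate archetype. Areas are split across
regions with a Dirichlet draw so that the configured global totals are
conserved exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants

GROUPS = ("AFR", "LAM", "ASIA", "NORTH", "OTHER_SOUTH")

#: Option ids carrying exogenous (non-simulated) sequestration coefficients.
COEFF_OPTIONS = ("soc_crop", "soc_pasture", "biochar")

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)


class ConfigurationError(ValueError):
    """Invalid world configuration."""


class WorldParseError(ValueError):
    """A serialized world table failed validation; message names file, row, column."""


def _float_eq(a, b) -> bool:
    return np.array_equal(np.asarray(a, float), np.asarray(b, float))


@dataclass(eq=False)
class ClimateRecord:
    """Twelve monthly values per climate variable.

    t_min/t_max/t_mean in degC, precipitation in mm per month, solar
    radiation in MJ m-2 d-1, frost days per month, vapour pressure deficit
    in kPa.
    """

    t_min: np.ndarray
    t_max: np.ndarray
    t_mean: np.ndarray
    precipitation: np.ndarray
    solar_radiation: np.ndarray
    frost_days: np.ndarray
    vpd: np.ndarray

    def __post_init__(self):
        for f in dataclasses.fields(self):
            arr = np.asarray(getattr(self, f.name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{f.name} must have 12 monthly values")
            setattr(self, f.name, arr)
        if np.any(self.t_min > self.t_mean + 1e-9) or np.any(self.t_mean > self.t_max + 1e-9):
            raise ValueError("monthly temperatures must satisfy t_min <= t_mean <= t_max")
        for name in ("precipitation", "solar_radiation", "frost_days"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(self.frost_days > DAYS_IN_MONTH):
            raise ValueError("frost_days cannot exceed days in month")

    @property
    def mean_annual_temperature(self) -> float:
        return float(np.mean(self.t_mean))

    def __eq__(self, other):
        if not isinstance(other, ClimateRecord):
            return NotImplemented
        return all(
            _float_eq(getattr(self, f.name), getattr(other, f.name))
            for f in dataclasses.fields(self)
        )


@dataclass
class SoilRecord:
    """Soil attributes: max available soil water (mm), fertility rating in
    [0, 1], and carbon / nitrogen stocks (t ha-1)."""

    max_asw: float
    fertility_rating: float
    soc_stock: float
    n_stock: float

    def __post_init__(self):
        if min(self.max_asw, self.fertility_rating, self.soc_stock, self.n_stock) < 0:
            raise ValueError("soil attributes must be non-negative")
        if not 0.0 <= self.fertility_rating <= 1.0:
            raise ValueError("fertility_rating must lie in [0, 1]")


@dataclass(eq=False)
class Region:
    """One synthetic world region.

    Areas in Mha, crop production in Mt dm yr-1, livestock output in index
    units yr-1, emission intensities per production unit, GDP per capita in
    USD2000. ``coefficients`` maps option id -> sequestration coefficient
    (tCO2e ha-1 yr-1, annualized over 2020-2050).
    """

    id: str
    group: str
    cropland_area: float
    pasture_area: float
    crop_production: float
    livestock_output: float
    n2o_intensity: float
    ch4_intensity: float
    gdp_per_capita: float
    crop_price: float
    livestock_price: float
    grazing_yield: float
    residue_product_ratio: float
    climate: ClimateRecord
    soil: SoilRecord
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown region group {self.group!r}")
        for name in (
            "cropland_area",
            "pasture_area",
            "crop_production",
            "livestock_output",
            "n2o_intensity",
            "ch4_intensity",
            "gdp_per_capita",
            "crop_price",
            "livestock_price",
            "grazing_yield",
            "residue_product_ratio",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def __eq__(self, other):
        if not isinstance(other, Region):
            return NotImplemented
        for f in dataclasses.fields(self):
            if getattr(self, f.name) != getattr(other, f.name):
                return False
        return True


@dataclass
class WorldConfig:
    """Configuration of the synthetic world generator.

    Global land totals default to values back-derived from published
    adoption shares (conservation agriculture on 900 Mha = 53% of cropland,
    improved grassland management on 1,100 Mha = 60% of managed grassland);
    they are illustrative, not census figures. Coefficient ranges bracket
    the printed per-hectare magnitudes (SOC around 0.5-0.6, biochar around
    2.1 tCO2e ha-1 yr-1).
    """

    n_regions: int = 10
    seed: int = 0
    global_cropland: float = 900.0 / 0.53
    global_pasture: float = 1100.0 / 0.60
    coeff_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "soc_crop": (0.45, 0.80),
            "soc_pasture": (0.35, 0.70),
            "biochar": (1.60, 2.10),
        }
    )
    bioenergy_demand_level: str = "baseline"
    dirichlet_concentration: float = 3.0
    # Exogenous residue/wood-sourced solid-bioenergy commitment, Mtdm yr-1
    # global, converted at 18 GJ per tdm. Baseline approximates 50% of
    # ~16 EJ yr-1 of other solid biomass; the 1.5 C level approximates
    # ~40 EJ yr-1 of solid-biomass feedstock pull in deep-mitigation
    # scenarios, drawn from the same pools.
    bioenergy_demand_mtdm: dict[str, float] = field(
        default_factory=lambda: {
            "baseline": 0.5 * 16.0e9 / constants.BIOMASS_ENERGY_GJ_PER_TDM / 1e6,
            "1p5C": 40.0e9 / constants.BIOMASS_ENERGY_GJ_PER_TDM / 1e6,
        }
    )
    other_wood_available: float = 200.0  # Mtdm yr-1, logging residues etc.
    other_wood_cost: float = 60.0  # USD2000 per tdm
    residue_base_cost: float = 40.0  # USD2000 per tdm at reference GDP
    reference_gdp: float = 5000.0  # USD2000 per capita
    livestock_feed_residue_fraction: float = 0.15

    def __post_init__(self):
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.global_cropland <= 0 or self.global_pasture <= 0:
            raise ConfigurationError("global land areas must be positive")
        for opt, (lo, hi) in self.coeff_ranges.items():
            if not (0 < lo <= hi and np.isfinite(hi)):
                raise ConfigurationError(f"invalid coefficient range for {opt}")
        if self.bioenergy_demand_level not in self.bioenergy_demand_mtdm:
            raise ConfigurationError(
                f"unknown bioenergy demand level {self.bioenergy_demand_level!r}"
            )


@dataclass(eq=False)
class World:
    """A generated world: configuration plus its regions."""

    config: WorldConfig
    regions: list[Region]

    @property
    def bioenergy_demand(self) -> float:
        """Exogenous bioenergy feedstock demand (Mtdm yr-1) at the configured level."""
        return self.config.bioenergy_demand_mtdm[self.config.bioenergy_demand_level]

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.id == region_id:
                return r
        raise KeyError(region_id)

    def __eq__(self, other):
        if not isinstance(other, World):
            return NotImplemented
        return self.config == other.config and self.regions == other.regions


# ---------------------------------------------------------------------------
# Climate archetypes


def _archetype_for_group(group: str) -> str:
    return {
        "AFR": "tropical",
        "LAM": "tropical",
        "OTHER_SOUTH": "tropical",
        "ASIA": "subtropical",
        "NORTH": "temperate",
    }[group]


def _generate_climate(rng: np.random.Generator, archetype: str) -> ClimateRecord:
    months = np.arange(12)
    season = np.sin(2 * np.pi * (months - 3) / 12)  # peaks mid-year (boreal summer)
    if archetype == "tropical":
        base_t, amp_t = 25.0, 2.0
        base_p, amp_p = 140.0, 80.0
        base_r, amp_r = 18.0, 2.0
        base_vpd = 1.0
    elif archetype == "subtropical":
        base_t, amp_t = 17.0, 8.0
        base_p, amp_p = 90.0, 50.0
        base_r, amp_r = 16.0, 5.0
        base_vpd = 0.9
    else:  # temperate
        base_t, amp_t = 8.0, 11.0
        base_p, amp_p = 70.0, 20.0
        base_r, amp_r = 11.0, 7.0
        base_vpd = 0.6

    t_mean = base_t + amp_t * season + rng.normal(0, 0.5, 12) + rng.normal(0, 1.5)
    spread = rng.uniform(4.0, 7.0)
    t_min = t_mean - spread
    t_max = t_mean + spread
    precipitation = np.maximum(
        0.0, base_p + amp_p * season + rng.normal(0, base_p * 0.1, 12)
    )
    solar_radiation = np.maximum(
        1.0, base_r + amp_r * season + rng.normal(0, 0.5, 12)
    )
    frost_days = np.clip(-2.5 * t_min, 0.0, DAYS_IN_MONTH)
    vpd = np.maximum(0.05, base_vpd + 0.4 * season * (base_vpd > 0.7) + rng.normal(0, 0.1, 12))
    return ClimateRecord(
        t_min=t_min,
        t_max=t_max,
        t_mean=t_mean,
        precipitation=precipitation,
        solar_radiation=solar_radiation,
        frost_days=frost_days,
        vpd=vpd,
    )


_GDP_RANGES = {
    "AFR": (500.0, 2500.0),
    "LAM": (4000.0, 9000.0),
    "ASIA": (1500.0, 6000.0),
    "NORTH": (25000.0, 45000.0),
    "OTHER_SOUTH": (2000.0, 8000.0),
}


def generate_world(config: WorldConfig) -> World:
    """Generate a deterministic synthetic world from ``config``.

    Region land areas are a Dirichlet split of the configured global totals
    (so they sum to them exactly); sequestration coefficients are uniform
    draws within the configured per-option ranges; climate follows the
    group's latitude-band archetype with additive noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_regions
    crop_shares = rng.dirichlet(np.full(n, config.dirichlet_concentration))
    past_shares = rng.dirichlet(np.full(n, config.dirichlet_concentration))
    # renormalize to kill accumulated rounding
    crop_areas = crop_shares / crop_shares.sum() * config.global_cropland
    past_areas = past_shares / past_shares.sum() * config.global_pasture

    regions: list[Region] = []
    for i in range(n):
        group = GROUPS[i % len(GROUPS)]
        climate = _generate_climate(rng, _archetype_for_group(group))
        soil = SoilRecord(
            max_asw=rng.uniform(100.0, 250.0),
            fertility_rating=rng.uniform(0.3, 0.9),
            soc_stock=rng.uniform(30.0, 120.0),
            n_stock=rng.uniform(2.0, 10.0),
        )
        crop_yield = rng.uniform(2.0, 5.0)  # t dm per ha
        livestock_yield = rng.uniform(0.4, 0.6)  # index units per pasture ha
        coeffs = {
            opt: rng.uniform(lo, hi) for opt, (lo, hi) in config.coeff_ranges.items()
        }
        regions.append(
            Region(
                id=f"R{i:02d}",
                group=group,
                cropland_area=float(crop_areas[i]),
                pasture_area=float(past_areas[i]),
                crop_production=float(crop_areas[i] * crop_yield),
                livestock_output=float(past_areas[i] * livestock_yield),
                n2o_intensity=float(rng.uniform(3e-4, 7e-4)),
                ch4_intensity=float(rng.uniform(0.08, 0.12)),
                gdp_per_capita=float(rng.uniform(*_GDP_RANGES[group])),
                crop_price=float(rng.uniform(100.0, 180.0)),
                livestock_price=float(rng.uniform(800.0, 1500.0)),
                grazing_yield=float(rng.uniform(1.5, 3.5)),
                residue_product_ratio=float(rng.uniform(1.0, 1.5)),
                climate=climate,
                soil=soil,
                coefficients=coeffs,
            )
        )
    return World(config=config, regions=regions)


# ---------------------------------------------------------------------------
# Serialization

_FLOAT_FMT = "%.17g"

_REGION_SCALARS = (
    "cropland_area",
    "pasture_area",
    "crop_production",
    "livestock_output",
    "n2o_intensity",
    "ch4_intensity",
    "gdp_per_capita",
    "crop_price",
    "livestock_price",
    "grazing_yield",
    "residue_product_ratio",
)

_CLIMATE_VARS = (
    "t_min",
    "t_max",
    "t_mean",
    "precipitation",
    "solar_radiation",
    "frost_days",
    "vpd",
)

_SOIL_VARS = ("max_asw", "fertility_rating", "soc_stock", "n_stock")


def write_world(world: World, path: str | Path) -> None:
    """Serialize a world to ``path`` as CSV tables plus a YAML config.

    Floats are written with 17 significant digits so that
    ``read_world(write_world(w)) == w`` holds exactly.
    """
    if not world.regions:
        raise ValueError("refusing to serialize a world with no regions")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = [
        {"region": r.id, "group": r.group, **{k: getattr(r, k) for k in _REGION_SCALARS}}
        for r in world.regions
    ]
    pd.DataFrame(rows).to_csv(path / "regions.csv", index=False, float_format=_FLOAT_FMT)

    clim_rows = []
    for r in world.regions:
        for m in range(12):
            clim_rows.append(
                {
                    "region": r.id,
                    "month": m + 1,
                    **{v: getattr(r.climate, v)[m] for v in _CLIMATE_VARS},
                }
            )
    pd.DataFrame(clim_rows).to_csv(path / "climate.csv", index=False, float_format=_FLOAT_FMT)

    soil_rows = [
        {"region": r.id, **{v: getattr(r.soil, v) for v in _SOIL_VARS}}
        for r in world.regions
    ]
    pd.DataFrame(soil_rows).to_csv(path / "soil.csv", index=False, float_format=_FLOAT_FMT)

    coeff_rows = [
        {"region": r.id, "option": opt, "coefficient": val}
        for r in world.regions
        for opt, val in sorted(r.coefficients.items())
    ]
    pd.DataFrame(coeff_rows).to_csv(
        path / "coefficients.csv", index=False, float_format=_FLOAT_FMT
    )

    cfg = dataclasses.asdict(world.config)
    cfg["coeff_ranges"] = {k: list(v) for k, v in cfg["coeff_ranges"].items()}
    (path / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def _require(cond: bool, file: str, row: int, column: str, msg: str) -> None:
    if not cond:
        raise WorldParseError(f"{file}, row {row}, column {column!r}: {msg}")


def read_world(path: str | Path) -> World:
    """Read a world serialized by :func:`write_world`.

    Raises :class:`WorldParseError` naming file, row and column on any
    invariant violation in the tables.
    """
    path = Path(path)
    cfg_raw = yaml.safe_load((path / "config.yaml").read_text())
    cfg_raw["coeff_ranges"] = {k: tuple(v) for k, v in cfg_raw["coeff_ranges"].items()}
    config = WorldConfig(**cfg_raw)

    regions_df = pd.read_csv(path / "regions.csv", float_precision="round_trip")
    if regions_df.empty:
        raise WorldParseError("regions.csv: world has no regions")
    climate_df = pd.read_csv(path / "climate.csv", float_precision="round_trip").set_index(["region", "month"])
    soil_df = pd.read_csv(path / "soil.csv", float_precision="round_trip").set_index("region")
    coeff_df = pd.read_csv(path / "coefficients.csv", float_precision="round_trip")

    regions = []
    for i, rec in regions_df.iterrows():
        for col in ("cropland_area", "pasture_area", "crop_production"):
            _require(rec[col] >= 0, "regions.csv", int(i), col, f"negative value {rec[col]}")
        _require(rec["group"] in GROUPS, "regions.csv", int(i), "group",
                 f"unknown group {rec['group']!r}")
        rid = rec["region"]
        clim = climate_df.loc[rid].sort_index()
        climate = ClimateRecord(**{v: clim[v].to_numpy() for v in _CLIMATE_VARS})
        soil = SoilRecord(**{v: float(soil_df.loc[rid, v]) for v in _SOIL_VARS})
        sub = coeff_df[coeff_df["region"] == rid]
        coeffs = dict(zip(sub["option"], sub["coefficient"].astype(float)))
        regions.append(
            Region(
                id=rid,
                group=rec["group"],
                **{k: float(rec[k]) for k in _REGION_SCALARS},
                climate=climate,
                soil=soil,
                coefficients=coeffs,
            )
        )
    return World(config=config, regions=regions)
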