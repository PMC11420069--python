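import numpy as np
import pytest

from agrocarbon.growth import load_species_table, species_from_row
from agrocarbon.world import (
    ClimateRecord,
    Region,
    SoilRecord,
    WorldConfig,
    generate_world,
)


@pytest.fixture(scope="session")
def world5():
    """Small five-region world shared by read-only tests."""
    return generate_world(WorldConfig(n_regions=5, seed=11))


@pytest.fixture(scope="session")
def eucalypt():
    table = load_species_table()
    return species_from_row(table[table["name"] == "eucalypt"].iloc[0])


@pytest.fixture(scope="session")
def poplar():
    table = load_species_table()
    return species_from_row(table[table["name"] == "poplar"].iloc[0])


def make_climate(t_base=20.0, amp=3.0, precip=120.0, rad=16.0, vpd=0.8, frost=0.0):
    """Hand-built benign climate record for controlled tests."""
    months = np.arange(12)
    season = np.sin(2 * np.pi * (months - 3) / 12)
    t_mean = t_base + amp * season
    return ClimateRecord(
        t_min=t_mean - 5.0,
        t_max=t_mean + 5.0,
        t_mean=t_mean,
        precipitation=np.full(12, precip),
        solar_radiation=np.full(12, rad),
        frost_days=np.full(12, frost),
        vpd=np.full(12, vpd),
    )


def make_region(t_base=20.0, group="AFR", cropland=100.0, pasture=80.0, **kw):
    defaults = dict(
        crop_production=300.0,
        livestock_output=40.0,
        n2o_intensity=5e-4,
        ch4_intensity=0.1,
        gdp_per_capita=2000.0,
        crop_price=140.0,
        livestock_price=1000.0,
        grazing_yield=2.0,
        residue_product_ratio=1.2,
        coefficients={"soc_crop": 0.6, "soc_pasture": 0.5, "biochar": 2.0},
    )
    defaults.update(kw)
    return Region(
        id="TST",
        group=group,
        cropland_area=cropland,
        pasture_area=pasture,
        climate=make_climate(t_base=t_base),
        soil=SoilRecord(max_asw=180.0, fertility_rating=0.7, soc_stock=80.0, n_stock=6.0),
        **defaults,
    )


@pytest.fixture()
def benign_region():
    return make_region()
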