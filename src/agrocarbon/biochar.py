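"""Crop-residue supply and the biochar production chain.

Residue potentials follow from crop production times crop-specific
residue-product ratios, with half of the technical potential removable
sustainably. Biochar is produced by pyrolysis: 45% of feedstock dry matter
is carbon, 50% of that carbon is retained in the char and 79.6% of the
retained carbon is stored for more than 100 years, giving a conversion
efficiency of 0.1791 tCe per tdm (displayed as 0.18). Half of the feedstock
mass re-emerges as a bioenergy byproduct. Feedstock competes with livestock
feed and exogenous bioenergy demand in a merit-order market.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants

USES = ("livestock", "bioenergy", "biochar")


@dataclass
class BiocharChainParams:
    """Pyrolysis chain factors.

    carbon_content: tC per tdm feedstock; retention: fraction of feedstock
    carbon retained in the char; storage_100yr: fraction of retained carbon
    stored beyond 100 years; pyrolysis_cost in USD2000 per tCO2e stored
    (pyrolysis, storage, processing, application); energy_byproduct:
    feedstock mass fraction re-usable for bioenergy; residue_removable:
    sustainably removable share of the technical residue potential.
    """

    carbon_content: float = 0.45
    retention: float = 0.50
    storage_100yr: float = 0.796
    pyrolysis_cost: float = 35.0
    energy_byproduct: float = 0.50
    residue_removable: float = 0.50

    def __post_init__(self):
        for name in ("carbon_content", "retention", "storage_100yr",
                     "energy_byproduct", "residue_removable"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.pyrolysis_cost < 0:
            raise ValueError("pyrolysis_cost must be non-negative")


@dataclass
class FeedstockPool:
    """One biomass feedstock source, Mtdm yr-1, with unit cost in USD2000
    per tdm and committed quantities per use."""

    source: str
    available: float
    unit_cost: float
    committed: dict[str, float] = field(default_factory=lambda: dict.fromkeys(USES, 0.0))

    def __post_init__(self):
        if self.available < 0 or self.unit_cost < 0:
            raise ValueError("availability and unit cost must be non-negative")
        if any(v < 0 for v in self.committed.values()):
            raise ValueError("committed quantities must be non-negative")
        if sum(self.committed.values()) > self.available + 1e-9:
            raise ValueError("committed quantities exceed availability")

    @property
    def remaining(self) -> float:
        return self.available - sum(self.committed.values())


def residue_potential(crop_production, rpr, params: BiocharChainParams | None = None):
    """Technical and sustainable residue potentials (Mtdm yr-1).

    ``crop_production`` and ``rpr`` (residue-product ratio) are scalars or
    aligned arrays over crop aggregates; technical = sum(production * rpr),
    sustainable = removable fraction (default 50%) of technical.
    """
    params = params or BiocharChainParams()
    production = np.asarray(crop_production, float)
    ratios = np.asarray(rpr, float)
    if np.any(production < 0) or np.any(ratios < 0):
        raise ValueError("production and residue-product ratios must be non-negative")
    technical = float(np.sum(production * ratios))
    return {"technical": technical, "sustainable": params.residue_removable * technical}


def residue_cost(base_cost: float, gdp_per_capita: float, reference_gdp: float) -> float:
    """Regional residue supply cost, rescaled by GDP per capita relative to
    a reference region (labour-cost proxy)."""
    if reference_gdp <= 0:
        raise ValueError("reference GDP must be positive")
    if base_cost < 0 or gdp_per_capita <= 0:
        raise ValueError("base cost must be non-negative and GDP positive")
    return base_cost * gdp_per_capita / reference_gdp


def conversion_efficiency(params: BiocharChainParams | None = None,
                          display: bool = False) -> float:
    """Stored carbon per unit feedstock, tCe per tdm.

    Full precision internally (0.45 * 0.50 * 0.796 = 0.1791); pass
    ``display=True`` for the two-decimal reporting convention (0.18).
    """
    params = params or BiocharChainParams()
    eff = params.carbon_content * params.retention * params.storage_100yr
    return round(eff, 2) if display else eff


def pyrolyze(feedstock: float, params: BiocharChainParams | None = None) -> dict[str, float]:
    """Convert ``feedstock`` Mtdm into stored carbon, CO2e sequestration,
    bioenergy byproduct and chain cost.

    Returns stored_c (MtC), seq (MtCO2e), bioenergy_byproduct (Mtdm
    equivalent) and cost (million USD2000). Linear in feedstock.
    """
    if feedstock < 0:
        raise ValueError("feedstock must be non-negative")
    params = params or BiocharChainParams()
    stored_c = feedstock * conversion_efficiency(params)
    seq = stored_c * constants.CO2_PER_C
    return {
        "stored_c": stored_c,
        "seq": seq,
        "bioenergy_byproduct": params.energy_byproduct * feedstock,
        "cost": params.pyrolysis_cost * seq,
    }


@dataclass
class FeedstockAllocation:
    """Outcome of the merit-order feedstock market.

    allocation maps (pool source, use) -> Mtdm; shadow_price is the unit
    cost of the marginal pool supplying the last unit; shortfall maps use ->
    unserved demand (infeasible demand is reported, never raised).
    """

    allocation: dict[tuple[str, str], float]
    shadow_price: float
    shortfall: dict[str, float]

    def total(self, use: str) -> float:
        return sum(q for (_, u), q in self.allocation.items() if u == use)


def allocate_feedstock(
    pools: list[FeedstockPool],
    demands: dict[str, float],
    params: BiocharChainParams | None = None,
) -> FeedstockAllocation:
    """Allocate feedstock pools to competing uses in merit order.

    Demands (Mtdm yr-1) are served cheapest-pool-first in the priority
    order livestock, bioenergy, biochar; biochar is the residual claimant,
    so raising exogenous bioenergy demand can never increase its feedstock.
    The bioenergy byproduct of pyrolysis (half the biochar feedstock mass)
    offsets exogenous bioenergy demand before fresh feedstock is drawn; the
    implied fixed point is solved by damped iteration (contraction 1/2).
    """
    params = params or BiocharChainParams()
    for use, d in demands.items():
        if d < 0:
            raise ValueError(f"negative demand for {use}")
        if use not in USES:
            raise ValueError(f"unknown feedstock use {use!r}")

    d_livestock = demands.get("livestock", 0.0)
    d_bioenergy = demands.get("bioenergy", 0.0)
    d_biochar = demands.get("biochar", 0.0)

    def _solve(biochar_served: float):
        order = sorted(pools, key=lambda p: (p.unit_cost, p.source))
        remaining = {p.source: p.remaining for p in order}
        alloc: dict[tuple[str, str], float] = {}
        shadow = 0.0
        bio_net = max(0.0, d_bioenergy - params.energy_byproduct * biochar_served)
        served = {}
        for use, dem in (("livestock", d_livestock), ("bioenergy", bio_net),
                         ("biochar", d_biochar)):
            left = dem
            for p in order:
                if left <= 0:
                    break
                take = min(left, remaining[p.source])
                if take > 0:
                    alloc[(p.source, use)] = alloc.get((p.source, use), 0.0) + take
                    remaining[p.source] -= take
                    left -= take
                    shadow = max(shadow, p.unit_cost)
            served[use] = dem - left
        return alloc, shadow, served

    # fixed point on the biochar quantity feeding the byproduct credit
    biochar_served = 0.0
    for _ in range(60):
        _, _, served = _solve(biochar_served)
        new = served["biochar"]
        if abs(new - biochar_served) < 1e-12:
            biochar_served = new
            break
        biochar_served = new
    alloc, shadow, served = _solve(biochar_served)

    shortfall = {
        "livestock": max(0.0, d_livestock - served["livestock"]),
        "bioenergy": max(
            0.0, d_bioenergy - params.energy_byproduct * served["biochar"] - served["bioenergy"]
        ),
        "biochar": max(0.0, d_biochar - served["biochar"]),
    }
    return FeedstockAllocation(allocation=alloc, shadow_price=shadow, shortfall=shortfall)
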