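"""Ex-post accounting of producer and government positions.

Scenario-vs-baseline impacts are decomposed per region and sector into
gross turnover changes (price times quantity differences), GHG tax payments
(emissions times price) and carbon subsidy receipts (removals times price).
The ledger identities are:

    net_producer   = turnover_change - tax + subsidy
    net_government = tax - subsidy

so that taxes and subsidies cancel between the two sides (transfer
neutrality) and the total welfare change equals the turnover change.
Prices are converted from constant USD2000 to USD2022 with a global uniform
factor of 1.63; non-CO2 gases convert to CO2e with AR4 global warming
potentials (298 for N2O, 25 for CH4).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants


@dataclass(frozen=True)
class ConversionConstants:
    usd2000_to_usd2022: float = constants.USD2000_TO_USD2022
    gwp_n2o: float = constants.GWP_N2O
    gwp_ch4: float = constants.GWP_CH4


_GWP = {"CO2": 1.0, "N2O": constants.GWP_N2O, "CH4": constants.GWP_CH4}


def co2e(gas: str, amount: float) -> float:
    """Convert ``amount`` Mt of ``gas`` to MtCO2e via its 100-yr GWP."""
    if gas not in _GWP:
        raise ValueError(f"unknown gas {gas!r}; expected one of {sorted(_GWP)}")
    if amount < 0:
        raise ValueError("gas amount must be non-negative")
    return _GWP[gas] * amount


def to_usd2022(x: float) -> float:
    """Exact USD2000 -> USD2022 conversion (linear, factor 1.63)."""
    if not math.isfinite(x):
        raise ValueError("amount must be finite")
    return constants.USD2000_TO_USD2022 * x


def display_usd2022(x_usd2000: float) -> float:
    """Reporting label for a converted GHG price: floored to the nearest
    multiple of 5 (so endpoints 50/100/150/200 USD2000 label as
    80/160/240/325 USD2022)."""
    return 5.0 * math.floor(to_usd2022(x_usd2000) / 5.0)


def turnover_change(
    prices_scn, qty_scn, prices_base, qty_base
) -> float:
    """Gross turnover change vs baseline: sum over commodities of
    p_scn*q_scn - p_base*q_base. Positive means producer gain. Inputs are
    scalars or aligned commodity arrays."""
    p_s, q_s = np.atleast_1d(np.asarray(prices_scn, float)), np.atleast_1d(np.asarray(qty_scn, float))
    p_b, q_b = np.atleast_1d(np.asarray(prices_base, float)), np.atleast_1d(np.asarray(qty_base, float))
    if not (p_s.shape == q_s.shape == p_b.shape == q_b.shape):
        raise ValueError("commodity lists must be aligned across scenario and baseline")
    return float(np.sum(p_s * q_s - p_b * q_b))


def tax_and_subsidy(emissions: float, removals: float, price: float) -> dict[str, float]:
    """GHG tax (on emissions) and carbon subsidy (on removals), billion
    currency units, from MtCO2e quantities and a per-tCO2e price."""
    if min(emissions, removals, price) < 0:
        raise ValueError("emissions, removals and price must be non-negative")
    return {"tax": emissions * price * 1e-3, "subsidy": removals * price * 1e-3}


def net_positions(components: pd.DataFrame) -> pd.DataFrame:
    """Apply the ledger identities to a component table.

    ``components`` needs columns turnover_change, tax, subsidy (billion,
    one currency year throughout; a ``currency_year`` column, if present,
    must be constant). Returns a copy with net_producer and net_government
    columns; the identities hold exactly row-wise and under any grouping.
    """
    required = {"turnover_change", "tax", "subsidy"}
    missing = required - set(components.columns)
    if missing:
        raise ValueError(f"missing ledger components: {sorted(missing)}")
    if "currency_year" in components.columns:
        if components["currency_year"].nunique() > 1:
            raise ValueError("mixed currency years in one ledger")
    out = components.copy()
    out["net_producer"] = out["turnover_change"] - out["tax"] + out["subsidy"]
    out["net_government"] = out["tax"] - out["subsidy"]
    return out


def net_option_revenue(subsidy: float, macc_area_cost: float) -> float:
    """Producers' net revenue from sequestration practices: GHG-price
    subsidy receipts minus the economic cost (area under the marginal
    abatement cost curve up to realized adoption), billions."""
    if subsidy < 0 or macc_area_cost < 0:
        raise ValueError("subsidy and cost must be non-negative")
    return subsidy - macc_area_cost


def display_billion(x: float) -> float:
    """Currency aggregates are reported to the nearest 5 billion."""
    return 5.0 * round(x / 5.0)


def load_reference_components() -> pd.DataFrame:
    """Packaged reference table of global ledger components (billion
    USD2022, year-2050, scenario minus baseline) for three GHG-pricing
    scenarios; used to validate the ledger identities against published
    aggregates."""
    with importlib.resources.files("agrocarbon.data").joinpath(
        "reference_global_components.csv"
    ).open() as fh:
        return pd.read_csv(fh)
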