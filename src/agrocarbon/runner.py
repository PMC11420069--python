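"""End-to-end scenario orchestration.

Runs the full pipeline — synthetic world, silvo-pasture rotations,
calibrated option catalog, recursive-dynamic adoption under the scenario's
GHG price, and the ex-post producer/government ledger against the baseline
— for any row of the scenario matrix (baseline, default, agCO2,
default_bio, agCO2_bio), and provides the sensitivity perturbation suite.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import constants, economics, market
from .market import (
    ModelState,
    ScenarioConfig,
    SCENARIO_MATRIX,
    initialize_state,
    make_scenario,
    run_horizon,
)
from .world import World, WorldConfig, generate_world, write_world

_FLOAT_FMT = "%.17g"

SENSITIVITY_IDS = (
    "C-SEQ+", "C-SEQ-", "COST+", "DIET", "BIO+",
    "TREE 20%", "TREE 15%", "MAX 75%", "MAX 50%",
)

#: DIET perturbation: fractional cut to livestock output in NORTH regions.
DIET_LIVESTOCK_CUT = 0.30


def config_hash(config: dict) -> str:
    """Stable hash of a config mapping, invariant to key ordering."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one scenario run."""

    scenario: str
    endpoint: float
    seed: int
    config_hash: str
    outputs: list[str] = field(default_factory=list)
    package_version: str = "0.1.0"
    wall_clock_s: float = 0.0


@dataclass
class ScenarioRun:
    """Everything one scenario run produced."""

    manifest: RunManifest
    scenario: ScenarioConfig
    state: ModelState
    report: pd.DataFrame
    nonco2: pd.DataFrame
    ledger: pd.DataFrame
    summary: dict[str, float]


def _world_config_from_mapping(config: dict, scenario: ScenarioConfig,
                               seed: int) -> WorldConfig:
    world_kwargs = dict(config.get("world", {}))
    world_kwargs.setdefault("seed", seed)
    if "coeff_ranges" in world_kwargs:
        world_kwargs["coeff_ranges"] = {
            k: tuple(v) for k, v in world_kwargs["coeff_ranges"].items()
        }
    world_kwargs["bioenergy_demand_level"] = scenario.bioenergy_level
    return WorldConfig(**world_kwargs)


def _apply_diet(world: World, cut: float = DIET_LIVESTOCK_CUT) -> World:
    regions = [
        dataclasses.replace(
            r, livestock_output=r.livestock_output * (1.0 - cut)
        ) if r.group == "NORTH" else r
        for r in world.regions
    ]
    return World(config=world.config, regions=regions)


def _build_ledger(run_state: ModelState, base_state: ModelState,
                  scenario: ScenarioConfig,
                  report: pd.DataFrame, nonco2: pd.DataFrame,
                  base_nonco2: pd.DataFrame) -> pd.DataFrame:
    """Per region x sector ledger components for the final year, scenario
    minus baseline, in billion USD2022."""
    year = scenario.end_year
    price2000 = scenario.trajectory.price(year)
    price2022 = economics.to_usd2022(price2000) if scenario.nonco2_priced or scenario.co2_priced else 0.0
    f = constants.USD2000_TO_USD2022

    scn = nonco2[nonco2["year"] == year].set_index("region")
    base = base_nonco2[base_nonco2["year"] == year].set_index("region")
    rows = []
    for region in run_state.world.regions:
        rid = region.id
        for sector, land_type in (("crop", "cropland"), ("livestock", "pasture")):
            turnover = economics.turnover_change(
                scn.loc[rid, f"{sector}_price"], scn.loc[rid, f"{sector}_qty"],
                base.loc[rid, f"{sector}_price"], base.loc[rid, f"{sector}_qty"],
            ) * 1e-3 * f  # million USD2000 -> billion USD2022
            tax = 0.0
            if scenario.nonco2_priced:
                tax = scn.loc[rid, f"{sector}_emissions"] * price2000 * 1e-3 * f
            removals = sum(
                run_state.ledger.option_flux(rid, opt, year)
                for opt in run_state.catalogs[rid]
                if opt.land_type == land_type
            )
            subsidy = 0.0
            if scenario.co2_priced:
                subsidy = removals * price2000 * 1e-3 * f
            rows.append(
                {
                    "scenario": scenario.name,
                    "region": rid,
                    "sector": sector,
                    "price_usd2022": price2022,
                    "turnover_change": turnover,
                    "tax": tax,
                    "subsidy": subsidy,
                    "removals_mtco2e": removals,
                }
            )
    return economics.net_positions(pd.DataFrame(rows))


def run_scenario(
    config: dict | str | Path | None,
    scenario_id: str,
    endpoint: float = 100.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    **state_kwargs,
) -> ScenarioRun:
    """Run one scenario of the matrix end to end.

    ``config`` is a mapping with optional sections ``world``, ``prices``,
    ``scenario`` (or a YAML file holding one, or None for defaults).
    Outputs, when ``out_dir`` is given: the serialized world, period
    report, non-CO2 table, economics ledger and a manifest; re-running
    with the same config and seed reproduces them bit-identically.
    """
    t0 = time.perf_counter()
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    config = config or {}
    if scenario_id not in SCENARIO_MATRIX:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; valid ids: {sorted(SCENARIO_MATRIX)}"
        )
    endpoint = float(config.get("prices", {}).get("endpoint", endpoint))
    scenario = make_scenario(scenario_id, endpoint=endpoint,
                             **config.get("scenario", {}))
    wc = _world_config_from_mapping(config, scenario, seed)
    world = generate_world(wc)
    if config.get("sensitivity", {}).get("diet"):
        world = _apply_diet(world)

    state = initialize_state(world, seed=seed, **state_kwargs)
    report = run_horizon(state, scenario)
    nonco2 = report.attrs["nonco2"]

    # baseline counterfactual on the identical world draw
    base_scenario = make_scenario("baseline", endpoint=endpoint)
    base_wc = _world_config_from_mapping(config, base_scenario, seed)
    base_state = initialize_state(generate_world(base_wc), seed=seed, **state_kwargs)
    base_report = run_horizon(base_state, base_scenario)
    base_nonco2 = base_report.attrs["nonco2"]

    ledger = _build_ledger(state, base_state, scenario, report, nonco2, base_nonco2)

    year = scenario.end_year
    summary = {
        "annual_flux_2050": market.annual_flux_total(state, year),
        "cumulative_mitigation": sum(
            market.cumulative_mitigation(state, scenario).values()
        ),
        "tax": float(ledger["tax"].sum()),
        "subsidy": float(ledger["subsidy"].sum()),
        "net_producer": float(ledger["net_producer"].sum()),
        "net_government": float(ledger["net_government"].sum()),
        "macc_area_cost": economics.to_usd2022(market.macc_area_cost(state)) * 1e-3,
    }

    manifest = RunManifest(
        scenario=scenario_id,
        endpoint=endpoint,
        seed=seed,
        config_hash=config_hash(config),
    )
    if out_dir is not None:
        out = Path(out_dir) / scenario_id
        out.mkdir(parents=True, exist_ok=True)
        write_world(world, out / "world")
        report.to_csv(out / "period_report.csv", index=False, float_format=_FLOAT_FMT)
        nonco2.to_csv(out / "nonco2.csv", index=False, float_format=_FLOAT_FMT)
        ledger.to_csv(out / "ledger.csv", index=False, float_format=_FLOAT_FMT)
        manifest.outputs = sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            and p.name != "manifest.yaml"
        )
        manifest.wall_clock_s = round(time.perf_counter() - t0, 3)
        (out / "manifest.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(manifest), sort_keys=True)
        )
    else:
        manifest.wall_clock_s = round(time.perf_counter() - t0, 3)
    return ScenarioRun(
        manifest=manifest, scenario=scenario, state=state, report=report,
        nonco2=nonco2, ledger=ledger, summary=summary,
    )


def run_matrix(config: dict | None = None, endpoint: float = 100.0,
               seed: int = 0) -> dict[str, ScenarioRun]:
    """Run all five scenario-matrix rows in one suite invocation."""
    return {
        name: run_scenario(config, name, endpoint=endpoint, seed=seed)
        for name in SCENARIO_MATRIX
    }


_PERTURBATIONS: dict[str, dict] = {
    "C-SEQ+": {"state": {"saturation_shift": 10}},
    "C-SEQ-": {"state": {"saturation_shift": -10}},
    "COST+": {"state": {"cost_multiplier": 2.0}},
    "DIET": {"config": {"sensitivity": {"diet": True}}},
    "BIO+": {"scenario_suffix_bio": True},
    "TREE 20%": {"state": {"tree_fraction": 0.20}},
    "TREE 15%": {"state": {"tree_fraction": 0.15}},
    "MAX 75%": {"state": {"cap_multiplier": 0.75}},
    "MAX 50%": {"state": {"cap_multiplier": 0.50}},
}


def sensitivity_suite(
    config: dict | None = None,
    which: tuple[str, ...] = SENSITIVITY_IDS,
    scenario_id: str = "agCO2",
    endpoint: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the sensitivity perturbations as pure config transforms.

    Each perturbation reruns the scenario with one knob changed (longer or
    shorter saturation, doubled adoption costs, reduced Western livestock
    demand, 1.5 C bioenergy pull, thinner tree strips, tighter caps) and
    reports cumulative mitigation relative to the base run.
    """
    for w in which:
        if w not in _PERTURBATIONS:
            raise ValueError(f"unknown perturbation {w!r}; valid: {SENSITIVITY_IDS}")
    base = run_scenario(config, scenario_id, endpoint=endpoint, seed=seed)
    rows = [{
        "perturbation": "base",
        "cumulative_mitigation": base.summary["cumulative_mitigation"],
        "relative_change": 0.0,
    }]
    for w in which:
        spec = _PERTURBATIONS[w]
        cfg = dict(config or {})
        if "config" in spec:
            cfg = {**cfg, **spec["config"]}
        sid = scenario_id
        if spec.get("scenario_suffix_bio") and not sid.endswith("_bio"):
            sid = sid + "_bio"
        run = run_scenario(cfg, sid, endpoint=endpoint, seed=seed,
                           **spec.get("state", {}))
        cm = run.summary["cumulative_mitigation"]
        rows.append({
            "perturbation": w,
            "cumulative_mitigation": cm,
            "relative_change": cm / base.summary["cumulative_mitigation"] - 1.0
            if base.summary["cumulative_mitigation"] else float("nan"),
        })
    return pd.DataFrame(rows)
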