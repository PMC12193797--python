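"""End-to-end scenario runs: demand → allocation → services → trade-offs.

Six scenarios cross three land-demand pathways (NIS natural increase,
EPS ecological protection, EDS economic development) with two climate
forcings (RCP4.5 moderate, RCP8.5 high).  Climate enters only the
service stage — water yield through precipitation/AET and erosivity —
so the allocated land-use map is identical across the two forcings of
the same land pathway; expansion suitability is fitted on
baseline-period climate.

Every run is fully determined by (configuration, seed) and serialises
to a canonical JSON report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .allocate import (
    CAState,
    allocate as run_allocation,
    class_counts,
    extract_samples,
    fit_suitability,
)
from . import demand as demand_mod
from . import es as es_mod
from . import synth as synth_mod
from . import tradeoff as tr_mod
from .raster import N_CLASSES, RasterGrid

#: The scenario grid: land pathway x climate forcing.
SCENARIO_GRID = {
    "S1": ("NIS", "RCP4.5"),
    "S2": ("NIS", "RCP8.5"),
    "S3": ("EPS", "RCP4.5"),
    "S4": ("EPS", "RCP8.5"),
    "S5": ("EDS", "RCP4.5"),
    "S6": ("EDS", "RCP8.5"),
}

#: Regional annual climate means per forcing (precip mm, temp °C).
RCP_CLIMATE = {
    "RCP4.5": {"precip_mean_mm": 851.55, "temp_mean_c": 16.55},
    "RCP8.5": {"precip_mean_mm": 1080.60, "temp_mean_c": 16.47},
}


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_GRID:
            raise ValueError(
                f"unknown scenario {self.id!r}; valid: {sorted(SCENARIO_GRID)}"
            )

    @property
    def lulc_scenario(self) -> str:
        return SCENARIO_GRID[self.id][0]

    @property
    def climate_scenario(self) -> str:
        return SCENARIO_GRID[self.id][1]


def _config_hash(config: synth_mod.SyntheticConfig, spec: ScenarioSpec) -> str:
    payload = json.dumps(
        {
            "shape": list(config.shape),
            "seed": config.seed,
            "fractions": list(config.class_fractions),
            "scenario": spec.id,
            "scenario_seed": spec.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _demand_cells(
    pathway: str,
    lulc_t0: RasterGrid,
    lulc_t1: RasterGrid,
) -> np.ndarray:
    """Per-class target cell counts for the allocated map.

    NIS projects the observed transition matrix one step; EPS/EDS scale
    the LP-optimal area shares onto the grid.  Largest-remainder rounding
    makes the targets sum exactly to the number of valid cells.
    """
    n_valid = int(lulc_t1.mask().sum())
    if pathway == "NIS":
        T = demand_mod.cross_tabulate(lulc_t0, lulc_t1)
        areas_now = demand_mod.LandUseAreas(
            class_counts(lulc_t1) * lulc_t1.cell_area_ha
        )
        proj = demand_mod.markov_project(areas_now, T, steps=1)
        shares = proj.areas / proj.total
    else:
        result = demand_mod.optimize_demand(pathway.lower())
        shares = result.areas.areas / result.areas.total
    raw = shares * n_valid
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n_valid - counts.sum()]:
        counts[i] += 1
    return counts


@dataclass
class RunReport:
    payload: dict

    def to_json(self) -> str:
        """Canonical serialisation: sorted keys, fixed float formatting."""
        return json.dumps(self.payload, sort_keys=True, indent=1, allow_nan=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _summary(grid: RasterGrid) -> dict:
    v = grid.values[grid.mask()]
    return {
        "mean": float(v.mean()),
        "min": float(v.min()),
        "max": float(v.max()),
        "sum": float(v.sum()),
    }


def compute_es_stack(
    lulc: RasterGrid,
    drivers: dict[str, RasterGrid],
    carbon_table: es_mod.CarbonDensityTable | None = None,
    habitat_config: es_mod.HabitatConfig | None = None,
    erodibility: float = 0.3,
) -> dict[str, RasterGrid]:
    """The four service rasters for one land-use map + climate stack."""
    carbon_table = carbon_table or es_mod.SYNTHETIC_CARBON_TABLE
    habitat_config = habitat_config or es_mod.default_habitat_config()
    wy = es_mod.water_yield(drivers["precip"], drivers["aet"])
    cs = es_mod.carbon_stock(lulc, carbon_table)
    hq = es_mod.habitat_quality(lulc, habitat_config)
    factors = es_mod.RusleFactors(
        erosivity=es_mod.erosivity_from_precip(drivers["precip"]),
        erodibility=lulc.copy_with(
            np.full(lulc.shape, erodibility), categorical=False, nodata=None
        ),
        ls=es_mod.ls_from_dem(drivers["dem"]),
        cover=es_mod.SYNTHETIC_COVER,
        practice=es_mod.SYNTHETIC_PRACTICE,
    )
    sr = es_mod.soil_retention(lulc, factors)
    return {"WY": wy, "CS": cs, "HQ": hq, "SR": sr}


def run_scenario(
    spec: ScenarioSpec,
    config: synth_mod.SyntheticConfig | None = None,
    unit_size_m: float = 300.0,
    run_gwr: bool = True,
    gwr_pairs=(("HQ", "SR"), ("WY", "CS")),
    sample_fraction: float = 0.5,
    n_trees: int = 50,
) -> RunReport:
    """Execute one full scenario and return its serialisable report.

    Stages: synthetic landscape → demand (Markov or LP) → expansion
    suitability (random forest) → CA allocation → four services →
    aggregation, Spearman matrix and (optionally) per-pair GWR.
    Intermediate failures yield a partial report with the failed stage
    recorded.
    """
    config = config or synth_mod.SyntheticConfig(seed=spec.seed)
    payload: dict = {
        "scenario": spec.id,
        "lulc_scenario": spec.lulc_scenario,
        "climate_scenario": spec.climate_scenario,
        "seed": spec.seed,
        "config_hash": _config_hash(config, spec),
        "stages": [],
    }
    try:
        # baseline landscape + drivers (baseline climate for suitability)
        scene = synth_mod.generate_landscape(config)
        drivers = scene["drivers"]
        t0, t1 = scene["lulc_t0"], scene["lulc_t1"]
        payload["stages"].append("landscape")

        # demand
        counts = _demand_cells(spec.lulc_scenario, t0, t1)
        payload["demand_cells"] = counts.tolist()
        payload["demand_ha"] = [
            round(float(c) * t1.cell_area_ha, 2) for c in counts
        ]
        payload["stages"].append("demand")

        # suitability + allocation
        samples = extract_samples(
            t0, t1, drivers, fraction=sample_fraction, seed=spec.seed
        )
        stack = fit_suitability(
            samples, drivers, n_estimators=n_trees, seed=spec.seed
        )
        state = CAState(lulc=t1, demand=counts, seed=spec.seed)
        allocated = run_allocation(state, stack)
        payload["allocated_counts"] = class_counts(allocated).tolist()
        payload["allocation_converged"] = bool(allocated.converged)
        payload["stages"].append("allocation")

        # scenario climate for the service stage
        clim_cfg = replace(config, **RCP_CLIMATE[spec.climate_scenario])
        precip, temp, aet = synth_mod.generate_climate(drivers["dem"], clim_cfg)
        es_drivers = dict(drivers, precip=precip, temp=temp, aet=aet)
        es_stack = compute_es_stack(allocated, es_drivers)
        payload["es_summary"] = {k: _summary(g) for k, g in es_stack.items()}
        payload["stages"].append("ecosystem_services")

        # trade-offs
        table = tr_mod.aggregate_grid(es_stack, unit_size_m)
        corr = tr_mod.spearman_matrix(table)
        payload["spearman"] = {
            f"{a}-{b}": round(float(corr.rho.loc[a, b]), 6)
            for a, b in tr_mod.ES_PAIRS
        }
        if run_gwr:
            gwr_out = {}
            for a, b in gwr_pairs:
                g = tr_mod.gwr_fit(
                    table[b].to_numpy(),
                    table[a].to_numpy(),
                    table[["U", "V"]].to_numpy(),
                )
                codes = tr_mod.classify_relationship(g)
                share = {
                    name: round(float((codes == code).mean()), 6)
                    for code, name in tr_mod.CATEGORY_CODES.items()
                }
                gwr_out[f"{a}-{b}"] = {
                    "bandwidth": g.bandwidth,
                    "r2": round(float(g.r2), 6),
                    "category_share": share,
                }
            payload["gwr"] = gwr_out
        payload["stages"].append("tradeoffs")
        payload["status"] = "completed"
    except Exception as exc:  # partial report with the failing stage
        payload["status"] = "failed"
        payload["error"] = f"{type(exc).__name__}: {exc}"
        return RunReport(payload)
    return RunReport(payload)


def compare_scenarios(reports: list[RunReport]) -> pd.DataFrame:
    """Per-service means and pairwise ρ by scenario, one row per quantity."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for rep in reports:
        p = rep.payload
        if p.get("status") != "completed":
            raise ValueError(f"scenario {p.get('scenario')} did not complete")
        for name, s in p["es_summary"].items():
            rows.append(
                {"scenario": p["scenario"], "quantity": f"{name}_mean", "value": s["mean"]}
            )
        for pair, r in p["spearman"].items():
            rows.append({"scenario": p["scenario"], "quantity": f"rho_{pair}", "value": r})
    df = pd.DataFrame(rows)
    return df.pivot(index="quantity", columns="scenario", values="value")
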