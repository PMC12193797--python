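"""Land-use demand for 2030: Markov projection and constrained LP optima.

Three demand scenarios are supported:

* **NIS** (natural increase): project the observed decadal transition
  matrix one step forward from the current areas.
* **EPS** (ecological protection): maximise total ecological benefit
  ``f1(x) = Σ ESV_i x_i`` subject to the policy constraint set.
* **EDS** (economic development): maximise total economic benefit
  ``f2(x) = Σ EC_i x_i`` subject to the same constraint set.

Decision variables are the six per-class areas x1..x6 (ha: cropland,
woodland, grassland, water, built-up, unused) and the population P in
10^4 persons.  The constraint set fixes the total area, bounds P by
carrying capacity, requires cropland to cover population food demand,
brackets woodland/grassland/water/built-up/unused areas by planning
bounds, ties built-up land to per-capita demand, and requires ecological
land (woodland + grassland + water) to stay above 75% of the region.

Benefit coefficients are in million CNY per hectare.  The LP is solved
exactly (HiGHS simplex); reported optima are vertex solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .raster import CLASS_CODES, N_CLASSES, RasterGrid, require_aligned

CLASS_NAMES = tuple(CLASS_CODES.values())

#: Ecological benefit per hectare (million CNY) for x1..x6 — EPS objective.
EPS_COEFFS = (0.5, 2.72, 1.55, 16.12, -1.58, 0.08)
#: Economic benefit per hectare (million CNY) for x1..x6 — EDS objective.
EDS_COEFFS = (12.88, 0.79, 7.74, 7.10, 785.85, 0.001)


@dataclass
class LandUseAreas:
    """Per-class areas (ha) plus the population scalar (10^4 persons)."""

    areas: np.ndarray  # shape (6,)
    population: float | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (N_CLASSES,):
            raise ValueError("areas must have 6 entries")
        if (self.areas < -1e-9).any():
            raise ValueError("areas must be non-negative")

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CLASS_NAMES, map(float, self.areas)))


@dataclass
class TransitionMatrix:
    """6x6 class-to-class converted areas (ha) over one interval."""

    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("transition matrix must be 6x6")
        if (self.areas < -1e-9).any():
            raise ValueError("transition areas must be non-negative")

    def probabilities(self) -> np.ndarray:
        """Row-stochastic form; rows with zero source area become identity."""
        row = self.areas.sum(axis=1, keepdims=True)
        p = np.where(row > 0, self.areas / np.where(row > 0, row, 1.0), 0.0)
        for i in range(N_CLASSES):
            if row[i, 0] == 0:
                p[i, i] = 1.0
        return p

    def source_areas(self) -> np.ndarray:
        return self.areas.sum(axis=1)


def cross_tabulate(lulc_t0: RasterGrid, lulc_t1: RasterGrid) -> TransitionMatrix:
    """Transition matrix in hectares from two aligned categorical maps."""
    require_aligned(lulc_t0, lulc_t1)
    m0, m1 = lulc_t0.mask(), lulc_t1.mask()
    if not np.array_equal(m0, m1):
        raise ValueError("land-cover maps have different nodata masks")
    if not m0.any():
        raise ValueError("no valid cells to cross-tabulate")
    a = lulc_t0.values[m0].astype(np.int64) - 1
    b = lulc_t1.values[m1].astype(np.int64) - 1
    counts = np.bincount(a * N_CLASSES + b, minlength=N_CLASSES**2).reshape(
        N_CLASSES, N_CLASSES
    )
    return TransitionMatrix(counts * lulc_t0.cell_area_ha)


def markov_project(
    areas_t: LandUseAreas, T: TransitionMatrix, steps: int = 1
) -> LandUseAreas:
    """Project areas forward by repeated application of the row-stochastic
    transition probabilities; total area is conserved."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    src = T.source_areas()
    for i, (s, a) in enumerate(zip(src, areas_t.areas)):
        if s == 0 and a > 0:
            raise ValueError(
                f"class {CLASS_NAMES[i]} has demand but no observed source area"
            )
    p = T.probabilities()
    out = areas_t.areas.copy()
    for _ in range(steps):
        out = out @ p
    return LandUseAreas(out, population=areas_t.population)


# ---------------------------------------------------------------------------
# Linear program
# ---------------------------------------------------------------------------

@dataclass
class ConstraintParams:
    """Policy constraint table for the demand LP (areas in ha).

    Bound pairs are interpreted as unordered {lo, hi} sets and sorted;
    defaults reproduce the study region's 2030 planning envelope.
    """

    total_area_ha: float = 11_141_039.34
    population_bounds: tuple[float, float] = (2127.0, 3050.0)   # 10^4 persons
    food_per_capita_kg: float = 141.2
    food_self_sufficiency: float = 1.1411
    grain_yield_kg_per_ha: float = 4316.24
    multiple_cropping_index: float = 1.11
    crop_planting_share: float = 0.67
    woodland_bounds: tuple[float, float] = (5_413_076.08, 5_522_431.16)
    grassland_bounds: tuple[float, float] = (2_920_662.98, 2_979_666.28)
    water_bounds: tuple[float, float] = (146_419.93, 164_919.00)
    builtup_bounds: tuple[float, float] = (332_112.95, 367_072.21)
    per_capita_builtup_ha: float = 0.0109
    unused_bounds: tuple[float, float] = (15_849.30, 16_049.16)
    ecological_min_share: float = 0.75

    @classmethod
    def from_projection(
        cls, woodland_2020: float, grassland_nis: float, tolerance: float = 0.01, **kw
    ) -> "ConstraintParams":
        """Derive the woodland/grassland brackets from their anchors
        (woodland: current area ±1%; grassland: projected area ±1%)."""
        return cls(
            woodland_bounds=(
                woodland_2020 * (1 - tolerance),
                woodland_2020 * (1 + tolerance),
            ),
            grassland_bounds=(
                grassland_nis * (1 - tolerance),
                grassland_nis * (1 + tolerance),
            ),
            **kw,
        )


@dataclass
class LPSpec:
    """Machine form of the demand LP over (x1..x6, P), sense = maximise."""

    objective: np.ndarray                 # length 7
    bounds: list[tuple[float | None, float | None]]
    A_ub: np.ndarray
    b_ub: np.ndarray
    ub_labels: list[str]
    A_eq: np.ndarray
    b_eq: np.ndarray
    eq_labels: list[str]
    scenario: str = ""

    @property
    def n_vars(self) -> int:
        return len(self.bounds)


@dataclass
class OptimizationResult:
    areas: LandUseAreas | None
    objective_value: float                # million CNY
    binding: list[str]
    status: str
    x: np.ndarray = field(default=None)


def _sorted_bounds(name: str, pair) -> tuple[float, float]:
    lo, hi = sorted(map(float, pair))
    if not np.isfinite([lo, hi]).all():
        raise ValueError(f"{name} bounds are not finite: {pair}")
    if lo > hi:
        raise ValueError(f"{name} bounds inverted after sorting: {pair}")
    return lo, hi


def build_lp(scenario: str, params: ConstraintParams | None = None) -> LPSpec:
    """Assemble the EPS or EDS linear program from the constraint table."""
    params = params or ConstraintParams()
    scenario = scenario.lower()
    if scenario == "eps":
        coeffs = EPS_COEFFS
    elif scenario == "eds":
        coeffs = EDS_COEFFS
    else:
        raise ValueError("scenario must be 'eps' or 'eds'")
    c = np.array(list(coeffs) + [0.0])  # P has no direct benefit

    bounds: list[tuple[float | None, float | None]] = [
        (0.0, None),
        _sorted_bounds("woodland", params.woodland_bounds),
        _sorted_bounds("grassland", params.grassland_bounds),
        _sorted_bounds("water", params.water_bounds),
        _sorted_bounds("built_up", params.builtup_bounds),
        _sorted_bounds("unused", params.unused_bounds),
        _sorted_bounds("population", params.population_bounds),
    ]

    # P is in 10^4 persons: per-capita coefficients apply to P x 10^4.
    food_lhs = np.zeros(7)
    food_lhs[6] = params.food_per_capita_kg * params.food_self_sufficiency * 1e4
    food_lhs[0] = -(
        params.grain_yield_kg_per_ha
        * params.multiple_cropping_index
        * params.crop_planting_share
    )
    built_lhs = np.zeros(7)
    built_lhs[6] = params.per_capita_builtup_ha * 1e4
    built_lhs[4] = -1.0
    eco_lhs = np.zeros(7)
    eco_lhs[1:4] = -1.0

    A_ub = np.vstack([food_lhs, built_lhs, eco_lhs])
    b_ub = np.array([0.0, 0.0, -params.ecological_min_share * params.total_area_ha])
    ub_labels = ["food_demand", "builtup_per_capita", "ecological_land_min"]

    A_eq = np.array([[1.0] * N_CLASSES + [0.0]])
    b_eq = np.array([params.total_area_ha])
    return LPSpec(
        objective=c,
        bounds=bounds,
        A_ub=A_ub,
        b_ub=b_ub,
        ub_labels=ub_labels,
        A_eq=A_eq,
        b_eq=b_eq,
        eq_labels=["total_area"],
        scenario=scenario,
    )


def _find_iis(spec: LPSpec) -> list[str]:
    """Greedy deletion filter for an irreducible infeasible constraint set."""
    rows = list(range(len(spec.b_ub)))

    def feasible(keep) -> bool:
        r = linprog(
            np.zeros(spec.n_vars),
            A_ub=spec.A_ub[keep] if keep else None,
            b_ub=spec.b_ub[keep] if keep else None,
            A_eq=spec.A_eq,
            b_eq=spec.b_eq,
            bounds=spec.bounds,
            method="highs",
        )
        return r.status == 0

    keep = rows[:]
    for r in rows:
        trial = [k for k in keep if k != r]
        if not feasible(trial):
            keep = trial
    return [spec.ub_labels[r] for r in keep] + spec.eq_labels


def solve_lp(spec: LPSpec, tol: float = 1e-6) -> OptimizationResult:
    """Exact LP solve (HiGHS); validates the optimum against every
    constraint and reports which ones are binding."""
    res = linprog(
        -spec.objective,
        A_ub=spec.A_ub,
        b_ub=spec.b_ub,
        A_eq=spec.A_eq,
        b_eq=spec.b_eq,
        bounds=spec.bounds,
        method="highs",
    )
    if res.status == 2:
        iis = _find_iis(spec)
        raise ValueError(f"LP infeasible; irreducible infeasible subset: {iis}")
    if res.status == 3:
        raise ValueError("LP unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")

    x = res.x
    scale = max(1.0, float(np.abs(spec.b_eq).max()))
    # machine-check feasibility of the reported vertex
    assert (spec.A_ub @ x <= spec.b_ub + tol * np.abs(spec.b_ub) + tol * scale).all()
    assert np.allclose(spec.A_eq @ x, spec.b_eq, rtol=tol)
    binding = [
        lab
        for lab, lhs, rhs in zip(spec.ub_labels, spec.A_ub @ x, spec.b_ub)
        if abs(lhs - rhs) <= tol * max(1.0, abs(rhs))
    ]
    var_names = (
        CLASS_NAMES + ("population",)
        if spec.n_vars == N_CLASSES + 1
        else tuple(f"x{i+1}" for i in range(spec.n_vars))
    )
    for i, (lo, hi) in enumerate(spec.bounds):
        if lo is not None and abs(x[i] - lo) <= tol * max(1.0, abs(lo)):
            binding.append(f"{var_names[i]}_lower")
        if hi is not None and abs(x[i] - hi) <= tol * max(1.0, abs(hi)):
            binding.append(f"{var_names[i]}_upper")
    areas = (
        LandUseAreas(x[:N_CLASSES], population=float(x[N_CLASSES]))
        if spec.n_vars == N_CLASSES + 1
        else None
    )
    return OptimizationResult(
        areas=areas,
        objective_value=float(spec.objective @ x),
        binding=binding,
        status="optimal",
        x=x,
    )


def optimize_demand(
    scenario: str, params: ConstraintParams | None = None
) -> OptimizationResult:
    """Convenience: build and solve the EPS or EDS demand LP."""
    return solve_lp(build_lp(scenario, params))


def demand_table(params: ConstraintParams | None = None) -> "pandas.DataFrame":
    """EPS and EDS optima side by side (rows = classes, ha, 2 decimals)."""
    import pandas as pd

    cols = {}
    for sc in ("eps", "eds"):
        cols[sc.upper()] = np.round(optimize_demand(sc, params).areas.areas, 2)
    return pd.DataFrame(cols, index=CLASS_NAMES)
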