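"""Per-cell ecosystem-service models: water yield, carbon stock, habitat
quality, and RUSLE soil retention.

All four services are deterministic raster functions:

* water yield ``Y = (1 - AET/P)·P = P - AET`` (mm), clamped at zero;
* carbon stock ``C_total = C_above + C_below + C_soil + C_dead`` looked up
  per land-cover class (t/hm²), with optional multiplicative climate
  correction factors;
* habitat quality ``Q = H_j·(1 - D^z/(D^z + k^z))`` where the degradation
  ``D`` accumulates distance-decayed threat pressure from source classes;
* soil retention ``A = R·K·LS·(1 - C·P)`` (t/hm²), with helper
  formulations for rainfall erosivity (power law of annual precipitation)
  and the LS factor (D8 flow accumulation + slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .raster import CLASS_CODES, N_CLASSES, RasterGrid, require_aligned
from .synth import slope_degrees


# ---------------------------------------------------------------------------
# Water yield
# ---------------------------------------------------------------------------

def water_yield(precip: RasterGrid, aet: RasterGrid) -> RasterGrid:
    """Annual water yield (mm) from the water balance P − AET, floored at 0."""
    require_aligned(precip, aet)
    if (precip.values[precip.mask()] < 0).any():
        raise ValueError("precipitation must be non-negative")
    y = np.clip(precip.values - aet.values, 0.0, None)
    y = np.where(precip.values == 0, 0.0, y)
    return precip.copy_with(y)


# ---------------------------------------------------------------------------
# Carbon stock
# ---------------------------------------------------------------------------

@dataclass
class CarbonDensityTable:
    """Four carbon pools (t/hm²) per land-cover class.

    ``pools[class_code] = (above, below, soil, dead)``; ``correction``
    holds optional per-class multiplicative climate factors (default 1),
    a hook for precipitation/temperature density adjustment.
    """

    pools: dict[int, tuple[float, float, float, float]]
    correction: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, p in self.pools.items():
            if len(p) != 4 or any(v < 0 for v in p):
                raise ValueError(f"class {k}: pools must be 4 non-negative values")

    def total_density(self, k: int) -> float:
        if k not in self.pools:
            raise KeyError(f"class {CLASS_CODES.get(k, k)} missing from carbon table")
        return sum(self.pools[k]) * self.correction.get(k, 1.0)


#: Placeholder per-class densities (synthetic; field-typical magnitudes for
#: subtropical plateau systems, NOT calibrated values).
SYNTHETIC_CARBON_TABLE = CarbonDensityTable(
    pools={
        1: (5.0, 1.0, 60.0, 0.5),    # cropland
        2: (35.0, 8.0, 90.0, 3.0),   # woodland
        3: (3.0, 8.0, 70.0, 1.5),    # grassland
        4: (0.0, 0.0, 25.0, 0.0),    # water
        5: (1.0, 0.5, 30.0, 0.0),    # built-up
        6: (0.5, 0.1, 20.0, 0.0),    # unused
    }
)


def carbon_stock(lulc: RasterGrid, table: CarbonDensityTable) -> RasterGrid:
    """Per-cell total carbon density (t/hm²) by land-cover lookup."""
    mask = lulc.mask()
    present = np.unique(lulc.values[mask]).astype(int)
    lut = np.zeros(N_CLASSES + 1)
    for k in present:
        lut[k] = table.total_density(int(k))
    out = lut[np.clip(lulc.values, 0, N_CLASSES).astype(np.int64)]
    out = np.where(mask, out, 0.0)
    return lulc.copy_with(out, categorical=False, nodata=None)


# ---------------------------------------------------------------------------
# Habitat quality
# ---------------------------------------------------------------------------

@dataclass
class Threat:
    """One habitat stress factor radiating from source land-cover classes."""

    name: str
    source_classes: tuple[int, ...]
    weight: float                       # W_r in [0, 1]
    max_distance_m: float               # d_max
    decay: str = "linear"               # 'linear' or 'exponential'
    sensitivity: dict[int, float] = field(default_factory=dict)  # S_jr per class

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError("threat weight must be in [0, 1]")
        if self.max_distance_m <= 0:
            raise ValueError("max_distance_m must be positive")
        if self.decay not in {"linear", "exponential"}:
            raise ValueError("decay must be 'linear' or 'exponential'")


@dataclass
class HabitatConfig:
    """Habitat suitability, threats, accessibility and saturation settings."""

    suitability: dict[int, float]       # H_j in [0, 1] per class
    threats: list[Threat]
    accessibility: float | np.ndarray = 1.0   # β_x
    z: float = 2.5
    half_saturation: float | None = None      # k; None -> half of max D

    def __post_init__(self) -> None:
        for k, h in self.suitability.items():
            if not 0 <= h <= 1:
                raise ValueError(f"H_{k} must be in [0, 1]")


def default_habitat_config() -> HabitatConfig:
    """Cropland and built-up land as stress sources (synthetic placeholder
    weights/sensitivities with field-typical magnitudes)."""
    sens_crop = {1: 0.0, 2: 0.5, 3: 0.45, 4: 0.6, 5: 0.0, 6: 0.2}
    sens_built = {1: 0.5, 2: 0.85, 3: 0.6, 4: 0.8, 5: 0.0, 6: 0.3}
    return HabitatConfig(
        suitability={1: 0.3, 2: 1.0, 3: 0.7, 4: 0.7, 5: 0.0, 6: 0.1},
        threats=[
            Threat("cropland", (1,), weight=0.6, max_distance_m=2000.0,
                   decay="linear", sensitivity=sens_crop),
            Threat("built_up", (5,), weight=1.0, max_distance_m=5000.0,
                   decay="exponential", sensitivity=sens_built),
        ],
    )


def _decay_kernel(threat: Threat, cell_size_m: float) -> np.ndarray:
    """Distance-decay kernel i(d) sampled at cell-centre offsets."""
    r = int(np.ceil(threat.max_distance_m / cell_size_m))
    off = np.arange(-r, r + 1) * cell_size_m
    d = np.hypot(off[:, None], off[None, :])
    if threat.decay == "linear":
        kern = np.maximum(0.0, 1.0 - d / threat.max_distance_m)
    else:
        kern = np.exp(-2.99 * d / threat.max_distance_m)
        kern[d > threat.max_distance_m] = 0.0
    return kern


def threat_degradation(lulc: RasterGrid, config: HabitatConfig) -> RasterGrid:
    """Total degradation D per cell: weight-normalised, distance-decayed
    pressure from every threat-source cell, scaled by accessibility and
    the exposed cell's class sensitivity.  Implemented as an FFT
    convolution of the source indicator with the decay kernel."""
    if not config.threats:
        raise ValueError("at least one threat must be defined")
    w_sum = sum(t.weight for t in config.threats)
    classes = np.clip(lulc.values, 0, N_CLASSES).astype(np.int64)
    total = np.zeros(lulc.shape)
    for t in config.threats:
        src = np.isin(lulc.values, t.source_classes).astype(float)
        if src.sum() == 0:
            continue
        kern = _decay_kernel(t, lulc.cell_size_m)
        pressure = fftconvolve(src, kern, mode="same")
        pressure = np.clip(pressure, 0.0, None)
        sens_lut = np.zeros(N_CLASSES + 1)
        for k, s in t.sensitivity.items():
            sens_lut[k] = s
        total += (t.weight / w_sum) * pressure * sens_lut[classes]
    total *= np.asarray(config.accessibility)
    total = np.where(lulc.mask(), total, 0.0)
    return lulc.copy_with(total, categorical=False, nodata=None)


def threat_degradation_bruteforce(
    lulc: RasterGrid, config: HabitatConfig
) -> RasterGrid:
    """O(N²) pairwise reference for :func:`threat_degradation` (small grids).

    Independent oracle: explicit double loop over all (exposed, source)
    cell pairs with centre-to-centre Euclidean distances.
    """
    w_sum = sum(t.weight for t in config.threats)
    rows, cols = lulc.shape
    cs = lulc.cell_size_m
    vals = lulc.values
    total = np.zeros(lulc.shape)
    beta = np.broadcast_to(np.asarray(config.accessibility), lulc.shape)
    for t in config.threats:
        srcs = np.argwhere(np.isin(vals, t.source_classes))
        for x in range(rows):
            for y in range(cols):
                s = t.sensitivity.get(int(vals[x, y]), 0.0)
                if s == 0:
                    continue
                acc = 0.0
                for sx, sy in srcs:
                    d = cs * np.hypot(x - sx, y - sy)
                    if t.decay == "linear":
                        i = max(0.0, 1.0 - d / t.max_distance_m)
                    else:
                        i = np.exp(-2.99 * d / t.max_distance_m)
                        if d > t.max_distance_m:
                            i = 0.0
                    acc += i
                total[x, y] += (t.weight / w_sum) * acc * beta[x, y] * s
    total = np.where(lulc.mask(), total, 0.0)
    return lulc.copy_with(total, categorical=False, nodata=None)


def habitat_quality(
    lulc: RasterGrid,
    config: HabitatConfig,
    degradation: RasterGrid | None = None,
) -> RasterGrid:
    """Habitat quality Q = H_j · (1 − D^z / (D^z + k^z)) in [0, 1]."""
    if degradation is None:
        degradation = threat_degradation(lulc, config)
    d = degradation.values
    k = config.half_saturation
    if k is None:
        k = 0.5 * float(d.max()) if d.max() > 0 else 0.5
    if k <= 0:
        raise ValueError("half-saturation constant must be positive")
    h_lut = np.zeros(N_CLASSES + 1)
    for c, h in config.suitability.items():
        h_lut[c] = h
    H = h_lut[np.clip(lulc.values, 0, N_CLASSES).astype(np.int64)]
    dz = np.power(d, config.z)
    q = H * (1.0 - dz / (dz + k**config.z))
    q = np.where(lulc.mask(), np.clip(q, 0.0, 1.0), 0.0)
    return lulc.copy_with(q, categorical=False, nodata=None)


# ---------------------------------------------------------------------------
# RUSLE soil retention
# ---------------------------------------------------------------------------

@dataclass
class RusleFactors:
    """Aligned factor rasters and per-class cover/practice lookups."""

    erosivity: RasterGrid               # R
    erodibility: RasterGrid             # K
    ls: RasterGrid                      # LS
    cover: dict[int, float]             # C per class, in [0, 1]
    practice: dict[int, float]          # P per class, in [0, 1]


#: Placeholder C/P lookups (synthetic; field-typical magnitudes).
SYNTHETIC_COVER = {1: 0.22, 2: 0.006, 3: 0.05, 4: 0.0, 5: 0.001, 6: 0.45}
SYNTHETIC_PRACTICE = {1: 0.35, 2: 1.0, 3: 1.0, 4: 0.0, 5: 1.0, 6: 1.0}


def soil_retention(lulc: RasterGrid, factors: RusleFactors) -> RasterGrid:
    """Soil retention A = R·K·LS·(1 − C·P) per cell (t/hm²)."""
    require_aligned(lulc, factors.erosivity, factors.erodibility, factors.ls)
    c_lut = np.zeros(N_CLASSES + 1)
    p_lut = np.zeros(N_CLASSES + 1)
    for k in range(1, N_CLASSES + 1):
        c_lut[k] = factors.cover.get(k, 0.0)
        p_lut[k] = factors.practice.get(k, 0.0)
    classes = np.clip(lulc.values, 0, N_CLASSES).astype(np.int64)
    cp = c_lut[classes] * p_lut[classes]
    if (cp > 1.0 + 1e-12).any():
        raise ValueError("C x P exceeds 1 for some class; retention would be negative")
    a = (
        factors.erosivity.values
        * factors.erodibility.values
        * factors.ls.values
        * (1.0 - cp)
    )
    a = np.where(lulc.mask(), np.clip(a, 0.0, None), 0.0)
    return lulc.copy_with(a, categorical=False, nodata=None)


def erosivity_from_precip(
    precip: RasterGrid, a: float = 0.0534, b: float = 1.6548
) -> RasterGrid:
    """Annual rainfall erosivity as a power law R = a·P^b of annual
    precipitation (mm); default coefficients are a common annual-scale
    regression for humid subtropical monsoon climates."""
    p = precip.values
    if (p[precip.mask()] < 0).any():
        raise ValueError("precipitation must be non-negative")
    return precip.copy_with(a * np.power(np.clip(p, 0, None), b))


def _d8_flow_accumulation(dem: RasterGrid) -> np.ndarray:
    """Cells drained through each cell (incl. itself), steepest-descent D8."""
    z = dem.values.astype(float)
    rows, cols = z.shape
    cs = dem.cell_size_m
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    dist = np.array([np.hypot(dr, dc) * cs for dr, dc in offs])
    target = -np.ones((rows, cols), dtype=np.int64)
    for i, (dr, dc) in enumerate(offs):
        shifted = np.full_like(z, np.inf)
        shifted[max(0, -dr):rows - max(0, dr), max(0, -dc):cols - max(0, dc)] = z[
            max(0, dr):rows - max(0, -dr), max(0, dc):cols - max(0, -dc)
        ]
        drop = (z - shifted) / dist[i]
        if i == 0:
            best = drop.copy()
            best_i = np.zeros_like(target)
        else:
            upd = drop > best
            best[upd] = drop[upd]
            best_i[upd] = i
    has_down = best > 0
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    tr = rr + np.array([o[0] for o in offs])[best_i]
    tc = cc + np.array([o[1] for o in offs])[best_i]
    flat_target = np.where(has_down, tr * cols + tc, -1)

    acc = np.ones(rows * cols)
    order = np.argsort(-z.ravel(), kind="stable")  # high to low
    ft = flat_target.ravel()
    for cell in order:
        t = ft[cell]
        if t >= 0:
            acc[t] += acc[cell]
    return acc.reshape(rows, cols)


def ls_from_dem(
    dem: RasterGrid, m: float = 0.4, n: float = 1.3, slope_floor_deg: float = 0.057
) -> RasterGrid:
    """Slope-length factor LS = (A_s/22.13)^m · (sin θ / 0.0896)^n with
    specific contributing area A_s from D8 flow accumulation.

    A small slope floor keeps LS a positive minimal constant on flat
    terrain instead of degenerating to zero.
    """
    slope = np.radians(np.maximum(slope_degrees(dem), slope_floor_deg))
    acc = _d8_flow_accumulation(dem)
    a_s = acc * dem.cell_size_m  # specific contributing area per unit width
    ls = np.power(a_s / 22.13, m) * np.power(np.sin(slope) / 0.0896, n)
    return dem.copy_with(np.clip(ls, 0.0, None))
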