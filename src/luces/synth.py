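"""Seeded synthetic landscapes: terrain, climate, drivers and land-cover pairs.

The generator emulates a plateau mountain–basin study region: a smooth
spectral-noise DEM, climate fields with an elevation lapse and a regional
trend, socio-economic driver surfaces concentrated in low flat terrain, and
a pair of six-class land-cover maps whose difference follows a known,
driver-dependent change process.  Because the change rules are returned as
ground truth, every downstream stage (expansion mining, suitability
modelling, allocation) can be tested for recovery of the generating
process.

All randomness flows from one integer seed; per-artifact sub-streams are
spawned deterministically so that, e.g., regenerating the climate never
perturbs the terrain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .raster import N_CLASSES, RasterGrid

logger = logging.getLogger(__name__)

# Default class fractions follow the regional composition reported for the
# study system: woodland-dominated (~49%), then grassland (~27%) and
# cropland (~20%), with small water / built-up / unused shares.
DEFAULT_FRACTIONS = (0.2023, 0.4908, 0.2684, 0.0131, 0.0234, 0.0020)

DRIVER_NAMES = ("dem", "slope", "precip", "temp", "aet", "popden", "gdp")


@dataclass(frozen=True)
class ChangeRule:
    """One directed land-conversion process with a known driving factor.

    ``dst`` gains ``growth_frac`` × (its current cell count) cells, taken
    from other classes, preferentially where the oriented driver value and
    the dst-neighbourhood fraction are high.
    """

    dst: int
    growth_frac: float
    driver: str            # one of DRIVER_NAMES
    direction: float = 1.0  # +1: grows where driver is high; -1: where low
    neigh_weight: float = 0.5
    src_classes: tuple[int, ...] = (1, 2, 3, 6)


# Emulates the observed decadal trend: built-up expansion around population
# centres, water spreading in low terrain, modest cropland reclamation.
DEFAULT_CHANGE_RULES = (
    ChangeRule(dst=5, growth_frac=0.30, driver="popden", direction=1.0),
    ChangeRule(dst=4, growth_frac=0.08, driver="dem", direction=-1.0,
               src_classes=(1, 2, 3, 6)),
    ChangeRule(dst=1, growth_frac=0.02, driver="slope", direction=-1.0,
               src_classes=(3, 6)),
)


@dataclass
class SyntheticConfig:
    shape: tuple[int, int] = (200, 200)
    seed: int = 0
    cell_size_m: float = 30.0
    class_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    autocorrelation_length: float = 8.0   # cells; spectral cutoff of noise
    # terrain
    base_elevation_m: float = 1500.0
    relief_m: float = 1200.0
    # climate (annual means; lapse rates per metre of elevation)
    precip_mean_mm: float = 851.55
    precip_lapse_mm_per_m: float = 0.25
    precip_trend_mm: float = 300.0        # north->south increase amplitude
    precip_noise_sd_mm: float = 60.0
    temp_mean_c: float = 16.55
    temp_lapse_c_per_m: float = -0.0065
    temp_noise_sd_c: float = 0.4
    aet_fraction_mean: float = 0.6
    aet_fraction_sd: float = 0.1
    change_rules: tuple[ChangeRule, ...] = DEFAULT_CHANGE_RULES

    def __post_init__(self) -> None:
        if len(self.class_fractions) != N_CLASSES:
            raise ValueError("class_fractions must have 6 entries")
        if any(f < 0 for f in self.class_fractions):
            raise ValueError("class_fractions must be non-negative")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-artifact sub-stream of the global seed."""
        ss = np.random.SeedSequence([self.seed, _stream_key(stream)])
        return np.random.default_rng(ss)


def _stream_key(stream: str) -> int:
    return int.from_bytes(stream.encode()[:8].ljust(8, b"\0"), "little") % (2**31)


def spectral_field(shape, rng, correlation_length=8.0, beta=1.5) -> np.ndarray:
    """Standardised Gaussian random field with power-law spectral falloff.

    Low-pass filtering white noise at wavenumbers above
    1 / ``correlation_length`` yields smooth, seeded, spatially
    autocorrelated surfaces at O(n log n) cost.
    """
    rows, cols = shape
    white = rng.standard_normal((rows, cols))
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    k = np.hypot(fy, fx)
    k0 = 1.0 / max(correlation_length, 1e-9)
    with np.errstate(divide="ignore"):
        amp = (1.0 + (k / k0) ** 2) ** (-beta)
    amp[0, 0] = 0.0
    f = np.fft.ifft2(np.fft.fft2(white) * amp).real
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def slope_degrees(dem: RasterGrid) -> np.ndarray:
    """Finite-difference slope in degrees (Horn-style central differences)."""
    dzdy, dzdx = np.gradient(dem.values.astype(float), dem.cell_size_m)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def generate_terrain(config: SyntheticConfig) -> tuple[RasterGrid, RasterGrid]:
    """Smooth spectral-noise DEM and its slope grid (degrees)."""
    rows, cols = config.shape
    if rows < 16 or cols < 16:
        raise ValueError("terrain grid must be at least 16x16")
    rng = config.rng("terrain")
    f = spectral_field(config.shape, rng, config.autocorrelation_length)
    dem_vals = config.base_elevation_m + config.relief_m * 0.25 * f
    dem = RasterGrid(dem_vals, cell_size_m=config.cell_size_m)
    slope = dem.copy_with(slope_degrees(dem))
    return dem, slope


def generate_climate(
    dem: RasterGrid, config: SyntheticConfig
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Precipitation, temperature and actual-ET grids tied to the terrain.

    Precipitation = regional mean + north→south trend + elevation lapse +
    autocorrelated noise, clipped at zero.  AET is a smooth fraction field
    of precipitation so 0 ≤ AET ≤ P holds cellwise by construction.
    """
    rng = config.rng("climate")
    rows, cols = dem.shape
    anom = dem.values - float(dem.values.mean())
    ns = (np.arange(rows)[:, None] / max(rows - 1, 1) - 0.5) * np.ones((1, cols))

    precip = (
        config.precip_mean_mm
        + config.precip_trend_mm * ns
        + config.precip_lapse_mm_per_m * anom
        + config.precip_noise_sd_mm
        * spectral_field(dem.shape, rng, config.autocorrelation_length)
    )
    n_neg = int((precip < 0).sum())
    if n_neg:
        logger.warning("clipping %d negative precipitation cells to 0", n_neg)
        precip = np.clip(precip, 0.0, None)

    temp = (
        config.temp_mean_c
        + config.temp_lapse_c_per_m * anom
        + config.temp_noise_sd_c
        * spectral_field(dem.shape, rng, config.autocorrelation_length)
    )

    frac = np.clip(
        config.aet_fraction_mean
        + config.aet_fraction_sd
        * spectral_field(dem.shape, rng, config.autocorrelation_length),
        0.0,
        1.0,
    )
    aet = frac * precip
    mk = dem.copy_with
    return mk(precip), mk(temp), mk(aet)


def generate_drivers(config: SyntheticConfig) -> dict[str, RasterGrid]:
    """Full driver stack: terrain, climate and socio-economic surfaces.

    Population density and GDP concentrate in low, flat terrain (basins),
    mimicking plateau urbanisation; GDP is population-correlated with its
    own noise.
    """
    dem, slope = generate_terrain(config)
    precip, temp, aet = generate_climate(dem, config)
    rng = config.rng("socio")
    z_dem = _standardise(dem.values)
    z_slope = _standardise(slope.values)
    pop_latent = (
        -0.8 * z_dem
        - 0.6 * z_slope
        + 0.8 * spectral_field(config.shape, rng, config.autocorrelation_length * 2)
    )
    popden = np.exp(pop_latent)  # persons / km^2, lognormal-like
    gdp = popden * np.exp(
        0.3 * spectral_field(config.shape, rng, config.autocorrelation_length)
    )
    mk = dem.copy_with
    return {
        "dem": dem,
        "slope": slope,
        "precip": precip,
        "temp": temp,
        "aet": aet,
        "popden": mk(popden),
        "gdp": mk(gdp),
    }


def _standardise(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)


def _latent_suitability(drivers: dict[str, RasterGrid], config: SyntheticConfig):
    """Per-class latent fields used to place the initial map.

    Weights encode field-plausible preferences: cropland in low flat warm
    basins, woodland on wet high slopes, water at elevation minima,
    built-up near population, unused at cold high ground.
    """
    rng = config.rng("lulc-latent")
    z = {k: _standardise(g.values) for k, g in drivers.items()}
    noise = {
        k: spectral_field(config.shape, rng, config.autocorrelation_length)
        for k in range(1, N_CLASSES + 1)
    }
    latent = {
        1: -0.9 * z["slope"] - 0.5 * z["dem"] + 0.3 * z["temp"] + 0.8 * noise[1],
        2: 0.7 * z["dem"] + 0.5 * z["precip"] + 0.4 * z["slope"] + 0.8 * noise[2],
        3: 0.3 * z["dem"] - 0.2 * z["precip"] + 1.0 * noise[3],
        4: -1.6 * z["dem"] - 0.8 * z["slope"] + 0.5 * noise[4],
        5: 1.2 * z["popden"] - 0.4 * z["slope"] + 0.5 * noise[5],
        6: 1.0 * z["dem"] - 0.6 * z["temp"] + 0.6 * noise[6],
    }
    return latent


#: Order in which classes claim cells during rank-thresholding; rarest and
#: most strongly driver-bound first so their targets are met exactly.
_ASSIGN_ORDER = (4, 5, 6, 1, 2, 3)


def _rank_threshold(latent, fractions, shape) -> np.ndarray:
    """Assign classes by descending latent value, hitting exact counts."""
    n = shape[0] * shape[1]
    counts = np.floor(np.asarray(fractions) * n).astype(int)
    # largest-remainder rounding to make counts sum to n
    rem = np.asarray(fractions) * n - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    out = np.zeros(n, dtype=np.int16)
    assigned = np.zeros(n, dtype=bool)
    for k in _ASSIGN_ORDER:
        want = counts[k - 1]
        if want == 0:
            continue
        score = latent[k].ravel().copy()
        score[assigned] = -np.inf
        idx = np.argpartition(-score, want - 1)[:want]
        out[idx] = k
        assigned[idx] = True
    # numerical safety: any leftover cells (should not occur) go to the modal class
    if not assigned.all():
        out[~assigned] = int(np.argmax(counts)) + 1
    return out.reshape(shape)


def _neighbour_fraction(classes: np.ndarray, k: int) -> np.ndarray:
    """Fraction of class-k cells in the 3x3 Moore neighbourhood (excl. centre)."""
    from scipy.ndimage import uniform_filter

    ind = (classes == k).astype(float)
    s = uniform_filter(ind, size=3, mode="constant") * 9.0
    c = uniform_filter(np.ones_like(ind), size=3, mode="constant") * 9.0
    return (s - ind) / np.maximum(c - 1.0, 1.0)


def apply_change_rules(
    lulc_t0: RasterGrid,
    drivers: dict[str, RasterGrid],
    rules,
    rng: np.random.Generator,
) -> RasterGrid:
    """Apply each change rule in order, producing the later map."""
    classes = lulc_t0.values.copy()
    for rule in rules:
        n_dst = int((classes == rule.dst).sum())
        n_convert = int(round(rule.growth_frac * n_dst))
        if n_convert == 0:
            continue
        z = _standardise(drivers[rule.driver].values) * rule.direction
        score = (
            z
            + rule.neigh_weight * _neighbour_fraction(classes, rule.dst)
            + 0.05 * rng.standard_normal(classes.shape)
        )
        eligible = np.isin(classes, rule.src_classes)
        flat = score.ravel().copy()
        flat[~eligible.ravel()] = -np.inf
        n_convert = min(n_convert, int(eligible.sum()))
        idx = np.argpartition(-flat, n_convert - 1)[:n_convert]
        out = classes.ravel()
        out[idx] = rule.dst
        classes = out.reshape(classes.shape)
    return lulc_t0.copy_with(classes)


def generate_lulc_pair(
    dem: RasterGrid,
    drivers: dict[str, RasterGrid],
    config: SyntheticConfig,
) -> tuple[RasterGrid, RasterGrid, tuple[ChangeRule, ...]]:
    """Paired land-cover maps with a known change process.

    Returns (t0, t1, rules): t0 is rank-thresholded from driver-weighted
    latent fields at the configured class fractions; t1 applies the
    configured change rules, whose driver ordering is the ground truth for
    suitability-recovery tests.
    """
    if dem.shape != config.shape:
        raise ValueError("dem shape does not match config.shape")
    latent = _latent_suitability(drivers, config)
    t0_vals = _rank_threshold(latent, config.class_fractions, config.shape)
    t0 = RasterGrid(
        t0_vals, cell_size_m=config.cell_size_m, nodata=0, categorical=True
    )
    rng = config.rng("lulc-change")
    t1 = apply_change_rules(t0, drivers, config.change_rules, rng)
    return t0, t1, tuple(config.change_rules)


def generate_landscape(config: SyntheticConfig) -> dict:
    """One-call convenience: drivers plus the land-cover pair and truth."""
    drivers = generate_drivers(config)
    t0, t1, rules = generate_lulc_pair(drivers["dem"], drivers, config)
    return {"drivers": drivers, "lulc_t0": t0, "lulc_t1": t1, "truth": rules}
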