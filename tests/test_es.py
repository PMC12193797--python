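"""Ecosystem-service models: substitution examples, brute-force threat
oracle, bounds and conservation identities."""

import numpy as np
import pytest

from luces.es import (
    CarbonDensityTable,
    HabitatConfig,
    RusleFactors,
    SYNTHETIC_CARBON_TABLE,
    Threat,
    carbon_stock,
    erosivity_from_precip,
    habitat_quality,
    ls_from_dem,
    soil_retention,
    threat_degradation,
    threat_degradation_bruteforce,
    water_yield,
)
from luces.raster import RasterGrid
from luces.synth import SyntheticConfig, generate_terrain


def _grid(vals, cell=30.0, **kw):
    return RasterGrid(np.asarray(vals, dtype=float), cell_size_m=cell, **kw)


def _cat(vals, cell=30.0):
    return RasterGrid(np.asarray(vals, dtype=np.int16), cell_size_m=cell,
                      nodata=0, categorical=True)


class TestWaterYield:
    def test_zero_aet_returns_precip(self):
        p = _grid(np.full((5, 5), 800.0))
        assert np.allclose(water_yield(p, _grid(np.zeros((5, 5)))).values, 800.0)

    def test_direct_substitution(self):
        y = water_yield(_grid([[1000.0]]), _grid([[400.0]]))
        assert y.values[0, 0] == pytest.approx(600.0)

    def test_conservation_identity(self):
        rng = np.random.default_rng(0)
        p = _grid(rng.uniform(0, 1500, (20, 20)))
        a = _grid(rng.uniform(0, 1800, (20, 20)))  # AET may exceed P
        y = water_yield(p, a)
        assert y.values.sum() == pytest.approx(
            p.values.sum() - np.minimum(a.values, p.values).sum()
        )
        assert (y.values >= 0).all()

    def test_zero_precip_cell_yields_zero(self):
        y = water_yield(_grid([[0.0, 100.0]]), _grid([[0.0, 30.0]]))
        assert y.values[0, 0] == 0.0


class TestCarbonStock:
    def test_zero_table_zero_raster(self, toy_lulc):
        table = CarbonDensityTable(pools={k: (0, 0, 0, 0) for k in range(1, 7)})
        assert np.allclose(carbon_stock(toy_lulc, table).values, 0.0)

    def test_uniform_woodland_constant_sum_of_pools(self):
        lulc = _cat(np.full((8, 8), 2))
        out = carbon_stock(lulc, SYNTHETIC_CARBON_TABLE)
        expected = sum(SYNTHETIC_CARBON_TABLE.pools[2])
        assert np.allclose(out.values, expected)

    def test_mixed_toy_map_enumerated(self):
        lulc = _cat([[1, 1, 1, 2, 2], [2, 2, 1, 1, 2]])
        table = CarbonDensityTable(pools={1: (1, 2, 3, 4), 2: (10, 0, 5, 0)})
        total = carbon_stock(lulc, table).values.sum()
        assert total == pytest.approx(5 * 10 + 5 * 15)

    def test_missing_class_named_in_error(self, toy_lulc):
        table = CarbonDensityTable(pools={1: (1, 1, 1, 1)})
        with pytest.raises(KeyError, match="woodland"):
            carbon_stock(toy_lulc, table)

    def test_regional_total_invariant_under_relabeling(self, toy_lulc):
        rng = np.random.default_rng(1)
        perm = rng.permutation(toy_lulc.values.size)
        shuffled = toy_lulc.copy_with(
            toy_lulc.values.ravel()[perm].reshape(toy_lulc.shape)
        )
        a = carbon_stock(toy_lulc, SYNTHETIC_CARBON_TABLE).values.sum()
        b = carbon_stock(shuffled, SYNTHETIC_CARBON_TABLE).values.sum()
        assert a == pytest.approx(b)

    def test_climate_correction_multiplier(self):
        lulc = _cat(np.full((4, 4), 2))
        table = CarbonDensityTable(pools={2: (10, 10, 10, 10)},
                                   correction={2: 1.5})
        assert np.allclose(carbon_stock(lulc, table).values, 60.0)


def _single_threat_config(decay="linear", d_max=60.0):
    return HabitatConfig(
        suitability={k: 1.0 for k in range(1, 7)},
        threats=[
            Threat("built", (5,), weight=1.0, max_distance_m=d_max, decay=decay,
                   sensitivity={k: 1.0 for k in range(1, 7)})
        ],
        half_saturation=1.0,
    )


class TestThreatDegradation:
    def test_no_threat_cells_zero(self):
        lulc = _cat(np.full((6, 6), 2))
        d = threat_degradation(lulc, _single_threat_config())
        assert np.allclose(d.values, 0.0)

    def test_linear_kernel_endpoints(self):
        # one threat cell; linear decay with d_max = 2 cells (60 m at 30 m)
        vals = np.full((7, 7), 2)
        vals[3, 3] = 5
        lulc = _cat(vals)
        d = threat_degradation(lulc, _single_threat_config(d_max=60.0)).values
        assert d[3, 3] == pytest.approx(d.max())     # distance 0 maximal
        assert d[3, 5] == pytest.approx(d[3, 3] - 1.0)  # exactly d_max from source
        # cells beyond d_max receive nothing from the source
        assert d[3, 6] == pytest.approx(d[3, 3] - 1.0)

    @pytest.mark.parametrize("decay", ["linear", "exponential"])
    def test_matches_bruteforce_oracle(self, decay):
        rng = np.random.default_rng(4)
        vals = rng.integers(1, 7, size=(16, 16))
        lulc = _cat(vals)
        cfg = HabitatConfig(
            suitability={k: 1.0 for k in range(1, 7)},
            threats=[
                Threat("crop", (1,), weight=0.6, max_distance_m=150.0,
                       decay=decay, sensitivity={2: 0.8, 3: 0.5, 4: 1.0}),
                Threat("built", (5,), weight=1.0, max_distance_m=90.0,
                       decay=decay, sensitivity={2: 1.0, 3: 0.4}),
            ],
        )
        fast = threat_degradation(lulc, cfg).values
        slow = threat_degradation_bruteforce(lulc, cfg).values
        assert np.max(np.abs(fast - slow)) < 1e-9

    def test_five_by_five_single_threat_bruteforce(self):
        vals = np.full((5, 5), 3)
        vals[2, 2] = 5
        lulc = _cat(vals)
        cfg = _single_threat_config(d_max=90.0)
        fast = threat_degradation(lulc, cfg).values
        slow = threat_degradation_bruteforce(lulc, cfg).values
        assert np.max(np.abs(fast - slow)) < 1e-9

    def test_requires_a_threat(self, toy_lulc):
        cfg = HabitatConfig(suitability={k: 1.0 for k in range(1, 7)}, threats=[])
        with pytest.raises(ValueError, match="threat"):
            threat_degradation(toy_lulc, cfg)


class TestHabitatQuality:
    def test_no_degradation_returns_suitability(self):
        lulc = _cat(np.full((5, 5), 2))
        cfg = _single_threat_config()
        cfg.suitability = {k: 0.7 for k in range(1, 7)}
        q = habitat_quality(lulc, cfg)   # no class-5 cells -> D = 0
        assert np.allclose(q.values, 0.7)

    def test_half_saturation_definition(self):
        lulc = _cat(np.full((3, 3), 2))
        cfg = _single_threat_config()
        cfg.half_saturation = 2.0
        deg = lulc.copy_with(np.full((3, 3), 2.0), categorical=False, nodata=None)
        q = habitat_quality(lulc, cfg, degradation=deg)
        assert np.allclose(q.values, 0.5)   # Q = H/2 at D = k

    def test_strictly_decreasing_in_degradation(self):
        lulc = _cat(np.full((1, 50), 2))
        cfg = _single_threat_config()
        cfg.half_saturation = 1.0
        deg = lulc.copy_with(np.linspace(0, 5, 50)[None, :], categorical=False,
                             nodata=None)
        q = habitat_quality(lulc, cfg, degradation=deg).values.ravel()
        assert (np.diff(q) < 0).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_invalid_half_saturation(self):
        lulc = _cat(np.full((3, 3), 2))
        cfg = _single_threat_config()
        cfg.half_saturation = -1.0
        with pytest.raises(ValueError, match="half-saturation"):
            habitat_quality(lulc, cfg)


class TestSoilRetention:
    def _factors(self, lulc, R=100.0, K=0.3, LS=2.0, cover=None, practice=None):
        mk = lambda v: lulc.copy_with(np.full(lulc.shape, v), categorical=False,
                                      nodata=None)
        return RusleFactors(
            erosivity=mk(R), erodibility=mk(K), ls=mk(LS),
            cover=cover or {k: 0.5 for k in range(1, 7)},
            practice=practice or {k: 0.8 for k in range(1, 7)},
        )

    def test_direct_substitution(self):
        lulc = _cat(np.full((4, 4), 1))
        a = soil_retention(lulc, self._factors(lulc))
        assert np.allclose(a.values, 100 * 0.3 * 2 * (1 - 0.4))  # = 36

    def test_zero_cover_gives_rkls(self):
        lulc = _cat(np.full((4, 4), 1))
        f = self._factors(lulc, cover={k: 0.0 for k in range(1, 7)})
        assert np.allclose(soil_retention(lulc, f).values, 60.0)

    def test_bounded_by_rkls(self, toy_lulc):
        f = self._factors(toy_lulc)
        a = soil_retention(toy_lulc, f).values
        rkls = f.erosivity.values * f.erodibility.values * f.ls.values
        assert (a <= rkls + 1e-12).all()
        assert (a >= 0).all()

    def test_cp_above_one_rejected(self):
        lulc = _cat(np.full((2, 2), 1))
        f = self._factors(lulc, cover={k: 1.5 for k in range(1, 7)},
                          practice={k: 1.0 for k in range(1, 7)})
        with pytest.raises(ValueError, match="exceeds 1"):
            soil_retention(lulc, f)


class TestErosivityAndLS:
    def test_identity_coefficients(self):
        p = _grid([[0.0, 100.0, 500.0]])
        r = erosivity_from_precip(p, a=1.0, b=1.0)
        assert np.allclose(r.values, p.values)

    def test_monotone_in_precip(self):
        p = _grid(np.linspace(0, 2000, 50)[None, :])
        r = erosivity_from_precip(p).values.ravel()
        assert (np.diff(r) >= 0).all()

    def test_negative_precip_rejected(self):
        with pytest.raises(ValueError):
            erosivity_from_precip(_grid([[-5.0]]))

    def test_flat_dem_minimal_constant_ls(self):
        dem = _grid(np.full((12, 12), 1000.0))
        ls = ls_from_dem(dem).values
        assert np.allclose(ls, ls[0, 0])
        assert ls[0, 0] >= 0

    def test_ls_increases_with_slope(self):
        vals = []
        for grad in (0.02, 0.1, 0.3):
            cols = np.arange(16, dtype=float) * 30.0 * grad
            dem = _grid(np.tile(cols, (16, 1)))
            vals.append(ls_from_dem(dem).values[8, 8])
        assert vals[0] < vals[1] < vals[2]

    def test_deterministic(self):
        cfg = SyntheticConfig(shape=(32, 32), seed=5)
        dem, _ = generate_terrain(cfg)
        assert np.array_equal(ls_from_dem(dem).values, ls_from_dem(dem).values)
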