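"""Expansion mining, suitability recovery, CA allocation, map agreement."""

import numpy as np
import pytest

from luces.allocate import (
    CAState,
    SuitabilityStack,
    agreement,
    allocate,
    class_counts,
    extract_samples,
    fit_suitability,
    neighborhood_effect,
)
from luces.raster import N_CLASSES, RasterGrid


def _cat(vals, cell=30.0):
    return RasterGrid(np.asarray(vals, dtype=np.int16), cell_size_m=cell,
                      nodata=0, categorical=True)


def _drivers_like(grid, arrays):
    return {name: grid.copy_with(a, categorical=False, nodata=None)
            for name, a in arrays.items()}


class TestExtractSamples:
    def test_no_change_flags_all_static(self, toy_lulc):
        drv = _drivers_like(toy_lulc, {"d1": np.random.default_rng(0).random((10, 10))})
        s = extract_samples(toy_lulc, toy_lulc, drv)
        assert sorted(s.static_classes) == list(range(1, 7))
        assert not s.X

    def test_known_conversion_count_recovered(self):
        rng = np.random.default_rng(1)
        t0 = _cat(np.full((40, 40), 2))
        t1_vals = t0.values.copy()
        idx = rng.choice(1600, size=500, replace=False)
        t1_vals.ravel()[idx] = 5
        t1 = t0.copy_with(t1_vals)
        drv = _drivers_like(t0, {"d1": rng.random((40, 40))})
        s = extract_samples(t0, t1, drv, fraction=1.0)
        assert (s.y[5] == 1).sum() == 500
        assert (s.y[5] == 0).sum() == 500  # balanced negatives

    def test_deterministic_under_seed(self, landscape):
        t0, t1, drv = landscape["lulc_t0"], landscape["lulc_t1"], landscape["drivers"]
        a = extract_samples(t0, t1, drv, fraction=0.5, seed=3)
        b = extract_samples(t0, t1, drv, fraction=0.5, seed=3)
        for k in a.X:
            assert np.array_equal(a.X[k], b.X[k])
            assert np.array_equal(a.y[k], b.y[k])

    def test_bad_fraction_rejected(self, toy_lulc):
        with pytest.raises(ValueError, match="fraction"):
            extract_samples(toy_lulc, toy_lulc, {}, fraction=0.0)


class TestFitSuitability:
    def _separable_fixture(self, n=60, seed=0):
        """Growth of class 5 is exactly indicator(driver1 > 0.5)."""
        rng = np.random.default_rng(seed)
        d1 = rng.random((n, n))
        d2 = rng.random((n, n))
        t0 = _cat(np.full((n, n), 2))
        t1_vals = np.where(d1 > 0.5, 5, 2).astype(np.int16)
        t1 = t0.copy_with(t1_vals)
        drv = _drivers_like(t0, {"d1": d1, "d2": d2})
        return t0, t1, drv

    def test_separable_case_high_auc(self):
        from sklearn.metrics import roc_auc_score

        t0, t1, drv = self._separable_fixture()
        s = extract_samples(t0, t1, drv, fraction=0.6, seed=1)
        stack = fit_suitability(s, drv, seed=1)
        # held-out: score every cell, label = truth
        y_true = (t1.values == 5).ravel()
        y_score = stack.probabilities[4].ravel()
        assert roc_auc_score(y_true, y_score) >= 0.99

    def test_generating_driver_ranks_first(self):
        t0, t1, drv = self._separable_fixture()
        s = extract_samples(t0, t1, drv, fraction=1.0, seed=2)
        stack = fit_suitability(s, drv, seed=2)
        imp = stack.importances[5]
        assert np.argmax(imp) == 0  # d1 drives the growth

    def test_all_static_landscape_zero_stack(self, toy_lulc):
        drv = _drivers_like(toy_lulc, {"d1": np.zeros((10, 10))})
        s = extract_samples(toy_lulc, toy_lulc, drv)
        stack = fit_suitability(s, drv)
        assert np.allclose(stack.probabilities, 0.0)
        assert sorted(stack.static_classes) == list(range(1, 7))


class TestNeighborhood:
    def test_uniform_map_interior_is_one(self):
        state = CAState(lulc=_cat(np.full((9, 9), 3)),
                        demand=np.array([0, 0, 81, 0, 0, 0]))
        eff = neighborhood_effect(state, 3)
        assert np.allclose(eff.values[1:-1, 1:-1], 1.0)
        # corners: 3 of 3 neighbours are class 3 -> still 1 (edge-normalised)
        assert eff.values[0, 0] == pytest.approx(1.0)

    def test_single_cell_gives_one_eighth_to_neighbours(self):
        vals = np.full((5, 5), 2)
        vals[2, 2] = 5
        state = CAState(lulc=_cat(vals), demand=np.array([0, 24, 0, 0, 1, 0]))
        eff = neighborhood_effect(state, 5)
        assert eff.values[1, 1] == pytest.approx(1 / 8)
        assert eff.values[2, 2] == pytest.approx(0.0)
        assert eff.values[0, 0] == pytest.approx(0.0)

    def test_empty_class_zero_raster(self, toy_lulc):
        vals = np.where(toy_lulc.values == 6, 1, toy_lulc.values)
        state = CAState(lulc=toy_lulc.copy_with(vals),
                        demand=np.full(6, 100 / 6))
        assert np.allclose(neighborhood_effect(state, 6).values, 0.0)

    def test_window_validation(self, toy_lulc):
        with pytest.raises(ValueError, match="window"):
            CAState(lulc=toy_lulc, demand=np.full(6, 100 / 6), window=4)


def _uniform_stack(shape, value=0.8):
    return SuitabilityStack(
        probabilities=np.full((N_CLASSES,) + shape, value),
        importances={},
        driver_names=[],
    )


class TestAllocate:
    def test_demand_equal_to_current_is_identity(self, toy_lulc):
        demand = class_counts(toy_lulc)
        state = CAState(lulc=toy_lulc, demand=demand, seed=0)
        out = allocate(state, _uniform_stack(toy_lulc.shape))
        assert np.array_equal(out.values, toy_lulc.values)
        assert out.converged

    def test_demand_sum_mismatch_rejected(self, toy_lulc):
        with pytest.raises(ValueError, match="sum"):
            allocate(
                CAState(lulc=toy_lulc, demand=np.full(6, 1.0), seed=0),
                _uniform_stack(toy_lulc.shape),
            )

    def test_growth_lands_in_high_suitability_region(self):
        n = 50
        t = _cat(np.full((n, n), 3))
        demand = class_counts(t).astype(float)
        demand[2] -= 100
        demand[4] += 100
        probs = np.zeros((N_CLASSES, n, n))
        probs[4, :, :] = 0.02
        probs[4, 10:25, 10:25] = 0.95   # one high-suitability block
        stack = SuitabilityStack(probabilities=probs, importances={}, driver_names=[])
        out = allocate(CAState(lulc=t, demand=demand, seed=4), stack)
        new5 = (out.values == 5)
        assert new5.sum() == 100
        assert new5[10:25, 10:25].sum() >= 90

    def test_determinism_and_count_conservation(self, landscape):
        t1 = landscape["lulc_t1"]
        demand = class_counts(t1).astype(float)
        demand[[0, 1]] += (-60, 60)
        stack = _uniform_stack(t1.shape, 0.6)
        out_a = allocate(CAState(lulc=t1, demand=demand, seed=7), stack)
        out_b = allocate(CAState(lulc=t1, demand=demand, seed=7), stack)
        assert np.array_equal(out_a.values, out_b.values)
        assert class_counts(out_a).sum() == class_counts(t1).sum()
        assert np.all(np.abs(class_counts(out_a) - demand) <= 1)

    def test_monotone_response_to_demand(self, landscape):
        t1 = landscape["lulc_t1"]
        base = class_counts(t1).astype(float)
        stack = _uniform_stack(t1.shape, 0.6)
        finals = []
        for extra in (50, 150):
            demand = base.copy()
            demand[4] += extra
            demand[1] -= extra
            out = allocate(CAState(lulc=t1, demand=demand, seed=9), stack)
            finals.append(class_counts(out)[4])
        assert finals[1] >= finals[0]


class TestAgreement:
    def test_identical_maps_perfect(self, toy_lulc):
        acc, kappa = agreement(toy_lulc, toy_lulc)
        assert acc == 1.0 and kappa == 1.0

    def test_two_class_confusion_hand_computed(self):
        # confusion [[40,10],[10,40]] -> accuracy 0.8, kappa 0.6
        truth = np.concatenate([np.ones(50), np.full(50, 2)])
        pred = truth.copy()
        pred[:10] = 2
        pred[50:60] = 1
        g_true = _cat(truth.reshape(10, 10))
        g_pred = _cat(pred.reshape(10, 10))
        acc, kappa = agreement(g_pred, g_true)
        assert acc == pytest.approx(0.8)
        assert kappa == pytest.approx(0.6)

    def test_matches_sklearn_on_random_maps(self):
        from sklearn.metrics import accuracy_score, cohen_kappa_score

        rng = np.random.default_rng(2)
        a = rng.integers(1, 7, size=(60, 60))
        b = rng.integers(1, 7, size=(60, 60))
        acc, kappa = agreement(_cat(a), _cat(b))
        assert acc == pytest.approx(accuracy_score(b.ravel(), a.ravel()))
        assert kappa == pytest.approx(cohen_kappa_score(b.ravel(), a.ravel()))

    def test_independent_random_maps_kappa_near_zero(self):
        rng = np.random.default_rng(3)
        shape = (400, 250)  # 1e5 cells
        a = rng.integers(1, 7, size=shape)
        b = rng.integers(1, 7, size=shape)
        _, kappa = agreement(_cat(a), _cat(b))
        assert abs(kappa) < 0.02

    def test_empty_overlap_errors(self):
        a = _cat([[0, 0], [0, 0]])
        b = _cat([[1, 1], [1, 1]])
        with pytest.raises(ValueError, match="overlap"):
            agreement(a, b)
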