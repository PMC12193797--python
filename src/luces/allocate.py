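"""Spatial allocation of land-use demand: expansion mining, suitability
modelling, and a patch-seeding cellular automaton.

The procedure has two stages.  *Expansion analysis* turns the observed
change between two dated maps into one binary classification problem per
class — cells that newly became class k against cells that did not — and
fits a random-forest classifier on driver surfaces, yielding a growth
suitability probability raster per class plus driver importances.
*Allocation* then iteratively converts cells until per-class counts meet
demand: each candidate conversion is drawn by roulette over
suitability × neighbourhood density × an adaptive inertia coefficient,
with random patch seeds letting a class colonise cells that have no
same-class neighbours yet (seed threshold τ decays geometrically), and an
allowed-transition matrix vetoing impossible conversions.

Agreement between a simulated and an observed map is summarised by
overall accuracy and Cohen's kappa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .raster import CLASS_CODES, N_CLASSES, RasterGrid, require_aligned

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LEAS: expansion sampling + suitability
# ---------------------------------------------------------------------------

@dataclass
class ExpansionSamples:
    """Per-class binary training sets over driver space."""

    X: dict[int, np.ndarray]          # class -> (n, p) driver matrix
    y: dict[int, np.ndarray]          # class -> binary labels
    static_classes: list[int]
    driver_names: list[str]
    fraction: float
    seed: int


@dataclass
class SuitabilityStack:
    """Growth-probability raster per class plus driver importances."""

    probabilities: np.ndarray          # (6, rows, cols), each in [0, 1]
    importances: dict[int, np.ndarray]
    driver_names: list[str]
    static_classes: list[int] = field(default_factory=list)


def extract_samples(
    lulc_t0: RasterGrid,
    lulc_t1: RasterGrid,
    drivers: dict[str, RasterGrid],
    fraction: float = 1.0,
    seed: int = 0,
) -> ExpansionSamples:
    """Mine expansion cells per class and draw balanced negatives.

    Positives for class k are cells with ``t0 != k`` and ``t1 == k``; an
    equal-sized negative sample is drawn (without replacement) from cells
    that did not become k.  ``fraction`` subsamples the positives first.
    Classes with no expansion cells are flagged static.
    """
    require_aligned(lulc_t0, lulc_t1, *drivers.values())
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mask = lulc_t0.mask() & lulc_t1.mask()
    a = lulc_t0.values[mask]
    b = lulc_t1.values[mask]
    D = np.column_stack([d.values[mask] for d in drivers.values()])

    X, y, static = {}, {}, []
    for k in range(1, N_CLASSES + 1):
        pos = np.flatnonzero((a != k) & (b == k))
        if pos.size == 0:
            static.append(k)
            continue
        if fraction < 1.0:
            n_keep = max(1, int(round(fraction * pos.size)))
            pos = rng.choice(pos, size=n_keep, replace=False)
        neg_pool = np.flatnonzero(b != k)
        n_neg = min(pos.size, neg_pool.size)
        neg = rng.choice(neg_pool, size=n_neg, replace=False)
        idx = np.concatenate([pos, neg])
        X[k] = D[idx]
        y[k] = np.concatenate([np.ones(pos.size), np.zeros(n_neg)]).astype(int)
    return ExpansionSamples(
        X=X,
        y=y,
        static_classes=static,
        driver_names=list(drivers),
        fraction=fraction,
        seed=seed,
    )


def fit_suitability(
    samples: ExpansionSamples,
    drivers: dict[str, RasterGrid],
    n_estimators: int = 100,
    max_depth: int | None = None,
    seed: int = 0,
) -> SuitabilityStack:
    """Per-class growth-probability surfaces from random forests.

    Static classes receive a zero surface; a degenerate single-label
    sample yields a constant surface with a warning.
    """
    from sklearn.ensemble import RandomForestClassifier

    ref = next(iter(drivers.values()))
    shape = ref.shape
    D = np.column_stack([d.values.ravel() for d in drivers.values()])
    probs = np.zeros((N_CLASSES,) + shape)
    importances: dict[int, np.ndarray] = {}
    for k, Xk in samples.X.items():
        yk = samples.y[k]
        if len(np.unique(yk)) < 2:
            warnings.warn(f"class {k}: single-label sample; constant surface")
            probs[k - 1] = float(yk[0])
            importances[k] = np.full(D.shape[1], np.nan)
            continue
        rf = RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth, random_state=seed, n_jobs=1
        )
        rf.fit(Xk, yk)
        p = rf.predict_proba(D)[:, list(rf.classes_).index(1)]
        probs[k - 1] = p.reshape(shape)
        importances[k] = rf.feature_importances_
    return SuitabilityStack(
        probabilities=probs,
        importances=importances,
        driver_names=samples.driver_names,
        static_classes=list(samples.static_classes),
    )


# ---------------------------------------------------------------------------
# CARS: patch-seeding cellular automaton
# ---------------------------------------------------------------------------

def default_transition_matrix() -> np.ndarray:
    """All conversions allowed except water -> unused; diagonal True."""
    m = np.ones((N_CLASSES, N_CLASSES), dtype=bool)
    m[3, 5] = False
    return m


@dataclass
class CAState:
    """Mutable cellular-automaton state for one allocation run."""

    lulc: RasterGrid
    demand: np.ndarray                   # per-class target cell counts
    inertia: np.ndarray = None
    seed_threshold: float = 0.5          # τ: min suitability for a patch seed
    decay: float = 0.9                   # δ: τ <- τ·δ per iteration
    window: int = 3
    allowed: np.ndarray = None
    tolerance_frac: float = 0.001        # per-class demand tolerance
    max_iter: int = 200
    rate: float = 0.25                   # fraction of remaining gap moved/iter
    seed: int = 0

    def __post_init__(self) -> None:
        self.demand = np.asarray(self.demand, dtype=float)
        if self.demand.shape != (N_CLASSES,):
            raise ValueError("demand must have 6 entries")
        if (self.demand < 0).any():
            raise ValueError("demand targets must be non-negative")
        if not 0 < self.seed_threshold <= 1:
            raise ValueError("seed threshold must be in (0, 1]")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.inertia is None:
            self.inertia = np.ones(N_CLASSES)
        if self.allowed is None:
            self.allowed = default_transition_matrix()
        if not np.all(np.diag(self.allowed)):
            raise ValueError("allowed-transition diagonal must be True")


def _neigh_frac(values: np.ndarray, k: int, window: int) -> np.ndarray:
    ind = (values == k).astype(float)
    s = uniform_filter(ind, size=window, mode="constant") * window * window
    c = uniform_filter(np.ones_like(ind), size=window, mode="constant") * window**2
    return np.clip((s - ind) / np.maximum(c - 1.0, 1.0), 0.0, 1.0)


def neighborhood_effect(state: CAState, k: int) -> RasterGrid:
    """Fraction of class-k cells in the Moore window, centre excluded,
    normalised by the realised window size at borders."""
    frac = _neigh_frac(state.lulc.values, k, state.window)
    return state.lulc.copy_with(frac, categorical=False, nodata=None)


def class_counts(lulc: RasterGrid) -> np.ndarray:
    m = lulc.mask()
    return np.bincount(lulc.values[m].astype(np.int64), minlength=N_CLASSES + 1)[1:]


def allocate(state: CAState, suitability: SuitabilityStack) -> RasterGrid:
    """Run the CA until per-class counts meet demand (within tolerance).

    Each iteration converts a capped batch of cells: receivers are classes
    below demand; donors are surplus-class cells whose conversion is
    allowed.  Candidate cells are drawn by weighted sampling without
    replacement (Gumbel top-k) with weight suitability × neighbourhood ×
    inertia, where cells with no class-k neighbours participate only as
    random patch seeds (suitability > τ).  Inertia coefficients adapt from
    the trend of each class's demand gap.  Returns the final map; a
    ``converged`` flag is attached as ``result.converged``.
    """
    lulc = state.lulc
    mask = lulc.mask()
    n_valid = int(mask.sum())
    if not np.isclose(state.demand.sum(), n_valid):
        raise ValueError(
            f"demand targets ({state.demand.sum():.0f}) must sum to the "
            f"number of valid cells ({n_valid})"
        )
    current = lulc.values.copy()
    counts = class_counts(lulc).astype(float)
    tol = np.maximum(1.0, state.tolerance_frac * np.maximum(state.demand, 1.0))
    rng = np.random.default_rng(state.seed)
    inertia = state.inertia.copy().astype(float)
    tau = state.seed_threshold
    prev_gap = None
    converged = False

    for it in range(state.max_iter):
        gap = state.demand - counts
        if np.all(np.abs(gap) <= tol):
            converged = True
            break
        # adaptive inertia: when a class's |gap| fails to shrink, scale its
        # coefficient by the successive gap ratio (boost deficits, damp surpluses)
        if prev_gap is not None:
            for k in range(N_CLASSES):
                g1, g0 = abs(gap[k]), abs(prev_gap[k])
                if g1 > tol[k] and g1 >= g0 > 0:
                    ratio = g1 / g0
                    inertia[k] *= ratio if gap[k] > 0 else 1.0 / ratio
            inertia = np.clip(inertia, 1e-3, 1e3)
        prev_gap = gap.copy()

        deficits = [k for k in range(N_CLASSES) if gap[k] >= 1]
        surplus = np.maximum(-gap, 0.0)
        donor_ok = np.isin(current, [k + 1 for k in range(N_CLASSES) if surplus[k] > 0])
        donor_ok &= mask
        for k in rng.permutation(deficits):
            want = int(min(np.ceil(gap[k] * state.rate) + 1, gap[k]))
            if want <= 0:
                continue
            suit = suitability.probabilities[k]
            if suit.max() <= 0:
                # static class (no observed expansion): neighbourhood-driven
                # growth from its current footprint
                suit = np.full(current.shape, 0.5)
            neigh = _neigh_frac(current, k + 1, state.window)
            # seeds: no same-class neighbour, but suitability above τ
            seed_draw = rng.random(current.shape) < 0.1
            seed_term = np.where((neigh == 0) & (suit > tau) & seed_draw, suit, 0.0)
            weight = suit * np.maximum(neigh, seed_term) * inertia[k]
            allowed_src = state.allowed[:, k][
                np.clip(current, 1, N_CLASSES) - 1
            ]
            eligible = donor_ok & (current != k + 1) & allowed_src & (weight > 0)
            if not eligible.any():
                # demand is a hard top-down target: when no weighted candidate
                # remains (zero suitability everywhere eligible), fall back to
                # an unweighted draw over convertible donor cells
                eligible = donor_ok & (current != k + 1) & allowed_src
                weight = np.where(eligible, 1e-9, 0.0)
            n_el = int(eligible.sum())
            if n_el == 0:
                continue
            w = weight[eligible]
            # Gumbel top-k == weighted sampling without replacement
            keys = np.log(w) + rng.gumbel(size=w.size)
            take = min(want, n_el)
            order = np.argsort(-keys)
            el_idx = np.flatnonzero(eligible.ravel())
            flat = current.ravel()
            moved = 0
            for j in order:
                if moved >= take:
                    break
                cell = el_idx[j]
                src = flat[cell] - 1
                if surplus[src] < 1:
                    continue
                flat[cell] = k + 1
                surplus[src] -= 1
                counts[src] -= 1
                counts[k] += 1
                moved += 1
            current = flat.reshape(current.shape)
            donor_ok = np.isin(
                current, [c + 1 for c in range(N_CLASSES) if surplus[c] > 0]
            ) & mask
        tau *= state.decay

    if not converged:
        gap = state.demand - counts
        if np.all(np.abs(gap) <= tol):
            converged = True
        else:
            warnings.warn(
                "allocation did not converge: residual gaps "
                f"{dict(zip(CLASS_CODES.values(), gap.astype(int)))}"
            )
    out = lulc.copy_with(current)
    out.converged = converged
    return out


# ---------------------------------------------------------------------------
# Map agreement
# ---------------------------------------------------------------------------

def confusion_matrix(map_pred: RasterGrid, map_true: RasterGrid) -> np.ndarray:
    require_aligned(map_pred, map_true)
    m = map_pred.mask() & map_true.mask()
    if not m.any():
        raise ValueError("no overlapping valid cells")
    a = map_true.values[m].astype(np.int64) - 1
    b = map_pred.values[m].astype(np.int64) - 1
    return np.bincount(a * N_CLASSES + b, minlength=N_CLASSES**2).reshape(
        N_CLASSES, N_CLASSES
    )


def agreement(map_pred: RasterGrid, map_true: RasterGrid) -> tuple[float, float]:
    """Overall accuracy and Cohen's kappa from the 6x6 confusion matrix."""
    cm = confusion_matrix(map_pred, map_true)
    n = cm.sum()
    po = np.trace(cm) / n
    pe = (cm.sum(axis=0) / n) @ (cm.sum(axis=1) / n)
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return float(po), float(kappa)
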