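"""Pairwise ecosystem-service trade-offs and synergies.

Temporal association is summarised by the Spearman rank correlation
(positive ρ = synergy, negative ρ = trade-off).  Spatial association is
mapped with geographically weighted regression (GWR): at every sample
location a weighted least-squares fit with a spatial kernel yields local
slope surfaces, whose sign and magnitude classify each location into
strong/weak synergy or trade-off.

GWR here is the standard local-linear estimator
``Y_i = β0(U_i, V_i) + Σ_k β_k(U_i, V_i) X_ik + ε_i`` with adaptive
bisquare (default), fixed Gaussian, or uniform kernels, and automatic
bandwidth selection by minimising the corrected AIC with a
golden-section search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .raster import RasterGrid, require_aligned

ES_NAMES = ("WY", "CS", "HQ", "SR")
ES_PAIRS = tuple(
    (ES_NAMES[i], ES_NAMES[j])
    for i in range(len(ES_NAMES))
    for j in range(i + 1, len(ES_NAMES))
)

CATEGORY_CODES = {
    1: "strong_tradeoff",
    2: "weak_tradeoff",
    3: "weak_synergy",
    4: "strong_synergy",
}


# ---------------------------------------------------------------------------
# Grid aggregation
# ---------------------------------------------------------------------------

def aggregate_grid(
    stack: dict[str, RasterGrid], unit_size_m: float, min_valid_frac: float = 0.5
) -> pd.DataFrame:
    """Mean service values over square sample units.

    Units with fewer than ``min_valid_frac`` of a full unit's cells valid
    are dropped.  Returns a table with one row per retained unit, the
    service columns, and unit-centroid coordinates ``U``/``V`` (metres).
    """
    rasters = list(stack.values())
    require_aligned(*rasters)
    ref = rasters[0]
    cs = ref.cell_size_m
    block = unit_size_m / cs
    if abs(block - round(block)) > 1e-9 or block < 1:
        raise ValueError("unit_size_m must be a positive multiple of the cell size")
    block = int(round(block))
    rows, cols = ref.shape
    mask = np.ones(ref.shape, dtype=bool)
    for g in rasters:
        mask &= g.mask()

    records = []
    x0, y0 = ref.origin
    for r0 in range(0, rows, block):
        for c0 in range(0, cols, block):
            sl = (slice(r0, min(r0 + block, rows)), slice(c0, min(c0 + block, cols)))
            m = mask[sl]
            if m.sum() < min_valid_frac * block * block:
                continue
            rec = {
                name: float(g.values[sl][m].mean()) for name, g in stack.items()
            }
            rec["U"] = x0 + (c0 + min(block, cols - c0) / 2.0) * cs
            rec["V"] = y0 - (r0 + min(block, rows - r0) / 2.0) * cs
            rec["row"] = r0 // block
            rec["col"] = c0 // block
            records.append(rec)
    if not records:
        raise ValueError("no sample units with enough valid cells")
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p_values: pd.DataFrame
    classification: pd.DataFrame        # 'synergy' / 'tradeoff' / 'undefined'
    n: int


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman ρ as the Pearson correlation of average ranks (ties averaged)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_matrix(table: pd.DataFrame, columns=ES_NAMES) -> CorrelationMatrix:
    """Pairwise Spearman ρ, two-sided t-approximation p-values, and the
    sign-based synergy/trade-off classification."""
    columns = [c for c in columns if c in table.columns]
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 rows for rank correlation")
    k = len(columns)
    rho = np.eye(k)
    pv = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = spearman_rho(table[columns[i]].to_numpy(), table[columns[j]].to_numpy())
            rho[i, j] = rho[j, i] = r
            if np.isnan(r) or abs(r) >= 1.0:
                pv[i, j] = pv[j, i] = np.nan if np.isnan(r) else 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                pv[i, j] = pv[j, i] = 2.0 * stats.t.sf(abs(t), df=n - 2)
    cls = np.where(
        np.isnan(rho), "undefined", np.where(rho > 0, "synergy", np.where(rho < 0, "tradeoff", "none"))
    )
    idx = list(columns)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p_values=pd.DataFrame(pv, index=idx, columns=idx),
        classification=pd.DataFrame(cls, index=idx, columns=idx),
        n=n,
    )


# ---------------------------------------------------------------------------
# Geographically weighted regression
# ---------------------------------------------------------------------------

@dataclass
class GWRResult:
    params: np.ndarray                  # (n, p+1): intercept + slopes
    fitted: np.ndarray
    residuals: np.ndarray
    bandwidth: float
    kernel: str
    adaptive: bool
    aicc: float
    trace_S: float
    r2: float
    valid: np.ndarray                   # per-sample fit flag
    coords: np.ndarray = None

    @property
    def slopes(self) -> np.ndarray:
        return self.params[:, 1:]


def _kernel_weights(d: np.ndarray, kernel: str, h: float) -> np.ndarray:
    if kernel == "gaussian":
        if np.isinf(h):
            return np.ones_like(d)
        return np.exp(-0.5 * (d / h) ** 2)
    if kernel == "bisquare":
        w = np.zeros_like(d)
        inside = d < h
        w[inside] = (1.0 - (d[inside] / h) ** 2) ** 2
        return w
    if kernel == "uniform":
        return (d <= h).astype(float)
    raise ValueError(f"unknown kernel {kernel!r}")


def _gwr_pass(y, X, D, kernel, adaptive, bw):
    """One full GWR sweep; returns params, fitted, leverage, valid flags."""
    n, p = X.shape
    params = np.full((n, p), np.nan)
    fitted = np.full(n, np.nan)
    lev = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        d = D[i]
        if adaptive:
            k = int(round(bw))
            h = np.partition(d, min(k, n - 1))[min(k, n - 1)]
            h = max(h, 1e-12)
        else:
            h = bw
        w = _kernel_weights(d, kernel, h)
        if w.sum() <= 0:
            continue
        Xw = X * w[:, None]
        xtx = X.T @ Xw
        try:
            beta = np.linalg.solve(xtx, Xw.T @ y)
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            continue
        params[i] = beta
        fitted[i] = X[i] @ beta
        lev[i] = w[i] * X[i] @ xtx_inv @ X[i]
        valid[i] = True
    return params, fitted, lev, valid


def _aicc(y, fitted, lev, valid) -> float:
    n = int(valid.sum())
    if n < 3:
        return np.inf
    rss = float(((y[valid] - fitted[valid]) ** 2).sum())
    tr = float(lev[valid].sum())
    if n - 2 - tr <= 0 or rss <= 0:
        return np.inf
    sigma2 = rss / n
    return n * np.log(sigma2) + n * np.log(2 * np.pi) + n * (n + tr) / (n - 2 - tr)


def _golden_section(f, lo, hi, tol=1e-2, max_iter=60):
    gr = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if abs(b - a) < tol * max(abs(b), 1.0):
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(d)
    return (a + b) / 2


def gwr_fit(
    y: np.ndarray,
    x: np.ndarray,
    coords: np.ndarray,
    kernel: str = "bisquare",
    bandwidth: float | str = "auto",
    adaptive: bool | None = None,
) -> GWRResult:
    """Fit a GWR model and return local coefficient surfaces.

    ``x`` may be 1-D (single regressor) or (n, k); an intercept is always
    added.  ``bandwidth='auto'`` selects the bandwidth minimising the
    corrected AIC by golden-section search — over neighbour counts for
    adaptive kernels, over distance for fixed kernels.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n < k + 2:
        raise ValueError("need at least p+2 samples")
    for j in range(k):
        if np.ptp(x[:, j]) == 0:
            raise ValueError(f"regressor {j} is constant; slope undefined")
    if adaptive is None:
        adaptive = kernel == "bisquare"
    coords = np.asarray(coords, dtype=float)
    D = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    )
    X = np.column_stack([np.ones(n), x])
    p = X.shape[1]

    if bandwidth == "auto":
        if adaptive:
            lo, hi = p + 2, n - 1
        else:
            pos = D[D > 0]
            lo, hi = float(pos.min()), float(D.max()) * 2.0

        def objective(bw):
            _, fit, lev, valid = _gwr_pass(y, X, D, kernel, adaptive, bw)
            return _aicc(y, fit, lev, valid)

        bw = _golden_section(objective, lo, hi)
        if adaptive:
            bw = int(round(bw))
    else:
        bw = float(bandwidth)
    if (not np.isinf(bw)) and bw <= 0:
        raise ValueError("bandwidth must be positive")

    params, fitted, lev, valid = _gwr_pass(y, X, D, kernel, adaptive, bw)
    if not valid.any():
        raise ValueError("no local fit succeeded")
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} local fits were singular; flagged")
    resid = y - fitted
    tss = float(((y[valid] - y[valid].mean()) ** 2).sum())
    rss = float((resid[valid] ** 2).sum())
    return GWRResult(
        params=params,
        fitted=fitted,
        residuals=resid,
        bandwidth=float(bw),
        kernel=kernel,
        adaptive=bool(adaptive),
        aicc=_aicc(y, fitted, lev, valid),
        trace_S=float(lev[valid].sum()),
        r2=1.0 - rss / tss if tss > 0 else np.nan,
        valid=valid,
        coords=coords,
    )


def classify_relationship(
    gwr: GWRResult, slope_index: int = 0, threshold: float | None = None
) -> np.ndarray:
    """Classify each sample by its local slope into four categories:
    1 strong trade-off, 2 weak trade-off, 3 weak synergy, 4 strong synergy
    (strong/weak split at the median absolute slope by default).  Samples
    whose local fit failed get 0."""
    slopes = gwr.slopes[:, slope_index]
    ok = gwr.valid & ~np.isnan(slopes)
    if not ok.any():
        raise ValueError("all local slopes missing")
    if threshold is None:
        threshold = float(np.median(np.abs(slopes[ok])))
    out = np.zeros(len(slopes), dtype=np.int8)
    strong = np.abs(slopes) > threshold
    out[ok & (slopes < 0) & strong] = 1
    out[ok & (slopes < 0) & ~strong] = 2
    out[ok & (slopes >= 0) & ~strong] = 3
    out[ok & (slopes >= 0) & strong] = 4
    return out


def classification_raster(
    table: pd.DataFrame, codes: np.ndarray, shape: tuple[int, int],
    unit_size_m: float, cell_size_m: float,
) -> RasterGrid:
    """Paint unit classification codes back onto a (unit-resolution) grid."""
    block = int(round(unit_size_m / cell_size_m))
    rows = int(np.ceil(shape[0] / block))
    cols = int(np.ceil(shape[1] / block))
    vals = np.zeros((rows, cols), dtype=np.int8)
    for (r, c), code in zip(table[["row", "col"]].to_numpy(), codes):
        vals[int(r), int(c)] = code
    return RasterGrid(vals, cell_size_m=unit_size_m, nodata=0)


def pairwise_gwr(
    table: pd.DataFrame,
    pairs=ES_PAIRS,
    kernel: str = "bisquare",
    bandwidth="auto",
    response_second: bool = True,
) -> dict[tuple[str, str], GWRResult]:
    """GWR for each service pair; by convention the second-named service
    is the response (configurable via ``response_second``)."""
    coords = table[["U", "V"]].to_numpy()
    out = {}
    for a, b in pairs:
        xcol, ycol = (a, b) if response_second else (b, a)
        out[(a, b)] = gwr_fit(
            table[ycol].to_numpy(), table[xcol].to_numpy(), coords,
            kernel=kernel, bandwidth=bandwidth,
        )
    return out
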