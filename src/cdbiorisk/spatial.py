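"""Variogram fitting, ordinary kriging and regional aggregation.

Ordinary kriging is the best linear unbiased interpolator under a
second-order stationary model: weights solve the semivariance system
with the unbiasedness constraint (weights sum to one). The empirical
semivariance uses the Matheron estimator,
gamma(h) = 1/2 mean[(z_i - z_j)^2] over point pairs in each lag bin,
and is fitted by weighted least squares (pair counts as weights) with a
spherical, exponential or gaussian family. Coordinates are planar
Cartesian; no geodesic correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist

from .grid import GridField

__all__ = [
    "Variogram",
    "fit_variogram",
    "empirical_variogram",
    "ordinary_kriging",
    "krige_grid",
    "regional_geometric_mean",
    "map_national_bioaccessibility",
]

_FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class Variogram:
    """gamma(h) = nugget + partial_sill * g(h / range), with g the chosen
    family's unit curve (effective-range convention for exponential and
    gaussian: g approaches 1 at h = range). gamma(0) = 0 exactly at zero
    lag; the curve limit as h -> 0+ is the nugget."""

    model: str = "spherical"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in _FAMILIES:
            raise ValueError(f"unknown variogram family {self.model!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("nugget/sill must be >= 0 and range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = h / self.range_
        if self.model == "spherical":
            g = np.where(r < 1.0, 1.5 * r - 0.5 * r ** 3, 1.0)
        elif self.model == "exponential":
            g = 1.0 - np.exp(-3.0 * r)
        else:
            g = 1.0 - np.exp(-3.0 * r ** 2)
        out = self.nugget + self.partial_sill * g
        return np.where(h == 0.0, 0.0, out)


def empirical_variogram(points, values, n_lags: int = 12,
                        max_lag: float | None = None) -> pd.DataFrame:
    """Matheron semivariance by equal-width lag bins."""
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    d = pdist(pts)
    if max_lag is None:
        max_lag = float(d.max())
    sq = pdist(z[:, None], metric="sqeuclidean") / 2.0
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    idx = np.clip(np.digitize(d, edges[1:-1]), 0, n_lags - 1)
    keep = d <= max_lag
    rows = []
    for b in range(n_lags):
        sel = keep & (idx == b)
        if not sel.any():
            continue
        rows.append({"lag": float(d[sel].mean()),
                     "gamma": float(sq[sel].mean()),
                     "n_pairs": int(sel.sum())})
    return pd.DataFrame(rows)


def fit_variogram(points, values, n_lags: int = 12,
                  model: str = "spherical",
                  max_lag: float | None = None) -> Variogram:
    """Weighted-least-squares variogram fit (pair counts as weights)."""
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 points to fit a variogram")
    emp = empirical_variogram(pts, z, n_lags, max_lag)
    span = float(pdist(pts).max())
    if np.ptp(z) == 0.0 or emp["gamma"].max() == 0.0:
        warnings.warn("constant field: degenerate variogram", stacklevel=2)
        return Variogram(model, 0.0, 0.0, span)

    lags = emp["lag"].to_numpy()
    gam = emp["gamma"].to_numpy()
    w = np.sqrt(emp["n_pairs"].to_numpy(dtype=float))
    var = float(np.var(z))

    def resid(theta):
        v = Variogram(model, theta[0], theta[1], theta[2])
        return w * (v(lags) - gam)

    sol = least_squares(
        resid, x0=[0.0, var, span / 2.0],
        bounds=([0.0, 0.0, 1e-9 * span], [np.inf, np.inf, 4.0 * span]))
    nugget, psill, rng_ = sol.x
    return Variogram(model, float(nugget), float(psill), float(rng_))


def _dedupe(points: np.ndarray, values: np.ndarray):
    uniq, inv = np.unique(points, axis=0, return_inverse=True)
    if len(uniq) == len(points):
        return points, values
    warnings.warn("duplicate point locations: values averaged before kriging",
                  stacklevel=3)
    agg = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(agg, inv, values)
    np.add.at(counts, inv, 1.0)
    return uniq, agg / counts


def ordinary_kriging(points, values, variogram: Variogram, targets,
                     max_neighbors: int | None = None,
                     return_variance: bool = False):
    """Ordinary-kriging predictions at target coordinates.

    Solves [[Gamma, 1], [1^T, 0]] [lambda; mu] = [gamma_0; 1] per target.
    Exact at data locations when the nugget is zero. Duplicate data
    points are averaged (with a warning). With ``max_neighbors`` the
    system is restricted to the nearest data points per target.
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    tg = np.asarray(targets, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 data points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < pts.shape[1]:
        raise ValueError("data points are collinear")
    pts, z = _dedupe(pts, z)
    n = len(pts)

    if max_neighbors is not None and max_neighbors < n:
        from scipy.spatial import cKDTree
        tree = cKDTree(pts)
        _, nbr = tree.query(tg, k=max_neighbors)
        pred = np.empty(len(tg))
        kvar = np.empty(len(tg))
        for t in range(len(tg)):
            idx = np.atleast_1d(nbr[t])
            p, v = _solve_ok(pts[idx], z[idx], variogram, tg[t:t + 1])
            pred[t], kvar[t] = p[0], v[0]
        return (pred, kvar) if return_variance else pred

    pred, kvar = _solve_ok(pts, z, variogram, tg)
    return (pred, kvar) if return_variance else pred


def _solve_ok(pts, z, vario, tg):
    n = len(pts)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = vario(cdist(pts, pts))
    A[n, :n] = A[:n, n] = 1.0
    A[n, n] = 0.0
    B = np.empty((n + 1, len(tg)))
    B[:n] = vario(cdist(pts, tg))
    B[n] = 1.0
    try:
        lam = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(A, B, rcond=None)[0]
    pred = lam[:n].T @ z
    kvar = np.maximum((lam * B).sum(axis=0), 0.0)
    return pred, kvar


def krige_grid(points, values, variogram: Variogram, grid: GridField,
               prop: str = "prediction",
               max_neighbors: int | None = None) -> GridField:
    """Krige scattered data onto the cell centers of a grid."""
    xx, yy = grid.cell_centers()
    tg = np.column_stack([xx.ravel(), yy.ravel()])
    pred = ordinary_kriging(points, values, variogram, tg,
                            max_neighbors=max_neighbors)
    return grid.with_property(prop, pred.reshape(grid.ny, grid.nx))


def regional_geometric_mean(values, region_labels) -> pd.DataFrame:
    """Per-region geometric mean exp(mean(ln x)) with arithmetic CV%."""
    v = np.asarray(values, dtype=float)
    labels = np.asarray(region_labels)
    bad = np.flatnonzero(~(v > 0))
    if bad.size:
        raise ValueError(f"non-positive value at row {bad[0]}")
    rows = []
    for region in pd.unique(labels):
        x = v[labels == region]
        rows.append({
            "region": region,
            "geometric_mean": float(np.exp(np.log(x).mean())),
            "n": int(x.size),
            "cv_percent": float(100.0 * x.std(ddof=1) / x.mean())
            if x.size > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def map_national_bioaccessibility(results, grid: GridField,
                                  regional_cd: pd.DataFrame,
                                  krige_smooth: bool = False,
                                  variogram_model: str = "spherical",
                                  ) -> tuple[GridField, pd.DataFrame]:
    """Predict bioaccessibility per grid cell and aggregate by region.

    Each cell's covariates come from the grid's property rasters; its
    total Cd is the geometric-mean concentration of the region the cell
    belongs to (``regional_cd`` columns: region, geometric_mean). Cells
    with any missing covariate propagate nodata. Returns the grid with
    ``ba_content`` and ``ba_percent`` rasters plus regional geometric
    means of ba_percent. ``krige_smooth`` adds an ordinary-kriging
    smoothing pass of ba_percent from a thinned subsample of cells.
    """
    if grid.regions is None:
        raise ValueError("grid has no region labels")
    frame = grid.to_long_frame()
    cd_by_region = dict(zip(regional_cd["region"], regional_cd["geometric_mean"]))
    missing_regions = set(frame["region"]) - set(cd_by_region)
    if missing_regions:
        raise ValueError(f"no Cd value for region(s): {sorted(missing_regions)}")
    frame["cd_total"] = frame["region"].map(cd_by_region).astype(float)

    feat_cols = [c for c in results.features if c != "log_cd_total"]
    ok = frame[feat_cols + ["cd_total"]].notna().all(axis=1)
    content = np.full(len(frame), np.nan)
    percent = np.full(len(frame), np.nan)
    if ok.any():
        c, p = results.predict_bioaccessibility(frame.loc[ok])
        content[ok.to_numpy()] = c
        percent[ok.to_numpy()] = p

    out = grid.with_property("ba_content", content.reshape(grid.ny, grid.nx))
    out = out.with_property("ba_percent", percent.reshape(grid.ny, grid.nx))

    if krige_smooth and ok.sum() >= 10:
        sub = frame.loc[ok].iloc[::4]
        pts = sub[["x", "y"]].to_numpy()
        vals = percent[ok.to_numpy()][::4]
        vario = fit_variogram(pts, vals, model=variogram_model)
        out = krige_grid(pts, vals, vario, out, prop="ba_percent_kriged")

    valid = np.isfinite(percent)
    summaries = regional_geometric_mean(percent[valid],
                                        frame["region"].to_numpy()[valid])
    return out, summaries
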