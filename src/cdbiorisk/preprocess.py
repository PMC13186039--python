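"""Screening statistics, unit conversion, imputation and outlier filtering.

The screening stage mirrors a standard compiled-dataset workflow for
bioaccessibility data: a Kruskal-Wallis test for overall differences
among in-vitro extraction methods, Mann-Whitney U for the PBET/UBM
pairwise comparison, TOC-to-SOM unit conversion, iterative random-forest
imputation of missing covariates (missForest-style single completion),
Cook's-distance filtering of influential observations on a log-scale OLS
fit, and a Spearman correlation matrix with significance stars.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "CorrelationMatrix",
    "InfluenceDiagnostics",
    "toc_to_som",
    "kruskal_wallis",
    "mann_whitney_u",
    "rf_impute",
    "cooks_filter",
    "spearman_matrix",
]

#: van-Bemmelen convention: TOC = 0.58 * SOM.
TOC_TO_SOM_FACTOR = 0.58


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_per_group: tuple
    method: str


@dataclass(frozen=True)
class CorrelationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame


@dataclass(frozen=True)
class InfluenceDiagnostics:
    cooks_d: pd.Series
    leverage: pd.Series
    flagged_ids: list
    threshold: float


def toc_to_som(toc, factor: float = TOC_TO_SOM_FACTOR):
    """Convert total organic carbon to soil organic matter: SOM = TOC / 0.58."""
    toc = np.asarray(toc, dtype=float)
    if np.any(toc < 0):
        raise ValueError("TOC must be non-negative")
    out = toc / factor
    return float(out) if out.ndim == 0 else out


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        h, p = 0.0, 1.0  # all values identical; scipy raises here
    else:
        h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), tuple(len(g) for g in groups),
                      "kruskal-wallis")


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact Mann-Whitney p by enumeration over all assignments,
    with midranks, symmetric around nx*ny/2."""
    nx, ny = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    mu = nx * ny / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(nx + ny), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U for the first sample, two-sided.

    Exact enumeration (with midranks) when nx*ny <= 100, otherwise the
    tie-corrected normal approximation without continuity correction (so
    the two-group Kruskal-Wallis chi-square p coincides with it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if nx * ny <= 100:
        p = _exact_mwu_p(x, y, u_x)
    else:
        pooled = np.concatenate([x, y])
        n = nx + ny
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts ** 3 - counts).sum()
        var = nx * ny / 12.0 * (n + 1 - tie_term / (n * (n - 1)))
        if var == 0:
            p = 1.0
        else:
            z = (u_x - nx * ny / 2.0) / math.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(u_x, float(min(p, 1.0)), (nx, ny), "mann-whitney-u")


def rf_impute(samples: pd.DataFrame, columns=None, max_iter: int = 5,
              tol: float = 1e-3, seed: int | None = 0,
              n_estimators: int = 50,
              exclude=("ba_content_ip", "ba_content_gp", "cd_total"),
              ) -> pd.DataFrame:
    """Iterative random-forest imputation (single completion).

    Columns are initialized with their medians, then updated in order of
    increasing missingness by regressing each on the other covariates
    with a random forest, until the relative change of the imputed values
    drops below ``tol`` or ``max_iter`` is reached. Observed cells are
    never altered; response columns are excluded from imputation.
    """
    out = samples.copy()
    num_cols = [c for c in out.columns
                if pd.api.types.is_numeric_dtype(out[c]) and c not in exclude]
    if columns is not None:
        num_cols = [c for c in num_cols if c in set(columns)]
    miss = {c: out[c].isna().to_numpy() for c in num_cols}
    targets = [c for c in num_cols if miss[c].any()]
    if not targets:
        return out
    for c in targets:
        if miss[c].all():
            raise ValueError(f"column {c!r} has no observed values")
    targets.sort(key=lambda c: (miss[c].sum(), c))

    work = out[num_cols].copy()
    for c in targets:
        work.loc[miss[c], c] = work[c].median()

    rng = np.random.default_rng(seed)
    prev = {c: work.loc[miss[c], c].to_numpy().copy() for c in targets}
    for _ in range(max_iter):
        for c in targets:
            feats = [f for f in num_cols if f != c]
            obs = ~miss[c]
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=int(rng.integers(2 ** 31 - 1)))
            rf.fit(work.loc[obs, feats], work.loc[obs, c])
            work.loc[miss[c], c] = rf.predict(work.loc[miss[c], feats])
        num = sum(((work.loc[miss[c], c].to_numpy() - prev[c]) ** 2).sum()
                  for c in targets)
        den = sum((work.loc[miss[c], c].to_numpy() ** 2).sum() for c in targets)
        prev = {c: work.loc[miss[c], c].to_numpy().copy() for c in targets}
        if den > 0 and num / den < tol:
            break
    for c in targets:
        out.loc[miss[c], c] = work.loc[miss[c], c]
    return out


def cooks_filter(samples: pd.DataFrame, response: str, predictors,
                 threshold: float = 1.0,
                 log_response: bool = True, log_cd: bool = True,
                 ) -> tuple[pd.DataFrame, InfluenceDiagnostics]:
    """Remove observations with Cook's distance above ``threshold``.

    A single OLS fit of the (optionally log-transformed) response on the
    predictors (cd_total entering as its natural log when ``log_cd``)
    yields D_i = (e_i^2 / (p s^2)) * (h_ii / (1-h_ii)^2); rows with
    D_i > threshold are dropped.
    """
    predictors = list(predictors)
    df = samples.dropna(subset=[response] + predictors)
    y = df[response].to_numpy(dtype=float)
    if log_response:
        y = np.log(y)
    X = df[predictors].astype(float).copy()
    if log_cd and "cd_total" in X.columns:
        X["cd_total"] = np.log(X["cd_total"])
        X = X.rename(columns={"cd_total": "log_cd_total"})
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations for the OLS fit")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    fit = sm.OLS(y, Xc).fit()
    infl = fit.get_influence()
    cooks = pd.Series(infl.cooks_distance[0], index=df.index)
    lev = pd.Series(infl.hat_matrix_diag, index=df.index)
    flagged = cooks.index[cooks > threshold]
    ids = (df.loc[flagged, "sample_id"].tolist()
           if "sample_id" in df.columns else list(flagged))
    diag = InfluenceDiagnostics(cooks, lev, ids, threshold)
    return samples.drop(index=flagged), diag


def spearman_matrix(samples: pd.DataFrame, columns) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations with significance stars.

    Stars: '*' for p < 0.05, '**' for p < 0.01. Cells with fewer than 4
    complete pairs or a constant column are undefined (NaN, with a
    warning for constant columns).
    """
    columns = list(columns)
    k = len(columns)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i] = 1.0
        pmat[i, i] = 0.0
    for i, j in itertools.combinations(range(k), 2):
        sub = samples[[columns[i], columns[j]]].dropna()
        if len(sub) < 4:
            continue
        a = sub.iloc[:, 0].to_numpy(dtype=float)
        b = sub.iloc[:, 1].to_numpy(dtype=float)
        if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
            warnings.warn(
                f"constant column in pair ({columns[i]}, {columns[j]}); "
                "correlation undefined", stacklevel=2)
            continue
        res = stats.spearmanr(a, b)
        rho[i, j] = rho[j, i] = res.statistic
        pmat[i, j] = pmat[j, i] = res.pvalue
    stars = np.where(pmat < 0.01, "**", np.where(pmat < 0.05, "*", ""))
    stars = np.where(np.isnan(pmat), "", stars)
    idx = pd.Index(columns)
    return CorrelationMatrix(pd.DataFrame(rho, idx, idx),
                             pd.DataFrame(pmat, idx, idx),
                             pd.DataFrame(stars, idx, idx))
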