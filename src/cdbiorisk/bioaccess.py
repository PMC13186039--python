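"""Predictive models of intestinal-phase bioaccessible Cd content.

Two model families are fitted to the log-transformed response:

* stepwise ordinary least squares (forward entry on the smallest
  partial-F p-value below ``alpha_enter``, backward removal of any
  retained predictor at or above ``alpha_remove``, iterated to a
  fixpoint), and
* a random forest tuned by grid search with k-fold cross-validation.

Both are exposed statsmodels-style: a :class:`BioaccessibilityModel`
built from a samples DataFrame whose ``fit`` returns a results object
(:class:`StepwiseResults` or :class:`ForestResults`) carrying the
estimates, metrics and interpretation artifacts, with ``predict`` and
``summary`` methods. The module-level functions (`split_data`,
`stepwise_fit`, `rf_grid_fit`, `evaluate_model`,
`predict_bioaccessibility`) are thin wrappers over these objects.

The response and total Cd are natural-log transformed; the other
covariates enter untransformed. Back-transformation is a plain exp (no
smearing correction by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = [
    "ModelMetrics",
    "BioaccessibilityModel",
    "StepwiseResults",
    "ForestResults",
    "DEFAULT_GRID",
    "REFERENCE_OPTIMUM",
    "split_data",
    "prepare_modeling_frame",
    "stepwise_fit",
    "rf_grid_fit",
    "evaluate_model",
    "predict_bioaccessibility",
]

#: Reported optimal random-forest hyperparameters for this problem class.
REFERENCE_OPTIMUM = {
    "n_estimators": 100,
    "max_depth": None,
    "max_features": 7,
    "min_samples_leaf": 2,
    "min_samples_split": 6,
}

#: Small default search lattice around the optimum.
DEFAULT_GRID = {
    "n_estimators": [100, 200],
    "max_depth": [None, 10],
    "max_features": [3, 7],
    "min_samples_leaf": [1, 2],
    "min_samples_split": [2, 6],
}

RESPONSE = "log_ba_ip"
DEFAULT_CANDIDATES = ("log_cd_total", "ph", "som", "cec", "fe", "clay", "sand")


def split_data(samples: pd.DataFrame, test_fraction: float = 0.2,
               seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive train/test split.

    The test size is the fraction rounded to the nearest integer (e.g.
    n=126 at 0.2 gives a 101/25 split).
    """
    n = len(samples)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return samples.iloc[train_idx], samples.iloc[test_idx]


def prepare_modeling_frame(samples: pd.DataFrame,
                           response: str = "ba_content_ip") -> pd.DataFrame:
    """Log-transform the response and total Cd for modeling.

    Returns a frame with ``log_ba_ip`` (ln of the response) and
    ``log_cd_total`` alongside the untransformed covariates; rows with a
    missing or non-positive response are dropped.
    """
    df = samples.copy()
    ok = df[response].notna() & (df[response] > 0) & (df["cd_total"] > 0)
    df = df.loc[ok]
    df[RESPONSE] = np.log(df[response].to_numpy(dtype=float))
    df["log_cd_total"] = np.log(df["cd_total"].to_numpy(dtype=float))
    return df


@dataclass(frozen=True)
class ModelMetrics:
    r2_train: float
    rmse_train: float
    r2_test: float | None = None
    rmse_test: float | None = None
    r2_cv: float | None = None

    @property
    def delta_r2(self) -> float | None:
        if self.r2_test is None:
            return None
        return self.r2_train - self.r2_test

    def to_frame(self) -> pd.DataFrame:
        d = {"r2_train": self.r2_train, "rmse_train": self.rmse_train,
             "r2_test": self.r2_test, "rmse_test": self.rmse_test,
             "r2_cv": self.r2_cv, "delta_r2": self.delta_r2}
        return pd.DataFrame({"value": d})


def _r2_rmse(y, yhat) -> tuple[float, float]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 rows to evaluate")
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return r2, float(np.sqrt(ss_res / y.size))


class _ResultsBase:
    """Shared evaluation/prediction surface of fitted bioaccessibility models."""

    features: list  # modeling-frame column names

    def predict_log(self, data: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def evaluate(self, data: pd.DataFrame, response: str = RESPONSE) -> dict:
        """R-squared and log-scale RMSE on a modeling frame."""
        missing = [f for f in self.features if f not in data.columns]
        if missing:
            raise ValueError(f"data lacks model features: {missing}")
        r2, rmse = _r2_rmse(data[response].to_numpy(dtype=float),
                            self.predict_log(data))
        return {"r2": r2, "rmse": rmse}

    def predict_bioaccessibility(self, soil, cd_total=None
                                 ) -> tuple[np.ndarray, np.ndarray]:
        """Back-transformed bioaccessible content (mg/kg) and percent.

        ``soil`` is a DataFrame (or dict of arrays/scalars) of covariates;
        ``cd_total`` overrides/provides the total Cd column. Content is
        exp of the log-scale prediction, capped at cd_total; the percent
        is 100*content/cd_total, hence in (0, 100].
        """
        if isinstance(soil, dict):
            soil = pd.DataFrame({k: np.atleast_1d(v) for k, v in soil.items()})
        df = soil.copy()
        if cd_total is not None:
            df["cd_total"] = np.atleast_1d(np.asarray(cd_total, dtype=float))
        cd = df["cd_total"].to_numpy(dtype=float)
        if np.any(cd[np.isfinite(cd)] <= 0):
            raise ValueError("cd_total must be strictly positive")
        df["log_cd_total"] = np.log(cd)
        content = np.exp(self.predict_log(df))
        content = np.minimum(content, cd)
        percent = 100.0 * content / cd
        return content, percent

    def plot_observed_vs_predicted(self, data: pd.DataFrame,
                                   response: str = RESPONSE, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = data[response].to_numpy(dtype=float)
        yhat = self.predict_log(data)
        ax.scatter(y, yhat, s=12)
        lims = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("observed ln(bioaccessible Cd)")
        ax.set_ylabel("predicted")
        return ax


class StepwiseResults(_ResultsBase):
    """Fitted stepwise OLS model of ln(bioaccessible Cd)."""

    def __init__(self, ols_results, selected: list, candidates: list,
                 alpha_enter: float, alpha_remove: float):
        self.ols = ols_results
        self.selected_predictors = list(selected)
        self.candidates = list(candidates)
        self.features = list(selected)
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove

    @property
    def params(self) -> pd.Series:
        return self.ols.params

    @property
    def pvalues(self) -> pd.Series:
        return self.ols.pvalues

    def predict_log(self, data: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(data[self.selected_predictors].astype(float),
                            has_constant="add")
        return np.asarray(self.ols.predict(X), dtype=float)

    def summary(self):
        return self.ols.summary()


class ForestResults(_ResultsBase):
    """Fitted random-forest model of ln(bioaccessible Cd)."""

    def __init__(self, estimator: RandomForestRegressor, features: list,
                 hyperparams: dict, cv_r2: float | None, cv_table: pd.DataFrame):
        self.estimator = estimator
        self.features = list(features)
        self.hyperparams = dict(hyperparams)
        self.cv_r2 = cv_r2
        self.cv_table = cv_table

    def predict_log(self, data: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(data[self.features].astype(float))

    def feature_importances(self) -> pd.Series:
        """Normalized impurity-decrease importances (sum to 1)."""
        imp = np.asarray(self.estimator.feature_importances_, dtype=float)
        s = imp.sum()
        if s > 0:
            imp = imp / s
        else:
            imp = np.full_like(imp, 1.0 / imp.size)
        return pd.Series(imp, index=self.features).sort_values(ascending=False)

    def shapley(self, data: pd.DataFrame, background: pd.DataFrame):
        from .attribution import shapley_attributions
        return shapley_attributions(self, data, background)

    def summary(self) -> str:
        lines = ["Random forest model of ln(bioaccessible Cd)",
                 f"  features: {', '.join(self.features)}"]
        for k, v in self.hyperparams.items():
            lines.append(f"  {k} = {v}")
        if self.cv_r2 is not None:
            lines.append(f"  CV R^2 = {self.cv_r2:.4f}")
        return "\n".join(lines)


class BioaccessibilityModel:
    """Model of intestinal-phase bioaccessible Cd content built from data.

    Parameters
    ----------
    data : DataFrame
        A modeling frame (see :func:`prepare_modeling_frame`) or a raw
        samples table (detected by the absence of the log columns).
    candidates : sequence of str
        Candidate predictors, in modeling-frame names.

    ``fit(method="stepwise")`` and ``fit(method="forest")`` return
    :class:`StepwiseResults` / :class:`ForestResults`.
    """

    def __init__(self, data: pd.DataFrame, candidates=DEFAULT_CANDIDATES,
                 response: str = RESPONSE):
        if response not in data.columns:
            if response == RESPONSE and "ba_content_ip" in data.columns:
                data = prepare_modeling_frame(data)
            else:
                raise ValueError(f"response column {response!r} not in data")
        self.data = data.dropna(subset=[response, *candidates])
        self.response = response
        self.candidates = list(candidates)

    @classmethod
    def from_dataframe(cls, samples: pd.DataFrame,
                       candidates=DEFAULT_CANDIDATES) -> "BioaccessibilityModel":
        return cls(prepare_modeling_frame(samples), candidates)

    def fit(self, method: str = "forest", **kwargs):
        if method == "stepwise":
            return self._fit_stepwise(**kwargs)
        if method == "forest":
            return self._fit_forest(**kwargs)
        raise ValueError(f"unknown method {method!r}")

    def _fit_stepwise(self, alpha_enter: float = 0.05,
                      alpha_remove: float = 0.05) -> StepwiseResults:
        y = self.data[self.response].to_numpy(dtype=float)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        selected: list = []
        changed = True
        while changed:
            changed = False
            if selected:  # stop at a (numerically) perfect fit
                X = sm.add_constant(self.data[selected].astype(float),
                                    has_constant="add")
                if sm.OLS(y, X).fit().ssr <= 1e-12 * (ss_tot + 1e-300):
                    break
            # forward: candidate with the smallest partial-F p-value
            best_p, best_c = np.inf, None
            for c in self.candidates:
                if c in selected:
                    continue
                X = sm.add_constant(self.data[selected + [c]].astype(float),
                                    has_constant="add")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = sm.OLS(y, X).fit().pvalues[c]
                if p < best_p:
                    best_p, best_c = p, c
            if best_c is not None and best_p < alpha_enter:
                selected.append(best_c)
                changed = True
            # backward: drop anything that lost significance
            while selected:
                X = sm.add_constant(self.data[selected].astype(float),
                                    has_constant="add")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pv = sm.OLS(y, X).fit().pvalues[selected]
                worst = pv.idxmax()
                if pv[worst] >= alpha_remove:
                    selected.remove(worst)
                    changed = True
                else:
                    break
        if not selected:
            warnings.warn("no candidate entered the stepwise model; "
                          "returning intercept-only fit", stacklevel=2)
        X = sm.add_constant(self.data[selected].astype(float),
                            has_constant="add")
        fit = sm.OLS(y, X).fit()
        return StepwiseResults(fit, selected, self.candidates,
                               alpha_enter, alpha_remove)

    def _fit_forest(self, grid: dict | None = None, k_folds: int = 5,
                    seed: int | None = 0) -> ForestResults:
        grid = grid if grid is not None else DEFAULT_GRID
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")
        n = len(self.data)
        if k_folds > n:
            raise ValueError("k_folds cannot exceed the number of rows")
        X = self.data[self.candidates].astype(float).reset_index(drop=True)
        y = self.data[self.response].to_numpy(dtype=float)
        keys = list(grid.keys())
        points = [dict(zip(keys, vals))
                  for vals in itertools.product(*(grid[k] for k in keys))]

        kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        folds = list(kf.split(X))
        rows = []
        for order, hp in enumerate(points):
            est = _make_forest(hp, n_features=len(self.candidates), seed=seed)
            scores = []
            for tr, te in folds:
                m = clone(est)
                m.fit(X.iloc[tr], y[tr])
                scores.append(_r2_rmse(y[te], m.predict(X.iloc[te]))[0])
            rows.append({**hp, "cv_r2": float(np.mean(scores)), "order": order})
        table = pd.DataFrame(rows)
        # best mean CV R^2; ties -> smaller ensemble, then grid order
        sort_cols = [c for c in ("cv_r2", "n_estimators", "order")
                     if c in table.columns]
        best = table.sort_values(
            sort_cols, ascending=[c != "cv_r2" for c in sort_cols],
            kind="mergesort").iloc[0]
        hp = points[int(best["order"])]
        est = _make_forest(hp, n_features=len(self.candidates), seed=seed)
        est.fit(X, y)
        return ForestResults(est, self.candidates, hp, float(best["cv_r2"]),
                             table.drop(columns="order"))


def _make_forest(hp: dict, n_features: int, seed) -> RandomForestRegressor:
    hp = dict(hp)
    mf = hp.get("max_features")
    if isinstance(mf, (int, np.integer)):
        hp["max_features"] = int(min(mf, n_features))  # cap at available count
    md = hp.get("max_depth")
    if md is not None and not (isinstance(md, str)):
        hp["max_depth"] = int(md) if not pd.isna(md) else None
    return RandomForestRegressor(random_state=seed, **hp)


# ---------------------------------------------------------------------------
# functional wrappers

def stepwise_fit(train: pd.DataFrame, response: str = RESPONSE,
                 candidates=DEFAULT_CANDIDATES, alpha_enter: float = 0.05,
                 alpha_remove: float = 0.05) -> StepwiseResults:
    model = BioaccessibilityModel(train, candidates, response)
    return model.fit("stepwise", alpha_enter=alpha_enter,
                     alpha_remove=alpha_remove)


def rf_grid_fit(train: pd.DataFrame, response: str = RESPONSE,
                candidates=DEFAULT_CANDIDATES, grid: dict | None = None,
                k_folds: int = 5, seed: int | None = 0) -> ForestResults:
    model = BioaccessibilityModel(train, candidates, response)
    return model.fit("forest", grid=grid, k_folds=k_folds, seed=seed)


def evaluate_model(results: _ResultsBase, data: pd.DataFrame,
                   response: str = RESPONSE) -> dict:
    """R-squared (1 - SS_res/SS_tot) and RMSE on the modeling (log) scale."""
    return results.evaluate(data, response)


def predict_bioaccessibility(results: _ResultsBase, soil, cd_total=None):
    """See :meth:`_ResultsBase.predict_bioaccessibility`."""
    return results.predict_bioaccessibility(soil, cd_total)


def metrics_for(results: _ResultsBase, train: pd.DataFrame,
                test: pd.DataFrame | None = None,
                response: str = RESPONSE) -> ModelMetrics:
    tr = results.evaluate(train, response)
    te = results.evaluate(test, response) if test is not None else None
    return ModelMetrics(
        r2_train=tr["r2"], rmse_train=tr["rmse"],
        r2_test=te["r2"] if te else None,
        rmse_test=te["rmse"] if te else None,
        r2_cv=getattr(results, "cv_r2", None))
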