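"""End-to-end orchestration: simulate -> preprocess -> train -> map -> risk
-> sensitivity, with a flat config, per-stage seeds, a hash manifest and
deterministic outputs under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import bioaccess, io, preprocess, risk, spatial, synthetic
from .grid import write_ascii_grid

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("cdbiorisk")

STAGES = ("simulate", "preprocess", "train", "map", "risk", "sensitivity")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "runs/run0",
    "stages": list(STAGES),
    # simulate
    "n_samples": 200,
    "missing_rate": 0.05,
    "n_outliers": 2,
    "grid_nx": 24,
    "grid_ny": 24,
    "grid_smoothness": 3.0,
    # preprocess
    "toc_factor": 0.58,
    "cooks_threshold": 1.0,
    # train
    "test_fraction": 0.2,
    "alpha_enter": 0.05,
    "alpha_remove": 0.05,
    "rf_grid": "optimum",       # "optimum", "default", or a dict of lists
    "k_folds": 5,
    "shap_subsample": 30,
    # map
    "variogram_family": "spherical",
    "krige_smooth": False,
    # risk
    "cf_ing": 1.0e-6,
    "n_iter": 10000,
    "populations": ["adult", "child"],
}


def load_config(path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    user = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg.update(user)
    return cfg


def _child_seed(seed: int, k: int) -> int:
    return int((int(seed) * 1000 + k) % (2 ** 31 - 1))


def _require(rundir: Path, name: str, produced_by: str) -> Path:
    p = rundir / name
    if not p.exists():
        raise RuntimeError(
            f"missing artifact {name!r}: enable or run stage "
            f"{produced_by!r} first")
    return p


def run_pipeline(config: dict | str | Path) -> Path:
    """Execute the toggled stages; returns the run directory.

    Outputs are deterministic for a fixed seed (no timestamps); a
    manifest.json records the config and the SHA-256 of every artifact.
    """
    cfg = load_config(config) if not isinstance(config, dict) else \
        {**DEFAULT_CONFIG, **config}
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    bad = [s for s in cfg["stages"] if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")

    rundir = Path(cfg["out_dir"])
    rundir.mkdir(parents=True, exist_ok=True)
    (rundir / "config.yaml").write_text(
        yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")

    stage_fns = {
        "simulate": _stage_simulate,
        "preprocess": _stage_preprocess,
        "train": _stage_train,
        "map": _stage_map,
        "risk": _stage_risk,
        "sensitivity": _stage_sensitivity,
    }
    for stage in STAGES:
        if stage in cfg["stages"]:
            log.info("running stage %s", stage)
            stage_fns[stage](cfg, rundir)

    _write_manifest(cfg, rundir)
    return rundir


def _stage_simulate(cfg, rundir: Path) -> None:
    seed = _child_seed(cfg["seed"], 1)
    truth = synthetic.GroundTruth()
    samples = synthetic.generate_soil_dataset(cfg["n_samples"], truth, seed)
    degraded, mask, outlier_ids = synthetic.degrade_dataset(
        samples, cfg["missing_rate"], cfg["n_outliers"],
        _child_seed(cfg["seed"], 2))
    io.write_samples_csv(rundir / "samples.csv", degraded)
    mask.to_csv(rundir / "missing_mask.csv", index=False)
    frames = []
    for pop in cfg["populations"]:
        specs = synthetic.generate_exposure_distributions(pop)
        frames.append(synthetic.exposure_specs_to_frame(specs, population=pop))
    io.write_exposure_csv(rundir / "exposure.csv", pd.concat(frames))
    io.write_toxicity_csv(rundir / "toxicity.csv", risk.DEFAULT_TOXICITY)
    grid = synthetic.generate_property_grid(
        cfg["grid_nx"], cfg["grid_ny"], cfg["grid_smoothness"],
        _child_seed(cfg["seed"], 3))
    for prop in grid.properties:
        write_ascii_grid(rundir / f"grid_{prop}.asc", grid, prop)
    pd.DataFrame(grid.regions).to_csv(rundir / "grid_regions.csv",
                                      index=False, header=False)
    (rundir / "truth.json").write_text(json.dumps({
        "b0": truth.b0, "b1_logcd": truth.b1_logcd, "b2_sand": truth.b2_sand,
        "interaction_strength": truth.interaction_strength,
        "sigma_noise": truth.sigma_noise,
        "method_shifts": truth.method_shifts,
        "outlier_ids": outlier_ids}, indent=1), encoding="utf-8")


def _stage_preprocess(cfg, rundir: Path) -> None:
    samples = io.read_samples_csv(_require(rundir, "samples.csv", "simulate"))
    # compare bioaccessibility (fraction of total) across in-vitro methods
    ba = samples["ba_content_ip"] / samples["cd_total"]
    groups = [ba[g.index].dropna().to_numpy()
              for _, g in samples.groupby("method")]
    kw = preprocess.kruskal_wallis(groups)
    pbet = ba[samples["method"] == "PBET"].dropna()
    ubm = ba[samples["method"] == "UBM"].dropna()
    mwu = preprocess.mann_whitney_u(pbet, ubm)
    pd.DataFrame([
        {"test": "kruskal-wallis (all methods)", "statistic": kw.statistic,
         "p_value": kw.p_value, "n": sum(kw.n_per_group)},
        {"test": "mann-whitney (PBET vs UBM)", "statistic": mwu.statistic,
         "p_value": mwu.p_value, "n": sum(mwu.n_per_group)},
    ]).to_csv(rundir / "screening_tests.csv", index=False)

    imputed = preprocess.rf_impute(samples, seed=_child_seed(cfg["seed"], 4))
    filtered, diag = preprocess.cooks_filter(
        imputed, "ba_content_ip",
        ["cd_total", "ph", "som", "clay", "sand"],
        threshold=cfg["cooks_threshold"])
    pd.DataFrame({"cooks_d": diag.cooks_d, "leverage": diag.leverage}
                 ).to_csv(rundir / "influence.csv", index=False)
    io.write_samples_csv(rundir / "samples_clean.csv", filtered)

    corr = preprocess.spearman_matrix(
        filtered.assign(
            ba_ip_pct=100 * filtered["ba_content_ip"] / filtered["cd_total"]),
        ["ba_ip_pct", "ph", "som", "clay", "silt", "sand", "fe", "cd_total"])
    corr.rho.to_csv(rundir / "spearman_rho.csv")
    corr.stars.to_csv(rundir / "spearman_stars.csv")


def _stage_train(cfg, rundir: Path) -> None:
    samples = io.read_samples_csv(
        _require(rundir, "samples_clean.csv", "preprocess"))
    frame = bioaccess.prepare_modeling_frame(samples)
    train, test = bioaccess.split_data(frame, cfg["test_fraction"],
                                       _child_seed(cfg["seed"], 5))
    sw = bioaccess.stepwise_fit(train, alpha_enter=cfg["alpha_enter"],
                                alpha_remove=cfg["alpha_remove"])
    grid = cfg["rf_grid"]
    if grid == "optimum":
        grid = {k: [v] for k, v in bioaccess.REFERENCE_OPTIMUM.items()}
    elif grid == "default":
        grid = bioaccess.DEFAULT_GRID
    rf = bioaccess.rf_grid_fit(train, grid=grid, k_folds=cfg["k_folds"],
                               seed=_child_seed(cfg["seed"], 6))
    rows = []
    for name, res in (("stepwise", sw), ("forest", rf)):
        m = bioaccess.metrics_for(res, train, test)
        rows.append({"model": name, "r2_train": m.r2_train,
                     "r2_test": m.r2_test, "r2_cv": m.r2_cv,
                     "rmse_train": m.rmse_train, "rmse_test": m.rmse_test,
                     "delta_r2": m.delta_r2})
    pd.DataFrame(rows).to_csv(rundir / "model_metrics.csv", index=False)
    rf.feature_importances().rename("importance").to_csv(
        rundir / "feature_importance.csv")
    k = min(int(cfg["shap_subsample"]), len(train))
    attr = rf.shapley(test.head(k), train.head(k))
    attr.values.to_csv(rundir / "shap_values.csv", index=False)
    joblib.dump({"format_version": 1, "stepwise": sw, "forest": rf},
                rundir / "models.joblib")


def _stage_map(cfg, rundir: Path) -> None:
    from .grid import GridField, read_ascii_grid

    _require(rundir, "models.joblib", "train")
    bundle = joblib.load(rundir / "models.joblib")
    rf = bundle["forest"]
    props = {}
    base = None
    for prop in synthetic.COVARIATE_COLUMNS:
        p = _require(rundir, f"grid_{prop}.asc", "simulate")
        g = read_ascii_grid(p, prop)
        props[prop] = g.properties[prop]
        base = g
    regions = pd.read_csv(rundir / "grid_regions.csv", header=None
                          ).to_numpy(dtype=object)
    grid = GridField(base.nx, base.ny, base.cell_size, base.origin,
                     props, regions)
    samples = io.read_samples_csv(
        _require(rundir, "samples_clean.csv", "preprocess"))
    regional_cd = spatial.regional_geometric_mean(
        samples["cd_total"], samples["region"]).rename(
        columns={"geometric_mean": "geometric_mean"})
    out, summaries = spatial.map_national_bioaccessibility(
        rf, grid, regional_cd, krige_smooth=cfg["krige_smooth"],
        variogram_model=cfg["variogram_family"])
    for prop in ("ba_content", "ba_percent"):
        write_ascii_grid(rundir / f"map_{prop}.asc", out, prop)
    summaries.to_csv(rundir / "regional_ba.csv", index=False)
    regional_cd.to_csv(rundir / "regional_cd.csv", index=False)


def _stage_risk(cfg, rundir: Path) -> None:
    from .grid import read_ascii_grid

    tox = io.read_toxicity_csv(_require(rundir, "toxicity.csv", "simulate"))
    regional_cd = pd.read_csv(_require(rundir, "regional_cd.csv", "map"))
    ba_map = read_ascii_grid(_require(rundir, "map_ba_percent.asc", "map"),
                             "ba_percent")
    ba_values = ba_map.properties["ba_percent"]
    ba_values = ba_values[np.isfinite(ba_values)] / 100.0
    ba_spec, ba_report = risk.fit_lognormal(
        np.clip(ba_values, 1e-6, 1.0), name="BA")
    ba_spec = risk.DistributionSpec("BA", "lognormal", ba_spec.p1, ba_spec.p2,
                                    lower=1e-6, upper=1.0)

    cd_gm = float(np.exp(np.log(regional_cd["geometric_mean"]).mean()))
    c_spec = risk.DistributionSpec("C", "lognormal", np.log(cd_gm), 0.5,
                                   lower=1e-3, upper=1e4, units="mg/kg")
    summaries, comparisons = [], []
    for i, pop in enumerate(cfg["populations"]):
        specs = synthetic.generate_exposure_distributions(pop)
        specs["C"] = c_spec
        specs["BA"] = ba_spec
        res = risk.run_monte_carlo(specs, tox, cfg["n_iter"],
                                   _child_seed(cfg["seed"], 7 + i),
                                   cf_ing=cfg["cf_ing"])
        s = res.summary().reset_index(names="metric")
        s.insert(0, "population", pop)
        summaries.append(s)
        res.draws.to_csv(rundir / f"risk_draws_{pop}.csv", index=False)
        cmp_ = risk.compare_adjustment(specs, tox, ba_spec, cfg["n_iter"],
                                       _child_seed(cfg["seed"], 7 + i),
                                       cf_ing=cfg["cf_ing"])
        cmp_ = cmp_.reset_index(names="metric")
        cmp_.insert(0, "population", pop)
        comparisons.append(cmp_)
    pd.concat(summaries).to_csv(rundir / "risk_summary.csv", index=False)
    pd.concat(comparisons).to_csv(rundir / "risk_adjustment.csv", index=False)
    (rundir / "ba_distribution.json").write_text(json.dumps(
        {"law": "lognormal", "p1": ba_spec.p1, "p2": ba_spec.p2,
         **ba_report}, indent=1), encoding="utf-8")


def _stage_sensitivity(cfg, rundir: Path) -> None:
    frames = []
    for pop in cfg["populations"]:
        p = _require(rundir, f"risk_draws_{pop}.csv", "risk")
        draws = pd.read_csv(p)
        inputs = draws[[c for c in risk.PARAMETERS if c in draws.columns]]
        for metric in ("HQ", "CR"):
            contrib = risk.variance_contributions(inputs, draws[metric])
            contrib = contrib.reset_index(names="parameter")
            contrib.insert(0, "metric", metric)
            contrib.insert(0, "population", pop)
            frames.append(contrib)
    pd.concat(frames).to_csv(rundir / "sensitivity.csv", index=False)


def _write_manifest(cfg, rundir: Path) -> None:
    hashes = {}
    for p in sorted(rundir.iterdir()):
        if p.name == "manifest.json" or p.is_dir() or \
                p.suffix not in (".csv", ".asc", ".json", ".yaml"):
            continue
        hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (rundir / "manifest.json").write_text(json.dumps(
        {"seed": cfg["seed"], "stages": list(cfg["stages"]),
         "config": {k: str(v) for k, v in sorted(cfg.items())},
         "sha256": hashes}, indent=1), encoding="utf-8")
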