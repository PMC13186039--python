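"""Synthetic soil-sample, exposure-parameter and raster generators.

The generators emulate the statistical structure of a literature-compiled
Chinese soil cadmium bioaccessibility dataset so that every downstream
stage (screening tests, imputation, outlier filtering, model fitting,
kriging, Monte Carlo risk) is testable without any external download:

* soil properties drawn from bounded laws inside the compilation's
  printed ranges (pH 3.01-11.37, SOM 0.17-131.03 g/kg, clay 0.02-44.43 %,
  silt 10.82-78.26 %, sand 2.30-89.16 %), with a shared latent
  "weathering" factor inducing the realistic cross-correlations
  (sandier soils tend to be more alkaline and organic-poor);
* texture as a 3-part composition (Dirichlet-type gamma construction,
  renormalized to 100, rejection-sampled into the printed ranges);
* in-vitro method labels multinomial with the compilation's mixture
  (PBET 73.3 %, UBM 15.8 %, other 10.9 %);
* intestinal-phase bioaccessible Cd log-linear in ln(total Cd) and sand
  with an optional pH x Cd interaction, per-method log-scale offsets
  (PBET = UBM = 0 so their pairwise test is null while the overall
  cross-method test is not), and Gaussian log-scale noise;
* lognormal-style exposure-parameter tables per population with child
  ingestion rate above, and child body weight below, the adult medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridField
from .risk import DistributionSpec

__all__ = [
    "GroundTruth",
    "PROPERTY_RANGES",
    "METHODS",
    "METHOD_PROPORTIONS",
    "COVARIATE_COLUMNS",
    "generate_soil_dataset",
    "degrade_dataset",
    "generate_exposure_distributions",
    "generate_property_grid",
    "exposure_specs_to_frame",
]

#: Printed ranges of the compiled dataset's soil properties (plus plausible
#: ranges for CEC and Fe, whose extremes are not printed).
PROPERTY_RANGES: dict[str, tuple[float, float]] = {
    "ph": (3.01, 11.37),
    "som": (0.17, 131.03),
    "cec": (2.0, 45.0),
    "fe": (5.0, 65.0),
    "clay": (0.02, 44.43),
    "silt": (10.82, 78.26),
    "sand": (2.30, 89.16),
}

METHODS = ("PBET", "UBM", "DIN", "IVG", "SBET")
#: PBET 73.3 %, UBM 15.8 %, the rest sharing the remaining 10.9 %.
METHOD_PROPORTIONS = (0.733, 0.158, 0.040, 0.035, 0.034)

COVARIATE_COLUMNS = ("ph", "som", "cec", "fe", "clay", "silt", "sand")

_REGIONS = ("north", "central", "south")


@dataclass(frozen=True)
class GroundTruth:
    """Generating coefficients of the log-linear bioaccessibility law.

    ln(ba_ip) = b0 + b1_logcd * ln(cd_total) + b2_sand * sand
                + interaction_strength * (pH - 7) * (ln cd - mu_lncd)
                + method_shift + N(0, sigma_noise)

    Defaults put the bioaccessible fraction roughly in the 2-55 % band
    across the sand range, with total Cd and sand the only true signals.
    """

    b0: float = -4.0
    b1_logcd: float = 1.0
    b2_sand: float = 0.03
    interaction_strength: float = 0.0
    sigma_noise: float = 0.4
    method_shifts: dict = field(default_factory=lambda: {
        "PBET": 0.0, "UBM": 0.0, "DIN": 0.5, "IVG": -0.5, "SBET": 0.8})
    cd_log_mean: float = -0.2   # ln mg/kg
    cd_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")
        if self.interaction_strength < 0:
            raise ValueError("interaction_strength must be non-negative")


def _bounded(rng, lo, hi, center, spread, n):
    """Truncated-normal draw strictly inside [lo, hi] (rejection)."""
    center = np.broadcast_to(np.asarray(center, dtype=float), (n,))
    out = rng.normal(center, spread)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(center[bad], spread)
        bad = (out < lo) | (out > hi)
    return out


def _texture(rng, u, n):
    """Dirichlet-type 3-part composition scaled to 100, inside the ranges.

    The gamma shape of the sand (clay) part increases (decreases) with the
    latent factor ``u``, tilting northern-style samples sandy.
    """
    a_clay = 2.2 * np.exp(-0.35 * u)
    a_silt = np.full(n, 4.6)
    a_sand = 3.2 * np.exp(0.35 * u)
    parts = np.column_stack([rng.gamma(a_clay), rng.gamma(a_silt),
                             rng.gamma(a_sand)])
    comp = 100.0 * parts / parts.sum(axis=1, keepdims=True)
    lo = np.array([PROPERTY_RANGES[k][0] for k in ("clay", "silt", "sand")])
    hi = np.array([PROPERTY_RANGES[k][1] for k in ("clay", "silt", "sand")])
    bad = ((comp < lo) | (comp > hi)).any(axis=1)
    while bad.any():
        k = int(bad.sum())
        parts = np.column_stack([rng.gamma(a_clay[bad]), rng.gamma(4.6, size=k),
                                 rng.gamma(a_sand[bad])])
        comp[bad] = 100.0 * parts / parts.sum(axis=1, keepdims=True)
        bad = ((comp < lo) | (comp > hi)).any(axis=1)
    return comp


def generate_soil_dataset(n: int, truth: GroundTruth | None = None,
                          seed: int | None = None) -> pd.DataFrame:
    """Generate ``n`` soil samples with the compiled dataset's structure.

    Returns a DataFrame with columns sample_id, region, method, the seven
    physicochemical covariates, cd_total and the gastric/intestinal
    bioaccessible Cd contents (mg/kg, both clipped to cd_total).
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)

    u = rng.normal(0.0, 1.0, n)  # latent weathering/region factor
    ph = _bounded(rng, *PROPERTY_RANGES["ph"], 7.2 + 1.3 * u, 0.9, n)
    som = np.exp(_bounded(rng, np.log(PROPERTY_RANGES["som"][0]),
                          np.log(PROPERTY_RANGES["som"][1]),
                          np.log(20.0) - 0.35 * u, 0.55, n))
    cec = np.clip(2.0 + 0.25 * som + rng.normal(0, 2.5, n),
                  *PROPERTY_RANGES["cec"])
    fe = _bounded(rng, *PROPERTY_RANGES["fe"], 30.0 - 4.0 * u, 6.0, n)
    comp = _texture(rng, u, n)
    clay, silt, sand = comp.T

    cd_total = np.exp(rng.normal(truth.cd_log_mean, truth.cd_log_sd, n))
    method = rng.choice(METHODS, size=n, p=METHOD_PROPORTIONS)
    shifts = np.array([truth.method_shifts.get(m, 0.0) for m in method])

    ln_cd = np.log(cd_total)
    eta = (truth.b0 + truth.b1_logcd * ln_cd + truth.b2_sand * sand
           + truth.interaction_strength * (ph - 7.0) * (ln_cd - truth.cd_log_mean)
           + shifts)
    noise = rng.normal(0.0, truth.sigma_noise, n) if truth.sigma_noise > 0 else 0.0
    ba_ip = np.minimum(np.exp(eta + noise), cd_total)
    gp_noise = rng.normal(0.0, 0.25, n)
    ba_gp = np.minimum(ba_ip * np.exp(0.6 + gp_noise), cd_total)

    region = np.where(u > 0.43, "north", np.where(u < -0.43, "south", "central"))
    return pd.DataFrame({
        "sample_id": [f"S{i:04d}" for i in range(n)],
        "region": region,
        "method": method,
        "ph": ph, "som": som, "cec": cec, "fe": fe,
        "clay": clay, "silt": silt, "sand": sand,
        "cd_total": cd_total,
        "ba_content_gp": ba_gp,
        "ba_content_ip": ba_ip,
    })


def degrade_dataset(samples: pd.DataFrame, missing_rate: float = 0.0,
                    n_outliers: int = 0, seed: int | None = None,
                    outlier_factor: float = 50.0,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Inject MCAR covariate missingness and gross response outliers.

    Exactly ``floor(missing_rate * n * n_covariates)`` covariate cells are
    blanked, chosen uniformly without replacement; ``n_outliers`` rows get
    their intestinal-phase content multiplied by ``outlier_factor``
    (deliberately not re-clipped to cd_total, so influence diagnostics can
    catch them). Returns (degraded copy, boolean truth mask over the
    covariate columns, list of outlier sample_ids).
    """
    n = len(samples)
    if not 0.0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    if n_outliers < 0 or (n_outliers and n_outliers >= n / 10):
        raise ValueError("n_outliers must be below n/10")
    rng = np.random.default_rng(seed)
    out = samples.copy()
    cols = list(COVARIATE_COLUMNS)
    mask = pd.DataFrame(False, index=samples.index, columns=cols)

    n_cells = int(np.floor(missing_rate * n * len(cols)))
    if n_cells:
        flat = rng.choice(n * len(cols), size=n_cells, replace=False)
        rows, jcols = np.unravel_index(flat, (n, len(cols)))
        for r, j in zip(rows, jcols):
            out.iloc[r, out.columns.get_loc(cols[j])] = np.nan
            mask.iloc[r, j] = True

    outlier_ids: list = []
    if n_outliers:
        rows = rng.choice(n, size=n_outliers, replace=False)
        loc = out.columns.get_loc("ba_content_ip")
        for r in rows:
            out.iloc[r, loc] = out.iloc[r, loc] * outlier_factor
        outlier_ids = list(samples["sample_id"].iloc[rows])
    return out, mask, outlier_ids


# Default exposure-parameter laws: synthetic stand-ins shaped like Chinese
# exposure-factor handbook entries. Tuples: (law, p1, p2, p3, lower, upper,
# units). Lognormal p1/p2 are on the ln scale.
_EXPOSURE_DEFAULTS: dict[str, dict[str, tuple]] = {
    "adult": {
        "IngR": ("lognormal", np.log(100.0), np.log(1.5), None, 10, 400, "mg/d"),
        "InhR": ("normal", 14.5, 2.0, None, 5, 25, "m3/d"),
        "EF": ("triangular", 180.0, 350.0, 365.0, 180, 365, "d/y"),
        "ED": ("uniform", 5.0, 25.0, None, 5, 25, "y"),
        "BW": ("normal", 60.8, 10.0, None, 40, 100, "kg"),
        "SA": ("normal", 5000.0, 600.0, None, 3000, 7000, "cm2"),
        "AF": ("lognormal", np.log(0.07), np.log(2.0), None, 0.007, 0.7,
               "mg/cm2"),
        "ABF": ("point", 0.001, 0.0, None, 0.001, 0.001, "-"),
        "PEF": ("point", 1.36e9, 0.0, None, 1.36e9, 1.36e9, "m3/kg"),
        "AT": ("point", 9125.0, 0.0, None, 9125, 9125, "d"),
        "BA": ("lognormal", np.log(0.15), np.log(1.8), None, 1e-4, 1.0, "-"),
    },
    "child": {
        "IngR": ("lognormal", np.log(200.0), np.log(1.6), None, 20, 1000, "mg/d"),
        "InhR": ("normal", 7.5, 1.5, None, 2, 15, "m3/d"),
        "EF": ("triangular", 180.0, 350.0, 365.0, 180, 365, "d/y"),
        "ED": ("uniform", 1.0, 6.0, None, 1, 6, "y"),
        "BW": ("normal", 19.2, 3.5, None, 10, 35, "kg"),
        "SA": ("normal", 2800.0, 400.0, None, 1500, 4500, "cm2"),
        "AF": ("lognormal", np.log(0.2), np.log(2.0), None, 0.02, 2.0,
               "mg/cm2"),
        "ABF": ("point", 0.001, 0.0, None, 0.001, 0.001, "-"),
        "PEF": ("point", 1.36e9, 0.0, None, 1.36e9, 1.36e9, "m3/kg"),
        "AT": ("point", 2190.0, 0.0, None, 2190, 2190, "d"),
        "BA": ("lognormal", np.log(0.15), np.log(1.8), None, 1e-4, 1.0, "-"),
    },
}


def generate_exposure_distributions(population: str, region: str = "national",
                                    seed: int | None = None,
                                    point_mass: bool = False,
                                    ) -> dict[str, DistributionSpec]:
    """Exposure-parameter distribution specs for one population.

    ``population`` is ``"adult"`` or ``"child"``. The laws are fixed
    synthetic defaults (the region label is recorded but does not change
    the values; per-region tables can be supplied externally through the
    same CSV schema). ``point_mass=True`` collapses every law to its
    median, which is useful for deterministic checks. The call is
    deterministic; ``seed`` is accepted for interface symmetry.
    """
    if population not in _EXPOSURE_DEFAULTS:
        raise ValueError(f"unknown population {population!r}; "
                         "expected 'adult' or 'child'")
    specs = {}
    for name, (law, p1, p2, p3, lo, hi, units) in \
            _EXPOSURE_DEFAULTS[population].items():
        spec = DistributionSpec(name, law, p1, p2 or 0.0, p3,
                                lower=lo, upper=hi, units=units)
        specs[name] = spec.as_point() if point_mass else spec
    return specs


def exposure_specs_to_frame(specs: dict[str, DistributionSpec],
                            population: str = "",
                            region: str = "national") -> pd.DataFrame:
    """Spec table in the CSV schema (parameter, population, region, law,
    p1, p2, p3, lower, upper, units)."""
    rows = []
    for name, s in specs.items():
        rows.append({"parameter": name, "population": population,
                     "region": region, "law": s.law, "p1": s.p1, "p2": s.p2,
                     "p3": s.p3 if s.p3 is not None else np.nan,
                     "lower": s.lower, "upper": s.upper, "units": s.units})
    return pd.DataFrame(rows)


def generate_property_grid(nx: int, ny: int, smoothness: float = 3.0,
                           seed: int | None = None, constant: bool = False,
                           n_region_bands: int = 3) -> GridField:
    """Spatially autocorrelated soil-property rasters inside the printed
    ranges (moving-average smoothing of white noise).

    ``smoothness`` is the half-width (in cells) of the uniform smoothing
    window; 0 gives white noise. ``constant=True`` makes every property
    flat at its range midpoint. Regions are horizontal bands (north at
    the top) so regional aggregation is exercised.
    """
    if nx < 4 or ny < 4:
        raise ValueError("grid dimensions must be at least 4")
    rng = np.random.default_rng(seed)

    def smooth_field():
        z = rng.normal(size=(ny, nx))
        w = int(round(smoothness))
        if w > 0:
            kernel = np.ones(2 * w + 1) / (2 * w + 1)
            z = np.apply_along_axis(
                lambda v: np.convolve(np.pad(v, w, mode="reflect"), kernel,
                                      mode="valid"), 0, z)
            z = np.apply_along_axis(
                lambda v: np.convolve(np.pad(v, w, mode="reflect"), kernel,
                                      mode="valid"), 1, z)
            z = (z - z.mean()) / (z.std() + 1e-12)
        return z

    shared = smooth_field()  # latent factor shared across properties
    props: dict[str, np.ndarray] = {}
    mixes = {"ph": 0.8, "som": -0.6, "cec": -0.4, "fe": -0.5}
    for name in ("ph", "som", "cec", "fe"):
        lo, hi = PROPERTY_RANGES[name]
        if constant:
            props[name] = np.full((ny, nx), 0.5 * (lo + hi))
            continue
        a = mixes[name]
        z = a * shared + np.sqrt(max(1 - a * a, 0.0)) * smooth_field()
        # map standard-normal-ish field into the central 90 % of the range
        zs = 0.5 * (1 + np.tanh(z / 2.0))
        props[name] = lo + (0.05 + 0.9 * zs) * (hi - lo)

    if constant:
        for name in ("clay", "silt", "sand"):
            lo, hi = PROPERTY_RANGES[name]
            props[name] = np.full((ny, nx), 0.5 * (lo + hi))
        tot = props["clay"] + props["silt"] + props["sand"]
        for name in ("clay", "silt", "sand"):
            props[name] = 100.0 * props[name] / tot
    else:
        # texture via softmax of latent fields, sand tilted by the shared factor
        lat = {"clay": np.log(2.2) - 0.5 * shared + 0.3 * smooth_field(),
               "silt": np.log(4.6) + 0.3 * smooth_field(),
               "sand": np.log(3.2) + 0.5 * shared + 0.3 * smooth_field()}
        w = {k: np.exp(v) for k, v in lat.items()}
        tot = w["clay"] + w["silt"] + w["sand"]
        for name in ("clay", "silt", "sand"):
            lo, hi = PROPERTY_RANGES[name]
            props[name] = np.clip(100.0 * w[name] / tot, lo, hi)

    band = np.clip((np.arange(ny)[::-1] * n_region_bands) // ny, 0,
                   n_region_bands - 1)
    labels = (_REGIONS + tuple(f"region{i}" for i in range(3, n_region_bands)))
    regions = np.repeat(np.array([labels[b] for b in band], dtype=object)[:, None],
                        nx, axis=1)
    return GridField(nx, ny, 1.0, (0.0, 0.0), props, regions)
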