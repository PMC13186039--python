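"""CSV input/output for the package's tabular interchange formats.

All files are UTF-8 with a header row, "." decimal separator, and an
empty cell for missing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .risk import DistributionSpec, ToxicityValues

__all__ = [
    "write_samples_csv", "read_samples_csv",
    "write_exposure_csv", "read_exposure_csv",
    "write_toxicity_csv", "read_toxicity_csv",
]

SAMPLE_COLUMNS = [
    "sample_id", "region", "method", "ph", "som", "cec", "fe",
    "clay", "silt", "sand", "cd_total", "ba_content_gp", "ba_content_ip",
]


def write_samples_csv(path, samples: pd.DataFrame) -> None:
    cols = [c for c in SAMPLE_COLUMNS if c in samples.columns]
    cols += [c for c in samples.columns if c not in cols]
    samples[cols].to_csv(path, index=False, encoding="utf-8")


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ("cd_total", "ba_content_ip") if c not in df.columns]
    if missing:
        raise ValueError(f"samples file lacks required column(s): {missing}")
    return df


def write_exposure_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, encoding="utf-8")


def read_exposure_csv(path, population: str | None = None,
                      region: str | None = None) -> dict[str, DistributionSpec]:
    """Load a spec table (columns parameter, population, region, law, p1,
    p2, p3, lower, upper, units) into a dict of DistributionSpec."""
    df = pd.read_csv(path, encoding="utf-8")
    if population is not None and "population" in df.columns:
        df = df[df["population"] == population]
    if region is not None and "region" in df.columns:
        df = df[df["region"] == region]
    specs = {}
    for _, row in df.iterrows():
        p3 = row.get("p3")
        specs[row["parameter"]] = DistributionSpec(
            name=row["parameter"], law=row["law"], p1=float(row["p1"]),
            p2=float(row["p2"]) if pd.notna(row.get("p2")) else 0.0,
            p3=float(p3) if pd.notna(p3) else None,
            lower=float(row["lower"]) if pd.notna(row.get("lower")) else -np.inf,
            upper=float(row["upper"]) if pd.notna(row.get("upper")) else np.inf,
            units=str(row.get("units", "") or ""))
    return specs


def write_toxicity_csv(path, tox: ToxicityValues) -> None:
    pathways = sorted(set(tox.rfd) | set(tox.sf))
    rows = [{"pathway": p, "rfd": tox.rfd.get(p, np.nan),
             "sf": tox.sf.get(p, np.nan)} for p in pathways]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_toxicity_csv(path) -> ToxicityValues:
    df = pd.read_csv(path, encoding="utf-8")
    rfd = {r["pathway"]: float(r["rfd"]) for _, r in df.iterrows()
           if pd.notna(r.get("rfd"))}
    sf = {r["pathway"]: float(r["sf"]) for _, r in df.iterrows()
          if pd.notna(r.get("sf"))}
    return ToxicityValues(rfd=rfd, sf=sf)
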