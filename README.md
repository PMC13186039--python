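# cdbiorisk

Soil cadmium bioaccessibility prediction and probabilistic human-health
risk assessment.

## The problem

Incidental ingestion of contaminated soil is a key human exposure route
for cadmium, but only the *bioaccessible* fraction — the share of total
Cd that dissolves in simulated gastrointestinal fluid (in-vitro assays
such as PBET or UBM) — can actually be absorbed. Risk assessments based
on total concentrations therefore overestimate exposure, and
deterministic exposure parameters hide the uncertainty in the result.
`cdbiorisk` is for environmental scientists and risk assessors who want
a tested, reproducible pipeline that

1. screens and cleans compiled soil bioaccessibility data
   (Kruskal–Wallis / Mann–Whitney method comparisons, random-forest
   imputation, Cook's-distance outlier removal, Spearman correlations),
2. fits predictive models of intestinal-phase bioaccessible Cd content —
   stepwise OLS and a cross-validated random forest with exact Shapley
   attribution — on the log scale,
3. maps predictions over property rasters with ordinary kriging and
   regional geometric-mean aggregation, and
4. propagates exposure-parameter uncertainty through a Monte Carlo risk
   engine with bioaccessibility adjustment and contribution-to-variance
   sensitivity analysis.

## The model

Bioaccessible content is modeled as ln(ba) = f(ln Cd_total, pH, SOM,
CEC, Fe, clay, sand) + ε; bioaccessibility is 100·ba/Cd_total ∈ (0,100].
Health risk follows the US-EPA average-daily-dose formulation, with
bioaccessibility (BA) correcting the ingestion dose:

    ADD_ing    = C·BA·IngR·CF_ing·EF·ED / (BW·AT)
    ADD_inh    = C·InhR·EF·ED / (PEF·BW·AT)
    ADD_dermal = C·SA·AF·ABF·EF·ED·10⁻⁶ / (BW·AT)

    HQ = Σᵢ ADDᵢ / RfDᵢ          CR = Σᵢ ADDᵢ · SFᵢ

Each exposure parameter carries a probability law (point / normal /
lognormal / uniform / triangular, truncated); `MonteCarloRiskModel`
samples them independently and returns per-iteration draws, summaries
(percentiles, exceedance probabilities vs HQ = 1 and CR = 10⁻⁶),
paired adjusted/unadjusted comparisons with common random numbers, and
variance contributions (normalized squared Spearman correlations).
See `docs/methods.md` for assumptions, defaults and limitations.

A synthetic-data module generates datasets with the statistical
structure of a compiled Chinese soil Cd bioaccessibility dataset
(printed property ranges, method mixture, log-linear dependence on
total Cd and sand), so the whole chain is testable without downloads.

## Worked example

```python
import numpy as np
import cdbiorisk as cb
from cdbiorisk.bioaccess import REFERENCE_OPTIMUM

samples = cb.generate_soil_dataset(126, seed=5)
frame = cb.prepare_modeling_frame(samples)
train, test = cb.split_data(frame, test_fraction=0.2, seed=5)

model = cb.BioaccessibilityModel(train)
forest = model.fit("forest", grid={k: [v] for k, v in REFERENCE_OPTIMUM.items()})
stepwise = model.fit("stepwise")

print(stepwise.selected_predictors)   # ['log_cd_total', 'sand']
print(forest.feature_importances().round(3).head(3))
# log_cd_total    0.830
# sand            0.082
# fe              0.026
```

The stepwise model recovers exactly the two generating predictors, and
total Cd dominates the forest's importances (83 % here). Feeding the
predicted bioaccessibility into the risk engine for a child receptor:

```python
_, percent = forest.predict_bioaccessibility(samples)
ba_spec, report = cb.fit_lognormal(percent / 100, name="BA")

specs = cb.generate_exposure_distributions("child")
specs["C"] = cb.DistributionSpec("C", "lognormal", np.log(1.2), 0.5,
                                 lower=1e-3, upper=1e4)
specs["BA"] = cb.DistributionSpec("BA", "lognormal", ba_spec.p1,
                                  ba_spec.p2, lower=1e-4, upper=1.0)
res = cb.run_monte_carlo(specs, cb.DEFAULT_TOXICITY, n_iter=10_000, seed=1)
print(res.summary())
#       mean       sd  cv_percent   ...      p95  threshold  p_exceed
# HQ 0.00138  0.00146         106   ...    0.004          1         0
# CR 2.4e-06 2.68e-06         112   ... 7.18e-06      1e-06     0.673

cmp_ = cb.compare_adjustment(specs, cb.DEFAULT_TOXICITY, specs["BA"],
                             n_iter=10_000, seed=1)
print(cmp_[["mean_ratio", "p95_decrease_percent"]])
#     mean_ratio  p95_decrease_percent
# HQ        6.28                  83.2
# CR       19.5                   94.5
```

Read: the child hazard quotient stays far below 1 (mean 1.4×10⁻³), the
95th-percentile carcinogenic index is 7.2×10⁻⁶, and replacing the
conventional BA = 1 assumption with the fitted bioaccessibility law
lowers the mean HQ 6.3-fold and its 95th percentile by 83 % — the
quantitative case for bioaccessibility-adjusted assessment. (These
numbers use the package's synthetic exposure and toxicity defaults;
swap in measured tables for a real site.)

The same chain runs end to end from the shell:

```sh
cdbiorisk run --seed 1 --out runs/demo         # six stages, manifest, logs
cdbiorisk simulate --seed 1 --out runs/demo    # or stage by stage
```

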