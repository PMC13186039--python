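# Methods

This note documents the models and procedures implemented in `cdbiorisk`,
the assumptions behind them, the synthetic data they are exercised on, and
the numerical and design choices that were genuinely open.

## Problem setting

Only the fraction of soil cadmium that dissolves in simulated
gastrointestinal fluid — the *bioaccessible* fraction — is available for
human uptake after incidental soil ingestion. Risk assessments built on
total Cd concentrations therefore overestimate exposure. The package
implements a chain of five components: (1) a synthetic-data generator for
compiled soil bioaccessibility datasets, (2) screening statistics and
cleaning, (3) predictive models of intestinal-phase bioaccessible Cd
content, (4) ordinary-kriging spatial prediction with regional
aggregation, and (5) a Monte Carlo health-risk engine in which
bioaccessibility corrects the ingestion dose.

## Synthetic data generator

The generator is first-class, tested code: it defines the study
conditions every downstream stage is validated under.

**Soil properties.** Each sample carries pH, soil organic matter (SOM,
g/kg), cation-exchange capacity (CEC, cmol(+)/kg), iron (g/kg) and a
clay/silt/sand composition (percent). Properties are drawn from truncated
laws strictly inside the ranges of the compiled dataset the generator
emulates (pH 3.01–11.37, SOM 0.17–131.03 g/kg, clay 0.02–44.43 %, silt
10.82–78.26 %, sand 2.30–89.16 %; CEC and Fe use plausible ranges of
2–45 cmol(+)/kg and 5–65 g/kg since their extremes are not part of that
summary). A shared standard-normal latent factor `u` (a
"weathering/region" axis) induces realistic cross-correlations: high-`u`
samples are sandier, more alkaline, organic-poorer and iron-poorer, the
pattern that distinguishes northern from southern Chinese soils. This
latent structure is what makes random-forest imputation of missing
covariates meaningfully better than a column median.

**Texture.** The three-part composition is built from gamma draws
(a Dirichlet-type construction) renormalized to 100, with the sand and
clay shape parameters tilted by `u`; draws outside the printed
per-component ranges are rejected and redrawn. The sum-to-100 invariant
holds exactly by construction.

**Response.** Intestinal-phase bioaccessible Cd content follows a
log-linear law:

    ln(ba_ip) = b0 + b1·ln(cd_total) + b2·sand
                + s·(pH − 7)(ln cd_total − μ_lncd)
                + shift(method) + ε,   ε ~ N(0, σ²)

with defaults b0 = −4, b1 = 1, b2 = 0.03, s = 0 and σ = 0.4, and the
result capped at `cd_total`. These defaults place the bioaccessible
fraction in roughly the 2–55 % band across the sand range and make total
Cd and sand the only true predictors — the configuration the stepwise
recovery tests assume. The interaction strength `s` is the dial for
nonlinearity; the model-ordering tests use s = 0.8, chosen so the pH×Cd
interaction term (sd ≈ 1.2 log units over the covariate ranges) is of
the same order as the main effect — a strong-interaction regime in which
a flexible learner should visibly beat a linear one, mirroring the
qualitative sign-reversal behaviour of pH effects between low- and
high-Cd soils that motivates nonlinear modeling in this problem class.
With σ = 0 and s = 0 the law is exactly affine in (ln cd, sand) and OLS
refitting recovers (b0, b1, b2) to machine precision, which the tests
assert.

**Methods.** In-vitro extraction labels are multinomial with the
compiled mixture (PBET 73.3 %, UBM 15.8 %, DIN/IVG/SBET sharing 10.9 %).
Log-scale offsets are 0 for PBET and UBM and {+0.5, −0.5, +0.8} for
DIN/IVG/SBET, so a Kruskal–Wallis test across methods rejects while the
PBET-vs-UBM Mann–Whitney comparison does not — the screening outcome the
preprocessing stage is designed around.

**Degradation.** `degrade_dataset` injects exactly
⌊rate·n·n_covariates⌋ missing-completely-at-random covariate cells
(chosen without replacement) and multiplies the response of selected
rows by a gross factor (default ×50, deliberately not re-capped at
`cd_total`) so that Cook's distance — a response-influence measure — is
the appropriate detector. Truth masks and outlier ids are returned for
scoring.

**Exposure parameters.** Per-population tables for IngR, InhR, EF, ED,
BW, SA, AF, ABF, PEF, AT and BA use point/normal/lognormal/uniform/
triangular laws with truncation. They are synthetic stand-ins shaped
like Chinese exposure-factor handbook entries (e.g. adult IngR lognormal
median 100 mg/d, child 200 mg/d; adult BW normal 60.8 kg, child
19.2 kg); the two constraints that drive the child-vs-adult risk
ordering — child IngR median above the adult's, child BW median below —
hold by construction. AT is a point mass at the upper truncation of
ED·365 for each population, so averaging time always covers the
exposure duration. Region labels are recorded but do not alter the
default values; per-region tables can be supplied through the same CSV
schema and should replace these defaults for any real assessment.

**What the generator does not emulate:** intra-regional hotspots,
non-random missingness, method-by-property interactions, measurement
error in total Cd, spatially clustered sampling. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not predictive validity on real compiled data.

## Preprocessing

* **TOC→SOM**: SOM = TOC / 0.58 (van-Bemmelen convention, in which
  organic matter is 58 % carbon). The factor is an argument.
* **Kruskal–Wallis / Mann–Whitney**: scipy implementations with midrank
  tie handling; the Mann–Whitney p-value is computed by exact
  enumeration over all assignments when n_x·n_y ≤ 100 (so identical
  samples give p = 1 exactly) and otherwise by the tie-corrected normal
  approximation *without* continuity correction, which makes the
  two-group Kruskal–Wallis chi-square p-value coincide with it — an
  invariant the tests check.
* **Imputation**: single-completion iterative random-forest imputation
  (missForest-style): initialize with column medians, update columns in
  increasing-missingness order, stop when the relative change of imputed
  values falls below `tol` (default 1e-3) or `max_iter` (default 5).
  Response columns are excluded; observed cells are never altered.
  Multiple completions can be obtained by calling with different seeds.
* **Influence filtering**: one OLS fit of ln(ba_ip) on the available
  covariates (total Cd entering as its natural log), Cook's
  D_i = (e_i²/(p·s²))·(h_ii/(1−h_ii)²) via statsmodels, rows with
  D_i > 1 removed. The tests verify D_i against the leave-one-out
  definition Σ_j(ŷ_j − ŷ_j(i))²/(p·s²) to 1e-8.
* **Spearman matrix**: pairwise-complete midrank correlations with
  significance stars at 0.05 / 0.01; constant columns yield an undefined
  cell with a warning.

## Bioaccessibility models

Both models work on the log scale: the response and total Cd are
natural-log transformed, other covariates untransformed. The default
candidate set is {ln Cd, pH, SOM, CEC, Fe, clay, sand}; silt is left out
of the default design because the three texture shares are closed
(sum = 100) and including all three makes the OLS design singular.

**Stepwise OLS.** Forward entry of the candidate with the smallest
partial-F p-value if below `alpha_enter` (0.05), then backward removal
of any retained predictor with p ≥ `alpha_remove` (0.05), iterated to a
fixpoint. The procedure is deterministic and stops early at a
numerically perfect fit. If nothing enters, an intercept-only model is
returned with a warning. Note the family-wise consequence of per-step
α = 0.05 testing: with m irrelevant candidates the probability of
recovering the true set exactly is ≈ 0.95^m, which is why the recovery
tests use the three-variable correlation-screened candidate set.

**Random forest.** scikit-learn `RandomForestRegressor` tuned by a
hand-rolled grid search with shuffled k-fold (default 5) cross-validation
maximizing mean fold R²; ties break toward the smaller ensemble, then
earlier grid order, making selection fully deterministic under a seed.
The reference optimum for this problem class (n_estimators = 100,
max_depth = None, max_features = 7, min_samples_leaf = 2,
min_samples_split = 6) is available as `REFERENCE_OPTIMUM`; `max_features`
is interpreted as "candidate features per split" and capped at the
number of available covariates.

**Metrics.** R² = 1 − SS_res/SS_tot and RMSE, both on the modeling (log)
scale, reported per split plus the CV R². Back-transformation of
predictions is a plain `exp` (no smearing correction); predicted content
is capped at total Cd, so the derived bioaccessibility percentage lies
in (0, 100].

**Attribution.** Shapley values use the interventional value function
(coalition features from the explained sample, the rest from a
background sample) computed *exactly* per tree: every leaf is a box of
per-feature intervals; classifying each constrained feature of a leaf as
satisfied-by-x-only, by-z-only, by both or by neither collapses the
2^k-coalition sum into a closed-form weight that depends only on the two
counts, evaluated with exact rational arithmetic. Local accuracy
(baseline + Σφ = prediction) holds to machine precision, and the tests
confirm equality with brute-force coalition enumeration to 1e-8.
Impurity-decrease importances are normalized to sum to one.

## Spatial mapping

The empirical semivariance uses the Matheron estimator on equal-width
lag bins; a spherical (default), exponential or gaussian family is
fitted by least squares weighted by pair counts, with the
effective-range convention for the exponential and gaussian curves. The
spherical default reflects common practice where the original
interpolation settings are unreported. Ordinary kriging solves the
standard system with the Σλ = 1 constraint; γ(0) is taken as 0 at
exactly zero lag, so the interpolator is exact at data locations when
the nugget is zero. Duplicate locations are averaged with a warning; a
`max_neighbors` cutoff switches to per-target local systems for large n.
Coordinates are planar Cartesian cell centers; CRS handling is out of
scope.

National-scale mapping follows predict-then-(optionally)-krige: each
cell's covariates come from the property rasters and its total Cd from
the regional geometric mean; bioaccessibility percent is derived per
cell, nodata propagates, and regional geometric means
(exp(mean(ln x)), CV = 100·sd/mean) summarize the map. An optional
kriging pass smooths the percent surface from a thinned cell subsample.

## Risk engine

Average daily doses for ingestion, inhalation and dermal contact follow
the US-EPA formulas given in the module docstring, with bioaccessibility
(a fraction in (0, 1]; percent inputs are divided by 100 at the
interface) multiplying only the ingestion dose. A configurable `CF_ing`
(default 1e-6 kg/mg for IngR in mg/d) makes the ingestion dose
dimensionally consistent; setting it to 1 reproduces the bare textbook
formula. HQ sums ADD_i/RfD_i over pathways with a reference dose; CR
sums ADD_i·SF_i over pathways with a slope factor; pathways without
toxicity values are excluded from the respective sums. The bundled
toxicity defaults (oral RfD 1e-3, inhalation RfD 1e-3, dermal RfD
2.5e-5 mg/(kg·d); oral SF 6.1, inhalation SF 6.3 kg·d/mg) are commonly
used literature values standing in for study-specific tables.

Monte Carlo propagation samples every parameter independently (no
cross-parameter correlation — matching the default behaviour of the
spreadsheet tools this replaces; correlated inputs are future work) from
one seeded generator in a fixed parameter order, truncating by rejection
(an error is raised if the rejection rate exceeds 99 %). Default
10,000 iterations. Summaries report moments, CV %, percentiles (linear
interpolation between closest ranks) and exceedance probabilities
against HQ = 1 and CR = 1e-6. The carcinogenic result is a
scenario-comparison index, not a lifetime risk: AT is not forced to a
70-year convention and is configurable through the spec table.

`compare_adjustment` runs the paired unadjusted (BA ≡ 1) and adjusted
(BA ~ fitted law) analyses on *literally the same draws* (common random
numbers), so a point-mass BA = 0.2 yields exactly fivefold mean and P95
reductions and a stochastic BA ≤ 1 can never increase a percentile.
Sensitivity uses contribution to variance: squared Spearman rank
correlations of each input with the output, normalized to 100 %, with
signs reported separately; constant inputs contribute zero with a
warning.

## Problem sizes used in the tests and acceptance script

Modeling runs use n = 126 samples (80/20 split → 101/25), mirroring the
refined-dataset scale this analysis is designed for; rate estimates use
100 generator seeds; Monte Carlo runs use 10,000 iterations; the mapping
fixture is a 24×24 grid with three region bands; imputation checks use
n = 120 with 10 % missingness and reduced forest settings
(30 trees, 3 iterations). These sizes were chosen as the smallest at
which the estimated rates and quantiles are stable.

## Known limitations

* The exposure-parameter and toxicity defaults are synthetic stand-ins;
  all headline risk magnitudes computed from them characterize the
  engine, not any real region.
* Stepwise selection inherits the usual per-step type-I behaviour;
  it is provided for comparison, not as the recommended model.
* The exact Shapley implementation is O(leaves · n · n_background) per
  tree and is intended for moderate explanation sets (tens of samples),
  not whole-dataset attribution.
* Kriging assumes second-order stationarity and planar coordinates;
  anisotropy and geodesic distances are not modeled.
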