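# hexinvade

Invasion-risk modelling for the emerald ash borer (EAB, *Agrilus
planipennis*) — and, more generally, for any invasive forest pest whose
occurrence records live on a regular spatial grid. The package implements a
complete, reproducible version of the standard survey-to-risk-map workflow:
binary presence/absence responses on a 1-km² hexagonal tessellation, a
lagged dispersal-kernel "infestation pressure" predictor, logistic
model selection across driver groups, a six-algorithm species-distribution
model (SDM) comparison scored by the True Skill Statistic with a
committee-averaging ensemble, permutation variable importance, and
projection of risk onto uninvaded regions. Because real EAB survey data are
not public, a synthetic stratified-dispersal simulator with known truth is a
first-class part of the package: every stage is exercised and validated
end-to-end on simulations.

Intended users: quantitative ecologists and forest-health analysts building
or auditing pest risk models, and methodologists who need a transparent,
fully seeded reference implementation of the kernel + logistic + SDM-ensemble
pipeline.

## The model

**Infestation pressure (the `spatial` term).** For hexagon *i* in year *t*,

```
Spatial_i(t) = Σ_k exp(−d_ik^a)        (form "power"; exp(−d_ik/a) available)
```

where the sum runs over every hexagon *k* recorded infested in year *t−1* or
*t−2* within a cutoff radius (one term per lag year), and `d_ik` is the
great-circle distance between centroids standardized to [0, 1] by the
cutoff. The shape parameter `a` reweights the kernel: small `a` concentrates
colonisation potential near sources, large `a` (power form) flattens it so
distant infestations weigh relatively more. `a` is chosen from {1, 3, 5, 10}
by AIC of single-predictor logistic fits.

**Occurrence model.** Presence/absence of hexagon-years follows a logit
model

```
logit P(y_i = 1) = β0 + β1·Spatial_i + Σ_j βj x_ij
```

with habitat, transport/human-activity, host and climate covariates x_j.
Candidate models are screened for collinearity (pairwise |r| < 0.75, VIF <
5), reduced by backward elimination on AIC, and compared via ΔAIC and Akaike
weights.

**Multi-model stage.** The predictors of the best logistic model feed six
learners — GLM, MARS, ANN, CTA, GBM, RF — fitted on balanced
presence/pseudo-absence sets (all training presences + an equal random
absence draw, 10 sets × 3 cross-validation runs = 180 model runs), each
binarised at its TSS-maximising calibration threshold and scored by

```
TSS = sensitivity + specificity − 1  ∈ [−1, 1].
```

Runs with validation TSS > 0.6 form a committee ensemble: each member votes
its thresholded binary prediction and the majority label is the consensus
(ties conservatively resolve to absence; the vote fraction is always
reported). Permutation variable importance is `1 − corr(predictions,
predictions after shuffling one predictor)`.

## Worked example

```python
from hexinvade import (LandscapeConfig, simulate_study, PressureConfig,
                       pressure_surface, select_kernel_shape, balanced_design,
                       backward_eliminate, make_split_plan, run_zoo)
from hexinvade.glmselect import build_design
from hexinvade.zoo import runs_table

cfg = LandscapeConfig(seed=42)              # 40×40 km landscape, 12 years
study = simulate_study(cfg)                 # predictors + invasion + surveys
occ = study.occurrences

base = PressureConfig(a=1.0, cutoff_m=cfg.cutoff_m, lags=cfg.lags)
best_a, fits = select_kernel_shape(occ, study.grid, (1, 3, 5, 10), base)
print("kernel-shape AICs:", {a: round(f.aic, 1) for a, f in fits.items()})

surf = pressure_surface(occ, study.grid, PressureConfig(a=best_a,
                        cutoff_m=cfg.cutoff_m, lags=cfg.lags),
                        sorted(occ.year.unique())[2:])
design = build_design(occ[occ.year.isin(surf.year.unique())], surf,
                      study.predictors)
final = backward_eliminate(balanced_design(design, seed=42), keep=("spatial",))
print(final.coefficient_table().round(3))
```

prints (seed 42):

```
occurrence rows: 2394, presences: 237
kernel-shape AICs: {1.0: 696.5, 3.0: 699.9, 5.0: 703.7, 10.0: 706.5}
selected a: 1.0
            term  estimate    se      z     p  odds_ratio  or_ci_low  or_ci_high
           const   -13.403 3.417 -3.923 0.000       0.000      0.000       0.001
         spatial     1.162 0.246  4.731 0.000       3.195      1.975       5.171
            elev    -0.005 0.003 -1.699 0.089       0.995      0.990       1.001
           ...
        deg_days     0.009 0.003  3.290 0.001       1.009      1.004       1.015
```

The generating kernel (a = 1) wins the AIC screen; the fitted signs match
the generating model — pressure from lagged neighbourhood infestations and
warm-season degree-days raise the odds of presence, elevation lowers them.
An odds ratio of 3.195 for `spatial` means each unit of infestation pressure
roughly triples the odds of detecting the beetle. Continuing into the
multi-model stage,

```python
cols = ["hex_id", "year", "presence"] + list(final.feature_names)
plan = make_split_plan(design[cols].reset_index(drop=True), seed=42,
                       n_absence_sets=2, n_cv=1)
runs = run_zoo(plan, design[cols].reset_index(drop=True), families=("GLM", "RF"))
print(runs_table(runs).groupby("family")[["tss_validation", "tss_evaluation"]].mean())
```

```
        tss_validation  tss_evaluation
GLM              0.738           0.698
RF               0.768           0.756
```

both families clear the TSS > 0.6 "good model" bar, with the random forest
slightly ahead — the typical ordering on these data.

## Command line

```bash
hexinvade simulate --seed 42 --outdir sim/           # synthetic scenario
hexinvade pressure --occ sim/occ.csv --grid sim/grid.geojson \
                   --a 1 --cutoff-km 3 --out spatial.csv
hexinvade run --config pipeline.yaml                 # full pipeline
hexinvade project --runs run/ --predictors region.csv --zero-spatial
```

`run` executes simulate/ingest → pressure → model selection → model zoo →
ensemble (→ projection) from one YAML config and writes plain CSV/JSON
artifacts plus a manifest of seeds and checksums; reruns with the same
config are byte-identical. `project` forecasts a new region, setting the
pressure term to zero where no infestation is recorded within the kernel
cutoff — the treatment used for risk forecasts in uninvaded cities.

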