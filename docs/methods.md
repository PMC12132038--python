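# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the known limits of what the test suite demonstrates.

## Grid and response

The analysis unit is a flat-top hexagon of configurable area (default
1 km²). The lattice is constructed in a local spherical Lambert azimuthal
equal-area projection centred on the study bounding box; an equal-area
projection is what the 1-km² property actually requires, and on a sphere the
projection preserves areas exactly, so every cell has the target area to
floating-point precision. Hexagons are the Voronoi cells of their centroids,
which makes point-to-hexagon assignment an exact nearest-centroid query;
ties on shared edges resolve to the lower hexagon id. Ids are assigned
row-major. Distances between centroids are haversine great-circle distances
on the IUGG mean-radius sphere (R = 6,371,008.8 m); ellipsoidal distances
differ by under 0.5%, which is immaterial relative to a 300-km kernel
cutoff, and the spherical form is dependency-free and easy to test.

Detection records aggregate to a binary hexagon-year response by the
any-detection rule: presence if any record in the hexagon-year is positive,
absence if the hexagon-year was surveyed with only negative records.
Hexagon-years never surveyed produce no row at all — absence means
"surveyed, not detected", never "no data". Landcover is dichotomised: 1 for
urban/built-up and medium-density mixed needle-leaved cold deciduous forest,
0 for every other class in the vocabulary.

## Infestation pressure

For hexagon *i* in year *t* the pressure term sums a negative-exponential
kernel over every hexagon recorded infested in years *t−1* and *t−2* within
the cutoff (default 300 km), with centroid distances standardized to [0, 1]
by the cutoff — the cutoff is the only length scale in the model, so it is
also the natural standardizer. The kernel has two functional forms,
`exp(−d^a)` (default, "power") and `exp(−d/a)` ("scale"); the power form is
the default because it reproduces the intended behaviour of the shape
parameter — on standardized distances in (0, 1), raising `a` raises the
kernel value, giving relatively more weight to far sources. A hexagon
infested in both lag years contributes one term per lag year, and a
hexagon's own lagged infestation contributes exp(0) = 1 per lag year. Years
whose lag years precede the data raise an insufficient-history error rather
than silently treating missing years as uninfested.

The indexed implementation (KD-tree over source centroids on the unit
sphere) is equality-tested (1e-10) against a literal all-pairs double loop.

## Synthetic data generator

The generator emulates the statistical structure of multi-source detection
survey data for an invading wood-borer:

* **Landscape.** Fourteen predictor surfaces (elevation, slope, aspect,
  road/rail length, stations, campgrounds, park cover, population density,
  crown closure, treed and broad-leaf fractions, degree-days > 10 °C,
  coldest-quarter mean temperature) are generated as Gaussian-smoothed white
  noise rescaled to realistic supports, with per-predictor autocorrelation
  ranges; counts are quantized from the smoothed fields so they are sparse
  and clustered; the urban landcover flag is the top 15% of the population
  field, so towns cluster.
* **Invasion.** Colonisation is a discrete-time hazard: an uninfested
  hexagon colonises with probability
  `inv_logit(β0 + βs·Spatial + Σ βj z_j)`, where Spatial uses the true
  kernel and z are standardized predictors whose coefficients carry the sign
  structure the field expects (pressure, population density, degree-days,
  slope, crown, urban landcover positive; elevation, campgrounds negative).
  Infested hexagons never recover. Long-distance human-assisted jumps arrive
  as a Poisson stream (default 0.5/yr) at uniformly random hexagons — the
  jump frequency is a scenario parameter, not an estimate. Epicenters are
  seeded as a cell plus its neighbour ring, since a lone infested cell
  rarely ignites a front under a sharp colonisation threshold.
* **Observation.** Each year, infested hexagons not yet confirmed are
  surveyed and detected with probability 0.9; once detected, a hexagon
  contributes no further rows (delimitation surveys move on), though
  re-surveying every year is available as an option (`resurvey_detected`),
  under which perfect detection and full survey coverage reproduce the
  latent table exactly. A 12% sample of uninfested hexagons is recorded
  absent each year. Infested-but-missed hexagons appear as false absences —
  imperfect detection is part of the emulation.

**Scale.** The default scenario is a 40×40 grid over 12 years — about 2,400
occurrence rows with roughly a 7% presence share, matching the strong class
imbalance of real survey tables; it runs in under a second. The kernel
cutoff defaults to 3 km in this scenario: the full-scale analysis uses
300 km on a landscape an order of magnitude wider than the cutoff, and the
toy landscape keeps that cutoff-to-extent ratio so standardized distances
span (0, 1] rather than collapsing near zero. The generator's defaults were
fixed once — the intercept (−7.25) and spatial coefficient (0.5) by a
prevalence calculation across seeds — and are not tuned per test.

**What the simulator does not emulate.** Survey effort is spatially uniform
rather than front-targeted; predictors are static over years (no annual
weather); there is no eradication, quarantine or management feedback; jumps
are uniform rather than traffic-weighted. Passing tests therefore
demonstrate correctness of the machinery and recoverability of parameters
under the stated generating process, not performance on real survey data.

## Kernel-shape identifiability

A genuine finding from building the simulator: once an invasion forms a
contiguous front, the candidate pressure surfaces for different shape values
are almost perfectly collinear (correlations ≈ 0.997 on the default
scenario), because pressure at any cell is dominated by the mass of the
adjacent cluster, which every kernel shape weighs similarly. No selection
criterion can separate the shapes from such data. The kernel-shape recovery
experiment (`simulate_colonization_trial`) therefore uses the design that
does identify the shape: independent yearly cohorts of scattered nascent
foci whose surrounding cells colonise by the true-kernel hazard, so events
sample the kernel profile across the whole standardized-distance range. At
~2,000 rows the AIC screen recovers a generating shape of 1 or 10 in ≥ 16 of
20 seeded replicates. For real analyses this implies the fitted shape is
informed mostly by satellite colonisations, not by the saturated core.

## Logistic model selection

Fits are maximum likelihood with a logit link via iteratively reweighted
least squares (statsmodels GLM; tolerance 1e-8, 100 iterations), verified
against direct numerical maximisation of the Bernoulli likelihood.
AIC = 2·K − 2·LL where K counts every estimated coefficient *including the
intercept*; published tables sometimes print K as the predictor count only —
the constant offset cancels in ΔAIC, which is what all comparisons use.
Likely complete separation (|β| > 15 or non-finite SEs) flags the fit
non-converged rather than raising: quasi-separation is expected when the
pressure term saturates near invasion cores. Confidence intervals are Wald
with the 1.96 multiplier; coverage of the generating coefficients is
verified by simulation (measured ≈ 0.94–0.955 per coefficient).

Collinearity screening drops, for each pair with |r| ≥ 0.75, the member
whose single-predictor model has the larger AIC, then iteratively drops the
largest VIF ≥ 5 (VIF from least-squares R²). Backward elimination considers
single-term deletions, never touches protected terms (the pressure term),
and stops when no deletion lowers AIC. Balanced designs pair all presences
with an equal-size seeded uniform draw of surveyed absences; a spatially
stratified draw (proportional allocation over coarse row/column blocks) is
provided for geographically skewed tables. Degenerate pressure columns with
no variation fall back to the intercept-only model, so a shape screen over a
sourceless landscape ties and resolves to the smallest candidate.

## Multi-model stage

The model families are thin adapters over established learners with fixed,
logged hyperparameters: unpenalised logistic regression; MARS written
in-package (greedy forward selection of reflected hinge pairs on marginal
quantile knots, backward pruning by GCV with penalty 3, predictions clipped
to [0, 1]); a one-hidden-layer (8-unit) perceptron on standardized inputs;
a cost-complexity-pruned decision tree (α = 0.01); gradient boosting (1,000
trees, learning rate 0.01); random forest (500 trees). Each (family,
absence-set, CV) run fits on a 70% calibration slice, takes the
TSS-maximising threshold from calibration predictions (candidate thresholds
are midpoints of sorted unique predictions plus {0, 1}; ties to the smallest),
and reports TSS on the 30% validation slice and on the held-out evaluation
table (evaluation presences plus an equal seeded absence draw). Exceptions
are contained as failed runs — a failed run is data, not an abort.

Committee ensembles take all runs with validation TSS above 0.6, each voting
its thresholded binary prediction; consensus is presence only when the vote
fraction strictly exceeds ½. Exact ties resolve to absence — conservative
for risk maps — and the vote fraction is always reported so users can
re-threshold. Family comparison uses one-way ANOVA on TSS plus pairwise
Welch t tests with Holm adjustment; with one fixed factor this matches
least-square-means contrasts in the balanced case. Permutation importance
shuffles one predictor (6 repetitions by default), and defines VI = 0 when
predictions are constant (std < 1e-12) since the correlation is degenerate;
negative correlations clamp VI at 1. Marginal response curves hold the other
continuous predictors at training medians and landcover at 0.

Every random draw — splits, absence sets, CV slices, learner seeds,
shuffles — derives from one master seed through fixed `SeedSequence`
spawn keys, so the entire pipeline is byte-reproducible.

## Pipeline

Stages (data, pressure, design, glmselect, zoo, ensemble, optional
projection) each write plain CSV/GeoJSON/JSON artifacts so any stage can be
re-entered; the manifest records the seed, per-stage record counts and
SHA-256 checksums of every artifact, and contains nothing
machine-dependent, so identical configs give identical manifests. Wall-clock
timings go to a separate log. No binary model objects are persisted; the
projection CLI re-fits members from the logged seed. Projection to an
uninvaded region forces the pressure column to zero — the standard treatment
when no detection is recorded within the kernel cutoff of the target region.

The default simulated scenario runs the full pipeline, including the
6 × 10 × 3 factorial, in a few minutes on one CPU; the test suite uses
smaller grids (15–25 cells a side) and reduced factorials where the full
sizes add nothing to the property under test.

## Known limitations

* The pressure term treats detection-based occurrence rows as the source
  set, as survey data require; sources infested but detected in earlier
  years than the lag window are invisible to the fitted kernel, which
  attenuates shape estimates on persistent-invasion data (see the
  identifiability note above).
* Wald intervals and AIC comparisons assume independent Bernoulli responses;
  hexagon-years from one invasion are spatially and serially dependent, and
  the pressure term absorbs only part of that dependence. Mixed-effects or
  autologistic variants are out of scope.
* MARS here is an additive hinge-basis approximation fitted by least squares
  on the binary response; it reproduces the family's qualitative behaviour
  but is not a drop-in for any particular reference implementation.
* The committee ensemble produces binary votes and vote fractions, not
  calibrated probabilities.
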