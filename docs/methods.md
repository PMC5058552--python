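# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `encroach`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Raster model and focal statistics

Grids are planar (no projection support): a 2D value array, a boolean
nodata mask, a square cell size in metres (default 25 m), and the
lower-left-corner origin. Cell centres sit at `origin + (i + 0.5) * cell`,
with row 0 at the south edge; point-to-cell lookups use this convention
throughout.

Focal statistics use a circular window whose membership rule is
centre-to-centre distance ≤ radius, ties included; at the default 100 m
radius on 25 m cells this is a fixed 49-cell neighbourhood. Windows are
clipped at grid edges and around masked cells: means, proportions and
densities are always normalized by the cells actually available, so edge
cells are estimated from their clipped windows rather than padded. A window
with no available cell yields a masked output cell. Densities divide the
window sum by available-cell count × cell area (hectares), i.e. the same
clipped-window convention.

Terrain: slope from central-difference gradients; aspect is the direction
of steepest **descent** measured clockwise from north, so
NORTH = cos(aspect) = −(∂z/∂y)/|∇z| and EAST = sin(aspect); flat cells get
NORTH = EAST = 0 by convention. Roughness is the focal (population) standard
deviation of elevation. PC1 standardizes bands to zero mean and unit
variance before the eigendecomposition and fixes the sign so the first
retained band loads non-negatively; constant bands are excluded with a
warning. Simpson diversity renormalizes the five vegetation proportions per
cell and is defined as 0 where all proportions vanish, keeping the layer
defined on bare ground.

I/O: ESRI ASCII grids (text; `%.17g` makes the round trip bit-exact for
float64) and single-band TIFF with cell size/origin/nodata carried in the
ImageDescription tag. No CRS handling — coordinates are metres in an
arbitrary planar frame.

## Synthetic landscapes

The generator emulates a treeline study area so that every downstream stage
can be scored against known truth.

- **Fields.** Stationary ~N(0,1) random fields by frequency-domain Gaussian
  filtering of white noise (autocorrelation range in metres; periodic
  boundary, irrelevant at the scales used). The DEM is 2050 ± 250 m
  (clipped to 1600–2500 m) with a 600 m range; covariate fields use a 200 m
  range, i.e. vegetation patches a few hundred metres across.
- **Vegetation truth.** Utilities for the six classes are a known linear
  map of three covariate fields plus standardized elevation, times a
  utility scale of 2; classes are *sampled* from the softmax (Gumbel-argmax)
  — the truth map is therefore itself a draw from the multinomial model the
  classifier estimates, which is what makes coefficient recovery a
  well-posed check. Forest recedes strongly with elevation. Default class
  shares are roughly pasture 22%, alder 15%, the three heathlands 8–14%
  each, forest 25%, with ~5% of the map masked as rock/glacier.
- **Planted patches.** Optional discs (class, centre, radius) are stamped
  into the truth map as the last step of map construction; spectral bands
  and the true suitability are computed from the stamped map, and the exact
  disc cells are recorded for recovery scoring.
- **Spectral bands.** Four reflectance archetypes per class (chosen so
  pasture is bright with high NIR, conifer forest dark, alder high-NIR
  deciduous), plus a mild elevation trend and Gaussian noise
  (SD 0.035 ≈ 2–6 class-separation SDs — the "good to excellent accuracy"
  regime).
- **True suitability.** The product of Gaussian kernels on the 100 m focal
  cover of the five non-forest vegetation types (optima: pasture 0.25,
  *Rhododendron* 0.30, juniper 0.10, mixed 0.50, alder 0.27 — the 10–50%
  range of field knowledge for breeding black grouse), a dense-forest
  kernel (optimum 0.20 — the ecotone), a June-temperature kernel (optimum
  10.5 °C, width 1.3 °C), and an increasing Simpson-diversity term
  (exp(1.5·SIDI)); scaled to [0, 1].
- **Sampling.** 600 training plots (labels = truth) drawn from cells whose
  single-class connected component covers at least 625 m², one per cell;
  67 breeding presences by rejection sampling proportional to true
  suitability, jittered by ≤ 100 m with the jitter magnitude recorded as
  the record's precision. The presence sampler consumes randomness in
  fixed-size proposal chunks so that scenes differing only locally (planted
  discs) share the rest of their proposal stream — common random numbers
  for scenario comparisons; the sampling distribution is unchanged.

What the generator does **not** emulate: real sensor radiometry and
atmospheric effects, seasonal time series, spatial sampling bias in the
occurrence data, observer error in plot labels, and landscape features
(roads, settlements, single trees) that influence the true suitability —
the infrastructure layers exist as predictors but carry no signal. Passing
tests therefore demonstrate internal statistical correctness and
recoverability under the stated generative law, not performance on real
remote-sensing data.

## Vegetation model

Multinomial logit over internally standardized predictors with a tiny ridge
(1e-6 on standardized coefficients; C = 1/(2·ridge) in the underlying
scikit-learn solver) for stability under quasi-separation; coefficients are
reported on the original scale in the reference-class parameterization
(alder pinned at zero). AIC = 2k − 2 lnL with k = (classes−1)(predictors+1).

Collinearity screening removes, from each pair with Spearman |r_s| > 0.7,
the predictor with the **higher univariate AIC** (the operationalization of
"lower explanatory power"); the loop repeats until no retained pair
violates the threshold. Stepwise backward selection removes the predictor
whose removal most lowers AIC until no removal lowers it.

Per-class evaluation is one-vs-rest on the class probability: Cohen's kappa
maximized over the threshold grid 0, 0.005, …, 1 (smallest maximizing
threshold on ties; the fine grid matches thresholds reported to three
decimals), rank-based AUC (ties ½), and sensitivity at the Kappa-max
threshold. Cross-validation is stratified by class (folds reduced with a
warning if a class is rarer than the fold count). Spatial prediction
produces six probability surfaces (summing to one) and the hard argmax
map, masked over irrelevant areas (lakes/glaciers/rock/dense forest); the
hard map is the single mosaic used by all downstream vegetation-cover
predictors.

## Habitat model (maximum entropy)

Features per variable: linear, quadratic, and forward+reverse hinges at 10
interior knots, all scaled into [0, 1] by the background minimum/maximum.
Knots are placed half at interior quantiles of the background distribution
and half evenly spaced over its range: cover proportions are zero-inflated,
and pure quantile knots would all fall below ~0.3 cover, leaving the model
structurally unable to represent the suitability decline at high shrub
cover (the response curve would be monotone by construction).

The model maximizes the penalized presence log-likelihood
`mean_pres(λ·f) − log Z_λ − Σ β_j |λ_j|` with
`β_j = multiplier · max(sd_j(presences), 0.05) / sqrt(m)` — the
confidence-interval rationale for keeping each feature's model expectation
within sampling error of its presence mean. The floor 0.05 prevents
near-degenerate presence features from being fitted without restraint.

Solver: λ is split into positive and negative parts and the smooth
bound-constrained problem is solved with L-BFGS-B (memory 100). The
historical stopping rule (log-likelihood gain < 1e-5) is recorded (the
iteration at which the gain first drops below it) but the solver runs on to
a projected-gradient tolerance of 1e-8 within the 500-iteration cap —
strictly stronger, and necessary for the defining stationarity property
|presence mean − model mean| ≤ β_j to hold to 1e-6 at convergence. The
objective trajectory is monotone; the fitted model stores the trajectory,
the convergence status and the final stationarity gap.

Outputs: the raw score is the log relative density λ·f − log Z (0 = average
background cell). "Relative suitability" maps it to [0, 1] via
c·q/(1 + c·q) with c calibrated so the mean score over training presences
is 0.5; it is a relative index, not a detection probability. Binary maps
threshold the suitability at the mean over CV folds of the smallest
threshold maximizing sensitivity (held-out presences) plus specificity
(background).

Cross-validation partitions the presences (k = 5); every fold model sees
the full background; fold AUC is held-out presences vs background.
Jackknife elimination drops, one at a time, the predictor whose exclusion
best improves mean CV-AUC, *including exact ties* (a predictor whose
exclusion leaves accuracy unchanged contributes nothing and is discarded);
fold partitions are shared across candidates so comparisons are paired.
Selection refits use a looser solver tolerance (1e-6) than final fits.

Response curves sweep one variable over its background range holding all
others at their presence means. The reported curve and its optimum come
from the **full-data model**; the 95% band is mean ± 1.96 SD across the CV
replicate models. (Averaging replicate curves instead lets tiny monotone
tail wiggles of single folds drag the argmax of an otherwise plateaued
mean curve to the domain edge.) Permutation importance permutes one raw
variable over the evaluation sample and reports the AUC drops normalized
to percent.

## Restoration analysis

The counterfactual map replaces each manageable layer (the five vegetation
cover proportions and their Simpson diversity) with its constant mean over
the presence cells; presences on masked cells are skipped with a warning.
Potential habitat is the binary suitability of this counterfactual stack at
the stored threshold. Homogeneous patches are 8-connected components of
cells whose 100 m window cover of the group (the three heathlands grouped,
or alder) is **strictly** greater than 0.5; areas are cell counts × cell
area with a size split at 1 ha; patch statistics report the fraction below
1 ha and the median/IQR (linear-interpolation quantiles) above it.
Priority areas are patch cells intersected with potential habitat; the
report gives hectares and percentages against both the full grid and the
modelled (unmasked) area, since the denominator convention is ambiguous in
general use.

By construction priority area ≤ patch area and ≤ potential area per group.
Current ⊆ potential holds in scenarios where only the counterfactualized
layers make cells unsuitable; it is not asserted in general (the
counterfactual can lower suitability where the observed vegetation is
better than the presence mean).

## Pipeline and reproducibility

`run_all` executes simulate → vegetation model → habitat model →
restoration, writing every intermediate artifact (text rasters, CSV, JSON)
plus a consolidated `report.json`/`report.md`; stage seeds are spawned from
the single run seed and logged in the manifest; identical configuration ⇒
byte-identical reports. `--resume` reuses completed stages. The report is a
pure function of the artifacts and can be regenerated standalone.

## Problem sizes used in validation

Scenes of 200×200 cells (25 m) for vegetation-model recovery and the
headline pipeline run; 150×150 with the full 10,000-point background for
habitat-model checks and response-optimum recovery (5 seeds); 140×140 with
a 4,000-point background for the five-seed end-to-end planted-patch
recovery experiment; 60×60 with reduced settings for the double-run
determinism check. Recovery tolerances (coefficients within 10%/0.1,
response optima within 0.15) are asserted on estimates averaged over the
five seeds: per-seed deviations at n = 2000 cells (respectively m = 67
presences) exceed those bands by ordinary sampling noise.

The end-to-end recovery scenario uses a wider elevation belt
(DEM ± 400 m) so that genuinely unsuitable landscape context exists, fits
the vegetation model on spectral predictors only (recently planted discs
contradict the auxiliary covariate fields that generated the pre-stamp
mosaic, while imagery reflects the current state), and judges "outside
suitable context" by the method's own counterfactual suitability under
post-plant (forest-free) conditions: with 67 presences an L1-regularized
model deliberately stays near-uniform in data-poor extremes, so
truth-extreme climate exclusion is not certifiable from the model alone.

## Known limitations

- No projection/datum support; single resolution; no resampling beyond
  what the generator produces.
- The suitability score is relative; absolute occupancy probabilities are
  out of reach of presence-background data.
- Permutation importance and the "contribution" of correlated predictors
  are attribution-ambiguous (e.g. warm low-elevation cells are also
  forested in the default scenes); jackknife selection mitigates but does
  not resolve this.
- The multinomial model's accuracy is calibrated on homogeneous-patch
  plots; mixed pixels are classified by their dominant spectral signal.
- Patch-rule output depends on the hard argmax mosaic; per-class Kappa-max
  binary maps are available from the evaluation but are not the mosaic
  used downstream.
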