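# encroach

Tools for locating **shrub-encroachment priority areas** in alpine treeline
ecosystems. The abandonment of traditional grazing lets green alder (*Alnus
viridis*) and dense dwarf-shrub heathland overgrow the heterogeneous pasture
mosaic that ground-breeding birds such as the black grouse (*Tetrao tetrix*)
depend on. `encroach` chains two spatial models and a counterfactual
simulation into one management product:

1. **Vegetation model** — a six-class multinomial logit (alpine pasture,
   *Rhododendron*-, *Juniperus*- and mixed heathland, green alder, conifer
   forest) fitted to field training plots over spectral and topographic
   raster predictors, with Spearman collinearity screening (|r_s| > 0.7) and
   stepwise backward AIC selection, evaluated per class by Cohen's
   Kappa-maximum, ROC-AUC and sensitivity under 3-fold cross-validation.
2. **Breeding-habitat model** — a presence-only maximum-entropy
   (presence-background) model over 100 m focal summaries of vegetation
   cover, Simpson diversity, climate, terrain and infrastructure, using
   linear/quadratic/hinge features, L1 regularization, 10,000 background
   points, 5-fold cross-validated AUC and a max(sensitivity + specificity)
   binary threshold.
3. **Restoration priorities** — habitat suitability is re-predicted after
   setting the manageable vegetation layers to their means at the breeding
   locations (the "optimal vegetation" counterfactual); homogeneous shrub
   patches (cells whose 100 m window holds > 50% grouped heathland or alder)
   are intersected with this potential-habitat map to yield priority areas,
   patch-size statistics and area summaries.

The package targets landscape ecologists and conservation planners.  Because
the underlying field and satellite data are proprietary, everything is
validated on **synthetic landscapes with known ground truth** generated by
`encroach.synth`: autocorrelated covariate fields, a vegetation mosaic
sampled from a known multinomial logit, class-dependent spectral bands,
breeding presences drawn from a known suitability law with unimodal
responses to shrub cover (optima between 10% and 50%), and optional
"planted" encroachment discs whose exact cells are recorded for recovery
scoring.

## The models in brief

Vegetation, for cell covariates x and classes k (alder as reference):

    P(class = k | x) = exp(b_k' x) / sum_j exp(b_j' x)

Habitat, a Gibbs distribution over the landscape with features f (linear,
quadratic, forward/reverse hinge, all scaled to [0, 1] by the background):

    q_lambda(x) = exp(lambda . f(x)) / Z_lambda

with lambda maximizing the presence log-likelihood minus the penalty
`sum_j beta_j |lambda_j|`, `beta_j = sd_j(presences) / sqrt(m)`. At the
optimum every feature satisfies |presence mean − model mean| ≤ beta_j — the
defining maximum-entropy property, which the fitted model verifies and
records.

## Worked example

```python
from encroach import (SceneConfig, build_scene, extract_predictors,
                      MultinomialVegetationClassifier, evaluate_vegclass)

scene = build_scene(SceneConfig(shape=(150, 150), seed=1))   # 600 plots, 67 presences
X = extract_predictors(scene.stack, scene.plots["x"], scene.plots["y"],
                       ["BAND1", "BAND2", "BAND3", "BAND4", "NDVI8"])
ev = evaluate_vegclass(MultinomialVegetationClassifier(), X,
                       scene.plots["veg_class"].to_numpy(), k=3)
print(ev["cv_mean"]["auc"].round(3))
```

prints the per-class cross-validated AUC of the vegetation model on this
scene:

```
ALNUS      0.997
FOREST     0.998
JUNI       0.982
MIXED      0.936
PASTURE    0.999
RHODO      0.979
```

i.e. every vegetation type is discriminated with cross-validated AUC above
0.9 at the default spectral separability, with the rarest type (mixed
heathland) the least accurate — the expected small-sample pattern. The full framework runs from the shell:

```bash
encroach run-all --seed 1 --out runs/demo
cat runs/demo/report.md
```

The report contains the per-class vegetation table (Kappa-max, threshold,
AUC, sensitivity, CV AUC), the habitat model's fit/CV AUC and threshold, the
response-curve optima for each vegetation variable, and the priority
summary: hectares and percentages of current and potential breeding habitat
and, per shrub group, the homogeneous patch area and the fraction of it that
falls inside potential habitat (the priority areas).

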