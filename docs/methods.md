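# Methods

`ensdm` implements an ensemble species-distribution-modelling (SDM) workflow
of the kind used to project habitat suitability of African dryland plants
(the motivating case is the lowland bamboo *Oxytenanthera abyssinica*) under
current and future climate, and validates every stage on a simulated
virtual-species world where the true niche is known.

## The modelling workflow

1. **Occurrence preparation.** Presence records are thinned to one per
   analysis-grid cell (first record by input order wins; records outside the
   grid or on nodata cells are dropped and counted). Pseudo-absence
   background points — default 2000 — are drawn uniformly without
   replacement over valid cell centres, rejecting candidates within a
   minimum great-circle distance (default 5 km, haversine on a sphere of
   radius 6371.0088 km) of any presence. Rejection sampling over a seeded
   permutation of candidate cells keeps the draw exact and reproducible; an
   attempts budget guards non-termination when the buffer exhausts the
   extent.

2. **Collinearity screening**, two stages, both deterministic given column
   order:
   * *Pairwise Pearson screen* (threshold |r| > 0.7): while any pair
     offends, drop the member of the worst pair with the larger mean |r|
     against everything else (ties go to the later column). Zero-variance
     columns are treated as uncorrelated, retained, and logged.
   * *Stepwise VIF* (threshold 10): VIF_j = 1/(1 − R²_j) from an OLS
     regression of predictor j on all others plus intercept; the largest
     VIF above threshold is removed repeatedly. Perfect collinearity is
     reported as a large finite cap (1/ε) rather than infinity.
   The order (Pearson first, then VIF) and both thresholds are exposed as
   arguments. Every removal is recorded with the statistic at removal time.

3. **Five base learners** behind one fit/predict-probability contract:
   random forest (500 trees), boosted regression trees (500 trees, learning
   rate 0.05, depth 3), an RBF-kernel SVM with Platt probabilities, a
   single-hidden-layer perceptron sized to the feature count (SVM and MLP
   are fitted on standardised features), and an in-package MARS — forward
   selection of reflected hinge pairs at quantile knots by residual
   correlation, GCV backward pruning (penalty 3 per knot), and a logistic
   calibration of the surviving basis. Hyperparameters are deliberately
   fixed defaults, overridable per `AlgorithmSpec` and recorded on the
   fitted model; every fit is deterministic given its seed.

4. **Evaluation.** Held-out scores come from 10 runs of seeded stratified
   4-fold cross-validation (a single stratified 70/30 split is available as
   an alternative scheme). AUC uses the exact rank (Mann–Whitney)
   formulation with ties counted ½; TSS(t) = sensitivity + specificity − 1
   is maximised over all observed scores plus {0, 1} with "positive iff
   score ≥ t", reporting the smallest maximising threshold. Grading bands
   (fail/poor/fair/good/excellent) are half-open with a closed top bin and
   are configuration, not hard-coded policy.

5. **Ensemble.** Weighted averaging with weight_i ∝ max(metric_i − floor, 0)
   — floor 0.5 for AUC (a no-skill member gets zero weight), 0 for TSS —
   normalised to sum to one, with a uniform fallback (and warning) if all
   members are at the floor. Raster prediction is block-wise over rows;
   block size provably does not change results. Variable importance is
   permutation-based: 100 × (1 − Pearson r) between predictions on the
   intact table and on a column-permuted copy, averaged over repeats
   (default 5), floored at 0. Contributions are per-variable and do not sum
   to 100. Importance is computed on the ensemble output (not per member
   then averaged) — one of several places where the procedure in the field
   is under-specified and a single documented choice was made.

6. **Suitability classes and change accounting.** Suitability is binned as
   not [0, 0.25), low [0.25, 0.5), moderate [0.5, 0.75), high [0.75, 1];
   the half-open/closed-top convention is mandatory because the verbal
   definition of these bins has overlapping endpoints. Area percentages are
   simple fractions of valid cells by default (a cosine-latitude weighting
   mode exists and is flagged in the output, since geographic cells shrink
   poleward). The change rate between a current and future area is
   AC = (A_f − A_c)/A_c × 100; the overlap area A_cf (suitable in both
   periods) is computed from the change map and reported but, following the
   source formulation, does not enter AC. The change map binarises both
   class maps at a configurable floor (default: class "low" and above is
   suitable) and assigns stable-unsuitable / gain / stable-suitable / loss.

## The synthetic world

Predictor layers are seeded Gaussian white noise smoothed with a Gaussian
kernel (σ = autocorrelation length, default 5 cells) and standardised to
mean 0, sd 1 — climate-like in being smooth and cross-comparable, nothing
more. The default stack is 100×100 cells at 5 arc-min with 2 signal layers
(the true niche axes), 4 decoys and 1 collinear copy of signal1 (parent +
N(0, 0.2) noise, r ≈ 0.98) for the screen to find.

The virtual species' truth is logistic:
p = σ(β₀ + Σ βⱼxⱼ + Σ γⱼxⱼ²), default β₀ = −2, β_signal1 = 4 (with
curvature γ = −2), β_signal2 = −3. These values put roughly 30 % of the
landscape at p ≥ 0.25 — a compact, strongly climate-limited range of the
same order as the ~19 % suitable fraction reported for the real species.
Prevalence matters: with presences drawn proportionally to p and uniform
background points, the *best possible* presence/background AUC (scoring by
the truth itself) is bounded by how rare suitable habitat is; at ~38 %
prevalence the ceiling is ≈ 0.78, at ~30 % it is ≈ 0.87. The default niche
is therefore chosen so that competent models can demonstrate skill, which
is what the end-to-end recovery test requires.

Presences (default 400) are drawn without replacement over cells with
probability proportional to truth — one record per cell, mirroring the
dedup rule. Future scenarios are additive mean shifts of named layers; the
pipeline also applies a shift to any collinear duplicate of a shifted layer
(a duplicate is the same physical variable, and a model that retained the
duplicate instead of the parent would otherwise see no future change).
The world does **not** emulate climate physics, sampling bias, dispersal or
observation error: a green recovery test establishes that the statistical
machinery recovers a known signal, not that any ecological projection is
right.

## Numerical choices

* Cell ownership is half-open: [west, east) × (south, north], with values
  numerically within 1e-9 of a cell edge snapped to the edge before
  assignment, so ownership is decided by the convention rather than by
  floating-point noise.
* Rasters are single-band north-up WGS84 GeoTIFFs, float64, nodata sentinel
  −9999 declared in metadata; reads and writes round-trip bit-exactly.
  There is no resampling or reprojection anywhere — co-registration is a
  hard precondition and any mismatch is an error naming the layers.
* Per-stage seeds derive from one master seed through `SeedSequence`;
  reruns reproduce every number, including fold assignments.
* Degenerate inputs fail loudly (single-class training tables, all-nodata
  rasters, zero current area in AC) except where a defined value exists
  (zero-variance screen columns, capped VIF, uniform ensemble fallback).

## Known limitations

* Pseudo-absence sampling is uniform over the stack extent; target-group or
  environmentally stratified backgrounds are out of scope.
* MARS is additive (main effects only); interaction products are not
  searched.
* The "statistical importance for presence prediction" criterion sometimes
  used to pre-select bioclim variables in the literature is not defined
  precisely enough to implement and is left to the user's include/exclude
  lists.
* Area percentages ignore cell-area variation unless the cosine-latitude
  mode is enabled.
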