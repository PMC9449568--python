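# ensdm

Ensemble species distribution modelling (SDM) with built-in virtual-species
validation.

`ensdm` is for ecologists who model where a species can live from occurrence
records and gridded environmental predictors, and who want every stage of
that workflow — background-point generation, collinearity screening,
multi-algorithm fitting, skill-weighted ensembling, suitability mapping and
range-change accounting — to be testable against a simulated world where
the true niche is known.

## What it computes

Given presences, a co-registered raster stack of predictors and one or more
future-scenario stacks, the pipeline:

1. thins presences to one per grid cell and draws pseudo-absences uniformly
   over valid cells, excluding a buffer (default 5 km great-circle) around
   every presence;
2. screens predictors by pairwise Pearson correlation (drop while
   |r| > 0.7) and then stepwise variance inflation factor,
   VIF_j = 1/(1 − R²_j), removing the worst column while VIF > 10;
3. fits five probabilistic classifiers — MARS, boosted regression trees,
   a multilayer perceptron, random forest and an SVM — and scores them by
   10 runs of stratified 4-fold cross-validation using AUC (exact
   Mann–Whitney rank form) and the true skill statistic
   TSS(t) = sensitivity(t) + specificity(t) − 1 maximised over thresholds;
4. combines them by weighted averaging, w_i ∝ max(AUC_i − 0.5, 0), predicts
   a suitability raster per scenario, and ranks predictors by permutation
   importance (100 × (1 − r) between intact and column-permuted
   predictions);
5. bins suitability into four classes (not / low / moderate / high at 0.25
   steps), tabulates class areas, overlays current and future maps into
   gain / loss / stable categories and reports the change rate
   AC = (A_f − A_c)/A_c × 100 per class and scenario.

The synthetic-data module generates the validation world: autocorrelated
standardised predictor fields, deliberate collinear duplicates, a logistic
virtual species, suitability-weighted presences and additive future shifts.
See `docs/methods.md` for the full model description and its assumptions.

## Worked example

```python
from ensdm import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1), outdir="run1")
print(result.performance)
```

prints the cross-validated skill of each member and their unweighted mean
(here on the default 100×100 synthetic world, 400 presences, 800
pseudo-absences):

```
             AUC   TSS  n_replicates
MARS        0.86  0.62            40
BRT         0.82  0.57            40
MLP         0.84  0.58            40
RF          0.82  0.57            40
SVM         0.84  0.58            40
Mean value  0.84  0.58           200
```

Every member clears the "good" AUC band (0.8–0.9), so all five get
meaningful ensemble weights. Permutation importance recovers the planted
niche — the two signal layers dominate every decoy:

```
signal2    61.3
signal1    45.8
decoy2      1.7
decoy1      1.2
decoy3      1.0
decoy4      0.9
```

and the change-rate table shows, per future scenario, the percentage change
of each class area relative to the current map, e.g. `not  -12.99` means
the unsuitable area shrinks by ~13 % of its current extent under that
scenario:

```
                       not    low  moderate   high
period scenario
2050   low-forcing  -12.99  31.82     16.51  32.30
       high-forcing -13.15  38.23     23.62 -13.54
2070   low-forcing  -20.58  41.50     35.30  47.51
       high-forcing  -8.82  38.30     16.38 -54.39
```

The same run is available from the shell:

```bash
ensdm run-all --outdir run1 --seed 1
```

and the individual stages as `ensdm simulate | prepare | select-vars | fit |
evaluate | predict | classify | change`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete synthetic-world pipeline from scratch at the given
seed — simulation, occurrence preparation, screening, cross-validated
fitting, ensemble prediction, classification and change accounting — prints
the performance, importance, area and change-rate tables, and writes the
target-value JSON to `--out`.
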