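# connectgene

Habitat suitability, landscape resistance, connectivity and landscape-genetics
inference for invasive-species management — a tested, desk-scale
implementation of the full analysis chain used to locate priority control
areas for riparian invaders such as the nutria (*Myocastor coypus*).

## Who this is for

Landscape geneticists and invasion ecologists who want to chain together,
with a single seed and verifiable ground truth:

1. **Ensemble species distribution modeling (SDM).** Presence-background
   design: occurrences against 10,000 uniform background points, a
   stratified 70–30 train/test split, five base learners (GLM with
   bidirectional stepwise AIC over squared and interaction terms; MARS with
   degree 1 and GCV knot penalty 2.0; boosted regression trees with bag
   fraction 0.75; random forest with OOB-tuned mtry; MaxEnt as penalized
   presence-background logistic regression). Models pass a 10-fold
   cross-validation gate (mean AUC > 0.75 **and** mean TSS > 0.4); variable
   importance is permutation ΔAUC; the ensemble is a **committee average**
   of each model's maxSSS-binarized map, with cells suitable when the
   committee value exceeds 0.5 (at least 3 of 5 votes).
2. **Resistance surface.** Suitability s ∈ [0, 1] maps to movement cost
   through the anchor points (0, 100), (0.2, 40), (0.4, 15), (0.6, 5),
   (0.8, 2), (1, 1) with log-linear (piecewise-exponential) interpolation;
   major roads are burned in at cost 10,000.
3. **Cost distances.** Least-cost distance (LCD) and circuit-theory
   resistance distance (IBR) between population sites over the 8-connected
   raster lattice, edge cost = mean cell resistance × center distance.
4. **Landscape genetics.** Mantel permutation tests (default 10,000
   permutations) of pairwise F_ST against LCD with roads, LCD without
   roads, and IBR.
5. **Habitat networks.** Suitable cells become graph nodes, linked when
   LCD < threshold (grid 5,000–25,000 by 5,000, searches capped at
   250,000); nodes are scored by **current-flow betweenness centrality**
   (CFBC, β = 0 so every patch injects unit current); the threshold whose
   log-CFBC best correlates with expected heterozygosity He selects the
   operative scale; the top 5% of nodes by CFBC are the priority control
   areas.

A synthetic-landscape generator produces worlds with known truth at every
stage — autocorrelated covariates, a virtual species, road barriers, and
genetic data generated from the true landscape distances — so the whole
chain is testable end to end.

## Worked example

```python
import connectgene as cg

cfg = cg.PipelineConfig(
    seed=7,
    world=cg.WorldParams(
        shape=(60, 60), n_layers=3, coefficients=(6.0, 4.0, 2.4), intercept=-9.0,
        n_occurrences=150, n_populations=8, corr_length=4.0, n_roads=3,
    ),
    n_background=500,
    cv_folds=3,
    model_settings={"BRT": {"n_estimators": 80}, "RF": {"n_estimators": 80}},
    thresholds=(5000.0, 15000.0),
    mantel_permutations=999,
    importance_repeats=5,
)
report = cg.run_pipeline(cfg, out_dir="run")
```

Output of this exact configuration:

```
selected models: ['GLM', 'MARS', 'BRT', 'RF', 'MAXENT']
{'GLM': 0.942, 'MARS': 0.928, 'BRT': 0.945, 'RF': 0.926, 'MAXENT': 0.948}
     test     r     p  n_perm alternative
LCD+roads 0.822 0.006     999     greater
LCD-roads 0.825 0.007     999     greater
      IBR 0.824 0.004     999     greater
      mean_delta_auc  rank
var0           0.321     1
var1           0.067     2
var2           0.022     3
best threshold: 5000.0
habitat nodes: 618 priority: 31
```

All five learners clear the CV gate and reach holdout AUC ≈ 0.93–0.95 on
this sharply confined virtual species. Permutation importance recovers the
generative coefficient order (var0 > var1 > var2). The Mantel row for LCD
with roads is strongly positive and significant — F_ST in this world was
generated linear in exactly that distance — and the He–CFBC correlation is
maximal at the generating network threshold of 5,000 cost units, where the
top 5% of the 618 habitat nodes (31 cells) are flagged as priority control
areas. `run/` then holds the JSON report, CSV tables (metrics, importance,
Mantel, scale correlations, priority nodes), ASCII-grid rasters of the
committee map and resistance surface, and GeoJSON priority points.

The same stages are exposed as a CLI:

```bash
connectgene simulate --seed 2 --out world/
connectgene resist --suitability world/true_suitability.asc --roads world/roads.asc --out world/resistance.asc
connectgene distance --resistance world/resistance.asc --sites world/populations.csv --metric lcd --out world/lcd.csv
connectgene genetics --fst world/fst.csv --distance world/lcd.csv --out world/mantel.csv
connectgene network --mask world/mask.asc --resistance world/resistance.asc --threshold 5000 --out world/net/
connectgene run --seed 7 --out run/
```

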