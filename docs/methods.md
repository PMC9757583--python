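# Methods

This note documents the models, conventions and numerical choices behind
`connectgene`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Species distribution modeling

**Design.** Presence-background: observed occurrences (label 1) are
contrasted with uniformly sampled background cells (label 0, default
10,000, never coinciding with occurrence cells). The split is stratified
70–30 by label, rounding the train count to the nearest integer per class
(the sampling design is silent on stratification; stratifying keeps both
classes in both parts at small n).

**Base learners.** All learners consume covariates standardized over the
combined training points and return probabilities in [0, 1]:

- **GLM** — binomial GLM with a bidirectional stepwise search by AIC,
  starting from the main-effects model with a candidate scope of all main
  effects, squares and pairwise interactions. AIC is computed from the
  binomial deviance with fitted probabilities clipped to
  [1e−12, 1 − 1e−12]: under (quasi-)separation the analytic log-likelihood
  is NaN while the clipped deviance stays finite and still ranks the
  separating model first.
- **MARS** — degree-1 multivariate adaptive regression splines,
  implemented in-repo: greedy forward selection of reflected hinge pairs
  max(0, x − t)/max(0, t − x) with knot candidates at 15 per-variable
  quantiles (5th–95th percentile), backward pruning by GCV with
  cost-complexity = n_terms + 2.0 × n_knots (penalty per knot 2.0,
  Friedman's degree μ = 1). The retained basis is refitted as a binomial
  GLM so predictions are probabilities.
- **BRT** — stochastic gradient boosting (bag fraction 0.75, default
  learning rate 0.1, tree depth 3). The tree count is selected by 3-fold
  cross-validated log-loss over the staged predictions, then the model is
  refitted on all data with that count. The learning rate is configurable;
  0.1 is the library default and a reasonable desk-scale choice.
- **RF** — random forest whose per-split variable count (mtry) is chosen
  by scanning 1..p and minimizing the out-of-bag misclassification rate
  (ties to the smaller mtry).
- **MaxEnt** — realized through the standard equivalence with penalized
  presence-background logistic regression: L1-penalized logistic
  regression (C = 1) over linear, quadratic and pairwise-product features
  of the standardized covariates. This approximates MaxEnt's
  linear/quadratic/product feature classes with automatic feature
  selection via the L1 path; hinge/threshold features are not included.

**Evaluation.** AUC is the Mann–Whitney rank statistic with midrank ties.
The classification threshold is maxSSS — the observed score maximizing
sensitivity + specificity, ties resolved toward the smaller (more
sensitive) threshold — computed on training data and applied to test data
to avoid leakage. TSS = sensitivity + specificity − 1 at that threshold
with the rule "score ≥ threshold ⇒ suitable". Model selection is a k-fold
(default 10) stratified cross-validation gate retaining kinds with mean
fold AUC > 0.75 and mean fold TSS > 0.4, both strict; fold thresholds are
per-fold maxSSS from the fold-train predictions.

**Importance and response.** ΔAUC importance = AUC(original) − mean AUC
over n_repeats (default 10) permutations of one covariate across the
evaluation points; it can be slightly negative for inert covariates.
Response curves use the evaluation-strip convention: the target covariate
sweeps its observed range while all others sit at their mean over
presences + background.

**Ensemble.** Committee averaging: each retained model votes with its own
maxSSS-binarized map; the committee value is the mean vote and cells with
committee value strictly greater than 0.5 are suitable (with five models:
at least three votes; exactly half the votes is not suitable).

## Resistance surface

Suitability maps to cost through six anchors — (0, 100), (0.2, 40),
(0.4, 15), (0.6, 5), (0.8, 2), (1, 1) — with log-linear interpolation
between adjacent anchors, i.e. exponential decay within each segment,
exact at every anchor. Anchor inputs snap to exact anchor costs and each
segment is clipped to its anchor bounds, so monotonicity holds to the last
ulp. Whether the original analysis interpolated or binned is unknowable
from the printed rule; a `mode="bin"` switch (nearest anchor) is provided,
with interpolation as the default. Roads are rasterized one cell wide and
override the cell cost at 10,000; nodata propagates from both inputs.
Optional resampling to a target cell size uses bilinear interpolation for
suitability and nearest-neighbour for the road mask.

## Cost distances and circuit theory

The raster is an 8-connected lattice. Edge cost = (r_i + r_j)/2 ×
cell_size × √2-for-diagonals — the PATHMATRIX/Circuitscape-style
average-resistance convention, the single convention supported (tools in
this space offer several; this choice is a documented potential source of
divergence from analyses made with other conventions, as is the 8- vs
4-neighbour choice). LCD matrices use exact Dijkstra; single optimal paths
use an in-repo Dijkstra with deterministic lexicographic tie-breaking.
Sites snap to the nearest valid cell (snap distance logged). Disconnected
pairs are stored as `inf` sentinels; Mantel tests refuse matrices
containing them.

The circuit model reuses the lattice edge costs as resistances
(conductance = 1/cost), so LCD and IBR share one conductance model.
Effective resistance is computed by grounding one node per component and
solving the reduced Laplacian with a sparse LU factorization (one
factorization per component, one solve per site); R(a, b) =
G_aa + G_bb − 2G_ab from the grounded Green's function. Pair throughflow
injects unit current at the source and extracts at the target; interior
nodes carry half the summed absolute edge current, endpoints carry exactly
1 (Newman's endpoint convention).

## Habitat network and CFBC

Habitat nodes are suitable committee cells (capacity 1) at cell centers; a
patch is a single cell by definition. Links join pairs with LCD strictly
below the threshold, searched over the full resistance lattice and
truncated at the 250,000 cap. CFBC sums throughflow over all unordered
source-target pairs per connected component, weighted by
(cap_s × cap_t)^β; β = 0 (unit amperage everywhere) is the default. With
the endpoint convention every node in a component of size ≥ 2 scores at
least 1; isolated nodes score 0. Scores are raw sums — no pair-count
normalization — because only correlations and rank cutoffs consume them,
and both are invariant to positive scaling.

The pair sum is evaluated exactly with an edge-wise sorting reduction:
for each edge, Σ_{s<t} w_s w_t |F_es − F_et| is computed from one sort of
the edge's current row (O(m n log n) per component instead of O(m n²)),
with the dense Laplacian-pseudoinverse computation retained as the test
oracle. Each population is assigned the Euclidean-nearest habitat node
(ties to the lowest node index). Scale selection computes Pearson r
between He and natural-log CFBC at each threshold (the log base only
rescales and leaves r unchanged) and returns the max-r threshold among
those with p < 0.05, ties to the smallest threshold; if none is
significant the max-r threshold is returned with a warning. Priority
nodes are those at or above the (1 − q) percentile of CFBC (default
q = 0.05), ties at the cut included. The source analyses mention both a
top-5% rule and top-10% areas; the quantile is configurable with 0.05 as
default.

## Mantel tests

The statistic is the Pearson correlation of vectorized upper triangles;
the null jointly permutes rows and columns of the second matrix. The
default alternative is one-tailed "greater" (isolation predicts a positive
correlation; the tail used in the original software's default), with
"less" and "two-sided" available. p uses the +1 correction,
p = (1 + #extreme)/(1 + n_perm), so p ≥ 1/(n_perm + 1); an exact mode
enumerates all n! relabelings for small n. Default 10,000 permutations.

## Synthetic worlds

`generate_world` draws covariate layers (Gaussian-smoothed white noise,
re-standardized; smoothing sigma = `corr_length` cells), builds a logistic
virtual species, samples occurrences proportional to suitability without
replacement (with a Chebyshev minimum-separation thinning rule, default 1
cell — the analogue of a 1 km rule on a 1 km grid), rasterizes random
border-to-border road transects, places population sites in suitable
habitat, and generates genetic data from the *true* landscape:

- F_ST(i, j) = clip(a + b·LCD_roads(i, j) + ε_ij, 0, 1), ε symmetric
  N(0, σ²) added to the upper triangle and mirrored;
- He(i) = clip(c + d·log CFBC_i + η_i, 0, 1) with CFBC from the
  true-suitability habitat graph at the generating threshold (default
  5,000).

Defaults follow the emulated study design where it states values: 7
covariate layers, 321 occurrences, 8 populations, 50 m cells, road cost
10,000. Desk-scale choices documented here: steep suitability
(coefficients 6/4/2.4/1.5, intercept −10) reproduces the sharply confined
~10% suitable coverage of real riparian habitat — which is also what makes
presence-background AUC ≈ 0.95 attainable, since the AUC ceiling of a
presence-background design is roughly 1 − suitable_fraction/2. Genetic
effect sizes (a = 0.05, b = 2×10⁻⁷, σ = 0.02; c = 0.45, d = 0.05,
τ = 0.02) keep F_ST in a realistic 0.05–0.35 band against road-dominated
distances (one road crossing adds ≈ 5×10⁵ cost units at 50 m cells) and
make truncation rare (< 1%, warned otherwise). Clipping is truncation, not
resampling.

**What the generator does not emulate.** No coalescent or individual-based
genetics — the linear-plus-noise model is a stated stand-in, so passing
tests show the *inference chain* recovers planted associations, not that
real microsatellite data behave this way. Covariates are stationary
isotropic fields, not climate gradients; roads are straight transects, not
networks; occurrence effort is spatially uniform. One structural property
deserves emphasis: because road crossings of random transects scale with
spatial separation and the cost range is bounded (1–100), the with-road
and road-free LCD matrices are strongly correlated (r ≈ 0.5–0.9) in any
random world. Genetic data generated from the with-road LCD therefore
usually also correlate detectably with the road-free LCD; a clean
"significant with roads, non-significant without" contrast like the one
reported for the real basin reflects a particular landscape configuration
and is not generically reproducible in random worlds.

## Determinism and seeds

A single master seed drives every stage. Stage seeds derive as
CRC32(stage name) mixed with the master seed through numpy's SeedSequence
(all below 2³¹); the scheme is stable across runs and platforms. RF/BRT
receive derived integer seeds; identical seeds give bit-identical worlds,
fits and reports.

## Problem sizes

Tests and the acceptance script run on 45×45–80×80 grids with 80–321
occurrences, 500–1,200 background points, and habitat graphs of a few
hundred nodes — sizes chosen so the full chain, including replicated
power checks, completes in minutes on one CPU while every stage remains
at the same parameter settings the emulated design prints. Paper-scale
inputs (10,000 background points, 50 m basin-wide rasters) run through
the same code paths; dense CFBC on graphs beyond ~3,000 nodes is the main
cost driver at that scale.

## Known limitations

- MaxEnt omits hinge/threshold features and SAHM-specific defaults.
- The BRT learning rate and MaxEnt regularization are configurable
  approximations; the emulated workflow does not print them.
- Single optimal least-cost path only (no corridor widths); no partial
  Mantel or mixed-model (MLPE) alternatives; no Circuitscape/Graphab file
  compatibility.
- GLM stepwise refits the full model per candidate move (O(terms²) fits);
  fine at desk scale, slow for dozens of covariates on 10⁴ points.
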