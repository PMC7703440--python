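# Methods

This note documents the models and procedures `sdmbias` implements, the
parameter choices that matter, what the synthetic data do and do not
emulate, and the numerical decisions behind the pipeline.  Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study extent

The default extent (`ireland_like_grid`) is a frozen irregular mask of
840 active 10 km × 10 km cells inside a 30 × 35 rectangle (84,000 km²),
emulating the scale and shape-irregularity of an island-wide atlas grid.
Cells live on a planar km grid (cell (r, c) centroid at
((c + 0.5)·side, (r + 0.5)·side), row 0 at the bottom); no geographic
projection or real coastline is used.  Rook contiguity (shared edges)
defines the neighbourhood graph for all spatial statistics.

Two statistics recur everywhere:

* **Moran's I** with binary, symmetric, non-row-standardised rook
  weights: I = (n/W)·ΣΣ w_ab (x_a−x̄)(x_b−x̄) / Σ(x_a−x̄)².  Tested
  against a brute-force double loop and against the permutation-null
  expectation −1/(n−1).
* **Simpson evenness** of per-cell effort: E = (1/Σ p_a²)/S with
  p_a = count_a/total over **all** S active cells (zero-count cells
  count in S; an extent where only one square is recorded has
  E = 1/S).  Computed as total²/Σc²/S so uniform integer counts give
  exactly 1.

## Synthetic environmental layers

Each layer is a **two-scale Gaussian random field**: a broad regional
gradient (exponential covariance, range 150 km) mixed with fine local
noise (range 2 km),

    layer = √w · broad + √(1−w) · fine,

standardised to mean 0 / sd 1 (landcover-like layers are then passed
through a logistic squash into [0, 1], as landcover variables are
proportions).  The mixing weight w is found by bisection so the layer's
measured Moran's I hits its target; the targets of the default
ten-layer stack (0.84, 0.83, 0.82, 0.86 for four climate-like layers,
0.53, 0.44, 0.41, 0.35, 0.55 for five landcover-like layers, 0.29 for
elevation) span the range measured on real island-scale predictor sets.

Two design choices deserve emphasis, because single-range fields fail
them both:

1. **Multi-scale structure.**  A single-range exponential field ties
   local autocorrelation to total spatial structure, so a layer
   calibrated to I ≈ 0.3 would be near-noise with no regional
   component.  Real low-I variables (elevation at 10-km resolution)
   still have mountains and lowlands.  Without the broad component,
   virtual species ranges are spatially incoherent at the 100-km block
   scale and covariate-free spatial interpolation degenerates to
   chance; with it, realised ranges form contiguous regional blocks.
2. **Correlated climate.**  The four climate-like layers share one
   broad-gradient field (pairwise correlations ≈ 0.9), as real climate
   variables are strongly cross-correlated; landcover and elevation
   layers get independent gradients.

Calibration bisects on the mean Moran's I of 5 seeded fine-field
replicates, then returns the replicate whose own realised I is closest
to the target (with a second single-replicate bisection pass if
needed); achieved values are stored on the layer.  Calibration is exact
to ±0.05 by construction and verified by measurement.  Dense Cholesky
factorisation makes this cheap below ~2,000 cells.

## Virtual species

For each species, 7 of the 10 layers are drawn uniformly without
replacement; the chosen layers are centred, scaled, and summarised by
correlation-matrix PCA (scores standardised to unit variance; loading
signs fixed so the largest-magnitude entry is positive, for
determinism).  Occurrence probability is the quadratic logistic

    logit(p_ij) = α_i + Σ_{k=1,2} (β_1ki V_kj + β_2ki V_kj²)

with α ~ U(−4, 0), β_1k ~ U(−4, 4), β_2k ~ U(−4, 0).  The intercept
range keeps most species rare-to-moderate (right-skewed prevalence
distribution); non-positive quadratics give unimodal niche responses;
the slope range is wide enough that responses saturate the logistic
over much of the extent.  The last point is deliberate: with shallow
slopes (|β| ≤ 2) probabilities sit mid-range, Bernoulli realisation
noise dominates the realised maps, and no model — not even the true
probability surface — can rank cells well, which is not a regime in
which distribution modelling is a sensible exercise.  With these
defaults the true surface ranks realised presences at AUC ≈ 0.9.

One realised map per species is drawn cell-wise Bernoulli(p).  Species
with realised prevalence < 0.01 or fewer than 8 occupied cells are
rejected and redrawn (fresh coefficients), up to 1,000 times.  The
default community holds 1,268 species; a 34-species preset exists; the
desk-scale preset uses 240 (below).

## Biased checklist sampling

A bias template assigns each cell a relative weight in [0, 1] with
max = 1 (a cell with half as many records as the most-recorded cell has
weight 0.5).  Synthetic templates use weights ∝ exp(γ·z) for a fixed
smooth field z (range 50 km), with γ ≥ 0 bisected until the weights'
Simpson evenness matches a target; the four default levels are 1 (none),
0.762 (low, bird-recording-like), 0.126 (median, butterfly-like) and
0.021 (severe, moth-like).  Templates can also be derived from a real
record table (count/max per cell).

In the factorial experiment the field z mixes (weight 0.5) the
standardised artificial-surfaces layer with an independent smooth
field: real recording effort is biased *through* environmental space
(towns, roads, accessibility), and it is exactly this coupling that
lets spatial bias distort covariate-based models — with an
env-independent bias field, logistic regression is almost immune to
even severe bias (the classic exogenous-selection result), and the bias
effect the experiment is designed to measure cannot appear.

Checklist simulation repeats until the number of unique
(event, species) records reaches `mean_records_per_species ×
community size`: draw a cell ∝ template weight; redraw (and count) if
no species is present; draw `draws_per_event` = 10 species with
replacement from those present, with probability ∝ global realised
prevalence; collapse duplicates into the event's detected set.
Non-detection inference produces the events × modeled-species 0/1
matrix used to train all models.  Sample-size presets are {2, 5, 10,
50, 100, 200} mean records per species.

## SDM methods

All methods share the fit gate (> 5 presences in the training rows) and
model the probability of the focal species being recorded on a
checklist, from 5 named predictors chosen at random per species (fixed
across methods and arms — deliberately imperfect knowledge of the true
drivers).  Predictors are standardised with training-row statistics.

* **GLM** (`ChecklistGLM`): binomial logistic regression; candidate
  terms are the 5 linear + 5 quadratic terms; the number of
  non-intercept terms is capped at ⌊min(#ones, #zeros)/10⌋;
  forward-backward stepwise search minimises AIC and never includes x²
  without x.  Quasi-separation falls back to a small ridge penalty
  (C = 100) with a deviance-based AIC, flagged in the description.
* **BRT** (`BoostedTreesSDM`): stagewise gradient boosting with
  logistic loss, bag fraction 0.75, tree complexities 2 and 5
  (max_leaf_nodes = complexity + 1).  For each complexity the learning
  rate starts at 0.01 and halves (floor 1e-5) until the 10-fold-CV
  deviance-optimal tree count reaches 1,000, capped at 30,000 trees;
  the complexity/rate pair with the lowest CV deviance is refitted on
  all rows at its optimal tree count.  Trees are grown in warm-started
  chunks and the search stops 500 trees past the running CV minimum.
  If no schedule satisfies the constraints the fit reports `failed`
  (recorded, never raised).
* **IDW** (`InverseDistanceSDM`): prediction at a cell is the weighted
  mean of the m nearest training events' 0/1 responses with weights
  d^(−power); co-located events are aggregated per cell and a query
  cell containing training events predicts the exact-cell mean.
  (power, m) is tuned over {1,2,3,4} × {5,10,25,all} by lowest RMSE
  under 5-fold **spatially blocked** CV within the training events
  (events grouped by 100-km block): random splits leak spatial
  information between co-located rows and systematically select
  over-local neighbourhoods that do not generalise across blocks;
  `tuning="random"` restores the naive split.

## Evaluation

5-fold spatial block cross-validation: 100 km × 100 km blocks tile the
bounding rectangle and are assigned to folds by seeded least-loaded
placement (fold cell-counts differ by at most one block).  For each
fold, models train on events outside the fold and predict every active
cell inside it; truth is the species' realised presence/absence.  A
species × arm counts as successfully modeled only when **all** folds
fit: pooled predictions then cover each active cell exactly once, so
the evaluation set is spatially even and identical across every
bias/size/method arm (metrics computed over partially fitted folds
would drop exactly the hard, sparsely sampled regions from the biased
arms and flip the bias contrast).  Metrics, computed once on the
pooled predictions: rank-based AUC (ties ½), maximum Cohen's Kappa over
score-midpoint thresholds (smallest maximiser reported), RMSE against
the 0/1 truth.

## Factorial experiment and meta-analysis

`run_experiment` crosses bias levels × sample sizes × methods × modeled
species with one community, one species subset, one predictor set per
species and one partition shared by all arms; all randomness flows from
named sub-seeds of one master seed, and reruns are byte-identical.  The
full design (4 × 6 × 3 × 110 species from 1,268) is the `full_scale`
preset; the tested desk-scale preset (`scaled_design`) uses 20 modeled
species from a 240-species community (preserving the ~12:1
community-to-modeled ratio, which sets the volume of inferred
non-detections per modeled species), sizes {2, 10, 100}, bias levels
{1.0, 0.126}, and the two fast methods (GLM, IDW).  Desk scale keeps
the whole factorial under ~2 minutes on one CPU.

`importance` regresses a performance metric on log₁₀ sample size, bias
evenness (numeric — bias is a continuous axis), and method (one-hot,
re-aggregated), plus prevalence for RMSE only (RMSE's expectation
depends strongly on how common a species is; AUC's does not); the
boosted-tree meta-model (depth 3, learning rate 0.01, bag fraction
0.75, tree count by 10-fold CV) reports each variable's reduction in
squared error over all splits, normalised to 100.  A zero-variance
response yields a uniform table with a `degenerate` flag.

**Comparisons between arms use matched species.**  Every arm models the
same species set, so any two arms are compared on the species both
evaluated; a comparison needs at least 3 shared species.  At desk scale
the size-2 arms fit 0–2 species across all folds (the gate bites
hard — the same behaviour as the fit-failure counts, which rise
steeply with sample size), so the 2→10 step is usually unsupported and
the supported steps (10→100) carry the monotonicity checks.  Means over
one or two species are reported but not treated as evidence.

## What the synthetic data do not emulate

* Observer-level heterogeneity, temporal bias, misidentification, and
  endogenous bias (recording *because* the species is present) are all
  absent; the bias here is purely exogenous through space/environment.
* Layers are stationary Gaussian mixtures; real predictors have
  anisotropy, hard coastline edges and heavy-tailed distributions.
* One realisation per species; no dispersal, dynamics or interactions.
* Passing tests therefore show the pipeline's internal logic and the
  direction/ordering of effects under controlled conditions — not
  numeric effect sizes for any real dataset or region.

## Numerical notes and degenerate inputs

* All bisections (Moran's I ↔ broad weight, evenness ↔ γ) exploit
  monotone response curves; both verify the achieved value and raise a
  calibration error rather than return an off-target artefact.
* Zero-variance fields, empty effort vectors, single-class metric
  inputs, disconnected extents, and templates with no weight on any
  occupied cell raise typed errors (`sdmbias.errors`); inside the
  experiment loop, per-fit problems are recorded as statuses instead.
* Constant predictor columns get unit scale during standardisation.
* Kappa at a threshold where expected agreement is 1 is defined as 0.
* Seeds derived anywhere in the package stay below 2³¹.
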