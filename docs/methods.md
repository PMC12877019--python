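# Methods

This note documents the models and procedures implemented in `immunotile`,
the parameter choices that matter, what the synthetic cohorts do and do not
emulate, and the package's known limitations.

## Input model and units

The unit of input is one per-cell table per slide: a centroid (or bounding
box, from which the centroid is the box midpoint) and one binary positivity
call per marker of an 8-plex panel. All coordinates are canonicalised to µm
at read time (pixel inputs are multiplied by the image resolution,
0.4992 µm/px by default) because every spatial scale in the method —
proximity radii 20/30/60/90 µm, the 60 µm neighborhood radius, 1 mm tiles —
is metric. Cells with a missing marker call are rejected rather than
imputed: the binary call is the atomic datum and imputing it would
fabricate phenotypes. Slide response labels are
`responder`/`non-responder`; tiles inherit their slide's label.

## Tiling

Slides are partitioned into square tiles of side 1000 µm by cell centroid.
The grid is anchored at the per-slide minimum centroid — deterministic and
data-driven, with no empty margin tiles — and uses half-open intervals
[x0, x1) × [y0, y1) so boundary centroids are assigned uniquely. Tiles with
fewer than 100 cells are dropped from *all* downstream computation; 100
cells is the floor at which tile-level proportions and pair statistics stop
being dominated by shot noise.

## Cell states

Cell states are the top-20 exact positivity patterns pooled over the
cohort, plus a singleton state for any marker lacking one, plus the stromal
state (no positive marker). Ties in pattern counts are broken
lexicographically by sorted marker names, then by smaller set, so the
catalog is deterministic. Counting uses exact patterns but *membership*
uses superset matching — a CD3+CD8+PD-L1+ cell is a member of CD3, CD8,
PD-L1, CD3+CD8, … — which is what makes marker-level proportions
interpretable while still ranking by the combinations that actually occur.
Rare-state pruning (< 0.1% prevalence) is available but off by default so
synthetic catalogs are fully controlled.

## Spatial statistics

Both families are computed per tile, with the tile rectangle as the
spatial window; a cell belonging to several states appears in each state's
point set, and a cell is never paired with itself.

**Proximity scores** count state-A–state-B pairs at distance strictly
below r (r ∈ {20, 30, 60, 90} µm; unordered distinct pairs when A = B) and
normalise by (prop_A + prop_B), the sum of the two states' tile
proportions, so the score is comparable across tiles of different
composition. The score is *missing* — not zero — when either state is
absent from the tile: an absent state is a different observation from two
present-but-distant states.

**Ripley's cross-K** uses the estimator
K̂(r) = |W| / (n_A n_B) · Σ_{i∈A} Σ_{j∈B, j≠i} w_ij 1(d_ij ≤ r), with
Ripley's isotropic edge correction: w_ij is the reciprocal of the arc
fraction of the circle centred at i with radius d_ij that lies inside the
window. For a rectangle this has a closed form — one 2·arccos(e/d) term
per edge closer than d, minus an (arccos(ex/d) + arccos(ey/d) − π/2)
overlap term per corner with ex² + ey² < d² — exact for the pair distances
(≤ 100 µm) used here, and verified in tests against numeric arc
integration. Inside fractions below 10⁻³ (circle nearly outside, only
possible near corners at large d) are capped and logged. The weight is
evaluated at the *first* point of the ordered pair; with weights forced
symmetric (all 1) K̂(A,B) = K̂(B,A) exactly, which the tests assert.
L = √(K̂/π) variance-stabilises K̂; ΔL(r) = L(r) − r is zero in expectation
under complete spatial randomness (verified: |mean ΔL| < 0.1 µm over 200
Poisson tiles of 500 points), and the cluster score is the trapezoidal
integral of ΔL on a fixed 1 µm grid from 0 to 100 µm. The indicator is
≤ for K̂ (the standard estimator convention) and strict < for proximity
counts; both conventions are frozen. K̂(0) is defined as 0 even for
coincident points.

## Recurrent cellular neighborhoods

Every cell seeds a neighborhood: all cells of the *same tile* within 60 µm
(boundary inclusive), including the seed itself — so neighborhoods are
never empty and proportions are always defined. Profiles are state
proportions among neighborhood members. k-means (Euclidean, seeded,
subsample-then-assign above 500,000 profiles) clusters the profiles;
clusters are relabelled by descending size (RCN1 largest). k is chosen by
an elbow rule: the smallest k whose relative WCSS decrease to k+1 falls
below τ = 0.10. Because WCSS decreases by a roughly scale-free factor when
an isotropic cluster is split (~32% of that cluster's WCSS), this rule
cannot detect fewer than four equally sized well-separated clusters; on
neighborhood-profile data, where clusters overlap heavily, it behaves as a
conventional elbow. τ is configurable. Tile-bounding the neighborhoods
truncates profiles at tile borders; this is accepted for locality and
parallelism, and because features are per-tile anyway.

## Univariate screens

The Wilcoxon rank-sum screen treats tiles as independent observations —
descriptively useful, but tiles within a slide are pseudo-replicates, so
its p-values overstate population-level evidence. Benjamini–Hochberg
adjustment is applied across whatever feature family is passed in one
call (compositional and spatial families are screened separately). Note
that BH-adjusted p-values are not a fixed point of the procedure;
re-adjusting adjusted values inflates them further.

The mixed-effects screen fits, per feature, value ~ group with a random
intercept per slide, by maximum likelihood, and tests the group effect
with a 1-df likelihood-ratio test against the intercept-only mixed model
(ML rather than REML, as REML likelihoods are not comparable across fixed
effects). Proportion-valued features are log10-transformed with a
pseudo-count of half the feature's smallest nonzero value. Features
observed in fewer than 10 slides are skipped — with 12 slides, a feature
missing from several slides cannot support a slide-level variance
estimate. Simulated type-I error under slide-permuted nulls is within
[0.01, 0.10] at nominal 0.05 (tested).

## Response classification

Three feature configurations: *compositional* (state proportions +
subpopulation fractions), *combined* (+ RCN proportions + ΔL at 20 µm —
the radius at which spatial differences are most informative), and
*immune-high* (combined, restricted to tiles with CD8+ proportion ≥ 0.02;
the boundary is inclusive). Evaluation is leave-one-slide-out
cross-validation repeated for n iterations with per-iteration classifier
seeds; within an iteration all folds' test predictions are pooled into one
set before computing accuracy, ROC AUC, AUPRC, precision, recall,
specificity, balanced accuracy and F1 (responder positive), and means ± sd
are reported across iterations. Patient calls are the majority predicted
class over a slide's (qualifying) tiles; an exact tie is called
non-responder — the majority class and the clinically conservative call —
and a slide with no qualifying tiles is a no-call.

The default classifier is LightGBM (gradient-boosted trees with native
missing-value handling): 100 trees, learning rate 0.05, 15 leaves,
min_child_samples 10, 80% row and column subsampling, L2 regularisation 1,
balanced class weights, single-threaded and deterministic per seed. Two
choices deserve comment. *Balanced class weights*: pooling raw
probabilities across leave-one-slide-out folds mixes models whose training
class balance depends on the held-out slide (4R/8NR cohorts), which alone
pushes pooled AUC below 0.5 on signal-free data. *Moderate tree
constraints*: with ~100 training tiles, unconstrained trees memorise
slide idiosyncrasies, and grouped CV then anti-generalises (the held-out
slide resembles the training slides of *either* class equally poorly).
Even so, pooled grouped-CV AUC on signal-free cohorts sits slightly below
0.5 (≈ 0.36 at the tested conditions, and varying with the cohort
realisation) rather than at it; this pessimistic bias of pooled
leave-one-group-out scores with few groups is a property of the evaluation
scheme, not evidence of signal, and is the reason null calibration is part
of the test suite. Feature attribution uses LightGBM's exact TreeSHAP
(`pred_contrib`); importance is the mean |attribution| over all test-tile
predictions across folds and iterations, with signed per-tile attributions
retained from the final iteration for beeswarm-style displays. Permutation
importance is the fallback for classifier families without additive
attributions. The classifier factory is pluggable; median imputation is
left to wrappers for families that cannot accept missing values.

The CD8-cutoff sweep re-runs the cross-validation at each cutoff in
[0, 0.05] (0 = all tiles, identical to the combined model) and reports
metrics plus qualifying-tile counts, which are non-increasing in the
cutoff.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline consumes,
not tissue biology. Per slide: background stroma is homogeneous Poisson
(600 cells/mm²); tumor nests follow a Thomas process (2.5 parents/mm²,
mean 60 offspring, σ = 40 µm Gaussian dispersion) — the simplest
stationary cluster process with analytic intensity; immune cells
(t-helper 80/mm², cytotoxic 10/mm², B 30/mm²) are sparse Poisson; and two
"immune aggregates" per slide (200 µm disks, 400 cells/mm², cytotoxic +
helper T cells) give *every* slide some CD8-moderate tiles so the
immune-high filter always has material in both classes. Markers are
independent Bernoulli draws given a cell's latent type (stroma: all zero,
so stromal cells are marker-negative by construction); co-expression is
induced through latent types only, keeping ground truth interpretable.

Responder slides additionally receive, at the `strong` preset, three
TIL-like niches per slide — 250 µm disks at 1200 cells/mm² of
CD8/PD-L1/LAG-3-high T cells (60%) and PD-L1/iNOS-high tumor cells (40%),
with background processes thinned to 30% inside the disk — and
cohort-level marker-probability shifts (+0.32 iNOS on cytotoxic T cells,
+0.20 iNOS and +0.09 PD-L1 on tumor cells). `weak` scales these to one
niche and half the shifts; `null` removes both. A `cd8_confined_config`
keeps the niches but zeroes the global shifts, confining all responder
signal to CD8-rich tiles — the designed setting in which immune-high
filtering should and does outperform the all-tile combined model. The
ground-truth niche flag marks any cell *located inside* a niche disk
(whatever its latent type), which is the region the RCN analysis can
actually recover.

Default cohort shape: 4 responders / 8 non-responders on 3 mm × 3 mm
slides (9 tiles each, ~8,000 cells per slide, ~96,000 per cohort). These
sizes were fixed once as the package's study conditions: large enough for
~25 cell states, a meaningful RCN clustering over ~10⁵ neighborhoods and
stable tile statistics, small enough that the full pipeline runs in tens
of seconds. What the generator does *not* emulate: segmentation and
thresholding errors, spatially varying marker intensity, tissue-shaped
(non-rectangular) slides, cell-size variation, biopsy-vs-resection
differences, or correlated marker noise — so passing tests demonstrate
correctness and sensitivity of the *methods*, not clinical performance on
real tissue.

## Numerical conventions

- Undefined proportions (empty denominator) are missing, never 0; missing
  values flow through to the tree models natively.
- Edge-correction weights are capped at inside-fraction 10⁻³ and logged.
- The Ripley grid is 0–100 µm in 1 µm steps; printed radii are read off
  the grid and the cluster score uses the trapezoid rule on it.
- k-means uses 10 restarts (4 during elbow scans) with seeded centers;
  RCN relabelling by size is deterministic when sizes are distinct.
- All cohort-level randomness derives from one seed via spawned
  `SeedSequence` streams; per-slide streams make generation
  order-independent.

## Limitations

Neighborhoods and spatial features do not cross tile borders; features
from the two mIF panels are never combined spatially (panels are analysed
separately); the elbow rule inherits the ambiguity of WCSS elbows on
overlapping clusters; pooled grouped-CV AUC is pessimistically biased
under the null (see above) and should be read against the permutation
reference, not against 0.5; and patient-level calls from 9-tile synthetic
slides are coarser than calls from the hundreds of tiles a resection
yields.
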