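# immunotile

Tile-based spatial analysis of multiplex immunofluorescence (mIF) cell
tables for predicting patient response to immune checkpoint blockade.

Targeted mIF assays report, for every segmented cell on a slide, a centroid
and a binary positivity call for each of ~8 protein markers (e.g. CD3, CD8,
PD-L1, LAG-3, SOX10, iNOS). `immunotile` turns a cohort of such per-cell
tables into interpretable tile-level features and a leave-one-patient-out
response classifier:

1. **Ingestion** — per-slide CSV/Parquet exports are normalised to µm
   coordinates (pixel inputs scaled by the image resolution, default
   0.4992 µm/px) and validated.
2. **Tiling** — each slide is partitioned into 1 mm × 1 mm tiles by cell
   centroid; tiles with ≥ 100 cells enter the analysis.
3. **Cell states** — the top-20 exact marker combinations across the cohort,
   plus singleton states and a stromal state (no positive marker). A cell
   belongs to every state whose marker set it expresses (superset
   membership).
4. **Compositional features** — per-tile state proportions and subpopulation
   fractions P(Y+ | X+) for marker pairs.
5. **Spatial features** — per-tile, per state pair:
   - *proximity scores*: pair counts at distance < r ∈ {20, 30, 60, 90} µm,
     normalised by the sum of the two states' tile proportions;
   - *Ripley's cross-K/L* with isotropic edge correction on the tile
     rectangle,

     K̂(r) = |W|/(n_A n_B) Σ_{i∈A} Σ_{j∈B, j≠i} w_ij 1(d_ij ≤ r),
     L(r) = √(K̂(r)/π),

     where w_ij is the reciprocal of the fraction of the circle centred at
     cell i with radius d_ij lying inside the tile. Under complete spatial
     randomness L(r) = r, so ΔL = L − r measures clustering (> 0) or
     separation (< 0); the *cluster score* integrates ΔL over 0–100 µm.
6. **Recurrent cellular neighborhoods (RCNs)** — every cell's 60 µm
   neighborhood is summarised as a state-proportion profile; k-means over
   all profiles (k from a WCSS elbow rule) yields RCNs, whose per-tile
   proportions become features.
7. **Univariate screens** — Wilcoxon rank-sum with Benjamini–Hochberg FDR
   across each feature family, per-group Pearson correlations, and a
   linear mixed model per feature (response group fixed, slide random
   intercept, likelihood-ratio test).
8. **Classification** — LightGBM over three feature configurations
   (*compositional*, *combined* = + RCN + ΔL(20 µm), *immune-high* =
   combined restricted to tiles with ≥ 2% CD8+ cells), evaluated by
   repeated leave-one-patient-out cross-validation with pooled metrics,
   tile-majority patient calls, SHAP feature importance and a CD8-cutoff
   sweep.

A synthetic cohort generator (`immunotile.synthetic`) emulates the data:
Poisson stroma, Thomas-process tumor nests, immune aggregates, and planted
TIL-like niches plus marker-probability shifts on responder slides, with
`null` / `weak` / `strong` effect presets and full ground truth — so every
stage is testable without patient data.

## Worked example

```python
import immunotile as it

tables, metadata, truth = it.generate_cohort(it.strong_config(seed=7))
result = it.run_feature_pipeline(tables, seed=0)

cfg = it.ModelConfig(mode="immune_high", n_iterations=5, base_seed=0)
x, y, groups = it.assemble_features(result.features, cfg)
cv = it.logo_cv(x, y, groups, cfg)
print(cv.metrics_summary()["mean"][["roc_auc", "accuracy"]])
print(cv.patient_calls()[["slide_id", "call", "correct"]])
```

On this cohort (12 slides, ~96,000 cells, 108 tiles) the pipeline finds 25
cell states and an elbow-selected k = 6 RCNs; RCN6 (the smallest, 3,322
neighborhoods) matches the planted niches with an adjusted Rand index of
0.937. The immune-high classifier reaches pooled ROC AUC ≈ 1.0 on the
strong preset and calls all 12 patients correctly — the planted effect is
deliberately blatant; the `null` preset calibrates the other end of the
scale. The `examples/` directory walks through each capability
(`python examples/04_recurrent_neighborhoods.py` prints the RCN table and
ARI above).

## Layout

- `src/immunotile/` — library modules (`cells`, `tiling`, `states`,
  `features`, `spatial`, `rcn`, `stats`, `model`, `synthetic`,
  `pipeline`).
- `examples/` — one narrative script per capability.
- `presets/` — versioned YAML synthetic-cohort presets.
- `docs/methods.md` — models, assumptions, parameter choices and
  limitations.
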