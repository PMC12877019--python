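"""Leave-one-patient-out response classification from tile features.

Three feature configurations are assembled from the tile feature table:

* ``compositional`` — cell-state proportions + subpopulation proportions;
* ``combined`` — compositional + RCN proportions + Ripley delta-L at 20 µm;
* ``immune_high`` — combined, restricted to tiles with a CD8+ cell
  proportion at or above a threshold (default 2%).

Tiles inherit their patient's response label. Cross-validation is
leave-one-group-out over slides, repeated for ``n_iterations`` with fresh
classifier seeds; per iteration, the 12 folds' test predictions are pooled
into one prediction set before computing metrics, and metric means ± sd
are reported across iterations. Patient-level calls are the majority class
over a slide's predicted tiles (exact tie -> non-responder, the cohort
majority class; no qualifying tiles -> no-call).

The default classifier is a LightGBM gradient-boosted tree ensemble
(native missing-value handling); the classifier factory is pluggable.
Feature importance is the mean |Shapley attribution| of each feature over
all test-tile predictions, computed with LightGBM's exact TreeSHAP
(``pred_contrib``); permutation importance is the fallback for classifier
families without additive attributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import feature_columns
from .stats import NON_RESPONDER, RESPONDER

logger = logging.getLogger(__name__)

DEFAULT_CD8_THRESHOLD = 0.02
DEFAULT_CD8_COLUMN = "comp/CD8"
RIPLEY_20UM_NAMESPACE = "ripley/dL@20"

METRIC_NAMES = (
    "accuracy",
    "roc_auc",
    "auprc",
    "precision",
    "recall",
    "specificity",
    "balanced_accuracy",
    "f1",
)


def default_classifier(seed: int) -> LGBMClassifier:
    """Gradient-boosted trees sized for cohort-scale tile tables.

    Balanced class weights keep predicted probabilities comparable across
    leave-one-slide-out folds whose class balance shifts with the held-out
    slide (4R/8NR cohorts), and the tree constraints limit noise fitting on
    ~100-tile training sets; both matter for honest pooled-AUC behaviour
    under label-permutation nulls.
    """
    return LGBMClassifier(
        n_estimators=100,
        learning_rate=0.05,
        num_leaves=15,
        min_child_samples=10,
        subsample=0.8,
        subsample_freq=1,
        colsample_bytree=0.8,
        class_weight="balanced",
        reg_lambda=1.0,
        random_state=seed,
        deterministic=True,
        n_jobs=1,
        verbose=-1,
    )


@dataclass
class ModelConfig:
    mode: str = "combined"  # compositional | combined | immune_high
    cd8_threshold: float = DEFAULT_CD8_THRESHOLD
    cd8_column: str = DEFAULT_CD8_COLUMN
    n_iterations: int = 100
    base_seed: int = 0
    classifier_factory: Callable[[int], object] = default_classifier
    feature_include: list[str] | None = None
    collect_importance: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("compositional", "combined", "immune_high"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.cd8_threshold <= 0.05:
            raise ValueError("cd8_threshold must lie in [0, 0.05]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def assemble_features(
    features: pd.DataFrame, config: ModelConfig
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Select feature columns and tiles for a model mode.

    Returns ``(X, y, groups)`` where ``X`` keeps tile_id as index and NaNs
    as NaNs, ``y`` is boolean (responder = positive class) and ``groups``
    holds slide ids. ``immune_high`` keeps tiles whose CD8+ proportion is
    >= the threshold; slides losing all tiles become no-call at the
    patient level.
    """
    if config.mode == "compositional":
        cols = feature_columns(features, "comp", "subpop")
    else:
        cols = feature_columns(features, "comp", "subpop", "rcn", RIPLEY_20UM_NAMESPACE)
    if config.feature_include is not None:
        cols = [c for c in cols if c in set(config.feature_include)]
    if not cols:
        raise ValueError(f"no feature columns for mode {config.mode!r}")

    rows = features
    if config.mode == "immune_high":
        if config.cd8_column not in features.columns:
            raise ValueError(f"missing CD8 column {config.cd8_column!r}")
        rows = features[features[config.cd8_column] >= config.cd8_threshold]
        dropped = set(features["slide_id"]) - set(rows["slide_id"])
        if dropped:
            logger.warning("slides with no qualifying tiles: %s", sorted(dropped))
    x = rows[cols]
    y = (rows["response"] == RESPONDER).to_numpy()
    groups = rows["slide_id"].to_numpy()
    return x, y, groups


def pool_metrics(
    y_true: np.ndarray, prob: np.ndarray, y_pred: np.ndarray | None = None
) -> dict[str, float]:
    """The eight pooled prediction metrics; responder is the positive class."""
    y_true = np.asarray(y_true, dtype=bool)
    prob = np.asarray(prob, dtype=float)
    if y_pred is None:
        y_pred = prob >= 0.5
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = int((y_true & y_pred).sum())
    fp = int((~y_true & y_pred).sum())
    tn = int((~y_true & ~y_pred).sum())
    fn = int((y_true & ~y_pred).sum())
    n = len(y_true)
    precision = tp / (tp + fp) if tp + fp else np.nan
    recall = tp / (tp + fn) if tp + fn else np.nan
    specificity = tn / (tn + fp) if tn + fp else np.nan
    f1 = (
        2 * precision * recall / (precision + recall)
        if np.isfinite(precision) and np.isfinite(recall) and precision + recall > 0
        else (0.0 if np.isfinite(precision) and np.isfinite(recall) else np.nan)
    )
    single_class = y_true.all() or not y_true.any()
    return {
        "accuracy": (tp + tn) / n if n else np.nan,
        "roc_auc": np.nan if single_class else float(roc_auc_score(y_true, prob)),
        "auprc": np.nan if single_class else float(average_precision_score(y_true, prob)),
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "balanced_accuracy": (
            (recall + specificity) / 2
            if np.isfinite(recall) and np.isfinite(specificity)
            else np.nan
        ),
        "f1": f1,
    }


def patient_vote(tile_predictions: np.ndarray | pd.Series) -> str:
    """Majority class over a slide's predicted tiles.

    ``tile_predictions`` is boolean (True = responder). Exact tie ->
    non-responder (the cohort majority class and the clinically
    conservative call); no tiles -> no-call.
    """
    preds = np.asarray(tile_predictions, dtype=bool)
    if len(preds) == 0:
        return "no-call"
    pos = int(preds.sum())
    return RESPONDER if pos > len(preds) - pos else NON_RESPONDER


@dataclass
class CVResult:
    predictions: pd.DataFrame  # iteration, tile_id, slide_id, y_true, prob, y_pred
    iteration_metrics: pd.DataFrame  # one row per iteration
    feature_names: list[str]
    importance: pd.DataFrame | None = None
    attributions: pd.DataFrame | None = None  # signed, last iteration
    config: ModelConfig | None = None

    def metrics_summary(self) -> pd.DataFrame:
        return self.iteration_metrics[list(METRIC_NAMES)].agg(["mean", "std"]).T

    def patient_calls(self) -> pd.DataFrame:
        """Per-slide majority call over all pooled tile predictions."""
        rows = []
        for slide, sub in self.predictions.groupby("slide_id"):
            call = patient_vote(sub["y_pred"].to_numpy())
            truth = RESPONDER if bool(sub["y_true"].iloc[0]) else NON_RESPONDER
            rows.append(
                {
                    "slide_id": slide,
                    "call": call,
                    "truth": truth,
                    "correct": call == truth,
                    "n_tiles": sub["tile_id"].nunique(),
                }
            )
        return pd.DataFrame(rows).sort_values("slide_id").reset_index(drop=True)


def _shap_attributions(model, x: np.ndarray) -> np.ndarray | None:
    """Exact TreeSHAP attributions (n, n_features + 1 base column)."""
    booster = getattr(model, "booster_", None)
    if booster is None:
        return None
    return booster.predict(x, pred_contrib=True)


def logo_cv(
    x: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    config: ModelConfig | None = None,
) -> CVResult:
    """Repeated leave-one-slide-out cross-validation with pooled metrics.

    Every tile is predicted exactly once per iteration by a model that
    never saw its slide; the split structure is asserted. Deterministic
    given (data, config, base seed).
    """
    config = config or ModelConfig()
    y = np.asarray(y, dtype=bool)
    groups = np.asarray(groups)
    unique_groups = np.unique(groups)
    for cls in (True, False):
        if len(np.unique(groups[y == cls])) < 2:
            raise ValueError("need >= 2 slides per class for grouped CV")

    feature_names = list(x.columns)
    x_values = x.to_numpy(dtype=float)
    tile_ids = np.asarray(x.index)

    pred_frames = []
    metric_rows = []
    abs_contrib_sum = np.zeros(len(feature_names))
    contrib_count = 0
    attributions = None
    for it in range(config.n_iterations):
        seed = config.base_seed + it
        probs = np.full(len(y), np.nan)
        signed_rows = [] if it == config.n_iterations - 1 else None
        for g in unique_groups:
            test = groups == g
            train = ~test
            assert not (set(groups[train]) & {g}), "slide leaked into training"
            if len(np.unique(y[train])) < 2:
                warnings.warn(f"fold {g}: training labels single-class, skipped")
                continue
            clf = config.classifier_factory(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(x_values[train], y[train])
                p = clf.predict_proba(x_values[test])[:, 1]
            probs[test] = p
            if config.collect_importance:
                contrib = _shap_attributions(clf, x_values[test])
                if contrib is not None:
                    abs_contrib_sum += np.abs(contrib[:, :-1]).sum(axis=0)
                    contrib_count += contrib.shape[0]
                    if signed_rows is not None:
                        signed = pd.DataFrame(
                            contrib[:, :-1], columns=feature_names,
                            index=tile_ids[test],
                        )
                        signed["base_value"] = contrib[:, -1]
                        signed_rows.append(signed)
                else:
                    config.collect_importance = False
                    logger.warning(
                        "classifier lacks additive attributions; use "
                        "permutation_importance() instead"
                    )
        evaluated = ~np.isnan(probs)
        pred = probs >= 0.5
        frame = pd.DataFrame(
            {
                "iteration": it,
                "tile_id": tile_ids[evaluated],
                "slide_id": groups[evaluated],
                "y_true": y[evaluated],
                "prob": probs[evaluated],
                "y_pred": pred[evaluated],
            }
        )
        pred_frames.append(frame)
        metric_rows.append(
            {"iteration": it, **pool_metrics(y[evaluated], probs[evaluated], pred[evaluated])}
        )
        if signed_rows:
            attributions = pd.concat(signed_rows)

    importance = None
    if contrib_count:
        importance = (
            pd.DataFrame(
                {
                    "feature": feature_names,
                    "mean_abs_shap": abs_contrib_sum / contrib_count,
                }
            )
            .sort_values("mean_abs_shap", ascending=False)
            .reset_index(drop=True)
        )
        importance["rank"] = np.arange(1, len(importance) + 1)
    return CVResult(
        predictions=pd.concat(pred_frames, ignore_index=True),
        iteration_metrics=pd.DataFrame(metric_rows),
        feature_names=feature_names,
        importance=importance,
        attributions=attributions,
        config=config,
    )


def permutation_importance_summary(
    x: pd.DataFrame, y: np.ndarray, fitted_model, seed: int = 0, n_repeats: int = 5
) -> pd.DataFrame:
    """Permutation-importance fallback for non-additive classifiers."""
    from sklearn.inspection import permutation_importance

    res = permutation_importance(
        fitted_model, x.to_numpy(dtype=float), np.asarray(y, dtype=bool),
        n_repeats=n_repeats, random_state=seed,
    )
    out = pd.DataFrame(
        {"feature": list(x.columns), "importance": res.importances_mean}
    ).sort_values("importance", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["method"] = "permutation"
    return out


def threshold_sweep(
    features: pd.DataFrame,
    cutoffs: list[float],
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """LOGO-CV metrics across CD8-proportion cutoffs (0 = all tiles).

    Returns one row per cutoff with mean pooled metrics and the number of
    qualifying tiles and no-call slides.
    """
    if sorted(cutoffs) != list(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    base = config or ModelConfig()
    rows = []
    for cutoff in cutoffs:
        cfg = ModelConfig(
            mode="combined" if cutoff == 0 else "immune_high",
            cd8_threshold=cutoff,
            cd8_column=base.cd8_column,
            n_iterations=base.n_iterations,
            base_seed=base.base_seed,
            classifier_factory=base.classifier_factory,
            collect_importance=False,
        )
        x, y, groups = assemble_features(features, cfg)
        n_slides = features["slide_id"].nunique()
        result = logo_cv(x, y, groups, cfg)
        summary = result.metrics_summary()["mean"]
        rows.append(
            {
                "cutoff": cutoff,
                "n_tiles": len(x),
                "n_no_call_slides": n_slides - pd.unique(groups).size,
                **{m: summary[m] for m in METRIC_NAMES},
            }
        )
    return pd.DataFrame(rows)


def permute_labels_by_slide(
    y: np.ndarray, groups: np.ndarray, seed: int
) -> np.ndarray:
    """Permute response labels at the patient level (null calibration)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=bool)
    groups = np.asarray(groups)
    slides = pd.unique(groups)
    slide_labels = np.array([y[groups == s][0] for s in slides])
    permuted = rng.permutation(slide_labels)
    mapping = dict(zip(slides, permuted))
    return np.array([mapping[g] for g in groups])
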