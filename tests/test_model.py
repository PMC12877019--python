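"""Response model: feature assembly, LOGO-CV structure, pooled metrics,
patient votes and attribution additivity."""

import numpy as np
import pandas as pd
import pytest

import immunotile as it
from immunotile.model import default_classifier, patient_vote, pool_metrics


def _feature_fixture():
    rng = np.random.default_rng(0)
    n = 40
    df = pd.DataFrame(
        {
            "slide_id": np.repeat([f"s{i}" for i in range(8)], 5),
            "response": np.repeat(
                ["responder"] * 2 + ["non-responder"] * 6, 5
            ),
            "n_cells": 100,
            "comp/CD3": rng.uniform(size=n),
            "comp/CD8": np.tile([0.01, 0.02, 0.05, 0.001, 0.03], 8),
            "comp/Stromal": rng.uniform(size=n),
            "subpop/CD8_in_CD3": rng.uniform(size=n),
            "subpop/PD-L1_in_SOX10": rng.uniform(size=n),
            "rcn/RCN1": rng.uniform(size=n),
            "rcn/RCN2": rng.uniform(size=n),
            "ripley/dL@20/CD3__CD3": rng.normal(size=n),
            "ripley/dL@30/CD3__CD3": rng.normal(size=n),
            "ripley/score/CD3__CD3": rng.normal(size=n),
        },
        index=pd.Index([f"t{i}" for i in range(n)], name="tile_id"),
    )
    return df


class TestAssembleFeatures:
    def test_compositional_selects_comp_and_subpop_only(self):
        df = _feature_fixture()
        x, y, g = it.assemble_features(df, it.ModelConfig(mode="compositional"))
        assert sorted(x.columns) == [
            "comp/CD3", "comp/CD8", "comp/Stromal",
            "subpop/CD8_in_CD3", "subpop/PD-L1_in_SOX10",
        ]

    def test_combined_adds_rcn_and_20um_ripley_only(self):
        df = _feature_fixture()
        x, _, _ = it.assemble_features(df, it.ModelConfig(mode="combined"))
        assert "rcn/RCN1" in x.columns
        assert "ripley/dL@20/CD3__CD3" in x.columns
        assert "ripley/dL@30/CD3__CD3" not in x.columns
        assert "ripley/score/CD3__CD3" not in x.columns
        assert len(x.columns) == 8

    def test_immune_high_threshold_is_inclusive(self):
        """Tiles at exactly the 2% CD8 threshold are retained (>= rule)."""
        df = _feature_fixture()
        x, _, _ = it.assemble_features(
            df, it.ModelConfig(mode="immune_high", cd8_threshold=0.02)
        )
        kept = df.loc[x.index, "comp/CD8"]
        assert (kept >= 0.02).all()
        assert set(kept.unique()) == {0.02, 0.03, 0.05}


class TestPoolMetrics:
    def test_confusion_arithmetic(self):
        """TP=3 FP=1 TN=5 FN=1."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        prob = pred.astype(float)
        m = pool_metrics(y, prob, pred)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["f1"] == pytest.approx(0.75)
        assert m["balanced_accuracy"] == pytest.approx((0.75 + 5 / 6) / 2)

    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0], dtype=bool)
        m = pool_metrics(y, np.array([0.9, 0.8, 0.2, 0.1]))
        assert m["roc_auc"] == 1.0 and m["auprc"] == 1.0

    def test_constant_score_gives_half_auc(self):
        y = np.array([1, 0, 1, 0], dtype=bool)
        m = pool_metrics(y, np.full(4, 0.5))
        assert m["roc_auc"] == pytest.approx(0.5)

    def test_single_class_truth_has_missing_auc(self):
        m = pool_metrics(np.ones(3, dtype=bool), np.array([0.9, 0.8, 0.7]))
        assert np.isnan(m["roc_auc"])


class TestPatientVote:
    def test_majority(self):
        assert patient_vote(np.array([1] * 7 + [0] * 3, dtype=bool)) == "responder"

    def test_exact_tie_goes_to_non_responder(self):
        assert patient_vote(np.array([1] * 5 + [0] * 5, dtype=bool)) == "non-responder"

    def test_no_tiles_is_no_call(self):
        assert patient_vote(np.array([], dtype=bool)) == "no-call"


class TestLogoCV:
    def test_no_slide_leaks_into_its_training_fold(self):
        df = _feature_fixture()
        cfg = it.ModelConfig(mode="combined", n_iterations=2, base_seed=0)
        x, y, g = it.assemble_features(df, cfg)
        res = it.logo_cv(x, y, g, cfg)
        # every tile predicted exactly once per iteration
        per_iter = res.predictions.groupby("iteration")["tile_id"].nunique()
        assert (per_iter == len(x)).all()

    def test_reproducible_given_seed(self):
        df = _feature_fixture()
        cfg = it.ModelConfig(mode="combined", n_iterations=2, base_seed=5)
        x, y, g = it.assemble_features(df, cfg)
        r1 = it.logo_cv(x, y, g, cfg)
        r2 = it.logo_cv(x, y, g, cfg)
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)
        pd.testing.assert_frame_equal(r1.iteration_metrics, r2.iteration_metrics)

    def test_balanced_accuracy_identity_on_pooled_sets(self):
        df = _feature_fixture()
        cfg = it.ModelConfig(mode="combined", n_iterations=3, base_seed=1)
        x, y, g = it.assemble_features(df, cfg)
        res = it.logo_cv(x, y, g, cfg)
        m = res.iteration_metrics
        np.testing.assert_allclose(
            m["balanced_accuracy"], (m["recall"] + m["specificity"]) / 2
        )

    def test_shap_attributions_sum_to_model_margin(self):
        """Shapley additivity: contributions + base = raw model output."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 5))
        y = (x[:, 0] + 0.5 * x[:, 1] + rng.normal(scale=0.5, size=200)) > 0
        clf = default_classifier(0)
        clf.fit(x, y)
        contrib = clf.booster_.predict(x, pred_contrib=True)
        margin = clf.booster_.predict(x, raw_score=True)
        np.testing.assert_allclose(contrib.sum(axis=1), margin, atol=1e-6)

    def test_importance_ranks_planted_signal_above_noise(self):
        rng = np.random.default_rng(2)
        n = 120
        slides = np.repeat([f"s{i}" for i in range(12)], 10)
        y_slide = {f"s{i}": i < 4 for i in range(12)}
        y = np.array([y_slide[s] for s in slides])
        df = pd.DataFrame(
            {
                "slide_id": slides,
                "response": np.where(y, "responder", "non-responder"),
                "n_cells": 100,
                "comp/signal": y + rng.normal(scale=0.3, size=n),
                "comp/noise": rng.normal(size=n),
            },
            index=pd.Index([f"t{i}" for i in range(n)], name="tile_id"),
        )
        cfg = it.ModelConfig(mode="compositional", n_iterations=2, base_seed=0)
        x, yy, g = it.assemble_features(df, cfg)
        res = it.logo_cv(x, yy, g, cfg)
        imp = res.importance.set_index("feature")["mean_abs_shap"]
        assert imp["comp/signal"] > imp["comp/noise"]


class TestThresholdSweep:
    def test_qualifying_tiles_non_increasing_and_zero_cutoff_is_combined(self):
        df = _feature_fixture()
        base = it.ModelConfig(n_iterations=1, base_seed=0, collect_importance=False)
        sweep = it.threshold_sweep(df, [0.0, 0.01, 0.02, 0.04], base)
        assert (np.diff(sweep["n_tiles"]) <= 0).all()
        assert sweep["n_tiles"].iloc[0] == len(df)
        cfg = it.ModelConfig(mode="combined", n_iterations=1, base_seed=0,
                             collect_importance=False)
        x, y, g = it.assemble_features(df, cfg)
        ref = it.logo_cv(x, y, g, cfg)
        assert sweep["roc_auc"].iloc[0] == pytest.approx(
            ref.iteration_metrics["roc_auc"].mean()
        )

    def test_unsorted_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            it.threshold_sweep(_feature_fixture(), [0.02, 0.01])


def test_permute_labels_by_slide_keeps_slide_constancy():
    g = np.repeat(list("abcdef"), 4)
    y = np.repeat([1, 1, 0, 0, 0, 0], 4).astype(bool)
    yp = it.permute_labels_by_slide(y, g, seed=0)
    assert yp.sum() == y.sum()
    for s in "abcdef":
        assert len(set(yp[g == s])) == 1
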