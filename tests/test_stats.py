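"""Univariate screens: BH, rank-sum, correlations, mixed-effects model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import immunotile as it
from immunotile.stats import mixed_effects_screen, wilcoxon_screen


def _tile_frame(values_by_slide, responders):
    rows = []
    for slide, values in values_by_slide.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "slide_id": slide,
                    "response": "responder" if slide in responders else "non-responder",
                    "n_cells": 100,
                    "feat": v,
                }
            )
    return pd.DataFrame(rows)


class TestBH:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            it.bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_single_p_unchanged(self):
        assert it.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(it.bh_adjust([0.05] * 10), [0.05] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            it.bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_dominating(self, p):
        adj = it.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestWilcoxon:
    def test_exact_two_sided_p(self):
        """{1,2,3} vs {4,5,6}: U=0, exact two-sided p = 2/C(6,3) = 0.1."""
        df = _tile_frame({"R1": [1, 2, 3], "N1": [4, 5, 6]}, {"R1"})
        res = wilcoxon_screen(df, feature_cols=["feat"])
        assert res.p_raw[0] == pytest.approx(0.1)

    def test_identical_groups(self):
        df = _tile_frame({"R1": [1, 2, 3], "N1": [1, 2, 3]}, {"R1"})
        res = wilcoxon_screen(df, feature_cols=["feat"])
        assert res.p_raw[0] == pytest.approx(1.0)
        assert res.fold_change[0] == pytest.approx(1.0)

    def test_constant_feature_all_ties(self):
        df = _tile_frame({"R1": [2, 2, 2], "N1": [2, 2, 2]}, {"R1"})
        res = wilcoxon_screen(df, feature_cols=["feat"])
        assert res.p_raw[0] == 1.0

    def test_one_group_all_missing_is_untestable(self):
        df = _tile_frame({"R1": [np.nan] * 3, "N1": [1, 2, 3]}, {"R1"})
        res = wilcoxon_screen(df, feature_cols=["feat"])
        assert np.isnan(res.p_raw[0]) and "untestable" in res.note[0]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        df = _tile_frame(
            {"R1": rng.normal(1, 1, 20), "N1": rng.normal(0, 1, 20)}, {"R1"}
        )
        p1 = wilcoxon_screen(df, feature_cols=["feat"]).p_raw[0]
        df2 = df.assign(feat=np.exp(df["feat"]))
        p2 = wilcoxon_screen(df2, feature_cols=["feat"]).p_raw[0]
        assert p1 == pytest.approx(p2)


class TestCorrelations:
    def test_perfect_and_hand_worked_r(self):
        df = pd.DataFrame(
            {
                "slide_id": "R1",
                "response": "responder",
                "n_cells": 100,
                "a": [1.0, 2, 3, 4],
                "b": [1.0, 2, 3, 4],
                "c": [-1.0, -2, -3, -4],
                "d": [1.0, 3, 2, 4],
            }
        )
        out = it.group_correlations(df, ["a", "b", "c", "d"])
        r = out["responder"]
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert r.loc["a", "d"] == pytest.approx(0.8)

    def test_zero_variance_column_gives_nan(self):
        df = pd.DataFrame(
            {
                "slide_id": "R1",
                "response": "responder",
                "n_cells": 1,
                "a": [1.0, 2, 3],
                "b": [5.0, 5, 5],
            }
        )
        out = it.group_correlations(df, ["a", "b"])
        assert np.isnan(out["responder"].loc["a", "b"])


class TestMixedEffects:
    def _cohort(self, rng, shift=0.0, n_tiles=15):
        responders = {"R1", "R2", "R3", "R4"}
        slides = list(responders) + [f"N{i}" for i in range(1, 9)]
        values = {}
        for s in slides:
            intercept = rng.normal(0, 0.5)
            mu = intercept + (shift if s in responders else 0.0)
            values[s] = mu + rng.normal(0, 1, n_tiles)
        return _tile_frame(values, responders)

    def test_planted_slide_level_effect_detected(self):
        rng = np.random.default_rng(1)
        df = self._cohort(rng, shift=2.0)
        res = mixed_effects_screen(df, feature_cols=["feat"])
        assert res.p_raw[0] < 0.01

    def test_feature_in_too_few_slides_skipped(self):
        rng = np.random.default_rng(2)
        df = self._cohort(rng)
        missing_slides = {"N6", "N7", "N8"}
        df.loc[df.slide_id.isin(missing_slides), "feat"] = np.nan
        res = mixed_effects_screen(df, feature_cols=["feat"], min_slides_present=10)
        assert np.isnan(res.p_raw[0]) and "skipped" in res.note[0]

    def test_type_one_error_under_slide_permuted_null(self):
        """100 slide-permuted replicates: rejection rate in [0.01, 0.10]."""
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(100):
            df = self._cohort(rng, shift=0.0, n_tiles=10)
            res = mixed_effects_screen(df, feature_cols=["feat"])
            if res.p_raw[0] < 0.05:
                hits += 1
        assert 0.01 <= hits / 100 <= 0.10

    def test_proportion_features_are_log_transformed(self):
        # a proportion-valued feature goes through log10+pseudocount without error
        rng = np.random.default_rng(4)
        df = self._cohort(rng, shift=0.0)
        df["feat"] = rng.uniform(0, 0.2, len(df))
        df.loc[df.index[:5], "feat"] = 0.0
        res = mixed_effects_screen(df, feature_cols=["feat"])
        assert np.isfinite(res.p_raw[0])
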