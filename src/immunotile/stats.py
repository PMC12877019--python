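"""Univariate screening of tile features between response groups.

Two complementary screens are provided, mirroring the trade-off between
power and pseudo-replication when tiles from the same slide are treated as
observations:

* :func:`wilcoxon_screen` — two-sided Wilcoxon rank-sum (Mann-Whitney U)
  per feature over tiles, with Benjamini-Hochberg FDR adjustment across
  the tested family and responder/non-responder mean fold changes.
* :func:`mixed_effects_screen` — a linear mixed model per feature
  (feature ~ response group, random intercept per slide, ML fit) with a
  likelihood-ratio test for the group effect; accounts for slide-to-slide
  variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NON_RESPONDER = "non-responder"


@dataclass
class FeatureTestResult:
    feature: str
    test: str
    n_r: int
    n_nr: int
    mean_r: float
    mean_nr: float
    fold_change: float
    p_raw: float
    p_adj: float = np.nan
    note: str = ""


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaNs (untestable features) are passed through and do not count toward
    the family size.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _fold_change(mean_r: float, mean_nr: float) -> float:
    if mean_nr == 0 or not np.isfinite(mean_nr) or not np.isfinite(mean_r):
        return np.nan
    fc = mean_r / mean_nr
    return fc if fc > 0 else np.nan


def wilcoxon_screen(
    features: pd.DataFrame,
    labels: pd.Series | None = None,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Rank-sum test per feature, responder vs non-responder tiles.

    ``labels`` defaults to the table's ``response`` column. Missing values
    are dropped per feature; a feature entirely missing in one group is
    reported untestable (NaN p). BH adjustment spans all testable features
    passed in one call (one family per feature set).
    """
    if labels is None:
        labels = features["response"]
    labels = pd.Series(np.asarray(labels), index=features.index)
    is_r = (labels == RESPONDER).to_numpy()
    is_nr = (labels == NON_RESPONDER).to_numpy()
    if not is_r.any() or not is_nr.any():
        raise ValueError("need tiles from both response groups")
    if feature_cols is None:
        from .features import is_feature_column

        feature_cols = [c for c in features.columns if is_feature_column(c)]

    results: list[FeatureTestResult] = []
    for col in feature_cols:
        x = features[col].to_numpy(dtype=float)
        r = x[is_r & ~np.isnan(x)]
        nr = x[is_nr & ~np.isnan(x)]
        if len(r) == 0 or len(nr) == 0:
            results.append(
                FeatureTestResult(
                    col, "wilcoxon", len(r), len(nr), np.nan, np.nan, np.nan,
                    np.nan, note="untestable: one group all-missing",
                )
            )
            continue
        if np.all(r == r[0]) and np.all(nr == r[0]):
            p = 1.0  # all ties: no evidence either way
        else:
            p = float(sps.mannwhitneyu(r, nr, alternative="two-sided").pvalue)
        mean_r, mean_nr = float(r.mean()), float(nr.mean())
        results.append(
            FeatureTestResult(
                col, "wilcoxon", len(r), len(nr), mean_r, mean_nr,
                _fold_change(mean_r, mean_nr), p,
            )
        )
    out = pd.DataFrame([vars(r) for r in results])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def group_correlations(
    features: pd.DataFrame,
    columns: list[str],
    labels: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson R over tiles, separately per response group.

    Pairwise-complete on missing values; zero-variance columns yield NaN
    rows/columns. Groups with fewer than 3 tiles are skipped.
    """
    if labels is None:
        labels = features["response"]
    labels = pd.Series(np.asarray(labels), index=features.index)
    out: dict[str, pd.DataFrame] = {}
    for group in (RESPONDER, NON_RESPONDER):
        sub = features.loc[(labels == group).to_numpy(), columns]
        if len(sub) < 3:
            logger.warning("group %s has <3 tiles; skipping correlations", group)
            continue
        out[group] = sub.corr(method="pearson", min_periods=3)
    return out


def _log10_with_pseudocount(x: np.ndarray) -> np.ndarray:
    nz = x[(x > 0) & ~np.isnan(x)]
    pseudo = nz.min() / 2.0 if len(nz) else 1.0
    return np.log10(x + pseudo)


def mixed_effects_screen(
    features: pd.DataFrame,
    labels: pd.Series | None = None,
    slide_ids: pd.Series | None = None,
    feature_cols: list[str] | None = None,
    min_slides_present: int = 10,
    log_transform: str = "auto",
) -> pd.DataFrame:
    """Per-feature linear mixed model with slide as random intercept.

    Model: ``value ~ response`` with a random intercept per slide, fitted
    by maximum likelihood; the group-effect p-value is a likelihood-ratio
    test against the intercept-only mixed model (chi-square, 1 df).
    Proportion-valued features (``log_transform="auto"``: all observed
    values in [0, 1]) are log10-transformed with a pseudo-count of half
    the smallest nonzero value. Features observed in fewer than
    ``min_slides_present`` slides are skipped. BH adjustment spans the
    tested features.
    """
    if labels is None:
        labels = features["response"]
    if slide_ids is None:
        slide_ids = features["slide_id"]
    labels = pd.Series(np.asarray(labels), index=features.index)
    slide_ids = pd.Series(np.asarray(slide_ids), index=features.index)
    for group in (RESPONDER, NON_RESPONDER):
        n_slides = slide_ids[(labels == group).to_numpy()].nunique()
        if n_slides < 2:
            raise ValueError(f"need >=2 slides in group {group!r}")
    if feature_cols is None:
        from .features import is_feature_column

        feature_cols = [c for c in features.columns if is_feature_column(c)]

    n_slides_total = slide_ids.nunique()
    is_r = (labels == RESPONDER).to_numpy()
    results: list[FeatureTestResult] = []
    for col in feature_cols:
        x = features[col].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        slides_present = slide_ids[ok].nunique()
        if slides_present < min(min_slides_present, n_slides_total):
            results.append(
                FeatureTestResult(
                    col, "mixed_effects", int(is_r[ok].sum()), int((~is_r)[ok].sum()),
                    np.nan, np.nan, np.nan, np.nan,
                    note=f"skipped: present in {slides_present} slides",
                )
            )
            continue
        y = x[ok]
        if log_transform == "always" or (
            log_transform == "auto" and np.nanmin(y) >= 0 and np.nanmax(y) <= 1
        ):
            y = _log10_with_pseudocount(y)
        g = is_r[ok].astype(float)
        slides = slide_ids[ok].to_numpy()
        mean_r = float(x[ok & is_r].mean()) if (ok & is_r).any() else np.nan
        mean_nr = float(x[ok & ~is_r].mean()) if (ok & ~is_r).any() else np.nan
        p, note = _lrt_mixed(y, g, slides)
        results.append(
            FeatureTestResult(
                col, "mixed_effects", int(is_r[ok].sum()), int((~is_r)[ok].sum()),
                mean_r, mean_nr, _fold_change(mean_r, mean_nr), p, note=note,
            )
        )
    out = pd.DataFrame([vars(r) for r in results])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def _lrt_mixed(y: np.ndarray, group: np.ndarray, slides: np.ndarray) -> tuple[float, str]:
    """Likelihood-ratio test for the group fixed effect (ML fits)."""
    exog_full = np.column_stack([np.ones_like(y), group])
    exog_null = np.ones((len(y), 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = MixedLM(y, exog_full, groups=slides).fit(reml=False)
            null = MixedLM(y, exog_null, groups=slides).fit(reml=False)
        lr = 2.0 * (full.llf - null.llf)
        p = float(sps.chi2.sf(max(lr, 0.0), df=1))
        return p, ""
    except (np.linalg.LinAlgError, ValueError) as exc:
        return np.nan, f"singular fit: {exc}"
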