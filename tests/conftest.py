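"""Shared fixtures: tiny hand-built slides and session-scoped synthetic
cohorts with their feature pipelines (computed once, reused across tests)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import immunotile as it


def make_table(
    xy: np.ndarray,
    positivity: np.ndarray | None = None,
    slide_id: str = "S",
    response: str = "unknown",
    panel: it.MarkerPanel = it.LYMPHOID_PANEL,
) -> it.CellTable:
    """Build a CellTable from coordinates and an optional positivity matrix."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if positivity is None:
        positivity = np.zeros((n, 8), dtype=bool)
    df = pd.DataFrame(
        {"cell_id": [f"{slide_id}-{i}" for i in range(n)], "x": xy[:, 0], "y": xy[:, 1]}
    )
    for i, m in enumerate(panel.markers):
        df[m] = np.asarray(positivity, dtype=bool)[:, i]
    return it.CellTable(
        panel=panel, slide_id=slide_id, cells=df, response=response
    )


def markers_to_positivity(
    marker_sets: list[set[str]], panel: it.MarkerPanel = it.LYMPHOID_PANEL
) -> np.ndarray:
    return np.array(
        [[m in s for m in panel.markers] for s in marker_sets], dtype=bool
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """Synthetic cohort at the 'strong' effect preset (4R / 8NR)."""
    config = it.strong_config(seed=1)
    tables, metadata, truth = it.generate_cohort(config)
    return config, tables, metadata, truth


@pytest.fixture(scope="session")
def strong_pipeline(strong_cohort):
    _, tables, _, _ = strong_cohort
    return it.run_feature_pipeline(tables, seed=0)


@pytest.fixture(scope="session")
def cd8_confined_features():
    """Cohort whose responder signal lives only in CD8-rich niches."""
    config = it.cd8_confined_config(seed=1)
    tables, _, _ = it.generate_cohort(config)
    result = it.run_feature_pipeline(tables, seed=0)
    return result.features
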