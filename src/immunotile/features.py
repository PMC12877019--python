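"""Per-tile feature extraction into a tile-by-feature table.

Feature namespaces (frozen, so importance reports are comparable between
runs):

* ``comp/<state>`` — proportion of tile cells that are members of a
  catalog cell state (superset membership; states overlap, so columns do
  not sum to 1).
* ``subpop/<Y>_in_<X>`` — P(Y+ | X+) within the tile for ordered marker
  pairs; missing (NaN), never 0, when the tile has no X+ cells.
* ``prox/<A>__<B>@<r>`` — normalised proximity score at radius r µm.
* ``ripley/L@<r>/<A>__<B>``, ``ripley/dL@<r>/<A>__<B>``,
  ``ripley/score/<A>__<B>`` — Ripley L_iso, delta-L and the 0-100 µm
  cluster score per state pair (unordered, A = catalog order first).
* ``rcn/RCN<i>`` — recurrent-neighborhood proportions (added by
  :mod:`immunotile.rcn`).

Metadata columns ``slide_id``, ``response``, ``n_cells`` ride along; the
table is indexed by ``tile_id``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cells import CellTable
from .spatial import PROXIMITY_RADII_UM, RIPLEY_RADII_UM, TilePairEngine
from .states import CellStateCatalog, membership_matrix

logger = logging.getLogger(__name__)

META_COLUMNS = ("slide_id", "response", "n_cells")


def is_feature_column(name: str) -> bool:
    return name not in META_COLUMNS


def state_proportions(
    membership: np.ndarray, catalog: CellStateCatalog
) -> dict[str, float]:
    """``comp/`` features: member count of each state / tile cell count."""
    n = membership.shape[0]
    if n == 0:
        raise ValueError("empty tile")
    props = membership.sum(axis=0) / n
    return {f"comp/{label}": float(p) for label, p in zip(catalog.labels, props)}


def subpop_proportions(positivity: np.ndarray, markers: tuple[str, ...]) -> dict[str, float]:
    """``subpop/`` features: P(Y+ | X+) for every ordered marker pair X != Y.

    Missing (NaN) when the tile has no X+ cells — absence of evidence is
    kept distinct from an observed zero.
    """
    pos = np.asarray(positivity, dtype=bool)
    totals = pos.sum(axis=0).astype(float)
    joint = (pos.T.astype(np.int64) @ pos.astype(np.int64)).astype(float)
    out: dict[str, float] = {}
    for ix, x in enumerate(markers):
        for iy, y in enumerate(markers):
            if ix == iy:
                continue
            value = joint[ix, iy] / totals[ix] if totals[ix] > 0 else np.nan
            out[f"subpop/{y}_in_{x}"] = value
    return out


def state_pairs(catalog: CellStateCatalog) -> list[tuple[int, int]]:
    """Unordered state-pair indices including self pairs, catalog order."""
    n = catalog.n_states
    return [(i, j) for i in range(n) for j in range(i, n)]


def compute_tile_features(
    tables: list[CellTable],
    tiles: pd.DataFrame,
    assignments: dict[str, pd.Series],
    catalog: CellStateCatalog,
    proximity_radii: tuple[float, ...] = PROXIMITY_RADII_UM,
    ripley_radii: tuple[float, ...] = RIPLEY_RADII_UM,
    include_spatial: bool = True,
) -> pd.DataFrame:
    """Compute compositional (+ optionally spatial) features per retained tile.

    Spatial features reuse one pairwise-distance computation per tile (the
    tile rectangle is the edge-correction window). Tiles flagged
    ``retained=False`` are skipped entirely.
    """
    pairs = state_pairs(catalog)
    labels = catalog.labels
    by_slide = {t.slide_id: t for t in tables}
    rows: list[dict] = []
    index: list[str] = []
    for _, tile in tiles[tiles["retained"]].iterrows():
        table = by_slide[tile["slide_id"]]
        mask = (assignments[table.slide_id] == tile["tile_id"]).to_numpy()
        cells = table.cells.loc[mask]
        xy = cells[["x", "y"]].to_numpy(dtype=float)
        pos = cells[list(table.panel.markers)].to_numpy(dtype=bool)
        mem = membership_matrix(pos, catalog)

        row: dict[str, float] = {
            "slide_id": table.slide_id,
            "response": table.response,
            "n_cells": int(len(cells)),
        }
        row.update(state_proportions(mem, catalog))
        row.update(subpop_proportions(pos, table.panel.markers))

        if include_spatial:
            window = (tile["x0"], tile["x1"], tile["y0"], tile["y1"])
            engine = TilePairEngine(xy, mem, window)
            for i, j in pairs:
                a, b = labels[i], labels[j]
                for r in proximity_radii:
                    row[f"prox/{a}__{b}@{r:g}"] = engine.proximity(i, j, r)
                curve = engine.ripley(i, j, labels=(a, b))
                if curve is None:
                    for r in ripley_radii:
                        row[f"ripley/L@{r:g}/{a}__{b}"] = np.nan
                        row[f"ripley/dL@{r:g}/{a}__{b}"] = np.nan
                    row[f"ripley/score/{a}__{b}"] = np.nan
                else:
                    for r in ripley_radii:
                        l_iso, d_l = curve.at(r)
                        row[f"ripley/L@{r:g}/{a}__{b}"] = l_iso
                        row[f"ripley/dL@{r:g}/{a}__{b}"] = d_l
                    row[f"ripley/score/{a}__{b}"] = curve.cluster_score
        rows.append(row)
        index.append(tile["tile_id"])

    out = pd.DataFrame(rows, index=pd.Index(index, name="tile_id"))
    if out.index.has_duplicates:
        raise ValueError("duplicate tile_ids in feature table")
    return out


def feature_columns(table: pd.DataFrame, *namespaces: str) -> list[str]:
    """Columns of the given namespaces (e.g. ``'comp'``, ``'ripley/dL@20'``)."""
    cols = []
    for c in table.columns:
        if not is_feature_column(c):
            continue
        if any(c == ns or c.startswith(ns + "/") for ns in namespaces):
            cols.append(c)
    return cols
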