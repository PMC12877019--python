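"""Partition slides into 1 mm x 1 mm tiles by cell centroid.

Tiles are the unit of all downstream feature computation. The grid is
anchored at the minimum cell centroid of the slide, uses half-open
[x0, x1) x [y0, y1) intervals so boundary cells are assigned
deterministically, and tiles with fewer than ``min_cells`` cells are flagged
``retained=False`` and excluded from every downstream feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cells import CellTable

DEFAULT_TILE_SIZE_UM = 1000.0
DEFAULT_MIN_CELLS = 100


def tile_id(slide_id: str, ix: int, iy: int) -> str:
    return f"{slide_id}:{ix}:{iy}"


def build_tiles(
    table: CellTable,
    tile_size: float = DEFAULT_TILE_SIZE_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign every cell of a slide to exactly one square tile.

    Returns
    -------
    tiles
        One row per non-empty tile: ``tile_id, slide_id, ix, iy, x0, x1,
        y0, y1, n_cells, retained``.
    assignment
        Series aligned to ``table.cells`` giving each cell's tile_id.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if table.n_cells == 0:
        raise ValueError(f"slide {table.slide_id}: empty cell table")

    xy = table.coords()
    origin = xy.min(axis=0)
    idx = np.floor((xy - origin) / tile_size).astype(int)
    ix, iy = idx[:, 0], idx[:, 1]
    assignment = pd.Series(
        [tile_id(table.slide_id, a, b) for a, b in zip(ix, iy)],
        index=table.cells.index,
        name="tile_id",
    )

    keys, counts = np.unique(idx, axis=0, return_counts=True)
    tiles = pd.DataFrame(
        {
            "tile_id": [tile_id(table.slide_id, a, b) for a, b in keys],
            "slide_id": table.slide_id,
            "ix": keys[:, 0],
            "iy": keys[:, 1],
            "x0": origin[0] + keys[:, 0] * tile_size,
            "y0": origin[1] + keys[:, 1] * tile_size,
            "n_cells": counts,
        }
    )
    tiles["x1"] = tiles["x0"] + tile_size
    tiles["y1"] = tiles["y0"] + tile_size
    tiles["retained"] = tiles["n_cells"] >= min_cells
    tiles = tiles[
        ["tile_id", "slide_id", "ix", "iy", "x0", "x1", "y0", "y1", "n_cells", "retained"]
    ]
    return tiles, assignment


def build_cohort_tiles(
    tables: list[CellTable],
    tile_size: float = DEFAULT_TILE_SIZE_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Tile every slide; returns concatenated tile table and per-slide assignments."""
    all_tiles = []
    assignments: dict[str, pd.Series] = {}
    for t in tables:
        tiles, assign = build_tiles(t, tile_size=tile_size, min_cells=min_cells)
        all_tiles.append(tiles)
        assignments[t.slide_id] = assign
    return pd.concat(all_tiles, ignore_index=True), assignments
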