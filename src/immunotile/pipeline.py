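"""End-to-end orchestration: cell tables -> tile feature table.

Chains tiling, cell-state cataloging, compositional and spatial feature
extraction and RCN analysis into one tile feature table ready for the
univariate screens and the response classifier. Each stage remains
individually callable; this module only wires defaults together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cells import CellTable
from .features import compute_tile_features
from .rcn import (
    RCNModel,
    cohort_profiles,
    fit_rcn,
    rcn_tile_proportions,
    select_k_elbow,
)
from .states import CellStateCatalog, enumerate_states
from .tiling import DEFAULT_MIN_CELLS, DEFAULT_TILE_SIZE_UM, build_cohort_tiles

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    tiles: pd.DataFrame
    catalog: CellStateCatalog
    features: pd.DataFrame  # tile_id-indexed feature table incl. rcn/ columns
    rcn_model: RCNModel | None
    profiles: pd.DataFrame | None  # per-cell neighborhood profiles


def run_feature_pipeline(
    tables: list[CellTable],
    tile_size: float = DEFAULT_TILE_SIZE_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
    top_n_states: int = 20,
    include_spatial: bool = True,
    include_rcn: bool = True,
    rcn_k: int | None = None,
    rcn_k_range: tuple[int, int] = (2, 12),
    rcn_radius: float = 60.0,
    seed: int = 0,
) -> PipelineResult:
    """Compute the full tile feature table for a cohort of slides.

    ``rcn_k=None`` selects k by the elbow rule; pass an integer to pin it.
    """
    tiles, assignments = build_cohort_tiles(tables, tile_size, min_cells)
    n_retained = int(tiles["retained"].sum())
    logger.info("tiled %d slides into %d tiles (%d retained)", len(tables), len(tiles), n_retained)
    catalog = enumerate_states(tables, top_n=top_n_states)
    features = compute_tile_features(
        tables, tiles, assignments, catalog, include_spatial=include_spatial
    )

    rcn_model = None
    profiles = None
    if include_rcn:
        profiles = cohort_profiles(tables, tiles, assignments, catalog, radius=rcn_radius)
        if rcn_k is None:
            rcn_k = select_k_elbow(profiles, k_range=rcn_k_range, seed=seed)
            logger.info("elbow-selected k=%d RCNs", rcn_k)
        rcn_model = fit_rcn(profiles, k=rcn_k, seed=seed)
        rcn_props = rcn_tile_proportions(rcn_model, profiles["tile_id"])
        features = features.join(rcn_props, how="left")

    return PipelineResult(
        tiles=tiles,
        catalog=catalog,
        features=features,
        rcn_model=rcn_model,
        profiles=profiles,
    )
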