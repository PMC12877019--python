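"""Recurrent cellular neighborhoods (RCNs).

Every cell seeds a neighborhood: all cells of the same tile whose centroid
lies within 60 µm (inclusive; the seed is its own neighbor, so
neighborhoods are never empty). Each neighborhood is summarised as the
vector of cell-state proportions among its members, and k-means over all
neighborhood profiles defines the recurrent neighborhoods, relabelled by
descending size (RCN1 = largest). Per-tile RCN label proportions become
``rcn/`` tile features.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .cells import CellTable
from .states import CellStateCatalog, membership_matrix

logger = logging.getLogger(__name__)

DEFAULT_NEIGHBORHOOD_RADIUS_UM = 60.0
DEFAULT_ELBOW_TAU = 0.10
DEFAULT_MAX_FIT_POINTS = 500_000


def neighborhood_profiles(
    xy: np.ndarray,
    membership: np.ndarray,
    radius: float = DEFAULT_NEIGHBORHOOD_RADIUS_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood state-proportion profile for every cell of one tile.

    Returns ``(profiles, n_neighbors)`` where ``profiles[i, s]`` is the
    fraction of cells within ``radius`` of cell *i* (inclusive boundary,
    seed included) that are members of state *s*.
    """
    xy = np.asarray(xy, dtype=float)
    membership = np.asarray(membership, dtype=float)
    n = len(xy)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    rows = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(n)])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(n)])
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    counts = np.asarray(adj.sum(axis=1)).ravel()
    profiles = adj @ membership / counts[:, None]
    return profiles, counts.astype(int)


def cohort_profiles(
    tables: list[CellTable],
    tiles: pd.DataFrame,
    assignments: dict[str, pd.Series],
    catalog: CellStateCatalog,
    radius: float = DEFAULT_NEIGHBORHOOD_RADIUS_UM,
) -> pd.DataFrame:
    """Neighborhood profiles for all cells of all retained tiles.

    Neighborhoods are tile-bounded: cells just across a tile border do not
    contribute to a seed's neighborhood. Returns a DataFrame with one row
    per profiled cell: state-proportion columns (catalog labels),
    ``tile_id``, ``slide_id``, ``cell_id`` and ``n_neighbors``.
    """
    by_slide = {t.slide_id: t for t in tables}
    frames = []
    for _, tile in tiles[tiles["retained"]].iterrows():
        table = by_slide[tile["slide_id"]]
        mask = (assignments[table.slide_id] == tile["tile_id"]).to_numpy()
        cells = table.cells.loc[mask]
        xy = cells[["x", "y"]].to_numpy(dtype=float)
        pos = cells[list(table.panel.markers)].to_numpy(dtype=bool)
        mem = membership_matrix(pos, catalog)
        profiles, counts = neighborhood_profiles(xy, mem, radius=radius)
        frame = pd.DataFrame(profiles, columns=catalog.labels)
        frame["tile_id"] = tile["tile_id"]
        frame["slide_id"] = table.slide_id
        frame["cell_id"] = cells["cell_id"].to_numpy()
        frame["n_neighbors"] = counts
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _profile_matrix(profiles: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(profiles, pd.DataFrame):
        cols = [
            c
            for c in profiles.columns
            if c not in ("tile_id", "slide_id", "cell_id", "n_neighbors")
        ]
        return profiles[cols].to_numpy(dtype=float)
    return np.asarray(profiles, dtype=float)


def _wcss_curve(
    x: np.ndarray, ks: list[int], seed: int, n_init: int = 4
) -> dict[int, float]:
    wcss = {}
    for k in ks:
        km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
        km.fit(x)
        wcss[k] = float(km.inertia_)
    return wcss


def select_k_elbow(
    profiles: pd.DataFrame | np.ndarray,
    k_range: tuple[int, int] = (2, 12),
    tau: float = DEFAULT_ELBOW_TAU,
    seed: int = 0,
    max_fit_points: int = DEFAULT_MAX_FIT_POINTS,
) -> int:
    """Elbow rule on the within-cluster sum of squares (WCSS).

    WCSS strictly decreases in k, so "until it does not decrease" is
    operationalised as the smallest k whose relative drop to k+1,
    ``(WCSS(k) - WCSS(k+1)) / WCSS(k)``, falls below ``tau``. If no k in
    the range qualifies, the maximum is returned with a warning.
    """
    x = _profile_matrix(profiles)
    x = _maybe_subsample(x, max_fit_points, seed)
    k_lo, k_hi = k_range
    if k_lo < 2:
        raise ValueError("k_range must start at >= 2")
    ks = list(range(k_lo, k_hi + 2))  # need WCSS at k_hi + 1 for the rule
    wcss = _wcss_curve(x, ks, seed)
    for k in range(k_lo, k_hi + 1):
        drop = (wcss[k] - wcss[k + 1]) / wcss[k]
        if drop < tau:
            return k
    warnings.warn(f"no elbow below tau={tau}; returning k={k_hi}")
    return k_hi


def elbow_from_wcss(wcss: list[float], k_start: int = 1, tau: float = DEFAULT_ELBOW_TAU) -> int:
    """Apply the relative-decrease elbow rule to a precomputed WCSS curve."""
    for i in range(len(wcss) - 1):
        if (wcss[i] - wcss[i + 1]) / wcss[i] < tau:
            return k_start + i
    return k_start + len(wcss) - 1


def _maybe_subsample(x: np.ndarray, max_fit_points: int, seed: int) -> np.ndarray:
    if len(x) <= max_fit_points:
        return x
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(x), size=max_fit_points, replace=False)
    logger.info("k-means fit on %d of %d profiles (seeded subsample)", max_fit_points, len(x))
    return x[idx]


@dataclass
class RCNModel:
    """Fitted k-means over neighborhood-profile space, size-ordered."""

    k: int
    centers: np.ndarray  # (k, n_states), row i = RCN{i+1}
    sizes: np.ndarray  # descending
    seed: int
    labels: np.ndarray  # per profiled cell, 0-based (0 = RCN1)
    state_labels: list[str]

    @property
    def rcn_names(self) -> list[str]:
        return [f"RCN{i + 1}" for i in range(self.k)]

    def assign(self, profiles: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = _profile_matrix(profiles)
        d2 = ((x[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def to_json(self, path=None) -> str:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "sizes": self.sizes.tolist(),
            "state_labels": self.state_labels,
            "centers": self.centers.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_rcn(
    profiles: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    max_fit_points: int = DEFAULT_MAX_FIT_POINTS,
    state_labels: list[str] | None = None,
) -> RCNModel:
    """K-means over neighborhood profiles, clusters relabelled by size.

    Centers are fitted on a seeded uniform subsample when the profile count
    exceeds ``max_fit_points``; all profiles are then assigned to their
    nearest center. An empty cluster (identical profiles, k too large) is
    an error.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = _profile_matrix(profiles)
    n_distinct = len(np.unique(x, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct profiles")
    fit_x = _maybe_subsample(x, max_fit_points, seed)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    km.fit(fit_x)
    labels = km.predict(x)
    sizes = np.bincount(labels, minlength=k)
    if (sizes == 0).any():
        raise ValueError("k-means produced an empty cluster; reduce k")
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    if state_labels is None and isinstance(profiles, pd.DataFrame):
        state_labels = [
            c
            for c in profiles.columns
            if c not in ("tile_id", "slide_id", "cell_id", "n_neighbors")
        ]
    return RCNModel(
        k=k,
        centers=km.cluster_centers_[order],
        sizes=sizes[order],
        seed=seed,
        labels=remap[labels],
        state_labels=state_labels or [],
    )


def rcn_tile_proportions(
    model: RCNModel, tile_ids: pd.Series | np.ndarray
) -> pd.DataFrame:
    """``rcn/`` tile features: per-tile proportion of cells in each RCN.

    Rows sum to 1 exactly (every profiled cell carries one RCN label).
    """
    df = pd.DataFrame({"tile_id": np.asarray(tile_ids), "label": model.labels})
    counts = (
        df.groupby(["tile_id", "label"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=range(model.k), fill_value=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"rcn/{name}" for name in model.rcn_names]
    props.index.name = "tile_id"
    return props
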