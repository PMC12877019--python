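"""Per-tile spatial statistics: proximity scores and cross-type Ripley's K/L.

Two families of second-order statistics are computed between cell-state
point sets within a tile:

* **Proximity scores** — the number of state-A/state-B cell pairs closer
  than a radius (strict ``<``, radii 20/30/60/90 µm by default), normalised
  by the sum of the two states' tile proportions.
* **Ripley's cross-K/L** — the edge-corrected estimator

  .. math:: \\hat K(r) = \\frac{|W|}{n_A n_B} \\sum_{i \\in A}
            \\sum_{j \\in B, j \\neq i} w_{ij}\\, \\mathbf 1(d_{ij} \\le r)

  with Ripley's isotropic correction :math:`w_{ij}` — the reciprocal of the
  fraction of the circle centred at cell *i* with radius :math:`d_{ij}`
  that lies inside the tile rectangle. The variance-stabilised
  :math:`L(r) = \\sqrt{K(r)/\\pi}` equals :math:`r` under complete spatial
  randomness; ``delta_L = L - r`` is positive for clustering and negative
  for repulsion, and the *cluster score* integrates delta-L over 0-100 µm.

Conventions (frozen): the weight is evaluated at the first (A) point of
each ordered pair; the Ripley indicator is ``<=`` while proximity counting
is strict ``<``; a cell belonging to both states of a pair contributes to
both sides but never pairs with itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

PROXIMITY_RADII_UM = (20.0, 30.0, 60.0, 90.0)
RIPLEY_RADII_UM = (20.0, 30.0, 60.0, 90.0)
CLUSTER_SCORE_MAX_R_UM = 100.0
#: isotropic-correction inside-fraction floor; weights are capped at 1/floor
WEIGHT_FRACTION_FLOOR = 1e-3


def default_r_grid() -> np.ndarray:
    """0-100 µm in 1 µm steps; serves both the printed radii and the integral."""
    return np.arange(0.0, CLUSTER_SCORE_MAX_R_UM + 1.0, 1.0)


def isotropic_weight(
    centers: np.ndarray,
    d: np.ndarray,
    window: tuple[float, float, float, float],
    fraction_floor: float = WEIGHT_FRACTION_FLOOR,
) -> np.ndarray:
    """Ripley isotropic edge-correction weights for a rectangular window.

    Parameters
    ----------
    centers
        (n, 2) circle centres (must lie inside the window).
    d
        (n,) circle radii (pair distances), > 0.
    window
        Rectangle ``(x0, x1, y0, y1)``.

    Returns the reciprocal of the arc fraction of each circle lying inside
    the rectangle (1 for fully interior circles, 2 for a centre on an edge
    far from corners). Fractions below ``fraction_floor`` are capped and
    logged. Exact for radii up to the distance to the furthest-but-one edge
    (always the case for pair distances well below the window size).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    d = np.asarray(d, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    x0, x1, y0, y1 = window
    if np.any(d <= 0):
        raise ValueError("radii must be positive")
    a1 = centers[:, 0] - x0  # distances to the four edges
    a2 = x1 - centers[:, 0]
    b1 = centers[:, 1] - y0
    b2 = y1 - centers[:, 1]
    if np.any((a1 < 0) | (a2 < 0) | (b1 < 0) | (b2 < 0)):
        raise ValueError("circle centres must lie inside the window")

    exterior = np.zeros_like(d)
    with np.errstate(invalid="ignore"):
        for e in (a1, a2, b1, b2):
            cut = e < d
            if np.any(cut):
                exterior[cut] += 2.0 * np.arccos(np.clip(e[cut] / d[cut], -1, 1))
        # corner overlap: the two adjacent edge arcs double-count the corner arc
        for ex, ey in ((a1, b1), (a1, b2), (a2, b1), (a2, b2)):
            over = ex**2 + ey**2 < d**2
            if np.any(over):
                exterior[over] -= (
                    np.arccos(np.clip(ex[over] / d[over], -1, 1))
                    + np.arccos(np.clip(ey[over] / d[over], -1, 1))
                    - np.pi / 2.0
                )
    fraction = 1.0 - exterior / (2.0 * np.pi)
    capped = fraction < fraction_floor
    if np.any(capped):
        logger.warning(
            "isotropic correction capped for %d pairs (inside fraction < %g)",
            int(capped.sum()),
            fraction_floor,
        )
        fraction = np.maximum(fraction, fraction_floor)
    w = 1.0 / fraction
    return float(w[0]) if scalar else w


@dataclass
class ProximityScore:
    state_a: str
    state_b: str
    radius: float
    count: int
    prop_a: float
    prop_b: float

    @property
    def score(self) -> float:
        denom = self.prop_a + self.prop_b
        return np.nan if denom == 0 else self.count / denom


def proximity_score(
    pts_a: np.ndarray,
    pts_b: np.ndarray,
    radius: float,
    n_total: int,
    shared_cells: int = 0,
    same_state: bool = False,
) -> ProximityScore | None:
    """Normalised count of A-B cell pairs at distance < ``radius``.

    ``n_total`` is the tile cell count (denominator of the two state
    proportions). ``shared_cells`` is the number of cells belonging to both
    states (their zero self-distances are excluded). With
    ``same_state=True`` the two point sets are identical and unordered
    distinct pairs are counted. Returns ``None`` (missing) when either
    state is absent from the tile.
    """
    pts_a = np.asarray(pts_a, dtype=float).reshape(-1, 2)
    pts_b = np.asarray(pts_b, dtype=float).reshape(-1, 2)
    n_a, n_b = len(pts_a), len(pts_b)
    if n_a == 0 or n_b == 0:
        return None
    # cKDTree.count_neighbors counts d <= r; shrink r one ulp for strict <
    r_open = np.nextafter(radius, 0.0)
    count = cKDTree(pts_a).count_neighbors(cKDTree(pts_b), r_open)
    if same_state:
        count = (count - n_a) // 2  # drop self pairs, halve ordered pairs
    else:
        count -= shared_cells
    return ProximityScore(
        state_a="A",
        state_b="B",
        radius=radius,
        count=int(count),
        prop_a=n_a / n_total,
        prop_b=n_b / n_total,
    )


@dataclass
class RipleyCurve:
    """Edge-corrected cross-K/L curve for one state pair on one tile."""

    state_a: str
    state_b: str
    r: np.ndarray
    k: np.ndarray

    @property
    def l(self) -> np.ndarray:  # noqa: E743 - L(r) is the field's name
        return np.sqrt(self.k / np.pi)

    @property
    def delta_l(self) -> np.ndarray:
        return self.l - self.r

    @property
    def cluster_score(self) -> float:
        mask = self.r <= CLUSTER_SCORE_MAX_R_UM
        return float(np.trapezoid(self.delta_l[mask], self.r[mask]))

    def at(self, radius: float) -> tuple[float, float]:
        """(L_iso, delta_L) at a radius on the grid."""
        i = int(np.argmin(np.abs(self.r - radius)))
        return float(self.l[i]), float(self.delta_l[i])


def ripley_cross_k(
    pts_a: np.ndarray,
    pts_b: np.ndarray,
    window: tuple[float, float, float, float],
    r_grid: np.ndarray | None = None,
    ids_a: np.ndarray | None = None,
    ids_b: np.ndarray | None = None,
    edge_correction: bool = True,
    labels: tuple[str, str] = ("A", "B"),
) -> RipleyCurve:
    """Cross-type Ripley K with isotropic border correction on a rectangle.

    ``ids_a``/``ids_b`` identify cells so that a cell present in both point
    sets (superset state membership) is never paired with itself; when
    omitted and ``pts_a is pts_b`` the diagonal is excluded. With
    ``edge_correction=False`` all weights are 1 (used by the brute-force
    oracle equivalence check).
    """
    same = pts_a is pts_b
    pts_a = np.asarray(pts_a, dtype=float).reshape(-1, 2)
    pts_b = pts_a if same else np.asarray(pts_b, dtype=float).reshape(-1, 2)
    if r_grid is None:
        r_grid = default_r_grid()
    r_grid = np.asarray(r_grid, dtype=float)
    n_a, n_b = len(pts_a), len(pts_b)
    if n_a == 0 or n_b == 0 or (same and n_a < 2):
        raise ValueError("each state needs at least one cell (two when A=B)")
    x0, x1, y0, y1 = window
    area = (x1 - x0) * (y1 - y0)

    d = cdist(pts_a, pts_b)
    if ids_a is not None and ids_b is not None:
        self_pair = np.asarray(ids_a).reshape(-1, 1) == np.asarray(ids_b).reshape(1, -1)
    elif same:
        self_pair = np.eye(n_a, dtype=bool)
    else:
        self_pair = np.zeros_like(d, dtype=bool)

    r_max = float(r_grid[-1])
    use = (d <= r_max) & ~self_pair
    ai, bj = np.nonzero(use)
    dists = d[ai, bj]
    if edge_correction and len(dists):
        w = _pair_weights(pts_a[ai], dists, window)
    else:
        w = np.ones_like(dists)
    k = _k_from_pairs(r_grid, dists, w, area, n_a, n_b)
    return RipleyCurve(state_a=labels[0], state_b=labels[1], r=r_grid, k=k)


def _pair_weights(centers: np.ndarray, dists: np.ndarray, window) -> np.ndarray:
    """Isotropic weights; co-located pairs (d=0) get weight 1."""
    w = np.ones_like(dists)
    pos = dists > 0
    if np.any(pos):
        w[pos] = isotropic_weight(centers[pos], dists[pos], window)
    return w


def _k_from_pairs(
    r_grid: np.ndarray,
    dists: np.ndarray,
    w: np.ndarray,
    area: float,
    n_a: int,
    n_b: int,
) -> np.ndarray:
    """Weighted cumulative pair counts on the grid (indicator d <= r)."""
    k = np.zeros_like(r_grid)
    if len(dists):
        order = np.searchsorted(r_grid, dists, side="left")
        if r_grid[0] == 0.0:
            # K(0) = 0 by definition; coincident pairs enter at the next radius
            order = np.maximum(order, 1)
        np.add.at(k, order, w)
        k = np.cumsum(k)
    return k * area / (n_a * n_b)


class TilePairEngine:
    """Shared distance/weight computation for all state pairs of one tile.

    Builds the full pairwise distance matrix of the tile's cells once, plus
    isotropic weights for pairs within the Ripley grid, and serves per-pair
    proximity counts and Ripley curves from slices of it.
    """

    def __init__(
        self,
        xy: np.ndarray,
        membership: np.ndarray,
        window: tuple[float, float, float, float],
        r_grid: np.ndarray | None = None,
    ):
        self.xy = np.asarray(xy, dtype=float)
        self.membership = np.asarray(membership, dtype=bool)
        self.window = window
        self.r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, float)
        x0, x1, y0, y1 = window
        self.area = (x1 - x0) * (y1 - y0)
        n = len(self.xy)
        self.n_cells = n
        self._d = cdist(self.xy, self.xy).astype(np.float32)
        np.fill_diagonal(self._d, np.inf)  # excludes self pairs everywhere
        r_max = float(self.r_grid[-1])
        ai, bj = np.nonzero(self._d <= r_max)
        self._pairs_a = ai
        self._pairs_b = bj
        self._pair_d = self._d[ai, bj].astype(float)
        if len(ai):
            self._pair_w = _pair_weights(self.xy[ai], self._pair_d, window)
        else:
            self._pair_w = np.zeros(0)

    def state_indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.membership[:, j])

    def proximity(self, j_a: int, j_b: int, radius: float) -> float:
        """Normalised proximity score (NaN when a state is absent)."""
        in_a = self.membership[:, j_a]
        in_b = self.membership[:, j_b]
        n_a, n_b = int(in_a.sum()), int(in_b.sum())
        if n_a == 0 or n_b == 0:
            return np.nan
        sel = in_a[self._pairs_a] & in_b[self._pairs_b] & (self._pair_d < radius)
        count = int(sel.sum())
        if j_a == j_b:
            count //= 2
        denom = (n_a + n_b) / self.n_cells
        return count / denom

    def ripley(self, j_a: int, j_b: int, labels: tuple[str, str]) -> RipleyCurve | None:
        """Ripley curve for a state pair; None when a state is absent."""
        in_a = self.membership[:, j_a]
        in_b = self.membership[:, j_b]
        n_a, n_b = int(in_a.sum()), int(in_b.sum())
        if n_a == 0 or n_b == 0 or (j_a == j_b and n_a < 2):
            return None
        sel = in_a[self._pairs_a] & in_b[self._pairs_b]
        k = _k_from_pairs(
            self.r_grid, self._pair_d[sel], self._pair_w[sel], self.area, n_a, n_b
        )
        return RipleyCurve(state_a=labels[0], state_b=labels[1], r=self.r_grid, k=k)
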