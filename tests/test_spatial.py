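"""Spatial statistics: edge-correction analytics, exhaustive pair oracles,
CSR calibration and sign checks for clustering/repulsion."""

import numpy as np
import pytest

import immunotile as it
from immunotile.spatial import (
    TilePairEngine,
    default_r_grid,
    isotropic_weight,
    proximity_score,
    ripley_cross_k,
)

WINDOW = (0.0, 1000.0, 0.0, 1000.0)


def _arc_fraction_numeric(center, d, window, n=200_000):
    """Independent oracle: sample the circle and measure the inside arc."""
    theta = (np.arange(n) + 0.5) / n * 2 * np.pi
    px = center[0] + d * np.cos(theta)
    py = center[1] + d * np.sin(theta)
    x0, x1, y0, y1 = window
    inside = (px >= x0) & (px <= x1) & (py >= y0) & (py <= y1)
    return inside.mean()


class TestIsotropicWeight:
    def test_interior_circle_weight_one(self):
        assert isotropic_weight(np.array([[500.0, 500.0]]), 50.0, WINDOW) == 1.0

    def test_centre_on_edge_weight_two(self):
        w = isotropic_weight(np.array([[0.0, 500.0]]), 10.0, WINDOW)
        assert w == pytest.approx(2.0)

    def test_near_edge_analytic_two_thirds(self):
        """Centre (1,5) in [0,10]^2 at d=2: inside fraction 2/3, weight 1.5."""
        w = isotropic_weight(np.array([[1.0, 5.0]]), 2.0, (0, 10, 0, 10))
        assert w == pytest.approx(1.5, abs=1e-12)

    @pytest.mark.parametrize(
        "center,d",
        [
            ((1.0, 5.0), 2.0),
            ((0.5, 0.5), 3.0),  # corner: adjacent edge arcs overlap
            ((9.9, 2.0), 4.0),
            ((5.0, 0.1), 2.5),
        ],
    )
    def test_matches_numeric_arc_integration(self, center, d):
        window = (0, 10, 0, 10)
        frac = _arc_fraction_numeric(center, d, window)
        w = isotropic_weight(np.array([center]), d, window)
        assert w == pytest.approx(1.0 / frac, rel=1e-3)

    def test_weight_floor_caps_blowup(self):
        # a corner-hugging centre with a huge radius: almost no arc inside
        w = isotropic_weight(
            np.array([[0.001, 0.001]]), 9.0, (0, 10, 0, 10), fraction_floor=0.25
        )
        assert w <= 4.0


class TestProximityScore:
    def test_hand_worked_four_cell_example(self):
        """A at (0,0),(10,0); B at (0,5); 1 stromal; r=20 -> score 2/0.75."""
        pts_a = np.array([[0.0, 0.0], [10.0, 0.0]])
        pts_b = np.array([[0.0, 5.0]])
        score = proximity_score(pts_a, pts_b, radius=20.0, n_total=4)
        assert score.count == 2
        assert score.score == pytest.approx(2 / 0.75)

    def test_absent_state_is_missing(self):
        assert proximity_score(np.zeros((0, 2)), np.ones((3, 2)), 20.0, 10) is None

    def test_same_state_distant_pair_counts_zero(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0]])
        score = proximity_score(pts, pts, 20.0, n_total=2, same_state=True)
        assert score.count == 0 and score.score == 0.0

    def test_strict_inequality_at_radius(self):
        pts_a = np.array([[0.0, 0.0]])
        pts_b = np.array([[20.0, 0.0]])
        assert proximity_score(pts_a, pts_b, 20.0, 2).count == 0
        assert proximity_score(pts_a, pts_b, 20.0 + 1e-9, 2).count == 1

    def test_engine_matches_exhaustive_oracle_on_random_tiles(self):
        """Normalised scores equal O(n^2) enumeration exactly, 100 tiles."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = rng.integers(20, 500)
            xy = rng.uniform(0, 1000, size=(n, 2))
            member = rng.uniform(size=(n, 3)) < 0.3
            engine = TilePairEngine(xy, member, WINDOW)
            d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
            radius = float(rng.choice([20.0, 30.0, 60.0, 90.0]))
            for a in range(3):
                for b in range(3):
                    in_a = np.flatnonzero(member[:, a])
                    in_b = np.flatnonzero(member[:, b])
                    got = engine.proximity(a, b, radius)
                    if len(in_a) == 0 or len(in_b) == 0:
                        assert np.isnan(got)
                        continue
                    count = sum(
                        1
                        for i in in_a
                        for j in in_b
                        if i != j and d[i, j] < radius
                    )
                    if a == b:
                        count //= 2
                    expected = count / ((len(in_a) + len(in_b)) / n)
                    assert got == pytest.approx(expected, abs=1e-12)


class TestRipley:
    def test_single_pair_analytic_case(self):
        """Two points 5 µm apart in [0,100]^2: K(5)=10^4, L(5)=sqrt(10^4/pi)."""
        a = np.array([[50.0, 50.0]])
        b = np.array([[50.0, 55.0]])
        grid = np.array([0.0, 4.9, 5.0])
        c = ripley_cross_k(a, b, (0, 100, 0, 100), grid)
        assert c.k[2] == pytest.approx(10000.0, abs=1e-9)
        assert c.l[2] == pytest.approx(np.sqrt(10000 / np.pi), abs=1e-9)
        assert c.delta_l[2] == pytest.approx(np.sqrt(10000 / np.pi) - 5.0, abs=1e-9)
        assert c.k[1] == 0.0 and c.delta_l[1] == pytest.approx(-4.9)
        assert c.k[0] == 0.0

    def test_unweighted_equals_brute_force_on_random_tiles(self):
        """With weights forced to 1, K equals pair counting x |W|/(nA nB)."""
        rng = np.random.default_rng(7)
        grid = np.array([0.0, 20.0, 30.0, 60.0, 90.0])
        for trial in range(100):
            n_a = int(rng.integers(2, 250))
            n_b = int(rng.integers(2, 250))
            a = rng.uniform(0, 1000, size=(n_a, 2))
            b = rng.uniform(0, 1000, size=(n_b, 2))
            c = ripley_cross_k(a, b, WINDOW, grid, edge_correction=False)
            d = np.sqrt(((a[:, None] - b[None, :]) ** 2).sum(-1))
            for gi, r in enumerate(grid[1:], start=1):
                brute = (d <= r).sum() * 1e6 / (n_a * n_b)
                assert c.k[gi] == pytest.approx(brute, abs=1e-9)

    def test_self_pairs_excluded_for_same_state(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 1000, size=(100, 2))
        c = ripley_cross_k(pts, pts, WINDOW, np.array([0.0, 50.0]), edge_correction=False)
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert c.k[1] == pytest.approx((d <= 50).sum() * 1e6 / 100**2)

    def test_symmetry_with_symmetric_weights(self):
        """cross-K(A,B) == cross-K(B,A) when the weight is symmetric (=1)."""
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 1000, size=(40, 2))
        b = rng.uniform(0, 1000, size=(60, 2))
        grid = default_r_grid()
        kab = ripley_cross_k(a, b, WINDOW, grid, edge_correction=False)
        kba = ripley_cross_k(b, a, WINDOW, grid, edge_correction=False)
        np.testing.assert_allclose(kab.k, kba.k, atol=1e-9)

    def test_k_monotone_nondecreasing(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pts = rng.uniform(0, 1000, size=(200, 2))
            c = ripley_cross_k(pts, pts, WINDOW)
            assert (np.diff(c.k) >= -1e-9).all()

    def test_csr_calibration_delta_l_near_zero(self):
        """200 homogeneous Poisson tiles: mean delta-L within ±1.5 µm of 0."""
        rng = np.random.default_rng(11)
        grid = default_r_grid()
        idx = [20, 30, 60, 90]
        deltas = []
        for _ in range(200):
            pts = rng.uniform(0, 1000, size=(500, 2))
            c = ripley_cross_k(pts, pts, WINDOW, grid)
            assert (np.diff(c.k) >= -1e-9).all()
            deltas.append(c.delta_l[idx])
        mean = np.asarray(deltas).mean(axis=0)
        assert np.abs(mean).max() < 1.5

    def test_colocated_clusters_cluster_positively(self):
        rng = np.random.default_rng(12)
        center = np.array([500.0, 500.0])
        a = center + rng.normal(scale=10, size=(50, 2))
        b = center + rng.normal(scale=10, size=(50, 2))
        c = ripley_cross_k(a, b, WINDOW)
        assert c.delta_l[20] > 0
        assert c.cluster_score > 0

    def test_separated_halves_give_floor_delta_l(self):
        """A and B >= 100 µm apart: L_iso(20)=0, delta-L(20) = -20."""
        rng = np.random.default_rng(13)
        a = rng.uniform([0, 0], [400, 1000], size=(50, 2))
        b = rng.uniform([600, 0], [1000, 1000], size=(50, 2))
        c = ripley_cross_k(a, b, WINDOW)
        assert c.k[20] == 0.0
        assert c.delta_l[20] == pytest.approx(-20.0)

    def test_engine_agrees_with_standalone_estimator(self):
        rng = np.random.default_rng(14)
        xy = rng.uniform(0, 1000, size=(150, 2))
        member = rng.uniform(size=(150, 2)) < 0.4
        engine = TilePairEngine(xy, member, WINDOW)
        curve = engine.ripley(0, 1, labels=("A", "B"))
        # same-cell pairs excluded by shared-cell identity in both paths
        ids = np.arange(150)
        in_a, in_b = member[:, 0], member[:, 1]
        ref = ripley_cross_k(
            xy[in_a], xy[in_b], WINDOW,
            ids_a=ids[in_a], ids_b=ids[in_b],
        )
        np.testing.assert_allclose(curve.k, ref.k, rtol=1e-6)
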