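import numpy as np
import pytest

from incaclust import (
    DistanceMatrix,
    Partition,
    allocate,
    between_group_distance,
    geometric_variability,
    inca_statistic,
    proximity,
    simplex_fixture,
)
from incaclust.geometry import w_statistics

from conftest import brute_force_w, distances_to, euclidean_dm


class TestGeometricVariability:
    def test_singleton_is_zero(self):
        D = DistanceMatrix(np.array([[0, 3.0], [3.0, 0]]))
        np.testing.assert_allclose(geometric_variability(D, [1, 2]), [0, 0])

    def test_two_point_group(self):
        # sum of squared distances = 2 t^2, divisor 2 * 2^2 -> t^2 / 4
        t = 3.0
        D = DistanceMatrix(np.array([[0, t], [t, 0]]))
        np.testing.assert_allclose(geometric_variability(D, [1, 1]), [t**2 / 4])

    def test_equilateral_triangle(self):
        D = DistanceMatrix(np.ones((3, 3)) - np.eye(3))
        np.testing.assert_allclose(geometric_variability(D, [1, 1, 1]), [1 / 3])

    def test_length_mismatch(self):
        D = DistanceMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="match"):
            geometric_variability(D, [1, 2])


class TestBetweenGroupDistance:
    def test_two_singletons(self):
        D = DistanceMatrix(np.array([[0, 5.0], [5.0, 0]]))
        geom = between_group_distance(D, [1, 2])
        assert geom.delta2[0, 1] == pytest.approx(25.0)
        assert geom.delta2[0, 0] == 0.0

    def test_coincident_pairs_at_distance_t(self):
        t = 4.0
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [t, 0.0], [t, 0.0]])
        geom = between_group_distance(euclidean_dm(pts), [1, 1, 2, 2])
        assert geom.delta2[0, 1] == pytest.approx(t**2)

    def test_symmetry(self, rng):
        pts = rng.standard_normal((12, 3))
        labels = rng.integers(1, 4, size=12)
        labels[:3] = [1, 2, 3]
        geom = between_group_distance(euclidean_dm(pts), labels)
        np.testing.assert_allclose(geom.delta2, geom.delta2.T)


class TestProximity:
    def test_coinciding_singleton(self):
        D = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]))
        phi2 = proximity([0.0, 1.0], [1, 2], d=D)
        assert phi2[0] == pytest.approx(0.0)
        assert phi2[1] == pytest.approx(1.0)

    def test_two_point_group_equidistant_probe(self):
        # side-1 pair, probe at distance 1 from both: 1 - 1/4 = 3/4
        D = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]))
        phi2 = proximity([1.0, 1.0], [1, 1], d=D)
        assert phi2[0] == pytest.approx(0.75)

    def test_length_mismatch(self):
        D = DistanceMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="length"):
            proximity([1.0, 2.0], [1, 2, 2], d=D)


class TestIncaStatistic:
    def test_triangle_height(self):
        # singleton clusters at (0,0),(2,0), probe (1,1): W = height^2 = 1
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        D = euclidean_dm(pts)
        geom = between_group_distance(D, [1, 2])
        phi2 = proximity(distances_to([1.0, 1.0], pts), [1, 2], geom.variabilities)
        st = inca_statistic(phi2, geom)
        assert st.W == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(st.alpha, [0.5, 0.5], atol=1e-10)
        np.testing.assert_allclose(st.U, [1.0, 1.0], atol=1e-10)

    def test_probe_on_segment_gives_zero(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        D = euclidean_dm(pts)
        geom = between_group_distance(D, [1, 2])
        phi2 = proximity(distances_to([0.7, 0.0], pts), [1, 2], geom.variabilities)
        assert inca_statistic(phi2, geom).W == pytest.approx(0.0, abs=1e-10)

    def test_k1_convention(self):
        geom = between_group_distance(
            DistanceMatrix(np.array([[0, 1.0], [1.0, 0]])), [1, 1]
        )
        st = inca_statistic([2.5], geom)
        assert st.W == pytest.approx(2.5)
        np.testing.assert_allclose(st.U, [0.0])

    def test_alpha_sums_to_one_and_u_definition(self, rng):
        for _ in range(20):
            k = rng.integers(2, 5)
            pts = rng.standard_normal((k * 3, 4))
            labels = np.repeat(np.arange(1, k + 1), 3)
            D = euclidean_dm(pts)
            geom = between_group_distance(D, labels)
            probe = rng.standard_normal(4)
            phi2 = proximity(distances_to(probe, pts), labels, geom.variabilities)
            st = inca_statistic(phi2, geom)
            assert st.alpha.sum() == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(st.U, st.phi2 - st.W)

    def test_matches_brute_force_minimization(self, rng):
        """Linear-system W equals numeric minimization of L on >= 200
        random planar instances with k <= 4 clusters."""
        checked = 0
        while checked < 200:
            k = int(rng.integers(2, 5))
            sizes = rng.integers(1, 4, size=k)
            pts = np.vstack(
                [rng.standard_normal(2) * 3 + 0.5 * rng.standard_normal((s, 2)) for s in sizes]
            )
            labels = np.repeat(np.arange(1, k + 1), sizes)
            D = euclidean_dm(pts)
            geom = between_group_distance(D, labels)
            probe = 3 * rng.standard_normal(2)
            phi2 = proximity(distances_to(probe, pts), labels, geom.variabilities)
            st = inca_statistic(phi2, geom)
            oracle = brute_force_w(phi2, geom.delta2)
            assert st.W == pytest.approx(oracle, abs=1e-6)
            checked += 1


class TestInvariances:
    def _w_of_config(self, pts, labels, probe):
        D = euclidean_dm(pts)
        geom = between_group_distance(D, labels)
        phi2 = proximity(distances_to(probe, pts), labels, geom.variabilities)
        return inca_statistic(phi2, geom)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.standard_normal((9, 3))
        labels = np.repeat([1, 2, 3], 3)
        probe = rng.standard_normal(3)
        st = self._w_of_config(pts, labels, probe)
        # random rotation + translation
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        shift = rng.standard_normal(3)
        st2 = self._w_of_config(pts @ Q + shift, labels, probe @ Q + shift)
        assert st2.W == pytest.approx(st.W, rel=1e-8, abs=1e-12)

    def test_quadratic_scaling(self, rng):
        pts = rng.standard_normal((8, 2))
        labels = np.repeat([1, 2], 4)
        probe = rng.standard_normal(2)
        c = 3.7
        D = euclidean_dm(pts)
        geom = between_group_distance(D, labels)
        d0 = distances_to(probe, pts)
        phi2 = proximity(d0, labels, geom.variabilities)
        st = inca_statistic(phi2, geom)

        geom_c = between_group_distance(DistanceMatrix(c * D.values), labels)
        phi2_c = proximity(c * d0, labels, geom_c.variabilities)
        st_c = inca_statistic(phi2_c, geom_c)

        np.testing.assert_allclose(geom_c.variabilities, c**2 * geom.variabilities)
        np.testing.assert_allclose(geom_c.delta2, c**2 * geom.delta2, atol=1e-9)
        np.testing.assert_allclose(phi2_c, c**2 * phi2)
        assert st_c.W == pytest.approx(c**2 * st.W, rel=1e-8)
        np.testing.assert_allclose(st_c.U, c**2 * st.U, rtol=1e-7, atol=1e-9)

    def test_w_nonnegative_for_euclidean(self, rng):
        for _ in range(30):
            pts = rng.standard_normal((10, 4))
            labels = np.r_[np.repeat([1, 2, 3], 3), [1]]
            probe = rng.standard_normal(4)
            st = self._w_of_config(pts, labels, probe)
            assert st.W >= 0
            assert (st.U >= -1e-8).all()

    def test_degenerate_when_centers_span_space(self, rng):
        """k singleton clusters spanning a (k-1)-simplex: any probe inside
        their affine hull has W ~ 0 (the k >= p degeneracy)."""
        for k, dim in [(3, 2), (4, 3)]:
            pts = rng.standard_normal((k, dim)) * 2
            labels = np.arange(1, k + 1)
            weights = rng.dirichlet(np.ones(k))
            probe = weights @ pts  # inside the affine hull
            st = self._w_of_config(pts, labels, probe)
            assert st.W == pytest.approx(0.0, abs=1e-8)


class TestAllocation:
    @pytest.mark.parametrize(
        "U, expected",
        [
            ((137.9698, 137.3148, 7.615953), 3),
            ((1.0, 1.0), 1),
            ((5.0, 2.0, 9.0), 2),
        ],
    )
    def test_argmin_with_tie_to_smallest_index(self, U, expected):
        assert allocate(np.array(U)) == expected


class TestSimplexAgreement:
    def test_w_statistics_matches_analytic_height(self):
        for k, dim, h in [(2, 2, 1.0), (3, 3, 0.7), (4, 6, 1.9)]:
            D, labels, d_probe, analytic = simplex_fixture(
                k, dim, spread=0.0, probe_offset=h, n_per_cluster=3
            )
            W, U, _, _ = w_statistics(D, labels, d_new=d_probe[None, :])
            assert W[0] == pytest.approx(analytic, abs=1e-8)

    def test_partition_remaps_labels_with_warning(self):
        with pytest.warns(UserWarning, match="remapping"):
            p = Partition(np.array([1, 3, 4, 3]))
        assert list(p.labels) == [1, 2, 3, 2]
        assert p.k == 3
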