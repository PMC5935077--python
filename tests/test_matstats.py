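"""Mantel tests, matrix regression, panels, nMDS and Kruskal stress."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

import marshtransplant as mt
from marshtransplant.io import ValidationError
from marshtransplant.matstats import _disparities, _tie_order


def random_dm(n, seed, ids=None):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.05, 1.0, (n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(m, ids=ids or [f"x{i}" for i in range(n)])


class TestMantel:
    def test_self_correlation_is_one(self):
        a = random_dm(6, 0)
        res = mt.mantel(a, a, n_permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self):
        a = random_dm(6, 1)
        vals = 3.0 * np.array(a.data) + 0.5
        np.fill_diagonal(vals, 0)
        b = DistanceMatrix(vals, ids=list(a.ids))
        assert mt.mantel(a, b, n_permutations=9, seed=0).r == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        a, b = random_dm(4, 2), random_dm(4, 3)
        res = mt.mantel(a, b, exhaustive=True)

        def upper(m, perm):
            arr = np.array(m.data)[np.ix_(perm, perm)]
            return arr[np.triu_indices(4, 1)]

        ua = upper(a, list(range(4)))
        r_obs = np.corrcoef(ua, upper(b, list(range(4))))[0, 1]
        rs = [np.corrcoef(ua, upper(b, list(p)))[0, 1]
              for p in itertools.permutations(range(4))]
        p_oracle = np.mean([r >= r_obs for r in rs])  # identity included
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == 23

    def test_statistic_agrees_with_skbio(self):
        from skbio.stats.distance import mantel as skbio_mantel
        a, b = random_dm(8, 4), random_dm(8, 5)
        r_skbio, p_skbio, _ = skbio_mantel(a, b, permutations=999,
                                           alternative="greater", seed=0)
        res = mt.mantel(a, b, n_permutations=999, seed=0)
        assert res.r == pytest.approx(r_skbio, abs=1e-12)
        assert res.p_value == pytest.approx(p_skbio, abs=0.06)

    def test_deterministic_given_seed(self):
        a, b = random_dm(7, 6), random_dm(7, 7)
        r1 = mt.mantel(a, b, n_permutations=199, seed=42)
        r2 = mt.mantel(a, b, n_permutations=199, seed=42)
        assert (r1.r, r1.p_value) == (r2.r, r2.p_value)

    def test_label_mismatch_rejected(self):
        a = random_dm(4, 0, ids=list("abcd"))
        b = random_dm(4, 1, ids=list("abce"))
        with pytest.raises(ValidationError, match="labels"):
            mt.mantel(a, b)

    def test_p_bounded_below_by_permutation_count(self):
        a = random_dm(5, 8)
        res = mt.mantel(a, a, n_permutations=99, seed=0)
        assert res.p_value >= 1 / (99 + 1)


class TestMatrixRegression:
    def test_exact_linear_relation(self):
        a = random_dm(5, 9)
        vals = 2.0 * np.array(a.data)
        b = DistanceMatrix(vals, ids=list(a.ids))
        slope, intercept, r2 = mt.matrix_regression(b, a)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        a, b = random_dm(5, 10), random_dm(5, 11)
        iu = np.triu_indices(5, 1)
        y, x = np.array(a.data)[iu], np.array(b.data)[iu]
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        slope, intercept, r2 = mt.matrix_regression(a, b)
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2 == pytest.approx(r2_oracle, abs=1e-10)

    def test_r_squared_equals_squared_mantel_statistic(self):
        a, b = random_dm(6, 12), random_dm(6, 13)
        res = mt.mantel(a, b, n_permutations=9, seed=0)
        _, _, r2 = mt.matrix_regression(a, b)
        assert r2 == pytest.approx(res.r ** 2, abs=1e-12)


class TestPairwisePanel:
    def test_three_matrices_three_rows_and_identity_pair(self):
        a = random_dm(5, 14)
        copy = DistanceMatrix(np.array(a.data), ids=list(a.ids))
        c = random_dm(5, 15)
        panel = mt.pairwise_panel({"a": a, "copy": copy, "c": c},
                                  n_permutations=99, seed=0)
        assert len(panel) == 3
        row = panel[(panel.name_a == "a") & (panel.name_b == "copy")].iloc[0]
        assert row.mantel_m == pytest.approx(1.0)

    def test_r_squared_is_squared_m_in_every_row(self):
        mats = {f"m{i}": random_dm(6, 20 + i) for i in range(4)}
        panel = mt.pairwise_panel(mats, n_permutations=49, seed=1)
        assert np.allclose(panel.r_squared, panel.mantel_m ** 2, atol=1e-12)

    def test_collinear_pair_has_maximum_m(self):
        d = random_dm(6, 30)
        collinear = DistanceMatrix(1.5 * np.array(d.data), ids=list(d.ids))
        other = random_dm(6, 31)
        panel = mt.pairwise_panel({"dist": d, "temp": collinear, "noise": other},
                                  n_permutations=9, seed=0)
        best = panel.loc[panel.mantel_m.idxmax()]
        assert {best.name_a, best.name_b} == {"dist", "temp"}


from tests_support import brute_force_isotonic


class TestKruskalStress:
    def test_perfect_configuration_has_zero_stress(self):
        X = np.array([[0, 0], [1, 0], [0.3, 2.0], [2, 1]], float)
        D = squareform(pdist(X))
        assert mt.kruskal_stress(D, X) == pytest.approx(0.0, abs=1e-12)

    def test_isotonic_identity_on_monotone_input(self):
        delta = np.array([0.1, 0.2, 0.5, 0.9])
        order = _tie_order(np.arange(4.0), delta)
        assert np.allclose(_disparities(delta, order), delta)

    @pytest.mark.parametrize("seq", [(3.0, 1.0, 2.0), (2.0, 2.0, 1.0), (1.0, 3.0, 2.0)])
    def test_pava_matches_brute_force_partition_oracle(self, seq):
        y = np.array(seq)
        order = np.arange(len(y))
        fit = _disparities(y, order)
        assert np.allclose(fit, brute_force_isotonic(y), atol=1e-10)

    def test_degenerate_configuration_rejected(self):
        X = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])  # equilateral
        D = np.array([[0, 1, 2.0], [1, 0, 1.5], [2.0, 1.5, 0]])
        with pytest.raises(ValidationError, match="degenerate"):
            mt.kruskal_stress(D, X)


class TestNMDS:
    def test_exactly_embeddable_square(self):
        X = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        res = mt.nmds(squareform(pdist(X)), k=2, n_starts=10, seed=0)
        assert res.stress < 0.01

    def test_collinear_points_in_one_dimension(self):
        D = np.array([[0, 1, 2.0], [1, 0, 1.0], [2.0, 1.0, 0]])
        res = mt.nmds(D, k=1, n_starts=5, seed=0)
        assert res.stress < 1e-3

    def test_coordinates_are_centred(self):
        res = mt.nmds(random_dm(10, 40), k=2, n_starts=3, seed=1)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_reproducible_given_seed(self):
        d = random_dm(8, 41)
        a = mt.nmds(d, k=2, n_starts=3, seed=7)
        b = mt.nmds(d, k=2, n_starts=3, seed=7)
        assert a.stress == b.stress
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_stress_invariant_under_rotation_and_reflection(self):
        d = random_dm(9, 42)
        res = mt.nmds(d, k=2, n_starts=3, seed=2)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        F = np.array([[1.0, 0.0], [0.0, -1.0]])
        s0 = mt.kruskal_stress(d, res.coordinates)
        assert mt.kruskal_stress(d, res.coordinates @ R) == pytest.approx(s0, abs=1e-9)
        assert mt.kruskal_stress(d, res.coordinates @ F) == pytest.approx(s0, abs=1e-9)

    def test_stress_non_increasing_within_a_start(self):
        from marshtransplant.matstats import _classical_mds, _nmds_single
        d = np.array(random_dm(12, 43).data)
        X = _classical_mds(d, 2)
        # run one long pass, then re-run in two halves: final stresses ordered
        _, s_full, _ = _nmds_single(d, X.copy(), 200, 0.0)
        X1, s_half, _ = _nmds_single(d, X.copy(), 50, 0.0)
        assert s_full <= s_half + 1e-12
        assert s_half <= mt.kruskal_stress(d, X) + 1e-12

    def test_nonfinite_distances_rejected(self):
        D = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValidationError):
            mt.nmds(D, k=1)
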