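import itertools

import numpy as np
import pytest
import sklearn.metrics
from hypothesis import given, settings, strategies as st

from sscclust import (ContingencyTable, LabelVector, ValidationError,
                      adjusted_rand, contingency, fraction_improved,
                      median_silhouette, nmi, pearson_correlation, rand_index,
                      silhouette)


def lv(seq):
    return LabelVector(np.asarray(seq))


def random_dissimilarity(rng, n):
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestSilhouette:
    def test_hand_computed_two_pairs(self):
        # 1-D points (0, 1 | 10, 11): for point 0, a = 1, b = 10.5
        x = np.array([0.0, 1.0, 10.0, 11.0])
        d = np.abs(x[:, None] - x[None, :])
        sv = silhouette(d, lv([0, 0, 1, 1]))
        assert sv.a[0] == pytest.approx(1.0)
        assert sv.b[0] == pytest.approx(10.5)
        expected = [(10.5 - 1) / 10.5, (9.5 - 1) / 9.5,
                    (9.5 - 1) / 9.5, (10.5 - 1) / 10.5]
        np.testing.assert_allclose(sv.s, expected)

    def test_duplicated_points_far_clusters_approach_one(self):
        d = np.array([
            [0, 0, 1e6, 1e6],
            [0, 0, 1e6, 1e6],
            [1e6, 1e6, 0, 0],
            [1e6, 1e6, 0, 0],
        ], dtype=float)
        sv = silhouette(d, lv([0, 0, 1, 1]))
        np.testing.assert_allclose(sv.s, 1.0)

    def test_bounded_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(4, 12)
            d = random_dissimilarity(rng, n)
            labels = rng.integers(0, 3, n)
            if len(set(labels)) < 2:
                continue
            sv = silhouette(d, lv(labels))
            assert np.all(sv.s >= -1 - 1e-12) and np.all(sv.s <= 1 + 1e-12)
            assert np.all(sv.a >= 0) and np.all(sv.b >= 0)

    def test_matches_sklearn(self, rng):
        d = random_dissimilarity(rng, 20)
        labels = rng.integers(0, 3, 20)
        labels[:3] = [0, 1, 2]
        sv = silhouette(d, lv(labels))
        expected = sklearn.metrics.silhouette_samples(d, labels,
                                                      metric="precomputed")
        np.testing.assert_allclose(sv.s, expected, atol=1e-10)

    def test_singleton_cluster_scores_zero(self):
        d = random_dissimilarity(np.random.default_rng(0), 5)
        sv = silhouette(d, lv([0, 0, 0, 0, 1]))
        assert sv.s[4] == 0.0

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValidationError):
            silhouette(random_dissimilarity(rng, 4), lv([0, 0, 0, 0]))

    def test_asymmetric_matrix_rejected(self, rng):
        d = rng.random((4, 4))
        np.fill_diagonal(d, 0)
        with pytest.raises(ValidationError, match="symmetric"):
            silhouette(d, lv([0, 0, 1, 1]))


class TestMedianAndFraction:
    def test_median_cases(self, rng):
        from sscclust.metrics import SilhouetteVector
        assert median_silhouette(
            SilhouetteVector(np.array([0.5]), np.zeros(1), np.zeros(1))) == 0.5
        assert median_silhouette(
            SilhouetteVector(np.array([-1.0, 0.0, 1.0]), np.zeros(3),
                             np.zeros(3))) == 0.0
        vals = rng.random(101)
        got = median_silhouette(
            SilhouetteVector(vals, np.zeros(101), np.zeros(101)))
        assert got == sorted(vals)[50]

    def test_fraction_improved(self, rng):
        from sscclust.metrics import SilhouetteVector
        s = rng.random(50)
        a = SilhouetteVector(s, np.zeros(50), np.zeros(50))
        same = SilhouetteVector(s.copy(), np.zeros(50), np.zeros(50))
        up = SilhouetteVector(s + 0.1, np.zeros(50), np.zeros(50))
        assert fraction_improved(a, same) == 0.0
        assert fraction_improved(a, up) == 1.0
        t = rng.random(50)
        b = SilhouetteVector(t, np.zeros(50), np.zeros(50))
        assert fraction_improved(a, b) == np.mean(t > s)


class TestContingency:
    def test_identical_partitions_diagonal(self):
        t = contingency(lv([0, 0, 1, 1]), lv([0, 0, 1, 1]))
        np.testing.assert_array_equal(t.counts, [[2, 0], [0, 2]])

    def test_relabeling_permutes_table(self):
        a = contingency(lv([0, 0, 1, 1]), lv([0, 0, 1, 1]))
        b = contingency(lv([0, 0, 1, 1]), lv([1, 1, 0, 0]))
        np.testing.assert_array_equal(a.counts, [[2, 0], [0, 2]])
        np.testing.assert_array_equal(b.counts, [[0, 2], [2, 0]])
        assert sorted(a.row_sums) == sorted(b.row_sums)
        assert sorted(a.col_sums) == sorted(b.col_sums)

    def test_matches_double_loop_oracle(self, rng):
        a = rng.integers(0, 4, 30)
        b = rng.integers(0, 3, 30)
        t = contingency(lv(a), lv(b))
        ua, ub = np.unique(a), np.unique(b)
        for i, ca in enumerate(ua):
            for j, cb in enumerate(ub):
                expected = sum(1 for x, y in zip(a, b) if x == ca and y == cb)
                assert t.counts[i, j] == expected


class TestNMI:
    def test_identical_partitions_give_one(self):
        for labels in ([0, 0, 0, 1, 1, 1], [0, 1, 2, 0, 1, 2], [0, 0, 1, 2]):
            assert nmi(contingency(lv(labels), lv(labels))) == pytest.approx(1.0)

    def test_independent_balanced_partitions_give_zero(self):
        # A = {1,2|3,4}, B = {1,3|2,4}: every table cell is 1
        table = contingency(lv([0, 0, 1, 1]), lv([0, 1, 0, 1]))
        np.testing.assert_array_equal(table.counts, [[1, 1], [1, 1]])
        assert nmi(table) == pytest.approx(0.0, abs=1e-12)

    def test_exact_arithmetic_oracle(self):
        import sympy
        # C = [[2,1],[1,2]]: evaluate the mutual-information form exactly
        n, log = 6, sympy.log
        I = (sympy.Rational(2, 6) * log(sympy.Rational(2 * 6, 3 * 3))
             + sympy.Rational(1, 6) * log(sympy.Rational(1 * 6, 3 * 3))
             + sympy.Rational(1, 6) * log(sympy.Rational(1 * 6, 3 * 3))
             + sympy.Rational(2, 6) * log(sympy.Rational(2 * 6, 3 * 3)))
        H = -(sympy.Rational(1, 2) * log(sympy.Rational(1, 2)) * 2)
        expected = float(2 * I / (2 * H))
        got = nmi(ContingencyTable(np.array([[2, 1], [1, 2]])))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_cluster_scheme_gives_zero(self):
        assert nmi(contingency(lv([0, 0, 0]), lv([0, 1, 2]))) == 0.0

    def test_matches_sklearn_on_random_partitions(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 40))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 5, n)
            ours = nmi(contingency(lv(a), lv(b)))
            ref = sklearn.metrics.normalized_mutual_info_score(
                a, b, average_method="arithmetic")
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_symmetric_and_permutation_invariant(self, rng):
        a = rng.integers(0, 3, 25)
        b = rng.integers(0, 4, 25)
        assert nmi(contingency(lv(a), lv(b))) == pytest.approx(
            nmi(contingency(lv(b), lv(a))), abs=1e-12)
        remap = {0: 7, 1: 3, 2: 5}
        a2 = np.array([remap[x] for x in a])
        assert nmi(contingency(lv(a2), lv(b))) == pytest.approx(
            nmi(contingency(lv(a), lv(b))), abs=1e-12)


class TestRandIndices:
    def test_identical_partitions(self):
        t = contingency(lv([0, 1, 1, 2]), lv([5, 3, 3, 1]))
        assert rand_index(t) == pytest.approx(1.0)
        assert adjusted_rand(t) == pytest.approx(1.0)

    def test_single_cluster_vs_single_cluster(self):
        t = contingency(lv([0, 0, 0]), lv([1, 1, 1]))
        assert rand_index(t) == pytest.approx(1.0)

    def test_independent_balanced_ari_matches_pair_enumeration(self):
        a, b = [0, 0, 1, 1], [0, 1, 0, 1]
        t = contingency(lv(a), lv(b))
        # enumerate all C(4,2)=6 pairs
        same_a = {frozenset(p) for p in itertools.combinations(range(4), 2)
                  if a[p[0]] == a[p[1]]}
        same_b = {frozenset(p) for p in itertools.combinations(range(4), 2)
                  if b[p[0]] == b[p[1]]}
        n11 = len(same_a & same_b)
        total = 6
        exp = len(same_a) * len(same_b) / total
        mx = (len(same_a) + len(same_b)) / 2
        expected_ari = (n11 - exp) / (mx - exp)
        assert adjusted_rand(t) == pytest.approx(expected_ari, abs=1e-12)

    def test_matches_sklearn_on_random_partitions(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 4, n)
            t = contingency(lv(a), lv(b))
            assert adjusted_rand(t) == pytest.approx(
                sklearn.metrics.adjusted_rand_score(a, b), abs=1e-9)
            assert rand_index(t) == pytest.approx(
                sklearn.metrics.rand_score(a, b), abs=1e-9)


class TestPearson:
    def test_exact_cases(self, rng):
        x = rng.random(10)
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        x, y = rng.random(50), rng.random(50)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation(np.ones(5), np.arange(5.0))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=4, max_size=30),
       st.integers(0, 10_000))
def test_nmi_base_free_and_bounded(labels_a, seed):
    """NMI is within [0,1] and invariant to label permutation (property)."""
    rng = np.random.default_rng(seed)
    a = np.array(labels_a)
    b = rng.integers(0, 4, a.size)
    val = nmi(contingency(lv(a), lv(b)))
    assert -1e-12 <= val <= 1 + 1e-12
    perm = rng.permutation(10)
    assert nmi(contingency(lv(perm[a]), lv(b))) == pytest.approx(val, abs=1e-12)
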