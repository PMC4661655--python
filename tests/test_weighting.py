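"""Separation statistics, margins and the weight update rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from miwas import (
    between_separations_modified,
    between_separations_original,
    corner_solution,
    margin_difference,
    margin_ratio,
    normalize_separations,
    sigma_dispersion,
    uniform_weights,
    update_weights,
    within_separations,
)

nonneg = st.floats(0.0, 1e6, allow_nan=False, allow_infinity=False)


def _rand_instance(rng, m=None, k=None, n=None):
    m = m or rng.integers(5, 51)
    k = k or rng.integers(2, 6)
    n = n or rng.integers(2, 7)
    X = rng.normal(size=(m, n))
    labels = rng.integers(0, k, size=m)
    # ensure every cluster non-empty for clean oracles
    labels[:k] = np.arange(k)
    c = np.stack([X[labels == kk].mean(axis=0) for kk in range(k)])
    sizes = np.bincount(labels, minlength=k)
    return X, labels, c, sizes


class TestSeparationOracles:
    def test_within_hand_example(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        a = within_separations(X, np.array([0, 0]), np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(a, [2.0, 0.0])

    def test_within_zero_when_samples_at_centroids(self):
        c = np.array([[1.0, 2.0], [3.0, 4.0]])
        X = c[[0, 1, 0, 1]]
        a = within_separations(X, np.array([0, 1, 0, 1]), c)
        np.testing.assert_allclose(a, 0, atol=1e-15)

    def test_within_quadratic_homogeneity(self):
        rng = np.random.default_rng(0)
        X, labels, c, _ = _rand_instance(rng)
        a1 = within_separations(X, labels, c)
        a2 = within_separations(2 * X, labels, 2 * c)
        np.testing.assert_allclose(a2, 4 * a1, rtol=1e-12)

    def test_between_modified_hand_example(self):
        c = np.array([[0.0, 0.0], [2.0, 0.0]])
        b = between_separations_modified(c, np.array([2, 2]))
        np.testing.assert_allclose(b, [16.0, 0.0])

    def test_between_modified_zero_and_symmetry(self):
        c = np.tile([1.0, 2.0], (3, 1))
        np.testing.assert_allclose(
            between_separations_modified(c, np.array([5, 5, 5])), 0, atol=1e-15
        )
        rng = np.random.default_rng(1)
        c = rng.normal(size=(4, 3))
        sizes = np.array([3, 1, 4, 2])
        perm = np.array([2, 0, 3, 1])
        b1 = between_separations_modified(c, sizes)
        b2 = between_separations_modified(c[perm], sizes[perm])
        np.testing.assert_allclose(b1, b2, rtol=1e-12)

    def test_between_modified_needs_two_clusters(self):
        with pytest.raises(ValueError):
            between_separations_modified(np.ones((1, 2)), np.array([5]))

    def test_between_original_hand_example(self):
        c = np.array([[0.0], [2.0]])
        b = between_separations_original(c, np.array([1, 1]), np.array([1.0]))
        np.testing.assert_allclose(b, [2.0])

    def test_between_original_zero_cases(self):
        g = np.array([1.0, 2.0])
        np.testing.assert_allclose(
            between_separations_original(np.tile(g, (3, 1)),
                                         np.array([1, 2, 3]), g),
            0, atol=1e-15,
        )
        np.testing.assert_allclose(
            between_separations_original(g[None, :], np.array([4]), g),
            0, atol=1e-15,
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_triple_loop_oracles(self, seed):
        """Vectorised separations agree with naive loops to 1e-9."""
        rng = np.random.default_rng(seed)
        X, labels, c, sizes = _rand_instance(rng)
        m, n = X.shape
        k = c.shape[0]
        a_ref = np.zeros(n)
        for i in range(m):
            for nn in range(n):
                a_ref[nn] += (X[i, nn] - c[labels[i], nn]) ** 2
        b_mod_ref = np.zeros(n)
        for kk in range(k):
            for jj in range(k):
                if jj == kk:
                    continue
                for nn in range(n):
                    b_mod_ref[nn] += sizes[kk] * (c[kk, nn] - c[jj, nn]) ** 2
        g = X.mean(axis=0)
        b_orig_ref = np.zeros(n)
        for kk in range(k):
            for nn in range(n):
                b_orig_ref[nn] += sizes[kk] * (c[kk, nn] - g[nn]) ** 2
        np.testing.assert_allclose(within_separations(X, labels, c), a_ref,
                                   atol=1e-9)
        np.testing.assert_allclose(between_separations_modified(c, sizes),
                                   b_mod_ref, atol=1e-9)
        np.testing.assert_allclose(between_separations_original(c, sizes, g),
                                   b_orig_ref, atol=1e-9)


class TestNormalize:
    def test_substitution(self):
        s = normalize_separations(np.array([2.0, 2.0]), np.array([1.0, 3.0]))
        np.testing.assert_allclose(s.a0, [0.5, 0.5])
        s = normalize_separations(np.array([1.0, 3.0]), np.array([3.0, 1.0]))
        np.testing.assert_allclose(s.delta, [0.5, -0.5])

    def test_equal_a_b_gives_zero_delta(self):
        v = np.array([0.3, 1.2, 2.5])
        s = normalize_separations(v, v)
        np.testing.assert_allclose(s.delta, 0, atol=1e-12)

    def test_degenerate_flags(self):
        s = normalize_separations(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        assert s.degenerate
        s = normalize_separations(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert s.degenerate

    def test_delta_sums_to_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = normalize_separations(rng.uniform(0.1, 5, 4),
                                      rng.uniform(0.1, 5, 4))
            assert abs(s.delta.sum()) < 1e-10


class TestCornerSolution:
    def test_argmax_of_ratios(self):
        np.testing.assert_array_equal(
            corner_solution(np.array([1.0, 1.0]), np.array([3.0, 1.0])), [1, 0]
        )

    def test_tie_breaks_to_lowest_index(self):
        w = corner_solution(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0, 2.0]))
        np.testing.assert_array_equal(w, [1, 0, 0])

    def test_only_nonzero_ratio_wins(self):
        w = corner_solution(np.ones(4), np.array([0.0, 0.0, 0.0, 0.5]))
        np.testing.assert_array_equal(w, [0, 0, 0, 1])

    def test_zero_a_raises(self):
        with pytest.raises(ZeroDivisionError):
            corner_solution(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_corner_enumeration(self, seed):
        """The winner-take-all weight maximises (w·b)/(w·a) over all corners."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 7)
        a = rng.uniform(0.1, 5, n)
        b = rng.uniform(0.0, 5, n)
        w = corner_solution(a, b)
        best = max(b[i] / a[i] for i in range(n))
        achieved = np.dot(w, b) / np.dot(w, a)
        assert achieved == pytest.approx(best, rel=1e-12)


class TestMargins:
    def test_ratio_substitution_with_zero_a(self):
        dw, fb = margin_ratio(np.array([0.0, 1.0]), np.array([1.0, 1.0]), 1.0)
        np.testing.assert_allclose(dw, [2 / 3, 1 / 3])
        assert not fb

    def test_ratio_uniform_symmetry(self):
        dw, _ = margin_ratio(np.full(4, 2.0), np.full(4, 3.0), 0.7)
        np.testing.assert_allclose(dw, 0.25)

    def test_ratio_large_sigma_limit(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 1.0, 1.0])
        dw, _ = margin_ratio(a, b, 1e12)
        np.testing.assert_allclose(dw, b / b.sum(), rtol=1e-6)

    def test_ratio_all_zero_b_falls_back(self):
        dw, fb = margin_ratio(np.ones(3), np.zeros(3), 1.0)
        assert fb
        np.testing.assert_allclose(dw, 1 / 3)

    def test_difference_substitution(self):
        s = normalize_separations(np.array([1.0, 1.0]), np.array([4.0, 1.0]))
        np.testing.assert_allclose(s.b0, [0.8, 0.2])
        dw, fb = margin_difference(s)
        np.testing.assert_allclose(dw, [1.0, 0.0])
        assert not fb

    def test_difference_three_way(self):
        # delta = (0.2, 0, -0.2) -> dw = (2/3, 1/3, 0)
        a0 = np.array([0.2, 0.3, 0.5])
        b0 = np.array([0.4, 0.3, 0.3])
        s = normalize_separations(a0, b0)
        dw, _ = margin_difference(s)
        np.testing.assert_allclose(dw, [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_difference_constant_delta_uniform(self):
        v = np.array([1.0, 2.0, 3.0])
        dw, fb = margin_difference(normalize_separations(v, v))
        assert fb
        np.testing.assert_allclose(dw, 1 / 3)

    def test_difference_degenerate_uniform(self):
        dw, fb = margin_difference(
            normalize_separations(np.zeros(4), np.ones(4))
        )
        assert fb
        np.testing.assert_allclose(dw, 0.25)

    @given(
        a=arrays(float, 5, elements=nonneg),
        b=arrays(float, 5, elements=nonneg),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_margins_stay_on_simplex(self, a, b):
        s = normalize_separations(a, b)
        dw, _ = margin_difference(s)
        assert abs(dw.sum() - 1.0) < 1e-10 and (dw >= 0).all()
        dw2, _ = margin_ratio(a, b, sigma=1.0)
        assert abs(dw2.sum() - 1.0) < 1e-10 and (dw2 >= -1e-15).all()

    @given(
        a=arrays(float, 6, elements=st.floats(1e-3, 1e3)),
        b=arrays(float, 6, elements=st.floats(1e-3, 1e3)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_difference_margin_rank_preserving(self, a, b):
        s = normalize_separations(a, b)
        dw, fb = margin_difference(s)
        if fb:
            return
        order = np.argsort(s.delta)
        sorted_dw = dw[order]
        assert (np.diff(sorted_dw) >= -1e-12).all()
        # strict ranking away from the shared minimum
        for i, j in zip(order[:-1], order[1:]):
            if s.delta[j] - s.delta[i] > 1e-9 and dw[i] > 0:
                assert dw[j] > dw[i]


class TestUpdateWeights:
    def test_direct_substitution(self):
        w = np.full(4, 0.25)
        dw = np.array([0.4, 0.3, 0.2, 0.1])
        np.testing.assert_allclose(update_weights(w, dw),
                                   [0.325, 0.275, 0.225, 0.175], atol=1e-15)

    def test_fixed_point(self):
        w = np.array([0.7, 0.2, 0.1])
        np.testing.assert_allclose(update_weights(w, w), w, atol=1e-15)

    def test_geometric_convergence_to_constant_margin(self):
        w = np.array([1.0, 0.0, 0.0])
        dw = np.array([0.2, 0.5, 0.3])
        prev_gap = np.linalg.norm(w - dw)
        for _ in range(30):
            w = update_weights(w, dw)
            gap = np.linalg.norm(w - dw)
            assert gap == pytest.approx(prev_gap / 2, rel=1e-9)
            prev_gap = gap

    def test_no_simplex_drift_over_many_iterations(self):
        rng = np.random.default_rng(3)
        w = uniform_weights(5)
        for _ in range(10_000):
            dw = rng.dirichlet(np.ones(5))
            w = update_weights(w, dw)
            assert abs(w.sum() - 1.0) < 1e-10 and (w >= 0).all()

    def test_off_simplex_inputs_rejected(self):
        with pytest.raises(ValueError):
            update_weights(np.array([0.6, 0.6]), np.array([0.5, 0.5]))


class TestSigmaDispersion:
    def test_identical_samples_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        assert sigma_dispersion(X) == 0.0

    def test_hand_computation(self):
        X = np.array([[0.0, 1.0], [2.0, 1.0]])
        assert sigma_dispersion(X) == pytest.approx(0.5)

    def test_standardized_population_table_near_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 3))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        assert sigma_dispersion(X) == pytest.approx(1.0, abs=1e-6)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            sigma_dispersion(np.ones((1, 3)))
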