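"""MIC, centroid selection and entropy weighting against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from fermsense import (
    MICConfig,
    compute_centroid,
    entropy_weights,
    feature_mi_matrix,
    grid_mutual_information,
    mic,
    pairwise_mic_matrix,
    select_centroid_index,
)


def oracle_mi(pairs, x_cuts, y_cuts):
    """Independent plug-in MI via histogram2d over (-inf, cuts, inf) edges."""
    pairs = np.asarray(pairs, dtype=float)
    xe = np.concatenate([[-np.inf], x_cuts, [np.inf]])
    ye = np.concatenate([[-np.inf], y_cuts, [np.inf]])
    # histogram2d treats the right edge as exclusive except the last bin,
    # matching the "value equal to a cut goes up" convention for finite cuts
    counts, _, _ = np.histogram2d(pairs[:, 0], pairs[:, 1], bins=[xe, ye])
    n = counts.sum()
    mi = 0.0
    px = counts.sum(axis=1) / n
    py = counts.sum(axis=0) / n
    for i, j in itertools.product(range(len(px)), range(len(py))):
        p = counts[i, j] / n
        if p > 0:
            mi += p * math.log2(p / (px[i] * py[j]))
    return mi


def oracle_mic(x, y, config):
    """Exhaustive enumeration over all admissible grids and cut placements."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    B = config.budget(n)
    xs, ys = np.unique(x), np.unique(y)
    cx = (xs[:-1] + xs[1:]) / 2
    cy = (ys[:-1] + ys[1:]) / 2
    best = 0.0
    pairs = np.column_stack([x, y])
    for a in range(config.min_bins, config.max_bins + 1):
        for b in range(config.min_bins, config.max_bins + 1):
            if a * b > B or cx.size < a - 1 or cy.size < b - 1:
                continue
            for xc in itertools.combinations(cx, a - 1):
                for yc in itertools.combinations(cy, b - 1):
                    val = oracle_mi(pairs, xc, yc) / math.log2(min(a, b))
                    best = max(best, val)
    return min(best, 1.0)


class TestGridMutualInformation:
    def test_single_cell_is_zero(self):
        pairs = [(0.1, 0.2), (0.3, 0.1), (0.2, 0.25)]
        assert grid_mutual_information(pairs, [10.0], [10.0]) == 0.0

    def test_diagonal_four_points_one_bit(self):
        pairs = [(0, 0), (1, 1), (2, 2), (3, 3)]
        assert grid_mutual_information(pairs, [1.5], [1.5]) == pytest.approx(1.0)

    def test_bounded_by_log_min_bins(self, rng):
        for _ in range(10):
            pairs = rng.normal(size=(15, 2))
            xc = sorted(rng.normal(size=2))
            yc = sorted(rng.normal(size=3))
            mi = grid_mutual_information(pairs, xc, yc)
            assert 0.0 <= mi <= math.log2(3) + 1e-12

    def test_matches_oracle(self, rng):
        for _ in range(20):
            pairs = rng.normal(size=(10, 2))
            xc = sorted(rng.normal(size=2))
            yc = sorted(rng.normal(size=2))
            assert grid_mutual_information(pairs, xc, yc) == pytest.approx(
                oracle_mi(pairs, xc, yc), abs=1e-12
            )

    def test_rejects_unsorted_cuts(self):
        with pytest.raises(ValueError):
            grid_mutual_information([(0, 0), (1, 1)], [2.0, 1.0], [0.5])


class TestMIC:
    def test_perfect_monotone_relation_saturates(self):
        x = np.arange(8.0)
        assert mic(x, x) == 1.0
        assert mic(x, np.exp(x)) == 1.0

    def test_constant_is_zero(self):
        assert mic(np.arange(8.0), np.zeros(8)) == 0.0

    def test_symmetry(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert mic(x, y) == pytest.approx(mic(y, x), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=8)
        y = np.sin(x)  # noiseless functional pair
        base = mic(x, y)
        assert mic(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert mic(x, 3.0 * y - 7.0) == pytest.approx(base, abs=1e-12)
        assert mic(x**3, y) == pytest.approx(base, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        cfg = MICConfig(b_exponent=0.8, max_bins=3)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert mic(x, y, cfg) == pytest.approx(oracle_mic(x, y, cfg), abs=1e-10)

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            mic(np.arange(3.0), np.arange(3.0))


class TestPairwiseMICMatrix:
    def test_duplicates_and_diagonal(self, rng):
        row = rng.normal(size=6)
        S = np.vstack([row, rng.normal(size=6), row])
        phi = pairwise_mic_matrix(S)
        assert phi[0, 2] == 1.0
        np.testing.assert_allclose(np.diag(phi), 1.0)
        np.testing.assert_allclose(phi, phi.T)

    def test_rejects_narrow_samples(self, rng):
        with pytest.raises(ValueError):
            pairwise_mic_matrix(rng.normal(size=(3, 3)))


class TestSelectCentroid:
    def test_two_sample_tie_takes_first(self, rng):
        phi = pairwise_mic_matrix(rng.normal(size=(2, 6)))
        assert select_centroid_index(phi) == 0

    def test_argmax_of_row_sums(self):
        phi = np.array([[1.0, 0.1, 0.1], [1.0, 1.0, 0.9], [0.3, 0.4, 1.0]])
        assert select_centroid_index(phi) == 1

    def test_permutation_equivariance(self, rng):
        S = rng.normal(size=(5, 6))
        k = select_centroid_index(pairwise_mic_matrix(S))
        perm = rng.permutation(5)
        k_perm = select_centroid_index(pairwise_mic_matrix(S[perm]))
        # the same underlying sample must win unless the permutation created
        # a tie resolved differently; row sums are permutation-invariant
        assert perm[k_perm] == k


def oracle_feature_mi(S, k, config):
    """Independent recomputation: per-point clamped PMI under the grid that
    maximizes normalized MI of the (x_k, x_i) channel scatter."""
    S = np.asarray(S, float)
    n_q, d = S.shape
    B = config.budget(d)
    psi = np.zeros((n_q, d))
    for i in range(n_q):
        x, y = S[k], S[i]
        xs, ys = np.unique(x), np.unique(y)
        cx = (xs[:-1] + xs[1:]) / 2
        cy = (ys[:-1] + ys[1:]) / 2
        best, best_cuts = 0.0, None
        for a in range(config.min_bins, config.max_bins + 1):
            for b in range(config.min_bins, config.max_bins + 1):
                if a * b > B or cx.size < a - 1 or cy.size < b - 1:
                    continue
                for xc in itertools.combinations(cx, a - 1):
                    for yc in itertools.combinations(cy, b - 1):
                        val = oracle_mi(np.column_stack([x, y]), xc, yc) / math.log2(
                            min(a, b)
                        )
                        if val > best:
                            best, best_cuts = val, (xc, yc)
        if best_cuts is None:
            continue
        xc, yc = best_cuts
        for dp in range(d):
            ix = sum(c < x[dp] or c == x[dp] for c in xc)
            iy = sum(c < y[dp] or c == y[dp] for c in yc)
            n_cell = sum(
                1
                for c in range(d)
                if sum(cc < x[c] or cc == x[c] for cc in xc) == ix
                and sum(cc < y[c] or cc == y[c] for cc in yc) == iy
            )
            n_row = sum(1 for c in range(d) if sum(cc < x[c] or cc == x[c] for cc in xc) == ix)
            n_col = sum(1 for c in range(d) if sum(cc < y[c] or cc == y[c] for cc in yc) == iy)
            psi[i, dp] = max(0.0, math.log2(d * n_cell / (n_row * n_col)))
    return psi


class TestFeatureMIMatrix:
    def test_identical_samples_give_column_constant_matrix(self):
        # with an all-identical subset every sample relates to the reference
        # the same way, so each column holds one repeated value
        S = np.tile(np.arange(6.0), (4, 1))
        psi = feature_mi_matrix(S, 0)
        for dp in range(6):
            np.testing.assert_allclose(psi[:, dp], psi[0, dp])

    def test_nonnegative(self, rng):
        S = rng.normal(size=(6, 5))
        assert np.all(feature_mi_matrix(S, 2) >= 0)

    def test_matches_reimplementation_oracle(self, rng):
        S = rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            feature_mi_matrix(S, 1), oracle_feature_mi(S, 1, MICConfig()), atol=1e-12
        )


class TestEntropyWeights:
    def test_sum_to_one_and_uniform_under_equal_entropy(self):
        # columns share the same entropy (same shares, permuted rows)
        psi = np.array([[0.7, 0.0, 0.3], [0.3, 0.7, 0.0], [0.0, 0.3, 0.7]])
        w = entropy_weights(psi)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, 1.0 / 3.0, atol=1e-12)

    def test_maximally_uniform_shares_are_degenerate(self, rng):
        psi = np.tile(rng.random(4), (3, 1))  # every column perfectly uniform
        with pytest.raises(ValueError, match="degenerate"):
            entropy_weights(psi)

    def test_hand_example_extreme_entropies(self):
        # column shares (0.5, 0.5) vs (1, 0) over two samples -> E = (1, 0)
        psi = np.array([[0.5, 1.0], [0.5, 0.0]])
        np.testing.assert_allclose(entropy_weights(psi), [0.0, 1.0], atol=1e-12)

    def test_antimonotone_in_column_entropy(self):
        # column 0 maximally uneven shares, column 1 nearly uniform
        psi = np.array([[1.0, 0.4], [0.0, 0.6], [0.0, 0.5]])
        w = entropy_weights(psi)
        assert w[0] > w[1]

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            entropy_weights(np.zeros((3, 2)))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            entropy_weights(np.array([[1.0, -0.1], [0.5, 0.2]]))


class TestComputeCentroid:
    def test_identical_subset_degenerates_to_uniform(self):
        row = np.arange(6.0) + 1.0
        S = np.tile(row, (3, 1))
        res = compute_centroid(S)
        np.testing.assert_allclose(res.raw_centroid, row)
        np.testing.assert_allclose(res.feature_weights, 1.0 / 6.0)
        np.testing.assert_allclose(res.weighted_centroid, row / 6.0)

    def test_deterministic_and_chains_the_steps(self, rng):
        S = rng.normal(size=(5, 6))
        r1, r2 = compute_centroid(S), compute_centroid(S)
        assert r1.index_k == r2.index_k
        np.testing.assert_array_equal(r1.weighted_centroid, r2.weighted_centroid)
        k = select_centroid_index(pairwise_mic_matrix(S))
        assert r1.index_k == k
        psi = feature_mi_matrix(S, k)
        try:
            w = entropy_weights(psi)
        except ValueError:
            w = np.full(6, 1 / 6)
        np.testing.assert_allclose(r1.feature_weights, w, atol=1e-12)
        np.testing.assert_allclose(r1.weighted_centroid, w * S[k], atol=1e-12)
        assert r1.feature_weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_sample_order_invariance(self, rng):
        S = rng.normal(size=(5, 6))
        base = compute_centroid(S)
        perm = rng.permutation(5)
        shuffled = compute_centroid(S[perm])
        np.testing.assert_allclose(
            shuffled.raw_centroid, base.raw_centroid, atol=1e-12
        )
        np.testing.assert_allclose(
            shuffled.weighted_centroid, base.weighted_centroid, atol=1e-10
        )
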