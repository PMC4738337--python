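import itertools

import numpy as np
import pandas as pd
import pytest

from orthoclust import (
    ConsensusClustering,
    average_linkage_cut,
    consensus_cluster,
    nmf_factorize,
    pac,
    pearson_distance,
    select_k_cophenetic,
    select_k_pac,
)

from conftest import make_matrix


class TestPearsonDistance:
    def test_duplicated_sample_has_zero_distance(self):
        X = make_matrix([[1, 1, 5], [2, 2, 1], [3, 3, 2]])
        D = pearson_distance(X)
        assert D.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation_gives_two(self):
        X = make_matrix([[1, 3], [2, 2], [3, 1]])
        assert pearson_distance(X).iloc[0, 1] == pytest.approx(2.0)

    def test_hand_computed_three_point_profiles(self):
        # r([1,2,3],[1,2,4]) = 3 / sqrt(2 * 42/9)
        X = make_matrix(np.array([[1, 1], [2, 2], [3, 4]]))
        r = 3 / np.sqrt(2 * 42 / 9)
        assert pearson_distance(X).iloc[0, 1] == pytest.approx(1 - r, abs=1e-9)
        assert r == pytest.approx(0.98198, abs=1e-5)

    def test_zero_variance_sample_named(self):
        X = make_matrix([[1, 7], [2, 7], [3, 7]], samples=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            pearson_distance(X)


def brute_force_upgma(d):
    """Naive UPGMA: clusters as frozensets, unweighted mean cross-pair distance."""
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    partitions = {n: list(clusters)}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        partitions[len(clusters)] = list(clusters)
    return partitions


def as_label_sets(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestAverageLinkage:
    def _distance(self, d):
        n = d.shape[0]
        ids = [f"s{i}" for i in range(n)]
        return pd.DataFrame(d, index=ids, columns=ids)

    def test_k_equals_n_gives_singletons(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        labels = average_linkage_cut(self._distance(d), 3)
        assert len(set(labels)) == 3

    def test_k_one_gives_single_cluster(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert len(set(average_linkage_cut(self._distance(d), 1))) == 1

    def test_two_separated_pairs(self):
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0
        labels = average_linkage_cut(self._distance(d), 2)
        assert as_label_sets(labels) == {frozenset({0, 1}), frozenset({2, 3})}

    def test_k_larger_than_n_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            average_linkage_cut(self._distance(d), 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_upgma(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        expected = brute_force_upgma(d)
        for k in range(1, 7):
            labels = average_linkage_cut(self._distance(d), k)
            assert as_label_sets(labels) == set(expected[k]), f"k={k}"


class TestPac:
    def test_crisp_consensus_is_zero(self):
        M = np.kron(np.eye(2), np.ones((2, 2)))
        assert pac(M) == 0.0

    def test_maximally_ambiguous_is_one(self):
        M = np.full((4, 4), 0.5)
        np.fill_diagonal(M, 1.0)
        assert pac(M) == 1.0

    def test_hand_counted_mixed_entries(self):
        assert pac(np.array([0.05, 0.5, 0.95, 1.0])) == pytest.approx(0.25)

    def test_monotone_in_bounds(self):
        rng = np.random.default_rng(1)
        entries = rng.uniform(size=50)
        base = pac(entries, 0.1, 0.9)
        assert pac(entries, 0.05, 0.9) >= base
        assert pac(entries, 0.1, 0.95) >= base

    def test_tiny_matrix_rejected(self):
        with pytest.raises(ValueError):
            pac(np.ones((1, 1)))


class TestModelSelection:
    def test_pac_argmin(self):
        assert select_k_pac({2: 0.40, 3: 0.05, 4: 0.20}) == 3

    def test_pac_tie_breaks_small(self):
        assert select_k_pac({2: 0.10, 3: 0.10}) == 2

    def test_cophenetic_argmax(self):
        assert select_k_cophenetic({2: 0.99, 3: 0.80}) == 2

    def test_cophenetic_tie_breaks_small(self):
        assert select_k_cophenetic({2: 0.95, 3: 0.95}) == 2


class TestConsensusClustering:
    def _block_matrix(self):
        rng = np.random.default_rng(5)
        u = rng.normal(6, 2, size=40)
        v = rng.normal(6, 2, size=40)
        X = np.column_stack([u, u, u, v, v, v])
        return make_matrix(X)

    def test_no_resampling_gives_exact_block_consensus(self):
        res = consensus_cluster(
            self._block_matrix(), k_range=[2], n_resamples=1, p_item=1.0, seed=0
        )
        M = res.consensus_matrices[2]
        expected = np.kron(np.eye(2), np.ones((3, 3)))
        np.testing.assert_array_equal(M, expected)
        assert as_label_sets(res.labels) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_fixed_seed_is_bit_reproducible(self):
        X = self._block_matrix()
        r1 = consensus_cluster(X, range(2, 4), n_resamples=20, seed=9)
        r2 = consensus_cluster(X, range(2, 4), n_resamples=20, seed=9)
        for k in r1.consensus_matrices:
            np.testing.assert_array_equal(
                r1.consensus_matrices[k], r2.consensus_matrices[k]
            )
        assert r1.pac == r2.pac and list(r1.labels) == list(r2.labels)

    def test_equivariant_under_sample_permutation(self):
        X = self._block_matrix()
        perm = np.array([3, 0, 5, 1, 4, 2])
        Xp = make_matrix(X.values.to_numpy()[:, perm],
                         samples=[f"p{j}" for j in range(6)])
        r = consensus_cluster(X, [2], n_resamples=3, p_item=1.0, seed=0)
        rp = consensus_cluster(Xp, [2], n_resamples=3, p_item=1.0, seed=0)
        np.testing.assert_allclose(
            rp.consensus_matrices[2],
            r.consensus_matrices[2][np.ix_(perm, perm)],
        )

    def test_never_cosampled_pairs_warn(self):
        X = self._block_matrix()
        with pytest.warns(UserWarning, match="never co-sampled"):
            consensus_cluster(X, [2], n_resamples=1, p_item=0.5, seed=0)

    def test_invalid_parameters_rejected(self):
        X = self._block_matrix()
        with pytest.raises(ValueError):
            consensus_cluster(X, k_range=[6], n_resamples=5)
        with pytest.raises(ValueError):
            ConsensusClustering(k_range=[2], p_item=0.0).fit(
                X.values.to_numpy().T
            )

    def test_sklearn_get_set_params_round_trip(self):
        est = ConsensusClustering(n_resamples=7, random_state=3)
        params = est.get_params()
        assert params["n_resamples"] == 7
        est.set_params(n_resamples=11)
        assert est.n_resamples == 11


class TestNmf:
    def test_rank_one_matrix_recovered(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2, size=30)
        h = rng.uniform(0.5, 2, size=8)
        V = np.outer(w, h)
        res = nmf_factorize(V, k=1, n_runs=3, max_iter=2000, tol=1e-14, seed=0)
        assert res.objective_traces[0][-1] <= 1e-6
        WH = res.W @ res.H
        assert np.max(np.abs(WH - V) / V) <= 1e-3

    def test_objective_traces_non_increasing(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(0.1, 5, size=(25, 10))
        res = nmf_factorize(V, k=3, n_runs=5, max_iter=150, seed=1)
        for trace in res.objective_traces:
            diffs = np.diff(trace)
            assert np.all(diffs <= 1e-8 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_block_diagonal_gives_perfect_connectivity(self):
        blockA = np.random.default_rng(3).uniform(2, 4, size=(20, 4))
        blockB = np.random.default_rng(4).uniform(2, 4, size=(20, 4))
        V = np.block([
            [blockA, np.full((20, 4), 1e-6)],
            [np.full((20, 4), 1e-6), blockB],
        ])
        res = nmf_factorize(V, k=2, n_runs=10, max_iter=300, seed=0)
        expected = np.kron(np.eye(2), np.ones((4, 4)))
        np.testing.assert_array_equal(res.connectivity_consensus, expected)
        assert res.cophenetic == pytest.approx(1.0)

    def test_negative_entries_require_explicit_clip(self):
        V = np.array([[1.0, -0.5], [2.0, 3.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="negative"):
            nmf_factorize(V, k=1)
        res = nmf_factorize(V, k=1, n_runs=2, clip_negative=True)
        assert np.all(res.W >= 0) and np.all(res.H >= 0)

    def test_k_must_be_below_min_dimension(self):
        V = np.ones((3, 4))
        with pytest.raises(ValueError):
            nmf_factorize(V, k=3)

    def test_matches_sklearn_mu_kl_objective(self):
        """Independent cross-check: sklearn's multiplicative-update KL NMF
        reaches a comparable divergence on the same matrix."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(7)
        V = rng.uniform(0.1, 5, size=(40, 12))
        ours = nmf_factorize(V, k=3, n_runs=5, max_iter=800, tol=1e-12, seed=0)

        def kl(V, W, H):
            WH = W @ H + 1e-12
            return np.sum(V * np.log(V / WH) - V + WH)

        best_ours = min(t[-1] for t in ours.objective_traces)
        sk = NMF(n_components=3, solver="mu", beta_loss="kullback-leibler",
                 init="random", max_iter=800, tol=1e-12, random_state=0).fit(V)
        sk_obj = kl(V, sk.transform(V), sk.components_)
        assert best_ours <= sk_obj * 1.05
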