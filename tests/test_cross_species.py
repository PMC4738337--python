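import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orthoclust import (
    OrthologMap,
    agdex_matrix,
    agdex_permutation_p,
    agdex_score,
    centroid_correlation,
    diff_vector,
    match_orthologs,
)

from conftest import make_matrix


def _vec(genes, values, species="mouse", group="g"):
    from orthoclust.cross_species import DiffVector

    return DiffVector(pd.Index(genes), np.asarray(values, float), species, group, "ref")


def _omap(pairs):
    return OrthologMap(pd.DataFrame(pairs, columns=["gene_a", "gene_b"]))


class TestDiffVector:
    def test_same_sets_give_zero(self):
        X = make_matrix([[1, 2], [3, 4]])
        d = diff_vector(X, ["s1", "s2"], ["s1", "s2"])
        np.testing.assert_array_equal(d.d, [0, 0])

    def test_single_sample_subtraction(self):
        X = make_matrix([[3, 1], [5, 1]])
        d = diff_vector(X, ["s1"], ["s2"])
        np.testing.assert_array_equal(d.d, [2, 4])

    def test_within_side_permutation_invariant(self):
        X = make_matrix(np.random.default_rng(0).normal(size=(5, 6)))
        d1 = diff_vector(X, ["s1", "s2", "s3"], ["s4", "s5", "s6"])
        d2 = diff_vector(X, ["s3", "s1", "s2"], ["s6", "s4", "s5"])
        np.testing.assert_allclose(d1.d, d2.d)

    def test_empty_side_rejected(self):
        X = make_matrix([[1, 2]])
        with pytest.raises(ValueError):
            diff_vector(X, [], ["s1"])


class TestMatchOrthologs:
    def test_identity_universe_full_pairing(self):
        dA = _vec(["a1", "a2"], [1, 2])
        dB = _vec(["b1", "b2"], [3, 4], species="human")
        a, b, pairs = match_orthologs(dA, dB, _omap([("a1", "b1"), ("a2", "b2")]))
        assert len(pairs) == 2
        np.testing.assert_array_equal(a, [1, 2])
        np.testing.assert_array_equal(b, [3, 4])

    def test_absent_gene_drops_pair(self):
        dA = _vec(["a1", "a2", "a3"], [1, 2, 3])
        dB = _vec(["b1", "b3"], [5, 7], species="human")
        a, b, pairs = match_orthologs(
            dA, dB, _omap([("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
        )
        assert len(pairs) == 2
        np.testing.assert_array_equal(b, [5, 7])

    def test_non_reduced_map_rejected(self):
        dA = _vec(["a1", "a2"], [1, 2])
        dB = _vec(["b1"], [3], species="human")
        with pytest.raises(ValueError, match="1:1"):
            match_orthologs(dA, dB, _omap([("a1", "b1"), ("a2", "b1")]))

    def test_zero_matches_rejected(self):
        dA = _vec(["a1"], [1])
        dB = _vec(["b9"], [3], species="human")
        with pytest.raises(ValueError, match="matched"):
            match_orthologs(dA, dB, _omap([("a1", "b1")]))


class TestAgdexScore:
    def test_self_agreement(self):
        d = [1.0, -2.0, 0.5]
        assert agdex_score(d, d) == pytest.approx(1.0)

    def test_antisymmetry(self):
        d = np.array([1.0, -2.0, 0.5])
        assert agdex_score(d, -d) == pytest.approx(-1.0)

    def test_hand_computed_cosine(self):
        assert agdex_score([2, 1, -1], [1, 1, 0]) == pytest.approx(
            3 / math.sqrt(12), abs=1e-9
        )

    def test_all_zero_vector_undefined(self):
        assert math.isnan(agdex_score([0, 0], [1, 2]))

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.01, 100), st.integers(0, 10_000))
    def test_scale_invariance_and_sign_flip(self, c, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        s = agdex_score(a, b)
        assert agdex_score(c * a, b) == pytest.approx(s, abs=1e-9)
        assert agdex_score(-c * a, b) == pytest.approx(-s, abs=1e-9)

    def test_common_permutation_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 9))
        perm = rng.permutation(9)
        assert agdex_score(a[perm], b[perm]) == pytest.approx(agdex_score(a, b))


class TestPermutationP:
    def test_exhaustive_matches_brute_enumeration(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 3.0])
        obs = abs(agdex_score(a, b))
        count = sum(
            abs(agdex_score(a, b[list(perm)])) >= obs - 1e-12
            for perm in itertools.permutations(range(3))
        )
        expected = (1 + count) / (math.factorial(3) + 1)
        assert agdex_permutation_p(a, b) == pytest.approx(expected)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 20))
        p1 = agdex_permutation_p(a, b, n_perm=200, seed=5)
        p2 = agdex_permutation_p(a, b, n_perm=200, seed=5)
        assert p1 == p2

    def test_monte_carlo_approaches_exhaustive(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 6))
        exact = agdex_permutation_p(a, b)          # 720 permutations
        from orthoclust import cross_species

        orig = cross_species.EXHAUSTIVE_LIMIT
        cross_species.EXHAUSTIVE_LIMIT = 0         # force Monte-Carlo path
        try:
            approx = agdex_permutation_p(a, b, n_perm=20_000, seed=0)
        finally:
            cross_species.EXHAUSTIVE_LIMIT = orig
        assert approx == pytest.approx(exact, abs=0.01)


class TestAgdexMatrix:
    def _paired_setup(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 1, size=(6, 6))
        A = make_matrix(X, genes=[f"a{i}" for i in range(6)], species="mouse")
        B = make_matrix(X, genes=[f"b{i}" for i in range(6)], species="human")
        omap = _omap([(f"a{i}", f"b{i}") for i in range(6)])
        groups = {"G1": ["s1", "s2"], "G2": ["s3", "s4"]}
        refs = ["s5", "s6"]
        return A, B, omap, groups, refs

    def test_identical_data_identity_map_diagonal_one(self):
        A, B, omap, groups, refs = self._paired_setup()
        scores, pvals, _ = agdex_matrix(
            A, groups, refs, B, groups, refs, omap, n_perm=10, seed=0
        )
        assert scores.loc["G1", "G1"] == pytest.approx(1.0)
        assert scores.loc["G2", "G2"] == pytest.approx(1.0)
        assert (pvals.to_numpy() > 0).all() and (pvals.to_numpy() <= 1).all()

    def test_swapping_species_transposes_scores(self):
        A, B, omap, groups, refs = self._paired_setup()
        fwd, _, _ = agdex_matrix(A, groups, refs, B, groups, refs, omap,
                                 n_perm=5, seed=0)
        swapped = OrthologMap(
            omap.pairs.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})[
                ["gene_a", "gene_b"]
            ]
        )
        rev, _, _ = agdex_matrix(B, groups, refs, A, groups, refs, swapped,
                                 n_perm=5, seed=0)
        np.testing.assert_allclose(fwd.to_numpy(), rev.to_numpy().T, atol=1e-12)


class TestCentroidCorrelation:
    def test_self_copy_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        X = make_matrix(rng.normal(5, 1, size=(10, 4)))
        corr = centroid_correlation(
            X, {"G": ["s1", "s2"]}, X, {"R": ["s1", "s2"]}
        )
        assert corr.loc["G", "R"] == pytest.approx(1.0)

    def test_negated_centroid_anticorrelates(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, size=8)
        X = make_matrix(np.column_stack([5 + v, 5 - v]))
        corr = centroid_correlation(X, {"G": ["s1"]}, X, {"R": ["s2"]})
        assert corr.loc["G", "R"] == pytest.approx(-1.0)

    def test_too_few_shared_genes_rejected(self):
        X = make_matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="shared gene"):
            centroid_correlation(X, {"G": ["s1"]}, X, {"R": ["s2"]})
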