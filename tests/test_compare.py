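"""MinHash sketches, Mash distance, fragment ANI and clustering."""

import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from prophagekit import synth
from prophagekit.compare import (
    DistanceMatrix,
    ani,
    classify_species,
    cluster,
    is_hit,
    mash_distance,
    pairwise_mash,
    similarity_percent,
    sketch,
    sketch_jaccard,
)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(_COMP)[::-1]


def exact_canonical_jaccard(a, b, k=21):
    """Independent full-set Jaccard oracle over canonical k-mers."""

    def canon(seq):
        out = set()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            out.add(min(km, revcomp(km)))
        return out

    A, B = canon(a), canon(b)
    return len(A & B) / len(A | B)


class TestSketch:
    def test_reverse_complement_gives_identical_sketch(self, rng):
        seq = synth.random_dna(3000, 0.5, rng)
        a, b = sketch(seq), sketch(revcomp(seq))
        assert np.array_equal(a.hashes, b.hashes)
        assert a.n_kmers == b.n_kmers

    def test_small_sequence_keeps_all_kmers(self, rng):
        seq = synth.random_dna(200, 0.5, rng)
        sk = sketch(seq, s=1000)
        assert sk.hashes.size == sk.n_kmers <= 180

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            sketch("ACGT", k=21)

    def test_jaccard_exact_when_sketch_covers_all_kmers(self, rng):
        a = synth.random_dna(2000, 0.5, rng)
        b = synth.mutate_sequence(a, 0.02, rng)
        est = sketch_jaccard(sketch(a, s=10**6), sketch(b, s=10**6))
        assert est == pytest.approx(exact_canonical_jaccard(a, b), abs=1e-12)

    def test_jaccard_estimate_within_binomial_bound(self):
        errors = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = synth.random_dna(2000, 0.5, rng)
            b = synth.mutate_sequence(a, 0.02, rng)
            j_true = exact_canonical_jaccard(a, b)
            j_est = sketch_jaccard(sketch(a, s=1000), sketch(b, s=1000))
            sigma = math.sqrt(j_true * (1 - j_true) / 1000)
            assert abs(j_est - j_true) <= 4.5 * sigma
            errors.append(abs(j_est - j_true) / sigma)
        assert np.mean(errors) <= 2.0


class TestMashDistance:
    def test_identical_sequences_have_zero_distance(self, rng):
        seq = synth.random_dna(5000, 0.5, rng)
        sk = sketch(seq)
        assert mash_distance(sk, sk) == 0.0

    def test_unrelated_sequences_capped_at_one(self, rng):
        a = sketch(synth.random_dna(2000, 0.5, rng))
        b = sketch(synth.random_dna(2000, 0.5, rng))
        assert mash_distance(a, b) == 1.0

    def test_k_mismatch_rejected(self, rng):
        seq = synth.random_dna(1000, 0.5, rng)
        with pytest.raises(ValueError, match="k mismatch"):
            mash_distance(sketch(seq, k=21), sketch(seq, k=17))

    def test_symmetry(self, rng):
        a = synth.random_dna(4000, 0.5, rng)
        b = synth.mutate_sequence(a, 0.05, rng)
        assert mash_distance(sketch(a), sketch(b)) == mash_distance(sketch(b), sketch(a))

    def test_tracks_per_base_mutation_rate(self):
        ds = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = synth.random_dna(10_000, 0.5, rng)
            b = synth.mutate_sequence(a, 0.03, rng)
            ds.append(mash_distance(sketch(a), sketch(b)))
        assert abs(np.mean(ds) - 0.03) <= 0.01


class TestSimilarity:
    @pytest.mark.parametrize(
        "d,sim,hit",
        [(0.0, 100.0, True), (0.30, 70.0, True), (0.31, 69.0, False)],
    )
    def test_similarity_and_hit_boundary(self, d, sim, hit):
        s = similarity_percent(d)
        assert s == pytest.approx(sim)
        assert is_hit(s) is hit


class TestAni:
    def test_identical_sequences_give_100(self, rng):
        seq = synth.random_dna(5000, 0.5, rng)
        assert ani(seq, seq) == pytest.approx(100.0)

    def test_tracks_mutation_rate_within_one_point(self):
        values = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = synth.random_dna(5000, 0.5, rng)
            b = synth.mutate_sequence(a, 0.05, rng)
            values.append(ani(a, b))
        assert abs(np.mean(values) - 95.0) <= 1.0

    def test_unrelated_sequences_undefined(self, rng):
        a = synth.random_dna(3000, 0.5, rng)
        b = synth.random_dna(3000, 0.5, rng)
        assert ani(a, b) is None

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            ani("ACGT" * 10, synth.random_dna(2000, 0.5, rng))


class TestClassifySpecies:
    @pytest.mark.parametrize(
        "value,expected",
        [(84.0, "different"), (85.0, "same"), (99.5, "same"), (None, "different")],
    )
    def test_species_boundary(self, value, expected):
        assert classify_species(value) == expected


class TestCluster:
    def test_identical_pair_merges_first_at_zero_height(self, rng):
        a = synth.random_dna(3000, 0.5, rng)
        distant = synth.random_dna(3000, 0.5, rng)
        matrix = pairwise_mash(["p1", "p2", "far"], [a, a, distant])
        root = cluster(matrix)
        (first,) = [n for n in (root.left, root.right) if not n.is_leaf]
        assert sorted(first.labels) == ["p1", "p2"]
        assert first.height == 0.0

    def test_agrees_with_scipy_agglomerative_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(6):
            n = 6
            m = rng.random((n, n)) * 0.9
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            dm = DistanceMatrix(tuple("ABCDEF"), m)
            mine = cluster(dm).merge_heights()
            oracle = np.sort(scipy_linkage(squareform(m), "average")[:, 2])
            assert np.allclose(mine, oracle)

    def test_label_permutation_preserves_merge_heights(self):
        rng = np.random.default_rng(4)
        m = rng.random((5, 5)) * 0.5
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = tuple("ABCDE")
        root = cluster(DistanceMatrix(labels, m))
        perm = [2, 0, 4, 1, 3]
        permuted = cluster(
            DistanceMatrix(tuple(labels[i] for i in perm), m[np.ix_(perm, perm)])
        )
        assert np.allclose(root.merge_heights(), permuted.merge_heights())
        assert sorted(root.labels) == sorted(permuted.labels)

    def test_non_symmetric_matrix_rejected(self):
        m = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), m)
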