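"""Sketch-based phage genome comparison, fragment ANI and clustering.

A bottom-s MinHash sketch stores the ``s`` smallest 64-bit hashes of the
distinct canonical k-mers of a sequence (k = 21, s = 1000 by default, the
parameters used for prophage database searches). The Jaccard index of two
k-mer sets is estimated from the shared hashes among the bottom-s of the
merged hash union and converted to a mutation-distance estimate

    d = -ln(2j / (1 + j)) / k

capped at 1 when no hashes are shared. "Similarity" is ``100 * (1 - d)``
with hits called at >= 70%.

Average nucleotide identity (ANI) chops the query into consecutive
1020-bp fragments, aligns each locally against the subject (match +1,
mismatch -1, gap open -5, extend -2) and averages the identity of fragments
passing identity and coverage filters; < 85% ANI indicates a different
phage species. Hierarchical clustering is average-linkage (UPGMA) with
deterministic tie-breaking by label order.

The k-mer hash is splitmix64 applied to the 2-bit-packed canonical k-mer
code: fixed, documented, bijective on 64 bits and identical across runs and
platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from Bio import Align

__all__ = [
    "Sketch",
    "DistanceMatrix",
    "ClusterNode",
    "sketch",
    "sketch_jaccard",
    "mash_distance",
    "similarity_percent",
    "is_hit",
    "ani",
    "classify_species",
    "cluster",
    "pairwise_mash",
]

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finaliser: a fixed bijective 64-bit mix."""
    x = x.astype(np.uint64, copy=True)
    x += np.uint64(0x9E3779B97F4A7C15)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def _canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Distinct canonical k-mer codes (2-bit packed), N-containing windows dropped.

    With A<C<G<T coded 0..3, numeric order of the packed code equals
    lexicographic order, so the canonical k-mer (the lexicographic minimum
    of a k-mer and its reverse complement) is the elementwise minimum of the
    forward and reverse-complement codes.
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k ({len(sequence)} < {k})")
    vals = _BASE_CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    n_kmers = len(sequence) - k + 1
    invalid = vals == 255
    fwd = np.zeros(n_kmers, dtype=np.uint64)
    rc = np.zeros(n_kmers, dtype=np.uint64)
    v64 = vals.astype(np.uint64)
    four = np.uint64(4)
    three = np.uint64(3)
    for j in range(k):
        fwd = fwd * four + v64[j : j + n_kmers]
    for j in range(k - 1, -1, -1):
        rc = rc * four + (three - v64[j : j + n_kmers])
    bad = np.convolve(invalid.astype(np.int8), np.ones(k, dtype=np.int8), mode="valid") > 0
    canonical = np.minimum(fwd, rc)[~bad]
    if canonical.size == 0:
        raise ValueError("no valid k-mers (sequence entirely ambiguous)")
    return np.unique(canonical)


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of a sequence's canonical k-mer set."""

    k: int
    s: int
    hashes: np.ndarray  # sorted ascending, uint64, |hashes| = min(s, n_kmers)
    n_kmers: int

    def __post_init__(self) -> None:
        if self.hashes.size != min(self.s, self.n_kmers):
            raise ValueError("sketch must keep min(s, n_kmers) hashes")
        if self.hashes.size > 1 and np.any(np.diff(self.hashes) == np.uint64(0)):
            raise ValueError("sketch hashes must be distinct")


def sketch(sequence: str, k: int = 21, s: int = 1000) -> Sketch:
    """Bottom-s sketch of the canonical k-mers of ``sequence``."""
    if s < 1:
        raise ValueError("sketch size s must be positive")
    codes = _canonical_kmer_codes(sequence, k)
    hashes = np.sort(_mix64(codes))
    return Sketch(k=k, s=s, hashes=hashes[:s], n_kmers=int(codes.size))


def sketch_jaccard(a: Sketch, b: Sketch) -> float:
    """Jaccard estimate from the bottom-s of the merged hash union."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)[:s]
    shared = np.intersect1d(union, np.intersect1d(a.hashes, b.hashes, assume_unique=True))
    if union.size == 0:
        return 0.0
    return float(shared.size / union.size)


def mash_distance(sketch_a: Sketch, sketch_b: Sketch) -> float:
    """MinHash mutation-distance estimate in [0, 1]."""
    j = sketch_jaccard(sketch_a, sketch_b)
    if j <= 0:
        return 1.0
    d = -math.log(2 * j / (1 + j)) / sketch_a.k
    return min(max(d, 0.0), 1.0)


def similarity_percent(d: float) -> float:
    """Similarity in percent: 100 * (1 - distance)."""
    if not 0 <= d <= 1:
        raise ValueError("distance must be in [0, 1]")
    return 100.0 * (1.0 - d)


def is_hit(similarity: float, threshold: float = 70.0) -> bool:
    """Database-hit call at a similarity of *at least* the threshold."""
    return similarity >= threshold


# ---------------------------------------------------------------------------
# Fragment ANI


def _fragment_identity_coverage(
    aligner: Align.PairwiseAligner, fragment: str, subject: str
) -> tuple[float, float]:
    alignments = aligner.align(fragment, subject)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0.0
    identity = counts.identities / columns
    aligned_query = sum(end - start for start, end in aln.aligned[0])
    return identity, aligned_query / len(fragment)


def ani(
    seq_a: str,
    seq_b: str,
    fragment_len: int = 1020,
    min_identity: float = 0.7,
    min_coverage: float = 0.7,
) -> float | None:
    """Fragment-based average nucleotide identity of ``seq_a`` against ``seq_b``.

    ``seq_a`` is chopped into consecutive full-length fragments, each aligned
    locally against ``seq_b`` (match +1, mismatch -1, gap open -5,
    extend -2). Fragments passing both the identity and coverage filters
    contribute their identity; the mean identity * 100 is returned, or
    ``None`` (undefined) when no fragment passes.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) < fragment_len or len(seq_b) < fragment_len:
        raise ValueError(f"sequences must be at least fragment_len ({fragment_len}) bp")
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-5,
        extend_gap_score=-2,
    )
    identities = []
    for i in range(0, len(seq_a) - fragment_len + 1, fragment_len):
        fragment = seq_a[i : i + fragment_len]
        identity, coverage = _fragment_identity_coverage(aligner, fragment, seq_b)
        if identity >= min_identity and coverage >= min_coverage:
            identities.append(identity)
    if not identities:
        return None
    return 100.0 * float(np.mean(identities))


def classify_species(ani_value: float | None, threshold: float = 85.0) -> Literal["same", "different"]:
    """Species call: 'different' iff ANI < threshold (or ANI undefined)."""
    if ani_value is None:
        return "different"
    return "different" if ani_value < threshold else "same"


# ---------------------------------------------------------------------------
# Hierarchical clustering


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match the number of labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("distances must be in [0, 1]")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def pairwise_mash(labels: Sequence[str], sequences: Sequence[str], k: int = 21, s: int = 1000) -> DistanceMatrix:
    """Pairwise Mash distance matrix for a set of sequences."""
    if len(labels) != len(sequences):
        raise ValueError("labels and sequences must have equal length")
    sketches = [sketch(seq, k=k, s=s) for seq in sequences]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = mash_distance(sketches[i], sketches[j])
    return DistanceMatrix(tuple(labels), d)


@dataclass(frozen=True)
class ClusterNode:
    """A dendrogram node: merge height, member labels, child nodes."""

    height: float
    labels: tuple[str, ...]
    left: "ClusterNode | None" = None
    right: "ClusterNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def merge_heights(self) -> list[float]:
        """Heights of all internal merges, sorted ascending."""
        if self.is_leaf:
            return []
        return sorted(self.left.merge_heights() + self.right.merge_heights() + [self.height])

    def to_nested(self):
        """Nested (left, right, height) tuples; leaves are label strings."""
        if self.is_leaf:
            return self.labels[0]
        return (self.left.to_nested(), self.right.to_nested(), self.height)


def cluster(matrix: DistanceMatrix, linkage: str = "average") -> ClusterNode:
    """Agglomerative clustering of a distance matrix into a dendrogram.

    ``linkage="average"`` (UPGMA) is the default; ``"single"`` and
    ``"complete"`` are also available. Ties are broken deterministically by
    the (sorted) label tuples of the candidate cluster pair.
    """
    if linkage not in {"average", "single", "complete"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    if len(matrix.labels) < 2:
        raise ValueError("at least two labels required")
    ids = list(range(len(matrix.labels)))
    next_id = len(ids)
    store: dict[int, ClusterNode] = {i: ClusterNode(0.0, (label,)) for i, label in enumerate(matrix.labels)}
    size_of: dict[int, int] = {i: 1 for i in ids}
    dist: dict[frozenset[int], float] = {}
    for i in ids:
        for j in ids:
            if i < j:
                dist[frozenset((i, j))] = float(matrix.values[i, j])

    while len(ids) > 1:
        best = min(
            (
                (dist[frozenset((i, j))], store[i].labels, store[j].labels, i, j)
                for a, i in enumerate(ids)
                for j in ids[a + 1 :]
            ),
        )
        d_ij, _, _, i, j = best
        left, right = sorted((store[i], store[j]), key=lambda n: n.labels)
        merged = ClusterNode(
            height=d_ij,
            labels=tuple(sorted(left.labels + right.labels)),
            left=left,
            right=right,
        )
        for other in ids:
            if other in (i, j):
                continue
            d_i = dist[frozenset((i, other))]
            d_j = dist[frozenset((j, other))]
            if linkage == "average":
                d_new = (size_of[i] * d_i + size_of[j] * d_j) / (size_of[i] + size_of[j])
            elif linkage == "single":
                d_new = min(d_i, d_j)
            else:
                d_new = max(d_i, d_j)
            dist[frozenset((next_id, other))] = d_new
        store[next_id] = merged
        size_of[next_id] = size_of[i] + size_of[j]
        ids = [x for x in ids if x not in (i, j)] + [next_id]
        next_id += 1
    return store[ids[0]]
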