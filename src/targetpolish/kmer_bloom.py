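"""Canonical k-mer hashing and Bloom-filter membership structures.

One Bloom filter is built per target region and per k-mer size, populated
with the canonical k-mers of the reads lifted to that target.  Restricting
each filter to locally mapped reads is what makes targeted polishing
specific: sequence from elsewhere in the assembly can neither mask a local
error nor lend support to a wrong edit (beyond the configured false-positive
rate).

K-mers are canonicalized (lexicographic min of k-mer and reverse
complement) so membership is strand-neutral; alignment strand is therefore
irrelevant when populating or querying.  Hashing is a double-hashing
scheme, index_i = (h1 + i*h2) mod m, over two seeded 64-bit mixes of the
2-bit-packed canonical k-mer (k <= 32 packs into one 64-bit word).  The
scalar and vectorized query paths compute bit-identical hashes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np

MAX_K = 32  # 2-bit packing limit for a 64-bit word

_U64 = np.uint64
_MASK64 = (1 << 64) - 1
_SEED1 = 0x9E3779B97F4A7C15
_SEED2 = 0xC2B2AE3D27D4EB4F

# base -> 2-bit code; anything outside ACGTacgt (incl. N/n) maps to 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to 2-bit codes (uint8); invalid bases become 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All canonical k-mers of ``seq`` as packed 64-bit words.

    Returns ``(kmers, valid)`` of length ``len(seq) - k + 1``; ``valid`` is
    False where the window contains a non-ACGT character (those entries of
    ``kmers`` are meaningless).  Empty arrays when the sequence is shorter
    than ``k``.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    codes = encode_bases(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=_U64), np.empty(0, dtype=bool)
    invalid = (codes >= 4).astype(np.int32)
    bad_in_window = np.convolve(invalid, np.ones(k, dtype=np.int32), mode="valid")
    valid = bad_in_window == 0
    safe = np.where(codes >= 4, 0, codes).astype(_U64)
    fwd = np.zeros(n, dtype=_U64)
    rev = np.zeros(n, dtype=_U64)
    two = _U64(2)
    for j in range(k):
        fwd = (fwd << two) | safe[j : j + n]
        rev |= (_U64(3) - safe[j : j + n]) << _U64(2 * j)
    return np.minimum(fwd, rev), valid


def canonical_kmer(seq: str, pos: int, k: int) -> Optional[str]:
    """Canonical form of the k-mer at ``pos``; None if it contains non-ACGT."""
    window = seq[pos : pos + k].upper()
    if len(window) < k or any(c not in "ACGT" for c in window):
        return None
    rc = reverse_complement(window)
    return window if window <= rc else rc


def _splitmix64_scalar(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def _splitmix64_vec(x: np.ndarray) -> np.ndarray:
    x = x + _U64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)
    return x ^ (x >> _U64(31))


def size_bloom(n_expected: int, fpr: float) -> tuple[int, int]:
    """Standard Bloom sizing: bits m and hash count h for n items at rate p.

    m = ceil(-n ln p / (ln 2)^2), h = max(1, round((m/n) ln 2)).
    """
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    if not 0.0 < fpr < 1.0:
        raise ValueError(f"fpr must be in (0, 1), got {fpr}")
    m = math.ceil(-n_expected * math.log(fpr) / (math.log(2) ** 2))
    h = max(1, round(m / n_expected * math.log(2)))
    return m, h


class BloomFilter:
    """Probabilistic canonical-k-mer set: no false negatives, bounded FPR."""

    def __init__(self, m: int, num_hashes: int, k: int):
        if m < 1 or num_hashes < 1:
            raise ValueError("m and num_hashes must be >= 1")
        self.m = m
        self.num_hashes = num_hashes
        self.k = k
        self.n_inserted = 0
        self.bits = np.zeros(m, dtype=bool)

    @classmethod
    def sized_for(cls, n_expected: int, fpr: float, k: int) -> "BloomFilter":
        m, h = size_bloom(max(1, n_expected), fpr)
        return cls(m, h, k)

    def _indices(self, kmers: np.ndarray) -> np.ndarray:
        """(n, num_hashes) bit indices for packed canonical k-mers."""
        h1 = _splitmix64_vec(kmers + _U64(_SEED1))
        h2 = _splitmix64_vec(kmers + _U64(_SEED2)) | _U64(1)
        steps = np.arange(self.num_hashes, dtype=_U64)
        return (h1[:, None] + steps[None, :] * h2[:, None]) % _U64(self.m)

    def insert_kmers(self, kmers: np.ndarray) -> None:
        if len(kmers) == 0:
            return
        # chunked so the (n, h) index matrix stays modest
        for lo in range(0, len(kmers), 1 << 20):
            chunk = kmers[lo : lo + (1 << 20)]
            self.bits[self._indices(chunk).ravel()] = True
        self.n_inserted += len(kmers)

    def insert_sequence(self, seq: str) -> int:
        """Insert every valid canonical k-mer of ``seq``; returns how many."""
        kmers, valid = canonical_kmers(seq, self.k)
        kept = kmers[valid]
        self.insert_kmers(kept)
        return len(kept)

    def contains_kmers(self, kmers: np.ndarray) -> np.ndarray:
        if len(kmers) == 0:
            return np.empty(0, dtype=bool)
        out = np.empty(len(kmers), dtype=bool)
        for lo in range(0, len(kmers), 1 << 20):
            chunk = kmers[lo : lo + (1 << 20)]
            out[lo : lo + len(chunk)] = self.bits[self._indices(chunk)].all(axis=1)
        return out

    def contains_encoded(self, kmer: int) -> bool:
        """Scalar membership query on a packed canonical k-mer."""
        h1 = _splitmix64_scalar((kmer + _SEED1) & _MASK64)
        h2 = _splitmix64_scalar((kmer + _SEED2) & _MASK64) | 1
        bits = self.bits
        m = self.m
        # 64-bit wrap before the modulus, to match the vectorized path
        return all(
            bits[((h1 + i * h2) & _MASK64) % m] for i in range(self.num_hashes)
        )

    def contains(self, kmer: str) -> bool:
        """Membership of a k-mer given as a string (canonicalized here)."""
        canon = canonical_kmer(kmer, 0, self.k)
        if canon is None:
            return False
        packed = 0
        for c in canon:
            packed = (packed << 2) | int(_ENCODE[ord(c)])
        return self.contains_encoded(packed)

    def presence_profile(self, seq: str) -> np.ndarray:
        """Boolean per-position profile: k-mer at i valid AND in the filter."""
        kmers, valid = canonical_kmers(seq, self.k)
        present = np.zeros(len(kmers), dtype=bool)
        if valid.any():
            present[valid] = self.contains_kmers(kmers[valid])
        return present


@dataclass
class BloomFilterSet:
    """Per-target filters, one per k-mer size, k descending."""

    target_name: str
    filters: Dict[int, BloomFilter] = field(default_factory=dict)

    @property
    def k_values(self) -> list[int]:
        return list(self.filters)

    def kmer_counts(self) -> Dict[int, int]:
        return {k: f.n_inserted for k, f in self.filters.items()}


def build_filters(
    target_name: str,
    read_seqs: Sequence[str],
    k_values: Sequence[int] = (32, 28, 24, 20),
    fpr: float = 0.01,
    min_count: int = 2,
) -> BloomFilterSet:
    """Build one filter per k from the reads assigned to a target.

    Only *solid* canonical k-mers — distinct k-mers occurring at least
    ``min_count`` times across the reads — enter a filter.  Long-read
    errors are mostly unreplicated, so singleton k-mers are overwhelmingly
    artefacts; admitting them both masks genuine draft errors (the
    erroneous draft k-mer "exists" in some read) and lends full support to
    wrong edit candidates that happen to replicate one read's error.  At
    the coverages targeted polishing assumes (tens of reads per region) a
    true k-mer is essentially never lost to ``min_count=2``; set
    ``min_count=1`` to keep every k-mer at very low coverage.

    K-mers are counted exactly (targets are small, so exact counting is
    cheap) and each filter is sized for its solid-k-mer count.  Zero reads
    — or reads all shorter than k — give an empty filter that answers
    False to every query.
    """
    if not k_values:
        raise ValueError("k_values must be non-empty")
    if list(k_values) != sorted(set(k_values), reverse=True):
        raise ValueError("k_values must be strictly descending")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    fset = BloomFilterSet(target_name)
    for k in k_values:
        chunks = []
        for seq in read_seqs:
            kmers, valid = canonical_kmers(seq, k)
            if valid.any():
                chunks.append(kmers[valid])
        if chunks:
            distinct, counts = np.unique(np.concatenate(chunks), return_counts=True)
            solid = distinct[counts >= min_count]
        else:
            solid = np.empty(0, dtype=_U64)
        if len(solid):
            filt = BloomFilter.sized_for(len(solid), fpr, k)
            filt.insert_kmers(solid)
        else:
            filt = BloomFilter(8, 1, k)
        fset.filters[k] = filt
    return fset
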