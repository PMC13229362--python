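"""High-confidence k-mer and spaced-seed indexing.

Reads are decomposed into canonical k-mers (lexicographic minimum of a
k-mer and its reverse complement), counted exactly, and a count
threshold is chosen at the first local minimum of the lightly smoothed
multiplicity histogram — the valley separating low-abundance
(presumably erroneous) k-mers from genomic ones.  Every k-mer at or
above the threshold is inserted into a Bloom filter; for every seed in
a :class:`~seedpolish.seeds.SeedSet`, the care-position projections of
those k-mers (both orientations) go into a per-seed Bloom filter.

The Bloom filters guarantee no false negatives, so an unsupported
window in the draft assembly is real evidence of a discrepancy with the
read set; false positives occur at a configurable rate and are
tolerated downstream.
"""

from __future__ import annotations

import hashlib
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .seeds import SeedSet

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Histogram truncation: multiplicities above this are pooled.
MAX_MULTIPLICITY = 10_000

#: Fallback threshold when the histogram has no interior local minimum.
FALLBACK_THRESHOLD = 2

DEFAULT_FPR = 0.001


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


_VALID = frozenset("ACGT")


def _is_valid(kmer: str) -> bool:
    return all(c in _VALID for c in kmer)


# ---------------------------------------------------------------------------
# Counting and thresholding


@dataclass
class KmerHistogram:
    """Multiplicity -> number of distinct canonical k-mers at that count."""

    counts: dict[int, int]
    k: int

    @property
    def n_distinct(self) -> int:
        return sum(self.counts.values())

    @property
    def max_multiplicity(self) -> int:
        return max(self.counts) if self.counts else 0


def iter_kmers(seq: str, k: int) -> Iterable[str]:
    """Canonical k-mers of ``seq``; windows with non-ACGT bases skipped."""
    seq = seq.upper()
    rc = reverse_complement(seq)
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if not _is_valid(fwd):
            continue
        rev = rc[n - k - i : n - i]
        yield fwd if fwd <= rev else rev


def count_kmer_multiplicities(reads: Iterable[str], k: int) -> Counter:
    """Exact canonical k-mer counts over a read collection."""
    if k < 3:
        raise ValueError("k must be >= 3")
    counts: Counter = Counter()
    any_long = False
    for read in reads:
        if len(read) < k:
            continue
        any_long = True
        counts.update(iter_kmers(read, k))
    if not any_long:
        raise ValueError("all reads shorter than k; empty histogram")
    return counts


def count_kmers(reads: Iterable[str], k: int) -> KmerHistogram:
    """Build the k-mer multiplicity histogram of a read collection."""
    counts = count_kmer_multiplicities(reads, k)
    hist: Counter = Counter()
    for mult in counts.values():
        hist[min(mult, MAX_MULTIPLICITY)] += 1
    return KmerHistogram(dict(hist), k)


def select_threshold(hist: KmerHistogram) -> int:
    """First local minimum of the smoothed histogram, else the fallback.

    The histogram is densified over multiplicities 1..max, smoothed with
    a 3-bin moving average, and scanned from multiplicity 2 upward for
    the first interior bin that is <= both neighbours.  Degenerate
    histograms (strictly decreasing, or a single occupied bin) fall back
    to a threshold of 2.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    mmax = hist.max_multiplicity
    if mmax < 3:
        return FALLBACK_THRESHOLD
    dense = np.zeros(mmax + 1, dtype=float)
    for mult, n in hist.counts.items():
        dense[mult] = n
    y = dense[1:]  # index i -> multiplicity i+1
    sm = np.copy(y)
    if len(y) >= 3:
        sm[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    for i in range(1, len(sm) - 1):
        if sm[i] <= sm[i - 1] and sm[i] <= sm[i + 1]:
            return i + 1
    return FALLBACK_THRESHOLD


# ---------------------------------------------------------------------------
# Bloom filter


class BloomFilter:
    """Plain Bloom filter over byte strings.

    Sized with m = -n ln(fpr) / (ln 2)^2 bits and h = round(m/n ln 2)
    hash functions; double hashing from a keyed blake2b digest keeps
    membership deterministic across processes.
    """

    def __init__(self, n_expected: int, fpr: float, salt: bytes = b"seedpolish"):
        if not 0.0 < fpr < 1.0:
            raise ValueError("fpr must be in (0,1)")
        n_expected = max(n_expected, 1)
        m = int(math.ceil(-n_expected * math.log(fpr) / (math.log(2) ** 2)))
        self.m = max(m, 64)
        self.n_hashes = max(1, round(self.m / n_expected * math.log(2)))
        self._bits = np.zeros((self.m + 7) // 8, dtype=np.uint8)
        self._salt = salt
        self.n_inserted = 0

    def _probes(self, item: bytes):
        d = hashlib.blake2b(item, digest_size=16, key=self._salt).digest()
        h1 = int.from_bytes(d[:8], "little")
        h2 = int.from_bytes(d[8:], "little") | 1
        m = self.m
        return [(h1 + i * h2) % m for i in range(self.n_hashes)]

    def add(self, item: bytes) -> None:
        bits = self._bits
        for idx in self._probes(item):
            bits[idx >> 3] |= 1 << (idx & 7)
        self.n_inserted += 1

    def __contains__(self, item: bytes) -> bool:
        bits = self._bits
        for idx in self._probes(item):
            if not (bits[idx >> 3] >> (idx & 7)) & 1:
                return False
        return True


# ---------------------------------------------------------------------------
# Confidence index


def _projection(window: str, care_positions: tuple[int, ...]) -> str | None:
    """Care-position characters of a window; None if any is not ACGT."""
    chars = [window[i] for i in care_positions]
    for c in chars:
        if c not in _VALID:
            return None
    return "".join(chars)


@dataclass
class ConfidenceIndex:
    """Queryable Bloom filters of high-confidence k-mers and projections."""

    k: int
    threshold: int
    fpr: float
    seed_set: SeedSet
    kmer_filter: BloomFilter
    seed_filters: list[BloomFilter]
    _care: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self._care:
            self._care = [s.care_positions for s in self.seed_set]

    def has_kmer(self, window: str) -> bool:
        """Membership of a draft window's canonical form in the k-mer filter.

        Windows containing non-ACGT characters (N, gap placeholders)
        are always unsupported.
        """
        if len(window) != self.k:
            raise ValueError("window length must equal k")
        if not _is_valid(window):
            return False
        return canonical(window).encode() in self.kmer_filter

    def has_seed(self, seed_id: int, window: str) -> bool:
        """Spaced-seed membership of a window under seed ``seed_id``.

        The forward care projection and the projection of the reverse
        complement are both tried, so either read orientation is found.
        A care position landing on a non-ACGT character (including the
        gap wildcard used by the context encoder) fails the match.
        """
        if len(window) != self.k:
            raise ValueError("window length must equal k")
        care = self._care[seed_id]
        filt = self.seed_filters[seed_id]
        fwd = _projection(window, care)
        if fwd is not None and fwd.encode() in filt:
            return True
        rev = _projection(reverse_complement(window), care)
        return rev is not None and rev.encode() in filt


def build_index_from_counts(
    counts: Mapping[str, int],
    k: int,
    seed_set: SeedSet,
    threshold: int,
    fpr: float = DEFAULT_FPR,
) -> ConfidenceIndex:
    """Build the index from precomputed canonical k-mer counts."""
    if seed_set.k != k:
        raise ValueError("seed set k must match index k")
    if not 0.0 < fpr < 1.0:
        raise ValueError("fpr must be in (0,1)")
    high = [km for km, c in counts.items() if c >= threshold]
    if not high:
        log.warning("threshold %d exceeds every multiplicity; index is empty", threshold)
    kmer_filter = BloomFilter(len(high), fpr, salt=b"seedpolish-kmer")
    care_sets = [s.care_positions for s in seed_set]
    seed_filters = [
        BloomFilter(2 * len(high), fpr, salt=b"seedpolish-seed-%d" % j)
        for j in range(seed_set.n_seeds)
    ]
    for km in high:
        kmer_filter.add(km.encode())
        rc = reverse_complement(km)
        for j, care in enumerate(care_sets):
            pf = _projection(km, care)
            pr = _projection(rc, care)
            filt = seed_filters[j]
            if pf is not None:
                filt.add(pf.encode())
            if pr is not None:
                filt.add(pr.encode())
    return ConfidenceIndex(
        k=k,
        threshold=threshold,
        fpr=fpr,
        seed_set=seed_set,
        kmer_filter=kmer_filter,
        seed_filters=seed_filters,
    )


def build_index(
    reads: Iterable[str],
    k: int,
    seed_set: SeedSet,
    threshold: int,
    fpr: float = DEFAULT_FPR,
) -> ConfidenceIndex:
    """Count reads and build the high-confidence index in one step."""
    counts = count_kmer_multiplicities(reads, k)
    return build_index_from_counts(counts, k, seed_set, threshold, fpr)


class CachedIndex:
    """Memoizing view of a :class:`ConfidenceIndex`.

    Region processing queries the same windows repeatedly (encoding
    shifts, candidate assignments, jittered anchors); a per-region cache
    removes the redundant hashing.  Not thread-safe across regions —
    create one per region.
    """

    def __init__(self, index: ConfidenceIndex):
        self._index = index
        self.k = index.k
        self.threshold = index.threshold
        self.fpr = index.fpr
        self.seed_set = index.seed_set
        self._kmer_cache: dict[str, bool] = {}
        self._seed_cache: dict[tuple[int, str], bool] = {}

    def has_kmer(self, window: str) -> bool:
        hit = self._kmer_cache.get(window)
        if hit is None:
            hit = self._index.has_kmer(window)
            self._kmer_cache[window] = hit
        return hit

    def has_seed(self, seed_id: int, window: str) -> bool:
        key = (seed_id, window)
        hit = self._seed_cache.get(key)
        if hit is None:
            hit = self._index.has_seed(seed_id, window)
            self._seed_cache[key] = hit
        return hit


def has_kmer(index: ConfidenceIndex, window: str) -> bool:
    return index.has_kmer(window)


def has_seed(index: ConfidenceIndex, seed_id: int, window: str) -> bool:
    return index.has_seed(seed_id, window)
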