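"""Canonical k-mer counting.

k-mers are packed into int64 with 2 bits per base (limiting k to <= 31,
which covers the k = 20 anchor and k = 21 quality-value use cases; the
ChIP module uses its own string-based k = 50 extraction). A k-mer and its
reverse complement are collapsed onto the lexicographically smaller of the
two encodings ("canonical" form). Windows containing non-ACGT symbols are
skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .seq import decode_kmer, encode

MAX_K = 31


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement packed k-mers for every window.

    Returns (fwd, rc) int64 arrays of length len(codes) - k + 1 for the
    windows free of non-ACGT symbols; invalid windows are dropped.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rc = np.zeros(n, dtype=np.int64)
    comp = 3 - codes  # A<->T, C<->G; invalid 4 -> -1, caught by mask below
    for j in range(k):
        fwd = (fwd << 2) | codes[j : n + j]
        rc |= comp[j : n + j] << (2 * j)
    bad = codes == 4
    if bad.any():
        # a window is invalid if any of its k positions is invalid
        csum = np.concatenate(([0], np.cumsum(bad)))
        mask = (csum[k:] - csum[:-k]) == 0
        fwd, rc = fwd[mask], rc[mask]
    return fwd, rc


def canonical_codes(seq: str, k: int) -> np.ndarray:
    """Canonical packed k-mer per valid window (order preserved)."""
    fwd, rc = _kmer_codes(encode(seq), k)
    return np.minimum(fwd, rc)


def scan_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(positions, canonical codes, is_forward) for every valid window.

    is_forward is True where the forward-strand k-mer is the canonical one.
    """
    codes = encode(seq)
    n = codes.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0, dtype=bool),)
    fwd = np.zeros(n, dtype=np.int64)
    rc = np.zeros(n, dtype=np.int64)
    comp = 3 - codes
    for j in range(k):
        fwd = (fwd << 2) | codes[j : n + j]
        rc |= comp[j : n + j] << (2 * j)
    pos = np.arange(n, dtype=np.int64)
    bad = codes == 4
    if bad.any():
        csum = np.concatenate(([0], np.cumsum(bad)))
        mask = (csum[k:] - csum[:-k]) == 0
        fwd, rc, pos = fwd[mask], rc[mask], pos[mask]
    canon = np.minimum(fwd, rc)
    return pos, canon, fwd <= rc


@dataclass
class KmerCountTable:
    """Counts of canonical k-mers, stored as parallel sorted arrays."""

    k: int
    kmers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def total_kmers(self) -> int:
        return int(self.counts.sum())

    @property
    def n_distinct(self) -> int:
        return int(self.kmers.size)

    def count_of(self, kmer: str) -> int:
        """Occurrence count of one k-mer (canonicalized)."""
        code = canonical_codes(kmer, self.k)
        if code.size != 1:
            raise ValueError(f"expected a single {self.k}-mer, got {kmer!r}")
        i = np.searchsorted(self.kmers, code[0])
        if i < self.kmers.size and self.kmers[i] == code[0]:
            return int(self.counts[i])
        return 0

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Counts for an array of canonical codes (0 where absent)."""
        idx = np.searchsorted(self.kmers, codes)
        idx_c = np.clip(idx, 0, max(self.kmers.size - 1, 0))
        out = np.zeros(codes.size, dtype=np.int64)
        if self.kmers.size:
            hit = self.kmers[idx_c] == codes
            out[hit] = self.counts[idx_c[hit]]
        return out

    def to_dict(self) -> dict[str, int]:
        """Decode into {kmer string: count} (desk-scale tables only)."""
        return {decode_kmer(int(c), self.k): int(n) for c, n in zip(self.kmers, self.counts)}


def count_kmers(reads: Iterable[str], k: int) -> KmerCountTable:
    """Count canonical k-mers over a read set.

    Equivalent to exhaustive window enumeration with canonicalization,
    skipping windows that contain non-ACGT symbols. Reads shorter than k
    contribute nothing; if every read is shorter than k an empty table is
    returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K} for packed counting")
    chunks = []
    any_read = False
    any_long_enough = False
    for read in reads:
        any_read = True
        if len(read) >= k:
            any_long_enough = True
        codes = canonical_codes(read, k)
        if codes.size:
            chunks.append(codes)
    if not any_read:
        raise ValueError("read set is empty")
    if not chunks:
        if not any_long_enough:
            warnings.warn(f"no read reached length k={k}; returning empty table")
        return KmerCountTable(k=k)
    allk = np.concatenate(chunks)
    uniq, counts = np.unique(allk, return_counts=True)
    return KmerCountTable(k=k, kmers=uniq, counts=counts)
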