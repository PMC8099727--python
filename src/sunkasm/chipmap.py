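"""k-mer placement of ChIP reads into repeat arrays, and read mappability.

Short-read alignment inside a near-identical satellite array is dominated
by mapper heuristics, so enrichment (e.g. CENP-A ChIP) is instead scored
at the k-mer level: every k-mer (default k = 50) from the read data is
placed once, uniformly at random, among all positions in the target
array with a perfect match (either strand). Placements are summarized in
a fixed-bin coverage histogram. A companion simulation measures raw
short-read mappability by counting exact-match sites of random fragments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .seq import revcomp

CHIP_K = 50


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def extract_read_kmers(reads: list[str], k: int = CHIP_K) -> Counter:
    """Canonical k-mer multiset over a read set (N windows skipped).

    Counts are per occurrence: duplicate reads double their k-mers.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if "N" in w:
                continue
            counts[_canonical(w)] += 1
    return counts


def _site_index(target: str, k: int) -> dict[str, list[int]]:
    """Canonical k-mer -> sorted forward-strand match positions."""
    sites: dict[str, list[int]] = {}
    target = target.upper()
    for i in range(len(target) - k + 1):
        w = target[i : i + k]
        if "N" in w:
            continue
        sites.setdefault(_canonical(w), []).append(i)
    return sites


@dataclass
class KmerPlacement:
    kmer: str
    n_sites: int
    chosen_site: int  # -1 when unplaced


@dataclass
class PlacementResult:
    placements: list[KmerPlacement]
    placed: int
    unplaced: int

    @property
    def total(self) -> int:
        return self.placed + self.unplaced

    @property
    def placed_fraction(self) -> float:
        return self.placed / self.total if self.total else float("nan")


def place_kmers(kmers: Counter, target: str, seed: int = 0, k: int | None = None) -> PlacementResult:
    """Place each k-mer occurrence uniformly at random among its sites.

    Sites are perfect matches on either strand of the target (canonical
    matching). Each occurrence draws independently; k-mers with no site
    are counted unplaced. Deterministic under the seed.
    """
    if not target:
        raise ValueError("target is empty")
    if not kmers:
        return PlacementResult([], 0, 0)
    if k is None:
        k = len(next(iter(kmers)))
    sites = _site_index(target, k)
    rng = np.random.default_rng(seed)
    placements: list[KmerPlacement] = []
    placed = unplaced = 0
    for kmer, n_occ in kmers.items():
        canon = _canonical(kmer.upper())
        pos = sites.get(canon)
        if not pos:
            unplaced += n_occ
            placements.extend(KmerPlacement(canon, 0, -1) for _ in range(n_occ))
            continue
        if len(pos) == 1:
            placed += n_occ
            placements.extend(KmerPlacement(canon, 1, pos[0]) for _ in range(n_occ))
            continue
        draws = rng.integers(0, len(pos), size=n_occ)
        placed += n_occ
        placements.extend(KmerPlacement(canon, len(pos), pos[int(d)]) for d in draws)
    return PlacementResult(placements, placed, unplaced)


@dataclass
class CoverageHistogram:
    bin_size: int
    counts: np.ndarray  # placed k-mers per bin

    @property
    def n_placed(self) -> int:
        return int(self.counts.sum())

    def argmax_bin(self) -> tuple[int, int]:
        """(start, end) of the most-covered bin."""
        b = int(self.counts.argmax())
        return b * self.bin_size, (b + 1) * self.bin_size


def coverage_histogram(
    result: PlacementResult, target_length: int, bin_size: int = 1000
) -> CoverageHistogram:
    """Histogram of placement positions in fixed bins (default 1 kb)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = max(1, -(-target_length // bin_size))
    counts = np.zeros(n_bins, dtype=np.int64)
    for p in result.placements:
        if p.chosen_site >= 0:
            counts[p.chosen_site // bin_size] += 1
    return CoverageHistogram(bin_size=bin_size, counts=counts)


@dataclass
class MappabilitySummary:
    n_fragments: int
    unique_fraction: float
    multi_fraction: float
    unmapped_fraction: float
    multiplicities: np.ndarray = field(repr=False, default=None)


def simulate_mappability(
    target: str,
    regions: list[tuple[int, int]],
    fragment_length: int = 150,
    n_fragments: int = 10_000,
    seed: int = 0,
) -> MappabilitySummary:
    """Exact-match multiplicity of random fragments drawn from regions.

    Fragments are sampled uniformly from the given regions of the target;
    each is looked up for perfect matches anywhere in the target (both
    strands). The summary reports the fraction of fragments with exactly
    one site (unique), several sites (multi) or none (possible only if a
    region contains N's).
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    for s, e in regions:
        if not (0 <= s < e <= len(target)):
            raise ValueError(f"region ({s}, {e}) outside target")
        if e - s < fragment_length:
            raise ValueError("fragment_length exceeds a region length")
    sites = _site_index(target, fragment_length)
    rng = np.random.default_rng(seed)
    region_arr = np.array(regions)
    weights = (region_arr[:, 1] - region_arr[:, 0] - fragment_length + 1).astype(float)
    weights /= weights.sum()
    mult = np.zeros(n_fragments, dtype=np.int64)
    target_u = target.upper()
    for i in range(n_fragments):
        ri = rng.choice(len(regions), p=weights)
        s, e = regions[ri]
        start = int(rng.integers(s, e - fragment_length + 1))
        frag = target_u[start : start + fragment_length]
        if "N" in frag:
            mult[i] = 0
            continue
        mult[i] = len(sites.get(_canonical(frag), ()))
    return MappabilitySummary(
        n_fragments=n_fragments,
        unique_fraction=float((mult == 1).mean()),
        multi_fraction=float((mult > 1).mean()),
        unmapped_fraction=float((mult == 0).mean()),
        multiplicities=mult,
    )
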