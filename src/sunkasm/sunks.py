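"""Singly unique nucleotide k-mer (SUNK) library construction.

A SUNK is a k-mer (default k = 20) that occurs approximately once per
haploid genome. Candidates are selected from accurate long-read k-mer
counts by keeping k-mers whose multiplicity falls inside a band around the
modal multiplicity (the single-copy coverage peak), then validated for
presence in an orthogonal short-read k-mer table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kmers import KmerCountTable, count_kmers  # noqa: F401  (re-export)
from .seq import decode_kmer


@dataclass
class SunkParams:
    """Selection and validation parameters.

    coverage_band multiplies the modal k-mer multiplicity m: k-mers with
    count in [low * m, high * m] are kept as single-copy candidates.
    """

    k: int = 20
    coverage_band: tuple[float, float] = (0.5, 1.5)
    validation_min_count: int = 1

    def __post_init__(self):
        low, high = self.coverage_band
        if not (0 < low < high):
            raise ValueError("coverage band must satisfy 0 < low < high")
        if self.validation_min_count < 0:
            raise ValueError("validation_min_count must be >= 0")


@dataclass
class SunkSet:
    """Validated SUNKs as a sorted array of canonical packed k-mers.

    The index of a k-mer in `kmers` serves as its sunk_id. Membership is
    strand-canonical: a k-mer and its reverse complement are one member.
    """

    k: int
    kmers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.kmers.size)

    def find(self, codes: np.ndarray) -> np.ndarray:
        """sunk_id per canonical code, -1 where not a member."""
        idx = np.searchsorted(self.kmers, codes)
        idx_c = np.clip(idx, 0, max(self.kmers.size - 1, 0))
        out = np.full(codes.size, -1, dtype=np.int64)
        if self.kmers.size:
            hit = self.kmers[idx_c] == codes
            out[hit] = idx_c[hit]
        return out

    def to_tsv(self, path: str | Path, table: KmerCountTable | None = None) -> None:
        """Write (kmer, count) TSV plus a JSON sidecar of parameters."""
        path = Path(path)
        counts = table.lookup(self.kmers) if table is not None else np.ones(len(self), dtype=int)
        with open(path, "w") as fh:
            for code, cnt in zip(self.kmers, counts):
                fh.write(f"{decode_kmer(int(code), self.k)}\t{int(cnt)}\n")
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump({"k": self.k, **self.provenance}, fh, indent=2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SunkSet":
        from .kmers import canonical_codes

        codes = []
        k = None
        with open(path) as fh:
            for line in fh:
                kmer = line.split("\t")[0].strip()
                if not kmer:
                    continue
                if k is None:
                    k = len(kmer)
                codes.append(int(canonical_codes(kmer, k)[0]))
        if k is None:
            raise ValueError(f"no k-mers in {path}")
        return cls(k=k, kmers=np.unique(np.array(codes, dtype=np.int64)))


def modal_count(table: KmerCountTable) -> int:
    """Location of the single-copy coverage peak of the count histogram.

    When mean multiplicity exceeds 5 the count-1 bin is excluded: at real
    coverage it is dominated by read errors, each of which spawns up to k
    novel k-mers. The peak is located in two passes: the median of the
    remaining counts (robust against multi-copy contamination, unlike the
    raw histogram argmax, which lands unpredictably on spurs of the lumpy
    per-count histogram), refined to the mean of the counts within ±50%
    of that median (the median of a skewed discrete peak is biased by up
    to a full count, which matters because the selection band scales off
    this value).
    """
    if table.n_distinct == 0:
        raise ValueError("empty k-mer table")
    counts = table.counts
    if counts.mean() > 5 and (counts >= 2).any():
        counts = counts[counts >= 2]
    med = float(np.median(counts))
    core = counts[(counts >= 0.5 * med) & (counts <= 1.5 * med)]
    if core.size == 0:
        return int(round(med))
    return int(round(float(core.mean())))


def select_sunks(table: KmerCountTable, params: SunkParams | None = None) -> SunkSet:
    """Select single-copy candidate k-mers from a long-read count table.

    Keeps k-mers with count in [low * m, high * m] where m is the modal
    multiplicity. An empty table yields an empty set; a table whose counts
    are all 1 at high apparent coverage triggers a warning (error-dominated
    input).
    """
    params = params or SunkParams(k=table.k)
    if params.k != table.k:
        raise ValueError(f"params.k={params.k} does not match table.k={table.k}")
    if table.n_distinct == 0:
        return SunkSet(k=table.k, provenance={"selected_from": 0})
    m = modal_count(table)
    if m == 1 and (table.counts == 1).all() and table.total_kmers > 5 * table.n_distinct:
        warnings.warn("count table looks error-dominated (all counts 1 at high coverage)")
    low, high = params.coverage_band
    keep = (table.counts >= low * m) & (table.counts <= high * m)
    return SunkSet(
        k=table.k,
        kmers=table.kmers[keep].copy(),
        provenance={
            "modal_count": m,
            "coverage_band": list(params.coverage_band),
            "selected_from": table.n_distinct,
            "selected": int(keep.sum()),
        },
    )


def validate_sunks(
    sunks: SunkSet,
    short_read_table: KmerCountTable,
    min_count: int | None = None,
) -> SunkSet:
    """Retain SUNKs supported by an orthogonal short-read k-mer table.

    A SUNK is kept iff its count in the short-read table is at least
    `min_count` (default 1 or the value stored in provenance). The retained
    fraction is recorded in the provenance (None for an empty input set).
    """
    if sunks.k != short_read_table.k:
        raise ValueError(f"k mismatch: sunks.k={sunks.k}, table.k={short_read_table.k}")
    if min_count is None:
        min_count = int(sunks.provenance.get("validation_min_count", 1))
    if len(sunks) == 0:
        return SunkSet(k=sunks.k, provenance={**sunks.provenance, "retained_fraction": None})
    counts = short_read_table.lookup(sunks.kmers)
    keep = counts >= min_count
    retained = float(keep.mean())
    return SunkSet(
        k=sunks.k,
        kmers=sunks.kmers[keep].copy(),
        provenance={
            **sunks.provenance,
            "validation_min_count": min_count,
            "retained_fraction": retained,
        },
    )
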