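"""Phred-scaled assembly quality values (QV).

Two estimators are provided. The k-mer estimator converts the fraction of
assembly k-mers unsupported by an orthogonal read set into a per-base
error probability,

    QV = -10 * log10(1 - (1 - E/T)^(1/k)),

where E is the number of assembly-only k-mers, T the total assembly
k-mers, and k the k-mer size (default 21). The alignment estimator counts
differences in an =/X-resolved alignment,

    QV = -10 * log10(1 - matches / (matches + mismatches + ins + del)).

Both use base-10 logarithms. An error-free input has no finite QV and is
reported with an unbounded marker (qv = inf, accuracy = 100).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass


@dataclass
class KmerQVInput:
    error_kmers: int
    total_kmers: int
    k: int = 21

    def __post_init__(self):
        if self.total_kmers < 1:
            raise ValueError("total_kmers must be >= 1")
        if not (0 <= self.error_kmers <= self.total_kmers):
            raise ValueError("error_kmers must be in [0, total_kmers]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class AlignmentTally:
    matches: int = 0
    mismatches: int = 0
    insertions: int = 0
    deletions: int = 0

    def __post_init__(self):
        if min(self.matches, self.mismatches, self.insertions, self.deletions) < 0:
            raise ValueError("tally entries must be non-negative")

    @property
    def total(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions


@dataclass
class QVResult:
    qv: float  # math.inf marks an unbounded (error-free) estimate
    accuracy_percent: float

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.qv)

    def rounded(self, ndigits: int = 2) -> float:
        """QV at presentation precision (round-half-even)."""
        return round(self.qv, ndigits)


def qv_to_accuracy(qv: float) -> float:
    """Percent accuracy implied by a Phred QV; unbounded -> exactly 100."""
    if qv < 0:
        raise ValueError("qv must be >= 0")
    if math.isinf(qv):
        return 100.0
    return 100.0 - 10.0 ** (qv / -10.0) * 100.0


def kmer_qv(inp: KmerQVInput) -> QVResult:
    """QV from assembly-only k-mer counts (see module docstring)."""
    if inp.error_kmers == 0:
        return QVResult(qv=math.inf, accuracy_percent=100.0)
    base_err = 1.0 - (1.0 - inp.error_kmers / inp.total_kmers) ** (1.0 / inp.k)
    qv = -10.0 * math.log10(base_err)
    return QVResult(qv=qv, accuracy_percent=qv_to_accuracy(qv))


def alignment_qv(tally: AlignmentTally) -> QVResult:
    """QV from alignment difference counts (see module docstring)."""
    if tally.total == 0:
        raise ValueError("alignment tally is empty")
    if tally.matches + tally.mismatches < 1:
        raise ValueError("tally must contain at least one aligned base")
    err = 1.0 - tally.matches / tally.total
    if err == 0.0:
        return QVResult(qv=math.inf, accuracy_percent=100.0)
    qv = -10.0 * math.log10(err)
    return QVResult(qv=qv, accuracy_percent=qv_to_accuracy(qv))


_CIGAR_RE = re.compile(r"(\d+)([=XIDMSH])")


def tally_from_alignment(cigar: str) -> AlignmentTally:
    """Sum an =/X-resolved CIGAR string into an AlignmentTally.

    Plain 'M' (match-or-mismatch) is rejected because it hides the
    difference counts the estimator needs; re-align with an =/X-emitting
    mode. Soft/hard clips are ignored.
    """
    consumed = _CIGAR_RE.sub("", cigar)
    if consumed.strip():
        raise ValueError(f"unparseable CIGAR fragment: {consumed!r}")
    t = AlignmentTally()
    for length, op in _CIGAR_RE.findall(cigar):
        n = int(length)
        if op == "=":
            t.matches += n
        elif op == "X":
            t.mismatches += n
        elif op == "I":
            t.insertions += n
        elif op == "D":
            t.deletions += n
        elif op == "M":
            raise ValueError(
                "CIGAR contains 'M' (match-or-mismatch); use an =/X-resolved alignment"
            )
        # S/H clips carry no alignment information
    return t
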