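"""All-vs-all window identity tables and decile-binned heat maps.

A sequence (typically a satellite array assembly) is cut into consecutive
5-kb windows; every unordered pair of windows is globally aligned in both
orientations and scored as

    identity = 100 * matches / (matches + mismatches + ins + del)

of the better orientation. Sorting the records by identity and splitting
them into 10 equal-count bins gives the decile structure that, plotted as
a raster, reveals the evolutionary layers of the array: pairs within a
young layer land in the top bins, cross-layer pairs lower down.

Alignment is unit-cost global (edit distance) via edlib; identity is
counted per base from the extended CIGAR.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .qv import tally_from_alignment
from .seq import revcomp

DEFAULT_WINDOW = 5000
IDENTITY_FLOOR = 70.0  # pairs below this are reported unaligned


@dataclass
class WindowFragment:
    source_id: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IdentityRecord:
    fragment_i: int  # index into the fragment list
    fragment_j: int
    identity: float  # percent, in [0, 100]
    aligned: bool
    orientation: str = "+"  # orientation of the better alignment


@dataclass
class HeatmapMatrix:
    fragments: list[WindowFragment]
    records: list[IdentityRecord]
    bin_edges: list[float] = field(default_factory=list)
    bin_assignment: dict[tuple[int, int], int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            fi, fj = self.fragments[r.fragment_i], self.fragments[r.fragment_j]
            rows.append(
                (
                    fi.start,
                    fi.end,
                    fj.start,
                    fj.end,
                    r.identity,
                    r.aligned,
                    self.bin_assignment.get((r.fragment_i, r.fragment_j), -1),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["frag_i_start", "frag_i_end", "frag_j_start", "frag_j_end", "identity", "aligned", "bin"],
        )


def fragment_sequence(
    seq: str, window_size: int = DEFAULT_WINDOW, source_id: str = "seq"
) -> list[WindowFragment]:
    """Cut a sequence into consecutive non-overlapping windows.

    A final partial window shorter than window_size/2 is merged into the
    previous window (so the last fragment may be up to 1.5 windows long);
    at least window_size/2 it is kept as its own fragment.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not seq:
        return []
    starts = list(range(0, len(seq), window_size))
    frags = [WindowFragment(source_id, s, min(s + window_size, len(seq)), seq[s : s + window_size]) for s in starts]
    if len(frags) > 1 and frags[-1].length < window_size / 2:
        last = frags.pop()
        prev = frags[-1]
        frags[-1] = WindowFragment(source_id, prev.start, last.end, prev.sequence + last.sequence)
    return frags


def _identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="path")
    t = tally_from_alignment(res["cigar"])
    return 100.0 * t.matches / t.total


def pairwise_identity(
    fragments: list[WindowFragment],
    identity_floor: float = IDENTITY_FLOOR,
) -> list[IdentityRecord]:
    """Global identity for every unordered fragment pair, both orientations.

    Each pair is computed once and is symmetric by construction. Pairs
    whose best-orientation identity falls below the floor are emitted with
    aligned=False (standing in for mapper alignment failure on divergent
    window pairs).
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments")
    rc_cache = {j: revcomp(f.sequence) for j, f in enumerate(fragments)}
    records = []
    for i, j in itertools.combinations(range(len(fragments)), 2):
        fwd = _identity(fragments[i].sequence, fragments[j].sequence)
        rev = _identity(fragments[i].sequence, rc_cache[j])
        ident, orient = (fwd, "+") if fwd >= rev else (rev, "-")
        records.append(IdentityRecord(i, j, ident, aligned=ident >= identity_floor, orientation=orient))
    return records


def bin_identities(
    fragments: list[WindowFragment],
    records: list[IdentityRecord],
    n_bins: int = 10,
) -> HeatmapMatrix:
    """Assign aligned records to equal-count identity bins.

    Records are sorted by (identity, fragment indices) for determinism and
    split into n_bins contiguous groups; when the count does not divide
    evenly the remainder goes to the lowest-identity bins. Bin index is
    monotone in identity (bin n_bins-1 = most identical). Fewer than
    n_bins aligned records collapse into a single bin with a warning.
    """
    aligned = [r for r in records if r.aligned]
    matrix = HeatmapMatrix(fragments=fragments, records=records)
    if not aligned:
        return matrix
    order = sorted(aligned, key=lambda r: (r.identity, r.fragment_i, r.fragment_j))
    if len(order) < n_bins:
        warnings.warn(f"only {len(order)} aligned records; using a single bin")
        for r in order:
            matrix.bin_assignment[(r.fragment_i, r.fragment_j)] = 0
        matrix.bin_edges = [order[0].identity, order[-1].identity]
        return matrix
    n = len(order)
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]  # remainder to low bins
    edges = [order[0].identity]
    idx = 0
    for b, size in enumerate(sizes):
        for _ in range(size):
            r = order[idx]
            matrix.bin_assignment[(r.fragment_i, r.fragment_j)] = b
            idx += 1
        edges.append(order[idx - 1].identity)
    matrix.bin_edges = edges
    return matrix


def identity_heatmap(
    seq: str,
    window_size: int = DEFAULT_WINDOW,
    identity_floor: float = IDENTITY_FLOOR,
) -> HeatmapMatrix:
    """fragment -> all-vs-all identity -> decile binning, in one call."""
    frags = fragment_sequence(seq, window_size)
    records = pairwise_identity(frags, identity_floor)
    return bin_identities(frags, records)


def within_layer_identity(
    matrix: HeatmapMatrix, layer_intervals: pd.DataFrame
) -> pd.DataFrame:
    """Median within-layer identity per layer, from truth layer intervals.

    A record contributes to a layer when both fragments lie entirely
    inside blocks of that layer. Returns columns (layer, median_identity,
    n_pairs), sorted by layer id.
    """

    def layer_of(frag: WindowFragment):
        hits = layer_intervals[(layer_intervals.start <= frag.start) & (layer_intervals.end >= frag.end)]
        if len(hits) == 1:
            return hits.layer.iloc[0]
        return None

    frag_layer = [layer_of(f) for f in matrix.fragments]
    per_layer: dict = {}
    for r in matrix.records:
        li, lj = frag_layer[r.fragment_i], frag_layer[r.fragment_j]
        if li is not None and li == lj and li != "flank":
            per_layer.setdefault(li, []).append(r.identity)
    rows = [(layer, float(np.median(v)), len(v)) for layer, v in sorted(per_layer.items(), key=lambda kv: str(kv[0]))]
    return pd.DataFrame(rows, columns=["layer", "median_identity", "n_pairs"])
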