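"""SUNK-anchored targeted assembly of repeat-spanning scaffolds.

Noisy ultra-long reads are barcoded with exact matches to a validated
SUNK library. Two reads sharing enough SUNKs are inspected for mutual
distance consistency: a shared SUNK is *valid* when its pairwise
distances to enough other shared SUNKs agree between the two reads
(within a fraction of the read length), which separates genuine
positional anchors from spurious matches created by sequencing error.
Offset-consistent reads are merged into tiles, tiles are extended with
pool reads until the target's flanking anchor sequences are contained,
and the noisy scaffold bases are finally replaced by high-accuracy
contigs placed via colinear SUNK anchor chains.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy import sparse

from .seq import revcomp
from .kmers import scan_positions
from .sunks import SunkSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# barcoding


@dataclass
class BarcodedRead:
    """A read with its ordered SUNK anchors.

    positions are 0-based k-mer start offsets on the read as given (no
    orientation applied); is_forward marks anchors whose forward-strand
    k-mer equals the canonical member.
    """

    read_id: str
    sequence: str
    k: int
    positions: np.ndarray  # int64, strictly increasing
    sunk_ids: np.ndarray  # int64, index into the SunkSet
    is_forward: np.ndarray  # bool

    @property
    def read_length(self) -> int:
        return len(self.sequence)

    @property
    def n_anchors(self) -> int:
        return int(self.positions.size)

    def unique_anchor_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sunk_ids, positions, is_forward) restricted to SUNKs occurring
        exactly once on this read, sorted by sunk_id."""
        order = np.argsort(self.sunk_ids, kind="stable")
        sid = self.sunk_ids[order]
        dup = np.zeros(sid.size, dtype=bool)
        dup[1:] = sid[1:] == sid[:-1]
        # drop every occurrence of a duplicated sunk
        keep = ~np.isin(sid, np.unique(sid[dup]))
        return sid[keep], self.positions[order][keep], self.is_forward[order][keep]


def barcode_read(read_id: str, sequence: str, sunks: SunkSet) -> BarcodedRead:
    """Anchor a read on every exact canonical match to the SUNK set."""
    pos, canon, fwd = scan_positions(sequence, sunks.k)
    ids = sunks.find(canon)
    hit = ids >= 0
    return BarcodedRead(
        read_id=read_id,
        sequence=sequence,
        k=sunks.k,
        positions=pos[hit],
        sunk_ids=ids[hit],
        is_forward=fwd[hit],
    )


# ---------------------------------------------------------------------------
# pair validation


@dataclass
class PairThresholds:
    min_shared_sunks: int = 50
    min_support_partners: int = 10
    min_valid_sunks: int = 3
    distance_tolerance_fraction: float = 0.01

    def __post_init__(self):
        if min(self.min_shared_sunks, self.min_support_partners, self.min_valid_sunks) < 1:
            raise ValueError("thresholds must be positive")
        if not (0 < self.distance_tolerance_fraction < 0.5):
            raise ValueError("distance tolerance must be in (0, 0.5)")


@dataclass
class ReadPairSupport:
    read_a: int  # indices into the read list
    read_b: int
    shared_sunk_count: int
    orientation: str  # "same" or "flipped"
    offset_estimate: int  # median(pos_a - oriented pos_b) over valid SUNKs
    valid_sunk_ids: np.ndarray
    valid_pos_a: np.ndarray  # own-frame positions on read a
    valid_pos_b: np.ndarray  # own-frame positions on read b

    @property
    def n_valid(self) -> int:
        return int(self.valid_sunk_ids.size)


def find_candidate_pairs(
    reads: list[BarcodedRead], thresholds: PairThresholds | None = None
) -> list[tuple[int, int, int]]:
    """Unordered read pairs sharing at least min_shared_sunks distinct SUNKs.

    Only SUNKs occurring exactly once on a read contribute. Returns
    (index_a, index_b, shared_count) triples with index_a < index_b.
    """
    thresholds = thresholds or PairThresholds()
    if len(reads) < 2:
        return []
    rows, cols = [], []
    for i, r in enumerate(reads):
        sid, _, _ = r.unique_anchor_arrays()
        rows.append(np.full(sid.size, i, dtype=np.int64))
        cols.append(sid)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    if cols.size == 0:
        return []
    # reindex sunk ids densely
    uniq, dense = np.unique(cols, return_inverse=True)
    m = sparse.csr_matrix(
        (np.ones(rows.size, dtype=np.int32), (rows, dense)),
        shape=(len(reads), uniq.size),
    )
    shared = (m @ m.T).tocoo()
    pairs = []
    for i, j, c in zip(shared.row, shared.col, shared.data):
        if i < j and c >= thresholds.min_shared_sunks:
            pairs.append((int(i), int(j), int(c)))
    pairs.sort()
    return pairs


def _delta_clusters(
    deltas: np.ndarray, tol: float, min_partners: int
) -> tuple[np.ndarray, int, int]:
    """Offset-agreement analysis of the shared-SUNK deltas.

    Returns (valid mask, dominant cluster size, second cluster size).
    The dominant cluster is centred on the delta with the most neighbours
    within ±tol; a SUNK is valid when it belongs to that cluster and
    agrees with >= min_partners other shared SUNKs. The second cluster is
    the best-supported delta further than 3*tol from the dominant centre
    — near-identical tandem repeats plus read error produce spurious
    anchor sets whose deltas pile up at multiples of the repeat unit, and
    a strong secondary cluster is the signature of that failure mode.
    """
    if deltas.size == 0:
        return np.zeros(0, dtype=bool), 0, 0
    order = np.argsort(deltas)
    ds = deltas[order]
    lo = np.searchsorted(ds, ds - tol, side="left")
    hi = np.searchsorted(ds, ds + tol, side="right")
    neighbours = hi - lo  # including self
    centre = ds[int(neighbours.argmax())]
    dominant = int(neighbours.max())
    in_cluster = np.abs(ds - centre) <= tol
    far = np.abs(ds - centre) > 3 * tol
    second = int(neighbours[far].max()) if far.any() else 0
    partners = neighbours - 1
    mask = np.zeros(deltas.size, dtype=bool)
    mask[order] = in_cluster & (partners >= min_partners)
    return mask, dominant, second


def validate_pair(
    read_a: BarcodedRead,
    read_b: BarcodedRead,
    thresholds: PairThresholds | None = None,
    shared_count: int | None = None,
) -> ReadPairSupport | None:
    """Distance-consistency validation of a candidate pair.

    Both orientations are evaluated (anchors split by strand agreement);
    the orientation with more valid SUNKs is kept. The pair is rejected
    (None) when no orientation reaches min_valid_sunks, when both do
    (unresolvable dual-orientation support), or when an orientation's
    second-best offset cluster holds at least half as many SUNKs as its
    dominant one (the lattice signature of spurious cross-repeat anchor
    matches; a genuine overlap concentrates essentially all agreement in
    one cluster). The offset estimate is the median anchor-position
    difference over the dominant cluster, with read b's positions
    mirrored for a flipped pair.
    """
    thresholds = thresholds or PairThresholds()
    sid_a, pos_a, fwd_a = read_a.unique_anchor_arrays()
    sid_b, pos_b, fwd_b = read_b.unique_anchor_arrays()
    common, ia, ib = np.intersect1d(sid_a, sid_b, return_indices=True)
    if shared_count is None:
        shared_count = int(common.size)
    if common.size < thresholds.min_valid_sunks:
        return None
    pa, pb = pos_a[ia], pos_b[ib]
    fa, fb = fwd_a[ia], fwd_b[ib]
    tol = thresholds.distance_tolerance_fraction * min(read_a.read_length, read_b.read_length)

    results = {}
    for orientation in ("same", "flipped"):
        if orientation == "same":
            sel = fa == fb
            deltas = pa[sel] - pb[sel]
        else:
            sel = fa != fb
            mirrored = read_b.read_length - read_b.k - pb[sel]
            deltas = pa[sel] - mirrored
        mask, dominant, second = _delta_clusters(
            deltas.astype(np.float64), tol, thresholds.min_support_partners
        )
        unimodal = second < 0.5 * dominant
        if not unimodal and dominant >= thresholds.min_valid_sunks:
            logger.info(
                "pair (%s, %s) %s orientation rejected: multimodal offset support (%d vs %d)",
                read_a.read_id, read_b.read_id, orientation, dominant, second,
            )
        results[orientation] = (sel, mask if unimodal else np.zeros_like(mask), deltas)

    n_same = int(results["same"][1].sum())
    n_flip = int(results["flipped"][1].sum())
    ok_same = n_same >= thresholds.min_valid_sunks
    ok_flip = n_flip >= thresholds.min_valid_sunks
    if ok_same and ok_flip:
        logger.info(
            "pair (%s, %s) rejected: ambiguous dual-orientation support (%d same, %d flipped)",
            read_a.read_id, read_b.read_id, n_same, n_flip,
        )
        return None
    if not (ok_same or ok_flip):
        return None
    orientation = "same" if ok_same else "flipped"
    sel, mask, deltas = results[orientation]
    offset = int(round(float(np.median(deltas[mask]))))
    return ReadPairSupport(
        read_a=-1,  # indices are attached by the caller when known
        read_b=-1,
        shared_sunk_count=shared_count,
        orientation=orientation,
        offset_estimate=offset,
        valid_sunk_ids=common[sel][mask],
        valid_pos_a=pa[sel][mask],
        valid_pos_b=pb[sel][mask],
    )


def validate_pairs(
    reads: list[BarcodedRead],
    candidates: list[tuple[int, int, int]],
    thresholds: PairThresholds | None = None,
) -> list[ReadPairSupport]:
    """validate_pair over candidate triples, attaching read indices."""
    thresholds = thresholds or PairThresholds()
    supports = []
    for i, j, c in candidates:
        s = validate_pair(reads[i], reads[j], thresholds, shared_count=c)
        if s is not None:
            s.read_a, s.read_b = i, j
            supports.append(s)
    return supports


# ---------------------------------------------------------------------------
# tiles


@dataclass
class TileMember:
    read_index: int
    orientation: str  # "F" or "R" relative to the tile
    offset: int  # tile coordinate of the read's left end (oriented)
    support: int  # total valid SUNKs over accepted pairs


@dataclass
class Tile:
    members: list[TileMember]
    sequence: str
    backbone: list[tuple[int, int, int]] = field(default_factory=list)
    # backbone: (read_index, start, end) slices of oriented read sequence

    @property
    def span(self) -> int:
        return len(self.sequence)


def _oriented_anchor_pos(pos: np.ndarray, length: int, k: int, orientation: str) -> np.ndarray:
    return pos if orientation == "F" else length - k - pos


def _layout_component(
    reads: list[BarcodedRead],
    nodes: list[int],
    edges: dict[tuple[int, int], ReadPairSupport],
    tol_frac: float,
) -> tuple[dict[int, tuple[str, int]], dict[tuple[int, int], float], dict[int, int]]:
    """Orient and offset reads along a maximum-support spanning tree.

    Returns ({read: (orientation, offset)}, {edge: worst residual},
    {read: support}).
    """
    support = {n: 0 for n in nodes}
    adj: dict[int, list[tuple[int, int]]] = {n: [] for n in nodes}
    for (i, j), s in edges.items():
        support[i] += s.n_valid
        support[j] += s.n_valid
        adj[i].append((j, s.n_valid))
        adj[j].append((i, s.n_valid))
    root = max(nodes, key=lambda n: support[n])
    placed: dict[int, tuple[str, int]] = {root: ("F", 0)}
    # Prim-style maximum spanning tree traversal
    import heapq

    heap = [(-w, root, nbr) for nbr, w in adj[root]]
    heapq.heapify(heap)
    while heap:
        negw, src, dst = heapq.heappop(heap)
        if dst in placed or src not in placed:
            continue
        key = (src, dst) if (src, dst) in edges else (dst, src)
        s = edges[key]
        a, b = key
        ra, rb = reads[a], reads[b]
        ori_a, off_a = placed.get(a, (None, None))
        ori_b, off_b = placed.get(b, (None, None))
        flip = s.orientation == "flipped"
        if ori_a is not None:
            ori_new = ("R" if ori_a == "F" else "F") if flip else ori_a
            ta = off_a + _oriented_anchor_pos(s.valid_pos_a, ra.read_length, ra.k, ori_a)
            tb = _oriented_anchor_pos(s.valid_pos_b, rb.read_length, rb.k, ori_new)
            placed[b] = (ori_new, int(round(float(np.median(ta - tb)))))
        else:
            ori_new = ("R" if ori_b == "F" else "F") if flip else ori_b
            tb = off_b + _oriented_anchor_pos(s.valid_pos_b, rb.read_length, rb.k, ori_b)
            ta = _oriented_anchor_pos(s.valid_pos_a, ra.read_length, ra.k, ori_new)
            placed[a] = (ori_new, int(round(float(np.median(tb - ta)))))
        for nbr, w in adj[dst]:
            if nbr not in placed:
                heapq.heappush(heap, (-w, dst, nbr))

    residuals: dict[tuple[int, int], float] = {}
    for (i, j), s in edges.items():
        if i not in placed or j not in placed:
            continue
        ri, rj = reads[i], reads[j]
        (oi, offi), (oj, offj) = placed[i], placed[j]
        flip = s.orientation == "flipped"
        consistent = (oi != oj) == flip
        if not consistent:
            residuals[(i, j)] = float("inf")
            continue
        ti = offi + _oriented_anchor_pos(s.valid_pos_a, ri.read_length, ri.k, oi)
        tj = offj + _oriented_anchor_pos(s.valid_pos_b, rj.read_length, rj.k, oj)
        residuals[(i, j)] = float(np.median(np.abs(ti - tj)))
    return placed, residuals, support


def assemble_tile(
    reads: list[BarcodedRead],
    supports: list[ReadPairSupport],
    thresholds: PairThresholds | None = None,
) -> list[Tile]:
    """Merge offset-consistent reads into tiles.

    Reads are grouped by single linkage over accepted pairs; within a
    group, orientations and offsets propagate along a maximum-support
    spanning tree. A pair whose two reads end up placed inconsistently
    (residual beyond the distance tolerance) is first treated as a
    spurious edge and dropped when its valid-SUNK support is under half
    of the best support at either endpoint; violations that survive this
    filter indicate a genuinely misplaced read (a chimera signature), and
    the worst offender is evicted before the layout is rebuilt. Reads
    with no accepted pair become singleton tiles.
    """
    thresholds = thresholds or PairThresholds()
    tol_frac = thresholds.distance_tolerance_fraction
    edges_all: dict[tuple[int, int], ReadPairSupport] = {}
    for s in supports:
        edges_all[(min(s.read_a, s.read_b), max(s.read_a, s.read_b))] = s

    # connected components
    parent = list(range(len(reads)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges_all:
        parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(len(reads)):
        comps.setdefault(find(i), []).append(i)

    tiles: list[Tile] = []
    dropped: set[tuple[int, int]] = set()
    for nodes in comps.values():
        active = set(nodes)
        while True:
            edges = {
                e: s
                for e, s in edges_all.items()
                if e[0] in active and e[1] in active and e not in dropped
            }
            if not edges:
                for n in sorted(active):
                    tiles.append(_singleton_tile(reads, n))
                break
            placed, residuals, support = _layout_component(reads, sorted(active), edges, tol_frac)
            bad_edges = {
                e: r
                for e, r in residuals.items()
                if r > tol_frac * max(reads[e[0]].read_length, reads[e[1]].read_length)
            }
            if not bad_edges:
                in_layout = sorted(placed)
                tiles.append(_build_tile(reads, in_layout, placed, support, edges))
                for n in sorted(active - set(placed)):
                    tiles.append(_singleton_tile(reads, n))
                break
            best_at: dict[int, int] = {}
            for (i, j), s in edges.items():
                best_at[i] = max(best_at.get(i, 0), s.n_valid)
                best_at[j] = max(best_at.get(j, 0), s.n_valid)
            spurious = [
                e
                for e in bad_edges
                if edges[e].n_valid < 0.5 * max(best_at[e[0]], best_at[e[1]])
            ]
            if spurious:
                for e in spurious:
                    logger.info(
                        "dropping spurious pair (%s, %s): inconsistent and weakly supported",
                        reads[e[0]].read_id, reads[e[1]].read_id,
                    )
                dropped.update(spurious)
                continue
            viol_count: dict[int, int] = {}
            for (i, j) in bad_edges:
                viol_count[i] = viol_count.get(i, 0) + 1
                viol_count[j] = viol_count.get(j, 0) + 1
            worst = max(viol_count, key=lambda n: (viol_count[n], -support.get(n, 0)))
            logger.info("evicting read %s (%d violated pairs)", reads[worst].read_id, viol_count[worst])
            active.discard(worst)
            if not active:
                break
    return tiles


def _singleton_tile(reads: list[BarcodedRead], n: int) -> Tile:
    r = reads[n]
    return Tile(
        members=[TileMember(n, "F", 0, 0)],
        sequence=r.sequence,
        backbone=[(n, 0, r.read_length)],
    )


def _tile_anchor_index(read: BarcodedRead, orientation: str, offset: int):
    """(tile positions sorted, read own-frame positions) for stitch lookup."""
    tp = offset + _oriented_anchor_pos(read.positions, read.read_length, read.k, orientation)
    order = np.argsort(tp)
    return tp[order], read.positions[order], read.sunk_ids[order]


def _build_tile(
    reads: list[BarcodedRead],
    nodes: list[int],
    placed: dict[int, tuple[str, int]],
    support: dict[int, int],
    edges: dict[tuple[int, int], ReadPairSupport],
) -> Tile:
    """Emit a tile sequence by stitching member reads at shared anchors.

    At each tile coordinate the backbone uses the overlapping read with
    the most valid SUNKs (ties to the longer read); switches between
    consecutive backbone reads happen at a SUNK anchor both reads carry,
    so junctions are exact over the anchor k-mer.
    """
    base = min(placed[n][1] for n in nodes)
    members = [
        TileMember(n, placed[n][0], placed[n][1] - base, support.get(n, 0)) for n in sorted(nodes)
    ]
    members_by_idx = {m.read_index: m for m in members}
    intervals = []  # (start, end, read_index)
    for m in members:
        intervals.append((m.offset, m.offset + reads[m.read_index].read_length, m.read_index))

    def better(n1, n2):
        m1, m2 = members_by_idx[n1], members_by_idx[n2]
        k1 = (m1.support, reads[n1].read_length)
        k2 = (m2.support, reads[n2].read_length)
        return n1 if k1 >= k2 else n2

    # segment sweep: best read per elementary segment
    points = sorted({p for s, e, _ in intervals for p in (s, e)})
    seg_best: list[tuple[int, int, int]] = []
    for s, e in zip(points[:-1], points[1:]):
        covering = [n for (cs, ce, n) in intervals if cs <= s and ce >= e]
        if not covering:
            continue  # gap in layout; tile splits are handled upstream
        best = covering[0]
        for n in covering[1:]:
            best = better(best, n)
        if seg_best and seg_best[-1][2] == best and seg_best[-1][1] == s:
            seg_best[-1] = (seg_best[-1][0], e, best)
        else:
            seg_best.append((s, e, best))

    oriented_seq = {}
    anchor_idx = {}
    for m in members:
        r = reads[m.read_index]
        oriented_seq[m.read_index] = r.sequence if m.orientation == "F" else revcomp(r.sequence)
        anchor_idx[m.read_index] = _tile_anchor_index(r, m.orientation, m.offset)

    def oriented_read_pos(n: int, tile_pos: int) -> int:
        """Oriented-read coordinate for a tile coordinate (offset arithmetic)."""
        m = members_by_idx[n]
        return int(np.clip(tile_pos - m.offset, 0, reads[n].read_length))

    def anchor_cut(n_prev: int, n_next: int, around: int):
        """Shared-anchor cut point near `around`: returns oriented-read
        positions (cut_prev, cut_next) or None.

        Candidate anchors must agree in tile coordinates between the two
        reads (within per-read indel drift) and lie close to the
        junction; otherwise the caller falls back to offset arithmetic,
        whose error is bounded by the same drift."""
        tp_p, own_p, sid_p = anchor_idx[n_prev]
        tp_n, own_n, sid_n = anchor_idx[n_next]
        common, ip, jn = np.intersect1d(sid_p, sid_n, return_indices=True)
        if common.size == 0:
            return None
        cand_tp = tp_p[ip]
        drift = max(300, int(0.01 * max(reads[n_prev].read_length, reads[n_next].read_length)))
        agree = (np.abs(cand_tp - tp_n[jn]) <= drift) & (np.abs(cand_tp - around) <= 5 * drift)
        if not agree.any():
            return None
        cand_tp, ip, jn = cand_tp[agree], ip[agree], jn[agree]
        pick = int(np.argmin(np.abs(cand_tp - around)))
        mprev, mnext = members_by_idx[n_prev], members_by_idx[n_next]
        rprev, rnext = reads[n_prev], reads[n_next]
        op = own_p[ip[pick]]
        on = own_n[jn[pick]]
        cut_prev = op if mprev.orientation == "F" else rprev.read_length - rprev.k - op
        cut_next = on if mnext.orientation == "F" else rnext.read_length - rnext.k - on
        return int(cut_prev), int(cut_next)

    pieces: list[str] = []
    backbone: list[tuple[int, int, int]] = []
    cursor_read = None
    cursor_pos = 0  # position in oriented read sequence
    for s, e, n in seg_best:
        if cursor_read is None:
            cursor_read, cursor_pos = n, oriented_read_pos(n, s)
        elif n != cursor_read:
            cut = anchor_cut(cursor_read, n, s)
            if cut is not None:
                cut_prev, cut_next = cut
                cut_prev = max(cut_prev, cursor_pos)
            else:
                cut_prev = oriented_read_pos(cursor_read, s)
                cut_prev = max(cut_prev, cursor_pos)
                cut_next = oriented_read_pos(n, s)
            pieces.append(oriented_seq[cursor_read][cursor_pos:cut_prev])
            backbone.append((cursor_read, cursor_pos, cut_prev))
            cursor_read, cursor_pos = n, cut_next
    if cursor_read is not None:
        end = len(oriented_seq[cursor_read])
        pieces.append(oriented_seq[cursor_read][cursor_pos:end])
        backbone.append((cursor_read, cursor_pos, end))
    return Tile(members=members, sequence="".join(pieces), backbone=backbone)


# ---------------------------------------------------------------------------
# scaffold extension


@dataclass
class Scaffold:
    sequence: str
    spanning: bool
    left_anchor_found: bool
    right_anchor_found: bool
    rounds: int
    member_reads: list[str] = field(default_factory=list)


def _contains_anchor(consensus: str, anchor: str, max_divergence: float = 0.2) -> bool:
    """Error-tolerant containment of a unique anchor sequence."""
    if not anchor:
        raise ValueError("anchor sequence is empty")
    limit = int(max_divergence * len(anchor))
    for probe in (anchor, revcomp(anchor)):
        res = edlib.align(probe, consensus, mode="HW", task="distance", k=limit)
        if res["editDistance"] != -1:
            return True
    return False


def extend_scaffold(
    seed_tile: Tile,
    reads: list[BarcodedRead],
    sunks: SunkSet,
    thresholds: PairThresholds | None = None,
    anchors: tuple[str, str] = ("", ""),
    max_rounds: int = 30,
) -> Scaffold:
    """Iteratively extend a tile until it spans between the target anchors.

    Each round barcodes the current consensus, validates unconsumed pool
    reads against it, and merges the best read extending each end (stitch
    at a shared SUNK). Stops when both anchors are contained, after two
    rounds without progress, or at max_rounds.
    """
    thresholds = thresholds or PairThresholds()
    left_anchor, right_anchor = anchors
    consensus = seed_tile.sequence
    consumed = {m.read_index for m in seed_tile.members}
    member_reads = [reads[m.read_index].read_id for m in seed_tile.members]
    stale_rounds = 0
    rounds = 0

    def anchors_found(seq):
        lf = _contains_anchor(seq, left_anchor) if left_anchor else False
        rf = _contains_anchor(seq, right_anchor) if right_anchor else False
        return lf, rf

    lf, rf = anchors_found(consensus)
    while rounds < max_rounds and not (lf and rf) and stale_rounds < 2:
        rounds += 1
        cbc = barcode_read("consensus", consensus, sunks)
        best_left = best_right = None  # (gain, support, read index, placement)
        for n, r in enumerate(reads):
            if n in consumed:
                continue
            s = validate_pair(cbc, r, thresholds)
            if s is None or s.shared_sunk_count < thresholds.min_shared_sunks:
                continue
            ori = "F" if s.orientation == "same" else "R"
            tb = _oriented_anchor_pos(s.valid_pos_b, r.read_length, r.k, ori)
            offset = int(round(float(np.median(s.valid_pos_a - tb))))
            left_gain = -offset
            right_gain = offset + r.read_length - len(consensus)
            if left_gain > 0 and (best_left is None or (left_gain, s.n_valid) > best_left[:2]):
                best_left = (left_gain, s.n_valid, n, ori, offset, s)
            if right_gain > 0 and (best_right is None or (right_gain, s.n_valid) > best_right[:2]):
                best_right = (right_gain, s.n_valid, n, ori, offset, s)
        progressed = False
        for side, pick in (("left", best_left), ("right", best_right)):
            if pick is None:
                continue
            _, _, n, ori, offset, s = pick
            if n in consumed:
                continue
            r = reads[n]
            oriented = r.sequence if ori == "F" else revcomp(r.sequence)
            # stitch at the valid anchor nearest the junction
            tb = _oriented_anchor_pos(s.valid_pos_b, r.read_length, r.k, ori)
            ca = s.valid_pos_a  # consensus positions
            if side == "left":
                pick_i = int(np.argmin(ca))
            else:
                pick_i = int(np.argmax(ca))
            cpos = int(ca[pick_i])
            rpos_oriented = int(tb[pick_i])
            if side == "left":
                consensus = oriented[:rpos_oriented] + consensus[cpos:]
            else:
                consensus = consensus[:cpos] + oriented[rpos_oriented:]
            consumed.add(n)
            member_reads.append(r.read_id)
            progressed = True
        lf, rf = anchors_found(consensus)
        stale_rounds = 0 if progressed else stale_rounds + 1

    return Scaffold(
        sequence=consensus,
        spanning=bool(lf and rf),
        left_anchor_found=bool(lf),
        right_anchor_found=bool(rf),
        rounds=rounds,
        member_reads=member_reads,
    )


# ---------------------------------------------------------------------------
# contig patching


@dataclass
class ContigPlacement:
    contig_id: str
    orientation: str  # "F"/"R"
    scaffold_start: int
    scaffold_end: int
    contig_start: int  # coordinates on the oriented contig
    contig_end: int
    n_anchors: int
    contig_length: int = 0


@dataclass
class PatchedAssembly:
    sequence: str
    provenance: list[tuple[int, int, str, str]]  # (start, end, source, name)

    @property
    def bp_from_contigs(self) -> int:
        return sum(e - s for s, e, src, _ in self.provenance if src == "contig")

    @property
    def bp_from_scaffold(self) -> int:
        return sum(e - s for s, e, src, _ in self.provenance if src == "scaffold")


def _lis_chain(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the longest chain strictly increasing in both x and y.

    x is assumed sorted ascending (ties allowed); patience algorithm on y.
    """
    order = np.lexsort((-y, x))  # by x asc, y desc within ties -> strict both
    ys = y[order]
    tails: list[int] = []  # index into ys of smallest tail per length
    prev = np.full(ys.size, -1, dtype=np.int64)
    tails_val: list[float] = []
    for i in range(ys.size):
        v = ys[i]
        pos = bisect_left(tails_val, v)
        if pos == len(tails_val):
            tails_val.append(v)
            tails.append(i)
        else:
            tails_val[pos] = v
            tails[pos] = i
        prev[i] = tails[pos - 1] if pos > 0 else -1
    chain = []
    cur = tails[-1] if tails else -1
    while cur != -1:
        chain.append(cur)
        cur = prev[cur]
    chain.reverse()
    return order[np.array(chain, dtype=np.int64)] if chain else np.empty(0, dtype=np.int64)


def _place_contig(
    scaffold_bc: BarcodedRead, contig_id: str, contig_seq: str, sunks: SunkSet
) -> tuple[ContigPlacement, np.ndarray, np.ndarray] | None:
    """Anchor a contig on the scaffold by its longest colinear SUNK chain."""
    sid_s, pos_s, _ = scaffold_bc.unique_anchor_arrays()
    best = None
    for orientation, seq in (("F", contig_seq), ("R", revcomp(contig_seq))):
        cbc = barcode_read(contig_id, seq, sunks)
        sid_c, pos_c, _ = cbc.unique_anchor_arrays()
        common, ic, is_ = np.intersect1d(sid_c, sid_s, return_indices=True)
        if common.size < 2:
            continue
        pc, ps = pos_c[ic], pos_s[is_]
        order = np.argsort(pc)
        chain = _lis_chain(pc[order], ps[order])
        if chain.size < 2:
            continue
        cpc, cps = pc[order][chain], ps[order][chain]
        # the LIS can be stretched by sparse spurious anchors (error-made
        # SUNK copies elsewhere in the array); keep the longest run whose
        # consecutive steps agree between contig and scaffold coordinates
        dc = np.diff(cpc).astype(float)
        dsf = np.diff(cps).astype(float)
        ok_step = np.abs(dsf - dc) <= np.maximum(300.0, 0.1 * np.maximum(dc, dsf))
        breaks = np.flatnonzero(~ok_step)
        segments = np.split(np.arange(cpc.size), breaks + 1)
        run = max(segments, key=len)
        if run.size < 2:
            continue
        cpc, cps = cpc[run], cps[run]
        if best is None or run.size > best[0].n_anchors:
            placement = ContigPlacement(
                contig_id=contig_id,
                orientation=orientation,
                scaffold_start=int(cps[0]),
                scaffold_end=int(cps[-1]) + scaffold_bc.k,
                contig_start=int(cpc[0]),
                contig_end=int(cpc[-1]) + scaffold_bc.k,
                n_anchors=int(cpc.size),
                contig_length=len(contig_seq),
            )
            best = (placement, cpc, cps)
    return best


def patch_with_contigs(
    scaffold: Scaffold | str,
    contigs: dict[str, str],
    sunks: SunkSet,
) -> PatchedAssembly:
    """Replace scaffold bases with high-accuracy contig bases.

    Each contig is placed by its longest strictly-colinear SUNK anchor
    chain (evaluated in both orientations). Where two placements claim
    overlapping scaffold intervals the chain with more anchors wins and
    the loser is truncated at the nearest chain anchor outside the
    winner's interval (ties: longer contig wins). Unpatched intervals
    retain scaffold sequence; per-interval provenance is recorded and
    partitions the output.
    """
    scaffold_seq = scaffold.sequence if isinstance(scaffold, Scaffold) else scaffold
    scaffold_bc = barcode_read("scaffold", scaffold_seq, sunks)
    placements: list[tuple[ContigPlacement, np.ndarray, np.ndarray, str]] = []
    for cid, cseq in contigs.items():
        hit = _place_contig(scaffold_bc, cid, cseq, sunks)
        if hit is None:
            logger.info("contig %s: no colinear anchor chain; skipped", cid)
            continue
        placement, cpc, cps = hit
        oriented = cseq if placement.orientation == "F" else revcomp(cseq)
        placements.append((placement, cpc, cps, oriented))

    # resolve scaffold-interval conflicts: strongest chain first
    placements.sort(key=lambda p: (-p[0].n_anchors, -p[0].contig_length))
    accepted: list[tuple[ContigPlacement, np.ndarray, np.ndarray, str]] = []
    for placement, cpc, cps, oriented in placements:
        lo, hi = placement.scaffold_start, placement.scaffold_end
        keep = np.ones(cps.size, dtype=bool)
        for acc, _, _, _ in accepted:
            keep &= ~((cps >= acc.scaffold_start) & (cps < acc.scaffold_end))
        if keep.sum() < 2:
            logger.info("contig %s fully shadowed by stronger placements", placement.contig_id)
            continue
        # truncate to the surviving chain; require it to stay contiguous
        idx = np.flatnonzero(keep)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        run = max(runs, key=len)
        if run.size < 2:
            continue
        cpc2, cps2 = cpc[run], cps[run]
        k = sunks.k
        placement.scaffold_start, placement.scaffold_end = int(cps2[0]), int(cps2[-1]) + k
        placement.contig_start, placement.contig_end = int(cpc2[0]), int(cpc2[-1]) + k
        accepted.append((placement, cpc2, cps2, oriented))

    accepted.sort(key=lambda p: p[0].scaffold_start)
    pieces: list[str] = []
    provenance: list[tuple[int, int, str, str]] = []
    cursor = 0
    out_pos = 0

    def emit(seq: str, source: str, name: str):
        nonlocal out_pos
        if not seq:
            return
        pieces.append(seq)
        provenance.append((out_pos, out_pos + len(seq), source, name))
        out_pos += len(seq)

    for placement, _, _, oriented in accepted:
        if placement.scaffold_start > cursor:
            emit(scaffold_seq[cursor : placement.scaffold_start], "scaffold", "scaffold")
        emit(oriented[placement.contig_start : placement.contig_end], "contig", placement.contig_id)
        cursor = placement.scaffold_end
    if cursor < len(scaffold_seq):
        emit(scaffold_seq[cursor:], "scaffold", "scaffold")
    return PatchedAssembly(sequence="".join(pieces), provenance=provenance)
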