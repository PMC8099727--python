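"""Alpha-satellite organization: digestion, monomer decomposition, HOR units.

A higher-order repeat (HOR) array is a tandem arrangement of cassettes of
~171-bp monomers. This module recovers that organization from an
assembled array three ways:

* in silico restriction digestion — HOR units often carry exactly one
  site of a diagnostic enzyme, so the fragment-length spectrum exposes
  the unit-length distribution;
* monomer decomposition — a dynamic program segments the array into
  consecutive blocks, each assigned the reference monomer minimizing its
  edit distance, jointly minimizing total edit distance over the whole
  sequence with free block boundaries (in the spirit of consensus-monomer
  string decomposition);
* HOR-unit typing and windowed admixture entropy over the unit sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from numba import njit

from .qv import tally_from_alignment
from .seq import encode, iupac_regex, iupac_revcomp, revcomp

GAP_ID = "gap"
IDENTITY_FLOOR = 60.0
SKIP_COST = 1  # cost per sequence base left outside any monomer block


def load_default_monomers() -> dict[str, str]:
    """The 11 alpha-satellite monomers (A-K) of the human chromosome 8
    D8Z2 11-monomer HOR unit, shipped as package data."""
    from importlib.resources import files

    text = files("sunkasm").joinpath("data/d8z2_monomers.fa").read_text()
    monomers: dict[str, str] = {}
    mid = None
    for line in text.splitlines():
        if line.startswith(">"):
            mid = line[1:].strip()
            monomers[mid] = ""
        elif mid:
            monomers[mid] += line.strip()
    return monomers


# ---------------------------------------------------------------------------
# restriction digestion


@dataclass
class RestrictionEnzyme:
    name: str
    site: str  # IUPAC string

    def __post_init__(self):
        if not self.site:
            raise ValueError("site must be non-empty")
        iupac_regex(self.site)  # validates the alphabet


@dataclass
class DigestFragment:
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def in_silico_digest(seq: str, enzyme: RestrictionEnzyme) -> list[DigestFragment]:
    """Fragments between consecutive recognition-site matches.

    Cut positions are the starts of forward-strand matches of the site
    plus the forward-strand start positions of reverse-strand matches;
    palindromic sites are counted once. Fragment lengths always sum to the
    sequence length.
    """
    seq = seq.upper()
    fwd = iupac_regex(enzyme.site)
    cuts = {m.start() for m in fwd.finditer(seq)}
    rc_site = iupac_revcomp(enzyme.site)
    if rc_site != enzyme.site.upper():
        rev = iupac_regex(rc_site)
        cuts |= {m.start() for m in rev.finditer(seq)}
    cuts = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0] + cuts + [len(seq)]
    return [DigestFragment(s, e) for s, e in zip(bounds[:-1], bounds[1:]) if e > s]


# ---------------------------------------------------------------------------
# monomer decomposition


@dataclass
class MonomerAnnotation:
    start: int
    end: int
    monomer_id: str  # reference monomer id, or "gap"
    strand: str
    identity: float  # percent identity of the block-vs-monomer alignment

    @property
    def is_gap(self) -> bool:
        return self.monomer_id == GAP_ID


@njit(cache=True)
def _decompose_kernel(seq_codes, mono_flat, mono_off, mono_len, skip_cost):
    """Joint segmentation DP over all monomers.

    score[i] = minimum cost of explaining seq[:i] as monomer blocks
    (unit-cost edit distance each) plus skipped bases (skip_cost each).
    One DP column per monomer is advanced a sequence position at a time;
    column cell r holds min_j score[j] + edit(seq[j:i], monomer[:r]) with
    the achieving block start j carried alongside, so the segmentation is
    recovered without storing the full matrices.
    """
    n = seq_codes.size
    m = mono_len.size
    INF = 1 << 30
    score = np.empty(n + 1, dtype=np.int64)
    best_mono = np.full(n + 1, -1, dtype=np.int64)
    best_start = np.full(n + 1, -1, dtype=np.int64)
    score[0] = 0

    maxL = int(mono_len.max())
    col = np.empty((m, maxL + 1), dtype=np.int64)
    start = np.empty((m, maxL + 1), dtype=np.int64)
    for t in range(m):
        col[t, 0] = 0
        start[t, 0] = 0
        for r in range(1, mono_len[t] + 1):
            col[t, r] = r  # monomer prefix vs empty sequence
            start[t, r] = 0

    ncol = np.empty(maxL + 1, dtype=np.int64)
    nstart = np.empty(maxL + 1, dtype=np.int64)

    for i in range(1, n + 1):
        c = seq_codes[i - 1]
        best = score[i - 1] + skip_cost
        bm = -1
        bs = -1
        for t in range(m):
            L = mono_len[t]
            off = mono_off[t]
            ncol[0] = INF  # true value is score[i]; fixed up below
            for r in range(1, L + 1):
                mc = 0 if mono_flat[off + r - 1] == c else 1
                v = col[t, r - 1] + mc  # consume both
                s = start[t, r - 1]
                v2 = col[t, r] + 1  # consume sequence base
                if v2 < v:
                    v, s = v2, start[t, r]
                v3 = ncol[r - 1] + 1  # consume monomer base
                if v3 < v:
                    v, s = v3, nstart[r - 1]
                ncol[r] = v
                nstart[r] = s
            if ncol[L] < best:
                best = ncol[L]
                bm = t
                bs = nstart[L]
            for r in range(1, L + 1):
                col[t, r] = ncol[r]
                start[t, r] = nstart[r]
        score[i] = best
        best_mono[i] = bm
        best_start[i] = bs
        # free-start fix-up: a block may start at i having consumed only
        # monomer bases so far (cost score[i] + r); never a better block
        # end at i itself, but feeds later columns
        for t in range(m):
            col[t, 0] = score[i]
            start[t, 0] = i
            run = score[i]
            for r in range(1, mono_len[t] + 1):
                run += 1
                if run < col[t, r]:
                    col[t, r] = run
                    start[t, r] = i
    return score, best_mono, best_start


def _block_identity(block: str, monomer: str) -> float:
    res = edlib.align(block, monomer, mode="NW", task="path")
    t = tally_from_alignment(res["cigar"])
    return 100.0 * t.matches / t.total


def decompose_monomers(
    seq: str,
    monomers: dict[str, str] | list[str],
    include_reverse: bool = True,
    identity_floor: float = IDENTITY_FLOOR,
    skip_cost: int = SKIP_COST,
) -> list[MonomerAnnotation]:
    """Segment a sequence into consecutive monomer blocks.

    Monomers may be given as {id: sequence} or as a list (ids assigned
    A, B, C, ... in order). With include_reverse, reverse complements
    compete as minus-strand candidates. Blocks whose alignment identity
    falls below the floor are emitted as "gap" annotations (adjacent gaps
    merged); the remaining annotations are non-overlapping, ordered, and
    cover the sequence exactly.
    """
    if not monomers:
        raise ValueError("monomer set is empty")
    if isinstance(monomers, dict):
        items = list(monomers.items())
    else:
        items = [(chr(ord("A") + i), m) for i, m in enumerate(monomers)]
    if len(seq) < min(len(m) for _, m in items) // 2:
        # far too short to hold a monomer; report one gap
        return [MonomerAnnotation(0, len(seq), GAP_ID, "+", 0.0)] if seq else []

    cands: list[tuple[str, str, str]] = [(mid, m.upper(), "+") for mid, m in items]
    if include_reverse:
        cands += [(mid, revcomp(m.upper()), "-") for mid, m in items]

    seq_codes = encode(seq.upper())
    mono_codes = [encode(m) for _, m, _ in cands]
    mono_len = np.array([c.size for c in mono_codes], dtype=np.int64)
    mono_off = np.concatenate(([0], np.cumsum(mono_len)[:-1]))
    mono_flat = np.concatenate(mono_codes)

    _, best_mono, best_start = _decompose_kernel(seq_codes, mono_flat, mono_off, mono_len, skip_cost)

    blocks: list[tuple[int, int, int]] = []  # (start, end, cand index or -1 for skip)
    i = len(seq)
    while i > 0:
        t = best_mono[i]
        if t < 0:
            blocks.append((i - 1, i, -1))
            i -= 1
        else:
            j = int(best_start[i])
            blocks.append((j, i, int(t)))
            i = j
    blocks.reverse()

    annotations: list[MonomerAnnotation] = []
    for s, e, t in blocks:
        if t < 0:
            ann = MonomerAnnotation(s, e, GAP_ID, "+", 0.0)
        else:
            mid, mseq, strand = cands[t]
            ident = _block_identity(seq[s:e].upper(), mseq)
            if ident < identity_floor:
                ann = MonomerAnnotation(s, e, GAP_ID, "+", ident)
            else:
                ann = MonomerAnnotation(s, e, mid, strand, ident)
        if ann.is_gap and annotations and annotations[-1].is_gap:
            prev = annotations[-1]
            annotations[-1] = MonomerAnnotation(prev.start, e, GAP_ID, "+", 0.0)
        else:
            annotations.append(ann)
    return annotations


def monomer_string(annotations: list[MonomerAnnotation]) -> str:
    """Concatenated monomer ids of the non-gap annotations."""
    return "".join(a.monomer_id for a in annotations if not a.is_gap)


# ---------------------------------------------------------------------------
# HOR units


@dataclass
class HorUnit:
    start: int
    end: int
    monomer_string: str
    partial: bool = False

    @property
    def monomer_count(self) -> int:
        return len(self.monomer_string)


def call_hor_units(
    annotations: list[MonomerAnnotation],
    start_monomer: str = "A",
) -> list[HorUnit]:
    """Group monomer annotations into HOR units.

    A unit begins at each occurrence of `start_monomer` and ends before
    the next one; gap annotations break the array into independent runs.
    Units that do not begin with the start monomer are flagged partial, as
    is a final unit whose monomer string is a strict prefix of another
    complete unit in the array (truncation at the array edge).
    """
    runs: list[list[MonomerAnnotation]] = []
    cur: list[MonomerAnnotation] = []
    for a in annotations:
        if a.is_gap:
            if cur:
                runs.append(cur)
                cur = []
        else:
            cur.append(a)
    if cur:
        runs.append(cur)
    if not runs:
        return []

    if not any(a.monomer_id == start_monomer for run in runs for a in run):
        warnings.warn(f"start monomer {start_monomer!r} absent; emitting one partial unit")
        allm = [a for run in runs for a in run]
        return [HorUnit(allm[0].start, allm[-1].end, "".join(a.monomer_id for a in allm), partial=True)]

    units: list[HorUnit] = []
    run_last: list[int] = []  # indices of each run's final unit
    for run in runs:
        begins = [k for k, a in enumerate(run) if a.monomer_id == start_monomer]
        if not begins:
            units.append(HorUnit(run[0].start, run[-1].end, "".join(a.monomer_id for a in run), partial=True))
            run_last.append(len(units) - 1)
            continue
        if begins[0] > 0:
            seg = run[: begins[0]]
            units.append(HorUnit(seg[0].start, seg[-1].end, "".join(a.monomer_id for a in seg), partial=True))
        for k, b in enumerate(begins):
            e = begins[k + 1] if k + 1 < len(begins) else len(run)
            seg = run[b:e]
            units.append(HorUnit(seg[0].start, seg[-1].end, "".join(a.monomer_id for a in seg)))
        run_last.append(len(units) - 1)

    complete = {u.monomer_string for u in units if not u.partial}
    for idx in run_last:
        u = units[idx]
        if not u.partial and any(s != u.monomer_string and s.startswith(u.monomer_string) for s in complete):
            units[idx] = HorUnit(u.start, u.end, u.monomer_string, partial=True)
    return units


# ---------------------------------------------------------------------------
# admixture entropy


@dataclass
class EntropyParams:
    window_units: int = 10
    slide_units: int = 1
    by: str = "count"  # HOR type key: "count" (monomer_count) or "string"

    def __post_init__(self):
        if self.window_units < 1 or self.slide_units < 1:
            raise ValueError("window_units and slide_units must be >= 1")
        if self.by not in ("count", "string"):
            raise ValueError("by must be 'count' or 'string'")


def hor_entropy(units: list[HorUnit], params: EntropyParams | None = None) -> pd.DataFrame:
    """Shannon entropy of HOR-type frequencies in sliding unit windows.

    Entropy = -sum_i f_i * log2(f_i) over the HOR types i present in each
    full window of `window_units` complete units (partial units are
    excluded; only full windows are evaluated). Returns a frame with
    columns (start, end, mid, entropy); empty with a warning when fewer
    complete units than one window exist.
    """
    params = params or EntropyParams()
    full = [u for u in units if not u.partial]
    w = params.window_units
    if len(full) < w:
        warnings.warn(f"only {len(full)} complete units; need {w} for one window")
        return pd.DataFrame(columns=["start", "end", "mid", "entropy"])
    rows = []
    for s in range(0, len(full) - w + 1, params.slide_units):
        window = full[s : s + w]
        keys = [u.monomer_count if params.by == "count" else u.monomer_string for u in window]
        _, counts = np.unique(np.array(keys, dtype=object), return_counts=True)
        freq = counts / w
        ent = float(-(freq * np.log2(freq)).sum())
        start, end = window[0].start, window[-1].end
        rows.append((start, end, (start + end) // 2, ent))
    return pd.DataFrame(rows, columns=["start", "end", "mid", "entropy"])
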