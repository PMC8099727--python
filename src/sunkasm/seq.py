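"""Small sequence utilities shared across the toolkit.

All sequences are plain Python strings over the ACGTN alphabet (uppercase).
Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import re

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide codes -> the set of bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BASES = "ACGT"

# 2-bit encoding: A=0 C=1 G=2 T=3; anything else -> 4 (invalid sentinel).
_ENC = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_revcomp(site: str) -> str:
    """Reverse complement of an IUPAC pattern."""
    return site.translate(_IUPAC_COMP)[::-1]


def iupac_regex(site: str) -> re.Pattern:
    """Compile an IUPAC site into a regex over ACGT.

    Raises ValueError on symbols outside the IUPAC nucleotide alphabet.
    """
    parts = []
    for ch in site.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in site {site!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int64 codes (A=0..T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_kmer(code: int, k: int) -> str:
    """Decode a 2-bit packed k-mer integer back to a string."""
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def random_dna(length: int, rng: np.random.Generator) -> str:
    """i.i.d. uniform ACGT sequence."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    *,
    sub_frac: float = 1.0,
    ins_frac: float = 0.0,
    del_frac: float = 0.0,
) -> str:
    """Apply i.i.d. per-base errors at `rate`, split into sub/ins/del classes.

    Substitutions always change the base. Insertions add one uniform base
    before the current one. Fractions must sum to 1.
    """
    if rate < 0 or rate > 1:
        raise ValueError("mutation rate must be in [0, 1]")
    if rate == 0:
        return seq
    total = sub_frac + ins_frac + del_frac
    if abs(total - 1.0) > 1e-9:
        raise ValueError("error-class fractions must sum to 1")
    n = len(seq)
    hit = rng.random(n) < rate
    if not hit.any():
        return seq
    kinds = rng.random(n)  # classify every position; only 'hit' ones used
    out = []
    for i, ch in enumerate(seq):
        if not hit[i]:
            out.append(ch)
            continue
        u = kinds[i]
        if u < sub_frac:
            out.append(BASES[(("ACGT".index(ch) if ch in BASES else 0) + rng.integers(1, 4)) % 4])
        elif u < sub_frac + ins_frac:
            out.append(BASES[rng.integers(0, 4)])
            out.append(ch)
        # else: deletion -> emit nothing
    return "".join(out)
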