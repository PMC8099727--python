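"""Sequence and interval I/O shared by every module.

FASTA/FASTQ parsing is delegated to Biopython; gzip is detected from the
filename. All interval output is 0-based half-open (BED convention);
1-based presentation happens only in formatting helpers.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = set("ACGTNacgtn")


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    quality: list[int] | None = None  # per-base phred scores

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _infer_format(path: Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[SequenceRecord]:
    """Stream records from a (possibly gzipped) FASTA/FASTQ file.

    Malformed records raise with the record id in the message. Round-trips
    losslessly with write_sequences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = rec.letter_annotations.get("phred_quality")
            try:
                yield SequenceRecord(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    quality=list(qual) if qual is not None else None,
                )
            except ValueError as exc:
                raise ValueError(f"malformed record in {path}: {exc}") from exc


def write_sequences(
    records: Iterable[SequenceRecord], path: str | Path, fmt: str | None = None
) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    bio_records = []
    for r in records:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = r.quality or [30] * len(r.sequence)
        bio_records.append(rec)
    with _open_maybe_gzip(path, "wt") as fh:
        SeqIO.write(bio_records, fh, fmt)


def write_intervals(
    intervals: Iterable[tuple],
    path: str | Path,
    fmt: str = "bed",
) -> None:
    """Write 0-based half-open intervals as BED, bedGraph or TSV.

    Rows are (chrom, start, end, *rest): BED uses rest[0] as name and
    rest[1] as score when present; bedGraph requires one numeric value.
    Output is sorted by (chrom, start); an empty input yields a file with
    a header comment only.
    """
    if fmt not in ("bed", "bedgraph", "tsv"):
        raise ValueError(f"unsupported interval format {fmt!r}")
    rows = sorted(intervals, key=lambda r: (str(r[0]), int(r[1])))
    for r in rows:
        if int(r[1]) < 0 or int(r[2]) < int(r[1]):
            raise ValueError(f"bad interval {r!r}: negative or inverted coordinates")
    with open(path, "w") as fh:
        if not rows:
            fh.write("# no intervals\n")
            return
        for r in rows:
            chrom, start, end, *rest = r
            if fmt == "bed":
                name = rest[0] if rest else "."
                score = rest[1] if len(rest) > 1 else 0
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\n")
            elif fmt == "bedgraph":
                if not rest:
                    raise ValueError("bedgraph rows need a value column")
                fh.write(f"{chrom}\t{start}\t{end}\t{rest[0]}\n")
            else:
                fh.write("\t".join(str(x) for x in r) + "\n")


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (presentation only)."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start < 1:
        raise ValueError("1-based start must be >= 1")
    return start - 1, end
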