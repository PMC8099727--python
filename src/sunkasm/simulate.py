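"""Synthetic layered satellite arrays and sequencing read sets.

The generator emulates the structure the rest of the toolkit assumes: a
tandem array of higher-order repeat (HOR) units built from ~171-bp
alpha-satellite-like monomers, organized into concentric evolutionary
layers that grow more homogeneous toward the centre (young, recently
expanded repeats in the middle; older, more divergent repeats pushed to
the edges), flanked by unique sequence. Read sets with platform-style
error profiles (accurate long "hifi-like", noisy ultra-long "ont-like",
short accurate "illumina-like") are sampled from the truth genome with
per-read truth placements.

The layer plan imposes the layered *outcome* directly; no unequal
crossing-over or other mechanistic process is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .seq import BASES, mutate, random_dna, revcomp

MONOMER_LENGTH = 171  # canonical alpha-satellite monomer size, bp


# ---------------------------------------------------------------------------
# monomer sets


@dataclass
class MonomerSpec:
    """Parameters for a synthetic monomer family.

    inter_monomer_divergence is the target mean pairwise divergence
    (substitutions per site) between family members.
    """

    monomer_count: int = 11
    monomer_length: int = MONOMER_LENGTH
    inter_monomer_divergence: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.monomer_count < 1:
            raise ValueError("monomer_count must be >= 1")
        if self.monomer_length < 1:
            raise ValueError("monomer_length must be >= 1")
        if not (0.0 <= self.inter_monomer_divergence <= 1.0):
            raise ValueError("inter_monomer_divergence must be in [0, 1]")


def simulate_monomer_set(spec: MonomerSpec) -> list[str]:
    """Generate monomer sequences around a common random ancestor.

    Each monomer substitutes ancestor sites independently at rate p chosen
    so that the expected pairwise divergence 2p - (4/3)p^2 equals the
    requested value. Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = random_dna(spec.monomer_length, rng)
    d = spec.inter_monomer_divergence
    # solve 2p - (4/3)p^2 = d for the smaller root
    p = 0.0 if d == 0 else (2.0 - np.sqrt(4.0 - 16.0 * d / 3.0)) / (8.0 / 3.0)
    return [mutate(ancestor, p, rng) for _ in range(spec.monomer_count)]


# ---------------------------------------------------------------------------
# layered arrays


@dataclass
class LayerSpec:
    """One evolutionary layer of the array.

    cassette: index into the cassette list, or several indices for an
    admixed layer (each unit draws its cassette uniformly).
    n_units: HOR units per emitted copy of the layer (mirrored layers are
    emitted once per side with this count each).
    substitution_rate: per-base substitution rate applied independently to
    every unit, relative to the pristine cassette sequence. Young layers
    get low rates, old peripheral layers high rates.
    """

    cassette: int | Sequence[int]
    n_units: int
    substitution_rate: float

    def cassette_choices(self) -> list[int]:
        if isinstance(self.cassette, (int, np.integer)):
            return [int(self.cassette)]
        return [int(c) for c in self.cassette]


@dataclass
class LayeredArraySpec:
    """Full specification of a mirrored, layered satellite array.

    layer_plan is ordered outermost -> innermost. With mirror=True every
    layer except the innermost appears once on each side of the centre
    (outermost ... innermost ... outermost), echoing the symmetric layout
    of primate centromeres.
    """

    monomers: MonomerSpec | Sequence[str] = field(default_factory=MonomerSpec)
    hor_cassettes: Sequence[Sequence[int]] = ((0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10),)
    layer_plan: Sequence[LayerSpec] = ()
    flank_length: int = 25_000
    mirror: bool = True
    seed: int = 0

    def resolve_monomers(self) -> list[str]:
        if isinstance(self.monomers, MonomerSpec):
            return simulate_monomer_set(self.monomers)
        return list(self.monomers)


def default_array_spec(seed: int = 0) -> LayeredArraySpec:
    """The reference five-layer mirrored array (~150-kb array, 25-kb flanks).

    Substitution rates (0.12, 0.08, 0.04, 0.02, 0.001) outermost to
    innermost reproduce the qualitative pattern of within-layer identity
    rising toward the centre of the array. Cassettes of 11, 7 and 8
    monomers are derivatives of the 11-monomer unit.
    """
    eleven = tuple(range(11))
    seven = tuple(range(7))
    eight = tuple(range(8))
    return LayeredArraySpec(
        monomers=MonomerSpec(monomer_count=11, inter_monomer_divergence=0.2, seed=seed),
        hor_cassettes=(eleven, seven, eight),
        layer_plan=(
            LayerSpec(cassette=0, n_units=7, substitution_rate=0.12),
            LayerSpec(cassette=0, n_units=8, substitution_rate=0.08),
            LayerSpec(cassette=0, n_units=9, substitution_rate=0.04),
            LayerSpec(cassette=(0, 1, 2), n_units=12, substitution_rate=0.02),
            LayerSpec(cassette=1, n_units=24, substitution_rate=0.001),
        ),
        flank_length=25_000,
        mirror=True,
        seed=seed,
    )


@dataclass
class SimulatedDataset:
    """Truth genome with per-base annotations and (optionally) read sets."""

    genome: str
    annotations: pd.DataFrame  # start, end, layer, unit, cassette, monomer, strand
    monomers: list[str] = field(default_factory=list)
    reads: dict[str, list["SimRead"]] = field(default_factory=dict)

    def layer_intervals(self) -> pd.DataFrame:
        """Merged (layer, start, end) intervals, one row per layer block."""
        rows = []
        ann = self.annotations
        block_start = None
        prev_layer = None
        prev_end = None
        for row in ann.itertuples():
            if row.layer != prev_layer:
                if prev_layer is not None:
                    rows.append((prev_layer, block_start, prev_end))
                block_start, prev_layer = row.start, row.layer
            prev_end = row.end
        if prev_layer is not None:
            rows.append((prev_layer, block_start, prev_end))
        return pd.DataFrame(rows, columns=["layer", "start", "end"])


def simulate_layered_array(spec: LayeredArraySpec) -> SimulatedDataset:
    """Emit flank - [mirrored layers] - flank with per-monomer truth rows.

    Truth annotations cover every emitted base exactly once: one row per
    monomer inside the array and one row per flank (layer = "flank").
    """
    if not spec.layer_plan:
        raise ValueError("layer_plan must be non-empty")
    monomers = spec.resolve_monomers()
    for layer in spec.layer_plan:
        if layer.n_units < 1:
            raise ValueError("every layer needs at least one unit")
        for ci in layer.cassette_choices():
            if not (0 <= ci < len(spec.hor_cassettes)):
                raise ValueError(f"cassette index {ci} out of range")
            for mi in spec.hor_cassettes[ci]:
                if not (0 <= mi < len(monomers)):
                    raise ValueError(f"monomer index {mi} out of range")

    rng = np.random.default_rng(spec.seed)
    n_layers = len(spec.layer_plan)
    # ordered list of (layer_id 1=outermost) to emit left-to-right
    if spec.mirror:
        order = list(range(1, n_layers + 1)) + list(range(n_layers - 1, 0, -1))
    else:
        order = list(range(1, n_layers + 1))

    pieces: list[str] = []
    rows: list[tuple] = []
    pos = 0
    unit_id = 0

    def emit_flank():
        nonlocal pos
        if spec.flank_length > 0:
            seq = random_dna(spec.flank_length, rng)
            pieces.append(seq)
            rows.append((pos, pos + len(seq), "flank", -1, -1, "", "+"))
            pos += len(seq)

    emit_flank()
    for layer_id in order:
        layer = spec.layer_plan[layer_id - 1]
        choices = layer.cassette_choices()
        for _ in range(layer.n_units):
            ci = choices[rng.integers(0, len(choices))] if len(choices) > 1 else choices[0]
            cassette = spec.hor_cassettes[ci]
            unit_seq = "".join(monomers[mi] for mi in cassette)
            unit_seq = mutate(unit_seq, layer.substitution_rate, rng)
            off = 0
            for mi in cassette:
                mlen = len(monomers[mi])
                rows.append((pos + off, pos + off + mlen, layer_id, unit_id, ci, chr(ord("A") + mi), "+"))
                off += mlen
            pieces.append(unit_seq)
            pos += len(unit_seq)
            unit_id += 1
    emit_flank()

    ann = pd.DataFrame(rows, columns=["start", "end", "layer", "unit", "cassette", "monomer", "strand"])
    return SimulatedDataset(genome="".join(pieces), annotations=ann, monomers=monomers)


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadProfile:
    """Sequencing platform emulation: length distribution, accuracy, coverage.

    Error events are i.i.d. per base at rate 1 - per_base_accuracy with a
    fixed substitution/insertion/deletion mix per platform (60/20/20 for
    ont-like, 90/5/5 for hifi-like, substitution-only for illumina-like).
    """

    platform_label: str = "ont-like"
    read_length: tuple[int, int, int] = (30_000, 80_000, 55_000)  # (min, max, mean)
    per_base_accuracy: float = 0.95
    coverage: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.per_base_accuracy <= 1.0):
            raise ValueError("per_base_accuracy must be in (0, 1]")
        lo, hi, mean = self.read_length
        if not (0 < lo <= mean <= hi):
            raise ValueError("read_length must satisfy min <= mean <= max")

    @property
    def error_mix(self) -> tuple[float, float, float]:
        if self.platform_label == "ont-like":
            return (0.6, 0.2, 0.2)
        if self.platform_label == "hifi-like":
            return (0.9, 0.05, 0.05)
        return (1.0, 0.0, 0.0)


def hifi_profile(coverage: float = 30.0, seed: int = 0) -> ReadProfile:
    return ReadProfile("hifi-like", (10_000, 25_000, 18_000), 0.999, coverage, seed)


def ont_profile(coverage: float = 20.0, seed: int = 0) -> ReadProfile:
    return ReadProfile("ont-like", (30_000, 80_000, 55_000), 0.95, coverage, seed)


def illumina_profile(coverage: float = 30.0, seed: int = 0) -> ReadProfile:
    return ReadProfile("illumina-like", (150, 150, 150), 0.999, coverage, seed)


@dataclass
class SimRead:
    """One simulated read with its truth placement on the forward genome."""

    read_id: str
    sequence: str
    start: int
    end: int
    strand: str  # '+' if sampled forward, '-' if reverse-complemented
    n_errors: int = 0  # error events injected by the generator

    def __len__(self) -> int:
        return len(self.sequence)


def _sample_length(profile: ReadProfile, rng: np.random.Generator) -> int:
    lo, hi, mean = profile.read_length
    if lo == hi:
        return lo
    sd = (hi - lo) / 6.0
    return int(np.clip(rng.normal(mean, sd), lo, hi))


def simulate_reads(genome: str, profile: ReadProfile) -> list[SimRead]:
    """Sample reads to the target coverage with the profile's error process.

    Read intervals are drawn uniformly and may overhang the genome ends,
    in which case they are truncated (so coverage stays uniform out to the
    boundaries, as in real data where the simulated region is embedded in
    a larger genome); truncated fragments shorter than min(150 bp, the
    profile minimum) are discarded. Reads are reverse-complemented with
    probability 1/2, then passed through the i.i.d. error process.
    Deterministic under the profile seed.
    """
    if not genome:
        raise ValueError("genome is empty")
    if profile.coverage <= 0:
        raise ValueError("coverage must be > 0")
    if profile.read_length[0] > len(genome):
        raise ValueError("minimum read length exceeds genome length")
    rng = np.random.default_rng(profile.seed)
    target = profile.coverage * len(genome)
    rate = 1.0 - profile.per_base_accuracy
    sub_f, ins_f, del_f = profile.error_mix
    keep_min = min(profile.read_length[0], 150)
    reads: list[SimRead] = []
    total = 0
    i = 0
    while total < target:
        length = min(_sample_length(profile, rng), len(genome))
        s0 = int(rng.integers(-(length - 1), len(genome)))
        start = max(0, s0)
        end = min(len(genome), s0 + length)
        if end - start < keep_min:
            continue
        length = end - start
        truth = genome[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = truth if strand == "+" else revcomp(truth)
        if rate > 0:
            n_before = len(seq)
            hit = rng.random(n_before) < rate
            n_events = int(hit.sum())
            if n_events:
                kinds = rng.random(n_before)
                out = []
                for j, ch in enumerate(seq):
                    if not hit[j]:
                        out.append(ch)
                        continue
                    u = kinds[j]
                    if u < sub_f:
                        out.append(BASES[(BASES.index(ch) + rng.integers(1, 4)) % 4])
                    elif u < sub_f + ins_f:
                        out.append(BASES[rng.integers(0, 4)])
                        out.append(ch)
                seq = "".join(out)
        else:
            n_events = 0
        reads.append(SimRead(f"{profile.platform_label}_{i:06d}", seq, start, start + length, strand, n_events))
        total += len(seq)
        i += 1
    return reads


def simulate_contigs(
    genome: str,
    n_contigs: int = 6,
    overlap: int = 0,
    seed: int = 0,
    coverage_fraction: float = 1.0,
) -> list[SimRead]:
    """Error-free contigs tiling the genome, emulating consensus assemblies.

    Consensus contigs are modelled error-free (their stated accuracy floor,
    >99.99%, is indistinguishable from perfect at desk scale). Contigs are
    equal slices of the genome; `coverage_fraction` < 1 trims each contig
    symmetrically so that gaps remain between them, and each contig is
    reverse-complemented with probability 1/2.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(genome)
    bounds = np.linspace(0, L, n_contigs + 1).astype(int)
    contigs = []
    for i in range(n_contigs):
        s, e = int(bounds[i]), int(bounds[i + 1])
        s = max(0, s - overlap)
        if coverage_fraction < 1.0:
            trim = int((e - s) * (1 - coverage_fraction) / 2)
            s, e = s + trim, e - trim
        truth = genome[s:e]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = truth if strand == "+" else revcomp(truth)
        contigs.append(SimRead(f"contig_{i:03d}", seq, s, e, strand, 0))
    return contigs


def write_truth_bed(dataset: SimulatedDataset, path, chrom: str = "sim") -> None:
    """Truth annotations as BED with name 'layer:unit:cassette:monomer'."""
    with open(path, "w") as fh:
        for row in dataset.annotations.itertuples():
            name = f"{row.layer}:{row.unit}:{row.cassette}:{row.monomer}"
            fh.write(f"{chrom}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n")


def accuracy_to_phred_char(accuracy: float) -> str:
    """FASTQ quality character encoding the profile-level accuracy."""
    import math

    if accuracy >= 1.0:
        q = 60
    else:
        q = min(60, int(round(-10 * math.log10(1 - accuracy))))
    return chr(q + 33)


def write_reads_fastq(reads: list[SimRead], profile: ReadProfile, path) -> None:
    """Reads as FASTQ with uniform qualities encoding the profile accuracy."""
    qchar = accuracy_to_phred_char(profile.per_base_accuracy)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} {r.start}-{r.end}({r.strand})\n{r.sequence}\n+\n{qchar * len(r.sequence)}\n")
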