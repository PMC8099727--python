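"""End-to-end synthetic workflow: simulate -> SUNKs -> scaffold -> patch.

This is the toolkit's reference pipeline, exercised entirely on the
synthetic layered-centromere dataset: build and validate a SUNK library
from accurate reads, barcode noisy ultra-long reads, assemble them into
a scaffold spanning the satellite array between unique flank anchors,
patch the scaffold with high-accuracy contigs, and report quality values
plus array-organization summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from . import assembly, heatmap, hor, qv, simulate, sunks
from .config import RunConfig

logger = logging.getLogger(__name__)

ANCHOR_LENGTH = 2000
ANCHOR_MARGIN = 1000  # distance of the anchor from the genome end


@dataclass
class PipelineBundle:
    config: RunConfig
    dataset: simulate.SimulatedDataset
    sunk_set: sunks.SunkSet
    scaffold: assembly.Scaffold
    patched: assembly.PatchedAssembly
    contigs: dict[str, str]
    qv_result: qv.QVResult
    tiles: list[assembly.Tile] = field(default_factory=list)
    layout: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "genome_length": len(self.dataset.genome),
            "n_sunks": len(self.sunk_set),
            "sunk_retained_fraction": self.sunk_set.provenance.get("retained_fraction"),
            "scaffold_length": len(self.scaffold.sequence),
            "scaffold_spanning": self.scaffold.spanning,
            "assembly_length": len(self.patched.sequence),
            "bp_from_contigs": self.patched.bp_from_contigs,
            "bp_from_scaffold": self.patched.bp_from_scaffold,
            "qv": None if self.qv_result.unbounded else round(self.qv_result.qv, 2),
            "accuracy_percent": self.qv_result.accuracy_percent,
        }


def default_read_profiles(config: RunConfig) -> dict[str, simulate.ReadProfile]:
    return {
        "hifi-like": simulate.hifi_profile(coverage=30.0, seed=config.module_seed("reads-hifi")),
        "ont-like": simulate.ont_profile(coverage=20.0, seed=config.module_seed("reads-ont")),
        "illumina-like": simulate.illumina_profile(coverage=30.0, seed=config.module_seed("reads-illumina")),
    }


def thresholds_from_config(config: RunConfig) -> assembly.PairThresholds:
    return assembly.PairThresholds(
        min_shared_sunks=config.min_shared_sunks,
        min_support_partners=config.min_support_partners,
        min_valid_sunks=config.min_valid_sunks,
        distance_tolerance_fraction=config.distance_tolerance_fraction,
    )


def run_pipeline(config: RunConfig | None = None, outdir: str | Path | None = None) -> PipelineBundle:
    """Run the full synthetic workflow; optionally write the artifact bundle.

    Deterministic under config.seed: the same config yields byte-identical
    outputs.
    """
    config = config or RunConfig()
    dataset = simulate.simulate_layered_array(
        simulate.default_array_spec(seed=config.module_seed("simulate"))
    )
    genome = dataset.genome
    profiles = default_read_profiles(config)
    reads = {label: simulate.simulate_reads(genome, prof) for label, prof in profiles.items()}
    logger.info("simulated %s", {k: len(v) for k, v in reads.items()})

    # SUNK library from accurate long reads, validated with short reads
    hifi_table = sunks.count_kmers((r.sequence for r in reads["hifi-like"]), k=config.sunk_k)
    params = sunks.SunkParams(
        k=config.sunk_k,
        coverage_band=config.sunk_coverage_band,
        validation_min_count=config.sunk_validation_min_count,
    )
    candidate_sunks = sunks.select_sunks(hifi_table, params)
    illumina_table = sunks.count_kmers((r.sequence for r in reads["illumina-like"]), k=config.sunk_k)
    sunk_set = sunks.validate_sunks(candidate_sunks, illumina_table, config.sunk_validation_min_count)
    logger.info("SUNKs: %d candidates, %d validated", len(candidate_sunks), len(sunk_set))

    # barcode + tile + extend
    thresholds = thresholds_from_config(config)
    barcoded = [
        assembly.barcode_read(r.read_id, r.sequence, sunk_set) for r in reads["ont-like"]
    ]
    candidates = assembly.find_candidate_pairs(barcoded, thresholds)
    supports = assembly.validate_pairs(barcoded, candidates, thresholds)
    tiles = assembly.assemble_tile(barcoded, supports, thresholds)
    seed_tile = max(tiles, key=lambda t: t.span)
    left_anchor = genome[ANCHOR_MARGIN : ANCHOR_MARGIN + ANCHOR_LENGTH]
    right_anchor = genome[-(ANCHOR_MARGIN + ANCHOR_LENGTH) : -ANCHOR_MARGIN]
    scaffold = assembly.extend_scaffold(
        seed_tile, barcoded, sunk_set, thresholds, anchors=(left_anchor, right_anchor)
    )
    logger.info("scaffold: %d bp, spanning=%s", len(scaffold.sequence), scaffold.spanning)

    # patch with consensus contigs
    contig_reads = simulate.simulate_contigs(
        genome, n_contigs=6, seed=config.module_seed("contigs"), coverage_fraction=0.99
    )
    contigs = {c.read_id: c.sequence for c in contig_reads}
    patched = assembly.patch_with_contigs(scaffold, contigs, sunk_set)

    # k-mer QV of the patched assembly against the short-read k-mer table
    qv_table = sunks.count_kmers((r.sequence for r in reads["illumina-like"]), k=config.qv_k)
    asm_table = sunks.count_kmers([patched.sequence], k=config.qv_k)
    present = qv_table.lookup(asm_table.kmers) > 0
    error_kmers = int(asm_table.counts[~present].sum())
    qv_result = qv.kmer_qv(
        qv.KmerQVInput(error_kmers=error_kmers, total_kmers=asm_table.total_kmers, k=config.qv_k)
    )

    layout = [
        {
            "read_id": barcoded[m.read_index].read_id,
            "offset": m.offset,
            "orientation": m.orientation,
            "valid_sunk_count": m.support,
        }
        for t in tiles
        for m in t.members
    ]
    bundle = PipelineBundle(
        config=config,
        dataset=dataset,
        sunk_set=sunk_set,
        scaffold=scaffold,
        patched=patched,
        contigs=contigs,
        qv_result=qv_result,
        tiles=tiles,
        layout=layout,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: PipelineBundle, outdir: Path) -> None:
    from .io import SequenceRecord, write_intervals, write_sequences

    outdir.mkdir(parents=True, exist_ok=True)
    write_sequences([SequenceRecord("truth", bundle.dataset.genome)], outdir / "truth.fa")
    write_sequences([SequenceRecord("scaffold", bundle.scaffold.sequence)], outdir / "scaffold.fa")
    write_sequences([SequenceRecord("patched", bundle.patched.sequence)], outdir / "patched.fa")
    simulate.write_truth_bed(bundle.dataset, outdir / "truth.bed")
    write_intervals(
        [("patched", s, e, f"{src}:{name}") for s, e, src, name in bundle.patched.provenance],
        outdir / "provenance.bed",
    )
    with open(outdir / "layout.tsv", "w") as fh:
        fh.write("read_id\toffset\torientation\tvalid_sunk_count\n")
        for row in bundle.layout:
            fh.write(
                f"{row['read_id']}\t{row['offset']}\t{row['orientation']}\t{row['valid_sunk_count']}\n"
            )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle.summary(), fh, indent=2)


@dataclass
class TruthComparison:
    identity_over_contigs: float  # percent, weighted by interval length
    collinear: bool
    n_contig_intervals: int
    truth_starts: list[int] = field(default_factory=list)


def evaluate_against_truth(bundle: PipelineBundle) -> TruthComparison:
    """Identity and collinearity of contig-sourced intervals vs the truth.

    Each contig-provenance interval of the patched assembly is located in
    the truth genome by infix alignment in both orientations; identity is
    1 - edits/length of the better one. The assembly's global orientation
    is arbitrary, so collinearity requires the located truth intervals to
    appear in strictly increasing or strictly decreasing order with a
    consistent strand.
    """
    from .seq import revcomp

    truth = bundle.dataset.genome
    total = 0
    edits = 0
    starts = []
    strands = []
    for s, e, src, _ in bundle.patched.provenance:
        if src != "contig":
            continue
        seg = bundle.patched.sequence[s:e]
        best = None
        for strand, probe in (("+", seg), ("-", revcomp(seg))):
            res = edlib.align(probe, truth, mode="HW", task="locations")
            if best is None or res["editDistance"] < best[0]:
                loc = res["locations"][0] if res["locations"] else (None,)
                best = (res["editDistance"], strand, loc[0])
        ed, strand, start = best
        total += len(seg)
        edits += ed
        starts.append(start if start is not None else -1)
        strands.append(strand)
    identity = 100.0 * (1 - edits / total) if total else float("nan")
    if starts:
        one_strand = len(set(strands)) == 1
        increasing = all(b > a for a, b in zip(starts[:-1], starts[1:]))
        decreasing = all(b < a for a, b in zip(starts[:-1], starts[1:]))
        collinear = one_strand and (increasing or decreasing)
    else:
        collinear = False
    return TruthComparison(
        identity_over_contigs=identity,
        collinear=collinear,
        n_contig_intervals=len(starts),
        truth_starts=starts,
    )
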