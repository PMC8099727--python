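"""Synthetic data generator: dimensions, determinism, error calibration."""

import edlib
import numpy as np
import pytest

from sunkasm import simulate
from sunkasm.seq import random_dna, revcomp


# ---------------------------------------------------------------------------
# monomer sets


def test_monomer_set_dimensions():
    spec = simulate.MonomerSpec(11, 171, 0.20, seed=1)
    monomers = simulate.simulate_monomer_set(spec)
    assert len(monomers) == 11
    assert all(len(m) == 171 for m in monomers)


def test_single_monomer_divergence_not_applicable():
    monomers = simulate.simulate_monomer_set(simulate.MonomerSpec(1, 100, 0.0, seed=7))
    assert len(monomers) == 1 and len(monomers[0]) == 100


def test_monomer_divergence_matches_request():
    """Mean pairwise divergence (edit-distance oracle over all 6 pairs)
    lands within ±20% relative of the requested 0.20."""
    monomers = simulate.simulate_monomer_set(simulate.MonomerSpec(4, 171, 0.20, seed=3))
    divs = [
        edlib.align(monomers[i], monomers[j])["editDistance"] / 171
        for i in range(4)
        for j in range(i + 1, 4)
    ]
    assert 0.16 <= np.mean(divs) <= 0.24


def test_monomer_spec_validation():
    with pytest.raises(ValueError):
        simulate.MonomerSpec(0, 171, 0.1)
    with pytest.raises(ValueError):
        simulate.MonomerSpec(2, 171, 1.5)


def test_monomer_set_deterministic():
    spec = simulate.MonomerSpec(5, 171, 0.1, seed=11)
    assert simulate.simulate_monomer_set(spec) == simulate.simulate_monomer_set(spec)


# ---------------------------------------------------------------------------
# layered arrays


def test_single_layer_array_length_arithmetic():
    """10 units of an 11-monomer cassette of 171-mers, no flanks."""
    spec = simulate.LayeredArraySpec(
        monomers=simulate.MonomerSpec(11, 171, 0.2, seed=0),
        hor_cassettes=(tuple(range(11)),),
        layer_plan=(simulate.LayerSpec(cassette=0, n_units=10, substitution_rate=0.0),),
        flank_length=0,
        mirror=False,
        seed=0,
    )
    dataset = simulate.simulate_layered_array(spec)
    assert len(dataset.genome) == 10 * 11 * 171 == 18_810


def test_flanks_carry_no_monomer_annotations(default_dataset):
    ann = default_dataset.annotations
    flank = 25_000
    inside_left = ann[(ann.start < flank) & (ann.layer != "flank")]
    inside_right = ann[(ann.end > len(default_dataset.genome) - flank) & (ann.layer != "flank")]
    assert inside_left.empty and inside_right.empty


def test_annotations_partition_genome(default_dataset):
    """Concatenating annotation intervals reproduces the genome exactly."""
    ann = default_dataset.annotations
    assert ann.start.iloc[0] == 0
    assert ann.end.iloc[-1] == len(default_dataset.genome)
    assert (ann.start.iloc[1:].to_numpy() == ann.end.iloc[:-1].to_numpy()).all()
    joined = "".join(default_dataset.genome[r.start : r.end] for r in ann.itertuples())
    assert joined == default_dataset.genome


def test_mirror_layout_each_layer_on_both_sides(default_dataset):
    blocks = default_dataset.layer_intervals()
    layers = [b for b in blocks.layer if b != "flank"]
    assert layers == [1, 2, 3, 4, 5, 4, 3, 2, 1]


def test_zero_unit_layer_rejected():
    spec = simulate.default_array_spec(0)
    bad = simulate.LayeredArraySpec(
        monomers=spec.monomers,
        hor_cassettes=spec.hor_cassettes,
        layer_plan=(simulate.LayerSpec(cassette=0, n_units=0, substitution_rate=0.0),),
    )
    with pytest.raises(ValueError, match="at least one unit"):
        simulate.simulate_layered_array(bad)


def test_array_deterministic_under_seed():
    a = simulate.simulate_layered_array(simulate.default_array_spec(3))
    b = simulate.simulate_layered_array(simulate.default_array_spec(3))
    assert a.genome == b.genome
    assert a.annotations.equals(b.annotations)


# ---------------------------------------------------------------------------
# reads


def test_illumina_read_count_matches_coverage(small_genome):
    reads = simulate.simulate_reads(
        small_genome, simulate.ReadProfile("illumina-like", (150, 150, 150), 0.999, 30.0, seed=5)
    )
    assert 1800 <= len(reads) <= 2300  # ~2,000 at 30x over 10 kb


def test_read_bases_match_coverage(small_genome):
    for maker in (simulate.hifi_profile, simulate.illumina_profile):
        prof = maker(coverage=20.0, seed=9)
        prof.read_length = (500, 1500, 1000) if prof.platform_label == "hifi-like" else prof.read_length
        reads = simulate.simulate_reads(small_genome, prof)
        total = sum(len(r) for r in reads)
        assert abs(total - 20.0 * len(small_genome)) <= 0.1 * 20.0 * len(small_genome) + 1500


def test_truth_placements_within_genome(small_genome):
    reads = simulate.simulate_reads(small_genome, simulate.illumina_profile(5.0, seed=2))
    for r in reads:
        assert 0 <= r.start < r.end <= len(small_genome)
        truth = small_genome[r.start : r.end]
        if r.strand == "-":
            truth = revcomp(truth)
        # error-free positions dominate at 0.999 accuracy
        assert edlib.align(r.sequence, truth)["editDistance"] <= max(10, 0.01 * len(truth))


def test_error_rate_within_three_binomial_sd():
    """Realized error (alignment to truth placement) sits in the 3-sigma
    band around 1 - accuracy, measured over >100 kb of ont-like bases."""
    genome = random_dna(200_000, np.random.default_rng(13))
    prof = simulate.ont_profile(coverage=1.0, seed=2)
    prof.per_base_accuracy = 0.92
    reads = simulate.simulate_reads(genome, prof)
    n = sum(r.end - r.start for r in reads)
    assert n > 100_000
    edits = 0
    for r in reads:
        truth = genome[r.start : r.end]
        if r.strand == "-":
            truth = revcomp(truth)
        edits += edlib.align(r.sequence, truth)["editDistance"]
    rate = edits / n
    sigma = np.sqrt(0.08 * 0.92 / n)
    # the optimal alignment is a lower bound on the injected events: nearby
    # insertion/deletion pairs occasionally cancel (~2-3% of events), so the
    # band gets a 3% one-sided measurement allowance on top of 3 sigma
    assert 0.08 * 0.97 - 3 * sigma <= rate <= 0.08 + 3 * sigma


def test_generator_event_count_calibration(small_genome):
    """Injected error events are binomial at rate 1 - accuracy."""
    prof = simulate.ReadProfile("ont-like", (2000, 4000, 3000), 0.95, 20.0, seed=8)
    reads = simulate.simulate_reads(small_genome, prof)
    n = sum(r.end - r.start for r in reads)
    events = sum(r.n_errors for r in reads)
    sigma = np.sqrt(n * 0.05 * 0.95)
    assert abs(events - 0.05 * n) <= 3 * sigma


def test_reads_deterministic_under_seed(small_genome):
    prof = simulate.ont_profile(coverage=2.0, seed=4)
    prof.read_length = (2000, 4000, 3000)
    a = simulate.simulate_reads(small_genome, prof)
    b = simulate.simulate_reads(small_genome, prof)
    assert [(r.read_id, r.sequence, r.start, r.strand) for r in a] == [
        (r.read_id, r.sequence, r.start, r.strand) for r in b
    ]


def test_read_parameter_errors(small_genome):
    with pytest.raises(ValueError, match="coverage"):
        simulate.simulate_reads(small_genome, simulate.ReadProfile("ont-like", (150, 150, 150), 0.95, 0.0))
    with pytest.raises(ValueError, match="exceeds genome"):
        simulate.simulate_reads("ACGT" * 10, simulate.ont_profile(1.0))
    with pytest.raises(ValueError):
        simulate.ReadProfile("ont-like", (150, 150, 150), 1.5, 1.0)


def test_contigs_tile_genome(small_genome):
    contigs = simulate.simulate_contigs(small_genome, n_contigs=4, seed=1)
    assert contigs[0].start == 0 and contigs[-1].end == len(small_genome)
    for c in contigs:
        truth = small_genome[c.start : c.end]
        assert c.sequence == (truth if c.strand == "+" else revcomp(truth))
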