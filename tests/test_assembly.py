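"""SUNK barcoding, pair validation, tiling and contig patching."""

import numpy as np
import pytest

from sunkasm import assembly, simulate
from sunkasm.kmers import count_kmers, scan_positions
from sunkasm.seq import mutate, random_dna, revcomp
from sunkasm.sunks import SunkSet


def sunks_from_genome(genome, k=20):
    """SUNK set = the genome's true single-copy canonical k-mers."""
    table = count_kmers([genome], k)
    return SunkSet(k=k, kmers=table.kmers[table.counts == 1].copy())


@pytest.fixture(scope="module")
def genome200():
    return random_dna(200_000, np.random.default_rng(42))


@pytest.fixture(scope="module")
def sunks200(genome200):
    return sunks_from_genome(genome200)


# ---------------------------------------------------------------------------
# barcoding


def test_barcode_matches_brute_force_scan(genome200, sunks200):
    read = genome200[5_000:15_000]
    bc = assembly.barcode_read("r", read, sunks200)
    # brute force: every window whose canonical form is in the set
    pos, canon, _ = scan_positions(read, 20)
    expected = pos[sunks200.find(canon) >= 0]
    assert np.array_equal(bc.positions, expected)
    assert (np.diff(bc.positions) > 0).all()


def test_barcode_of_all_n_read_is_empty(sunks200):
    bc = assembly.barcode_read("n", "N" * 500, sunks200)
    assert bc.n_anchors == 0


def test_barcode_mirror_identity_under_revcomp(genome200, sunks200):
    read = genome200[30_000:40_000]
    fwd = assembly.barcode_read("f", read, sunks200)
    rev = assembly.barcode_read("r", revcomp(read), sunks200)
    assert set(fwd.sunk_ids.tolist()) == set(rev.sunk_ids.tolist())
    mirrored = len(read) - 20 - rev.positions[::-1]
    assert np.array_equal(fwd.positions, mirrored)
    assert np.array_equal(fwd.is_forward, ~rev.is_forward[::-1])


# ---------------------------------------------------------------------------
# candidate pairs


def test_overlapping_reads_emitted_as_candidates(genome200, sunks200):
    a = assembly.barcode_read("a", genome200[0:40_000], sunks200)
    b = assembly.barcode_read("b", genome200[10_000:50_000], sunks200)  # 30-kb overlap
    pairs = assembly.find_candidate_pairs([a, b])
    assert pairs and pairs[0][:2] == (0, 1)
    assert pairs[0][2] >= 60


def test_pairs_below_shared_threshold_not_emitted():
    # two synthetic barcodes sharing only 10 sunk ids
    def fake(read_id, ids):
        n = len(ids)
        return assembly.BarcodedRead(
            read_id, "A" * 10_000, 20,
            positions=np.arange(n) * 100,
            sunk_ids=np.array(ids), is_forward=np.ones(n, dtype=bool),
        )

    a = fake("a", list(range(60)))
    b = fake("b", list(range(50, 100)))  # 10 shared
    assert assembly.find_candidate_pairs([a, b]) == []


def test_single_read_yields_no_pairs(genome200, sunks200):
    a = assembly.barcode_read("a", genome200[:30_000], sunks200)
    assert assembly.find_candidate_pairs([a]) == []


# ---------------------------------------------------------------------------
# pair validation


def test_error_free_pair_recovers_exact_offset(genome200, sunks200):
    a = assembly.barcode_read("a", genome200[0:40_000], sunks200)
    b = assembly.barcode_read("b", genome200[12_000:52_000], sunks200)
    s = assembly.validate_pair(a, b)
    assert s is not None
    assert s.orientation == "same"
    # a shared SUNK at genome position x sits at x on read a and x - 12000
    # on read b, so the median position difference is exactly +12000
    assert s.offset_estimate == 12_000
    assert s.n_valid == s.shared_sunk_count  # every shared SUNK is valid


def test_flipped_pair_detected(genome200, sunks200):
    a = assembly.barcode_read("a", genome200[0:40_000], sunks200)
    b = assembly.barcode_read("b", revcomp(genome200[12_000:52_000]), sunks200)
    s = assembly.validate_pair(a, b)
    assert s is not None and s.orientation == "flipped"


def test_spurious_anchors_marked_invalid(genome200, sunks200):
    """Five injected wrong-position SUNK matches do not poison the offset."""
    read_b = list(genome200[12_000:52_000])
    # splice distant-genome 20-mers into read b at scattered positions
    for i, pos in enumerate((1_000, 9_000, 17_000, 25_000, 33_000)):
        distant = genome200[150_000 + i * 50 : 150_020 + i * 50]
        read_b[pos : pos + 20] = distant
    a = assembly.barcode_read("a", genome200[0:40_000], sunks200)
    b = assembly.barcode_read("b", "".join(read_b), sunks200)
    s = assembly.validate_pair(a, b)
    assert s is not None
    injected = {sid for sid in sunks200.find(
        np.array([int(c) for c in count_kmers([genome200[150_000:150_270]], 20).kmers])
    ) if sid >= 0}
    assert not injected & set(s.valid_sunk_ids.tolist())
    assert abs(s.offset_estimate - 12_000) <= 0.01 * 40_000


def test_insufficient_distance_consistency_rejected():
    """50 shared SUNKs of which only 8 agree on an offset fail the
    10-partner support rule and the pair is rejected."""
    rng = np.random.default_rng(0)
    n = 50
    pos_a = np.sort(rng.choice(20_000, size=n, replace=False)).astype(np.int64)
    pos_b = rng.permutation(20_000)[:n].astype(np.int64)  # scrambled: no consistency
    pos_b[:8] = pos_a[:8] + 5_000  # 8 mutually consistent
    ids = np.arange(n)
    a = assembly.BarcodedRead("a", "A" * 30_000, 20, pos_a, ids, np.ones(n, dtype=bool))
    order = np.argsort(pos_b)
    b = assembly.BarcodedRead("b", "A" * 30_000, 20, pos_b[order], ids[order], np.ones(n, dtype=bool))
    assert assembly.validate_pair(a, b) is None


# ---------------------------------------------------------------------------
# tiles


def _slice_reads(genome, sunks, spans):
    return [
        assembly.barcode_read(f"r{i}", genome[s:e], sunks) for i, (s, e) in enumerate(spans)
    ]


def test_three_reads_form_one_tile_with_true_offsets(genome200, sunks200):
    spans = [(0, 35_000), (30_000, 65_000), (60_000, 95_000)]
    reads = _slice_reads(genome200, sunks200, spans)
    supports = assembly.validate_pairs(reads, assembly.find_candidate_pairs(reads))
    tiles = assembly.assemble_tile(reads, supports)
    assert len(tiles) == 1
    tile = tiles[0]
    offsets = {r.read_index: m.offset for r, m in zip(tile.members, tile.members)}
    got = sorted(m.offset for m in tile.members)
    assert all(abs(o - t) <= 0.01 * 35_000 for o, t in zip(got, (0, 30_000, 60_000)))
    assert tile.span == 95_000  # error-free slices stitch exactly
    assert tile.sequence == genome200[:95_000]


def test_chimeric_read_evicted(genome200, sunks200):
    spans = [(i * 10_000, i * 10_000 + 30_000) for i in range(0, 17)]
    reads = _slice_reads(genome200, sunks200, spans)
    chimera = assembly.barcode_read(
        "chimera", genome200[0:15_000] + genome200[150_000:165_000], sunks200
    )
    reads.append(chimera)
    supports = assembly.validate_pairs(reads, assembly.find_candidate_pairs(reads))
    tiles = assembly.assemble_tile(reads, supports)
    big = max(tiles, key=lambda t: t.span)
    member_ids = {reads[m.read_index].read_id for m in big.members}
    assert "chimera" not in member_ids
    assert len(member_ids) == 17


def test_single_read_becomes_singleton_tile(genome200, sunks200):
    read = assembly.barcode_read("solo", genome200[:30_000], sunks200)
    tiles = assembly.assemble_tile([read], [])
    assert len(tiles) == 1
    assert tiles[0].sequence == genome200[:30_000]


def test_offset_consistency_invariant(genome200, sunks200):
    """Post-layout offsets honour every accepted pairwise offset."""
    spans = [(i * 12_000, i * 12_000 + 40_000) for i in range(8)]
    reads = _slice_reads(genome200, sunks200, spans)
    supports = assembly.validate_pairs(reads, assembly.find_candidate_pairs(reads))
    tiles = assembly.assemble_tile(reads, supports)
    tile = max(tiles, key=lambda t: t.span)
    offset = {m.read_index: m.offset for m in tile.members}
    for s in supports:
        if s.read_a in offset and s.read_b in offset:
            # all reads forward here: the layout offset difference must match
            # the pairwise estimate (offset_b - offset_a = median(pa - pb))
            diff = offset[s.read_b] - offset[s.read_a]
            assert abs(diff - s.offset_estimate) <= 0.01 * 40_000


# ---------------------------------------------------------------------------
# scaffold extension


def test_left_only_pool_gives_non_spanning_scaffold(genome200, sunks200):
    left_reads = _slice_reads(genome200, sunks200, [(0, 30_000), (20_000, 50_000), (40_000, 70_000)])
    supports = assembly.validate_pairs(left_reads, assembly.find_candidate_pairs(left_reads))
    tiles = assembly.assemble_tile(left_reads, supports)
    seed_tile = max(tiles, key=lambda t: t.span)
    sc = assembly.extend_scaffold(
        seed_tile, left_reads, sunks200,
        anchors=(genome200[1_000:3_000], genome200[-3_000:-1_000]),
    )
    assert sc.left_anchor_found and not sc.right_anchor_found
    assert not sc.spanning


def test_extension_reaches_both_anchors(genome200, sunks200):
    spans = [(i * 15_000, min(i * 15_000 + 40_000, 200_000)) for i in range(12)]
    reads = _slice_reads(genome200, sunks200, spans)
    supports = assembly.validate_pairs(reads[:4], assembly.find_candidate_pairs(reads[:4]))
    seed_tile = max(assembly.assemble_tile(reads[:4], supports), key=lambda t: t.span)
    sc = assembly.extend_scaffold(
        seed_tile, reads, sunks200,
        anchors=(genome200[1_000:3_000], genome200[-3_000:-1_000]),
    )
    assert sc.spanning


# ---------------------------------------------------------------------------
# contig patching


def noisy_scaffold(genome, seed=3):
    rng = np.random.default_rng(seed)
    return mutate(genome, 0.08, rng, sub_frac=0.6, ins_frac=0.2, del_frac=0.2)


def test_patching_restores_truth_over_contig_intervals(genome200, sunks200):
    scaffold = noisy_scaffold(genome200)
    contigs = {
        c.read_id: c.sequence
        for c in simulate.simulate_contigs(genome200, 5, seed=1, coverage_fraction=0.99)
    }
    patched = assembly.patch_with_contigs(scaffold, contigs, sunks200)
    assert patched.bp_from_contigs + patched.bp_from_scaffold == len(patched.sequence)
    # contig-sourced intervals reproduce the truth verbatim
    for s, e, src, name in patched.provenance:
        if src == "contig":
            seg = patched.sequence[s:e]
            assert seg in genome200 or revcomp(seg) in genome200
    assert patched.bp_from_scaffold <= 0.03 * len(patched.sequence)


def test_empty_contig_set_returns_scaffold(genome200, sunks200):
    scaffold = noisy_scaffold(genome200)
    patched = assembly.patch_with_contigs(scaffold, {}, sunks200)
    assert patched.sequence == scaffold
    assert patched.bp_from_contigs == 0


def test_reverse_complement_contig_places_identically(genome200, sunks200):
    scaffold = noisy_scaffold(genome200)
    contig = genome200[50_000:90_000]
    fwd = assembly.patch_with_contigs(scaffold, {"c": contig}, sunks200)
    rev = assembly.patch_with_contigs(scaffold, {"c": revcomp(contig)}, sunks200)
    assert fwd.sequence == rev.sequence
    assert fwd.bp_from_contigs == rev.bp_from_contigs


def test_overlapping_contig_claims_resolved_by_anchor_count(genome200, sunks200):
    scaffold = noisy_scaffold(genome200)
    big = genome200[40_000:100_000]
    small = genome200[60_000:80_000]  # fully shadowed by big
    patched = assembly.patch_with_contigs(scaffold, {"big": big, "small": small}, sunks200)
    names = {name for _, _, src, name in patched.provenance if src == "contig"}
    assert names == {"big"}


def test_provenance_partitions_assembly(genome200, sunks200):
    scaffold = noisy_scaffold(genome200)
    contigs = {
        c.read_id: c.sequence for c in simulate.simulate_contigs(genome200, 4, seed=2)
    }
    patched = assembly.patch_with_contigs(scaffold, contigs, sunks200)
    cursor = 0
    for s, e, _, _ in patched.provenance:
        assert s == cursor
        cursor = e
    assert cursor == len(patched.sequence)
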