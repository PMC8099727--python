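"""Restriction digestion, monomer decomposition, HOR units and entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sunkasm import hor, simulate
from sunkasm.seq import mutate, random_dna

XBAI = hor.RestrictionEnzyme("XbaI", "TCTAGA")
ECORI = hor.RestrictionEnzyme("EcoRI", "GAATTC")


# ---------------------------------------------------------------------------
# digestion


def test_no_site_yields_whole_sequence():
    frags = hor.in_silico_digest("ACGT" * 250, XBAI)
    assert len(frags) == 1 and frags[0].length == 1000


def test_single_site_splits_at_match_start(rng):
    seq = random_dna(1000, rng).replace("GAATTC", "GAATAC")
    seq = seq[:400] + "GAATTC" + seq[406:]
    frags = hor.in_silico_digest(seq, ECORI)
    assert [f.length for f in frags] == [400, 600]


def test_reverse_strand_site_cuts():
    # BsaI (GGTCTC) is non-palindromic, so reverse-strand matches add cuts
    enz = hor.RestrictionEnzyme("BsaI", "GGTCTC")
    seq = "G" * 300 + "GGTCTC" + "A" * 194  # forward site at 300
    frags = hor.in_silico_digest(seq, enz)
    assert [f.length for f in frags] == [300, 200]
    # in the reverse complement the site occupies [194, 200); cutting at
    # the match start places the cut at 194
    from sunkasm.seq import revcomp

    frags_rc = hor.in_silico_digest(revcomp(seq), enz)
    assert sorted(f.length for f in frags_rc) == [194, 306]


def test_invalid_iupac_symbol_rejected():
    with pytest.raises(ValueError, match="IUPAC"):
        hor.RestrictionEnzyme("bad", "ACGTZ")


def test_hor_array_digest_concentrates_at_unit_length(rng):
    """One embedded site per 11-monomer unit cuts the array into
    unit-length (1,881 bp) fragments."""
    monomers = simulate.simulate_monomer_set(simulate.MonomerSpec(11, 171, 0.2, seed=9))
    unit = "".join(monomers)
    assert len(unit) == 1881
    assert "TCTAGA" not in unit * 2
    unit = unit[:100] + "TCTAGA" + unit[106:]  # exactly one site per unit
    frags = hor.in_silico_digest(unit * 20, XBAI)
    # 20 sites -> 21 fragments: a 100-bp leader, 19 full unit-length
    # fragments, and a trailing partial unit
    interior = [f.length for f in frags[1:-1]]
    assert interior == [1881] * 19


@settings(derandomize=True, deadline=None, max_examples=30)
@given(seq=st.text(alphabet="ACGT", min_size=1, max_size=300))
def test_digest_conserves_length(seq):
    for enz in (XBAI, ECORI, hor.RestrictionEnzyme("DdeI", "CTNAG")):
        frags = hor.in_silico_digest(seq, enz)
        assert sum(f.length for f in frags) == len(seq)
        for prev, cur in zip(frags, frags[1:]):
            assert prev.end == cur.start


# ---------------------------------------------------------------------------
# decomposition


def test_printed_monomer_concatenation_decomposes_exactly(printed_monomers):
    seq = "".join(printed_monomers.values())
    ann = hor.decompose_monomers(seq, printed_monomers)
    assert hor.monomer_string(ann) == "ABCDEFGHIJK"
    assert all(a.identity == 100.0 for a in ann if not a.is_gap)
    assert all(a.strand == "+" for a in ann if not a.is_gap)


def test_mutated_concatenation_keeps_monomer_string(printed_monomers):
    rng = np.random.default_rng(17)
    seq = mutate("".join(printed_monomers.values()), 0.02, rng)
    ann = hor.decompose_monomers(seq, printed_monomers)
    assert hor.monomer_string(ann) == "ABCDEFGHIJK"
    # 2% i.i.d. substitution leaves ~98% identity per monomer; 93% allows
    # for the binomial spread of hits on a 171-bp block
    assert all(a.identity >= 93.0 for a in ann if not a.is_gap)
    assert np.mean([a.identity for a in ann if not a.is_gap]) >= 96.0


def test_short_random_sequence_is_single_gap(printed_monomers, rng):
    ann = hor.decompose_monomers(random_dna(90, rng), printed_monomers)
    assert len(ann) == 1 and ann[0].is_gap


def test_annotations_cover_sequence(printed_monomers):
    rng = np.random.default_rng(3)
    seq = random_dna(200, rng) + "".join(printed_monomers.values()) + random_dna(150, rng)
    ann = hor.decompose_monomers(seq, printed_monomers)
    assert ann[0].start == 0 and ann[-1].end == len(seq)
    for prev, cur in zip(ann, ann[1:]):
        assert prev.end == cur.start


def test_reverse_strand_monomers_detected(printed_monomers):
    from sunkasm.seq import revcomp

    seq = revcomp("".join(printed_monomers.values()))
    ann = hor.decompose_monomers(seq, printed_monomers)
    non_gap = [a for a in ann if not a.is_gap]
    assert all(a.strand == "-" for a in non_gap)
    assert "".join(a.monomer_id for a in non_gap) == "KJIHGFEDCBA"


def test_empty_monomer_set_rejected():
    with pytest.raises(ValueError):
        hor.decompose_monomers("ACGT" * 100, {})


# ---------------------------------------------------------------------------
# HOR units


def _ann_from_string(s):
    return [
        hor.MonomerAnnotation(i * 171, (i + 1) * 171, c, "+", 99.0) for i, c in enumerate(s)
    ]


def test_two_full_units():
    units = hor.call_hor_units(_ann_from_string("ABCDEFGHIJK" * 2), "A")
    assert [u.monomer_count for u in units] == [11, 11]
    assert not any(u.partial for u in units)


def test_seven_and_eleven_monomer_units():
    units = hor.call_hor_units(_ann_from_string("ABCDEFG" + "ABCDEFGHIJK"), "A")
    assert [(u.monomer_count, u.partial) for u in units] == [(7, False), (11, False)]


def test_truncated_final_unit_flagged_partial():
    units = hor.call_hor_units(_ann_from_string("ABCDEFGHIJK" + "ABCDE"), "A")
    assert [u.partial for u in units] == [False, True]


def test_leading_fragment_flagged_partial():
    units = hor.call_hor_units(_ann_from_string("HIJK" + "ABCDEFGHIJK"), "A")
    assert units[0].partial and units[0].monomer_string == "HIJK"


def test_missing_start_monomer_single_partial_unit():
    with pytest.warns(UserWarning, match="absent"):
        units = hor.call_hor_units(_ann_from_string("BCDEFG"), "A")
    assert len(units) == 1 and units[0].partial


def test_units_on_simulated_array(default_dataset):
    """Monomer-count typing recovers the generative cassette sizes."""
    ds = default_dataset
    ann_rows = ds.annotations[ds.annotations.layer != "flank"]
    truth_counts = ann_rows.groupby("unit").size()
    ann = [
        hor.MonomerAnnotation(r.start, r.end, r.monomer, "+", 100.0)
        for r in ann_rows.itertuples()
    ]
    units = hor.call_hor_units(ann, "A")
    got = [u.monomer_count for u in units if not u.partial]
    assert sorted(set(got)) == sorted(set(truth_counts.tolist()))


# ---------------------------------------------------------------------------
# entropy


def _units_of_counts(counts):
    units = []
    pos = 0
    for i, c in enumerate(counts):
        units.append(hor.HorUnit(pos, pos + c * 171, "ABCDEFGHIJK"[:c]))
        pos += c * 171
    return units


def test_entropy_single_type_is_zero():
    track = hor.hor_entropy(_units_of_counts([11] * 10))
    assert track.entropy.tolist() == [0.0]


def test_entropy_two_equal_types_is_one():
    track = hor.hor_entropy(_units_of_counts([11, 7] * 5))
    assert track.entropy.iloc[0] == pytest.approx(1.0)


def test_entropy_4321_window():
    counts = [11] * 4 + [7] * 3 + [8] * 2 + [4] * 1
    track = hor.hor_entropy(_units_of_counts(counts))
    assert track.entropy.iloc[0] == pytest.approx(1.8464, abs=1e-4)


def test_entropy_bounds_and_window_positions():
    counts = [11, 7, 8, 4] * 5
    track = hor.hor_entropy(_units_of_counts(counts))
    assert ((track.entropy >= 0) & (track.entropy <= np.log2(4) + 1e-12)).all()
    assert (track.mid == (track.start + track.end) // 2).all()
    assert len(track) == len(counts) - 10 + 1


def test_entropy_insufficient_units_warns_empty():
    with pytest.warns(UserWarning, match="complete units"):
        track = hor.hor_entropy(_units_of_counts([11] * 5))
    assert track.empty


def test_admixed_centre_has_maximal_entropy():
    """Homogeneous periphery, admixed centre: the entropy track peaks in
    the central window."""
    rng = np.random.default_rng(4)
    centre = [int(rng.choice([11, 7, 8, 4])) for _ in range(20)]
    counts = [11] * 15 + centre + [11] * 15
    track = hor.hor_entropy(_units_of_counts(counts))
    peak = track.mid[track.entropy.idxmax()]
    centre_start = track.start.min() + 15 * 11 * 171
    centre_end = centre_start + sum(c * 171 for c in centre)
    assert centre_start <= peak <= centre_end
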