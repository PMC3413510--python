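"""Cross-genome comparison, in-silico PCR and ORF scanning."""

import numpy as np
import pytest
from Bio.Seq import Seq

from orgcircle.seqio import GenomeSequence, Interval, SequenceRecord, revcomp
from orgcircle.xcompare import (PrimerPair, flank_insertion_scan, insilico_pcr,
                                orf_scan, shared_segments, similarity_fraction)

from conftest import make_genome, random_dna


def linear(seq, name="g"):
    return GenomeSequence(SequenceRecord(name, seq), "linear")


def test_planted_block_found_in_both_genomes():
    block = random_dna(100, 1)
    a = linear(random_dna(2000, 2) + block + random_dna(2000, 3), "A")
    b = linear(random_dna(1500, 4) + block + random_dna(1500, 5), "B")
    segs = shared_segments(a, b)
    assert len(segs) == 1
    s = segs[0]
    assert abs(s.interval_a.start - 2000) <= 3
    assert abs(s.interval_b.start - 1500) <= 3
    assert s.identity == 1.0


def test_block_below_min_length_not_reported():
    block = random_dna(39, 6)
    a = linear(random_dna(2000, 7) + block + random_dna(2000, 8), "A")
    b = linear(random_dna(1500, 9) + block + random_dna(1500, 10), "B")
    assert shared_segments(a, b, min_length=45) == []


def test_mask_clips_segment_into_qualifying_pieces():
    block = random_dna(200, 11)
    a = linear(random_dna(1000, 12) + block + random_dna(1000, 13), "A")
    b = linear(random_dna(500, 14) + block + random_dna(500, 15), "B")
    mask = (Interval("A", 1090, 1110),)  # 20 nt hole in the middle
    segs = shared_segments(a, b, mask_intervals=mask)
    assert len(segs) == 2
    assert all(s.interrupted_by_mask for s in segs)
    assert all(s.length >= 40 for s in segs)
    for s in segs:
        assert not (s.interval_a.start < 1110 and s.interval_a.end > 1090)
    # a mask obliterating the block removes it entirely
    segs2 = shared_segments(a, b, mask_intervals=(Interval("A", 1000, 1200),))
    assert [s for s in segs2 if s.interval_a.start >= 900
            and s.interval_a.end <= 1300] == []


def test_inverted_block_reported_on_minus_strand():
    block = random_dna(150, 16)
    a = linear(random_dna(1000, 17) + block + random_dna(1000, 18), "A")
    b = linear(random_dna(800, 19) + revcomp(block) + random_dna(800, 20), "B")
    segs = shared_segments(a, b)
    assert len(segs) == 1
    assert segs[0].interval_b.strand == "-"
    assert abs(segs[0].interval_b.start - 800) <= 3


def test_similarity_fraction_self_is_one_and_unrelated_is_zero():
    a = make_genome(3000, 21, topology="linear")
    assert similarity_fraction(a, a) == pytest.approx(1.0)
    b = make_genome(3000, 22, topology="linear")
    assert similarity_fraction(a, b) <= 0.02


def test_similarity_fraction_matches_per_base_oracle():
    rng = np.random.default_rng(23)
    shared_blocks = [random_dna(150 + int(rng.integers(200)), 500 + i)
                     for i in range(3)]
    a_parts, covered = [], []
    pos = 0
    filler = [random_dna(700, 600 + i) for i in range(4)]
    for i, blk in enumerate(shared_blocks):
        a_parts.append(filler[i]); pos += len(filler[i])
        a_parts.append(blk)
        covered.append((pos, pos + len(blk)))
        pos += len(blk)
    a_parts.append(filler[3])
    a = linear("".join(a_parts), "A")
    b = linear(random_dna(400, 700) + "".join(shared_blocks) + random_dna(400, 701),
               "B")
    frac = similarity_fraction(a, b, min_length=50, min_identity=0.80)
    mask = np.zeros(len(a), dtype=bool)
    for s, e in covered:
        mask[s:e] = True
    # exact extension can add a few chance bases at block edges
    assert frac == pytest.approx(mask.mean(), abs=0.005)


# ---------------------------------------------------------------------------
# flank insertion scan


def test_planted_insertion_length_recovered_exactly():
    left, right = random_dna(60, 24), random_dna(60, 25)
    ins = random_dna(1452, 26)
    g = GenomeSequence(SequenceRecord(
        "g", random_dna(900, 27) + left + ins + right + random_dna(900, 28)),
        "circular")
    (call,) = flank_insertion_scan(left, right, {"g": g})
    assert call.status == "insertion-present"
    assert call.intervening_length == 1452
    assert call.intervening_sequence == ins


def test_abutting_flanks_are_reference_like():
    left, right = random_dna(60, 29), random_dna(60, 30)
    g = GenomeSequence(SequenceRecord(
        "g", random_dna(500, 31) + left + right + random_dna(500, 32)), "circular")
    (call,) = flank_insertion_scan(left, right, {"g": g})
    assert call.status == "reference-like"
    assert call.intervening_length == 0


def test_missing_flank_reported():
    left, right = random_dna(60, 33), random_dna(60, 34)
    g = GenomeSequence(SequenceRecord(
        "g", random_dna(500, 35) + right + random_dna(500, 36)), "circular")
    (call,) = flank_insertion_scan(left, right, {"g": g})
    assert call.status == "flank-missing"


def test_insertion_on_reverse_strand_recovered():
    left, right = random_dna(60, 37), random_dna(60, 38)
    ins = random_dna(333, 39)
    locus = left + ins + right
    g = GenomeSequence(SequenceRecord(
        "g", random_dna(700, 40) + revcomp(locus) + random_dna(700, 41)),
        "circular")
    (call,) = flank_insertion_scan(left, right, {"g": g})
    assert call.status == "insertion-present"
    assert call.intervening_length == 333
    assert call.intervening_sequence == ins


def test_insertion_recovery_across_seeds():
    ok = 0
    for seed in range(20):
        left = random_dna(60, 4000 + seed)
        right = random_dna(60, 5000 + seed)
        n_ins = 100 + seed * 37
        ins = random_dna(n_ins, 6000 + seed)
        g = GenomeSequence(SequenceRecord(
            "g", random_dna(800, 7000 + seed) + left + ins + right
            + random_dna(800, 8000 + seed)), "circular")
        (call,) = flank_insertion_scan(left, right, {"g": g})
        ok += call.status == "insertion-present" and \
            call.intervening_length == n_ins
    assert ok == 20


def test_short_flanks_rejected():
    with pytest.raises(ValueError, match="30"):
        flank_insertion_scan("ACGT" * 5, "ACGT" * 10, {})


# ---------------------------------------------------------------------------
# in-silico PCR


def _primer_fixture(seed=42, L=20_000):
    g = make_genome(L, seed)
    fwd = g.seq[1000:1020]
    rev = revcomp(g.seq[1980:2000])
    return g, fwd, rev


def test_planted_primers_give_single_expected_amplicon():
    g, fwd, rev = _primer_fixture()
    amps = insilico_pcr(g, PrimerPair(fwd, rev))
    assert len(amps) == 1
    assert amps[0].start == 1000
    assert amps[0].length == 1000


def test_three_prime_terminal_mismatch_blocks_product():
    g, fwd, rev = _primer_fixture()
    bad_last = "A" if rev[-1] != "A" else "C"
    bad_rev = rev[:-1] + bad_last
    assert insilico_pcr(g, PrimerPair(fwd, bad_rev, max_mismatches=1)) == []
    # the same mismatch away from the 3' end is tolerated
    bad_mid = ("A" if rev[5] != "A" else "C")
    rev_mid = rev[:5] + bad_mid + rev[6:]
    assert len(insilico_pcr(g, PrimerPair(fwd, rev_mid, max_mismatches=1))) == 1


def brute_force_pcr(genome, primers):
    """Independent oracle: test every (position, strand) primer placement."""
    L = len(genome)
    seq = genome.seq + genome.seq[: primers.max_product]
    found = set()
    for fwd, rev, strand in ((primers.forward, primers.reverse, "+"),
                             (primers.reverse, primers.forward, "-")):
        rc_rev = revcomp(rev)
        f_hits, r_hits = [], []
        for i in range(len(seq) - len(fwd) + 1):
            w = seq[i : i + len(fwd)]
            mm = sum(a != b for a, b in zip(w, fwd))
            if mm <= primers.max_mismatches and w[-3:] == fwd[-3:]:
                f_hits.append(i)
        for i in range(len(seq) - len(rc_rev) + 1):
            w = seq[i : i + len(rc_rev)]
            mm = sum(a != b for a, b in zip(w, rc_rev))
            if mm <= primers.max_mismatches and w[:3] == rc_rev[:3]:
                r_hits.append(i)
        for f in f_hits:
            if f >= L:
                continue
            for r in r_hits:
                end = r + len(rev)
                length = end - f
                if length > L:
                    continue
                if len(fwd) + len(rev) <= length <= primers.max_product \
                        and r >= f + len(fwd):
                    found.add((f % L, end % L, length, strand))
    return found


def test_pcr_matches_exhaustive_placement_scan():
    rng = np.random.default_rng(44)
    g = make_genome(20_000, 45)
    fwd = g.seq[3000:3020]
    rev = revcomp(g.seq[4430:4450])
    for mm in (0, 2):
        primers = PrimerPair(fwd, rev, max_mismatches=mm, max_product=5000)
        got = {(a.start, a.end % len(g), a.length, a.strand)
               for a in insilico_pcr(g, primers)}
        assert got == brute_force_pcr(g, primers)


def test_pcr_product_count_invariant_under_rotation():
    g, fwd, rev = _primer_fixture(seed=46, L=6000)
    primers = PrimerPair(fwd, rev)
    n0 = len(insilico_pcr(g, primers))
    assert n0 == 1
    for rot in (500, 1500, 5990):
        rotated = GenomeSequence(
            SequenceRecord("r", g.seq[rot:] + g.seq[:rot]), "circular")
        assert len(insilico_pcr(rotated, primers)) == n0


def test_origin_spanning_amplicon_on_circle():
    g = make_genome(5000, 47)
    fwd = g.fetch(4500, 4520)
    rev = revcomp(g.fetch(500, 520))
    amps = insilico_pcr(g, PrimerPair(fwd, rev))
    assert len(amps) == 1
    assert amps[0].start == 4500
    assert amps[0].length == 1020


# ---------------------------------------------------------------------------
# ORF scan


def test_orf_length_boundary():
    # in-frame stop just before the start keeps the ORF anchored at our ATG
    core303 = "TAA" + "ATG" + "GCT" * 98 + "GCC" + "TAA"
    stuffer = ("CGT" * 40)[:99]  # no ATG, no stop in any frame of this repeat
    g = linear(stuffer + core303 + stuffer)
    orfs = orf_scan(g, min_length=300)
    assert any(o.length == 303 and o.interval.start == 102 for o in orfs)
    core297 = "TAA" + "ATG" + "GCT" * 96 + "GCC" + "TAA"
    g2 = linear(stuffer + core297 + stuffer)
    assert not any(o.length >= 300 for o in orf_scan(g2, min_length=300))


def brute_force_orfs(seq, min_length):
    """Oracle via protein-level regex on all six frame translations."""
    import re

    L = len(seq)
    found = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            trimmed = s[frame : frame + 3 * ((L - frame) // 3)]
            prot = str(Seq(trimmed).translate())
            for m in re.finditer(r"(?:^|(?<=\*))([^*M]*?)(M[^*]*)\*", prot):
                aa_start = m.start(2)
                nt_start = frame + 3 * aa_start
                nt_len = 3 * (len(m.group(2)) + 1)
                if nt_len < min_length:
                    continue
                if strand == "+":
                    found.add((nt_start, nt_len, "+"))
                else:
                    f_end = L - nt_start
                    found.add((f_end - nt_len, nt_len, "-"))
    return found


def test_orf_scan_matches_six_frame_translation_oracle():
    g = make_genome(10_000, 48, topology="linear")
    got = {(o.interval.start, o.length, o.interval.strand)
           for o in orf_scan(g, min_length=150)}
    assert got == brute_force_orfs(g.seq, 150)
    assert len(got) > 0


def test_orf_crossing_circular_origin_found():
    core = "TAA" + "ATG" + "GGT" * 120 + "TAA"
    stuffer = ("CGT" * 200)[:300]
    seq = stuffer + core + stuffer
    # rotate so the ORF spans the origin
    rot = 300 + 3 + 180
    g = GenomeSequence(SequenceRecord("g", seq[rot:] + seq[:rot]), "circular")
    orfs = orf_scan(g, min_length=300)
    assert any(o.length == 366 and o.interval.start > o.interval.end
               for o in orfs)
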