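"""Repeat detection, super-repeat merging, digestion and band prediction."""

import itertools
import re

import numpy as np
import pytest

from orgcircle import circularize, repeatscan
from orgcircle.repeatscan import (EAM1105I, XHOI, Enzyme, FragmentSet,
                                  RepeatPair, cut_positions, digest,
                                  find_repeats, merge_super_repeats,
                                  repeat_report, southern_predict)
from orgcircle.seqio import GenomeSequence, Interval, SequenceRecord, revcomp

from conftest import make_genome, random_dna


def plant(seq_parts):
    return GenomeSequence(SequenceRecord("g", "".join(seq_parts)), "circular")


def test_planted_direct_duplicate_found_at_truth_coordinates():
    rep = random_dna(5000, 1)
    g = plant([rep, random_dna(8000, 2), rep, random_dna(8000, 3)])
    pairs = find_repeats(g)
    assert len(pairs) == 1
    p = pairs[0]
    # exact extension may add a base or two of chance agreement at the edges
    assert p.interval1.start <= 0 + 3 and abs(p.interval1.end - 5000) <= 3
    assert abs(p.interval2.start - 13_000) <= 3 and abs(p.interval2.end - 18_000) <= 3
    assert p.length >= 5000
    assert p.orientation == "direct"
    assert p.identity == 1.0


def test_copy_below_min_length_not_reported():
    rep = random_dna(39, 4)
    g = plant([random_dna(3000, 5), rep, random_dna(3000, 6), rep,
               random_dna(3000, 7)])
    assert all(p.length < 45 for p in find_repeats(g, min_length=40)) \
        or find_repeats(g, min_length=40) == []
    # the planted 39-mer may extend by chance by a base or two, never to 45
    assert find_repeats(g, min_length=45) == []


def test_reverse_complement_copy_is_inverted():
    rep = random_dna(500, 8)
    g = plant([rep, random_dna(2000, 9), revcomp(rep), random_dna(2000, 10)])
    pairs = find_repeats(g)
    assert len(pairs) == 1
    assert pairs[0].orientation == "inverted"
    assert (pairs[0].interval1.start, pairs[0].interval1.end) == (0, 500)
    assert (pairs[0].interval2.start, pairs[0].interval2.end) == (2500, 3000)


def test_planted_recovery_across_seeds():
    """Exact planted pairs (direct or inverted) recovered in 50 fixtures."""
    rng = np.random.default_rng(11)
    hits = 0
    for trial in range(50):
        rep = random_dna(200 + int(rng.integers(400)), 1000 + trial)
        inverted = bool(rng.integers(2))
        copy2 = revcomp(rep) if inverted else rep
        g = plant([random_dna(1500, 2000 + trial), rep,
                   random_dna(1500, 3000 + trial), copy2,
                   random_dna(1500, 4000 + trial)])
        pairs = find_repeats(g)
        want = "inverted" if inverted else "direct"
        found = [p for p in pairs
                 if p.orientation == want and p.length >= len(rep)
                 and p.interval1.contains(1500) and p.interval2.contains(
                     1500 + len(rep) + 1500)]
        hits += bool(found)
    assert hits == 50


def test_no_false_pairs_on_repeat_free_sequence():
    g = make_genome(50_000, 12)
    assert find_repeats(g, min_length=40, min_identity=0.90) == []


def test_coverage_percent_arithmetic():
    rep = random_dna(100, 13)
    pairs = [RepeatPair(Interval("g", 1000, 1100, "+"),
                        Interval("g", 5000, 5100, "+"), "direct", 1.0, 100)]
    df = repeat_report(pairs, 10_000)
    assert df.loc["total", "coverage_pct"] == pytest.approx(2.0)
    assert df.loc["total", "count"] == 1
    assert df.loc["total", "direct"] == 1


def test_empty_pair_list_gives_zero_table():
    df = repeat_report([], 10_000)
    assert (df["count"] == 0).all()
    assert (df["coverage_pct"] == 0).all()


def test_coverage_matches_per_base_oracle():
    rng = np.random.default_rng(14)
    for trial in range(20):
        L = 5000
        pairs = []
        covered = np.zeros(L, dtype=bool)
        for _ in range(int(rng.integers(1, 6))):
            n = int(rng.integers(50, 400))
            s1 = int(rng.integers(0, L - n))
            s2 = int(rng.integers(0, L - n))
            pairs.append(RepeatPair(Interval("g", s1, s1 + n, "+"),
                                    Interval("g", s2, s2 + n, "+"),
                                    "direct", 1.0, n))
            covered[s1 : s1 + n] = True
            covered[s2 : s2 + n] = True
        df = repeat_report(pairs, L)
        assert df.loc["total", "coverage_pct"] == \
            pytest.approx(100.0 * covered.mean())


def test_adjacent_repeats_merge_into_one_block():
    pairs = [RepeatPair(Interval("g", 0, 100, "+"), Interval("g", 500, 600, "+"),
                        "direct", 1.0, 100),
             RepeatPair(Interval("g", 100, 250, "+"), Interval("g", 600, 750, "+"),
                        "direct", 1.0, 150)]
    blocks = merge_super_repeats(pairs, max_gap=0)
    assert [(b.start, b.end) for b in blocks] == [(0, 250), (500, 750)]
    assert blocks[0].length == 250


def test_gap_above_threshold_keeps_blocks_apart():
    pairs = [RepeatPair(Interval("g", 0, 100, "+"), Interval("g", 150, 250, "+"),
                        "direct", 1.0, 100)]
    assert len(merge_super_repeats(pairs, max_gap=10)) == 2
    assert len(merge_super_repeats(pairs, max_gap=50)) == 1


def test_merge_matches_sweep_line_oracle():
    rng = np.random.default_rng(15)
    for trial in range(20):
        ivs = []
        for _ in range(int(rng.integers(2, 10))):
            s = int(rng.integers(0, 4000))
            ivs.append((s, s + int(rng.integers(20, 300))))
        pairs = [RepeatPair(Interval("g", a, b, "+"),
                            Interval("g", a, b, "-"), "inverted", 1.0, b - a)
                 for a, b in ivs]
        gap = int(rng.integers(0, 60))
        blocks = merge_super_repeats(pairs, max_gap=gap)
        # oracle: mark positions, dilate by gap, count components
        allivs = sorted(itertools.chain.from_iterable(
            [(p.interval1.start, p.interval1.end),
             (p.interval2.start, p.interval2.end)] for p in pairs))
        merged = []
        for s, e in allivs:
            if merged and s <= merged[-1][1] + gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        assert [(b.start, b.end) for b in blocks] == \
            [tuple(m) for m in merged]


def test_mito_fixture_super_repeat_detected(mito_fixture):
    genome = mito_fixture["genome"]
    truth = mito_fixture["truth"]
    pairs = find_repeats(genome)
    blocks = merge_super_repeats(pairs, max_gap=0)
    super_truth = truth["super_blocks"]
    big = super_truth[super_truth.labels == "R2+R1+R3"]
    expected_len = int(big.iloc[0].end - big.iloc[0].start)
    assert any(abs(b.length - expected_len) <= 2 for b in blocks)


# ---------------------------------------------------------------------------
# digestion


def test_circular_fragments_sum_to_genome_length():
    g = make_genome(10_000, 16)
    for enzyme in (XHOI, EAM1105I):
        fset = digest(g, enzyme)
        if not fset.uncut:
            assert sum(fset.lengths) == 10_000
            assert len(fset.fragments) == len(cut_positions(g, enzyme))


def test_linear_digest_has_one_more_fragment_than_sites():
    seq = random_dna(2000, 17) + "CTCGAG" + random_dna(2000, 18)
    g = GenomeSequence(SequenceRecord("g", seq), "linear")
    fset = digest(g, XHOI)
    n_sites = len(cut_positions(g, XHOI))
    assert len(fset.fragments) == n_sites + 1
    assert sum(fset.lengths) == len(seq)


def test_uncut_circle_flagged():
    g = GenomeSequence(SequenceRecord("g", "ATATATAT" * 100), "circular")
    fset = digest(g, XHOI)
    assert fset.uncut
    assert fset.lengths == [800]


def test_eam1105i_matches_brute_force_iupac_scan():
    rng = np.random.default_rng(19)
    seq = random_dna(5000, 20)
    # plant a degenerate site
    seq = seq[:2000] + "GACTTTAAGTC" + seq[2011:]
    g = GenomeSequence(SequenceRecord("g", seq), "linear")
    cuts = cut_positions(g, EAM1105I)
    pattern = re.compile("GAC[ACGT][ACGT][ACGT][ACGT][ACGT]GTC")
    expected = sorted({m.start() + 6 for m in pattern.finditer(seq)})
    assert cuts == [c for c in expected if 0 < c < len(seq)]
    assert 2006 in cuts


def test_digestion_conservation_over_random_fixtures():
    """Circular fragment lengths always sum to the genome length."""
    rng = np.random.default_rng(21)
    bases = "ACGT"
    for trial in range(100):
        L = int(rng.integers(1000, 6000))
        g = make_genome(L, 5000 + trial)
        site_len = int(rng.integers(4, 9))
        site = "".join(bases[int(b)] for b in rng.integers(0, 4, site_len))
        enzyme = Enzyme(f"E{trial}", site, int(rng.integers(0, site_len + 1)))
        fset = digest(g, enzyme)
        assert sum(fset.lengths) == L


def test_enzyme_validation():
    with pytest.raises(ValueError):
        Enzyme("bad", "ACG", 1)
    with pytest.raises(ValueError):
        Enzyme("bad", "ACGTAC", 9)
    with pytest.raises(ValueError):
        Enzyme("bad", "ACGUAC", 2)


# ---------------------------------------------------------------------------
# Southern band prediction


def test_probe_inside_one_fragment_gives_exactly_that_band():
    frags = FragmentSet("circular", "XhoI",
                        [repeatscan.Fragment(0, 4000, 4000),
                         repeatscan.Fragment(4000, 10_000, 6000)])
    df = southern_predict({"mc": frags}, {"mc": Interval("g", 4500, 4700)},
                          {"mc": 10_000})
    assert list(df["band_length"]) == [6000]


def test_probe_spanning_a_cut_site_gives_two_bands():
    frags = FragmentSet("circular", "XhoI",
                        [repeatscan.Fragment(0, 4000, 4000),
                         repeatscan.Fragment(4000, 10_000, 6000)])
    df = southern_predict({"mc": frags}, {"mc": Interval("g", 3900, 4100)},
                          {"mc": 10_000})
    assert sorted(df["band_length"]) == [4000, 6000]


def test_master_circle_and_subcircles_band_pattern():
    """A probe in the shared repeat lights up bands from every conformation."""
    rng = np.random.default_rng(22)
    rep = random_dna(800, 23)
    arc1 = random_dna(3000, 24)
    arc2 = random_dna(5000, 25)
    parent = plant([rep, arc1, rep, arc2])
    pair = RepeatPair(Interval("g", 0, 800, "+"),
                      Interval("g", 3800, 4600, "+"), "direct", 1.0, 800)
    sc = circularize.enumerate_subcircles(parent, pair)
    # use an enzyme pattern cutting each conformation at least twice
    enzyme = XHOI
    seqs = {"mc1": parent, "sc1": sc.child1, "sc2": sc.child2}
    fsets, probes, lengths = {}, {}, {}
    for name, genome in seqs.items():
        fsets[name] = digest(genome, enzyme)
        pos = genome.seq.find(rep[100:200])
        probes[name] = Interval(name, pos, pos + 100)
        lengths[name] = len(genome)
    df = southern_predict(fsets, probes, lengths)
    assert set(df["conformation"]) == {"mc1", "sc1", "sc2"}
    # constructed truth: the probe overlaps exactly one fragment per
    # conformation unless a cut falls inside the probe window
    for name, genome in seqs.items():
        sub = df[df.conformation == name]
        cuts = cut_positions(genome, enzyme)
        probe = probes[name]
        inside = [c for c in cuts if probe.start < c < probe.end]
        expected = 1 + len(inside) if cuts else 1
        assert len(sub) == expected
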