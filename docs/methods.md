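# Methods

`orgcircle` finishes and validates circular organelle genome assemblies. This
note documents the models, conventions, defaults and known limitations of each
stage, and what the synthetic benchmark does and does not demonstrate.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open; report files use 1-based
inclusive positions only where labelled. Circular sequences support
origin-spanning features, stored as intervals with `start > end` and
serialised to BED as two lines sharing a name. Circular sequences are
compared in *canonical form*: the lexicographically least rotation over both
strands (computed with Booth's least-rotation algorithm), which is invariant
under rotation and reflection and idempotent.

## Contig graph and copy number

The graph dialect is TSV: `C <id> <length> <depth>` contig records and
`L <idA> <side> <idB> <side> <support>` connection records, where a side is
L (5′ of the stored strand) or R (3′). Keeping sides explicit lets the graph
represent inverted joins, which is what distinguishes an inverted repeat from
a direct one at the graph level. Connections are undirected; duplicate
unordered endpoint pairs merge with summed support.

Copy number is called from read depth. The baseline is the length-weighted
median depth of contigs whose ends both have degree ≤ 1 — the unambiguous
single-copy backbone — and each contig's copy count is `round(depth /
baseline)`, floor 1. One refinement pass removes contigs called repeat from
the baseline set and re-estimates. The call is scale-invariant in depth. If
no contig qualifies for the baseline (every end is branched), the caller must
supply a baseline depth explicitly (`classify_with_baseline`); silently
guessing would be worse. The connection-support threshold used to discard
spurious (e.g. nuclear-noise) connections has no principled default and is
exposed as a parameter, default 0.

## Master-circle enumeration

A master circle is a closed walk using every contig exactly its copy-count
times, with each step supported by a side-compatible connection. Enumeration
is exhaustive backtracking with a solution cap (default 64) and
rotation/reflection deduplication; organelle graphs are small (tens of
contigs), so completeness is preferred over clever pruning. The enumerator is
property-tested against a brute-force permutation oracle on small random
layouts.

Concatenation joins adjacent contig sequences, collapsing an exact
suffix–prefix overlap of ≥ 20 nt once per junction (longest such overlap) and
abutting otherwise; the closing junction is treated identically. Exact-only
collapsing keeps junction behaviour auditable when the upstream assembler's
junction convention is unknown.

Recombination across a *direct* repeat pair fissions the circle into two
sub-circles, each carrying one repeat copy, with child lengths summing to the
parent length; an *inverted* pair instead yields an inversion isomer —
another master circle — so `enumerate_subcircles` rejects inverted input with
an explanatory error rather than fabricating a fission product.

## Read mapping

`maplite` is a k-mer seed-and-extend mapper for desk-scale validation, not a
general-purpose aligner. Candidate loci come from shared k-mers (default
k = 17) clustered by diagonal (band 16); circular targets are extended by one
read length so placements may span the origin, with coordinates reported
modulo the genome length. Candidate windows are aligned with edlib and the
alignment is locally re-scored (match +1, mismatch −1, gap −2) with a
maximum-scoring-segment trim; because edit distance ties can prefer a gap
pair over two mismatches, the best gapless placement in the window is also
scored and the higher-scoring representation kept. Every placement passing
both thresholds — identity = matches/aligned columns, and read fraction =
aligned read bases/read length — is reported, best first. Defaults mirror the
validation thresholds used throughout: identity ≥ 0.95, read fraction
≥ 0.85.

Coverage tracks are per-base depth with windowed depth and GC fraction and
their Pearson correlation; read-origin accounting assigns each read to the
genome of its best qualifying placement, with equal-best across genomes
counted ambiguous.

## Paired-end validation

A pair *agrees* with the assembly when **any** combination of qualifying
placements of its two ends (≥ 50 aligned nt per end, the dual thresholds
above, opposite strands, inward-facing) has separation within the expected
insert range, default [1000, 5000] nt for a 3 kb jumping library. Separation
is the outer distance: from the leftmost aligned base of the forward-strand
placement along the inward arc to the rightmost aligned base of the reverse
placement. The existential ("at least once") quantification is deliberate —
repeat-induced multi-mapping must not flag a correct assembly. Pairs where
both ends place but no combination is in range *disagree*; pairs missing a
qualifying placement on either end are *not evaluable*. Disagreements are
attributed in precedence order: an end within 100 nt (configurable) of a
repeat boundary → repeat-border; an end inside a segment shared with another
organelle genome → shared-with-other-genome; otherwise unexplained.
Unexplained disagreements that cluster positionally are the signature of a
mis-join.

## Homopolymer polishing

Maximal single-base runs ≥ 5 nt are re-measured from short-read pileups.
A read votes for a site only if it fully spans the run plus one flanking base
each side and every base of that read window has quality ≥ 28 — local
quality is what certifies an observed run length. A site is rewritten only on
a strict majority (> 50 % of qualified votes, minimum 3 votes, configurable)
for a single alternative length; plurality is not enough. Edits apply right
to left; an edit map projects polished coordinates back to the draft so
later passes (re-detection to a fixpoint, cycle guard 5) keep voting against
the original alignments. Excluded intervals (e.g. regions verified
independently) are reported but never altered. The error report tabulates
sites, cumulative run length, corrected sites and corrected length by coding
status, with percent error = 100 × corrected length / cumulative run length.

## Replicate consensus

Replicates of one circle are first normalised — rotated and strand-flipped so
a user-supplied anchor (unique per replicate, either strand) starts at
position 0 — then merged: k-mers (k = 21) unique within every replicate and
shared by all are chained colinearly as anchors (uniqueness suppresses
repeat-induced false anchors), and inter-anchor blocks are column-voted,
pairwise-aligning a block against the first replicate carrying sequence there
when lengths differ. Masked (`N`) positions do not vote; ties emit IUPAC
ambiguity codes and are listed rather than resolved arbitrarily. Guard
rails: pairwise identity of replicates must be ≥ 95 % (N treated as
matching), and the anchor chain must span ≥ 50 % of the median replicate.

## Repeats, digestion and band prediction

Repeat detection is k-mer-seeded (k = 14) self-comparison against the genome
and its reverse complement, chaining seeds on a common diagonal (gap ≤ 30
nt), extending exactly outward, and scoring identity over aligned columns
with edlib; defaults min length 40 nt, min identity 0.90. The self-diagonal
is excluded and mirror pairs are reported once; orientation comes from the
strand of the second copy; layout-adjacent copies are flagged tandem but
reported uniformly. Note the scan runs on the linearised circle, so a repeat
copy spanning the sequence origin would be missed; rotate the genome if that
matters. Same-diagonal chaining means large indel-containing repeats are
reported as separate pairs rather than one gapped pair.

Digestion expands IUPAC recognition sites on both strands
(palindrome-aware), cuts at the enzyme's offset, and assembles fragments per
topology: a circle with *s* ≥ 1 sites gives *s* fragments summing exactly to
the genome length; a linear molecule gives *s* + 1; an uncut circle gives one
flagged pseudo-fragment. Shipped enzymes: XhoI (C^TCGAG) and Eam1105I
(GACNNN^NNGTC). A predicted hybridisation lane is the union over co-existing
conformations (master circle plus recombination sub-circles) of fragments
overlapping the probe by ≥ 1 nt.

## Cross-genome comparison and transfer detection

Shared segments reuse the seed-chain-extend machinery across two genomes
(both strands of B), clipped at masked positions of A (defaults 40 nt /
0.90); the genome similarity fraction is the unioned coverage of qualifying
segments on A (defaults 50 nt / 0.80). The flank-anchored insertion scan
locates both flanks of a candidate insertion locus in each target genome with
the mapper and reports the intervening stretch: `insertion-present`,
`reference-like` (abutting), `flank-missing`, or `ambiguous` when equal-best
placements tie. In-silico PCR matches primers with a mismatch budget but
requires an exact 3′-terminal 3-mer (the standard proxy for extension
competence); amplicon length is 5′-to-5′ inclusive, the convention gel sizes
use, and circular templates allow origin-spanning products. The ORF scanner
is start-codon-initiated (ATG) and stop-terminated, length counted including
the stop codon, ≥ 300 nt by default, all six frames, with origin-crossing
frames handled by scanning the doubled circle.

## Synthetic benchmark: what it emulates and what it does not

The generator builds a circular genome from an explicit block layout. The
default emulates the structure of a small plant mitochondrial genome: five
single-copy regions (A–E) and four large repeats, with R1 between R2 and R3
forming a direct super-repeat present twice, and R4 present twice with the
second copy inverted, both R4 copies on the same arc between the super-repeat
copies. That last choice is structural: with the inverted pair inside one
arc, direct-repeat recombination products cannot re-fuse into additional
master circles, and the graph admits exactly two conformations (the original
and the inversion isomer across R4) — the two-master-circle structure the
fixture is meant to emulate. Default block sizes total 43 kb (scale 1.0);
tests and the acceptance script run at scale 0.1–0.25 (4.3–10.75 kb) to keep
suites fast; the structural properties being tested (conformation counts,
conservation laws, recovery rates) do not depend on absolute size.

Read models: long reads (length ~N(380, 60²)) with ±1 nt homopolymer length
errors at a configurable per-run rate; short accurate reads (100 nt,
substitution rate 0.001, qualities ~N(38, 2²)) with optional GC-dependent
start-position bias `w ∝ exp(−b·GC(window))`; inward-facing 3 kb ± 300 read
pairs. The draft-distortion generator plants ±1 errors at runs ≥ 5 nt,
lengthening runs at exactly 5 (a shortened 5-run leaves the detectable-run
universe and is invisible to run-directed correction — a genuine limitation
of the method, not of the simulation). All generators are deterministic
under an explicit seed; no global random state.

What passing the synthetic suite does **not** show: real pyrosequencing
error structure (flowgram noise, indels outside runs, chimeras), real
GC-coverage response curves, heterogeneous repeat families at sub-identity,
or biological heteroplasmy. The arithmetic checks on published counts verify
the reporting conventions, not the upstream measurements.

## Numerical and degenerate-input choices

Ties in copy-number rounding go to `round()` (banker's at .5 — depths that
close to a boundary are genuinely ambiguous and surface in the depth-ratio
field). Mapper candidate clusters are capped at 64 per read; enumeration
caps at 64 solutions with a warning. Empty FASTA files parse to empty lists;
an uncut circular digestion, a probe absent from a conformation, and a seed
matching no contig each produce an explicit flagged result or error rather
than silence. The CLI exposes every threshold as a flag with the defaults
above; precedence is flag over default, and `orgcircle run` writes a JSON
manifest (seed, thresholds, digests) so runs are reproducible byte for byte.
A separate config-file layer was considered and dropped: at this surface
area, flags plus the manifest give the same auditability with less
machinery.
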