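# Methods

`novelmine` re-implements, at desk scale and with full ground truth, the
pseudo-de novo analysis of unmapped whole-genome resequencing reads: reads
that fail to align to a reference are assembled into contigs, the contigs
are screened for quality and novelty, placed back onto the reference using
one-end-anchored (OEA) read pairs, and intersected with assembly gaps and
gene models to quantify how much missing reference sequence the novel
contigs recover.  This note documents the models, the parameter choices,
and the places where the design was genuinely open.

## The synthetic study

Real studies of this kind compare tens of resequenced individuals against a
reference built from a single individual; their headline counts depend on
those specific genomes and are not reproducible at desk scale.  The
synthetic-data module therefore defines a *standard study* whose structure
mirrors the analysis assumptions, with every planted event recorded in a
truth table:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 2 Mb | reference size (single chromosome by default) |
| `n_gaps` | 10 | assembly gaps, emitted as N-runs of 300–800 bp |
| `n_novel_at_gap` | 5 | gaps whose true sequence the donor restores (`gap_fill`) |
| `n_novel_nongap` | 5 | donor-specific insertions at non-gap loci, 1–3 kb |
| `read_length` / `insert_mean` / `insert_sd` | 100 bp / 290 bp / 30 bp | Illumina-like paired-end geometry |
| `coverage` | 10× per sample | sequencing depth |
| `base_error_rate` | 0.2 % | uniform substitution errors |
| `snp_rate` | 0.1 % | donor-vs-reference SNPs outside novel segments; a realistic within-population divergence scale |
| `n_samples` | 3 | individuals sequenced from the same donor genome |

Gaps are placed at least `2·insert_mean` from the sequence ends and from
each other (in practice ≥ 2 kb, to leave room for the gene scaffolds built
around genic gaps).  Alternating gaps are made genic by constructing a gene
around them so the gap falls inside an intron, inside an exon, or inside an
ncRNA, cycling through the three classes; the remaining gaps are
intergenic.  Gene models carry ≥ 2 exons, introns, and 50 bp terminal UTRs;
splice sites are modelled downstream as the 2 bp at each intron end.
Simulated BAC clone inserts cover 70 % of the gaps by default.

Read simulation draws fragment starts uniformly and insert lengths from
`Normal(insert_mean, insert_sd)` truncated to ≥ `read_length`; mate 1 is
the fragment's 5′ read and mate 2 the reverse complement of its 3′ end.
Fragments overlapping an N-run are redrawn — a sequencer reads molecules,
and no molecule consists of Ns — so unfilled gaps produce no reads.
Qualities are constant phred 37, except that a configurable fraction of
reads (10 %) carries a low-quality tail (phred 2, ≤ 30 bp, 10 % error) so
the trimming stage has real work to do.  Read names encode the true
fragment coordinates, which several tests use as an oracle.

What the generator deliberately does **not** model: indel and
structural-variant sequencing errors, PCR duplicates, GC-coverage bias,
repeat families, or contaminant genomes (beyond an optional labelled extra
FASTA).  Passing tests therefore demonstrate the correctness of the
pipeline's logic and geometry under clean, repeat-poor conditions — not its
robustness to repetitive real genomes, where ambiguous mapping and
mis-assembly dominate and the mapq and min-support filters would carry far
more weight.

## Trimming and triage

Trimming follows the cited sliding-window semantics: bases at or below
phred 3 are clipped from both ends, the read is scanned 5′→3′ in 4-base
windows and cut at the first window whose mean phred drops below 20, and
survivors shorter than 50 bp are discarded.  Two refinements make the
operation well behaved: individually good bases at the cut point are kept
(a good base dragged down by bad followers survives, matching the reference
trimmer's behaviour), and the clip–scan–clip cycle iterates to a fixpoint
so trimming is provably idempotent.

Each aligned pair receives exactly one class: `MAPPED_CONCORDANT` (both
mates on one target, forward/reverse, implied insert within ±50 % of the
expectation), `OEA` (exactly one mate aligned), `BOTH_UNMAPPED`, or
`DISCARDED` (a mate removed by trimming).  Discordant both-mapped pairs
join the assembly pool by default — they did not align concordantly — with
a flag to exclude them.  Class counts always sum to the number of input
pairs.

## The micro-mapper

A deliberately small seed-and-extend mapper stands in for a production
aligner (external SAM can be substituted at every stage).  Targets are
2-bit packed into a sorted k-mer array (k = 21, N-containing windows never
indexed); reads are seeded at five offsets on both strands, candidate
diagonals are scored by gapless mismatch counting, and a banded
edit-distance alignment (edlib) around the best seeded diagonal is the
fallback when the gapless score fails, so small indels do not fail a read
outright.  Mapping quality is a deliberate three-valued surrogate — 60
(unique, no close second), 30 (unique, weaker second), 0 (tied) — because
the pipeline only ever consumes the `mapq ≥ 30` threshold; a calibrated
probabilistic MAPQ is out of scope.

The local aligner is an exact Smith–Waterman with linear gap costs
(match +2, mismatch −2, gap −3), vectorised row-wise with a running-max
trick that collapses within-row gap chains.  Instances larger than ~4 M
cells are seeded with 16-mers and the DP runs on windows around candidate
diagonals.  Its best score is checked against an independent
Smith–Waterman implementation on small random instances in the test suite.

## Assembly

The two-tier assembler is a greedy overlap-layout-consensus: qualifying
overlaps (exact 14-mer seeded, gaplessly verified at ≥ 97 % identity over
≥ 40 bp for reads, ≥ 100 bp for contig merging, containment always
allowed) are merged longest-first, with deterministic tie-breaks following
lexicographic input-id order, so input order never matters.  The consensus
is a per-column weighted majority with base weights `1 + phred/1000` —
quality breaks ties but never outvotes coverage.  Overlap verification is
gapless by design: the simulator's error model is substitution-only, so a
gapped overlap extension would have nothing to align.

The secondary tier pools every sample's primary contigs (each weighted by
its supporting read count) and re-assembles them; secondary contigs
supported by a single primary contig from a single sample are binned as
debris, since they cannot be distinguished from sample-private noise.  A
minimum-length debris filter (off by default) is exposed for parity with
assemblers whose debris definition also covers short contigs.

## Contig QC and the novelty screen

GC, DUST, and entropy are whole-contig triplet statistics on a 0–100 scale
(definitions in `qc.py`); one score is reported per contig, with a
windowed mode (64-base windows, step 32, max over windows) available for
parity with windowing QC tools.  Scores are clamped to [0, 100] against
floating-point spillover.  The thresholds DUST > 7 or entropy < 70 flag a
contig low-complexity; the flags are report-only by default because the
source analysis reports the distributions rather than applying a hard
filter.  Exact duplicates (including reverse complements) collapse to the
lexicographically smallest id, making deduplication order-independent.
The optional contaminant screen flags a contig when ≥ 50 % of its
canonical 31-mers occur in a user-supplied contaminant k-mer set.

The novelty screen removes contigs present in the reference at 100 %
identity and 100 % coverage.  "100 % coverage" is read strictly: every
base of the contig participates in a single ungapped exact match, so exact
containment is decided by literal string search in both orientations and
no alignment is needed.  Contigs with high-identity partial hits (≥ 90 %
identity over ≥ 50 bp) are PARTIAL and retained with their best identity
and coverage reported — retention requires failing the exact test, and
whether the original refinement also removed strong partial hits is not
stated, so the choice is left to the user.  Cross-sample support maps an
outgroup read set (reads from the reference individual) onto the contigs;
contigs representing reference errors or gaps attract outgroup coverage
while group-specific novel sequence does not.

## OEA placement geometry

The fragment-length arithmetic that projects a contig onto the genome from
one anchor is spelled out in `placement.py` and is validated by a
round-trip oracle: simulating one error-free OEA pair from a known
placement and inverting it recovers the placement exactly in all four
strand configurations.  Only self-consistent geometry passes that oracle,
which is how the under-specified "cross-referencing" step was resolved.

Clustering needed one non-obvious decision.  Anchors from the two
junctions of a **gap fill** agree on the contig's genome start (the filled
gap occupies reference space), but anchors from the two junctions of a
**pure insertion** disagree by the insertion length, because the insertion
occupies no reference space.  Clustering raw predicted starts within a
fixed radius would therefore split every insertion longer than the radius
into two loci.  Instead, single linkage joins anchors whose predicted
intervals overlap (link distance `max(2·insert_mean, contig_length)` on
predicted starts), and the reported locus interval is the intersection of
the median left-junction (genome-mate `+`) and median right-junction
(genome-mate `-`) predictions.  For a gap fill this reduces to the median
interval; for an insertion the interval collapses to the flank-supported
region around the insertion point, so the locus midpoint lands at the
insertion site regardless of how unevenly the two junctions are sampled.
`min_support = 2` anchors per locus suppresses singleton mismaps; the
radius exceeds the insert-length variability by design.

Verification realigns the contig against the reference window (locus ±
2·insert_mean) and requires a local alignment of score ≥ 60 with ≥ 40
matched bases overlapping the predicted interval.  An anchor-strength
criterion is used instead of a whole-alignment identity threshold because
a novel-insertion contig matches only at its junction-spanning flanks, and
the local optimum may extend a perfect ~80 bp flank match a short way into
the novel interior, diluting whole-alignment identity while leaving the
anchor itself unambiguous.

## Gap accounting

Reference gaps are maximal N-runs (regex scan, checked against a per-
character oracle) or a user BED.  A *gap contig* overlaps a gap by ≥ 1 bp;
a gap is *closed* when the union of overlapping placed contigs covers it
entirely — two deliberately distinct definitions, so partially filled
sequence and fully closed gaps are both countable.  Genic gaps overlap an
exon, splice site (2 bp intron ends), UTR, intron, or ncRNA.  A contig
overlapping two gaps counts once in the gap-contig total; per-(contig,
gap) detail stays in the per-gap rows.  Gap contigs without BAC-insert
overlap form the novel-no-BAC set; with no BAC file supplied, every gap
contig is novel-no-BAC.

## Numerical and degenerate-input choices

All internal coordinates are 0-based half-open; BED is written natively
and GFF3 converted at the boundary.  All randomness flows from a single
integer seed through `numpy` seed sequences, and every stage writes its
outputs to plain files, so two runs with one seed are byte-identical and
the pipeline can resume from any stage.  Degenerate inputs are explicit:
an infeasible simulation configuration raises instead of silently
truncating; an all-N sequence has undefined GC; sequences shorter than 3 bp
have undefined complexity scores; an empty contig set yields all-zero
assembly statistics; a donor identical to the reference completes the
pipeline with an explicit "no novel sequence" summary.

## Problem sizes

The default study (2 Mb, 3 samples × ~50 k pairs) runs end to end in about
a minute on one core, and the full test suite — including one complete
study — in under two; these sizes were chosen as the smallest at which
every stage (triage, two assembly tiers, screening, placement, closure)
still operates on non-trivial input.  Larger genomes and depths scale
roughly linearly in read count for triage and placement and are dominated
by the k-mer index and the greedy assembler beyond that.

## Known limitations

Greedy OLC mis-assembles repetitive pools that a multipass assembler would
resolve; the mapper's three-valued mapq has no probabilistic calibration;
placement does not refine breakpoints to base resolution, does not
genotype insertion presence/absence across samples, and reports both loci
of a two-locus contig without reconciling them; taxonomic contaminant
identification is reduced to a user-supplied k-mer screen; and no
patch-FASTA of a gap-filled reference is produced.
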