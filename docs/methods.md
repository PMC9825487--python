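# Methods

## Coordinates and sequence conventions

All internal coordinates are 0-based, half-open, in transcript orientation;
GTF (1-based inclusive) and VCF (1-based) are converted at the I/O boundary
only.  Sequences are stored as DNA (ACGT), so codon matching uses ATG, not
AUG, uniformly.  The CDS span of a transcript is the min–max of its CDS
features, extended by `stop_codon` features when the annotation keeps the
stop outside the CDS (GENCODE convention); the 5′UTR is everything upstream
of the CDS start in transcript coordinates.  Transcripts with annotated but
incomplete CDS (e.g. `cds_start_NF` tags) are kept and carry their tags.
Coordinate projection (`tx_to_genome` / `genome_to_tx`) is exact and tested
per base against exhaustive enumeration; genomic blocks are reported in
ascending genomic order.

## Candidate uORF model

A candidate uORF starts at any occurrence of ATG/CTG/GTG/TTG/ACG strictly
upstream of the CDS start and runs in frame to the first TAG/TGA/TAA.  The
minimum length default of 18 nt is interpreted as *coding* sequence (six
amino acids), excluding the stop codon, and is configurable.  Categories
are fully determined by the stop position and frame: stop at or before the
CDS start → non-overlapping; past it out of frame → overlapping; in frame →
N-terminal extension, which by construction shares the CDS stop.  An
in-frame start with no intervening stop is rescued as an extension ending
at the annotated CDS stop; an out-of-frame ORF that reaches the transcript
end without a stop is discarded — it is not a start-to-stop ORF.  ORFs
starting at or after the CDS start are never emitted, which implements the
rule that ORFs entirely overlapping the CDS are not uORFs.  Translation
renders the first codon as methionine regardless of near-cognate identity
(initiator tRNA delivers Met), giving a deterministic peptide contract.

Kozak context is AUG-anchored: strong iff the −3 base is A/G *and* the +4
base is G; moderate iff exactly one holds; weak otherwise.  Non-ATG starts,
and starts whose −3 base falls outside the transcript, are
`not_applicable` rather than being forced into a class the motifs do not
define.

uORFs with identical genomic blocks (and start codon) across isoforms of a
gene are collapsed into one record listing all supporting transcripts,
keyed by the lexicographically smallest transcript id.

## P-site assignment

The P-site of a ribosome-protected fragment (RPF) is its 5′ end plus a
length-dependent offset.  Offsets are estimated per read length L as the
argmax over offsets o ∈ [10, L−10] of the number of reads whose 5′ end + o
lands exactly on an annotated CDS start, with ties broken toward the
smaller offset; length classes with fewer than 500 reads, or with no
CDS-anchored evidence, fall back to 12 nt and are flagged.  This
CDS-start-anchoring derivation is the toolkit's own design and can be
overridden with a user-supplied two-column offset table.  The absolute
offset (not merely its frame class) is identifiable because initiation
codons carry a coverage pileup; a library with perfectly uniform CDS
coverage would determine the offset only modulo 3.  Reads outside the
27–32 nt filter (default, configurable) are excluded; within the filter,
P-site counts are conserved exactly.

Soft-clipped alignments are excluded (the 5′ end would be unreliable), as
are multimappers (NH > 1) and antisense transcript-space hits.  Genome-space
reads are projected through the exon structure of every same-strand
transcript overlapping their biological 5′ end (reference start on the plus
strand, reference end − 1 on the minus strand); intronic 5′ ends are
dropped.  A plain P-site TSV dialect (`transcript_id`, `tx_pos`,
`read_length`, `count`) makes the whole downstream path testable without an
aligner.

## Library QC

Three admission gates, all configurable:

- **size** — collapsed FASTA > 5,000,000 bytes of the file as given, or, for
  in-memory input, total read count ≥ 100,000.  The byte rule mirrors the
  file-based criterion used when screening public libraries; the count
  floor is its testable in-memory proxy.
- **length** — ≥ 90% of reads within 26–34 nt *and* modal length within
  27–32 nt (ties toward the smaller length).  The 90% tolerance
  operationalises "distribution within 26–34 nt": demanding literally all
  reads in range would fail essentially every real library.
- **frame** — over CDS-internal P-sites, with frame defined as
  (p − cds_start) mod 3, frame 0 must be modal and hold strictly more than
  50% of the signal.  A fraction of exactly 0.5 fails.

The metagene profile normalises each transcript's P-site density to mean 1
over the transcript, linearly rebins the 5′UTR/CDS/3′UTR into 50/100/50
bins by fractional overlap, and averages per bin over the transcripts that
have the region.

## Active-translation calling

Within a candidate's span (stop codon included), with n P-sites of which k
are in the uORF's own frame:

- `f0u = k/n`, with an upper-tail exact binomial test of k against the
  uniform null p = 1/3 (scipy's `binomtest`);
- `PME = H(c)/log(m)` where c are the per-codon P-site counts over the m
  codons of the scored span and H is Shannon entropy (0·log 0 = 0): 1 for
  perfectly even coverage, 0 for a point mass;
- score = `f0u × PME`; active ⇔ n ≥ 10 ∧ p < 0.05 ∧ score ≥ 0.5.

The score is a transparent periodicity-and-uniformity statistic designed
for this toolkit; it is not a replica of externally trained ORF classifiers,
and no equivalence is claimed.  The 0.5 threshold, 0.05 alpha and 10-read
floor are the shipped defaults, all user-adjustable.  The read floor exists
because a score from one or two P-sites is meaningless.  The score is
invariant to multiplying all counts by a positive constant; the p-value is
not — more depth buys power, which is the point of a significance gate.
For overlapping and extension uORFs, only whole codons upstream of the CDS
start are scored so that main-ORF signal cannot inflate the uORF's score;
such calls are flagged `cds_masked`.  Degenerate cases: zero P-sites or a
masked span shorter than one codon give score 0, inactive; a one-codon
span defines PME = 1.

Among active calls sharing a stop codon on one transcript, the
representative is chosen by ordering AUG starts first (ascending position),
then near-cognate starts, and advancing down the order whenever zero
(offset) P-sites fall between the current and next start; the first
candidate that fails to advance wins.  When a group has no AUG start the
same closest-to-5′ rule applies over near-cognate starts.  Exactly one
representative is flagged per non-empty group.

## Variant-effect annotation

Variants are projected per transcript; a (variant, transcript) pair is kept
when the reference span is fully exonic and begins in the 5′UTR.  The
alternate allele is applied in transcript space (reverse-complemented on
minus-strand transcripts after an exact REF check — a mismatch raises an
error flagging annotation/genome inconsistency) and candidates are
re-enumerated on the mutated sequence.  Effects per affected uORF follow
the precedence start/stop changes > frameshift > Kozak change; a gained
start is reported only when the variant itself creates the start codon of
a new valid candidate.  Deletions spanning the UTR/CDS boundary are flagged
out of 5′UTR scope rather than silently dropped.  Indels that straddle an
exon junction are rejected as unsupported geometry.  Effects are annotated
against all candidates by default (an active-set restriction can be applied
by the caller by passing a filtered candidate list).

## Synthetic data

The generator emulates the conditions the toolkit is validated under:
transcriptomes of single- to three-exon transcripts on both strands (5′UTR
90–240 nt, CDS 150–450 nt, 3′UTR 60–180 nt by default), planted uORFs of
each category (60 nt for non-overlapping by default; overlap planting uses
a 20 nt upstream portion, extensions 21 nt), and RPF libraries at 1
P-site/nt of translated region with frame-0 probability 0.9, a length
distribution peaking at 28 nt within 27–32 nt, per-length offsets
(default 12 nt) and a 5× initiation-codon pileup.  Untranslated planted
uORFs receive only frame-uniform background at 0.05 P-sites/nt, so they
fall below the caller's read floor at realistic spans — distinguishing
"silent" from "translated" the way a real library would.

Clean 5′UTR backgrounds use a start-codon-suppressed alphabet ({A,C,T}:
every accepted start codon contains G) with TAA excluded from in-frame body
codons, which *guarantees* the planted uORFs are the only candidates; the
element junctions were chosen so no start codon can form across them.
Because of this, passing truth-recovery tests demonstrates correctness of
the machinery on unambiguous inputs — they do not measure performance under
the nucleotide composition, overlapping-ORF density, or coverage biases
(ligation, nuclease, ramp effects) of real libraries, which the generator
deliberately does not model.  A single integer seed drives everything
through per-transcript split generator streams, so outputs are
byte-identical across runs and insensitive to iteration order.
Variant planting engineers one variant per transcript (stop-codon effects
claim non-overlapping uORFs first); frameshift insertions are planted on
plus-strand transcripts only, where the anchored-indel genome coordinates
are unambiguous.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use 30-transcript transcriptomes
at depth 1 P-site/nt for end-to-end recovery, 500 random transcripts for
enumeration-oracle equivalence, 1000 random spliced models for coordinate
round-trips, 1000 simulated uORFs each for caller calibration and power,
200 random shared-stop groups for representative uniqueness, 30 planted
variants (5 per class) plus ≥ 200 random variants against the
re-enumeration oracle, and six length classes for exact offset recovery —
sizes at which every check is exact or has negligible Monte-Carlo error
while the whole suite runs in seconds.

## Known limitations

- QC thresholds assume RPF-sized fragments; the gates are not meaningful
  for e.g. 40S-footprint or disome data.
- The caller scores each uORF independently; overlapping uORFs sharing
  P-sites are not deconvolved.
- Offset estimation needs initiation-peak signal; harringtonine/LTM-free
  libraries with flat CDS coverage resolve offsets only modulo 3 and fall
  back to the default for the remaining ambiguity.
- Variant annotation handles one variant at a time; compound haplotypes are
  out of scope, as are consequence predictions beyond uORF structure.
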