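"""Candidate uORF enumeration, classification and annotation.

A candidate uORF is a start-to-stop ORF whose start codon lies in the 5′UTR
(strictly upstream of the main CDS start).  Starts are ATG plus the four
most frequently used near-cognate codons (CTG/GTG/TTG/ACG); stops are
TAG/TGA/TAA.  Candidates fall into exactly one of three categories:

* ``non_overlapping`` — the stop lies at or before the CDS start,
* ``overlapping_out_of_frame`` — the ORF runs past the CDS start in a
  shifted reading frame,
* ``n_terminal_extension`` — the ORF is in frame with the CDS and shares
  its stop codon, extending the protein N-terminus.

ORFs that begin at or after the CDS start are never uORFs and are not
enumerated.  The minimum length is 18 nt of coding sequence (six amino
acids), excluding the stop codon.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .transcript_model import TranscriptModel, TranscriptSequence, tx_to_genome

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = ("ATG", "CTG", "GTG", "TTG", "ACG")
CATEGORIES = ("non_overlapping", "overlapping_out_of_frame", "n_terminal_extension")
KOZAK_CLASSES = ("strong", "moderate", "weak", "not_applicable")


@dataclass(frozen=True)
class CandidateUORF:
    uorf_id: str
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    start_codon: str
    category: str
    frame_vs_cds: int
    peptide: str
    kozak: str
    genomic_blocks: tuple[tuple[int, int], ...]
    member_transcripts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.tx_end - self.tx_start) % 3 != 0:
            raise ValueError("uORF length must be a multiple of 3")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def length_nt(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3


def classify(tx_start: int, tx_end: int, model: TranscriptModel) -> str:
    """Assign one of the three uORF categories from span and frame alone."""
    if tx_start >= model.cds_tx_start:
        raise ValueError("uORF must start in the 5'UTR")
    if tx_end <= model.cds_tx_start:
        return "non_overlapping"
    if (tx_start - model.cds_tx_start) % 3 == 0:
        return "n_terminal_extension"
    return "overlapping_out_of_frame"


def translate_orf(seq: str, tx_start: int, tx_end: int, include_stop_codon: bool = True) -> str:
    """Translate an ORF; the first codon yields initiator Met regardless of
    near-cognate identity, and the stop codon is not included in the peptide."""
    coding_end = tx_end - 3 if include_stop_codon else tx_end
    body = seq[tx_start + 3 : coding_end]
    return "M" + str(Seq(body).translate(table=1))


def kozak_strength(seq: str, tx_start: int, start_codon: str) -> str:
    """Kozak context class of a start codon from the -3 and +4 positions.

    strong: [AG]NNATGG; moderate: [AG]NNATGN or NNNATGG; weak: NNNATGN.
    Non-ATG starts, or starts whose -3 base falls outside the transcript,
    are ``not_applicable`` (the motifs are AUG-anchored).
    """
    if start_codon != "ATG":
        return "not_applicable"
    if tx_start < 3 or tx_start + 4 > len(seq):
        return "not_applicable"
    minus3 = seq[tx_start - 3]
    plus4 = seq[tx_start + 3]
    good_minus3 = minus3 in "AG"
    good_plus4 = plus4 == "G"
    if good_minus3 and good_plus4:
        return "strong"
    if good_minus3 or good_plus4:
        return "moderate"
    return "weak"


def _make_uorf_id(transcript_id: str, tx_start: int, tx_end: int, start_codon: str) -> str:
    return f"{transcript_id}:{tx_start}-{tx_end}:{start_codon}"


def enumerate_candidates(
    model: TranscriptModel,
    seq: TranscriptSequence | str,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    min_len_nt: int = 18,
) -> list[CandidateUORF]:
    """Enumerate all candidate uORFs of one transcript.

    Every occurrence of a start codon strictly upstream of the CDS start is
    scanned in frame for the first stop codon.  ORFs with at least
    ``min_len_nt`` nucleotides of coding sequence (stop excluded) are
    emitted.  In-frame starts with no intervening stop run into the CDS and
    terminate at its stop (N-terminal extensions); out-of-frame ORFs that
    reach the transcript end without a stop are discarded (not
    start-to-stop).  A transcript without a 5′UTR yields no candidates.
    """
    s = seq.seq if isinstance(seq, TranscriptSequence) else seq
    start_set = frozenset(c.upper() for c in start_codons)
    cds_start = model.cds_tx_start
    out: list[CandidateUORF] = []
    for p in range(cds_start):
        codon = s[p : p + 3]
        if codon not in start_set:
            continue
        tx_end = None
        q = p + 3
        while q + 3 <= len(s):
            if s[q : q + 3] in STOP_CODONS:
                tx_end = q + 3
                break
            q += 3
        in_frame = (p - cds_start) % 3 == 0
        if tx_end is None:
            # ran off the transcript without a stop: only an in-frame start
            # is rescued, as an extension ending at the annotated CDS stop
            if not in_frame:
                continue
            tx_end = model.cds_tx_end
            if (tx_end - p) % 3 != 0:
                continue
        if tx_end - 3 - p < min_len_nt:
            continue
        category = classify(p, tx_end, model)
        peptide = translate_orf(s, p, tx_end)
        out.append(
            CandidateUORF(
                uorf_id=_make_uorf_id(model.transcript_id, p, tx_end, codon),
                transcript_id=model.transcript_id,
                gene_id=model.gene_id,
                chrom=model.chrom,
                strand=model.strand,
                tx_start=p,
                tx_end=tx_end,
                start_codon=codon,
                category=category,
                frame_vs_cds=(p - cds_start) % 3,
                peptide=peptide,
                kozak=kozak_strength(s, p, codon),
                genomic_blocks=tuple(tx_to_genome(model, p, tx_end)),
                member_transcripts=(model.transcript_id,),
            )
        )
    return out


def collapse_isoforms(candidates: Iterable[CandidateUORF]) -> list[CandidateUORF]:
    """Merge uORFs with identical genomic coordinates across isoforms.

    Records whose (chrom, strand, genomic block list, start codon) agree are
    collapsed into one, listing every supporting transcript; the merged
    record keeps the identity of the lexicographically smallest
    transcript_id.  Output is deterministically ordered.
    """
    groups: dict[tuple, list[CandidateUORF]] = {}
    for c in candidates:
        key = (c.chrom, c.strand, c.genomic_blocks, c.start_codon)
        groups.setdefault(key, []).append(c)
    merged: list[CandidateUORF] = []
    for group in groups.values():
        group.sort(key=lambda c: c.transcript_id)
        members = tuple(
            sorted({t for c in group for t in (c.member_transcripts or (c.transcript_id,))})
        )
        merged.append(replace(group[0], member_transcripts=members))
    merged.sort(key=lambda c: (c.chrom, c.genomic_blocks, c.transcript_id))
    return merged


CANDIDATE_TSV_COLUMNS = [
    "uorf_id",
    "genome_position",
    "uorf_type",
    "start_codon",
    "transcript_id",
    "tx_start",
    "tx_end",
    "gene_id",
    "frame_vs_cds",
    "kozak",
    "peptide",
    "member_transcripts",
]


def write_candidates_tsv(candidates: Iterable[CandidateUORF], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_TSV_COLUMNS) + "\n")
        for c in candidates:
            gpos = ";".join(f"{c.chrom}:{s}-{e}" for s, e in c.genomic_blocks)
            fh.write(
                "\t".join(
                    [
                        c.uorf_id,
                        gpos,
                        c.category,
                        c.start_codon,
                        c.transcript_id,
                        str(c.tx_start),
                        str(c.tx_end),
                        c.gene_id,
                        str(c.frame_vs_cds),
                        c.kozak,
                        c.peptide,
                        ",".join(c.member_transcripts),
                    ]
                )
                + "\n"
            )


def write_peptides_fasta(candidates: Iterable[CandidateUORF], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.uorf_id}\n{c.peptide}\n")
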