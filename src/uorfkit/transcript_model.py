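"""Transcript models and transcript↔genome coordinate projection.

A :class:`TranscriptModel` stores one mRNA's exon structure, strand and CDS
span.  All internal coordinates are 0-based, half-open, and *transcript
oriented* (position 0 is the 5′ cap); GTF input/output is converted at the
I/O boundary only (GTF is 1-based inclusive).  Sequences are stored with DNA
letters (ACGT) in transcript orientation, so all downstream codon matching
uses ``ATG`` rather than ``AUG``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import gffutils
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's structure with CDS span in transcript coordinates.

    ``exons`` are genomic ``(start, end)`` intervals (0-based half-open),
    ordered 5′→3′ in *transcript* orientation — i.e. ascending genomic start
    on the plus strand, descending on the minus strand.  ``cds_tx_start`` /
    ``cds_tx_end`` delimit the CDS (stop codon included) in transcript
    coordinates; the 5′UTR is ``[0, cds_tx_start)``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_tx_start: int
    cds_tx_end: int
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        lengths = [e - s for s, e in self.exons]
        if any(l <= 0 for l in lengths):
            raise ValueError("exons must be non-empty intervals")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != self.exons:
            raise ValueError("exons not ordered 5'->3' in transcript orientation")
        if not (0 <= self.cds_tx_start < self.cds_tx_end <= self.tx_length):
            raise ValueError(
                f"invalid CDS span [{self.cds_tx_start}, {self.cds_tx_end}) "
                f"for transcript of length {self.tx_length}"
            )

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def utr5_length(self) -> int:
        return self.cds_tx_start

    @property
    def has_utr5(self) -> bool:
        return self.cds_tx_start > 0

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole transcript."""
        genomic = sorted(self.exons)
        return genomic[0][0], genomic[-1][1]


@dataclass(frozen=True)
class TranscriptSequence:
    """Transcript-oriented sequence (DNA letters) matching a TranscriptModel."""

    transcript_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def tx_to_genome(model: TranscriptModel, start: int, end: int) -> list[tuple[int, int]]:
    """Project a transcript interval ``[start, end)`` to genomic blocks.

    Blocks are maximal runs within exons, returned in ascending genomic
    order (so minus-strand projections come out reversed relative to
    transcript order).  Total block length equals ``end - start``.
    """
    if not (0 <= start < end <= model.tx_length):
        raise ValueError(
            f"interval [{start}, {end}) outside transcript "
            f"[0, {model.tx_length})"
        )
    blocks: list[tuple[int, int]] = []
    offset = 0
    for gs, ge in model.exons:
        elen = ge - gs
        lo = max(start, offset)
        hi = min(end, offset + elen)
        if lo < hi:
            if model.strand == "+":
                blocks.append((gs + (lo - offset), gs + (hi - offset)))
            else:
                blocks.append((ge - (hi - offset), ge - (lo - offset)))
        offset += elen
    blocks.sort()
    assert sum(e - s for s, e in blocks) == end - start
    return blocks


def genome_to_tx(model: TranscriptModel, gpos: int) -> int | None:
    """Transcript coordinate of a genomic position, or None if intronic/outside."""
    offset = 0
    for gs, ge in model.exons:
        if gs <= gpos < ge:
            if model.strand == "+":
                return offset + (gpos - gs)
            return offset + (ge - 1 - gpos)
        offset += ge - gs
    return None


def _validate_gtf_lines(gtf_path: str) -> None:
    with open(gtf_path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise AnnotationError(
                    f"{gtf_path}: malformed GTF line {i}: {line.rstrip()!r}"
                )


def parse_annotation(
    gtf_path: str | os.PathLike,
    genome_fasta: str | os.PathLike,
) -> list[tuple[TranscriptModel, TranscriptSequence]]:
    """Parse a GTF plus genome FASTA into transcript models and sequences.

    Only transcripts with both ``exon`` and ``CDS`` features are returned
    (protein coding).  The CDS span is the min–max over CDS features,
    extended by any ``stop_codon`` features lying outside it (GENCODE-style
    GTFs exclude the stop from CDS).  Minus-strand sequences are
    reverse-complemented into transcript orientation.  Transcripts on
    chromosomes absent from the FASTA are skipped with a warning.
    """
    gtf_path = os.fspath(gtf_path)
    _validate_gtf_lines(gtf_path)
    try:
        db = gffutils.create_db(
            gtf_path,
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error passthrough
        raise AnnotationError(f"failed to parse {gtf_path}: {exc}") from exc

    per_tx: dict[str, dict] = {}
    for ftype in ("exon", "CDS", "stop_codon"):
        for feat in db.features_of_type(ftype):
            tid = feat.attributes.get("transcript_id", [None])[0]
            if tid is None:
                raise AnnotationError(
                    f"{gtf_path}: {ftype} feature without transcript_id "
                    f"at {feat.seqid}:{feat.start}"
                )
            rec = per_tx.setdefault(
                tid,
                {
                    "gene_id": feat.attributes.get("gene_id", [tid])[0],
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "exon": [],
                    "CDS": [],
                    "stop_codon": [],
                    "tags": set(),
                },
            )
            # GTF 1-based inclusive -> 0-based half-open
            rec[ftype].append((feat.start - 1, feat.end))
            rec["tags"].update(feat.attributes.get("tag", []))

    fasta = Fasta(os.fspath(genome_fasta))
    out: list[tuple[TranscriptModel, TranscriptSequence]] = []
    for tid in sorted(per_tx):
        rec = per_tx[tid]
        if not rec["exon"]:
            logger.warning("transcript %s has CDS but no exon features; skipped", tid)
            continue
        if not rec["CDS"]:
            logger.debug("transcript %s has no CDS; skipped (non-coding)", tid)
            continue
        if rec["chrom"] not in fasta:
            logger.warning(
                "transcript %s: chromosome %s missing from FASTA; skipped",
                tid,
                rec["chrom"],
            )
            continue
        exons = sorted(rec["exon"])
        if rec["strand"] == "-":
            exons = exons[::-1]
        cds_feats = rec["CDS"] + rec["stop_codon"]
        cds_gstart = min(s for s, _ in cds_feats)
        cds_gend = max(e for _, e in cds_feats)
        tags = tuple(sorted(rec["tags"]))
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(exons),
            cds_tx_start=0,
            cds_tx_end=1,
            tags=tags,
        )
        # provisional model above only validates exon structure; now place CDS
        five_most = cds_gstart if rec["strand"] == "+" else cds_gend - 1
        three_most = cds_gend - 1 if rec["strand"] == "+" else cds_gstart
        cds_tx_start = genome_to_tx(model, five_most)
        cds_tx_3p = genome_to_tx(model, three_most)
        if cds_tx_start is None or cds_tx_3p is None:
            logger.warning("transcript %s: CDS endpoint not exonic; skipped", tid)
            continue
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(exons),
            cds_tx_start=cds_tx_start,
            cds_tx_end=cds_tx_3p + 1,
            tags=tags,
        )
        if not model.has_utr5:
            logger.info("transcript %s has no 5'UTR", tid)
        chrom_seq = fasta[rec["chrom"]]
        parts = [str(chrom_seq[s:e]).upper() for s, e in sorted(rec["exon"])]
        seq = "".join(parts)
        if rec["strand"] == "-":
            seq = reverse_complement(seq)
        out.append((model, TranscriptSequence(tid, seq)))
    return out


def write_gtf(
    records: Iterable[tuple[TranscriptModel, TranscriptSequence | None]],
    path: str | os.PathLike,
) -> None:
    """Write models back to GTF (1-based inclusive), transcript/exon/CDS lines."""
    with open(path, "w") as fh:
        for model, _seq in records:
            attrs = (
                f'gene_id "{model.gene_id}"; transcript_id "{model.transcript_id}";'
            )
            span = model.span
            fh.write(
                "\t".join(
                    [
                        model.chrom,
                        "uorfkit",
                        "transcript",
                        str(span[0] + 1),
                        str(span[1]),
                        ".",
                        model.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for gs, ge in sorted(model.exons):
                fh.write(
                    "\t".join(
                        [
                            model.chrom,
                            "uorfkit",
                            "exon",
                            str(gs + 1),
                            str(ge),
                            ".",
                            model.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
            for gs, ge in tx_to_genome(model, model.cds_tx_start, model.cds_tx_end):
                fh.write(
                    "\t".join(
                        [
                            model.chrom,
                            "uorfkit",
                            "CDS",
                            str(gs + 1),
                            str(ge),
                            ".",
                            model.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_bed12(
    entries: Iterable[tuple[str, str, str, list[tuple[int, int]]]],
    path: str | os.PathLike,
) -> None:
    """Write (chrom, name, strand, blocks) tuples as BED12 for genome browsers."""
    with open(path, "w") as fh:
        for chrom, name, strand, blocks in entries:
            blocks = sorted(blocks)
            start = blocks[0][0]
            end = blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - start) for s, _ in blocks)
            fh.write(
                "\t".join(
                    [
                        chrom,
                        str(start),
                        str(end),
                        name,
                        "0",
                        strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
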