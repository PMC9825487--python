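"""Ribo-seq read and alignment I/O, P-site offset estimation and profiles.

Collapsed FASTA is the dialect ``>ID_xCOUNT`` where COUNT is the read
multiplicity.  Alignments may arrive as BAM/SAM in transcript or genome
space, or as a plain P-site TSV (columns ``transcript_id``, ``tx_pos`` —
the 0-based transcript coordinate of the read 5′ end — ``read_length``,
``count``), which keeps the toolkit testable without an aligner.  P-site
positions are the read 5′ end plus a length-dependent offset.
"""

from __future__ import annotations

import logging
import os
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

from .transcript_model import TranscriptModel, genome_to_tx

logger = logging.getLogger(__name__)

_COLLAPSED_RE = re.compile(r"^(?P<rid>.*)_x(?P<count>\d+)$")

DEFAULT_LENGTH_FILTER = range(27, 33)  # 27-32 nt inclusive
DEFAULT_OFFSET = 12


class RiboIOError(ValueError):
    """Raised for malformed read or alignment input."""


@dataclass(frozen=True)
class CollapsedRead:
    read_id: str
    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise RiboIOError(f"read {self.read_id!r}: count must be >= 1")

    @property
    def header(self) -> str:
        return f"{self.read_id}_x{self.count}"


class AlignedHit(NamedTuple):
    """One (collapsed) read placed on a transcript by its 5′ end."""

    transcript_id: str
    tx_pos: int
    read_length: int
    count: int


@dataclass
class OffsetTable:
    """Per-read-length P-site offsets (nt from the read 5′ end)."""

    offsets: dict[int, int]
    default: int = DEFAULT_OFFSET
    defaulted: frozenset[int] = frozenset()

    def __getitem__(self, length: int) -> int:
        return self.offsets.get(length, self.default)

    def __contains__(self, length: int) -> bool:
        return length in self.offsets

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("read_length\tp_site_offset\n")
            for length in sorted(self.offsets):
                fh.write(f"{length}\t{self.offsets[length]}\n")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "OffsetTable":
        df = pd.read_csv(path, sep="\t")
        if not {"read_length", "p_site_offset"}.issubset(df.columns):
            raise RiboIOError(f"{path}: expected columns read_length, p_site_offset")
        offsets = dict(zip(df["read_length"].astype(int), df["p_site_offset"].astype(int)))
        for length, off in offsets.items():
            if not 0 <= off < length:
                raise RiboIOError(f"offset {off} out of range for length {length}")
        return cls(offsets=offsets)


@dataclass
class PSiteProfile:
    """Per-transcript P-site counts keyed by (position, read length)."""

    transcript_id: str
    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, pos: int, length: int, count: int = 1) -> None:
        key = (pos, length)
        self.counts[key] = self.counts.get(key, 0) + count

    def position_counts(self) -> dict[int, int]:
        agg: dict[int, int] = defaultdict(int)
        for (pos, _length), c in self.counts.items():
            agg[pos] += c
        return dict(agg)

    def count_in(self, start: int, end: int) -> int:
        return sum(c for (pos, _l), c in self.counts.items() if start <= pos < end)


def collapse_reads(in_path: str | os.PathLike, out_path: str | os.PathLike) -> int:
    """Collapse a FASTA/FASTQ file into collapsed FASTA; returns #unique reads.

    Sequences are uppercased before merging; output order is by descending
    count then sequence, with ids ``seq1, seq2, ...`` — deterministic and
    idempotent on already-collapsed input.
    """
    in_path = os.fspath(in_path)
    fmt = _sniff_format(in_path)
    counter: Counter[str] = Counter()
    if fmt is not None:
        for rec in SeqIO.parse(in_path, fmt):
            mult = 1
            m = _COLLAPSED_RE.match(rec.id)
            if m:
                mult = int(m.group("count"))
            counter[str(rec.seq).upper()] += mult
    if not counter:
        logger.warning("%s: no reads; writing empty collapsed FASTA", in_path)
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(out_path, "w") as fh:
        for i, (seq, count) in enumerate(ordered, 1):
            fh.write(f">seq{i}_x{count}\n{seq}\n")
    return len(ordered)


def _sniff_format(path: str) -> str | None:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise RiboIOError(f"{path}: not FASTA/FASTQ (first record {line[:20]!r})")
    return None


def read_collapsed_fasta(path: str | os.PathLike) -> list[CollapsedRead]:
    reads: list[CollapsedRead] = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        m = _COLLAPSED_RE.match(rec.id)
        if not m:
            raise RiboIOError(
                f"{path}: header {rec.id!r} does not match the '>ID_xCOUNT' dialect"
            )
        count = int(m.group("count"))
        if count < 1:
            raise RiboIOError(f"{path}: record {rec.id!r} has count {count} < 1")
        reads.append(CollapsedRead(m.group("rid"), str(rec.seq).upper(), count))
    return reads


def write_collapsed_fasta(reads: Iterable[CollapsedRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.header}\n{r.seq}\n")


def _transcript_index(models: Mapping[str, TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for model in models.values():
        start, end = model.span
        trees[model.chrom].addi(start, end, model)
    return dict(trees)


def load_alignments(
    path: str | os.PathLike,
    space: str,
    models: Mapping[str, TranscriptModel],
) -> tuple[list[AlignedHit], dict[str, int]]:
    """Load aligned RPFs as 5′-end transcript hits.

    ``space`` is ``transcript`` or ``genome`` for BAM/SAM input, or ``tsv``
    input is auto-detected from the extension.  Soft-clipped alignments and
    multimappers (NH tag > 1) are excluded; collapsed-read multiplicities
    are parsed from the ``_xCOUNT`` read-name suffix when present.
    Genome-space records are projected through the exon structure of every
    same-strand transcript overlapping the read 5′ end; intronic hits are
    dropped.  Returns the hits plus a counter of dropped records.
    """
    path = os.fspath(path)
    if path.endswith((".tsv", ".txt")):
        return _load_tsv_hits(path, models)
    if space not in ("transcript", "genome"):
        raise ValueError(f"space must be 'transcript' or 'genome', got {space!r}")
    stats: Counter[str] = Counter()
    hits: list[AlignedHit] = []
    trees = _transcript_index(models) if space == "genome" else {}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                stats["unmapped_or_secondary"] += 1
                continue
            if rec.cigarstring and "S" in rec.cigarstring:
                stats["soft_clipped"] += 1
                continue
            if rec.has_tag("NH") and rec.get_tag("NH") > 1:
                stats["multimapper"] += 1
                continue
            count = 1
            m = _COLLAPSED_RE.match(rec.query_name or "")
            if m:
                count = int(m.group("count"))
            length = rec.query_length or rec.infer_read_length() or 0
            if space == "transcript":
                if rec.is_reverse:
                    stats["antisense"] += 1
                    continue
                tid = rec.reference_name
                if tid not in models:
                    stats["unknown_reference"] += 1
                    continue
                hits.append(AlignedHit(tid, rec.reference_start, length, count))
            else:
                chrom = rec.reference_name
                tree = trees.get(chrom)
                if tree is None:
                    stats["unknown_reference"] += 1
                    continue
                strand = "-" if rec.is_reverse else "+"
                g5 = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
                matched = False
                for iv in tree.at(g5):
                    model: TranscriptModel = iv.data
                    if model.strand != strand:
                        continue
                    tx_pos = genome_to_tx(model, g5)
                    if tx_pos is None:
                        continue
                    hits.append(AlignedHit(model.transcript_id, tx_pos, length, count))
                    matched = True
                if not matched:
                    stats["intronic_or_intergenic"] += 1
    return hits, dict(stats)


def _load_tsv_hits(
    path: str, models: Mapping[str, TranscriptModel]
) -> tuple[list[AlignedHit], dict[str, int]]:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "tx_pos", "read_length", "count"}
    if not required.issubset(df.columns):
        raise RiboIOError(
            f"{path}: P-site TSV must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    stats: Counter[str] = Counter()
    hits: list[AlignedHit] = []
    for row in df.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in models:
            stats["unknown_transcript"] += 1
            continue
        hits.append(AlignedHit(tid, int(row.tx_pos), int(row.read_length), int(row.count)))
    return hits, dict(stats)


def write_hits_tsv(hits: Iterable[AlignedHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\ttx_pos\tread_length\tcount\n")
        for h in hits:
            fh.write(f"{h.transcript_id}\t{h.tx_pos}\t{h.read_length}\t{h.count}\n")


def estimate_offsets(
    hits: Sequence[AlignedHit],
    models: Mapping[str, TranscriptModel],
    lengths: Iterable[int] = DEFAULT_LENGTH_FILTER,
    min_reads: int = 500,
    default: int = DEFAULT_OFFSET,
) -> OffsetTable:
    """Estimate P-site offsets from the CDS-start anchoring of each read length.

    For each read length L, the offset is the value o in [10, L-10] that
    maximises the number of reads whose 5′ end + o lands exactly on an
    annotated CDS start; ties break toward the smaller offset.  Length
    classes with fewer than ``min_reads`` reads, or with no CDS-anchored
    evidence at all, fall back to the default offset (12) and are flagged.
    """
    by_length: dict[int, list[AlignedHit]] = defaultdict(list)
    for h in hits:
        by_length[h.read_length].append(h)
    offsets: dict[int, int] = {}
    defaulted: set[int] = set()
    for length in lengths:
        group = by_length.get(length, [])
        n = sum(h.count for h in group)
        candidates = range(10, max(length - 10, 10) + 1)
        if n < min_reads:
            offsets[length] = default
            defaulted.add(length)
            continue
        scores: Counter[int] = Counter()
        for h in group:
            model = models.get(h.transcript_id)
            if model is None:
                continue
            o = model.cds_tx_start - h.tx_pos
            if o in candidates:
                scores[o] += h.count
        if not scores:
            offsets[length] = default
            defaulted.add(length)
            continue
        best = min(candidates, key=lambda o: (-scores.get(o, 0), o))
        offsets[length] = best
    if defaulted:
        logger.warning(
            "no offset evidence for read length(s) %s; default %d used",
            sorted(defaulted),
            default,
        )
    return OffsetTable(offsets=offsets, default=default, defaulted=frozenset(defaulted))


def build_psite_profiles(
    hits: Iterable[AlignedHit],
    offsets: OffsetTable,
    models: Mapping[str, TranscriptModel],
    length_filter: Iterable[int] = DEFAULT_LENGTH_FILTER,
) -> dict[str, PSiteProfile]:
    """Turn 5′-end hits into per-transcript P-site profiles.

    Reads outside the length filter (27-32 nt by default) are dropped;
    within the filter, every read contributes its full count at position
    ``tx_pos + offset(length)`` — counts are conserved.
    """
    allowed = frozenset(length_filter)
    profiles: dict[str, PSiteProfile] = {}
    for h in hits:
        if h.read_length not in allowed:
            continue
        model = models.get(h.transcript_id)
        if model is None:
            continue
        psite = h.tx_pos + offsets[h.read_length]
        if not 0 <= psite < model.tx_length:
            continue
        prof = profiles.setdefault(h.transcript_id, PSiteProfile(h.transcript_id))
        prof.add(psite, h.read_length, h.count)
    return profiles
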