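"""5′UTR variant extraction and uORF-structural effect annotation.

Variants from a VCF are projected onto transcripts; those landing in a
5′UTR are classified by their consequence on uORF structure by applying
the alternate allele to the transcript sequence and locally re-enumerating
ORFs.  Effect vocabulary:

``uAUG_gained``   a new in-UTR start codon creating a valid candidate appears
``uSTART_lost``   an existing candidate's start codon is destroyed
``uSTOP_gained``  a new in-frame stop appears upstream of a candidate's stop
``uSTOP_lost``    a candidate's stop codon is destroyed
``uFrameshift``   an indel of length ≢ 0 (mod 3) inside a candidate
``kozak_changed`` the -3/+4 context class of an AUG start changes
``no_uorf_effect`` none of the above

Precedence within one uORF: start/stop changes > frameshift > kozak change.
Multiple effects on different uORFs of one transcript are all reported.
"""

from __future__ import annotations

import logging
import os
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .transcript_model import (
    TranscriptModel,
    TranscriptSequence,
    genome_to_tx,
    reverse_complement,
)
from .uorf_discovery import (
    DEFAULT_START_CODONS,
    STOP_CODONS,
    CandidateUORF,
    enumerate_candidates,
    kozak_strength,
)

logger = logging.getLogger(__name__)

EFFECT_CLASSES = (
    "uAUG_gained",
    "uSTART_lost",
    "uSTOP_gained",
    "uSTOP_lost",
    "uFrameshift",
    "kozak_changed",
    "no_uorf_effect",
)


class RefMismatchError(ValueError):
    """The VCF REF allele disagrees with the transcript sequence."""


class UnsupportedVariantError(ValueError):
    """Variant geometry this annotator does not handle (e.g. exon-junction indel)."""


@dataclass(frozen=True)
class UTRVariant:
    variant_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    transcript_id: str
    tx_pos: int
    in_5utr: bool

    @property
    def nucleotide_change(self) -> str:
        return f"{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantEffect:
    variant_id: str
    transcript_id: str
    uorf_id: str | None
    effect: str
    detail: str
    nucleotide_change: str

    @property
    def affects_uorf(self) -> bool:
        return self.effect != "no_uorf_effect"


def _normalise_chrom(chrom: str, known: frozenset[str]) -> str | None:
    if chrom in known:
        return chrom
    if chrom.startswith("chr") and chrom[3:] in known:
        return chrom[3:]
    if "chr" + chrom in known:
        return "chr" + chrom
    return None


def extract_utr5_variants(
    vcf_path: str | os.PathLike,
    models: Mapping[str, TranscriptModel],
) -> tuple[list[UTRVariant], dict[str, int]]:
    """Extract all (variant, transcript) pairs whose position lies in a 5′UTR.

    Multiallelic records are split per alternate allele; contig names are
    reconciled with the annotation by chr-prefix normalisation.  Variants on
    contigs absent from the annotation, intronic positions, and positions at
    or downstream of the CDS start are skipped (counted).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for model in models.values():
        s, e = model.span
        trees[model.chrom].addi(s, e, model)
    known = frozenset(trees)
    stats: Counter[str] = Counter()
    out: list[UTRVariant] = []
    for i, rec in enumerate(VCF(os.fspath(vcf_path)), 1):
        chrom = _normalise_chrom(rec.CHROM, known)
        if chrom is None:
            stats["unknown_contig"] += 1
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{i}"
        for alt in rec.ALT:
            g0 = rec.POS - 1
            matched = False
            for iv in trees[chrom].overlap(g0, g0 + max(len(rec.REF), 1)):
                model: TranscriptModel = iv.data
                span = _tx_span(model, g0, len(rec.REF))
                if span is None:
                    continue
                t0, _t1 = span
                if t0 >= model.cds_tx_start:
                    stats["not_in_5utr"] += 1
                    continue
                out.append(
                    UTRVariant(
                        variant_id=vid if len(rec.ALT) == 1 else f"{vid}:{alt}",
                        chrom=chrom,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        transcript_id=model.transcript_id,
                        tx_pos=t0,
                        in_5utr=True,
                    )
                )
                matched = True
            if not matched:
                stats["no_5utr_transcript"] += 1
    out.sort(key=lambda v: (v.chrom, v.pos, v.transcript_id, v.alt))
    return out, dict(stats)


def _tx_span(model: TranscriptModel, g0: int, ref_len: int) -> tuple[int, int] | None:
    """Transcript-space [t0, t1) of a genomic ref span, or None if any base
    is intronic/outside; raises for spans broken across an exon junction."""
    positions = []
    for g in range(g0, g0 + ref_len):
        t = genome_to_tx(model, g)
        if t is None:
            return None
        positions.append(t)
    t0, t1 = min(positions), max(positions) + 1
    if t1 - t0 != ref_len:
        raise UnsupportedVariantError(
            f"variant at {model.chrom}:{g0 + 1} spans an exon junction of "
            f"{model.transcript_id}"
        )
    return t0, t1


def apply_variant(
    v: UTRVariant,
    model: TranscriptModel,
    seq: TranscriptSequence | str,
) -> tuple[str, int, int, str, str]:
    """Apply the alternate allele in transcript space.

    Returns ``(mutated_seq, t0, t1, tx_ref, tx_alt)`` where ``[t0, t1)`` is
    the transcript span of the reference allele.  Raises
    :class:`RefMismatchError` when the REF allele disagrees with the
    transcript sequence (annotation/genome inconsistency).
    """
    s = seq.seq if isinstance(seq, TranscriptSequence) else seq
    span = _tx_span(model, v.pos - 1, len(v.ref))
    if span is None:
        raise UnsupportedVariantError(
            f"variant {v.variant_id}: reference span not fully exonic"
        )
    t0, t1 = span
    if model.strand == "+":
        tx_ref, tx_alt = v.ref.upper(), v.alt.upper()
    else:
        tx_ref, tx_alt = (
            reverse_complement(v.ref.upper()),
            reverse_complement(v.alt.upper()),
        )
    if s[t0:t1] != tx_ref:
        raise RefMismatchError(
            f"variant {v.variant_id}: REF {tx_ref!r} does not match transcript "
            f"{model.transcript_id} sequence {s[t0:t1]!r} at tx position {t0}"
        )
    return s[:t0] + tx_alt + s[t1:], t0, t1, tx_ref, tx_alt


def annotate_effect(
    v: UTRVariant,
    model: TranscriptModel,
    seq: TranscriptSequence | str,
    candidates: Sequence[CandidateUORF],
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    min_len_nt: int = 18,
) -> list[VariantEffect]:
    """Classify one 5′UTR variant's consequences on uORF structure.

    The alternate allele is applied to the transcript sequence and ORFs are
    re-enumerated on the mutated transcript; effects are derived per
    affected uORF with the documented precedence.  Deletions spanning the
    UTR/CDS boundary are flagged out of 5′UTR scope rather than annotated.
    """
    s = seq.seq if isinstance(seq, TranscriptSequence) else seq
    mut_seq, t0, t1, tx_ref, tx_alt = apply_variant(v, model, s)
    delta = len(tx_alt) - len(tx_ref)
    change = v.nucleotide_change

    if t1 > model.cds_tx_start:
        return [
            VariantEffect(
                v.variant_id,
                model.transcript_id,
                None,
                "no_uorf_effect",
                "reference span crosses the UTR/CDS boundary; out of 5'UTR scope",
                change,
            )
        ]

    mut_model = TranscriptModel(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand="+",
        exons=((0, len(mut_seq)),),
        cds_tx_start=model.cds_tx_start + delta,
        cds_tx_end=model.cds_tx_end + delta,
    )
    mut_cands = enumerate_candidates(mut_model, mut_seq, start_codons, min_len_nt)
    start_set = frozenset(start_codons)

    def fwd(t: int) -> int | None:
        if t < t0:
            return t
        if t >= t1:
            return t + delta
        return None

    def anchor(t: int) -> int:
        m = fwd(t)
        return m if m is not None else t0

    def overlaps(a: int, b: int) -> bool:
        return a < t1 and t0 < b

    mine = [c for c in candidates if c.transcript_id == model.transcript_id]
    effects: list[VariantEffect] = []
    for u in mine:
        effect = None
        detail = ""
        m_start = anchor(u.tx_start)
        mut_start_codon = mut_seq[m_start : m_start + 3]
        if overlaps(u.tx_start, u.tx_start + 3) and mut_start_codon not in start_set:
            effect = "uSTART_lost"
            detail = f"{u.start_codon}->{mut_start_codon}"
        elif (
            u.category != "n_terminal_extension"
            and overlaps(u.tx_end - 3, u.tx_end)
        ):
            m_stop = anchor(u.tx_end - 3)
            mut_stop = mut_seq[m_stop : m_stop + 3]
            if mut_stop not in STOP_CODONS:
                effect = "uSTOP_lost"
                detail = f"{s[u.tx_end - 3:u.tx_end]}->{mut_stop}"
        if effect is None and overlaps(u.tx_start, u.tx_end):
            if delta % 3 != 0:
                effect = "uFrameshift"
                detail = f"indel of {delta:+d} nt inside uORF"
            else:
                # in-place change inside the body: look for a newly gained
                # in-frame stop upstream of the original one
                old_end_m = fwd(u.tx_end)
                q = m_start + 3
                new_end = None
                while q + 3 <= len(mut_seq):
                    if mut_seq[q : q + 3] in STOP_CODONS:
                        new_end = q + 3
                        break
                    q += 3
                if new_end is not None and old_end_m is not None and new_end < old_end_m:
                    effect = "uSTOP_gained"
                    detail = f"new stop {mut_seq[new_end - 3:new_end]} at tx {new_end - 3}"
        if (
            effect is None
            and u.start_codon == "ATG"
            and overlaps(u.tx_start - 3, u.tx_start + 4)
        ):
            old_class = kozak_strength(s, u.tx_start, "ATG")
            new_class = kozak_strength(mut_seq, m_start, mut_start_codon)
            if mut_start_codon == "ATG" and new_class != old_class:
                effect = "kozak_changed"
                detail = f"{old_class}->{new_class}"
        if effect is not None:
            effects.append(
                VariantEffect(v.variant_id, model.transcript_id, u.uorf_id, effect, detail, change)
            )

    def back(m: int) -> int | None:
        if m < t0 or delta == 0:
            return m
        if m >= t0 + len(tx_alt):
            return m - delta
        return None

    orig_starts = {u.tx_start for u in mine}
    for c in mut_cands:
        gs = back(c.tx_start)
        if gs is not None and gs in orig_starts:
            continue
        codon_touches_alt = c.tx_start < t0 + len(tx_alt) and t0 < c.tx_start + 3
        if gs is None or codon_touches_alt:
            effects.append(
                VariantEffect(
                    v.variant_id,
                    model.transcript_id,
                    c.uorf_id,
                    "uAUG_gained",
                    f"new {c.start_codon} start at tx {c.tx_start} ({c.category})",
                    change,
                )
            )

    if not effects:
        effects.append(
            VariantEffect(v.variant_id, model.transcript_id, None, "no_uorf_effect", "", change)
        )
    return effects


def summarize_effects(effects: Sequence[VariantEffect]) -> pd.DataFrame:
    """Count table of effect classes by nucleotide change (plus totals row)."""
    counts: Counter[tuple[str, str]] = Counter()
    for e in effects:
        counts[(e.effect, e.nucleotide_change)] += 1
    rows = [
        {"effect": eff, "nucleotide_change": chg, "count": n}
        for (eff, chg), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["effect", "nucleotide_change", "count"])


def write_effects_tsv(
    effects: Sequence[VariantEffect],
    variants: Mapping[str, UTRVariant] | None,
    path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "variant_id\tnucleotide_change\tposition\tgene_id\ttranscript_id\t"
            "uorf_id\teffect\tdetail\taffects_uorf\n"
        )
        for e in effects:
            pos = ""
            if variants and e.variant_id in variants:
                var = variants[e.variant_id]
                pos = f"{var.chrom}:{var.pos}"
            fh.write(
                "\t".join(
                    [
                        e.variant_id,
                        e.nucleotide_change,
                        pos,
                        "",
                        e.transcript_id,
                        e.uorf_id or "",
                        e.effect,
                        e.detail,
                        str(int(e.affects_uorf)),
                    ]
                )
                + "\n"
            )
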