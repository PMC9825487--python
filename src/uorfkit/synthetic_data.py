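"""Synthetic transcriptomes, RPF libraries and variant sets with known truth.

The generator emulates the study conditions the rest of the toolkit is
validated under: protein-coding transcripts with defined 5′UTR/CDS/3′UTR
structure (optionally multi-exon, both strands), planted uORFs of each
category, and ribosome-protected-fragment libraries with a configurable
length distribution, 3-nt frame periodicity and initiation-site pileup.

Clean-background 5′UTRs are built from a start-codon-suppressed alphabet
({A,C,T} — every accepted start codon contains a G), so the only candidate
uORFs on a transcript are the planted ones and truth recovery is exact.
A single integer seed governs all randomness; per-transcript generator
streams are split from it, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .ribo_io import AlignedHit, CollapsedRead, OffsetTable, write_hits_tsv
from .transcript_model import TranscriptModel, TranscriptSequence, reverse_complement, tx_to_genome, write_gtf
from .uorf_discovery import STOP_CODONS

SENSE_CODONS = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)
# start-codon-suppressed background: no G anywhere, and TAA (the only G-free
# stop) excluded from in-frame body codons
CLEAN_BASES = "ACT"
CLEAN_BODY_CODONS = tuple(
    "".join(c) for c in product(CLEAN_BASES, repeat=3) if "".join(c) != "TAA"
)

DEFAULT_LENGTH_DIST = {27: 0.08, 28: 0.34, 29: 0.28, 30: 0.16, 31: 0.09, 32: 0.05}


class SimulationParameterError(ValueError):
    """Raised for infeasible simulation requests."""


@dataclass(frozen=True)
class PlantedUORF:
    transcript_id: str
    tx_start: int
    tx_end: int
    start_codon: str
    category: str
    translated: bool


@dataclass
class SimulationTruth:
    planted_uorfs: list[PlantedUORF]
    seed: int
    offsets: OffsetTable | None = None
    frame0_prob: float | None = None


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _rand_codons(rng: np.random.Generator, n: int, pool: Sequence[str]) -> str:
    return "".join(pool[i] for i in rng.integers(0, len(pool), size=n))


def _build_utr5(
    rng: np.random.Generator,
    utr_len: int,
    cds_start_offset_irrelevant: int,
    plant: tuple[str, bool] | None,
    uorf_len_nt: int,
    overlap_upstream_nt: int,
    extension_upstream_nt: int,
) -> tuple[str, tuple[int, str] | None]:
    """Build a clean 5′UTR, returning (utr_seq, (uorf_tx_start, start_codon)).

    For the overlap categories only the upstream portion is written here;
    the planted element always ends flush with the UTR 3′ end in that case.
    """
    if plant is None:
        return _rand_seq(rng, utr_len, CLEAN_BASES), None
    category, _translated = plant
    if category == "non_overlapping":
        if uorf_len_nt % 3 != 0 or uorf_len_nt < 21:
            raise SimulationParameterError("uorf_len_nt must be a multiple of 3, >= 21")
        if utr_len < uorf_len_nt + 6:
            raise SimulationParameterError(
                f"5'UTR of {utr_len} nt cannot hold a {uorf_len_nt} nt uORF"
            )
        start = int(rng.integers(3, utr_len - uorf_len_nt - 2))
        body = _rand_codons(rng, uorf_len_nt // 3 - 2, CLEAN_BODY_CODONS)
        element = "ATG" + body + "TAA"
        utr = (
            _rand_seq(rng, start, CLEAN_BASES)
            + element
            + _rand_seq(rng, utr_len - start - uorf_len_nt, CLEAN_BASES)
        )
        return utr, (start, "ATG")
    if category == "overlapping_out_of_frame":
        k = overlap_upstream_nt
        if k % 3 == 0:
            raise SimulationParameterError("overlap_upstream_nt must not be a multiple of 3")
        if utr_len < k + 3:
            raise SimulationParameterError("5'UTR too short for overlap planting")
        r = k % 3
        body = _rand_codons(rng, (k - r) // 3 - 1, CLEAN_BODY_CODONS)
        element = "ATG" + body + "C" * r
        start = utr_len - k
        return _rand_seq(rng, start, CLEAN_BASES) + element, (start, "ATG")
    if category == "n_terminal_extension":
        m = extension_upstream_nt
        if m % 3 != 0 or m < 6:
            raise SimulationParameterError("extension_upstream_nt must be a multiple of 3, >= 6")
        if utr_len < m + 3:
            raise SimulationParameterError("5'UTR too short for extension planting")
        body = _rand_codons(rng, m // 3 - 1, CLEAN_BODY_CODONS)
        element = "ATG" + body
        start = utr_len - m
        return _rand_seq(rng, start, CLEAN_BASES) + element, (start, "ATG")
    raise SimulationParameterError(f"unknown plant category {category!r}")


def _first_inframe_stop(seq: str, start: int) -> int | None:
    q = start + 3
    while q + 3 <= len(seq):
        if seq[q : q + 3] in STOP_CODONS:
            return q + 3
        q += 3
    return None


def simulate_transcriptome(
    n_tx: int = 20,
    utr5_len_range: tuple[int, int] = (90, 240),
    cds_len_range: tuple[int, int] = (150, 450),
    utr3_len_range: tuple[int, int] = (60, 180),
    n_exons_range: tuple[int, int] = (1, 3),
    plant: Sequence[tuple[str, bool] | None] | None = (("non_overlapping", True),),
    uorf_len_nt: int = 60,
    overlap_upstream_nt: int = 20,
    extension_upstream_nt: int = 21,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
) -> tuple[dict[str, TranscriptModel], dict[str, TranscriptSequence], SimulationTruth]:
    """Simulate a transcriptome with planted uORFs of known position and kind.

    ``plant`` is cycled across transcripts; entry ``i % len(plant)`` is a
    ``(category, translated)`` pair or None for a uORF-free transcript.
    Clean 5′UTR backgrounds guarantee the planted uORFs are the *only*
    candidates.  When ``out_dir`` is given, a GTF and genome FASTA are
    written there (deterministically, given the seed).
    """
    if n_tx < 1:
        raise SimulationParameterError("n_tx must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_tx + 1)
    layout_rng = np.random.default_rng(children[-1])

    models: dict[str, TranscriptModel] = {}
    seqs: dict[str, TranscriptSequence] = {}
    planted: list[PlantedUORF] = []
    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 0

    for i in range(n_tx):
        rng = np.random.default_rng(children[i])
        tid = f"TX{i + 1:04d}"
        gid = f"G{i + 1:04d}"
        strand = "+" if i % 2 == 0 else "-"
        plant_spec = None
        if plant:
            plant_spec = plant[i % len(plant)]
        utr5_len = int(rng.integers(utr5_len_range[0], utr5_len_range[1] + 1))
        n_cds_codons = int(rng.integers(cds_len_range[0] // 3, cds_len_range[1] // 3 + 1))
        utr3_len = int(rng.integers(utr3_len_range[0], utr3_len_range[1] + 1))

        utr5, plant_pos = _build_utr5(
            rng, utr5_len, 0, plant_spec, uorf_len_nt, overlap_upstream_nt, extension_upstream_nt
        )
        cds = "ATG" + _rand_codons(rng, n_cds_codons - 2, SENSE_CODONS) + "TAA"
        utr3 = _rand_seq(rng, utr3_len, CLEAN_BASES)
        seq = utr5 + cds + utr3
        cds_tx_start = len(utr5)
        cds_tx_end = cds_tx_start + len(cds)

        if plant_spec is not None:
            category, translated = plant_spec
            start, codon = plant_pos  # type: ignore[misc]
            if category == "non_overlapping":
                tx_end = start + uorf_len_nt
            else:
                tx_end = _first_inframe_stop(seq, start)
                if category == "n_terminal_extension":
                    tx_end = cds_tx_end
                elif tx_end is None or (tx_end - start) < 21:
                    # guarantee a stop for the shifted frame in the 3'UTR
                    frame_pos = cds_tx_end + ((start - cds_tx_end) % 3 + 3) % 3
                    while frame_pos + 3 <= len(seq) and (frame_pos - start) % 3 != 0:
                        frame_pos += 1
                    if frame_pos + 3 > len(seq):
                        raise SimulationParameterError("3'UTR too short to place a stop")
                    seq = seq[:frame_pos] + "TAA" + seq[frame_pos + 3 :]
                    tx_end = _first_inframe_stop(seq, start)
                    assert tx_end is not None
            planted.append(PlantedUORF(tid, start, tx_end, codon, category, translated))

        # exon layout
        tx_len = len(seq)
        n_exons = int(layout_rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        n_exons = max(1, min(n_exons, tx_len // 30))
        cuts = sorted(
            int(c) for c in layout_rng.choice(np.arange(20, tx_len - 20), size=n_exons - 1, replace=False)
        ) if n_exons > 1 else []
        bounds = [0] + cuts + [tx_len]
        pieces = [seq[a:b] for a, b in zip(bounds, bounds[1:])]

        gap = int(layout_rng.integers(50, 151))
        genome_parts.append(_rand_seq(layout_rng, gap))
        cursor += gap
        exon_coords: list[tuple[int, int]] = []
        if strand == "+":
            ordered = pieces
        else:
            ordered = [reverse_complement(p) for p in pieces[::-1]]
        for j, piece in enumerate(ordered):
            if j > 0:
                intron = int(layout_rng.integers(30, 91))
                genome_parts.append(_rand_seq(layout_rng, intron))
                cursor += intron
            exon_coords.append((cursor, cursor + len(piece)))
            genome_parts.append(piece)
            cursor += len(piece)
        if strand == "-":
            exon_coords = exon_coords[::-1]  # back to transcript orientation

        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=tuple(exon_coords),
            cds_tx_start=cds_tx_start,
            cds_tx_end=cds_tx_end,
        )
        models[tid] = model
        seqs[tid] = TranscriptSequence(tid, seq)

    genome_parts.append(_rand_seq(layout_rng, 100))
    truth = SimulationTruth(planted_uorfs=planted, seed=seed)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        genome = "".join(genome_parts)
        with open(os.path.join(out_dir, "genome.fa"), "w") as fh:
            fh.write(f">{chrom}\n")
            for k in range(0, len(genome), 80):
                fh.write(genome[k : k + 80] + "\n")
        write_gtf(
            [(models[t], seqs[t]) for t in sorted(models)],
            os.path.join(out_dir, "annotation.gtf"),
        )
    return models, seqs, truth


def simulate_rpf_library(
    models: Mapping[str, TranscriptModel],
    sequences: Mapping[str, TranscriptSequence],
    truth: SimulationTruth,
    depth: float = 1.0,
    frame0_prob: float = 0.9,
    length_dist: Mapping[int, float] | None = None,
    offsets: Mapping[int, int] | None = None,
    init_peak: float = 5.0,
    background_rate: float = 0.05,
    seed: int = 0,
    out_fasta: str | os.PathLike | None = None,
    out_tsv: str | os.PathLike | None = None,
) -> tuple[list[AlignedHit], list[CollapsedRead], SimulationTruth]:
    """Simulate an RPF library over CDSs and planted uORFs.

    Translated regions (every CDS plus planted uORFs marked translated)
    receive ``round(depth × length)`` P-sites: codon positions are drawn
    multinomially with the initiation codon up-weighted by ``init_peak``
    (the start-codon pileup real libraries show), and the within-codon frame
    is 0 with probability ``frame0_prob``, else 1 or 2 equally.
    Untranslated planted uORFs receive only frame-uniform background at
    ``background_rate`` P-sites/nt.  Read 5′ ends are P-site minus the
    per-length offset, with lengths drawn from ``length_dist``.
    Returns (5′-end hits, collapsed reads, truth updated with the library's
    offsets and frame purity).
    """
    if not 1 / 3 <= frame0_prob <= 1:
        raise SimulationParameterError("frame0_prob must be in [1/3, 1]")
    length_dist = dict(length_dist or DEFAULT_LENGTH_DIST)
    lengths = sorted(length_dist)
    probs = np.array([length_dist[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    offsets = dict(offsets or {l: 12 for l in lengths})
    for l in lengths:
        if l not in offsets:
            raise SimulationParameterError(f"no offset supplied for read length {l}")

    planted_by_tx: dict[str, list[PlantedUORF]] = {}
    for p in truth.planted_uorfs:
        planted_by_tx.setdefault(p.transcript_id, []).append(p)

    root = np.random.SeedSequence(seed)
    tids = sorted(models)
    children = root.spawn(len(tids))
    frame_p = np.array([frame0_prob, (1 - frame0_prob) / 2, (1 - frame0_prob) / 2])

    counter: dict[tuple[str, int, int], int] = {}
    for tid, child in zip(tids, children):
        rng = np.random.default_rng(child)
        model = models[tid]
        tx_len = model.tx_length
        regions: list[tuple[int, int, bool]] = [
            (model.cds_tx_start, model.cds_tx_end, True)
        ]
        for p in planted_by_tx.get(tid, []):
            end = min(p.tx_end, tx_len)
            end = p.tx_start + 3 * ((end - p.tx_start) // 3)
            regions.append((p.tx_start, end, p.translated))
        psites: list[int] = []
        for start, end, translated in regions:
            n_codons = (end - start) // 3
            if n_codons <= 0:
                continue
            if translated:
                n = int(round(depth * (end - start)))
                if n <= 0:
                    continue
                w = np.ones(n_codons)
                w[0] = init_peak
                w /= w.sum()
                codons = rng.choice(n_codons, size=n, p=w)
                frames = rng.choice(3, size=n, p=frame_p)
                psites.extend((start + 3 * codons + frames).tolist())
            else:
                n = int(rng.poisson(background_rate * (end - start)))
                if n > 0:
                    psites.extend(rng.integers(start, end, size=n).tolist())
        if not psites:
            continue
        read_lengths = rng.choice(len(lengths), size=len(psites), p=probs)
        for psite, li in zip(psites, read_lengths):
            L = lengths[int(li)]
            five = psite - offsets[L]
            if five < 0 or five + L > tx_len:
                continue
            key = (tid, five, L)
            counter[key] = counter.get(key, 0) + 1

    hits = [AlignedHit(tid, pos, L, c) for (tid, pos, L), c in sorted(counter.items())]
    out_truth = replace(
        truth,
        offsets=OffsetTable(offsets=dict(offsets)),
        frame0_prob=frame0_prob,
    )
    if out_tsv is not None:
        write_hits_tsv(hits, out_tsv)
    reads: list[CollapsedRead] = []
    seq_counter: dict[str, int] = {}
    for h in hits:
        rseq = sequences[h.transcript_id].seq[h.tx_pos : h.tx_pos + h.read_length]
        seq_counter[rseq] = seq_counter.get(rseq, 0) + h.count
    ordered = sorted(seq_counter.items(), key=lambda kv: (-kv[1], kv[0]))
    reads = [CollapsedRead(f"seq{i}", s, c) for i, (s, c) in enumerate(ordered, 1)]
    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for r in reads:
                fh.write(f">{r.header}\n{r.seq}\n")
    return hits, reads, out_truth


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_vcf(
    models: Mapping[str, TranscriptModel],
    sequences: Mapping[str, TranscriptSequence],
    truth: SimulationTruth,
    effect_mix: Mapping[str, int],
    out_vcf: str | os.PathLike | None = None,
    seed: int = 0,
    min_len_nt: int = 18,
) -> list[dict]:
    """Engineer 5′UTR variants producing requested uORF effect classes.

    Each transcript carries at most one variant so planted effects cannot
    interfere.  Returns truth labels: one dict per variant with chrom, pos,
    ref, alt, target transcript/uORF and the expected effect class.
    Frameshift insertions are planted on plus-strand transcripts only.
    Raises :class:`SimulationParameterError` when the request cannot be met
    on the given transcriptome.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    planted_by_tx = {p.transcript_id: p for p in truth.planted_uorfs}
    available = sorted(models)
    used: set[str] = set()
    records: list[dict] = []

    def tx_base_to_genome(model: TranscriptModel, t: int) -> int:
        blocks = tx_to_genome(model, t, t + 1)
        return blocks[0][0]

    def snv_record(model: TranscriptModel, t: int, new_tx_base: str) -> tuple[int, str, str]:
        seq = sequences[model.transcript_id].seq
        gpos = tx_base_to_genome(model, t)
        old_tx = seq[t]
        if model.strand == "+":
            return gpos + 1, old_tx, new_tx_base
        return gpos + 1, _COMP[old_tx], _COMP[new_tx_base]

    def take(pred, avoid_non_overlapping: bool = False) -> tuple[str, PlantedUORF | None] | None:
        pool = available
        if avoid_non_overlapping:
            # leave non_overlapping uORFs for the stop-codon effects
            pool = sorted(
                available,
                key=lambda tid: (
                    planted_by_tx.get(tid) is not None
                    and planted_by_tx[tid].category == "non_overlapping",
                    tid,
                ),
            )
        for tid in pool:
            if tid in used:
                continue
            u = planted_by_tx.get(tid)
            if pred(tid, u):
                used.add(tid)
                return tid, u
        return None

    # stop-codon effects first: they can only target non-overlapping uORFs
    priority = ["uSTOP_gained", "uSTOP_lost", "uFrameshift", "uAUG_gained", "uSTART_lost", "kozak_changed"]
    for effect in sorted(effect_mix, key=lambda e: (priority.index(e) if e in priority else 99, e)):
        count = effect_mix[effect]
        for _ in range(count):
            planted_var = None
            if effect == "uSTART_lost":
                got = take(lambda tid, u: u is not None and u.start_codon == "ATG", avoid_non_overlapping=True)
                if got is None:
                    raise SimulationParameterError("no transcript available for uSTART_lost")
                tid, u = got
                model = models[tid]
                pos, ref, alt = snv_record(model, u.tx_start + 2, "A")  # ATG -> ATA
                planted_var = (tid, u, pos, ref, alt)
            elif effect == "uSTOP_lost":
                got = take(
                    lambda tid, u: u is not None and u.category == "non_overlapping"
                )
                if got is None:
                    raise SimulationParameterError("no transcript available for uSTOP_lost")
                tid, u = got
                model = models[tid]
                seq = sequences[tid].seq
                stop = seq[u.tx_end - 3 : u.tx_end]
                # mutate the middle base of the stop into a sense codon
                new_mid = {"TAA": "C", "TAG": "C", "TGA": "C"}[stop]
                pos, ref, alt = snv_record(model, u.tx_end - 2, new_mid)
                planted_var = (tid, u, pos, ref, alt)
            elif effect == "uSTOP_gained":

                def has_site(tid, u):
                    if u is None or u.category != "non_overlapping":
                        return False
                    return _stop_gain_site(sequences[tid].seq, u, min_len_nt) is not None

                got = take(has_site)
                if got is None:
                    raise SimulationParameterError("no transcript available for uSTOP_gained")
                tid, u = got
                model = models[tid]
                t, base = _stop_gain_site(sequences[tid].seq, u, min_len_nt)
                pos, ref, alt = snv_record(model, t, base)
                planted_var = (tid, u, pos, ref, alt)
            elif effect == "uFrameshift":

                def fs_ok(tid, u):
                    if u is None or models[tid].strand != "+":
                        return False
                    # anchor and its successor must share an exon
                    t = u.tx_start + 4
                    model = models[tid]
                    b1 = tx_to_genome(model, t, t + 1)[0][0]
                    b2 = tx_to_genome(model, t + 1, t + 2)[0][0]
                    return b2 == b1 + 1 and u.tx_end - t > 6

                got = take(fs_ok)
                if got is None:
                    raise SimulationParameterError("no transcript available for uFrameshift")
                tid, u = got
                model = models[tid]
                t = u.tx_start + 4
                gpos = tx_base_to_genome(model, t)
                ref = sequences[tid].seq[t]
                pos, ref, alt = gpos + 1, ref, ref + "C"
                planted_var = (tid, u, pos, ref, alt)
            elif effect == "kozak_changed":
                got = take(
                    lambda tid, u: u is not None
                    and u.start_codon == "ATG"
                    and u.tx_start >= 3,
                    avoid_non_overlapping=True,
                )
                if got is None:
                    raise SimulationParameterError("no transcript available for kozak_changed")
                tid, u = got
                model = models[tid]
                seq = sequences[tid].seq
                minus3 = seq[u.tx_start - 3]
                new = "C" if minus3 in "AG" else "A"
                pos, ref, alt = snv_record(model, u.tx_start - 3, new)
                planted_var = (tid, u, pos, ref, alt)
            elif effect == "uAUG_gained":

                def gain_site(tid, u):
                    return _aug_gain_site(
                        sequences[tid].seq, models[tid], u, min_len_nt
                    )

                got = take(lambda tid, u: gain_site(tid, u) is not None, avoid_non_overlapping=True)
                if got is None:
                    raise SimulationParameterError("no transcript available for uAUG_gained")
                tid, u = got
                model = models[tid]
                t = _aug_gain_site(sequences[tid].seq, model, u, min_len_nt)
                pos, ref, alt = snv_record(model, t, "G")
                planted_var = (tid, u, pos, ref, alt)
            else:
                raise SimulationParameterError(f"unknown effect class {effect!r}")
            tid, u, pos, ref, alt = planted_var
            records.append(
                {
                    "variant_id": f"var{len(records) + 1}",
                    "chrom": models[tid].chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "transcript_id": tid,
                    "uorf_id": None if u is None else f"{tid}:{u.tx_start}-{u.tx_end}:{u.start_codon}",
                    "effect": effect,
                }
            )

    records.sort(key=lambda r: (r["chrom"], r["pos"], r["variant_id"]))
    if out_vcf is not None:
        chrom_len = 1 + max(
            (m.span[1] for m in models.values()), default=1
        )
        with open(out_vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in sorted({m.chrom for m in models.values()}):
                fh.write(f"##contig=<ID={chrom},length={chrom_len}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in records:
                fh.write(
                    f"{r['chrom']}\t{r['pos']}\t{r['variant_id']}\t{r['ref']}\t"
                    f"{r['alt']}\t.\t.\t.\n"
                )
    return records


def _stop_gain_site(seq: str, u: PlantedUORF, min_len_nt: int) -> tuple[int, str] | None:
    """Find (tx_pos, new_base) converting a body codon into TAA, keeping the
    shortened uORF at least min_len_nt of coding sequence."""
    first_codon = max(min_len_nt // 3, 1)
    n_codons = (u.tx_end - u.tx_start) // 3
    for j in range(first_codon + 1, n_codons - 1):
        cpos = u.tx_start + 3 * j
        codon = seq[cpos : cpos + 3]
        if codon.startswith("TA") and codon != "TAA":
            return cpos + 2, "A"
        if codon[0] == "T" and codon[2] == "A" and codon != "TAA" and codon[1] != "A":
            return cpos + 1, "A"
        if codon.endswith("AA") and codon[0] != "T":
            return cpos, "T"
    return None


def _aug_gain_site(
    seq: str,
    model: TranscriptModel,
    planted: PlantedUORF | None,
    min_len_nt: int,
) -> int | None:
    """Find a tx position whose mutation to G creates 'ATG' starting a valid
    new candidate, clear of any planted uORF and its Kozak window."""
    cds_start = model.cds_tx_start
    forbidden: tuple[int, int] | None = None
    if planted is not None:
        forbidden = (planted.tx_start - 4, min(planted.tx_end, model.tx_length) + 1)
    for p in range(3, cds_start - 2):
        if seq[p : p + 2] != "AT" or seq[p + 2] == "G":
            continue
        mut = seq[:p] + "ATG" + seq[p + 3 :]
        end = _first_inframe_stop(mut, p)
        if end is None:
            if (p - cds_start) % 3 == 0:
                end = model.cds_tx_end
            else:
                continue
        if end - 3 - p < min_len_nt:
            continue
        if forbidden is not None and not (end <= forbidden[0] or p >= forbidden[1]):
            continue
        return p + 2
    return None
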