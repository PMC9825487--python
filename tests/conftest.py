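import numpy as np
import pytest

from uorfkit.transcript_model import TranscriptModel, TranscriptSequence


@pytest.fixture
def three_exon_plus():
    """Plus-strand 3-exon toy: exons 10-20, 30-45, 60-75 → tx length 40."""
    return TranscriptModel(
        transcript_id="T1",
        gene_id="G1",
        chrom="chr1",
        strand="+",
        exons=((10, 20), (30, 45), (60, 75)),
        cds_tx_start=12,
        cds_tx_end=36,
    )


@pytest.fixture
def three_exon_minus():
    """Minus-strand 3-exon toy with the same genomic exons."""
    return TranscriptModel(
        transcript_id="T2",
        gene_id="G2",
        chrom="chr1",
        strand="-",
        exons=((60, 75), (30, 45), (10, 20)),
        cds_tx_start=12,
        cds_tx_end=36,
    )


def random_model(rng: np.random.Generator, idx: int = 0) -> TranscriptModel:
    """A random multi-exon model on either strand for projection testing."""
    n_exons = int(rng.integers(1, 5))
    cursor = int(rng.integers(0, 50))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(5, 60))
        exons.append((cursor, cursor + length))
        cursor += length + int(rng.integers(10, 40))
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        exons = exons[::-1]
    tx_len = sum(e - s for s, e in exons)
    cds_start = int(rng.integers(0, tx_len - 1))
    cds_end = int(rng.integers(cds_start + 1, tx_len + 1))
    return TranscriptModel(
        transcript_id=f"R{idx}",
        gene_id=f"RG{idx}",
        chrom="chrR",
        strand=strand,
        exons=tuple(exons),
        cds_tx_start=cds_start,
        cds_tx_end=cds_end,
    )


def single_exon_model(seq_len: int, cds_start: int, cds_end: int, tid: str = "TX") -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=f"g_{tid}",
        chrom="chrT",
        strand="+",
        exons=((0, seq_len),),
        cds_tx_start=cds_start,
        cds_tx_end=cds_end,
    )


def make_transcript(utr5: str, cds: str, utr3: str = "", tid: str = "TX"):
    """Assemble a single-exon transcript (model, sequence) from region strings."""
    seq = utr5 + cds + utr3
    model = single_exon_model(len(seq), len(utr5), len(utr5) + len(cds), tid)
    return model, TranscriptSequence(tid, seq)
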