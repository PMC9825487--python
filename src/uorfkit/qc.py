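"""Library-level Ribo-seq quality control.

Three admission gates decide whether a library is usable for uORF calling:

* size gate — the collapsed FASTA must exceed 5 Mb (or, for in-memory
  profiles, the total read count must reach a configurable floor);
* length gate — at least 90% of RPFs must be 26-34 nt and the modal length
  must fall in 27-32 nt;
* frame gate — over CDS-internal P-sites, frame 0 must be the modal frame
  and hold strictly more than 50% of the signal.

A metagene profile (average normalised P-site density over 5′UTR / CDS /
3′UTR bins) summarises where the footprints sit on transcripts.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ribo_io import AlignedHit, PSiteProfile
from .transcript_model import TranscriptModel

SIZE_GATE_BYTES = 5_000_000  # "larger than 5 Mb" collapsed FASTA rule
SIZE_GATE_MIN_READS = 100_000
LENGTH_RANGE = (26, 34)
PEAK_RANGE = (27, 32)
LENGTH_MIN_FRACTION = 0.9
DEFAULT_METAGENE_BINS = (50, 100, 50)


@dataclass
class QCReport:
    n_reads: int
    length_hist: dict[int, int]
    peak_length: int | None
    frame_counts: tuple[int, int, int]
    frame0_fraction: float
    metagene: list[float]
    gates: dict[str, bool]
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.gates.values())

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "length_hist": {str(k): v for k, v in sorted(self.length_hist.items())},
            "peak_length": self.peak_length,
            "frame_counts": list(self.frame_counts),
            "frame0_fraction": round(self.frame0_fraction, 6),
            "metagene": [round(x, 6) for x in self.metagene],
            "gates": self.gates,
            "reasons": self.reasons,
            "pass": self.passed,
        }

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def length_gate(
    length_hist: Mapping[int, int],
    length_range: tuple[int, int] = LENGTH_RANGE,
    peak_range: tuple[int, int] = PEAK_RANGE,
    min_fraction: float = LENGTH_MIN_FRACTION,
) -> tuple[bool, int | None, str]:
    """Pass iff >=90% of reads are 26-34 nt and the peak length is 27-32 nt.

    Ties at the histogram maximum break toward the smaller length.  Returns
    (passed, peak_length, reason).
    """
    total = sum(length_hist.values())
    if total == 0:
        return False, None, "empty length histogram"
    peak = min(length_hist, key=lambda l: (-length_hist[l], l))
    in_range = sum(c for l, c in length_hist.items() if length_range[0] <= l <= length_range[1])
    frac = in_range / total
    if frac < min_fraction:
        return False, peak, (
            f"only {frac:.1%} of reads within {length_range[0]}-{length_range[1]} nt"
        )
    if not peak_range[0] <= peak <= peak_range[1]:
        return False, peak, f"peak length {peak} outside {peak_range[0]}-{peak_range[1]} nt"
    return True, peak, ""


def frame_gate(frame_counts: Sequence[int]) -> tuple[bool, str]:
    """Pass iff frame 0 is the modal frame and holds strictly >50% of P-sites."""
    f0, f1, f2 = frame_counts
    total = f0 + f1 + f2
    if total == 0:
        return False, "no CDS-mapped P-sites"
    if f0 < max(f1, f2):
        return False, "maximum P-site fraction not in frame 0"
    if f0 / total <= 0.5:
        return False, f"frame-0 fraction {f0 / total:.1%} not larger than 50%"
    return True, ""


def size_gate(
    fasta_path: str | os.PathLike | None = None,
    n_reads: int | None = None,
    min_bytes: int = SIZE_GATE_BYTES,
    min_reads: int = SIZE_GATE_MIN_READS,
) -> tuple[bool, str]:
    """Pass iff the collapsed FASTA exceeds 5 Mb, or (count mode) the total
    read count reaches the floor (100,000 by default)."""
    if fasta_path is not None:
        size = os.path.getsize(fasta_path)
        if size > min_bytes:
            return True, ""
        return False, f"collapsed FASTA is {size} bytes (<= {min_bytes})"
    if n_reads is None:
        return False, "neither file nor read count supplied"
    if n_reads >= min_reads:
        return True, ""
    return False, f"{n_reads} reads (< {min_reads})"


def cds_frame_counts(
    profiles: Mapping[str, PSiteProfile],
    models: Mapping[str, TranscriptModel],
) -> tuple[int, int, int]:
    """P-site counts by reading frame over CDS-internal positions."""
    frames = [0, 0, 0]
    for tid, prof in profiles.items():
        model = models.get(tid)
        if model is None:
            continue
        for (pos, _length), c in prof.counts.items():
            if model.cds_tx_start <= pos < model.cds_tx_end:
                frames[(pos - model.cds_tx_start) % 3] += c
    return tuple(frames)  # type: ignore[return-value]


def length_histogram(hits: Iterable[AlignedHit]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for h in hits:
        hist[h.read_length] = hist.get(h.read_length, 0) + h.count
    return hist


def _rebin(density: np.ndarray, start: int, end: int, nbins: int) -> np.ndarray | None:
    """Linearly rebin density over [start, end) into nbins by fractional overlap."""
    if end - start <= 0 or nbins <= 0:
        return None
    edges = np.linspace(start, end, nbins + 1)
    out = np.empty(nbins)
    for i in range(nbins):
        lo, hi = edges[i], edges[i + 1]
        first, last = int(np.floor(lo)), int(np.ceil(hi))
        acc = 0.0
        for pos in range(first, last):
            overlap = min(hi, pos + 1) - max(lo, pos)
            if overlap > 0:
                acc += density[pos] * overlap
        out[i] = acc / (hi - lo)
    return out


def metagene_profile(
    profiles: Mapping[str, PSiteProfile],
    models: Mapping[str, TranscriptModel],
    bins: tuple[int, int, int] = DEFAULT_METAGENE_BINS,
) -> np.ndarray:
    """Average P-site density over normalised 5′UTR / CDS / 3′UTR bins.

    Each transcript's density is normalised to mean 1 over the transcript,
    linearly rebinned per region, then averaged across transcripts; a
    transcript lacking a region contributes only to the regions it has.
    """
    u5, cds, u3 = bins
    sums = np.zeros(u5 + cds + u3)
    counts = np.zeros(u5 + cds + u3)
    for tid, prof in profiles.items():
        model = models.get(tid)
        if model is None or prof.total == 0:
            continue
        dens = np.zeros(model.tx_length)
        for pos, c in prof.position_counts().items():
            if 0 <= pos < model.tx_length:
                dens[pos] = c
        dens /= dens.mean() if dens.mean() > 0 else 1.0
        regions = [
            (0, model.cds_tx_start, 0, u5),
            (model.cds_tx_start, model.cds_tx_end, u5, cds),
            (model.cds_tx_end, model.tx_length, u5 + cds, u3),
        ]
        for start, end, offset, nbins in regions:
            binned = _rebin(dens, start, end, nbins)
            if binned is not None:
                sums[offset : offset + nbins] += binned
                counts[offset : offset + nbins] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return out


def evaluate_library(
    hits: Sequence[AlignedHit],
    profiles: Mapping[str, PSiteProfile],
    models: Mapping[str, TranscriptModel],
    fasta_path: str | os.PathLike | None = None,
    metagene_bins: tuple[int, int, int] = DEFAULT_METAGENE_BINS,
    size_min_reads: int = SIZE_GATE_MIN_READS,
) -> QCReport:
    """Compute the full QC report (all three gates + metagene) for one library."""
    hist = length_histogram(hits)
    n_reads = sum(hist.values())
    size_ok, size_reason = size_gate(
        fasta_path=fasta_path,
        n_reads=n_reads if fasta_path is None else None,
        min_reads=size_min_reads,
    )
    length_ok, peak, length_reason = length_gate(hist)
    frames = cds_frame_counts(profiles, models)
    frame_ok, frame_reason = frame_gate(frames)
    total_frames = sum(frames)
    meta = metagene_profile(profiles, models, metagene_bins)
    reasons = {
        k: v
        for k, v in [
            ("size_gate", size_reason),
            ("length_gate", length_reason),
            ("frame_gate", frame_reason),
        ]
        if v
    }
    return QCReport(
        n_reads=n_reads,
        length_hist=hist,
        peak_length=peak,
        frame_counts=frames,
        frame0_fraction=frames[0] / total_frames if total_frames else 0.0,
        metagene=[float(x) for x in meta],
        gates={"size_gate": size_ok, "length_gate": length_ok, "frame_gate": frame_ok},
        reasons=reasons,
    )
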