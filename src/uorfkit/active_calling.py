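"""Active-translation calling for candidate uORFs.

A uORF is called actively translated from its P-site profile using two
signatures of elongating ribosomes:

* 3-nt periodicity — the fraction of P-sites in the uORF's own reading
  frame (``f0u``), tested against the uniform null p=1/3 with an upper-tail
  exact binomial test;
* uniformity — the percentage of maximum entropy (PME) of the per-codon
  count distribution, 1 for perfectly even coverage and 0 for a point mass.

The uORF score is ``f0u × PME`` in [0, 1]; a call is active when the
P-site count reaches a floor, the periodicity test is significant, and the
score reaches the threshold (0.5 by default).  This transparent statistic
is this toolkit's own scoring rule for periodicity-and-uniformity based
ORF calling; no equivalence with externally trained classifiers is implied.

For uORFs overlapping the CDS (out-of-frame overlaps and N-terminal
extensions) only P-sites upstream of the CDS start are scored, so that main
ORF signal cannot inflate the uORF's score.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .ribo_io import PSiteProfile
from .transcript_model import TranscriptModel
from .uorf_discovery import CandidateUORF

DEFAULT_SCORE_THRESHOLD = 0.5
DEFAULT_PERIODICITY_ALPHA = 0.05
DEFAULT_MIN_READS = 10


@dataclass
class UORFCall:
    uorf_id: str
    transcript_id: str
    tx_start: int
    tx_end: int
    start_codon: str
    category: str
    n_psites: int
    f0u: float
    periodicity_p: float
    pme: float
    score: float
    active: bool
    cds_masked: bool
    representative: bool = False
    sample_id: str = ""


def _scored_region(uorf: CandidateUORF, model: TranscriptModel) -> tuple[int, int]:
    """Codon-aligned region over which P-sites are scored.

    Non-overlapping uORFs are scored over their full span (stop codon
    included); overlap categories are truncated to whole codons upstream of
    the CDS start.
    """
    if uorf.category == "non_overlapping":
        return uorf.tx_start, uorf.tx_end
    end = min(uorf.tx_end, model.cds_tx_start)
    n_codons = (end - uorf.tx_start) // 3
    return uorf.tx_start, uorf.tx_start + 3 * n_codons


def score_uorf(
    uorf: CandidateUORF,
    profile: PSiteProfile | None,
    model: TranscriptModel,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_PERIODICITY_ALPHA,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    sample_id: str = "",
) -> UORFCall:
    """Score one candidate uORF against a P-site profile.

    With zero P-sites in the scored region the call is returned inactive
    with score 0.  The score is invariant to scaling all counts by a
    positive integer; the binomial p-value is not (more reads give more
    power), which is the intended behaviour of a significance gate.
    """
    start, end = _scored_region(uorf, model)
    masked = uorf.category != "non_overlapping"
    pos_counts: dict[int, int] = {}
    if profile is not None:
        for pos, c in profile.position_counts().items():
            if start <= pos < end:
                pos_counts[pos] = c
    n = sum(pos_counts.values())
    n_codons = (end - start) // 3
    if n == 0 or n_codons == 0:
        return UORFCall(
            uorf_id=uorf.uorf_id,
            transcript_id=uorf.transcript_id,
            tx_start=uorf.tx_start,
            tx_end=uorf.tx_end,
            start_codon=uorf.start_codon,
            category=uorf.category,
            n_psites=n,
            f0u=0.0,
            periodicity_p=1.0,
            pme=0.0,
            score=0.0,
            active=False,
            cds_masked=masked,
            sample_id=sample_id,
        )
    in_frame = sum(c for pos, c in pos_counts.items() if (pos - uorf.tx_start) % 3 == 0)
    f0u = in_frame / n
    periodicity_p = binomtest(in_frame, n, 1 / 3, alternative="greater").pvalue
    codon_counts = np.zeros(n_codons)
    for pos, c in pos_counts.items():
        codon_counts[(pos - start) // 3] += c
    if n_codons == 1:
        pme = 1.0
    else:
        p = codon_counts / n
        nz = p[p > 0]
        entropy = -(nz * np.log(nz)).sum()
        pme = float(entropy / np.log(n_codons))
    score = f0u * pme
    active = n >= min_reads and periodicity_p < alpha and score >= threshold
    return UORFCall(
        uorf_id=uorf.uorf_id,
        transcript_id=uorf.transcript_id,
        tx_start=uorf.tx_start,
        tx_end=uorf.tx_end,
        start_codon=uorf.start_codon,
        category=uorf.category,
        n_psites=n,
        f0u=f0u,
        periodicity_p=float(periodicity_p),
        pme=pme,
        score=score,
        active=active,
        cds_masked=masked,
        sample_id=sample_id,
    )


def select_representative(
    calls: Sequence[UORFCall],
    profile: PSiteProfile | None,
) -> UORFCall | None:
    """Pick the representative uORF among calls sharing one stop codon.

    Candidates are ordered ATG starts first (ascending start position),
    then near-cognate starts (ascending).  Starting from the first, the
    selection advances to the next candidate whenever no P-site falls
    between the current and the next start; the first candidate that fails
    to advance is the representative.  Exactly one call is flagged for a
    non-empty group.
    """
    if not calls:
        return None
    ordered = sorted(
        calls, key=lambda c: (0 if c.start_codon == "ATG" else 1, c.tx_start)
    )
    pos_counts = profile.position_counts() if profile is not None else {}
    current = 0
    while current + 1 < len(ordered):
        lo = min(ordered[current].tx_start, ordered[current + 1].tx_start)
        hi = max(ordered[current].tx_start, ordered[current + 1].tx_start)
        between = sum(c for pos, c in pos_counts.items() if lo <= pos < hi)
        if between == 0:
            current += 1
        else:
            break
    for c in ordered:
        c.representative = False
    ordered[current].representative = True
    return ordered[current]


def call_sample(
    candidates: Sequence[CandidateUORF],
    profiles: Mapping[str, PSiteProfile],
    models: Mapping[str, TranscriptModel],
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_PERIODICITY_ALPHA,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    sample_id: str = "",
) -> list[UORFCall]:
    """Score all candidates of one sample and flag representatives.

    Representatives are selected among *active* calls within each
    (transcript, shared stop) group.
    """
    calls: list[UORFCall] = []
    for uorf in candidates:
        model = models[uorf.transcript_id]
        profile = profiles.get(uorf.transcript_id)
        calls.append(
            score_uorf(
                uorf,
                profile,
                model,
                min_reads=min_reads,
                alpha=alpha,
                threshold=threshold,
                sample_id=sample_id,
            )
        )
    groups: dict[tuple[str, int], list[UORFCall]] = defaultdict(list)
    for call in calls:
        if call.active:
            groups[(call.transcript_id, call.tx_end)].append(call)
    for (tid, _stop), group in groups.items():
        select_representative(group, profiles.get(tid))
    calls.sort(key=lambda c: (c.transcript_id, c.tx_start, c.tx_end))
    return calls


def aggregate_samples(calls_by_sample: Mapping[str, Sequence[UORFCall]]) -> pd.DataFrame:
    """Summarise calls across samples: one row per uORF with support counts."""
    rows: dict[str, dict] = {}
    for sample_id in sorted(calls_by_sample):
        for call in calls_by_sample[sample_id]:
            row = rows.setdefault(
                call.uorf_id,
                {
                    "uorf_id": call.uorf_id,
                    "transcript_id": call.transcript_id,
                    "tx_start": call.tx_start,
                    "tx_end": call.tx_end,
                    "start_codon": call.start_codon,
                    "category": call.category,
                    "n_samples_detected": 0,
                    "n_samples_active": 0,
                    "samples_active": [],
                    "max_score": 0.0,
                },
            )
            row["n_samples_detected"] += 1
            row["max_score"] = max(row["max_score"], call.score)
            if call.active:
                row["n_samples_active"] += 1
                row["samples_active"].append(sample_id)
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["transcript_id"], r["tx_start"])))
    if not df.empty:
        df["samples_active"] = df["samples_active"].map(",".join)
    return df


CALL_TSV_COLUMNS = [
    "uorf_id",
    "transcript_id",
    "tx_start",
    "tx_end",
    "start_codon",
    "uorf_type",
    "n_psites",
    "f0u",
    "periodicity_p",
    "pme",
    "score",
    "active",
    "representative",
    "cds_masked",
    "sample_id",
]


def write_calls_tsv(calls: Iterable[UORFCall], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_TSV_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.uorf_id,
                        c.transcript_id,
                        str(c.tx_start),
                        str(c.tx_end),
                        c.start_codon,
                        c.category,
                        str(c.n_psites),
                        f"{c.f0u:.6f}",
                        f"{c.periodicity_p:.6g}",
                        f"{c.pme:.6f}",
                        f"{c.score:.6f}",
                        str(int(c.active)),
                        str(int(c.representative)),
                        str(int(c.cds_masked)),
                        c.sample_id,
                    ]
                )
                + "\n"
            )
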